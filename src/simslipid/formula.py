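"""Elemental mass bookkeeping for lipid ion calculus.

Monoisotopic masses are the CODATA/NIST values to the precision that matters
at the 100 ppm assignment tolerance used throughout (a ToF-SIMS peak binned
to 0.05 Da carries ~60 ppm uncertainty at m/z 800, so sub-ppm element masses
are ample). Isotope labels (13C, 15N) are carried as a count of substituted
atoms and applied as exact mass shifts, never by rewriting the formula.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass

#: Monoisotopic masses in Da of the elements occurring in membrane lipids
#: and their common salt adducts.
MONOISOTOPIC: dict[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737615,
    "S": 31.9720707,
    "Na": 22.9897693,
    "K": 38.9637065,
}

PROTON = 1.00727646
ELECTRON = 0.00054858
#: 13C - 12C mass difference (one substituted carbon).
DELTA_C13 = 1.0033548
#: 15N - 14N mass difference.
DELTA_N15 = 0.9970349
#: Neutral water, lost by [M+H-H2O]+ ions.
WATER = 2 * MONOISOTOPIC["H"] + MONOISOTOPIC["O"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Label:
    """An isotope label: ``kind`` is ``"c13"`` or ``"n15"``, ``count`` the
    number of substituted atoms."""

    kind: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("c13", "n15"):
            raise ValueError(f"unknown label kind {self.kind!r}")
        if self.count < 1:
            raise ValueError("label count must be >= 1")

    @property
    def mass_shift(self) -> float:
        return self.count * (DELTA_C13 if self.kind == "c13" else DELTA_N15)

    @property
    def element(self) -> str:
        return "C" if self.kind == "c13" else "N"

    def __str__(self) -> str:
        base = "13C" if self.kind == "c13" else "15N"
        return base if self.count == 1 else f"{base}{self.count}"


class Formula(Mapping):
    """An immutable molecular formula: element symbol -> count.

    Supports ``+``/``-`` (element-wise, result counts must stay >= 0) and
    ``*`` by a non-negative integer, so composite rules read as chemistry:
    ``CER + HEXOSE`` or ``acyl * 2``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in merged.items():
            if el not in MONOISOTOPIC:
                raise KeyError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        self._counts = {el: n for el, n in sorted(merged.items()) if n > 0}

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse e.g. ``"C46H88NO8P"`` (Hill-ish order not required)."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text.strip()):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {pos}")
            pos = m.end()
            el = m.group(1)
            if el not in MONOISOTOPIC:
                raise KeyError(f"unknown element {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(text.strip()):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    # Mapping protocol ----------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el) -> bool:  # Mapping default uses __getitem__
        return el in self._counts

    # Arithmetic ----------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        if k < 0:
            raise ValueError("multiplier must be >= 0")
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"Formula({self})"

    def __str__(self) -> str:
        order = ["C", "H"] + sorted(el for el in self._counts if el not in ("C", "H"))
        return "".join(
            f"{el}{self._counts[el] if self._counts[el] != 1 else ''}"
            for el in order
            if el in self._counts
        ) or "(empty)"


def monoisotopic_mass(formula: Mapping[str, int], label: Label | None = None) -> float:
    """Neutral monoisotopic mass in Da of ``formula``, plus the exact isotope
    shift of ``label`` if given.

    Additive by construction: mass(A + B) == mass(A) + mass(B). The label's
    substituted-atom count must not exceed the corresponding element count.
    """
    total = 0.0
    for el, n in formula.items():
        try:
            total += n * MONOISOTOPIC[el]
        except KeyError:
            raise KeyError(f"unknown element {el!r}") from None
    if label is not None:
        if label.count > formula.get(label.element, 0):
            raise ValueError(
                f"label {label} exceeds {label.element} count in formula"
            )
        total += label.mass_shift
    return total
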