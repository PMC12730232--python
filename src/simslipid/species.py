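"""Lipid shorthand parsing and class composition rules.

Shorthand follows the field's ``CLASS n:d`` convention — total acyl/chain
carbons ``n``, double-bond equivalents ``d`` — with ``;O``/``;O2``/... suffixes
for the shorthand oxygen count, an ``O-`` prefix per ether linkage, and an
optional isotope-label prefix (``13C-``, ``13C2-``, ``15N-``). Bracketed forms
such as ``[PS 36:1-87-H]-`` additionally carry the ion form (adduct, water
loss, named neutral losses) and are parsed into an :class:`IonSpec` alongside
the species.

Composition rules map a species to its molecular formula: each diacyl
glycerophospholipid class is glycerol + headgroup + two acyl chains minus the
esterification waters, collapsed here into closed-form per-class rules; lyso
classes are the diacyl rule minus one acyl unit; the ceramide family is built
from the Cer ``n:d;O2`` baseline plus hexose / sulfohexose / phosphoethanolamine
/ phosphocholine head extensions. Sterols and cholesteryl esters have no
closed-form rule (their ring systems break the acyl arithmetic) and must be
supplied as explicit formulas.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .formula import Formula, Label, monoisotopic_mass

# -- class composition rules -------------------------------------------------

# Closed-form rules: class -> (formula of the n:d member). Verified against
# an independent backbone-plus-chains constructor in the test suite.
_GLYCERO_RULES: dict[str, tuple[int, int, dict[str, int]]] = {
    # class: (carbon offset, hydrogen offset, other elements); formula is
    # C(n+dc) H(2n-2d+dh) + others
    "FA": (0, 0, {"O": 2}),
    "MG": (3, 6, {"O": 4}),
    "DG": (3, 4, {"O": 5}),
    "TG": (3, 2, {"O": 6}),
    "PA": (3, 5, {"O": 8, "P": 1}),
    "PC": (8, 16, {"N": 1, "O": 8, "P": 1}),
    "PE": (5, 10, {"N": 1, "O": 8, "P": 1}),
    "PS": (6, 10, {"N": 1, "O": 10, "P": 1}),
    "PG": (6, 11, {"O": 10, "P": 1}),
    "PI": (9, 15, {"O": 13, "P": 1}),
    "LPA": (3, 7, {"O": 7, "P": 1}),
    "LPC": (8, 18, {"N": 1, "O": 7, "P": 1}),
    "LPE": (5, 12, {"N": 1, "O": 7, "P": 1}),
    "LPS": (6, 12, {"N": 1, "O": 9, "P": 1}),
    "LPG": (6, 13, {"O": 9, "P": 1}),
    "LPI": (9, 17, {"O": 12, "P": 1}),
}

_HEXOSE = Formula(C=6, H=10, O=5)
_SULFATE = Formula(S=1, O=3)
_PHOSPHOETHANOLAMINE = Formula(C=2, H=6, N=1, O=3, P=1)
_PHOSPHOCHOLINE = Formula(C=5, H=12, N=1, O=3, P=1)

#: Ceramide-family classes share the Cer n:d;O2 baseline rule.
CERAMIDE_FAMILY = ("Cer", "HexCer", "SHexCer", "CerPE", "SM")

#: Classes with no composition rule; explicit formulas required.
UNSUPPORTED_CLASSES = ("ST", "CE")

CLASS_CODES = tuple(_GLYCERO_RULES) + CERAMIDE_FAMILY + UNSUPPORTED_CLASSES

#: Shorthand oxygen-suffix baseline per class (``;O2`` for ceramides).
_OXYGEN_BASELINE = {c: 2 for c in CERAMIDE_FAMILY}


class ParseError(ValueError):
    """Raised when a lipid shorthand string does not match the grammar."""


class NoCompositionRule(ValueError):
    """Raised for classes (ST, CE) that require an explicit formula."""


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at shorthand (sum-composition) resolution.

    ``extra_oxygens`` is the signed oxygen count relative to the class
    baseline (Cer-family baseline ;O2, all others 0), so ``Cer 34:1;O4`` has
    ``extra_oxygens=2`` and ``Cer 38:0;O`` has ``-1``.
    """

    class_code: str
    n_carbons: int
    n_double_bonds: int
    extra_oxygens: int = 0
    ether_links: int = 0
    label: Label | None = None
    explicit_formula: Formula | None = field(default=None, compare=True)

    def __post_init__(self) -> None:
        if self.class_code not in CLASS_CODES and self.explicit_formula is None:
            raise ParseError(f"unknown lipid class {self.class_code!r}")
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be >= 1")
        if self.n_double_bonds < 0:
            raise ValueError("n_double_bonds must be >= 0")
        if self.ether_links not in (0, 1, 2):
            raise ValueError("ether_links must be 0, 1 or 2")

    @property
    def name(self) -> str:
        label = f"{self.label}-" if self.label else ""
        ether = "O-" * self.ether_links
        k = self.extra_oxygens + _OXYGEN_BASELINE.get(self.class_code, 0)
        if self.class_code in _OXYGEN_BASELINE or self.extra_oxygens:
            suffix = {0: "", 1: ";O"}.get(k, f";O{k}")
        else:
            suffix = ""
        return f"{label}{self.class_code} {ether}{self.n_carbons}:{self.n_double_bonds}{suffix}"

    def __str__(self) -> str:
        return self.name


def formula_of(species: LipidSpecies) -> Formula:
    """Molecular formula of ``species`` from its class composition rule.

    Explicit formulas short-circuit the rules; ST/CE without one raise
    :class:`NoCompositionRule`.
    """
    if species.explicit_formula is not None:
        return species.explicit_formula
    n, d = species.n_carbons, species.n_double_bonds
    code = species.class_code
    if code in _GLYCERO_RULES:
        dc, dh, other = _GLYCERO_RULES[code]
        h = 2 * n - 2 * d + dh
        if h < 0:
            raise ValueError(f"negative hydrogen count for {species.name}")
        base = Formula({"C": n + dc, "H": h}) + Formula(other)
    elif code in CERAMIDE_FAMILY:
        h = 2 * n - 2 * d + 1
        if h < 0:
            raise ValueError(f"negative hydrogen count for {species.name}")
        base = Formula({"C": n, "H": h, "N": 1, "O": 3})  # Cer n:d;O2 baseline
        if code == "HexCer":
            base = base + _HEXOSE
        elif code == "SHexCer":
            base = base + _HEXOSE + _SULFATE
        elif code == "CerPE":
            base = base + _PHOSPHOETHANOLAMINE
        elif code == "SM":
            base = base + _PHOSPHOCHOLINE
    else:
        raise NoCompositionRule(
            f"no composition rule for class {code!r}; supply an explicit formula"
        )
    # ;O suffix relative to baseline, then -O +2H per ether linkage.
    base = base + Formula(O=species.extra_oxygens) if species.extra_oxygens >= 0 else base - Formula(
        O=-species.extra_oxygens
    )
    for _ in range(species.ether_links):
        base = base - Formula(O=1) + Formula(H=2)
    return base


def species_mass(species: LipidSpecies) -> float:
    """Neutral monoisotopic mass including any isotope label."""
    return monoisotopic_mass(formula_of(species), species.label)


# -- shorthand grammar -------------------------------------------------------

_LABEL_RE = re.compile(
    r"^(?:(?P<c13>13C|¹³C)(?:_?(?P<kc>\d)_?)?|"
    r"(?P<n15>15N|¹⁵N)(?:_?(?P<kn>\d)_?)?)-"
)
_SPECIES_RE = re.compile(
    r"^(?P<cls>[A-Za-z]+)\s+(?P<eth>(?:O-)*)(?P<n>\d+):(?P<d>\d+)"
    r"(?:[;,]O_?(?P<k>\d+)?_?)?$"
)
# ion-form tokens after the species name inside brackets; hyphen variants
# (ASCII -, en-dash, minus) all accepted.
_ION_TOKEN_RE = re.compile(r"([+\-–−])(H2O|H_2_O|TMA|Na|K|H|\d+)")

_DASHES = {"–": "-", "−": "-"}


def _normalize(text: str) -> str:
    for bad, good in _DASHES.items():
        text = text.replace(bad, good)
    return text.strip()


def _parse_label(text: str):
    m = _LABEL_RE.match(text)
    if not m:
        return None, text
    if m.group("c13"):
        label = Label("c13", int(m.group("kc") or 1))
    else:
        label = Label("n15", int(m.group("kn") or 1))
    return label, text[m.end():]


def parse_shorthand(text: str):
    """Parse a lipid name, returning ``(LipidSpecies, IonSpec | None)``.

    Bare names (``"PC 38:2"``, ``"13C-Cer 34:1;O2"``) yield ``(species,
    None)``; bracketed ion forms (``"[PS 36:1-87-H]-"``) also yield the
    parsed :class:`~simslipid.ions.IonSpec`.
    """
    from .ions import IonSpec, NEUTRAL_LOSSES  # cycle-free at call time

    raw = _normalize(text)
    if raw.startswith("["):
        close = raw.rfind("]")
        if close < 0:
            raise ParseError(f"unbalanced bracket in {text!r}")
        inner, sign = raw[1:close], raw[close + 1 :].strip()
        if sign not in ("+", "-"):
            raise ParseError(f"missing/unknown charge sign in {text!r}")
        polarity = 1 if sign == "+" else -1

        label, rest = _parse_label(inner)
        # species part = up to the first ion token after the n:d core
        m = re.match(
            r"^(?P<name>[A-Za-z]+\s+(?:O-)*\d+:\d+(?:[;,]O_?\d*_?)?)(?P<terms>.*)$",
            rest,
        )
        if not m:
            raise ParseError(f"cannot parse bracketed name {text!r}")
        species = _parse_bare(m.group("name"), label)

        adduct: str | None = None
        water_loss = False
        losses: list[str] = []
        terms = m.group("terms")
        pos = 0
        for tok in _ION_TOKEN_RE.finditer(terms):
            if tok.start() != pos:
                raise ParseError(f"cannot parse ion terms {terms!r} in {text!r}")
            pos = tok.end()
            sgn, what = tok.group(1), tok.group(2).replace("_", "")
            sgn = _DASHES.get(sgn, sgn)
            if sgn == "+":
                if what not in ("H", "Na", "K"):
                    raise ParseError(f"unknown adduct +{what} in {text!r}")
                if adduct is not None:
                    raise ParseError(f"multiple adducts in {text!r}")
                adduct = f"+{what}"
            elif what == "H2O":
                water_loss = True
            elif what == "H":
                if adduct is not None:
                    raise ParseError(f"multiple adducts in {text!r}")
                adduct = "-H"
            elif what in NEUTRAL_LOSSES:
                losses.append(what)
            else:
                raise ParseError(f"unknown neutral loss -{what} in {text!r}")
        if pos != len(terms.strip()) and terms.strip():
            raise ParseError(f"cannot parse ion terms {terms!r} in {text!r}")
        if adduct is None:
            raise ParseError(f"no adduct found in {text!r}")
        ion = IonSpec(
            adduct=adduct,
            water_loss=water_loss,
            neutral_losses=tuple(losses),
            polarity=polarity,
        )
        return species, ion

    label, rest = _parse_label(raw)
    return _parse_bare(rest, label), None


def _parse_bare(text: str, label: Label | None) -> LipidSpecies:
    clean = _normalize(text).replace("_", "")
    m = _SPECIES_RE.match(clean)
    if not m:
        raise ParseError(f"cannot parse lipid shorthand {text!r}")
    code = m.group("cls")
    if code not in CLASS_CODES:
        raise ParseError(f"unknown lipid class {code!r} in {text!r}")
    has_suffix = ";O" in clean or ",O" in clean
    if has_suffix:
        k = int(m.group("k")) if m.group("k") else 1
        extra = k - _OXYGEN_BASELINE.get(code, 0)
    else:
        extra = 0  # class baseline (Cer family implies ;O2)
    return LipidSpecies(
        class_code=code,
        n_carbons=int(m.group("n")),
        n_double_bonds=int(m.group("d")),
        extra_oxygens=extra,
        ether_links=m.group("eth").count("O-"),
        label=label,
    )
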