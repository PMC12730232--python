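"""Ion m/z calculus and peak annotation.

Singly charged ion forms only, matching what a (CO2)6000+ GCIB ToF-SIMS
produces from membrane lipids: [M+H]+, [M+H-H2O]+, [M+Na]+, [M+K]+ in
positive polarity, [M-H]- in negative, with optional named neutral losses
(the serine 87 Da fragment from PS, trimethylamine from PC). The electron
mass is carried explicitly — subtracted for cations, added for anions — so
the calculus stays exact even though at a 100 ppm tolerance it never changes
an assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formula import (
    ELECTRON,
    MONOISOTOPIC,
    PROTON,
    WATER,
    Formula,
    Label,
    monoisotopic_mass,
)
from .species import LipidSpecies, formula_of

#: Named neutral losses: token -> neutral formula. "87" is the serine
#: C3H5NO2 fragment lost from PS; "TMA" trimethylamine from PC headgroups.
NEUTRAL_LOSSES: dict[str, Formula] = {
    "87": Formula(C=3, H=5, N=1, O=2),
    "TMA": Formula(C=3, H=9, N=1),
}

#: adduct token -> (mass added to M, polarity)
_ADDUCTS: dict[str, tuple[float, int]] = {
    "+H": (PROTON + ELECTRON, 1),   # neutral H; electron handled separately
    "+Na": (MONOISOTOPIC["Na"], 1),
    "+K": (MONOISOTOPIC["K"], 1),
    "-H": (-(PROTON + ELECTRON), -1),
}


@dataclass(frozen=True)
class IonSpec:
    """One singly charged ion form.

    ``adduct`` is ``"+H"``, ``"+Na"``, ``"+K"``, ``"-H"``, or ``None`` for an
    intrinsically charged explicit-formula ion (e.g. the phosphocholine
    headgroup cation C5H15NO4P+), in which case ``polarity`` decides the
    electron bookkeeping alone.
    """

    adduct: str | None
    water_loss: bool = False
    neutral_losses: tuple[str, ...] = ()
    polarity: int = 0

    def __post_init__(self) -> None:
        if self.adduct is not None:
            if self.adduct not in _ADDUCTS:
                raise ValueError(f"unknown adduct {self.adduct!r}")
            pol = _ADDUCTS[self.adduct][1]
            if self.polarity == 0:
                object.__setattr__(self, "polarity", pol)
            elif self.polarity != pol:
                raise ValueError(
                    f"polarity {self.polarity} inconsistent with adduct {self.adduct}"
                )
        elif self.polarity not in (-1, 1):
            raise ValueError("explicit-formula ions need polarity +1 or -1")
        for loss in self.neutral_losses:
            if loss not in NEUTRAL_LOSSES:
                raise ValueError(f"unknown neutral loss {loss!r}")

    @property
    def suffix(self) -> str:
        """The bracket suffix, e.g. ``"+K"``, ``"-87-H"`` or ``"+H-H2O"``."""
        parts: list[str] = []
        if self.adduct == "+H":
            parts.append("+H-H2O" if self.water_loss else "+H")
            parts += [f"-{loss}" for loss in self.neutral_losses]
        else:
            parts += [f"-{loss}" for loss in self.neutral_losses]
            if self.water_loss:
                parts.append("-H2O")
            if self.adduct is not None:
                parts.append(self.adduct)
        return "".join(parts)

    def label_for(self, species_name: str) -> str:
        sign = "+" if self.polarity > 0 else "-"
        return f"[{species_name}{self.suffix}]{sign}"


def ion_mz(
    formula: Formula,
    ion_spec: IonSpec,
    label: Label | None = None,
) -> float:
    """m/z (Da per unit charge) of the ion built from a neutral ``formula``.

    mz = M + adduct mass -/+ electron - water (if lost) - neutral losses,
    with the isotope-label shift of ``label`` included in M.
    """
    mz = monoisotopic_mass(formula, label)
    if ion_spec.adduct is not None:
        mz += _ADDUCTS[ion_spec.adduct][0]
    mz -= ion_spec.polarity * ELECTRON
    if ion_spec.water_loss:
        mz -= WATER
    for loss in ion_spec.neutral_losses:
        mz -= monoisotopic_mass(NEUTRAL_LOSSES[loss])
    if mz <= 0:
        raise ValueError("non-positive ion m/z")
    return mz


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class TheoreticalIon:
    """A library entry: species in a specific ion form with computed m/z."""

    species: LipidSpecies
    ion_spec: IonSpec
    formula: Formula
    mz: float

    @classmethod
    def create(cls, species: LipidSpecies, ion_spec: IonSpec) -> "TheoreticalIon":
        formula = formula_of(species)
        return cls(
            species=species,
            ion_spec=ion_spec,
            formula=formula,
            mz=ion_mz(formula, ion_spec, species.label),
        )

    @property
    def name(self) -> str:
        return self.ion_spec.label_for(self.species.name)

    @property
    def polarity(self) -> int:
        return self.ion_spec.polarity


@dataclass(frozen=True)
class Candidate:
    ion: TheoreticalIon
    ppm: float


@dataclass(frozen=True)
class Assignment:
    """All library candidates for one observed peak within tolerance,
    sorted by |ppm| (ties broken by class code, then n:d, for determinism)."""

    observed_mz: float
    candidates: tuple[Candidate, ...] = ()

    @property
    def assigned(self) -> bool:
        return bool(self.candidates)

    @property
    def best(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


def _candidate_sort_key(c: Candidate):
    sp = c.ion.species
    return (abs(c.ppm), sp.class_code, sp.n_carbons, sp.n_double_bonds)


def annotate(
    peaks,
    library,
    tol_ppm: float = 100.0,
    polarity: int | None = None,
) -> list[Assignment]:
    """Assign each observed m/z to polarity-consistent library ions.

    Every candidate within ``tol_ppm`` is retained, sorted by |ppm|; peaks
    with no candidate yield an empty (flagged-unassigned) Assignment. The
    result is independent of peak order and library order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    library = list(library)
    if not library:
        raise ValueError("library is empty")
    out = []
    for mz in peaks:
        cands = [
            Candidate(ion, ppm_error(mz, ion.mz))
            for ion in library
            if (polarity is None or ion.polarity == polarity)
            and abs(ppm_error(mz, ion.mz)) <= tol_ppm
        ]
        cands.sort(key=_candidate_sort_key)
        out.append(Assignment(observed_mz=float(mz), candidates=tuple(cands)))
    return out
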