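"""Seeded generator of ground-truthed ToF-SIMS datacube experiments.

The generative model mirrors a single-cell membrane-lipid acquisition on ITO
glass: elliptical cell footprints on a 128x128 pixel grid (the instrument's
default raster over a 600 um field), a cell-pixel lipid spectrum built from a
configurable lipidome with delta-into-bin peaks at the theoretical ion m/z,
indium substrate peaks on background pixels, a uniform low chemical
background, and independent Poisson ion counting per (pixel, bin).

Stable-isotope incubation arms move a fixed incorporation fraction ``f`` of
each target species' intensity from its bin to the isotope-shifted bin
(+1.0034 per 13C, +0.9970 for 15N) — a pseudo-steady-state picture of a
multi-day incubation, which is exactly what an intensity-based turnover
analysis can observe. Every draw is seeded; ground truth (cell masks,
planted means, truly shifted bins) is returned alongside each cube.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datacube import MassAxis, SpectralImage
from .formula import DELTA_C13, DELTA_N15
from .ions import TheoreticalIon
from .roi import (
    SUBSTRATE_MZ_NEGATIVE,
    SUBSTRATE_MZ_POSITIVE,
    RoiMask,
    RoiSpectrum,
)
from .species import parse_shorthand
from scipy import sparse

# ---------------------------------------------------------------------------
# Default lipidome: 45 "top" ions per polarity with the class mix of a
# midbrain-neuron plasma membrane profile (30 PC / 10 PS / 10 Cer / 8 SHexCer
# / 8 PE among the 90, the remainder spread over FA, PI, LPI, DG, MG, HexCer,
# PA, LPA, LPE), plus 16 minor ions per polarity so peak picking has more
# than the top-45 to find. Relative intensities decay geometrically with
# rank; the three most intense ions per polarity follow the field's typical
# ordering (PC molecular/salt adducts in positive; the PS 36:1 serine-loss
# fragment and palmitate in negative).

_POSITIVE_TOP = [
    # (printed-style ion name, or None for the explicit headgroup entry)
    "[PC 38:2+H]+",
    "HEADGROUP",          # phosphocholine fragment C5H15NO4P+, m/z 184.07
    "[PC 36:2+Na]+",
    "[PC 38:4+Na]+",
    "[PC 34:1+H]+",
    "[PC 32:0+H]+",
    "[PC 36:1+H]+",
    "[PC 34:1+K]+",
    "[PC 36:4+H]+",
    "[PC 38:6+H]+",
    "[PC 32:1+H]+",
    "[PC 40:6+H]+",
    "[PC 30:0+H]+",
    "[PC 34:0+H]+",
    "[PC 36:2+H]+",
    "[PC 33:1+H]+",
    "[PC 35:1+H]+",
    "[PC 32:0+K]+",
    "[PC 38:2+K]+",
    "[PC 40:4+H]+",
    "[PC 31:0+K]+",
    "[PC 37:4+H]+",
    "[PC 39:6+H]+",
    "[PC 41:6+H]+",
    "[PC 42:6+H]+",
    "[PC 30:1+K]+",
    "[PC 33:2+Na]+",
    "[PC 35:2+K]+",
    "[PC 42:8+H]+",
    "[PC 40:2+Na]+",
    "[Cer 34:1;O2+H]+",
    "[Cer 36:1;O2+H]+",
    "[Cer 38:1;O2+H]+",
    "[Cer 40:1;O2+H]+",
    "[Cer 42:2;O2+H]+",
    "[Cer 42:1;O2+H]+",
    "[Cer 34:1;O2+K]+",
    "[Cer 38:2;O2+H]+",
    "[Cer 40:2;O2+Na]+",
    "[Cer 36:2;O2+K]+",
    "[PE 34:1+H]+",
    "[PE 36:4+K]+",
    "[HexCer 34:1;O2+H]+",
    "[HexCer 40:1;O2+K]+",
    "[DG 34:3+H-H2O]+",
]

_POSITIVE_MINOR = [
    "[MG 20:5+K]+",
    "[MG 18:1+H-H2O]+",
    "[DG 36:2+H-H2O]+",
    "[DG 32:0+Na]+",
    "[PC 28:0+H]+",
    "[PC 44:10+H]+",
    "[Cer 33:1;O2+H]+",
    "[Cer 41:2;O2+H]+",
    "[HexCer 36:1;O2+Na]+",
    "[HexCer 42:2;O2+H]+",
    "[PE 38:4+H]+",
    "[PE 32:1+K]+",
    "[PG 22:4+H]+",
    "[PG 34:1+Na]+",
    "[SM 34:1;O2+H]+",
    "[SM 36:1;O2+K]+",
]

_NEGATIVE_TOP = [
    "[PS 36:1-87-H]-",
    "[FA 16:0-H]-",
    "[FA 18:0-H]-",
    "[FA 18:1-H]-",
    "[PS 36:1-H]-",
    "[PS 34:1-H]-",
    "[PS 38:4-H]-",
    "[PS 40:6-H]-",
    "[PS 36:2-H]-",
    "[PS 38:1-H]-",
    "[PS 40:4-H]-",
    "[PS 42:1-H]-",
    "[PS 44:12-H]-",
    "[SHexCer 34:1;O2-H]-",
    "[SHexCer 36:1;O2-H]-",
    "[SHexCer 38:2;O2-H]-",
    "[SHexCer 40:1;O2-H]-",
    "[SHexCer 42:2;O2-H]-",
    "[SHexCer 42:1;O2-H]-",
    "[SHexCer 41:1;O2-H]-",
    "[SHexCer 43:2;O2-H]-",
    "[PE 34:1-H]-",
    "[PE 36:2-H]-",
    "[PE 38:4-H]-",
    "[PE 40:4-H]-",
    "[PE 36:1-H]-",
    "[PE 38:6-H]-",
    "[PI 38:4-H]-",
    "[PI 38:3-H]-",
    "[PI 36:1-H]-",
    "[PI 38:5-H]-",
    "[PI 40:6-H]-",
    "[PI 34:1-H]-",
    "[FA 16:1-H]-",
    "[FA 20:4-H]-",
    "[FA 22:6-H]-",
    "[LPI 18:0-H]-",
    "[LPI O-18:2-H]-",
    "[LPI 20:4-H]-",
    "[LPA 18:0-H]-",
    "[LPA 20:4-H]-",
    "[LPE 18:1-H]-",
    "[LPE 22:6-H]-",
    "[PA 34:1-H]-",
    "[PA 36:2-H]-",
]

_NEGATIVE_MINOR = [
    "[FA 14:0-H]-",
    "[FA 18:2-H]-",
    "[FA 18:3;O-H]-",
    "[FA 20:1-H]-",
    "[FA 22:4-H]-",
    "[PS 20:0;O-H]-",
    "[PS 42:7-H]-",
    "[PS 44:2-H]-",
    "[PI 36:2-H]-",
    "[PI 40:4-H]-",
    "[LPA 16:1-H]-",
    "[LPE 18:3-H]-",
    "[LPE 16:0-H]-",
    "[PA 24:2;O3-H]-",
    "[PG 36:2-H]-",
    "[PG 34:1-H]-",
]


def _headgroup_ion() -> TheoreticalIon:
    from .formula import Formula
    from .ions import IonSpec
    from .species import LipidSpecies

    sp = LipidSpecies("PC", 5, 0, explicit_formula=Formula.parse("C5H15NO4P"))
    return TheoreticalIon.create(sp, IonSpec(adduct=None, polarity=1))


def _make_ion(name: str) -> TheoreticalIon:
    if name == "HEADGROUP":
        return _headgroup_ion()
    sp, ionspec = parse_shorthand(name)
    return TheoreticalIon.create(sp, ionspec)


#: Geometric intensity decay per abundance rank within a polarity.
_RANK_DECAY = 0.93


def default_lipidome() -> pd.DataFrame:
    """The generator's ground-truth lipidome table.

    Columns: name, species, lipid_class, polarity, mz, rel_intensity, top
    (whether the entry belongs to the 45 most abundant of its polarity).
    Deterministic; >= 60 ions per polarity.
    """
    rows = []
    for polarity, top, minor in (
        (1, _POSITIVE_TOP, _POSITIVE_MINOR),
        (-1, _NEGATIVE_TOP, _NEGATIVE_MINOR),
    ):
        for rank, name in enumerate(top + minor):
            ion = _make_ion(name)
            rows.append(
                {
                    "name": name if name != "HEADGROUP" else "[C5H15PNO4]+",
                    "species": ion.species.name,
                    "lipid_class": ion.species.class_code,
                    "polarity": polarity,
                    "mz": ion.mz,
                    "rel_intensity": 100.0 * _RANK_DECAY**rank,
                    "top": rank < len(top),
                }
            )
    return pd.DataFrame(rows)


#: Default incubation arms: isotope mass shift and target species (which
#: lipids incorporate the precursor). Incorporation fraction f defaults to
#: 0.3 for every target — the regime a 4-day 50 uM incubation plausibly
#: reaches and the smallest effect the power analysis is specified at.
DEFAULT_ARMS: dict[str, dict] = {
    "15N-choline": {
        "delta": DELTA_N15,
        "label": ["n15", 1],
        "targets": [
            "PC 5:0", "PC 38:2", "PC 36:2", "PC 34:1", "PC 32:0",
            "PC 36:1", "PC 32:1", "PC 30:0", "PC 38:4", "PC 34:0",
        ],
    },
    "13C2-ethanolamine": {
        "delta": 2 * DELTA_C13,
        "label": ["c13", 2],
        "targets": [
            "PE 34:1", "PE 38:4", "PE 40:4", "PE 36:1", "PE 38:6",
            "PE 36:4", "LPE 18:1", "LPE 22:6", "PS 36:1", "PS 38:4",
        ],
    },
    "13C-stearic": {
        "delta": DELTA_C13,
        "label": ["c13", 1],
        "targets": [
            "FA 18:0", "PC 36:1", "PC 34:0", "PC 38:2", "PI 36:1",
            "PI 38:4", "LPI 18:0", "Cer 36:1;O2", "Cer 34:1;O2", "PS 38:1",
        ],
    },
}

DEFAULT_INCORPORATION = 0.3


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment."""

    seed: int
    nx: int = 128
    ny: int = 128
    n_cells: int = 5
    cell_semi_axes: tuple[float, float] = (5.0, 9.0)  # min/max, pixels
    counts_per_pixel: float = 2000.0   # expected lipid counts per cell pixel
    background_per_bin: float = 0.005  # uniform chemical floor, counts/px/bin
    substrate_intensity: float = 50.0  # counts/px per substrate peak (bg px)
    incorporation: float = DEFAULT_INCORPORATION
    arms: dict = field(default_factory=lambda: DEFAULT_ARMS)
    lipidome: pd.DataFrame | None = None
    mass_axis: MassAxis = field(default_factory=MassAxis)
    n_control: int = 20        # control ROIs (5 biological reps x 4 fields)
    n_treated: int = 8         # ROIs per treated arm
    roi_pixels: int = 150      # nominal cell footprint for spectrum-level sim

    def __post_init__(self) -> None:
        if self.lipidome is None:
            self.lipidome = default_lipidome()
        if not 0.0 <= self.incorporation <= 1.0:
            raise ValueError("incorporation fraction must be in [0, 1]")
        self.validate()

    def validate(self) -> None:
        axis = self.mass_axis
        mzs = self.lipidome["mz"].to_numpy()
        if not np.all(axis.in_range(mzs)):
            bad = self.lipidome.loc[~axis.in_range(mzs), "name"].tolist()
            raise ValueError(f"species m/z outside the mass axis: {bad}")
        # planted ions (and their isotope-shifted twins) must occupy
        # distinct, well-separated bins within each polarity's cube, or
        # intensities would merge and ground truth becomes ambiguous
        # different arms never share a cube, so collisions are checked
        # per (polarity, arm)
        for pol in (1, -1):
            lip = self.lipidome[self.lipidome["polarity"] == pol]
            for arm_name, arm in [("control", None)] + list(self.arms.items()):
                all_mz = list(lip["mz"])
                if arm is not None:
                    shifted = lip[lip["species"].isin(set(arm["targets"]))]["mz"]
                    all_mz.extend(shifted + arm["delta"])
                all_mz = np.sort(np.asarray(all_mz))
                gaps = np.diff(all_mz)
                if gaps.size and np.any(gaps < 2 * axis.bin_width):
                    i = int(np.argmin(gaps))
                    raise ValueError(
                        f"planted ions too close (polarity {pol:+d}, arm "
                        f"{arm_name}): {all_mz[i]:.4f} vs {all_mz[i + 1]:.4f}"
                    )

    def arm_delta(self, arm: str) -> float:
        if arm == "control":
            return 0.0
        return self.arms[arm]["delta"]

    def arm_targets(self, arm: str) -> set[str]:
        if arm == "control":
            return set()
        return set(self.arms[arm]["targets"])


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    cell_masks: list[RoiMask]
    species: pd.DataFrame     # lipidome + bin + per-arm expected intensity
    shifted_bins: np.ndarray  # bins receiving isotope-shifted intensity
    unlabeled_bins: np.ndarray
    arm: str
    polarity: int


def _expected_cell_spectrum(config: SimConfig, arm: str, polarity: int):
    """Expected lipid counts per cell pixel per bin, after incorporation.

    Returns (lambda vector, species table with planted/shifted bins).
    """
    axis = config.mass_axis
    lip = config.lipidome[config.lipidome["polarity"] == polarity].copy()
    total_rel = lip["rel_intensity"].sum()
    lip["intensity"] = lip["rel_intensity"] / total_rel * config.counts_per_pixel
    targets = config.arm_targets(arm)
    delta = config.arm_delta(arm)
    f = config.incorporation if arm != "control" else 0.0
    lip["f"] = np.where(lip["species"].isin(targets), f, 0.0)
    lip["bin"] = axis.bin_of(lip["mz"].to_numpy())
    lip["shifted_bin"] = np.where(
        lip["f"] > 0, axis.bin_of(lip["mz"].to_numpy() + delta), -1
    )
    lam = np.zeros(axis.n_bins)
    np.add.at(lam, lip["bin"].to_numpy(),
              lip["intensity"].to_numpy() * (1 - lip["f"].to_numpy()))
    shifted = lip[lip["shifted_bin"] >= 0]
    np.add.at(lam, shifted["shifted_bin"].to_numpy(),
              shifted["intensity"].to_numpy() * shifted["f"].to_numpy())
    return lam, lip


def _substrate_spectrum(config: SimConfig, polarity: int) -> np.ndarray:
    axis = config.mass_axis
    lam = np.zeros(axis.n_bins)
    peaks = SUBSTRATE_MZ_POSITIVE if polarity > 0 else SUBSTRATE_MZ_NEGATIVE
    for mz in peaks:
        if axis.in_range(mz):
            lam[int(axis.bin_of(mz))] += config.substrate_intensity
    return lam


def place_cells(config: SimConfig, rng: np.random.Generator) -> list[RoiMask]:
    """Seeded non-overlapping elliptical cell footprints (with a 2 px moat
    so segmentation sees distinct components)."""
    ny, nx = config.ny, config.nx
    yy, xx = np.mgrid[0:ny, 0:nx]
    lo, hi = config.cell_semi_axes
    margin = hi + 2
    # sequential rejection sampling can wedge itself on small grids (an
    # unlucky first cell blocks every remaining position), so restart the
    # whole arrangement when a round stalls
    for _ in range(50):
        taken = np.zeros((ny, nx), dtype=bool)
        masks: list[RoiMask] = []
        attempts = 0
        while len(masks) < config.n_cells and attempts < 300:
            attempts += 1
            a, b = rng.uniform(lo, hi, size=2)
            theta = rng.uniform(0, np.pi)
            cx = rng.uniform(margin, nx - margin)
            cy = rng.uniform(margin, ny - margin)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            halo = (u / (a + 2)) ** 2 + (v / (b + 2)) ** 2 <= 1.0
            if not mask.any() or (halo & taken).any():
                continue
            taken |= halo
            masks.append(RoiMask(mask=mask, roi_id=len(masks) + 1))
        if len(masks) == config.n_cells:
            return masks
    raise RuntimeError("could not place the requested number of cells")


def render_arm(config: SimConfig, arm: str, polarity: int,
               rng: np.random.Generator | None = None,
               noiseless: bool = False,
               cell_masks: list[RoiMask] | None = None):
    """One synthetic cube for (arm, polarity): (SpectralImage, GroundTruth).

    Cell pixels carry the lipidome spectrum (isotope-shifted per the arm),
    background pixels the substrate peaks; a uniform chemical floor covers
    every pixel in Poisson mode. ``noiseless`` returns the expected signal
    itself (no Poisson draws, no uniform floor) for exact-recovery checks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    axis = config.mass_axis
    masks = cell_masks if cell_masks is not None else place_cells(config, rng)
    cell_union = np.zeros((config.ny, config.nx), dtype=bool)
    for m in masks:
        cell_union |= m.mask
    cell_rows = np.nonzero(cell_union.ravel())[0]
    bg_rows = np.nonzero(~cell_union.ravel())[0]

    lam_cell, species = _expected_cell_spectrum(config, arm, polarity)
    lam_sub = _substrate_spectrum(config, polarity)
    n_px = config.nx * config.ny

    cell_bins = np.nonzero(lam_cell)[0]
    sub_bins = np.nonzero(lam_sub)[0]
    if noiseless:
        rows, cols, vals = [], [], []
        for r in cell_rows:
            rows.append(np.full(cell_bins.size, r))
            cols.append(cell_bins)
            vals.append(lam_cell[cell_bins])
        for r in bg_rows:
            rows.append(np.full(sub_bins.size, r))
            cols.append(sub_bins)
            vals.append(lam_sub[sub_bins])
        counts = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_px, axis.n_bins),
        ).tocsr()
    else:
        rows_list, cols_list, vals_list = [], [], []
        # lipid signal on cell pixels
        draws = rng.poisson(
            np.broadcast_to(lam_cell[cell_bins], (cell_rows.size, cell_bins.size))
        )
        nz = np.nonzero(draws)
        rows_list.append(cell_rows[nz[0]])
        cols_list.append(cell_bins[nz[1]])
        vals_list.append(draws[nz])
        # substrate on background pixels
        if sub_bins.size:
            draws = rng.poisson(
                np.broadcast_to(lam_sub[sub_bins], (bg_rows.size, sub_bins.size))
            )
            nz = np.nonzero(draws)
            rows_list.append(bg_rows[nz[0]])
            cols_list.append(sub_bins[nz[1]])
            vals_list.append(draws[nz])
        # uniform chemical floor: total per pixel is Poisson, bins uniform
        if config.background_per_bin > 0:
            totals = rng.poisson(config.background_per_bin * axis.n_bins,
                                 size=n_px)
            n_events = int(totals.sum())
            ev_rows = np.repeat(np.arange(n_px), totals)
            ev_cols = rng.integers(0, axis.n_bins, size=n_events)
            rows_list.append(ev_rows)
            cols_list.append(ev_cols)
            vals_list.append(np.ones(n_events))
        counts = sparse.coo_matrix(
            (
                np.concatenate(vals_list).astype(float),
                (np.concatenate(rows_list), np.concatenate(cols_list)),
            ),
            shape=(n_px, axis.n_bins),
        ).tocsr()

    image = SpectralImage(
        nx=config.nx, ny=config.ny, counts=counts, polarity=polarity,
        mass_axis=axis,
        metadata={"arm": arm, "noiseless": noiseless, "seed": config.seed},
    )
    shifted = species.loc[species["shifted_bin"] >= 0, "shifted_bin"]
    truth = GroundTruth(
        cell_masks=masks,
        species=species,
        shifted_bins=np.unique(shifted.to_numpy()).astype(int),
        unlabeled_bins=np.unique(species["bin"].to_numpy()).astype(int),
        arm=arm,
        polarity=polarity,
    )
    return image, truth


def simulate_roi_spectra(config: SimConfig, arm: str, polarity: int, n: int,
                         rng: np.random.Generator,
                         condition: str | None = None) -> list[RoiSpectrum]:
    """Spectrum-level simulation of n ROI spectra for one arm.

    Each ROI is a cell footprint of ``roi_pixels`` pixels (lognormal size
    scatter between cells): expected spectrum = pixels x (lipid spectrum +
    uniform floor), Poisson counts per bin. Used for replicate-heavy
    statistical studies where rendering full images adds nothing — the ROI
    spectrum is the statistical unit.
    """
    lam_cell, _ = _expected_cell_spectrum(config, arm, polarity)
    lam_cell = lam_cell + config.background_per_bin
    out = []
    for i in range(n):
        size = config.roi_pixels * rng.lognormal(mean=0.0, sigma=0.2)
        raw = rng.poisson(lam_cell * size).astype(float)
        out.append(
            RoiSpectrum(
                roi_id=i + 1, raw=raw, mass_axis=config.mass_axis,
                polarity=polarity, condition=condition or arm,
                replicate=str(i // max(1, n // 2) + 1),
            )
        )
    return out


def generate_experiment(config: SimConfig, outdir,
                        arms: list[str] | None = None,
                        polarities=(1, -1),
                        fields_per_replicate: int = 4) -> dict:
    """Write a full experiment tree (imzML cubes + ground-truth manifest).

    Control: ``n_control`` fields split over 5 biological replicates;
    each treated arm: ``n_treated`` fields over 2 replicates — the group
    sizes of the emulated study design. Returns the manifest dict (also
    written as manifest.json).
    """
    from .datacube import write_imzml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arms = ["control"] + (arms if arms is not None
                          else list(config.arms.keys()))
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "incorporation": config.incorporation,
        "mass_axis": {
            "start": config.mass_axis.start,
            "stop": config.mass_axis.stop,
            "bin_width": config.mass_axis.bin_width,
        },
        "arms": {},
        "lipidome": config.lipidome.drop(columns=["species"])
        .assign(species=config.lipidome["species"])
        .to_dict(orient="records"),
    }
    for arm in arms:
        n_fields = config.n_control if arm == "control" else config.n_treated
        n_reps = 5 if arm == "control" else 2
        entries = []
        for i in range(n_fields):
            rep = i % n_reps + 1
            for pol in polarities:
                image, truth = render_arm(config, arm, pol, rng=rng)
                tag = "pos" if pol > 0 else "neg"
                path = outdir / f"{arm}_rep{rep}_field{i + 1}_{tag}.imzML"
                write_imzml(image, path)
                entries.append(
                    {
                        "path": path.name,
                        "replicate": rep,
                        "field": i + 1,
                        "polarity": pol,
                        "n_cells": len(truth.cell_masks),
                        "shifted_bins": truth.shifted_bins.tolist(),
                    }
                )
        manifest["arms"][arm] = {
            "delta": config.arm_delta(arm),
            "label": None if arm == "control"
            else list(config.arms[arm].get("label", ())) or None,
            "targets": sorted(config.arm_targets(arm)),
            "images": entries,
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def simulation_library(config: SimConfig, polarity: int | None = None,
                       arm: str | None = None):
    """TheoreticalIon library matching the planted lipidome (one entry per
    planted ion form), for annotating synthetic data.

    With ``arm`` given, the isotope-labeled counterparts of that arm's
    target species are appended, so label-shifted peaks annotate by name
    instead of only raising the isotope-shift flag.
    """
    from dataclasses import replace as _dc_replace

    from .formula import Label

    ions = []
    lip = config.lipidome
    if polarity is not None:
        lip = lip[lip["polarity"] == polarity]
    for name in lip["name"]:
        ions.append(_make_ion("HEADGROUP" if name == "[C5H15PNO4]+" else name))
    if arm is not None and arm != "control":
        kind, count = config.arms[arm].get("label", ["c13", 1])
        label = Label(kind, int(count))
        targets = config.arm_targets(arm)
        for ion, species_name in zip(ions, lip["species"]):
            if species_name in targets:
                labeled = _dc_replace(ion.species, label=label)
                ions.append(TheoreticalIon.create(labeled, ion.ion_spec))
    return ions
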