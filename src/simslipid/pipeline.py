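"""Run-level orchestration: configuration, the abundance-profile run and the
turnover run, with parameter-stamped TSV outputs.

These functions tie the stages together exactly as the two deliverables
require: cubes -> marker-ion ROI segmentation -> interference removal -> TIC
normalization -> (a) top-45-per-polarity abundance profile with class
summary, or (b) PCA-selected peak set -> Mann-Whitney turnover table against
the control arm. Every output file starts with header lines recording the
package version and a hash of the full configuration, so a run can be
reproduced from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import profile
from .datacube import MassAxis, read_imzml
from .roi import marker_image, preprocess_roi, segment_rois
from .turnover import GroupDesign, TurnoverModel, TurnoverResults, compare_conditions


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit code 2)."""


class DataError(ValueError):
    """Unusable input data (maps to CLI exit code 3)."""


@dataclass
class RunConfig:
    """Parameters of one analysis run."""

    data_dir: str
    out_dir: str = "results"
    top_n: int = 45
    tol_ppm: float = 100.0
    alpha: float = 0.05
    top_fraction: float = 0.05
    pca_scaling: str = "center"
    adjust: str | None = None
    min_roi_pixels: int = 20
    interference_mzs: tuple | None = None
    markers_positive: tuple | None = None
    markers_negative: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.tol_ppm <= 0:
            raise ConfigError("tol_ppm must be > 0")
        if not (0 < self.top_fraction <= 1):
            raise ConfigError("top_fraction must be in (0, 1]")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if not Path(self.data_dir).exists():
            raise ConfigError(f"data directory {self.data_dir} does not exist")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header(self, extra: str = "") -> str:
        return (
            f"# simslipid {__version__}  config {self.config_hash}\n"
            f"# {json.dumps(asdict(self), sort_keys=True, default=str)}\n"
            + (f"# {extra}\n" if extra else "")
        )


def _write_tsv(frame: pd.DataFrame, path: Path, config: RunConfig,
               extra: str = "") -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(config.header(extra))
        frame.to_csv(fh, sep="\t", index=False)


def load_manifest(data_dir) -> dict:
    path = Path(data_dir) / "manifest.json"
    if not path.exists():
        raise DataError(f"no manifest.json under {data_dir}")
    with open(path) as fh:
        return json.load(fh)


def _axis_from_manifest(manifest: dict) -> MassAxis:
    ax = manifest.get("mass_axis", {})
    return MassAxis(ax.get("start", 100.0), ax.get("stop", 1000.0),
                    ax.get("bin_width", 0.05))


def collect_roi_spectra(config: RunConfig, manifest: dict, arm: str) -> dict:
    """ROI spectra per polarity for one arm: load each cube, segment on the
    marker image, preprocess every ROI."""
    axis = _axis_from_manifest(manifest)
    if arm not in manifest["arms"]:
        raise DataError(f"arm {arm!r} not present in the manifest")
    spectra: dict[int, list] = {1: [], -1: []}
    for entry in manifest["arms"][arm]["images"]:
        path = Path(config.data_dir) / entry["path"]
        image = read_imzml(path, axis=axis, polarity=entry["polarity"])
        image.metadata.update(entry)
        markers = (config.markers_positive if image.polarity > 0
                   else config.markers_negative)
        marker = marker_image(image, markers=markers)
        rois = segment_rois(marker, min_roi_pixels=config.min_roi_pixels)
        for roi in rois:
            spec = preprocess_roi(
                image, roi, interference_mzs=config.interference_mzs,
                condition=arm, replicate=str(entry.get("replicate", "")),
            )
            spectra[image.polarity].append(spec)
    return spectra


def _library_from_manifest(manifest: dict, polarity: int | None = None,
                           arm: str | None = None):
    from dataclasses import replace as _dc_replace

    from .formula import Label
    from .ions import TheoreticalIon
    from .simulate import _make_ion

    ions, species_names = [], []
    for row in manifest["lipidome"]:
        if polarity is not None and row["polarity"] != polarity:
            continue
        name = row["name"]
        ions.append(_make_ion("HEADGROUP" if name == "[C5H15PNO4]+" else name))
        species_names.append(row["species"])
    arm_info = manifest["arms"].get(arm or "", {})
    if arm_info.get("label"):
        kind, count = arm_info["label"]
        label = Label(kind, int(count))
        targets = set(arm_info.get("targets", ()))
        for ion, species_name in zip(list(ions), species_names):
            if species_name in targets:
                labeled = _dc_replace(ion.species, label=label)
                ions.append(TheoreticalIon.create(labeled, ion.ion_spec))
    return ions


def run_profile(config: RunConfig, arm: str = "control"):
    """The abundance deliverable: top-N peaks per polarity + class summary."""
    manifest = load_manifest(config.data_dir)
    axis = _axis_from_manifest(manifest)
    spectra = collect_roi_spectra(config, manifest, arm)
    spectra = {pol: specs for pol, specs in spectra.items() if specs}
    if not spectra:
        raise DataError(f"no ROIs found in any {arm} cube")
    library = _library_from_manifest(manifest)
    peak_table, summary = profile(
        spectra, library, axis, n_per_polarity=config.top_n,
        tol_ppm=config.tol_ppm,
    )
    out = Path(config.out_dir)
    _write_tsv(peak_table, out / f"profile_{arm}_peaks.tsv", config, f"arm={arm}")
    _write_tsv(summary, out / f"profile_{arm}_classes.tsv", config, f"arm={arm}")
    return peak_table, summary


def run_turnover(config: RunConfig, arm: str,
                 control_arm: str = "control") -> dict[int, TurnoverResults]:
    """The turnover deliverable: per-polarity treated-vs-control tables."""
    manifest = load_manifest(config.data_dir)
    axis = _axis_from_manifest(manifest)
    if control_arm not in manifest["arms"]:
        raise DataError(f"control arm {control_arm!r} missing from manifest")
    control = collect_roi_spectra(config, manifest, control_arm)
    treated = collect_roi_spectra(config, manifest, arm)
    delta = manifest["arms"][arm].get("delta") or None
    results = {}
    out = Path(config.out_dir)
    for pol in (1, -1):
        if len(treated[pol]) < 2 or len(control[pol]) < 2:
            continue
        design = GroupDesign(condition=arm, treated=treated[pol],
                             control=control[pol], polarity=pol)
        model = TurnoverModel(
            design, library=_library_from_manifest(manifest, pol, arm=arm),
            label_delta=delta, scaling=config.pca_scaling,
            tol_ppm=config.tol_ppm,
        )
        res = model.fit(top_fraction=config.top_fraction, alpha=config.alpha,
                        adjust=config.adjust)
        tag = "pos" if pol > 0 else "neg"
        _write_tsv(res.table, out / f"turnover_{arm}_{tag}.tsv", config,
                   f"arm={arm} polarity={tag}")
        results[pol] = res
    if not results:
        raise DataError("no polarity had enough ROIs in both groups")
    return results


def run_compare(config: RunConfig, arm_a: str, arm_b: str) -> dict[int, pd.DataFrame]:
    """Two precursor arms side by side against the shared control."""
    res_a = run_turnover(config, arm_a)
    res_b = run_turnover(config, arm_b)
    out = Path(config.out_dir)
    joint = {}
    for pol in set(res_a) & set(res_b):
        table = compare_conditions(res_a[pol], res_b[pol], names=(arm_a, arm_b))
        tag = "pos" if pol > 0 else "neg"
        _write_tsv(table, out / f"compare_{arm_a}_vs_{arm_b}_{tag}.tsv", config)
        joint[pol] = table
    return joint
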