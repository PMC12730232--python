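"""Cell-area (ROI) selection and per-ROI spectral preprocessing.

Cells are located from marker-ion images — the phosphocholine headgroup at
m/z 184.07 in positive polarity, the palmitic/stearic acid carboxylates at
255.23 / 283.26 in negative — thresholded (Otsu by default) into 4-connected
components. Each ROI's summed spectrum is the statistical unit downstream:
substrate interference bins (ITO glass: indium and indium-cluster ions) are
zeroed first, then the spectrum is normalized to the total retained ion
intensity, so intensities are comparable across cells and acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .datacube import IonImage, MassAxis, SpectralImage, ion_image

#: Default marker windows (m/z centers) per polarity; half-width defaults to
#: one bin width in `ion_image`.
POSITIVE_MARKERS = (184.0733,)   # phosphocholine headgroup cation
NEGATIVE_MARKERS = (255.2330, 283.2643)  # [FA 16:0-H]-, [FA 18:0-H]-

#: Default substrate interference m/z for ITO glass: In+, In2+, InO/In2O+
#: style cluster ions per polarity. A documented stand-in list — the real
#: interference set depends on the substrate batch — and fully configurable.
SUBSTRATE_MZ_POSITIVE = (114.904, 229.808, 245.803)
SUBSTRATE_MZ_NEGATIVE = (130.899, 146.894, 261.798)


def default_interference(polarity: int):
    return SUBSTRATE_MZ_POSITIVE if polarity > 0 else SUBSTRATE_MZ_NEGATIVE


@dataclass
class RoiMask:
    """One connected cell area on the pixel grid."""

    mask: np.ndarray  # bool, shape (ny, nx)
    roi_id: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def anchor(self) -> tuple[int, int]:
        """(y, x) of the top-most then left-most pixel (ordering key)."""
        ys, xs = np.nonzero(self.mask)
        i = np.lexsort((xs, ys))[0]
        return int(ys[i]), int(xs[i])


@dataclass
class RoiSpectrum:
    """Summed, optionally interference-cleaned and TIC-normalized spectrum
    of one cell area."""

    roi_id: int
    raw: np.ndarray
    mass_axis: MassAxis
    polarity: int
    condition: str = ""
    replicate: str = ""
    normalized: np.ndarray | None = None
    removed_bins: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (self.mass_axis.n_bins,):
            raise ValueError("raw spectrum length must equal n_bins")


def marker_image(image: SpectralImage, markers=None,
                 half_width: float | None = None) -> IonImage:
    """Summed marker-ion image used to find cell footprints."""
    if markers is None:
        markers = POSITIVE_MARKERS if image.polarity > 0 else NEGATIVE_MARKERS
    total = None
    for mz in markers:
        ii = ion_image(image, mz, half_width)
        total = ii.values if total is None else total + ii.values
    return IonImage(nx=image.nx, ny=image.ny, values=total,
                    center_mz=float(np.mean(markers)), half_width=ii.half_width)


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def segment_rois(marker: IonImage, method: str = "otsu",
                 min_roi_pixels: int = 20,
                 threshold_fraction: float = 0.5) -> list[RoiMask]:
    """Threshold the marker image and split it into 4-connected ROIs.

    ``method="otsu"`` (default) or ``"fraction"`` (fixed fraction of the
    max). Components smaller than ``min_roi_pixels`` are discarded. ROIs are
    ordered by their top-most, left-most pixel; ids are 1-based in that
    order. An all-zero or unseparable marker yields an empty list.
    """
    values = np.asarray(marker.values, dtype=float)
    if not np.any(values > 0) or np.ptp(values) == 0:
        return []
    if method == "otsu":
        thr = threshold_otsu(values)
    elif method == "fraction":
        thr = threshold_fraction * values.max()
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    binary = values > thr
    labels, n = ndimage.label(binary, structure=_FOUR_CONN)
    rois = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() >= min_roi_pixels:
            rois.append(RoiMask(mask=mask, roi_id=0))
    rois.sort(key=lambda r: r.anchor)
    return [replace(r, roi_id=i + 1) for i, r in enumerate(rois)]


def roi_spectrum(image: SpectralImage, mask: RoiMask, condition: str = "",
                 replicate: str = "") -> RoiSpectrum:
    """Per-bin sum of counts over the masked pixels (raw, unnormalized)."""
    m = np.asarray(mask.mask, dtype=bool)
    if m.shape != (image.ny, image.nx):
        raise ValueError("mask shape does not match image")
    if not m.any():
        raise ValueError("empty ROI mask")
    rows = np.nonzero(m.ravel())[0]
    raw = np.asarray(image.counts[rows].sum(axis=0)).ravel()
    return RoiSpectrum(roi_id=mask.roi_id, raw=raw, mass_axis=image.mass_axis,
                       polarity=image.polarity, condition=condition,
                       replicate=replicate)


def remove_interference(spectrum: RoiSpectrum, interference_mzs=None) -> RoiSpectrum:
    """Zero the whole 0.05 Da bin containing each listed substrate m/z.

    Idempotent; the zeroed bins are recorded in ``removed_bins``. Applied
    before normalization (the fixed pipeline order).
    """
    if interference_mzs is None:
        interference_mzs = default_interference(spectrum.polarity)
    axis = spectrum.mass_axis
    bins = sorted(
        {int(axis.bin_of(mz)) for mz in interference_mzs if axis.in_range(mz)}
    )
    raw = spectrum.raw.copy()
    for b in bins:
        raw[b] = 0.0
    return replace(
        spectrum,
        raw=raw,
        normalized=None,
        removed_bins=tuple(sorted(set(spectrum.removed_bins) | set(bins))),
    )


def tic_normalize(spectrum: RoiSpectrum) -> RoiSpectrum:
    """Divide every retained bin by the total retained intensity."""
    total = spectrum.raw.sum()
    if total <= 0:
        raise ValueError("cannot TIC-normalize a zero-total spectrum")
    return replace(spectrum, normalized=spectrum.raw / total)


def preprocess_roi(image: SpectralImage, mask: RoiMask, interference_mzs=None,
                   condition: str = "", replicate: str = "") -> RoiSpectrum:
    """roi_spectrum -> remove_interference -> tic_normalize, in that order."""
    spec = roi_spectrum(image, mask, condition=condition, replicate=replicate)
    spec = remove_interference(spec, interference_mzs)
    return tic_normalize(spec)


# -- mask interchange --------------------------------------------------------

def write_mask_png(mask: RoiMask, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (mask.mask * np.uint8(255)))


def read_mask_png(path, roi_id: int = 1) -> RoiMask:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return RoiMask(mask=arr > 127, roi_id=roi_id)


def write_mask_tsv(mask: RoiMask, path) -> None:
    ys, xs = np.nonzero(mask.mask)
    np.savetxt(path, np.column_stack([xs, ys]), fmt="%d", delimiter="\t",
               header="x\ty", comments="")


def read_mask_tsv(path, shape: tuple[int, int], roi_id: int = 1) -> RoiMask:
    pix = np.loadtxt(path, skiprows=1, delimiter="\t", dtype=int, ndmin=2)
    mask = np.zeros(shape, dtype=bool)
    if pix.size:
        mask[pix[:, 1], pix[:, 0]] = True
    return RoiMask(mask=mask, roi_id=roi_id)


def spectrum_to_frame(spectrum: RoiSpectrum):
    """Per-ROI spectrum as a (bin_center, raw, normalized) table."""
    import pandas as pd

    return pd.DataFrame(
        {
            "bin_center": spectrum.mass_axis.centers,
            "raw": spectrum.raw,
            "normalized": spectrum.normalized
            if spectrum.normalized is not None
            else np.full(spectrum.mass_axis.n_bins, np.nan),
        }
    )
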