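"""Binned hyperspectral datacubes: mass axis, event binning, ion images,
and imzML interchange.

A cube is one polarity of one acquisition: an nx-by-ny pixel grid, each pixel
holding ion counts on a shared uniform m/z grid (default 100-1000 Da in
0.05 Da bins, 18000 bins). Counts are stored sparsely (scipy CSR over
pixels x bins) because a lipid spectrum occupies a tiny fraction of the axis.
Pixels are row-major, 0-based, origin top-left; imzML's 1-based coordinates
are converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

DEFAULT_START = 100.0
DEFAULT_STOP = 1000.0
DEFAULT_BIN_WIDTH = 0.05


@dataclass(frozen=True)
class MassAxis:
    """Uniform half-open binning [start + i*w, start + (i+1)*w)."""

    start: float = DEFAULT_START
    stop: float = DEFAULT_STOP
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        n = (self.stop - self.start) / self.bin_width
        if not np.isclose(n, round(n)) or n <= 0:
            raise ValueError("(stop - start) must be an integer number of bins")

    @property
    def n_bins(self) -> int:
        return int(round((self.stop - self.start) / self.bin_width))

    def bin_of(self, mz):
        """Bin index of m/z (array-friendly); no range check.

        A 1e-9 relative guard keeps exact bin boundaries in the upper bin
        despite floating-point division error (5e-11 Da at 0.05 Da bins,
        far below any mass difference that matters here).
        """
        frac = (np.asarray(mz) - self.start) / self.bin_width
        return np.floor(frac + 1e-9).astype(int)

    def in_range(self, mz):
        mz = np.asarray(mz)
        return (mz >= self.start) & (mz < self.stop)

    @property
    def centers(self) -> np.ndarray:
        return self.start + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def window(self, center_mz: float, half_width: float | None = None):
        """Bin indices intersecting [center - hw, center + hw); default
        hw = one bin width."""
        hw = self.bin_width if half_width is None else half_width
        lo = max(int(self.bin_of(center_mz - hw)), 0)
        hi = min(int(self.bin_of(center_mz + hw - 1e-12)), self.n_bins - 1)
        if hi < 0 or lo > self.n_bins - 1 or lo > hi:
            raise ValueError(f"window {center_mz}+/-{hw} does not overlap the axis")
        return np.arange(lo, hi + 1)


@dataclass
class SpectralImage:
    """Per-pixel binned ion counts for one polarity.

    ``counts`` is CSR of shape (nx*ny, n_bins); pixel (x, y) is row
    ``y * nx + x``.
    """

    nx: int
    ny: int
    counts: sparse.csr_matrix
    polarity: int
    mass_axis: MassAxis = field(default_factory=MassAxis)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (self.nx * self.ny, self.mass_axis.n_bins):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{self.nx}x{self.ny} pixels and {self.mass_axis.n_bins} bins"
            )
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    def pixel_index(self, x, y):
        return np.asarray(y) * self.nx + np.asarray(x)

    def pixel_spectrum(self, x: int, y: int) -> np.ndarray:
        return np.asarray(self.counts[self.pixel_index(x, y)].todense()).ravel()

    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class IonImage:
    """Per-pixel summed counts within one m/z window."""

    nx: int
    ny: int
    values: np.ndarray  # shape (ny, nx)
    center_mz: float
    half_width: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.ny, self.nx):
            raise ValueError("values must have shape (ny, nx)")


def bin_events(events, axis: MassAxis, nx: int, ny: int, polarity: int,
               metadata: dict | None = None) -> SpectralImage:
    """Sum raw (pixel, m/z, intensity) events into a binned cube.

    ``events`` is an iterable of ((x, y), mz, intensity). Intensity is
    conserved for in-range events; out-of-range m/z are dropped, tallied in
    ``metadata["dropped_events"]``, and warned about.
    """
    xs, ys, mzs, vals = [], [], [], []
    for (x, y), mz, inten in events:
        if inten < 0:
            raise ValueError("event intensities must be >= 0")
        xs.append(x); ys.append(y); mzs.append(mz); vals.append(inten)
    xs, ys = np.asarray(xs, dtype=int), np.asarray(ys, dtype=int)
    mzs, vals = np.asarray(mzs, dtype=float), np.asarray(vals, dtype=float)
    ok = axis.in_range(mzs) if len(mzs) else np.zeros(0, bool)
    n_dropped = int(len(mzs) - ok.sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} out-of-range m/z events", stacklevel=2)
    rows = ys[ok] * nx + xs[ok]
    cols = axis.bin_of(mzs[ok]) if ok.any() else np.zeros(0, int)
    counts = sparse.coo_matrix(
        (vals[ok], (rows, cols)), shape=(nx * ny, axis.n_bins)
    ).tocsr()
    md = dict(metadata or {})
    md["dropped_events"] = n_dropped
    return SpectralImage(nx=nx, ny=ny, counts=counts, polarity=polarity,
                         mass_axis=axis, metadata=md)


def ion_image(image: SpectralImage, center_mz: float,
              half_width: float | None = None) -> IonImage:
    """Per-pixel sum over the bins intersecting the m/z window."""
    cols = image.mass_axis.window(center_mz, half_width)
    vals = np.asarray(image.counts[:, cols].sum(axis=1)).ravel()
    return IonImage(
        nx=image.nx, ny=image.ny,
        values=vals.reshape(image.ny, image.nx),
        center_mz=center_mz,
        half_width=image.mass_axis.bin_width if half_width is None else half_width,
    )


# -- imzML interchange -------------------------------------------------------

def write_imzml(image: SpectralImage, path, mode: str = "processed") -> None:
    """Write the cube as imzML + ibd.

    ``mode="processed"`` stores, per pixel, only the nonzero bins (their
    centers as the m/z array) — compact, and exactly re-binnable because the
    stored m/z are bin centers. ``mode="continuous"`` stores the full shared
    axis per pixel.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    centers = image.mass_axis.centers
    polarity = "positive" if image.polarity > 0 else "negative"
    with ImzMLWriter(str(path), polarity=polarity, mode=mode) as writer:
        for y in range(image.ny):
            for x in range(image.nx):
                row = image.counts[image.pixel_index(x, y)]
                if mode == "continuous":
                    inten = np.asarray(row.todense()).ravel()
                    writer.addSpectrum(centers, inten, (x + 1, y + 1, 1))
                else:
                    row = row.tocoo()
                    if row.nnz == 0:
                        # keep pixel geometry: one zero-intensity anchor point
                        # (dropped again on read)
                        writer.addSpectrum(centers[:1], np.zeros(1), (x + 1, y + 1, 1))
                        continue
                    order = np.argsort(row.col)
                    writer.addSpectrum(
                        centers[row.col[order]], row.data[order], (x + 1, y + 1, 1)
                    )


def read_imzml(path, axis: MassAxis | None = None,
               polarity: int | None = None) -> SpectralImage:
    """Read an imzML cube, re-binning onto ``axis`` (default axis if None).

    Continuous files whose m/z array already equals the axis centers load
    exactly; anything else is summed into bins. Missing pixels stay zero.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    axis = axis or MassAxis()
    parser = ImzMLParser(str(path))
    coords = parser.coordinates
    if coords:
        nx = max(c[0] for c in coords)
        ny = max(c[1] for c in coords)
    else:
        nx = ny = 0
    if polarity is None:
        pol_str = (parser.polarity or "").lower()
        polarity = -1 if pol_str.startswith("neg") else 1
    rows, cols, vals = [], [], []
    n_dropped = 0
    for i, (cx, cy, *_) in enumerate(coords):
        mzs, intens = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        intens = np.asarray(intens, dtype=float)
        nz = intens != 0
        mzs, intens = mzs[nz], intens[nz]
        ok = axis.in_range(mzs)
        n_dropped += int(len(mzs) - ok.sum())
        pix = (cy - 1) * nx + (cx - 1)
        rows.append(np.full(int(ok.sum()), pix))
        cols.append(axis.bin_of(mzs[ok]))
        vals.append(intens[ok])
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} out-of-range m/z values", stacklevel=2)
    if rows:
        counts = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(max(nx * ny, 1), axis.n_bins),
        ).tocsr()
    else:
        counts = sparse.csr_matrix((max(nx * ny, 1), axis.n_bins))
        nx = nx or 1
        ny = ny or 1
    n_missing = nx * ny - len(coords)
    if n_missing > 0:
        warnings.warn(f"{n_missing} missing pixels read as zero spectra", stacklevel=2)
    return SpectralImage(nx=max(nx, 1), ny=max(ny, 1), counts=counts,
                         polarity=polarity, mass_axis=axis,
                         metadata={"source": str(path)})
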