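"""Air / cornea / anterior-chamber segmentation from the intensity histogram.

An anterior-segment B-scan is, from top to bottom, dark air, a bright corneal
band, and the dark aqueous of the anterior chamber.  The global intensity
histogram is therefore bimodal: a dark lobe (air + chamber + speckle noise)
and a bright lobe (cornea, iris, strong artifacts).  The corneal cutoff is
the valley between the two lobes, located on an 11-bin moving average of the
histogram of the median-blurred image; thresholding the *original* image at
that cutoff and taking per-column envelopes of the corneal band then yields
disjoint, exhaustive air / cornea / chamber masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import rank, threshold_otsu
from skimage.measure import label

from .raster_io import OCTScan

__all__ = [
    "IntensityHistogram",
    "CutoffResult",
    "RegionMasks",
    "SegmentationError",
    "compute_histogram",
    "median_blur",
    "smooth_scan",
    "moving_average",
    "find_corneal_cutoff",
    "build_region_masks",
]


class SegmentationError(RuntimeError):
    """Raised when air, cornea and anterior chamber cannot be distinguished."""


@dataclass
class IntensityHistogram:
    """256-bin histogram of 8-bit pixel intensities."""

    counts: np.ndarray  # shape (256,), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,) or (counts < 0).any():
            raise ValueError("counts must be 256 non-negative integers")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class CutoffResult:
    """Corneal cutoff intensity and how it was found.

    ``method`` is ``"valley"`` when the first local minimum of the moving
    average right of the dark peak was found, ``"fallback"`` when the
    histogram had no usable valley and Otsu's threshold was used instead.
    """

    cutoff: int
    method: str  # "valley" | "fallback"
    moving_average: np.ndarray
    left_peak: Optional[int] = None
    right_peak: Optional[int] = None


@dataclass
class RegionMasks:
    """Pairwise-disjoint boolean masks covering every pixel of a scan."""

    air: np.ndarray
    cornea: np.ndarray
    chamber: np.ndarray
    top_envelope: Optional[np.ndarray] = None  # per-column first corneal row
    bottom_envelope: Optional[np.ndarray] = None  # per-column last corneal row

    def validate(self) -> None:
        assert self.air.shape == self.cornea.shape == self.chamber.shape
        overlap = (
            (self.air & self.cornea) | (self.air & self.chamber) | (self.cornea & self.chamber)
        )
        if overlap.any():
            raise AssertionError("region masks overlap")
        if not (self.air | self.cornea | self.chamber).all():
            raise AssertionError("region masks do not cover the image")


def compute_histogram(scan: OCTScan | np.ndarray) -> IntensityHistogram:
    """Histogram of the entire image's pixel intensities (256 bins)."""
    pixels = scan.pixels if isinstance(scan, OCTScan) else np.asarray(scan)
    counts = np.bincount(pixels.ravel(), minlength=256)
    return IntensityHistogram(counts)


def median_blur(pixels: np.ndarray, kernel: int) -> np.ndarray:
    """Square median filter with replicate borders on an 8-bit image.

    Implemented as a sliding-histogram rank filter over an edge-padded copy,
    which is exactly the per-pixel median of the replicate-padded
    neighbourhood (verified against a direct sorted-neighbourhood median).
    ``kernel`` must be odd; ``kernel=1`` is the identity.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return pixels.copy()
    pad = kernel // 2
    padded = np.pad(pixels, pad, mode="edge")
    footprint = np.ones((kernel, kernel), dtype=bool)
    out = rank.median(padded, footprint)
    return out[pad:-pad, pad:-pad]


def smooth_scan(scan: OCTScan, kernel: int = 5) -> OCTScan:
    """Median-blurred copy of a scan (used to regularise the histogram)."""
    return OCTScan(
        pixels=median_blur(scan.pixels, kernel),
        scan_id=scan.scan_id,
        slice_index=scan.slice_index,
        axial_um_per_px=scan.axial_um_per_px,
        transverse_um_per_px=scan.transverse_um_per_px,
        grade_label=scan.grade_label,
        diagnosis_label=scan.diagnosis_label,
    )


def moving_average(counts: np.ndarray, window: int = 11) -> np.ndarray:
    """Centred moving average of histogram counts, truncated at the edges.

    At bin ``i`` the average runs over bins ``[i-w, i+w]`` clipped to
    ``[0, 255]`` (``w = window // 2``), divided by the number of bins
    actually inside — no phantom zero bins beyond the histogram ends.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    counts = np.asarray(counts, dtype=float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    idx = np.arange(counts.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, counts.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def find_corneal_cutoff(
    hist: IntensityHistogram,
    window: int = 11,
    left_peak_max_bin: int = 127,
) -> CutoffResult:
    """Locate the valley between the dark and bright histogram lobes.

    The dark (noise) peak is the argmax of the moving average over bins
    ``[0, left_peak_max_bin]``; the bright (cornea/structure) peak is the
    argmax over the remaining bins.  The cutoff is the first zero-gradient
    point between them — the (leftmost) minimum of the moving average on the
    open interval between the two peaks.  A genuine valley must lie strictly
    below both peaks; otherwise (unimodal or flat histogram) Otsu's threshold
    on the smoothed histogram is returned with ``method="fallback"``.

    The between-peaks minimum rather than the first local dip makes the
    search immune to small comb ripples that integer rescaling of exposures
    imprints on the histogram.
    """
    if hist.total == 0:
        raise ValueError("cannot find a cutoff on an empty histogram")
    m = moving_average(hist.counts, window)
    left_peak = int(np.argmax(m[: left_peak_max_bin + 1]))
    right_peak = left_peak_max_bin + 1 + int(np.argmax(m[left_peak_max_bin + 1 :]))

    if right_peak - left_peak >= 2 and m[right_peak] > 0:
        valley = left_peak + 1 + int(np.argmin(m[left_peak + 1 : right_peak]))
        if m[valley] < m[left_peak] and m[valley] < m[right_peak]:
            return CutoffResult(
                cutoff=valley,
                method="valley",
                moving_average=m,
                left_peak=left_peak,
                right_peak=right_peak,
            )

    cutoff = int(threshold_otsu(hist=(m, np.arange(256))))
    return CutoffResult(cutoff=cutoff, method="fallback", moving_average=m, left_peak=left_peak)


def _interpolate_envelope(values: np.ndarray, have: np.ndarray) -> np.ndarray:
    """Linearly interpolate per-column envelope rows across missing columns."""
    cols = np.arange(values.size)
    return np.interp(cols, cols[have], values[have])


def build_region_masks(
    binary: np.ndarray,
    scan: OCTScan,
    large_structures: Optional[np.ndarray] = None,
    min_width_fraction: float = 0.5,
    large_component_min_px: int = 64,
) -> RegionMasks:
    """Partition a scan into air, cornea/large-structure and chamber masks.

    ``binary`` is the original image thresholded at the corneal cutoff.  The
    corneal band is the largest 8-connected above-cutoff structure; it must
    span at least ``min_width_fraction`` of the image width, otherwise the
    scan is rejected (:class:`SegmentationError` — the air/cornea/chamber
    decomposition does not exist for the image).

    Per column, pixels above the band's top envelope are air and pixels below
    its bottom envelope are chamber; anything between the envelopes, plus all
    ``large_structures`` (the 21x21-median artifact mask, which also holds
    iris/lens bands), is assigned to the cornea class.  Any other above-cutoff
    component of at least ``large_component_min_px`` pixels — far larger than
    any cell — joins the structure class too: the median mask under-covers
    right-angle corners of iris/lens bands, and those corners must not leak
    into the chamber.  Columns the band does not reach use envelopes linearly
    interpolated from neighbouring columns.
    """
    if binary.shape != scan.pixels.shape:
        raise ValueError("binary mask and scan shapes differ")
    h, w = binary.shape
    labels, n = label(binary, connectivity=2, return_num=True)
    if n == 0:
        raise SegmentationError("cannot distinguish air, cornea, and anterior chamber")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    core = labels == int(np.argmax(sizes))
    big_ids = np.flatnonzero(sizes >= large_component_min_px)
    big_components = np.isin(labels, big_ids) if big_ids.size else None

    core_cols = core.any(axis=0)
    if core_cols.sum() < min_width_fraction * w:
        raise SegmentationError("cannot distinguish air, cornea, and anterior chamber")

    rows = np.arange(h)[:, None]
    top = np.where(core_cols, np.where(core, rows, h).min(axis=0), 0).astype(float)
    # bottom of the corneal band = end of the contiguous core run that starts
    # at the top envelope: a reflection line crossing the iris can fuse the
    # band and the iris into one component, and the bottommost core pixel
    # would then misplace the band's lower edge by hundreds of rows
    below_gap = (~core) & (rows > top[None, :])
    first_gap = np.where(below_gap, rows, h).min(axis=0)
    bottom = np.where(core_cols, first_gap - 1, 0).astype(float)
    top = np.rint(_interpolate_envelope(top, core_cols)).astype(int)
    bottom = np.rint(_interpolate_envelope(bottom, core_cols)).astype(int)

    cornea = (rows >= top[None, :]) & (rows <= bottom[None, :])
    cornea |= core
    if big_components is not None:
        cornea |= big_components
    if large_structures is not None:
        cornea |= large_structures
    air = (rows < top[None, :]) & ~cornea
    chamber = ~cornea & ~air
    masks = RegionMasks(
        air=air, cornea=cornea, chamber=chamber, top_envelope=top, bottom_envelope=bottom
    )
    masks.validate()
    return masks
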