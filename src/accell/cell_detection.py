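"""Noise-floor estimation and connected-component cell extraction.

Air contains no scatterers, so any signal recorded above the anterior
chamber is instrument noise.  Its intensity distribution is right-skewed and
non-Gaussian (a mean + 2 SD rule badly misplaces the floor), so the noise
threshold is the 99.5th percentile of the air pixels — a nonparametric
estimate recomputed per image, which also absorbs global brightness and
exposure differences between scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.measure import label, regionprops

from .artifact_removal import ArtifactMask, remove_column_artifacts, small_candidate_image
from .raster_io import OCTScan
from .segmentation import RegionMasks

__all__ = [
    "NoiseEstimate",
    "CellCandidate",
    "estimate_noise_threshold",
    "binarize_chamber",
    "extract_components",
]


@dataclass
class NoiseEstimate:
    """Per-image noise floor derived from air-pixel intensities."""

    threshold: int
    n_air_pixels: int
    percentile: float = 99.5

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("noise threshold must lie in [0, 255]")
        if self.n_air_pixels <= 0:
            raise ValueError("noise estimate requires at least one air pixel")


@dataclass
class CellCandidate:
    """One 8-connected component of candidate pixels inside the chamber."""

    pixel_coords: list[tuple[int, int]]  # (x, y), 0-based
    pixel_count: int
    centroid: tuple[float, float]  # (x, y)
    bounding_box: tuple[int, int, int, int]  # (x0, y0, x1, y1) inclusive


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> int:
    """Nearest-rank percentile of a discrete sample (no interpolation).

    The ``ceil(p/100 * n)``-th order statistic — always an observed value,
    hence an integer threshold on 8-bit data.
    """
    values = np.sort(np.asarray(values).ravel())
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    rank = int(np.ceil(percentile / 100.0 * values.size))
    rank = min(max(rank, 1), values.size)
    return int(values[rank - 1])


def estimate_noise_threshold(
    scan: OCTScan, air_mask: np.ndarray, percentile: float = 99.5
) -> NoiseEstimate:
    """Noise floor = the given percentile of the air-pixel intensity multiset."""
    air_values = scan.pixels[air_mask]
    if air_values.size == 0:
        raise ValueError("air mask is empty; cannot estimate the noise floor")
    return NoiseEstimate(
        threshold=nearest_rank_percentile(air_values, percentile),
        n_air_pixels=int(air_values.size),
        percentile=percentile,
    )


def binarize_chamber(
    scan: OCTScan,
    masks: RegionMasks,
    artifact: ArtifactMask,
    noise: NoiseEstimate,
    small_kernel: int = 3,
    column_threshold: int = 16,
) -> np.ndarray:
    """Binary candidate raster for the anterior chamber.

    A pixel is a candidate iff its intensity is strictly above the noise
    threshold, it lies in the chamber mask, its ``small_kernel`` median is
    also above the threshold (shot-noise rejection) and it is outside the
    large-structure mask.  Both brightness conditions are required, so the
    result does not depend on whether the median runs before or after the
    thresholding.  Column artifacts are then removed in place; the cleared
    column indices are appended to ``artifact.removed_columns``.
    """
    small = small_candidate_image(scan, small_kernel)
    candidates = (
        (scan.pixels > noise.threshold)
        & (small > noise.threshold)
        & masks.chamber
        & ~artifact.large_structures
    )
    cleaned, removed = remove_column_artifacts(candidates, column_threshold)
    artifact.removed_columns.extend(removed)
    return cleaned


def extract_components(binary: np.ndarray, min_pixels: int = 2) -> list[CellCandidate]:
    """8-connected components of the candidate raster, smallest ones dropped.

    Components are returned in deterministic raster order of their bounding
    box top-left corner ``(y0, x0)``; the result is independent of any
    processing order.
    """
    labels = label(binary, connectivity=2)
    out: list[CellCandidate] = []
    for region in regionprops(labels):
        if region.num_pixels < min_pixels:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        y0, x0, y1, x1 = region.bbox  # half-open
        cy, cx = region.centroid
        out.append(
            CellCandidate(
                pixel_coords=[(int(c), int(r)) for r, c in zip(rr, cc)],
                pixel_count=int(region.num_pixels),
                centroid=(float(cx), float(cy)),
                bounding_box=(int(x0), int(y0), int(x1 - 1), int(y1 - 1)),
            )
        )
    out.sort(key=lambda c: (c.bounding_box[1], c.bounding_box[0]))
    return out
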