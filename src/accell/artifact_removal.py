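"""Artifact masking by median filtering and the column rule.

Anterior-chamber cells are a few pixels across; artifacts (specular
reflection lines, inverted-vertex ghosts) and anatomical structures (cornea,
iris) are large.  A 21x21 median filter erases small bright specks but
preserves wide bright structures, so thresholding the 21x21-filtered image
yields a mask of everything *except* cells.  A 3x3 median keeps compact
specks of a few pixels while erasing single-pixel shot noise; candidate cell
pixels are those bright in the 3x3-median image but absent from the 21x21
mask.  Residual full-height reflection lines too narrow for the 21x21 mask
are caught by the column rule: any image column holding at least 16 candidate
pixels is treated as a reflection artifact and cleared wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_io import OCTScan
from .segmentation import median_blur

__all__ = [
    "ArtifactMask",
    "build_large_structure_mask",
    "small_candidate_image",
    "remove_column_artifacts",
]


@dataclass
class ArtifactMask:
    """Mask of large hyperreflective structures plus removed artifact columns."""

    large_structures: np.ndarray
    removed_columns: list[int] = field(default_factory=list)


def build_large_structure_mask(
    scan: OCTScan, cutoff: int, large_kernel: int = 21
) -> ArtifactMask:
    """Mask pixels whose ``large_kernel`` x ``large_kernel`` median exceeds ``cutoff``.

    The interior of any bright structure wider than about half the kernel
    survives the median and enters the mask; isolated specks of a few pixels
    never do.
    """
    if large_kernel < 3 or large_kernel % 2 == 0:
        raise ValueError(f"large_kernel must be odd and >= 3, got {large_kernel}")
    filtered = median_blur(scan.pixels, large_kernel)
    return ArtifactMask(large_structures=filtered > cutoff)


def small_candidate_image(scan: OCTScan, small_kernel: int = 3) -> np.ndarray:
    """The ``small_kernel`` median-filtered image.

    Downstream, a pixel is a cell candidate only if it is bright in this
    image *and* outside the large-structure mask: surviving the small median
    but not the large one is what distinguishes a cell from both shot noise
    and artifacts.
    """
    return median_blur(scan.pixels, small_kernel)


def remove_column_artifacts(
    candidates: np.ndarray, threshold: int = 16
) -> tuple[np.ndarray, list[int]]:
    """Clear every column with at least ``threshold`` candidate pixels.

    Specular reflections appear as straight bright lines running top to
    bottom; no plausible cell puts that many bright pixels into a single
    column.  Returns the cleaned raster (a subset of the input — the rule
    never creates candidates) and the list of cleared column indices.
    """
    if threshold < 1:
        raise ValueError(f"column threshold must be >= 1, got {threshold}")
    counts = candidates.sum(axis=0)
    bad = np.flatnonzero(counts >= threshold)
    cleaned = candidates.copy()
    cleaned[:, bad] = False
    return cleaned, bad.tolist()
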