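"""Per-cell area, perimeter, eccentricity, and per-image cell density.

A detected cell is modelled as an ellipse with semi-axes ``a <= b``.  Its
area and perimeter are approximated by

    S = pi * a * b
    L ~ 2 * pi * sqrt((a^2 + b^2) / 2)

and eliminating ``a`` and ``b`` gives the eccentricity
``e = sqrt(1 - a^2/b^2)`` directly from the measured pair ``(S, L)``:

    e = sqrt(1 - [L^4 - 8 pi^2 S^2 - L^2 sqrt(L^4 - 16 pi^2 S^2)] / (8 pi^2 S^2))

``S`` and ``L`` come from the boundary polygon traced through the outermost
pixel centres of the component (Moore neighbourhood tracing, diagonal steps
contributing sqrt(2)).  Under this convention a single pixel has zero area
and perimeter, and pixelation overestimates the perimeter — and hence the
eccentricity — of very small cells, which is why eccentricity statistics
only include cells of at least 3 pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cell_detection import CellCandidate

__all__ = [
    "CellMeasurement",
    "ScanResult",
    "trace_boundary",
    "polygon_area",
    "polygon_perimeter",
    "measure_cell",
    "eccentricity_from_area_perimeter",
    "eccentricity_for_cells",
    "compute_density",
]

TWO_PI = 2.0 * math.pi


@dataclass
class CellMeasurement:
    """Geometry of one detected cell."""

    candidate: CellCandidate
    area: float  # px^2, boundary-polygon (shoelace) area
    perimeter: float  # px, boundary-polygon arc length
    eccentricity: Optional[float]  # in [0, 1], None when undefined
    boundary_pixels: list[tuple[int, int]] = field(default_factory=list)  # ordered (x, y)
    scan_id: str = "scan"

    @property
    def semi_axes(self) -> Optional[tuple[float, float]]:
        """Equivalent-ellipse semi-axes ``(a, b)``, ``a <= b``, from (S, L)."""
        S, L = self.area, self.perimeter
        if S <= 0 or L <= 0:
            return None
        disc = L**4 - 16.0 * math.pi**2 * S**2
        if disc < 0:
            disc = 0.0
        half_sum = L**2 / (4.0 * math.pi**2)  # a^2 + b^2
        half_diff = math.sqrt(disc) / (4.0 * math.pi**2)  # b^2 - a^2
        a2 = (half_sum - half_diff) / 2.0
        b2 = (half_sum + half_diff) / 2.0
        if a2 < 0:
            return None
        return (math.sqrt(a2), math.sqrt(b2))


@dataclass
class ScanResult:
    """Per-image summary emitted by the pipeline."""

    scan_id: str
    qc_status: str  # "ok" | "warning" | "unanalyzable"
    corneal_cutoff: Optional[int] = None
    cutoff_method: Optional[str] = None
    noise_threshold: Optional[int] = None
    ac_area_px: int = 0
    cell_count: int = 0
    density: Optional[float] = None  # cells per 1e6 chamber pixels
    mean_eccentricity: Optional[float] = None
    removed_columns: list[int] = field(default_factory=list)
    slice_index: Optional[int] = None
    grade_label: Optional[str] = None
    diagnosis_label: Optional[str] = None
    qc_reason: Optional[str] = None


# Moore neighbourhood in clockwise screen order (x right, y down).
_CLOCKWISE = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]


def trace_boundary(pixel_coords: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Ordered outer-boundary pixel centres of an 8-connected component.

    Moore-neighbourhood tracing, clockwise in screen coordinates, starting
    from the topmost-then-leftmost pixel, with Jacob's stopping criterion
    (terminate on re-entering the start pixel from the initial direction).
    A single-pixel component returns just that pixel.
    """
    pixels = set((int(x), int(y)) for x, y in pixel_coords)
    if not pixels:
        raise ValueError("cannot trace an empty component")
    start = min(pixels, key=lambda p: (p[1], p[0]))  # topmost, then leftmost
    if len(pixels) == 1:
        return [start]

    def next_on_boundary(p: tuple[int, int], b: tuple[int, int]):
        """First foreground neighbour of p clockwise from b; new backtrack."""
        bdir = (b[0] - p[0], b[1] - p[1])
        k = _CLOCKWISE.index(bdir)
        prev = b
        for j in range(1, 9):
            dx, dy = _CLOCKWISE[(k + j) % 8]
            q = (p[0] + dx, p[1] + dy)
            if q in pixels:
                return q, prev
            prev = q
        return None, prev  # isolated pixel

    b0 = (start[0] - 1, start[1])  # left of start is background by construction
    contour = [start]
    p, b = next_on_boundary(start, b0)
    if p is None:
        return [start]
    first_move = (p, b)
    state = first_move
    for _ in range(8 * len(pixels) + 8):
        p, b = state
        contour.append(p)
        state = next_on_boundary(p, b)
        if state == first_move:
            break
    else:  # pragma: no cover - cannot happen on a finite component
        raise RuntimeError("boundary trace failed to terminate")
    return contour


def polygon_area(vertices: Sequence[tuple[int, int]]) -> float:
    """Unsigned shoelace area of the closed polygon through the vertices."""
    if len(vertices) < 3:
        return 0.0
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def polygon_perimeter(vertices: Sequence[tuple[int, int]]) -> float:
    """Arc length of the closed polygon (axis steps 1, diagonal steps sqrt 2)."""
    if len(vertices) < 2:
        return 0.0
    v = np.asarray(vertices, dtype=float)
    diffs = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def measure_cell(candidate: CellCandidate, scan_id: str = "scan") -> CellMeasurement:
    """Boundary-polygon area and perimeter, plus closed-form eccentricity."""
    boundary = trace_boundary(candidate.pixel_coords)
    S = polygon_area(boundary)
    L = polygon_perimeter(boundary)
    e = eccentricity_from_area_perimeter(S, L)
    return CellMeasurement(
        candidate=candidate,
        area=S,
        perimeter=L,
        eccentricity=e,
        boundary_pixels=boundary,
        scan_id=scan_id,
    )


def eccentricity_from_area_perimeter(S: float, L: float) -> Optional[float]:
    """Ellipse eccentricity from area ``S`` and perimeter ``L``.

    Returns ``None`` when the pair is off the ellipse manifold
    (``L^4 < 16 pi^2 S^2``, i.e. below the isoperimetric-style bound for the
    perimeter approximation used) or degenerate (``S <= 0`` or ``L <= 0``);
    such cells are excluded from eccentricity statistics rather than mapped
    to 0 or 1.  A circle gives exactly 0.  The result is clamped to [0, 1].
    """
    if S is None or L is None or S <= 0.0 or L <= 0.0:
        return None
    pi2S2 = math.pi**2 * S * S
    disc = L**4 - 16.0 * pi2S2
    if abs(disc) <= 1e-9 * max(L**4, 1.0):
        return 0.0  # on the circle manifold (L^4 = 16 pi^2 S^2) up to rounding
    if disc < 0.0:
        return None
    inner = 1.0 - (L**4 - 8.0 * pi2S2 - L * L * math.sqrt(disc)) / (8.0 * pi2S2)
    inner = min(max(inner, 0.0), 1.0)
    return math.sqrt(inner)


def eccentricity_for_cells(
    cells: Sequence[CellMeasurement], min_pixels: int = 3
) -> list[float]:
    """Defined eccentricities of cells with at least ``min_pixels`` pixels.

    Small components carry a strong pixelation bias, so 1–2-pixel cells are
    excluded from eccentricity statistics by default.
    """
    return [
        c.eccentricity
        for c in cells
        if c.candidate.pixel_count >= min_pixels and c.eccentricity is not None
    ]


def compute_density(cell_count: int, ac_area_px: int) -> Optional[float]:
    """Cell density in cells per million anterior-chamber pixels."""
    if ac_area_px <= 0:
        return None
    return cell_count / ac_area_px * 1e6
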