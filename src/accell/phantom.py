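"""Synthetic anterior-segment B-scan phantoms with full ground truth.

A phantom reproduces the structures the analysis pipeline has to cope with:
dark air above a bright, parabolically curved corneal band; a dark anterior
chamber below it; an optional iris band with a pupil gap; right-skewed
non-Gaussian speckle noise shared by air and chamber; rare hyperreflective
"hot" pixels; vertical reflection-line artifacts; an optional inverted-vertex
ghost blob; a global brightness offset; and planted cells rendered as filled
rasterized ellipses of controlled size and elongation.  Every random draw is
owned by a per-scan generator seeded from the spec, so a phantom is
reproducible bit for bit.

The noise model is a two-component mixture: a gamma-distributed speckle body
(most mass below ~60 on the 8-bit scale) plus a small weight of hot pixels
uniform over the upper intensity range.  The mixture is strongly right-skewed
and fails normality, and its discretized 99.5th percentile is computable in
closed form, giving an exact reference value for the pipeline's
nonparametric noise-floor estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .raster_io import OCTScan
from .segmentation import RegionMasks

__all__ = [
    "NoiseModel",
    "LineArtifact",
    "BlobArtifact",
    "PlantedCell",
    "PhantomSpec",
    "SyntheticGroundTruth",
    "theoretical_noise_threshold",
    "generate_scan",
    "generate_cohort",
]


@dataclass(frozen=True)
class NoiseModel:
    """Speckle-noise mixture for air and chamber pixels.

    ``gamma_shape`` / ``gamma_scale`` parameterise the speckle body;
    ``hot_fraction`` of pixels are instead drawn uniformly from
    ``[hot_low, hot_high]`` (discrete), emulating rare hyperreflective
    shot-noise specks.
    """

    gamma_shape: float = 2.0
    gamma_scale: float = 8.0
    hot_fraction: float = 0.007
    hot_low: int = 60
    hot_high: int = 255


@dataclass(frozen=True)
class LineArtifact:
    """Full-height vertical reflection line."""

    column: int
    width: int = 2
    intensity: int = 200
    intensity_sd: float = 12.0


@dataclass(frozen=True)
class BlobArtifact:
    """Bright elliptical ghost (e.g. inverted-vertex artifact)."""

    center: tuple[int, int]  # (x, y)
    semi_axes: tuple[float, float] = (18.0, 9.0)
    intensity: int = 190
    intensity_sd: float = 12.0


@dataclass(frozen=True)
class PlantedCell:
    """Ground truth for one planted cell."""

    pixels: tuple[tuple[int, int], ...]  # (x, y)
    centroid: tuple[float, float]
    a: float  # semi-minor axis, px
    b: float  # semi-major axis, px
    theta: float  # orientation, radians

    @property
    def true_eccentricity(self) -> float:
        return math.sqrt(1.0 - (self.a / self.b) ** 2)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic scan.

    Cell sizes are drawn log-normally (``cell_log_size_mu`` is the log of the
    median pixel count) and clipped to ``cell_size_range``; elongation
    ``b/a`` is uniform over ``cell_aspect_range``.  ``cell_intensity`` is a
    multiplier applied to the noise model's theoretical 99.5th-percentile
    threshold.
    """

    shape: tuple[int, int] = (496, 512)
    # cornea geometry: top(c) = vertex_row + curvature * (c - cols/2)^2
    cornea_vertex_row: int = 190
    cornea_thickness: int = 42
    cornea_curvature: float = 8e-4
    cornea_intensity: int = 180
    cornea_intensity_sd: float = 18.0
    iris: bool = True
    iris_top_row: int = 430
    iris_thickness: int = 30
    iris_pupil_halfwidth: int = 90
    iris_intensity: int = 150
    iris_intensity_sd: float = 18.0
    n_cells: int = 0
    cell_size_range: tuple[int, int] = (4, 20)
    cell_log_size_mu: float = math.log(10.0)
    cell_log_size_sigma: float = 0.35
    cell_aspect_range: tuple[float, float] = (1.1, 2.2)
    cell_intensity: float = 2.0  # multiplier on the theoretical noise threshold
    cell_intensity_sd: float = 8.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    lines: tuple[LineArtifact, ...] = ()
    blobs: tuple[BlobArtifact, ...] = ()
    brightness_offset: int = 0
    seed: int = 0


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows about a phantom scan."""

    true_masks: RegionMasks
    cells: list[PlantedCell]
    artifact_columns: list[int]
    noise: NoiseModel
    noise_threshold: int  # theoretical 99.5th-percentile of the noise model
    cell_intensity: float  # mean planted intensity, 8-bit
    seed: int

    @property
    def chamber_area_px(self) -> int:
        return int(self.true_masks.chamber.sum())

    @property
    def planted_density(self) -> Optional[float]:
        area = self.chamber_area_px
        return None if area == 0 else len(self.cells) / area * 1e6


def _noise_cdf(model: NoiseModel, offset: int = 0) -> np.ndarray:
    """Exact CDF of the discretized, clipped noise mixture over bins 0..255."""
    from scipy import stats

    v = np.arange(256)
    # body: round(clip(gamma + offset)) <= v  <=>  gamma <= v - offset + 0.5
    body = stats.gamma.cdf(v - offset + 0.5, a=model.gamma_shape, scale=model.gamma_scale)
    lo, hi = model.hot_low + offset, model.hot_high + offset
    hot = np.clip((np.floor(np.minimum(v, 255)) - lo + 1) / (hi - lo + 1), 0.0, 1.0)
    hot[v < lo] = 0.0
    cdf = (1.0 - model.hot_fraction) * body + model.hot_fraction * hot
    cdf[-1] = 1.0  # clipping piles residual mass on 255
    return cdf


def theoretical_noise_threshold(
    model: NoiseModel, percentile: float = 99.5, brightness_offset: int = 0
) -> int:
    """Smallest intensity whose CDF reaches ``percentile`` under the model."""
    cdf = _noise_cdf(model, brightness_offset)
    return int(np.searchsorted(cdf, percentile / 100.0, side="left"))


def _draw_noise(rng: np.random.Generator, model: NoiseModel, n: int) -> np.ndarray:
    body = rng.gamma(model.gamma_shape, model.gamma_scale, size=n)
    values = np.rint(np.clip(body, 0, 255)).astype(np.int16)
    hot = rng.random(n) < model.hot_fraction
    values[hot] = rng.integers(model.hot_low, model.hot_high + 1, size=int(hot.sum()))
    return values


def _true_masks(spec: PhantomSpec) -> tuple[RegionMasks, np.ndarray, np.ndarray]:
    rows, cols = spec.shape
    c = np.arange(cols)
    top = np.rint(spec.cornea_vertex_row + spec.cornea_curvature * (c - cols / 2.0) ** 2)
    top = np.clip(top, 0, rows - 1).astype(int)
    bottom = np.clip(top + spec.cornea_thickness - 1, 0, rows - 1)
    r = np.arange(rows)[:, None]
    cornea = (r >= top[None, :]) & (r <= bottom[None, :])
    if spec.iris and spec.iris_top_row < rows:
        iris_cols = np.abs(c - cols / 2.0) > spec.iris_pupil_halfwidth
        iris = (
            (r >= spec.iris_top_row)
            & (r < spec.iris_top_row + spec.iris_thickness)
            & iris_cols[None, :]
        )
        cornea = cornea | iris
    air = (r < top[None, :]) & ~cornea
    chamber = ~air & ~cornea
    masks = RegionMasks(
        air=air, cornea=cornea, chamber=chamber, top_envelope=top, bottom_envelope=bottom
    )
    masks.validate()
    return masks, top, bottom


def _rasterize_ellipse(
    cx: float, cy: float, a: float, b: float, theta: float, shape: tuple[int, int]
) -> list[tuple[int, int]]:
    """Pixels whose centres fall inside the ellipse (a = semi-minor, b = semi-major)."""
    rows, cols = shape
    rad = int(math.ceil(b)) + 1
    x0, x1 = max(0, int(cx) - rad), min(cols - 1, int(cx) + rad)
    y0, y1 = max(0, int(cy) - rad), min(rows - 1, int(cy) + rad)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    dx, dy = xs - cx, ys - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)  # along the major axis
    w = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / b) ** 2 + (w / a) ** 2 <= 1.0
    return [(int(x), int(y)) for x, y in zip(xs[inside].ravel(), ys[inside].ravel())]


def _forbidden_columns(spec: PhantomSpec) -> set[int]:
    cols: set[int] = set()
    for line in spec.lines:
        half = line.width // 2
        lo = line.column - half - 2
        hi = line.column - half + line.width - 1 + 2
        cols.update(range(lo, hi + 1))
    return cols


def _plant_cells(
    rng: np.random.Generator,
    spec: PhantomSpec,
    chamber: np.ndarray,
    occupied_margin: np.ndarray,
) -> list[PlantedCell]:
    rows, cols = spec.shape
    lo, hi = spec.cell_size_range
    forbidden_cols = _forbidden_columns(spec)
    # interior chamber pixels (clear of structures and borders) as candidate centres
    from scipy import ndimage

    interior = ndimage.binary_erosion(chamber, iterations=4, border_value=0)
    cand_r, cand_c = np.nonzero(interior)
    if cand_r.size == 0 and spec.n_cells > 0:
        raise ValueError("phantom chamber too small to plant cells")
    taken = occupied_margin.copy()
    cells: list[PlantedCell] = []
    attempts = 0
    max_attempts = 400 * max(spec.n_cells, 1)
    while len(cells) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {spec.n_cells} non-overlapping cells "
                f"({len(cells)} placed)"
            )
        size = float(np.clip(rng.lognormal(spec.cell_log_size_mu, spec.cell_log_size_sigma), lo, hi))
        aspect = rng.uniform(*spec.cell_aspect_range)
        a = math.sqrt(size / (math.pi * aspect))
        b = aspect * a
        theta = rng.uniform(0.0, math.pi)
        k = rng.integers(cand_r.size)
        cy = cand_r[k] + rng.uniform(-0.5, 0.5)
        cx = cand_c[k] + rng.uniform(-0.5, 0.5)
        pixels = _rasterize_ellipse(cx, cy, a, b, theta, spec.shape)
        if not pixels:
            continue
        ok = True
        for x, y in pixels:
            if (
                not chamber[y, x]
                or taken[y, x]
                or x in forbidden_cols
                or x < 1
                or x > cols - 2
                or y < 1
                or y > rows - 2
            ):
                ok = False
                break
        if not ok:
            continue
        # reserve the cell plus a 2-px moat so neighbouring cells cannot merge
        for x, y in pixels:
            taken[max(0, y - 2) : y + 3, max(0, x - 2) : x + 3] = True
        px = np.array(pixels, dtype=float)
        cells.append(
            PlantedCell(
                pixels=tuple((int(x), int(y)) for x, y in pixels),
                centroid=(float(px[:, 0].mean()), float(px[:, 1].mean())),
                a=a,
                b=b,
                theta=theta,
            )
        )
    return cells


def generate_scan(spec: PhantomSpec) -> tuple[OCTScan, SyntheticGroundTruth]:
    """Render one phantom scan and its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    masks, top, bottom = _true_masks(spec)

    img = np.zeros((rows, cols), dtype=np.int16)
    background = masks.air | masks.chamber
    img[background] = _draw_noise(rng, spec.noise, int(background.sum()))

    cornea_band = masks.cornea & ~(masks.air | masks.chamber)
    # split cornea-class pixels into the band proper and the iris (if any)
    r = np.arange(rows)[:, None]
    band = (r >= top[None, :]) & (r <= bottom[None, :])
    iris_px = cornea_band & ~band
    img[band] = np.rint(
        rng.normal(spec.cornea_intensity, spec.cornea_intensity_sd, size=int(band.sum()))
    )
    if iris_px.any():
        img[iris_px] = np.rint(
            rng.normal(spec.iris_intensity, spec.iris_intensity_sd, size=int(iris_px.sum()))
        )

    noise_thr = theoretical_noise_threshold(spec.noise)
    cell_level = min(spec.cell_intensity * noise_thr, 250.0)
    occupied = np.zeros((rows, cols), dtype=bool)
    cells = _plant_cells(rng, spec, masks.chamber, occupied)
    for cell in cells:
        for x, y in cell.pixels:
            img[y, x] = int(np.rint(np.clip(rng.normal(cell_level, spec.cell_intensity_sd), 0, 255)))

    artifact_columns: list[int] = []
    for line in spec.lines:
        half = line.width // 2
        c0 = line.column - half
        for c in range(c0, c0 + line.width):
            if 0 <= c < cols:
                img[:, c] = np.rint(
                    np.clip(rng.normal(line.intensity, line.intensity_sd, size=rows), 0, 255)
                )
                artifact_columns.append(c)
    for blob in spec.blobs:
        bx, by = blob.center
        ax, ay = blob.semi_axes
        for x, y in _rasterize_ellipse(bx, by, ay, ax, 0.0, spec.shape):
            img[y, x] = int(np.rint(np.clip(rng.normal(blob.intensity, blob.intensity_sd), 0, 255)))

    img = np.clip(img + spec.brightness_offset, 0, 255).astype(np.uint8)
    scan = OCTScan(pixels=img, scan_id=f"phantom-{spec.seed}")
    truth = SyntheticGroundTruth(
        true_masks=masks,
        cells=cells,
        artifact_columns=sorted(artifact_columns),
        noise=spec.noise,
        noise_threshold=theoretical_noise_threshold(spec.noise, brightness_offset=spec.brightness_offset),
        cell_intensity=float(cell_level),
        seed=spec.seed,
    )
    return scan, truth


def generate_cohort(
    grades: Sequence[str],
    scans_per_grade: int,
    density_map: dict[str, float],
    seed: int,
    base_spec: Optional[PhantomSpec] = None,
    slices_per_eye: Optional[int] = None,
) -> list[tuple[OCTScan, SyntheticGroundTruth, str]]:
    """Generate a labelled cohort with grade-dependent planted cell density.

    ``density_map`` gives the planted density (cells per million chamber
    pixels) per grade and must be strictly increasing in the given grade
    order.  Per-scan counts are Poisson around ``density * chamber_area``.
    When ``slices_per_eye`` is set, scans cycle through slice indices
    ``0..slices_per_eye-1``.  Each scan draws from its own seeded stream, so
    the cohort is reproducible independent of generation order.
    """
    densities = [density_map[g] for g in grades]
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError("density_map must be strictly increasing in grade order")
    base = base_spec if base_spec is not None else PhantomSpec()
    chamber_area = int(_true_masks(base)[0].chamber.sum())
    out: list[tuple[OCTScan, SyntheticGroundTruth, str]] = []
    master = np.random.SeedSequence(seed)
    scan_index = 0
    for grade in grades:
        lam = density_map[grade] * chamber_area / 1e6
        for i in range(scans_per_grade):
            child = np.random.SeedSequence(entropy=master.entropy, spawn_key=(scan_index,))
            scan_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            n = int(np.random.default_rng(scan_seed ^ 0x5EED).poisson(lam))
            spec = replace(base, n_cells=n, seed=scan_seed)
            scan, truth = generate_scan(spec)
            scan.scan_id = f"g{grade.replace('/', '_').replace('+', '')}-{i:03d}"
            scan.grade_label = grade
            if slices_per_eye is not None:
                scan.slice_index = scan_index % slices_per_eye
            out.append((scan, truth, grade))
            scan_index += 1
    return out
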