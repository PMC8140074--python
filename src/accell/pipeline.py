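"""Per-scan orchestration, batch processing and group aggregation.

The per-image stages run in a fixed order: histogram of the median-blurred
image -> corneal cutoff (valley search) -> threshold the original image ->
large-structure/artifact mask (21x21 median) -> air/cornea/chamber masks ->
noise floor from air (99.5th percentile) -> chamber binarization (3x3-median
condition, large-structure exclusion, column rule) -> connected components
-> per-cell geometry -> density.  Quality control propagates instead of
aborting: a scan in which air, cornea and chamber cannot be distinguished is
reported as ``unanalyzable`` with an empty cell list; a fallback cutoff or a
globally dark image downgrade the scan to ``warning``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import artifact_removal, cell_detection, cell_geometry, segmentation
from .cell_geometry import CellMeasurement, ScanResult
from .raster_io import OCTScan

logger = logging.getLogger("accell")

__all__ = ["PipelineConfig", "process_scan", "process_batch", "aggregate_by_group"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the analysis pipeline.

    The defaults are the method's published operating point: 5x5 histogram
    median blur, 11-bin moving-average valley search, 21x21 / 3x3 artifact
    and candidate median kernels, 99.5th-percentile noise floor, 16-pixel
    column rule, 2-pixel detection minimum and 3-pixel eccentricity minimum.
    """

    histogram_smooth_kernel: int = 5
    histogram_window: int = 11
    left_peak_max_bin: int = 127
    large_kernel: int = 21
    small_kernel: int = 3
    column_threshold: int = 16
    noise_percentile: float = 99.5
    min_pixels: int = 2
    eccentricity_min_pixels: int = 3
    min_cornea_width_fraction: float = 0.5
    large_component_min_px: int = 64  # above-cutoff components this big are structures
    dark_image_floor: float = 10.0  # mean 8-bit intensity below which QC warns

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def process_scan(
    scan: OCTScan, config: PipelineConfig = PipelineConfig()
) -> tuple[ScanResult, list[CellMeasurement]]:
    """Run the full analysis on one scan.  Never raises on image content."""

    def _qc_fail(reason: str, cutoff=None, method=None) -> tuple[ScanResult, list]:
        logger.info("scan %s unanalyzable: %s", scan.scan_id, reason)
        return (
            ScanResult(
                scan_id=scan.scan_id,
                qc_status="unanalyzable",
                corneal_cutoff=cutoff,
                cutoff_method=method,
                slice_index=scan.slice_index,
                grade_label=scan.grade_label,
                diagnosis_label=scan.diagnosis_label,
                qc_reason=reason,
            ),
            [],
        )

    warnings: list[str] = []
    if float(scan.pixels.mean()) < config.dark_image_floor:
        warnings.append("image too dark; noise may be misrecognized as cells")

    smoothed = segmentation.smooth_scan(scan, config.histogram_smooth_kernel)
    hist = segmentation.compute_histogram(smoothed)
    cut = segmentation.find_corneal_cutoff(
        hist, window=config.histogram_window, left_peak_max_bin=config.left_peak_max_bin
    )
    if cut.method == "fallback":
        warnings.append("no histogram valley; fallback (Otsu) cutoff used")

    binary = scan.pixels > cut.cutoff
    artifact = artifact_removal.build_large_structure_mask(
        scan, cut.cutoff, config.large_kernel
    )
    try:
        masks = segmentation.build_region_masks(
            binary,
            scan,
            large_structures=artifact.large_structures,
            min_width_fraction=config.min_cornea_width_fraction,
            large_component_min_px=config.large_component_min_px,
        )
    except segmentation.SegmentationError as exc:
        return _qc_fail(str(exc), cutoff=cut.cutoff, method=cut.method)

    if not masks.air.any():
        return _qc_fail("empty air region; no noise reference", cut.cutoff, cut.method)
    noise = cell_detection.estimate_noise_threshold(
        scan, masks.air, config.noise_percentile
    )

    candidates = cell_detection.binarize_chamber(
        scan,
        masks,
        artifact,
        noise,
        small_kernel=config.small_kernel,
        column_threshold=config.column_threshold,
    )
    components = cell_detection.extract_components(candidates, config.min_pixels)
    cells = [cell_geometry.measure_cell(c, scan_id=scan.scan_id) for c in components]

    ac_area = int(masks.chamber.sum())
    density = cell_geometry.compute_density(len(cells), ac_area)
    eccs = cell_geometry.eccentricity_for_cells(cells, config.eccentricity_min_pixels)
    status = "warning" if warnings else "ok"
    if density is None:
        status = "unanalyzable"
    result = ScanResult(
        scan_id=scan.scan_id,
        qc_status=status,
        corneal_cutoff=int(cut.cutoff),
        cutoff_method=cut.method,
        noise_threshold=int(noise.threshold),
        ac_area_px=ac_area,
        cell_count=len(cells),
        density=density,
        mean_eccentricity=float(np.mean(eccs)) if eccs else None,
        removed_columns=list(artifact.removed_columns),
        slice_index=scan.slice_index,
        grade_label=scan.grade_label,
        diagnosis_label=scan.diagnosis_label,
        qc_reason="; ".join(warnings) if warnings else None,
    )
    logger.info(
        "scan %s: cutoff=%d (%s) noise=%d area=%d cells=%d density=%s qc=%s",
        scan.scan_id,
        cut.cutoff,
        cut.method,
        noise.threshold,
        ac_area,
        len(cells),
        "NA" if density is None else f"{density:.2f}",
        status,
    )
    return result, cells


def process_batch(
    scans: Sequence[OCTScan], config: PipelineConfig = PipelineConfig()
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[ScanResult, list[CellMeasurement]]]]:
    """Process scans independently and return tidy per-scan / per-cell tables.

    Each scan is processed in isolation (no shared state), so batch
    composition and ordering never affect per-scan values.  Tables are sorted
    by ``scan_id`` for order-independent output.
    """
    if len(scans) == 0:
        raise ValueError("process_batch requires at least one scan")
    outputs = [process_scan(s, config) for s in scans]
    scan_rows = []
    cell_rows = []
    for result, cells in outputs:
        scan_rows.append(
            {
                "scan_id": result.scan_id,
                "slice_index": result.slice_index,
                "qc_status": result.qc_status,
                "corneal_cutoff": result.corneal_cutoff,
                "noise_threshold": result.noise_threshold,
                "ac_area_px": result.ac_area_px,
                "cell_count": result.cell_count,
                "density_per_1e6px": result.density,
                "mean_eccentricity": result.mean_eccentricity,
                "grade_label": result.grade_label,
                "diagnosis_label": result.diagnosis_label,
            }
        )
        for cell in cells:
            cx, cy = cell.candidate.centroid
            cell_rows.append(
                {
                    "scan_id": result.scan_id,
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "pixel_count": cell.candidate.pixel_count,
                    "area": cell.area,
                    "perimeter": cell.perimeter,
                    "eccentricity": cell.eccentricity,
                }
            )
    scans_df = pd.DataFrame(scan_rows).sort_values("scan_id", kind="stable").reset_index(drop=True)
    cells_df = pd.DataFrame(
        cell_rows,
        columns=[
            "scan_id",
            "centroid_x",
            "centroid_y",
            "pixel_count",
            "area",
            "perimeter",
            "eccentricity",
        ],
    )
    if not cells_df.empty:
        cells_df = cells_df.sort_values(
            ["scan_id", "centroid_y", "centroid_x"], kind="stable"
        ).reset_index(drop=True)
    return scans_df, cells_df, outputs


def aggregate_by_group(
    results: pd.DataFrame, group_key: str, sqrt_density: bool = True
) -> pd.DataFrame:
    """Summarise cell density (and eccentricity) per group.

    ``group_key`` is one of ``grade_label``, ``slice_index`` or
    ``diagnosis_label``.  Returns per-group n, median, interquartile range
    and mean +/- SD of density, the same for mean eccentricity when grouping
    by diagnosis, and optionally the square-root-transformed median density
    (useful because clinical grade intervals widen with grade).
    Unanalyzable scans (undefined density) are excluded.
    """
    if group_key not in results.columns:
        raise ValueError(f"missing grouping column: {group_key}")
    valid = results[results["density_per_1e6px"].notna()].copy()
    if valid.empty or valid[group_key].isna().all():
        raise ValueError(f"no analyzable rows with a '{group_key}' value")
    valid = valid[valid[group_key].notna()]

    def _summary(g: pd.DataFrame) -> pd.Series:
        d = g["density_per_1e6px"]
        out = {
            "n": len(g),
            "density_median": d.median(),
            "density_q1": d.quantile(0.25),
            "density_q3": d.quantile(0.75),
            "density_mean": d.mean(),
            "density_sd": d.std(ddof=1),
        }
        if sqrt_density:
            out["sqrt_density_median"] = np.sqrt(d).median()
        if group_key == "diagnosis_label" and "mean_eccentricity" in g.columns:
            e = g["mean_eccentricity"].dropna()
            out["eccentricity_mean"] = e.mean() if len(e) else np.nan
            out["eccentricity_sd"] = e.std(ddof=1) if len(e) > 1 else np.nan
        return pd.Series(out)

    grouped = valid.groupby(group_key, sort=True).apply(_summary, include_groups=False)
    return grouped.reset_index()
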