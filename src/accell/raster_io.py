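"""Reading and writing of B-scan rasters, sidecar metadata and result tables.

Coordinate convention used throughout the package: row-major arrays with the
origin at the top-left corner; ``x`` is the column index, ``y`` the row index,
both 0-based.  Images are 8-bit grayscale (BMP or PNG — both lossless).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

__all__ = [
    "OCTScan",
    "ScanFormatError",
    "read_scan",
    "read_metadata_csv",
    "write_scan",
    "write_overlay",
    "write_results_tables",
]

#: Known clinical grade labels (Standardization of Uveitis Nomenclature scale).
SUN_GRADES = ("0+", "1/2+", "1+", "2+", "3+", "4+")

#: Default highlight colour for detected-cell boundaries in overlays (RGB).
OVERLAY_COLOR = (255, 64, 64)


class ScanFormatError(ValueError):
    """Raised when an input raster cannot be interpreted as a grayscale scan."""


@dataclass
class OCTScan:
    """One grayscale anterior-segment B-scan plus acquisition metadata.

    Parameters
    ----------
    pixels:
        2-D ``uint8`` array of reflectance intensities in ``[0, 255]``.
    scan_id:
        Identifier for the scan (defaults to the file stem on read).
    slice_index:
        Position within a 21-slice series, 0 (top) to 20 (bottom), or ``None``.
    axial_um_per_px, transverse_um_per_px:
        Physical pixel pitch of the scanner, in micrometres per pixel.
    grade_label:
        Optional clinical SUN grade label for the eye at examination time.
    diagnosis_label:
        Optional diagnosis label (e.g. ``uveitis``).
    """

    pixels: np.ndarray
    scan_id: str = "scan"
    slice_index: Optional[int] = None
    axial_um_per_px: float = 3.9
    transverse_um_per_px: float = 5.7
    grade_label: Optional[str] = None
    diagnosis_label: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.slice_index is not None:
            self.slice_index = int(self.slice_index)
            if not 0 <= self.slice_index <= 20:
                raise ValueError("slice_index must be in [0, 20]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _collapse_channels(arr: np.ndarray, path: Path) -> np.ndarray:
    """Collapse a (H, W, C) array with identical channels to a single channel."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # ignore a fully opaque alpha channel
            if not np.all(arr[:, :, 3] == 255):
                raise ScanFormatError(f"{path}: image has a non-trivial alpha channel")
            arr = arr[:, :, :3]
        if not all(np.array_equal(arr[:, :, 0], arr[:, :, c]) for c in range(1, arr.shape[2])):
            raise ScanFormatError(f"{path}: colour channels differ; not a grayscale scan")
        return arr[:, :, 0]
    raise ScanFormatError(f"{path}: unsupported raster dimensionality {arr.ndim}")


def read_scan(path: str | Path, metadata: Optional[Mapping[str, object]] = None) -> OCTScan:
    """Read one grayscale scan image (BMP or PNG) plus optional metadata.

    ``metadata`` is a mapping with optional keys ``scan_id``, ``slice_index``,
    ``grade_label``, ``diagnosis_label``, ``axial_um_per_px``,
    ``transverse_um_per_px``.  When absent, a sidecar JSON file
    ``<image>.json`` next to the image is used if it exists.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L") if im.mode in ("L", "I;16", "1", "P") else im)
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot read scan image {path}: {exc}") from exc
    arr = _collapse_channels(arr, path)
    if arr.dtype != np.uint8:
        raise ScanFormatError(f"{path}: expected 8-bit intensities, got {arr.dtype}")

    if metadata is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            metadata = json.loads(sidecar.read_text())
        else:
            metadata = {}

    def _get(key: str, default=None):
        val = metadata.get(key, default)
        return default if val is None or (isinstance(val, float) and np.isnan(val)) else val

    slice_index = _get("slice_index")
    return OCTScan(
        pixels=arr,
        scan_id=str(_get("scan_id", path.stem)),
        slice_index=None if slice_index is None else int(slice_index),
        axial_um_per_px=float(_get("axial_um_per_px", 3.9)),
        transverse_um_per_px=float(_get("transverse_um_per_px", 5.7)),
        grade_label=_get("grade_label"),
        diagnosis_label=_get("diagnosis_label"),
    )


def read_metadata_csv(path: str | Path) -> dict[str, dict[str, object]]:
    """Read a batch metadata CSV keyed by image filename.

    Expected columns: ``filename`` (required), then any of ``scan_id``,
    ``slice_index``, ``grade_label``, ``diagnosis_label``.
    """
    df = pd.read_csv(path)
    if "filename" not in df.columns:
        raise ValueError(f"{path}: metadata CSV must have a 'filename' column")
    records: dict[str, dict[str, object]] = {}
    for row in df.to_dict(orient="records"):
        fname = str(row.pop("filename"))
        records[fname] = {k: v for k, v in row.items() if not pd.isna(v)}
    return records


def write_scan(scan: OCTScan, path: str | Path) -> None:
    """Write a scan's pixels as a grayscale image (format from extension)."""
    Image.fromarray(scan.pixels, mode="L").save(Path(path))


def write_overlay(scan: OCTScan, cells: Sequence, path: str | Path) -> None:
    """Write the scan as a colour image with every cell boundary highlighted.

    ``cells`` are :class:`~accell.cell_geometry.CellMeasurement` objects (or
    anything exposing ``boundary_pixels`` / a candidate with pixel coords).
    The grayscale image is replicated into RGB and the boundary pixels of each
    cell are painted in a fixed highlight colour.
    """
    h, w = scan.pixels.shape
    rgb = np.repeat(scan.pixels[:, :, None], 3, axis=2).copy()
    for cell in cells:
        coords = getattr(cell, "boundary_pixels", None)
        if coords is None:
            coords = cell.candidate.pixel_coords  # fall back to the full component
        for x, y in coords:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(
                    f"cell boundary pixel ({x}, {y}) outside image bounds {w}x{h}"
                )
            rgb[y, x] = OVERLAY_COLOR
    Image.fromarray(rgb, mode="RGB").save(Path(path))


_SCANS_COLUMNS = [
    "scan_id",
    "slice_index",
    "qc_status",
    "corneal_cutoff",
    "noise_threshold",
    "ac_area_px",
    "cell_count",
    "density_per_1e6px",
    "grade_label",
    "diagnosis_label",
]

_CELLS_COLUMNS = [
    "scan_id",
    "centroid_x",
    "centroid_y",
    "pixel_count",
    "area",
    "perimeter",
    "eccentricity",
]


def write_results_tables(results: Iterable, cells: Iterable, out_dir: str | Path) -> None:
    """Write ``scans.csv`` (one row per image) and ``cells.csv`` (one per cell).

    Undefined quantities (density of an unanalyzable scan, eccentricity of a
    1–2-pixel cell) are written as empty fields, never as 0 or 1.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise OSError(f"output directory does not exist: {out_dir}")

    scan_rows = []
    for r in results:
        scan_rows.append(
            {
                "scan_id": r.scan_id,
                "slice_index": r.slice_index,
                "qc_status": r.qc_status,
                "corneal_cutoff": r.corneal_cutoff,
                "noise_threshold": r.noise_threshold,
                "ac_area_px": r.ac_area_px,
                "cell_count": r.cell_count,
                "density_per_1e6px": r.density,
                "grade_label": r.grade_label,
                "diagnosis_label": r.diagnosis_label,
            }
        )
    cell_rows = []
    for c in cells:
        cx, cy = c.candidate.centroid
        cell_rows.append(
            {
                "scan_id": c.scan_id,
                "centroid_x": cx,
                "centroid_y": cy,
                "pixel_count": c.candidate.pixel_count,
                "area": c.area,
                "perimeter": c.perimeter,
                "eccentricity": c.eccentricity,
            }
        )
    scans_df = pd.DataFrame(scan_rows, columns=_SCANS_COLUMNS)
    cells_df = pd.DataFrame(cell_rows, columns=_CELLS_COLUMNS)
    # repr-style floats keep full precision (well beyond 6 significant digits)
    scans_df.to_csv(out_dir / "scans.csv", index=False)
    cells_df.to_csv(out_dir / "cells.csv", index=False)
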