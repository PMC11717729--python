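"""Image and result I/O plus the shared domain types.

The scanner exports single 14 mm horizontal line B-scans as 8-bit grayscale
PNGs; :func:`read_bscan` also accepts TIFF, RGB (converted to luminance) and
16-bit input (linearly rescaled).  Row 0 of a :class:`BScan` is the
anterior-most (air) row and depth increases with the row index.  Physical
scale is carried as metadata only — no algorithm downstream depends on mm.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .exceptions import InputError, InvariantError

__all__ = [
    "BScan",
    "Focus",
    "HRFResult",
    "read_bscan",
    "write_result",
    "read_result",
    "render_overlay",
]


@dataclass
class BScan:
    """A 2-D 8-bit grayscale B-scan with physical-scale metadata.

    ``pixels`` is a ``(height, width)`` uint8 array; (row, col) coordinates
    are 0-based with row 0 at the top of the image (anterior / air side).
    """

    pixels: np.ndarray
    lateral_mm_per_px: float
    axial_mm_per_px: float
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InvariantError("BScan pixels must be a 2-D array")
        if self.pixels.size == 0 or min(self.pixels.shape) == 0:
            raise InvariantError("BScan must have positive height and width")
        if self.pixels.dtype != np.uint8:
            arr = np.asarray(self.pixels)
            if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
                self.pixels = arr.astype(np.uint8)
            else:
                raise InvariantError("BScan gray levels must be integers in [0, 255]")
        if self.lateral_mm_per_px <= 0 or self.axial_mm_per_px <= 0:
            raise InvariantError("physical scales must be positive")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class Focus:
    """One detected hyper-reflective focus.

    Intensities are gray levels measured on the *source* (pre-blur,
    pre-binarization) image over the particle's pixels.
    """

    centroid_row: float
    centroid_col: float
    area_px: int
    peak_intensity: int
    mean_intensity: float

    def __post_init__(self):
        if self.area_px < 1:
            raise InvariantError("focus area must be positive")
        if self.peak_intensity < self.mean_intensity - 1e-9:
            raise InvariantError("peak intensity cannot be below mean intensity")


@dataclass
class HRFResult:
    """Final automated count for one scan plus per-focus records."""

    count: int
    foci: list[Focus]
    background_mean: float
    binarization_threshold: int
    roi_area_px: int
    params_digest: str = ""

    def __post_init__(self):
        if self.count != len(self.foci):
            raise InvariantError("count must equal the number of foci")
        if not (0 <= self.binarization_threshold <= 255):
            raise InvariantError("binarization threshold must be in [0, 255]")


# ITU-R 601 luma weights, integer arithmetic with rounding.
def _rgb_to_gray(arr: np.ndarray) -> np.ndarray:
    r = arr[..., 0].astype(np.int64)
    g = arr[..., 1].astype(np.int64)
    b = arr[..., 2].astype(np.int64)
    return ((299 * r + 587 * g + 114 * b + 500) // 1000).astype(np.uint8)


def read_bscan(path: str | os.PathLike, lateral_mm: float = 14.0,
               axial_mm: float = 7.0, source_id: str | None = None) -> BScan:
    """Read a PNG/TIFF export into a :class:`BScan`.

    RGB images are converted to integer luminance; 16-bit images are linearly
    rescaled to [0, 255].  ``lateral_mm`` is the scan's lateral field (the
    device's line scan covers 14 mm); the per-pixel scale is derived from the
    image width.
    """
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {os.fspath(path)!r}: {exc}") from exc
    if arr.size == 0:
        raise InputError(f"image {os.fspath(path)!r} is empty")
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] == 3:
            if arr.dtype == np.uint16:
                arr = np.round(arr.astype(np.float64) * 255.0 / 65535.0).astype(np.uint8)
            arr = _rgb_to_gray(arr)
        elif arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise InputError(f"unsupported channel count {arr.shape[2]} in {os.fspath(path)!r}")
    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) * 255.0 / 65535.0).astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    if arr.shape[1] == 0:
        raise InvariantError("image has zero width")
    sid = source_id if source_id is not None else os.path.basename(os.fspath(path))
    return BScan(
        pixels=arr,
        lateral_mm_per_px=lateral_mm / arr.shape[1],
        axial_mm_per_px=axial_mm / arr.shape[0],
        source_id=sid,
    )


_FOCUS_FIELDS = ["centroid_row", "centroid_col", "area_px", "peak_intensity", "mean_intensity"]


def write_result(result: HRFResult, path: str | os.PathLike, format: str = "json") -> None:
    """Write an :class:`HRFResult` as JSON or CSV.

    The CSV has one row per focus plus a trailing summary row; integer fields
    round-trip losslessly through either format.
    """
    path = os.fspath(path)
    if format == "json":
        payload = {
            "count": result.count,
            "background_mean": result.background_mean,
            "binarization_threshold": result.binarization_threshold,
            "roi_area_px": result.roi_area_px,
            "params_digest": result.params_digest,
            "foci": [
                {f: getattr(focus, f) for f in _FOCUS_FIELDS} for focus in result.foci
            ],
        }
        try:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
                fh.write("\n")
        except OSError as exc:
            raise InputError(f"cannot write result to {path!r}: {exc}") from exc
    elif format == "csv":
        try:
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["kind"] + _FOCUS_FIELDS
                                + ["count", "background_mean", "binarization_threshold",
                                   "roi_area_px", "params_digest"])
                for focus in result.foci:
                    writer.writerow(["focus"] + [getattr(focus, f) for f in _FOCUS_FIELDS]
                                    + ["", "", "", "", ""])
                writer.writerow(["summary"] + [""] * len(_FOCUS_FIELDS)
                                + [result.count, result.background_mean,
                                   result.binarization_threshold, result.roi_area_px,
                                   result.params_digest])
        except OSError as exc:
            raise InputError(f"cannot write result to {path!r}: {exc}") from exc
    else:
        raise ValueError(f"unknown result format {format!r}")


def read_result(path: str | os.PathLike, format: str = "json") -> HRFResult:
    """Read back a result written by :func:`write_result`."""
    path = os.fspath(path)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        foci = [Focus(**{f: rec[f] for f in _FOCUS_FIELDS}) for rec in payload["foci"]]
        return HRFResult(
            count=payload["count"],
            foci=foci,
            background_mean=payload["background_mean"],
            binarization_threshold=payload["binarization_threshold"],
            roi_area_px=payload["roi_area_px"],
            params_digest=payload.get("params_digest", ""),
        )
    if format == "csv":
        foci = []
        summary = None
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                if row["kind"] == "focus":
                    foci.append(Focus(
                        centroid_row=float(row["centroid_row"]),
                        centroid_col=float(row["centroid_col"]),
                        area_px=int(row["area_px"]),
                        peak_intensity=int(row["peak_intensity"]),
                        mean_intensity=float(row["mean_intensity"]),
                    ))
                elif row["kind"] == "summary":
                    summary = row
        if summary is None:
            raise InputError(f"no summary row in {path!r}")
        return HRFResult(
            count=int(summary["count"]),
            foci=foci,
            background_mean=float(summary["background_mean"]),
            binarization_threshold=int(summary["binarization_threshold"]),
            roi_area_px=int(summary["roi_area_px"]),
            params_digest=summary["params_digest"],
        )
    raise ValueError(f"unknown result format {format!r}")


_FOCUS_MARKER = np.array(
    [[0, 1, 1, 1, 0],
     [1, 1, 1, 1, 1],
     [1, 1, 1, 1, 1],
     [1, 1, 1, 1, 1],
     [0, 1, 1, 1, 0]], dtype=bool)
FOCUS_COLOR = (255, 255, 0)       # yellow, as in the device overlay
ROI_BOUNDARY_COLOR = (0, 160, 255)


def render_overlay(scan: BScan, result: HRFResult, seg, path: str | os.PathLike) -> None:
    """Write a QC overlay PNG: gray source, yellow focus markers, ROI outline.

    Pure output: neither ``result`` nor ``seg`` is modified.
    """
    roi = np.asarray(seg.roi_mask, dtype=bool)
    if roi.shape != scan.pixels.shape:
        raise InvariantError("segmentation shape does not match scan shape")
    rgb = np.repeat(scan.pixels[:, :, None], 3, axis=2).copy()
    boundary = roi & ~ndimage.binary_erosion(roi, structure=np.ones((3, 3), bool))
    rgb[boundary] = ROI_BOUNDARY_COLOR
    h, w = scan.pixels.shape
    mr = _FOCUS_MARKER.shape[0] // 2
    for focus in result.foci:
        r0 = int(round(focus.centroid_row))
        c0 = int(round(focus.centroid_col))
        for dr in range(-mr, mr + 1):
            for dc in range(-mr, mr + 1):
                if _FOCUS_MARKER[dr + mr, dc + mr]:
                    r, c = r0 + dr, c0 + dc
                    if 0 <= r < h and 0 <= c < w:
                        rgb[r, c] = FOCUS_COLOR
    iio.imwrite(os.fspath(path), rgb)
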