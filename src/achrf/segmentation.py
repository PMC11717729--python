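"""Automatic anterior-chamber segmentation.

From the cleaned binary mask the module extracts large connected structures
(cornea, iris, lens capsule), identifies the cornea as the anterior-most
band spanning at least half the image width, traces the anterior iris/lens
boundary per column (interpolating across the pupillary gap where the lens
capsule is faint), and builds two masks:

* ``roi_mask`` — the whole anterior chamber between posterior cornea and
  anterior iris/lens, shrunk by a safety margin; and
* ``background_mask`` — the air region above the anterior corneal surface,
  which contains only speckle noise and anchors the intensity rule.

No human ROI selection is involved anywhere; the whole stage is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

from .exceptions import ParameterError, SegmentationError
from .preprocess import BinaryMask

__all__ = [
    "SegmentationParams",
    "Structure",
    "ACSegmentation",
    "find_structures",
    "identify_cornea",
    "trace_iris_lens_boundary",
    "build_roi",
    "segment_scan",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    roi_margin_px: int = 3
    min_structure_area_px: int = 500
    interp: str = "linear"  # linear | pchip

    def __post_init__(self):
        if self.min_structure_area_px < 1:
            raise ParameterError("min_structure_area_px must be >= 1")
        if self.roi_margin_px < 0:
            raise ParameterError("roi_margin_px must be >= 0")
        if self.interp not in ("linear", "pchip"):
            raise ParameterError(f"unknown interpolation {self.interp!r}")


@dataclass
class Structure:
    """One large connected component with per-column vertical extents.

    ``col_top``/``col_bottom`` are float arrays over the full image width,
    NaN where the structure is absent from a column.
    """

    label: int
    area_px: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    col_top: np.ndarray
    col_bottom: np.ndarray

    @property
    def cols_present(self) -> np.ndarray:
        return ~np.isnan(self.col_top)

    @property
    def span_cols(self) -> int:
        return int(self.cols_present.sum())


@dataclass
class ACSegmentation:
    """Per-column AC boundaries plus the derived ROI and background masks."""

    posterior_cornea_row: np.ndarray   # float, NaN where undefined
    anterior_iris_lens_row: np.ndarray
    roi_mask: np.ndarray               # bool
    background_mask: np.ndarray        # bool
    roi_margin_px: int = 3

    @property
    def roi_area_px(self) -> int:
        return int(self.roi_mask.sum())


def find_structures(mask: BinaryMask, min_structure_area_px: int = 500) -> list[Structure]:
    """8-connected components of the cleaned mask with area >= the minimum.

    Small particles (candidate foci) fall below the area cutoff and never
    influence the anatomy.
    """
    if min_structure_area_px < 1:
        raise ParameterError("min_structure_area_px must be >= 1")
    pixels = np.asarray(mask.pixels, dtype=bool)
    labels, n = ndimage.label(pixels, structure=_STRUCT8)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())
    width = pixels.shape[1]
    rows = np.arange(pixels.shape[0])[:, None]
    out: list[Structure] = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        area = int(areas[lab])
        if area < min_structure_area_px:
            continue
        sl = slices[lab - 1]
        sub = labels[sl] == lab
        r0, c0 = sl[0].start, sl[1].start
        col_top = np.full(width, np.nan)
        col_bottom = np.full(width, np.nan)
        present = sub.any(axis=0)
        sub_rows = rows[: sub.shape[0]]
        top = np.where(present, sub.argmax(axis=0), 0)
        bottom = np.where(present, sub.shape[0] - 1 - sub[::-1].argmax(axis=0), 0)
        cols = np.nonzero(present)[0] + c0
        col_top[cols] = top[present] + r0
        col_bottom[cols] = bottom[present] + r0
        out.append(Structure(
            label=lab,
            area_px=area,
            bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            col_top=col_top,
            col_bottom=col_bottom,
        ))
    return out


def identify_cornea(structures: list[Structure], width_px: int) -> Structure:
    """Pick the anterior-most structure spanning at least half the width.

    Its per-column bottom extent is the posterior corneal boundary.  Raises
    a segmentation failure when no structure spans >= 50 % of the width,
    which mirrors rejecting an unusable scan.
    """
    if not structures:
        raise SegmentationError("identify_cornea", "no structures found")
    candidates = [s for s in structures if s.span_cols >= 0.5 * width_px]
    if not candidates:
        raise SegmentationError("identify_cornea", "no cornea found (no structure spans half the image width)")
    return min(candidates, key=lambda s: float(np.nanmean(s.col_top)))


def trace_iris_lens_boundary(structures: list[Structure], cornea: Structure,
                             interp: str = "linear") -> np.ndarray:
    """Per-column anterior iris / anterior lens capsule boundary.

    For each column, the minimum top extent over all non-cornea structures
    lying below the posterior corneal boundary at that column.  Interior
    gaps (the pupillary space when the lens capsule reflects faintly) are
    filled by ``linear`` or ``pchip`` interpolation between the nearest
    defined columns; columns outside the outermost defined columns stay NaN.
    """
    if interp not in ("linear", "pchip"):
        raise ParameterError(f"unknown interpolation {interp!r}")
    width = cornea.col_top.shape[0]
    boundary = np.full(width, np.nan)
    for s in structures:
        if s is cornea or s.label == cornea.label:
            continue
        below = s.col_top > cornea.col_bottom  # NaN comparisons are False
        cand = np.where(below, s.col_top, np.nan)
        boundary = np.fmin(boundary, cand)
    defined = np.nonzero(~np.isnan(boundary))[0]
    if defined.size < 2:
        raise SegmentationError("trace_iris_lens_boundary",
                                "no iris/lens found (fewer than 2 defined columns)")
    first, last = defined[0], defined[-1]
    interior = np.arange(first, last + 1)
    if interp == "linear":
        filled = np.interp(interior, defined, boundary[defined])
    else:
        filled = PchipInterpolator(defined, boundary[defined])(interior)
    out = np.full(width, np.nan)
    out[interior] = filled
    return out


def build_roi(posterior_cornea_row: np.ndarray, anterior_iris_lens_row: np.ndarray,
              margin_px: int, shape: tuple[int, int],
              cornea: Structure | None = None) -> ACSegmentation:
    """Assemble the ROI and outside-cornea background masks.

    Per column the ROI is the open band
    ``(posterior_cornea_row + margin, anterior_iris_lens_row - margin)``;
    the background is everything strictly above the cornea's top extent
    minus a ``margin_px`` guard band.  Any pixel belonging to a large
    structure is excluded from the ROI as a safety net (the bands exclude
    them by construction in well-formed scans).
    """
    h, w = shape
    rows = np.arange(h)[:, None]
    post = np.asarray(posterior_cornea_row, dtype=float)[None, :]
    ant = np.asarray(anterior_iris_lens_row, dtype=float)[None, :]
    valid = ~np.isnan(post) & ~np.isnan(ant)
    roi = valid & (rows > post + margin_px) & (rows < ant - margin_px)
    if cornea is not None:
        top = np.asarray(cornea.col_top, dtype=float)[None, :]
        background = ~np.isnan(top) & (rows < top - margin_px)
    else:
        background = np.zeros(shape, dtype=bool)
    if not roi.any():
        raise SegmentationError("build_roi", "empty ROI (boundaries cross everywhere)")
    background &= ~roi
    return ACSegmentation(
        posterior_cornea_row=np.asarray(posterior_cornea_row, dtype=float),
        anterior_iris_lens_row=np.asarray(anterior_iris_lens_row, dtype=float),
        roi_mask=roi,
        background_mask=background,
        roi_margin_px=margin_px,
    )


def segment_scan(mask: BinaryMask, params: SegmentationParams | None = None) -> ACSegmentation:
    """Full AC segmentation from a cleaned binary mask."""
    params = params or SegmentationParams()
    structures = find_structures(mask, params.min_structure_area_px)
    cornea = identify_cornea(structures, mask.pixels.shape[1])
    iris = trace_iris_lens_boundary(structures, cornea, params.interp)
    seg = build_roi(cornea.col_bottom, iris, params.roi_margin_px,
                    mask.pixels.shape, cornea=cornea)
    # invariant: the ROI contains no pixel of any large structure
    for s in structures:
        cols = np.nonzero(s.cols_present)[0]
        top = s.col_top[cols].astype(int)
        bottom = s.col_bottom[cols].astype(int)
        for c, t, b in zip(cols, top, bottom):
            if seg.roi_mask[t:b + 1, c].any():
                sub = mask.pixels[t:b + 1, c]
                seg.roi_mask[t:b + 1, c] &= ~sub
    return seg
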