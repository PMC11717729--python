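"""HRF detection and counting inside the anterior-chamber ROI.

The background speckle level is estimated as the mean gray value of the
region outside (above) the cornea, which contains only speckle noise.
Candidate particles are connected components of the cleaned binary mask
restricted to the ROI; a particle is counted as a hyper-reflective focus
when its area lies within configured bounds and its peak source-image
intensity exceeds the background mean (optionally plus k standard
deviations).  The whole chain composing preprocessing, segmentation and
counting is exposed as :func:`count_scan` and is fully deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError, SegmentationError
from .io import BScan, Focus, HRFResult
from .preprocess import BinaryMask, PreprocessParams, preprocess
from .segmentation import ACSegmentation, SegmentationParams, segment_scan

__all__ = [
    "DetectionParams",
    "Particle",
    "estimate_background",
    "extract_particles",
    "filter_and_count",
    "count_scan",
    "params_digest",
]

_CONNECTIVITY = {
    8: np.ones((3, 3), dtype=bool),
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


@dataclass
class DetectionParams:
    """Particle filter configuration.

    ``min_area_px=2`` encodes the manual counting rule's size clause
    conservatively (set 1 to count any supra-threshold signal);
    ``max_area_px`` excludes large artifacts such as fibrin strands or
    boundary bleed.  ``intensity_rule='mean_out'`` is the literal rule —
    peak intensity strictly above the outside-cornea mean — and pins
    ``k_sd`` to 0; ``mean_plus_k_sd`` raises the bar by ``k_sd`` background
    standard deviations.
    """

    min_area_px: int = 2
    max_area_px: int = 50
    connectivity: int = 8
    intensity_rule: str = "mean_out"  # mean_out | mean_plus_k_sd
    k_sd: float = 0.0

    def __post_init__(self):
        if not (1 <= self.min_area_px <= self.max_area_px):
            raise ParameterError("need 1 <= min_area_px <= max_area_px")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.intensity_rule not in ("mean_out", "mean_plus_k_sd"):
            raise ParameterError(f"unknown intensity rule {self.intensity_rule!r}")
        if self.intensity_rule == "mean_out":
            self.k_sd = 0.0

    @property
    def structure(self) -> np.ndarray:
        return _CONNECTIVITY[self.connectivity]


@dataclass
class Particle:
    """A candidate connected component inside the ROI."""

    centroid_row: float
    centroid_col: float
    area_px: int
    rows: np.ndarray
    cols: np.ndarray


def estimate_background(scan: BScan, seg: ACSegmentation) -> tuple[float, float]:
    """Mean and SD of source-image gray levels over the outside-cornea region."""
    bg = np.asarray(seg.background_mask, dtype=bool)
    if bg.shape != scan.pixels.shape:
        raise SegmentationError("estimate_background", "background mask shape mismatch")
    values = scan.pixels[bg]
    if values.size == 0:
        raise SegmentationError("estimate_background", "empty background mask")
    return float(values.mean()), float(values.std())


def extract_particles(mask: BinaryMask, seg: ACSegmentation,
                      params: DetectionParams | None = None) -> list[Particle]:
    """Connected components of ``mask AND roi_mask``.

    A component that touches the ROI border is retained iff its centroid
    (rounded to the nearest pixel) lies inside the ROI — this prevents
    double counting of foci split by the ROI margin.
    """
    params = params or DetectionParams()
    roi = np.asarray(seg.roi_mask, dtype=bool)
    if roi.shape != mask.pixels.shape:
        raise SegmentationError("extract_particles", "mask and segmentation shapes differ")
    inter = mask.pixels & roi
    labels, n = ndimage.label(inter, structure=params.structure)
    particles: list[Particle] = []
    if n == 0:
        return particles
    all_rows, all_cols = np.nonzero(labels)
    order = np.argsort(labels[all_rows, all_cols], kind="stable")
    all_rows, all_cols = all_rows[order], all_cols[order]
    labs = labels[all_rows, all_cols]
    boundaries = np.searchsorted(labs, np.arange(1, n + 2))
    for lab in range(1, n + 1):
        rows = all_rows[boundaries[lab - 1]:boundaries[lab]]
        cols = all_cols[boundaries[lab - 1]:boundaries[lab]]
        cr = float(rows.mean())
        cc = float(cols.mean())
        if not roi[int(round(cr)), int(round(cc))]:
            continue
        particles.append(Particle(cr, cc, int(rows.size), rows, cols))
    return particles


def filter_and_count(particles: list[Particle], scan: BScan,
                     mu_out: float, sd_out: float,
                     params: DetectionParams | None = None,
                     binarization_threshold: int = 0,
                     roi_area_px: int = 0,
                     digest: str = "") -> HRFResult:
    """Apply the size and intensity rules and tally the final HRF count.

    Intensity uses the PEAK of the source (pre-blur) image within the
    component, which is robust to partial-volume dimming of two-pixel foci.
    """
    params = params or DetectionParams()
    cutoff = mu_out + params.k_sd * sd_out
    foci: list[Focus] = []
    for p in particles:
        if not (params.min_area_px <= p.area_px <= params.max_area_px):
            continue
        values = scan.pixels[p.rows, p.cols]
        peak = int(values.max())
        if peak <= cutoff:
            continue
        foci.append(Focus(
            centroid_row=p.centroid_row,
            centroid_col=p.centroid_col,
            area_px=p.area_px,
            peak_intensity=peak,
            mean_intensity=float(values.mean()),
        ))
    foci.sort(key=lambda f: (f.centroid_row, f.centroid_col))
    return HRFResult(
        count=len(foci),
        foci=foci,
        background_mean=mu_out,
        binarization_threshold=binarization_threshold,
        roi_area_px=roi_area_px,
        params_digest=digest,
    )


def params_digest(pre: PreprocessParams, det: DetectionParams,
                  seg: SegmentationParams) -> str:
    """Stable short digest of the full parameter set, for provenance."""
    payload = {"preprocess": asdict(pre), "detection": asdict(det),
               "segmentation": asdict(seg)}
    raw = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(raw).hexdigest()[:16]


def count_scan(scan: BScan,
               pre: PreprocessParams | None = None,
               det: DetectionParams | None = None,
               seg_params: SegmentationParams | None = None
               ) -> tuple[HRFResult, ACSegmentation]:
    """Fully automated count for one B-scan.

    Composes blur -> Triangle threshold -> binarize -> morphological cleanup
    -> AC segmentation -> background estimate -> particle extraction ->
    size/intensity filter.  Segmentation failures propagate with the stage
    name; everything else is deterministic given the scan and parameters.
    """
    pre = pre or PreprocessParams()
    det = det or DetectionParams()
    seg_params = seg_params or SegmentationParams()
    _, mask = preprocess(scan, pre)
    seg = segment_scan(mask, seg_params)
    mu_out, sd_out = estimate_background(scan, seg)
    particles = extract_particles(mask, seg, det)
    result = filter_and_count(
        particles, scan, mu_out, sd_out, det,
        binarization_threshold=mask.threshold_used,
        roi_area_px=seg.roi_area_px,
        digest=params_digest(pre, det, seg_params),
    )
    return result, seg
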