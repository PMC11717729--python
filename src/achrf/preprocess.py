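"""Denoise–binarize–clean front end.

The pipeline smooths speckle with an isotropic Gaussian blur, binarizes with
the Triangle (Zack) threshold on the 256-bin histogram, and cleans residual
single-pixel speckle with a small binary opening.  Everything here is
deterministic; there is no randomness anywhere in the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import InvariantError, ParameterError
from .io import BScan

__all__ = [
    "PreprocessParams",
    "BinaryMask",
    "gaussian_blur",
    "triangle_threshold",
    "binarize",
    "morph_clean",
    "preprocess",
]


@dataclass
class PreprocessParams:
    """Tunable front-end parameters.

    ``gaussian_sigma_px`` should not exceed the focus radius, or neighbouring
    foci merge.  The default opening uses the plus-shaped 3x3 element: after
    blurring, speckle exceedances are spatially correlated and survive as
    compact 2x2 blocks, which a 2x2-square opening preserves by construction;
    the cross removes them, while any real blurred focus bright enough to
    clear the threshold is round and at least three pixels wide and passes.
    """

    gaussian_sigma_px: float = 1.0
    hist_bins: int = 256
    morph_op: str = "open"          # none | open | close
    morph_element: str = "cross3"   # square2 | cross3 | square3

    def __post_init__(self):
        if self.gaussian_sigma_px < 0:
            raise ParameterError("gaussian_sigma_px must be >= 0")
        if self.hist_bins != 256:
            raise ParameterError("hist_bins must be 256 for 8-bit input")
        if self.morph_op not in ("none", "open", "close"):
            raise ParameterError(f"unknown morph_op {self.morph_op!r}")
        if self.morph_element not in _ELEMENTS:
            raise ParameterError(f"unknown morph_element {self.morph_element!r}")


@dataclass
class BinaryMask:
    pixels: np.ndarray  # 2-D bool
    threshold_used: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise InvariantError("mask must be 2-D")


def gaussian_blur(scan: BScan, sigma_px: float) -> BScan:
    """Isotropic Gaussian smoothing with reflective boundary handling.

    sigma 0 returns the input unchanged; otherwise the smoothed image is
    re-quantized to [0, 255] by rounding.
    """
    if sigma_px < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma_px == 0:
        return scan
    out = ndimage.gaussian_filter(scan.pixels.astype(np.float64), sigma_px, mode="reflect")
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return BScan(out, scan.lateral_mm_per_px, scan.axial_mm_per_px, scan.source_id)


def triangle_threshold(scan: BScan | np.ndarray) -> int:
    """Triangle (Zack) threshold on the 256-bin gray-level histogram.

    Locates the histogram peak and the farthest nonempty bin on the
    longer-tail side (ties between the two sides go to the bright side,
    since foci are bright on a dark aqueous background), then returns the
    bin between them that maximizes the perpendicular distance from the
    histogram to the peak-to-tail chord.  If several bins attain the maximal
    distance the one closest to the peak wins; a single-bin histogram
    returns that bin.

    The argmax of the perpendicular distance equals the argmax of the
    (integer) cross product of the chord vector with the peak-to-bin vector,
    so the computation is exact.
    """
    pixels = scan.pixels if isinstance(scan, BScan) else np.asarray(scan)
    if pixels.size == 0:
        raise ParameterError("cannot threshold an empty image")
    hist = np.bincount(pixels.ravel().astype(np.int64), minlength=256)
    nonzero = np.nonzero(hist)[0]
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    peak = int(np.argmax(hist))
    if lo == hi:
        return lo
    # longer-tail side; ties go bright
    if (peak - lo) > (hi - peak):
        tail = lo
    else:
        tail = hi
    if abs(tail - peak) <= 1:
        return peak
    step = 1 if tail > peak else -1
    bins = np.arange(peak + step, tail, step, dtype=np.int64)
    # |cross((tail-peak, h[tail]-h[peak]), (b-peak, h[b]-h[peak]))|, exact ints
    dx = np.int64(tail - peak)
    dy = hist[tail] - hist[peak]
    cross = np.abs(dx * (hist[bins] - hist[peak]) - dy * (bins - peak))
    best = cross.max()
    candidates = bins[cross == best]
    # closest to the peak; bins are ordered outward from the peak already
    return int(candidates[0])


def binarize(scan: BScan, threshold: int) -> BinaryMask:
    """Pixel true iff its gray level is strictly above ``threshold``."""
    if not (0 <= threshold <= 255):
        raise ParameterError("threshold must be in [0, 255]")
    return BinaryMask(scan.pixels > threshold, int(threshold))


_ELEMENTS = {
    "square2": np.ones((2, 2), dtype=bool),
    "cross3": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    "square3": np.ones((3, 3), dtype=bool),
}


def morph_clean(mask: BinaryMask, op: str = "open", element: str = "square2") -> BinaryMask:
    """Binary opening/closing with a named structuring element; ``none`` is identity."""
    if op == "none":
        return BinaryMask(mask.pixels.copy(), mask.threshold_used)
    if op not in ("open", "close"):
        raise ParameterError(f"unknown morphology op {op!r}")
    try:
        struct = _ELEMENTS[element]
    except KeyError:
        raise ParameterError(f"unknown structuring element {element!r}") from None
    fn = ndimage.binary_opening if op == "open" else ndimage.binary_closing
    return BinaryMask(fn(mask.pixels, structure=struct), mask.threshold_used)


def preprocess(scan: BScan, params: PreprocessParams | None = None) -> tuple[BScan, BinaryMask]:
    """Run blur -> Triangle threshold -> binarize -> morphological cleanup.

    Returns the blurred scan and the cleaned binary mask (with the threshold
    it used).
    """
    params = params or PreprocessParams()
    blurred = gaussian_blur(scan, params.gaussian_sigma_px)
    t = triangle_threshold(blurred)
    mask = binarize(blurred, t)
    return blurred, morph_clean(mask, params.morph_op, params.morph_element)
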