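"""Synthetic anterior-segment B-scan phantoms with known ground truth.

A phantom renders, top to bottom: a speckle-only air region, a bright
corneal band between two concentric downward-convex circular arcs, a dark
aqueous (anterior chamber) with speckle, bright iris bands left and right
of a central pupillary gap, and a thin bright anterior-lens-capsule arc
spanning the gap.  Hyper-reflective foci are implanted in the aqueous as
isotropic Gaussian intensity bumps with known count, position, size and
peak, mimicking the point-spread blur of individual cells.

Speckle is modelled as a Rayleigh-distributed additive noise floor in air
and aqueous (heavy-tailed and non-negative, like OCT speckle) and Gaussian
jitter on the tissue bands.  The iris bands stop short of the corneal
periphery by a small angle gap so that cornea and iris remain separate
connected components, as they appear in a usable line scan.

Everything is deterministic given ``seed``: the same spec yields a
byte-identical image, and increasing ``focus_count`` by one leaves the
anatomy, the noise and the previously placed foci untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError, PlacementError
from .io import BScan

__all__ = [
    "PhantomSpec",
    "TrueFocus",
    "PhantomTruth",
    "generate_phantom",
    "sample_cohort",
    "DEFAULT_GRADE_PROFILE",
    "rayleigh_mean",
    "rayleigh_sd",
]


def rayleigh_mean(scale: float) -> float:
    """Mean of a Rayleigh distribution with the given scale."""
    return scale * math.sqrt(math.pi / 2.0)


def rayleigh_sd(scale: float) -> float:
    """Standard deviation of a Rayleigh distribution with the given scale."""
    return scale * math.sqrt(2.0 - math.pi / 2.0)


@dataclass
class PhantomSpec:
    """Geometry, noise and focus parameters of one synthetic B-scan.

    All lengths are in pixels.  The defaults emulate a 14 mm line scan taken
    just below the corneal apex: a thin bright cornea high in the frame, a
    deep dark chamber, and an iris plane with a central pupillary gap
    bridged by the anterior lens capsule.
    """

    height_px: int = 512
    width_px: int = 768
    cornea_anterior_apex_row: int = 40
    cornea_thickness_px: int = 35
    cornea_anterior_radius_px: float = 420.0
    cornea_posterior_radius_px: float = 380.0
    ac_depth_px: int = 170
    pupil_halfwidth_px: int = 110
    iris_thickness_px: int = 30
    tissue_mean: float = 200.0
    tissue_sd: float = 15.0
    noise_scale: float = 8.0
    focus_count: int = 0
    focus_radius_px: float = 1.0
    focus_peak: float = 180.0
    min_focus_separation_px: float = 8.0
    seed: int = 0
    # secondary geometry (anterior lens capsule arc and angle recess)
    lens_radius_px: float = 600.0
    lens_thickness_px: int = 4
    lens_apex_drop_px: int = 2
    angle_gap_px: int = 12
    placement_margin_px: float | None = None

    def __post_init__(self):
        if min(self.height_px, self.width_px) <= 0:
            raise ParameterError("image dimensions must be positive")
        if self.focus_count < 0:
            raise ParameterError("focus_count must be non-negative")
        if (self.cornea_anterior_apex_row + self.cornea_thickness_px
                + self.ac_depth_px >= self.height_px):
            raise ParameterError("cornea band plus chamber depth must fit above the image bottom")
        if self.focus_peak <= 2.0 * rayleigh_mean(self.noise_scale):
            raise ParameterError("focus_peak must exceed twice the expected speckle mean")
        if self.min_focus_separation_px < 0 or self.focus_radius_px <= 0:
            raise ParameterError("focus geometry must be positive")

    @property
    def iris_top_row(self) -> int:
        return self.cornea_anterior_apex_row + self.cornea_thickness_px + self.ac_depth_px

    @property
    def effective_placement_margin(self) -> int:
        if self.placement_margin_px is not None:
            return int(math.ceil(self.placement_margin_px))
        # clear of the rendered bump window (4 sigma) plus boundary bloom
        return int(math.ceil(4.0 * self.focus_radius_px)) + 2


@dataclass
class TrueFocus:
    row: int
    col: int
    radius_px: float
    peak: float


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom image."""

    foci: list[TrueFocus]
    ac_mask: np.ndarray          # true aqueous between posterior cornea and iris/lens
    countable_flags: np.ndarray  # per focus: satisfies the manual-count rule
    tissue_mask: np.ndarray      # cornea | iris | lens pixels
    air_mask: np.ndarray         # speckle-only region above the anterior cornea


def _arc_rows(spec: PhantomSpec, radius: float, apex_row: float) -> np.ndarray:
    """Row of a downward-convex circular arc per column (NaN where undefined)."""
    cc = (spec.width_px - 1) / 2.0
    off = np.arange(spec.width_px) - cc
    inside = np.abs(off) < radius
    rows = np.full(spec.width_px, np.nan)
    rows[inside] = apex_row + radius - np.sqrt(radius ** 2 - off[inside] ** 2)
    return rows


def _geometry(spec: PhantomSpec):
    """Tissue masks and per-column chamber boundaries for a spec."""
    h, w = spec.height_px, spec.width_px
    cc = (w - 1) / 2.0
    off = np.abs(np.arange(w) - cc)
    rows = np.arange(h)[:, None]

    ant = _arc_rows(spec, spec.cornea_anterior_radius_px, spec.cornea_anterior_apex_row)
    post = _arc_rows(spec, spec.cornea_posterior_radius_px,
                     spec.cornea_anterior_apex_row + spec.cornea_thickness_px)
    cornea_cols = ~np.isnan(ant) & ~np.isnan(post)
    ant_c = np.where(cornea_cols, ant, np.nan)
    post_c = np.where(cornea_cols, post, np.nan)
    cornea = cornea_cols[None, :] & (rows >= ant_c[None, :]) & (rows <= post_c[None, :])

    iris_top = spec.iris_top_row
    iris_cols = (off > spec.pupil_halfwidth_px) & cornea_cols \
        & (post_c + spec.angle_gap_px < iris_top)
    iris = iris_cols[None, :] & (rows >= iris_top) \
        & (rows < iris_top + spec.iris_thickness_px)

    lens_cols = off <= spec.pupil_halfwidth_px + 2  # overlap the iris by 2 columns
    lens_row = _arc_rows(spec, spec.lens_radius_px, iris_top + spec.lens_apex_drop_px)
    lens_row = np.where(lens_cols, lens_row, np.nan)
    lens = lens_cols[None, :] & (rows >= lens_row[None, :]) \
        & (rows < lens_row[None, :] + spec.lens_thickness_px)

    tissue = cornea | iris | lens

    bottom = np.full(w, np.nan)
    pupil = off <= spec.pupil_halfwidth_px
    bottom[pupil] = lens_row[pupil]
    bottom[iris_cols] = float(iris_top)
    ac = (rows > post_c[None, :]) & (rows < bottom[None, :])  # NaN compares False

    air = cornea_cols[None, :] & (rows < ant_c[None, :])
    return cornea, iris, lens, tissue, ac, air


def _place_foci(spec: PhantomSpec, ac_mask: np.ndarray,
                rng: np.random.Generator) -> list[tuple[int, int]]:
    margin = spec.effective_placement_margin
    if margin > 0:
        y, x = np.ogrid[-margin:margin + 1, -margin:margin + 1]
        disk = (y ** 2 + x ** 2) <= margin ** 2
        allowed = ndimage.binary_erosion(ac_mask, structure=disk)
    else:
        allowed = ac_mask
    idx = np.argwhere(allowed)
    if idx.size == 0 and spec.focus_count > 0:
        raise PlacementError(spec.focus_count, 0)
    placed: list[tuple[int, int]] = []
    max_attempts = 200 * spec.focus_count + 1000
    attempts = 0
    min_sep2 = spec.min_focus_separation_px ** 2
    pos = np.empty((spec.focus_count, 2))
    while len(placed) < spec.focus_count and attempts < max_attempts:
        attempts += 1
        r, c = idx[int(rng.integers(len(idx)))]
        if placed:
            d2 = ((pos[: len(placed), 0] - r) ** 2 + (pos[: len(placed), 1] - c) ** 2).min()
            if d2 < min_sep2:
                continue
        pos[len(placed)] = (r, c)
        placed.append((int(r), int(c)))
    if len(placed) < spec.focus_count:
        raise PlacementError(spec.focus_count, len(placed))
    return placed


def generate_phantom(spec: PhantomSpec) -> tuple[BScan, PhantomTruth]:
    """Render a phantom B-scan and its ground truth.

    Byte-identical for identical specs.  The anatomy and noise fields are
    drawn from dedicated random substreams so that changing ``focus_count``
    alters the image only within the added foci's footprints.
    """
    ss = np.random.SeedSequence(spec.seed)
    noise_rng, place_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    h, w = spec.height_px, spec.width_px

    cornea, iris, lens, tissue, ac_mask, air_mask = _geometry(spec)

    # full-size noise fields keep the streams independent of geometry
    speckle = noise_rng.rayleigh(scale=spec.noise_scale, size=(h, w))
    jitter = noise_rng.standard_normal(size=(h, w))
    img = speckle.copy()
    img[tissue] = spec.tissue_mean + spec.tissue_sd * jitter[tissue]

    centers = _place_foci(spec, ac_mask, place_rng)
    win = int(math.ceil(4.0 * spec.focus_radius_px))
    two_s2 = 2.0 * spec.focus_radius_px ** 2
    dy, dx = np.ogrid[-win:win + 1, -win:win + 1]
    bump = spec.focus_peak * np.exp(-(dy ** 2 + dx ** 2) / two_s2)
    for r, c in centers:
        r0, r1 = max(0, r - win), min(h, r + win + 1)
        c0, c1 = max(0, c - win), min(w, c + win + 1)
        img[r0:r1, c0:c1] += bump[r0 - (r - win):r1 - (r - win),
                                  c0 - (c - win):c1 - (c - win)]

    # manual-count rule on the rendered (pre-clip) image:
    # brighter than background noise (3 sd above the speckle mean) OR
    # covering more than two detectable pixels
    bg_mu = rayleigh_mean(spec.noise_scale)
    bg_sd = rayleigh_sd(spec.noise_scale)
    cut = bg_mu + 3.0 * bg_sd
    flags = np.zeros(len(centers), dtype=bool)
    for i, (r, c) in enumerate(centers):
        bright = img[r, c] >= cut
        detectable_area = int((bump >= cut - bg_mu).sum())
        flags[i] = bright or detectable_area > 2

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    scan = BScan(
        pixels=pixels,
        lateral_mm_per_px=14.0 / w,
        axial_mm_per_px=7.0 / h,
        source_id=f"phantom-seed{spec.seed}-n{spec.focus_count}",
    )
    truth = PhantomTruth(
        foci=[TrueFocus(r, c, spec.focus_radius_px, spec.focus_peak) for r, c in centers],
        ac_mask=ac_mask,
        countable_flags=flags,
        tissue_mask=tissue,
        air_mask=air_mask,
    )
    return scan, truth


# Per-SUN-grade automated-count profile of a representative uveitis cohort at
# desk scale (60 eyes): medians near 2 / 10 / 22 / 27 / 128 / 474 with
# IQR-like spread at the lower grades.
DEFAULT_GRADE_PROFILE: list[tuple[float, int, tuple]] = [
    (0.0, 28, ("uniform", 0, 4)),
    (0.5, 12, ("uniform", 6, 15)),
    (1.0, 10, ("uniform", 15, 33)),
    (2.0, 4, ("uniform", 24, 30)),
    (2.0, 2, ("constant", 120)),
    (3.0, 3, ("uniform", 107, 149)),
    (4.0, 1, ("constant", 474)),
]


def _draw_count(dist, rng: np.random.Generator) -> int:
    if callable(dist):
        return int(dist(rng))
    if isinstance(dist, (int, np.integer)):
        return int(dist)
    kind = dist[0]
    if kind == "constant":
        return int(dist[1])
    if kind == "uniform":
        return int(rng.integers(int(dist[1]), int(dist[2]) + 1))
    if kind == "poisson":
        return int(rng.poisson(float(dist[1])))
    raise ParameterError(f"unknown count distribution {dist!r}")


def sample_cohort(grade_profile: list[tuple[float, int, tuple]], seed: int,
                  base_spec: PhantomSpec | None = None
                  ) -> list[tuple[PhantomSpec, float]]:
    """One phantom spec per synthetic eye, counts drawn per SUN grade.

    ``grade_profile`` is a list of ``(sun_grade, n_eyes, count_distribution)``
    where the distribution is a constant int, ``("constant", v)``,
    ``("uniform", lo, hi)`` (inclusive), ``("poisson", lam)`` or a callable
    taking a Generator.  Reproducible given ``seed``.
    """
    if not grade_profile:
        raise ParameterError("grade profile must not be empty")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[tuple[PhantomSpec, float]] = []
    for grade, n_eyes, dist in grade_profile:
        for _ in range(int(n_eyes)):
            k = _draw_count(dist, rng)
            eye_seed = int(rng.integers(0, 2 ** 31))
            out.append((replace(base, focus_count=k, seed=eye_seed), float(grade)))
    return out
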