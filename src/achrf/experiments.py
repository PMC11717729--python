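"""Reproducible validation experiments on phantom cohorts.

Each function re-enacts, at desk scale and with known ground truth, one leg
of the validation a study of this kind performs on patient images: counting
agreement against a reference count, exact equivalence of the numerical
primitives with brute-force reference implementations, segmentation quality,
count specificity/sensitivity, statistical-model recovery, and end-to-end
determinism.  Everything is driven by a single integer seed.
"""

from __future__ import annotations

import hashlib
import io
import json
import math
from collections import deque
from dataclasses import asdict
from fractions import Fraction

import imageio.v3 as iio
import numpy as np

from .detection import DetectionParams, count_scan, extract_particles
from .phantom import (DEFAULT_GRADE_PROFILE, PhantomSpec, generate_phantom,
                      sample_cohort)
from .preprocess import BinaryMask, gaussian_blur, preprocess, triangle_threshold
from .segmentation import ACSegmentation, find_structures, segment_scan
from .stats import EyeRecord, compare_groups, grade_model, icc_agreement, pearson
from .stats import grade_to_step

__all__ = [
    "cohort_agreement",
    "oracle_equivalence",
    "segmentation_quality",
    "count_recovery",
    "statistics_recovery",
    "group_separation_power",
    "determinism_check",
]

_GRADES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def cohort_agreement(seed: int, profile=None) -> dict:
    """Automated counts vs ground truth over a graded phantom cohort.

    Mirrors the manual-vs-automated agreement design: one phantom per
    synthetic eye with per-grade count distributions, agreement summarized
    by the two-way mixed-model ICC (method and grade fixed, subject random)
    and the Pearson coefficient.
    """
    cohort = sample_cohort(profile or DEFAULT_GRADE_PROFILE, seed)
    truth_counts, auto_counts, grades = [], [], []
    for spec, grade in cohort:
        scan, truth = generate_phantom(spec)
        result, _ = count_scan(scan)
        truth_counts.append(int(truth.countable_flags.sum()))
        auto_counts.append(result.count)
        grades.append(grade)
    adjusted = icc_agreement(truth_counts, auto_counts, grades)
    unadjusted = icc_agreement(truth_counts, auto_counts)
    return {
        "n_eyes": len(cohort),
        "icc": adjusted.icc,
        "icc_unadjusted": unadjusted.icc,
        "pearson_r": adjusted.pearson_r,
        "total_abs_error": int(np.abs(np.array(auto_counts) - np.array(truth_counts)).sum()),
    }


def _triangle_bruteforce(hist) -> int:
    """Exhaustive chord-distance search with exact rational arithmetic."""
    hist = [int(v) for v in hist]
    nz = [i for i, v in enumerate(hist) if v > 0]
    lo, hi = nz[0], nz[-1]
    peak = max(range(len(hist)), key=lambda i: (hist[i], -i))
    if lo == hi:
        return lo
    tail = lo if (peak - lo) > (hi - peak) else hi
    if abs(tail - peak) <= 1:
        return peak
    x1, y1, x2, y2 = peak, hist[peak], tail, hist[tail]
    denom = (x2 - x1) ** 2 + (y2 - y1) ** 2
    step = 1 if tail > peak else -1
    best_d2, best_b = Fraction(-1), peak
    for b in range(peak + step, tail, step):
        cross = (x2 - x1) * (hist[b] - y1) - (y2 - y1) * (b - x1)
        d2 = Fraction(cross * cross, denom)
        if d2 > best_d2:
            best_d2, best_b = d2, b
    return best_b


def _flood_fill(mask: np.ndarray) -> set[frozenset]:
    """8-connected components by breadth-first flood fill."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1),
               (-1, -1), (-1, 1), (1, -1), (1, 1)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = set()
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                queue = deque([(i, j)])
                seen[i, j] = True
                comp = []
                while queue:
                    r, c = queue.popleft()
                    comp.append((r, c))
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                comps.add(frozenset(comp))
    return comps


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    """A 256-bin histogram with a dark peak and a sparse bright tail."""
    hist = np.zeros(256, dtype=np.int64)
    peak = int(rng.integers(3, 60))
    hist[peak] = int(rng.integers(5_000, 60_000))
    sparse = rng.random(256) < 0.4
    hist[sparse] += rng.integers(0, 200, size=int(sparse.sum()))
    width = int(rng.integers(3, 20))
    lo, hi = max(0, peak - width), min(255, peak + width)
    hist[lo:hi] += rng.integers(100, 3000, size=hi - lo)
    return hist


def oracle_equivalence(seed: int, n_histograms: int = 1000, n_masks: int = 1000) -> dict:
    """Exact agreement of the numerical primitives with brute force.

    The Triangle threshold is compared against an exhaustive max-distance
    search on random histograms, and ROI particle labeling against a
    flood-fill labeling of random binary masks; both must agree exactly.
    """
    rng = _rng(seed)
    triangle_mismatches = 0
    for _ in range(n_histograms):
        hist = random_histogram(rng)
        values = np.repeat(np.arange(256, dtype=np.uint8), hist)
        pad = (-values.size) % 256
        if pad:
            values = np.concatenate(
                [values, np.full(pad, int(np.argmax(hist)), dtype=np.uint8)])
        img = values.reshape(-1, 256)
        got = triangle_threshold(img)
        expected = _triangle_bruteforce(np.bincount(img.ravel(), minlength=256))
        triangle_mismatches += int(got != expected)

    label_mismatches = 0
    full_roi = ACSegmentation(
        posterior_cornea_row=np.zeros(64), anterior_iris_lens_row=np.full(64, 64.0),
        roi_mask=np.ones((64, 64), dtype=bool),
        background_mask=np.zeros((64, 64), dtype=bool))
    params = DetectionParams(min_area_px=1, max_area_px=64 * 64)
    for _ in range(n_masks):
        density = rng.uniform(0.2, 0.55)
        pixels = rng.random((64, 64)) < density
        particles = extract_particles(BinaryMask(pixels, 0), full_roi, params)
        got = {frozenset(zip(p.rows.tolist(), p.cols.tolist())) for p in particles}
        label_mismatches += int(got != _flood_fill(pixels))
    return {
        "n_histograms": n_histograms,
        "triangle_mismatches": triangle_mismatches,
        "n_masks": n_masks,
        "label_mismatches": label_mismatches,
    }


def segmentation_quality(seed: int, n_scans: int = 50) -> dict:
    """Cornea detection rate, ROI IoU vs truth and structure exclusion."""
    rng = _rng(seed)
    found = 0
    ious = []
    structure_violations = 0
    for _ in range(n_scans):
        spec = PhantomSpec(focus_count=10, seed=int(rng.integers(0, 2 ** 31)))
        scan, truth = generate_phantom(spec)
        try:
            _, mask = preprocess(scan)
            seg = segment_scan(mask)
        except Exception:
            ious.append(0.0)
            continue
        found += 1
        inter = (seg.roi_mask & truth.ac_mask).sum()
        union = (seg.roi_mask | truth.ac_mask).sum()
        ious.append(float(inter) / float(union))
        for s in find_structures(mask):
            cols = np.nonzero(s.cols_present)[0]
            for c in cols:
                lo, hi = int(s.col_top[c]), int(s.col_bottom[c]) + 1
                if (seg.roi_mask[lo:hi, c] & mask.pixels[lo:hi, c]).any():
                    structure_violations += 1
                    break
    ious = np.array(ious)
    return {
        "n_scans": n_scans,
        "cornea_found_rate": 100.0 * found / n_scans,
        "roi_iou_median": float(np.median(ious)),
        "roi_iou_pass_rate": 100.0 * float(np.mean(ious >= 0.90)),
        "structure_violations": structure_violations,
    }


def count_recovery(seed: int, n_zero: int = 50, n_increment: int = 100) -> dict:
    """Specificity on empty chambers and unit response to one extra focus."""
    rng = _rng(seed)
    zero_exact = 0
    for _ in range(n_zero):
        spec = PhantomSpec(focus_count=0, seed=int(rng.integers(0, 2 ** 31)))
        scan, _ = generate_phantom(spec)
        zero_exact += int(count_scan(scan)[0].count == 0)
    increment_exact = 0
    for _ in range(n_increment):
        s = int(rng.integers(0, 2 ** 31))
        base = count_scan(generate_phantom(PhantomSpec(focus_count=10, seed=s))[0])[0]
        plus = count_scan(generate_phantom(PhantomSpec(focus_count=11, seed=s))[0])[0]
        increment_exact += int(plus.count - base.count == 1)
    return {
        "n_zero": n_zero,
        "zero_count_rate": 100.0 * zero_exact / n_zero,
        "n_increment": n_increment,
        "increment_exact_rate": 100.0 * increment_exact / n_increment,
    }


def statistics_recovery(seed: int, n_reps: int = 200) -> dict:
    """Known-answer checks for the agreement and grade-model statistics."""
    rng = _rng(seed)
    x = rng.normal(20, 8, size=12)
    icc_identity = icc_agreement(x, x).icc

    # closed form vs an independent ANOVA decomposition on random data
    max_anova_diff = 0.0
    for _ in range(50):
        a = rng.normal(20, 8, size=10)
        b = a + rng.normal(0, 1, size=10)
        got = icc_agreement(a, b).icc
        v = np.stack([a, b])
        grand = v.mean()
        msr = 2 * ((v.mean(axis=0) - grand) ** 2).sum() / 9
        mse = ((v - v.mean(axis=0) - v.mean(axis=1)[:, None] + grand) ** 2).sum() / 9
        sb2 = (msr - mse) / 2
        max_anova_diff = max(max_anova_diff, abs(got - sb2 / (sb2 + mse)))

    # noiseless slope of 38 counts per grade step
    records = [EyeRecord(f"p{i}", "OD", "uveitis", _GRADES[i % 6],
                         5 + 38 * grade_to_step(_GRADES[i % 6]),
                         age_years=float(rng.integers(10, 70)), sex="FM"[i % 2])
               for i in range(24)]
    slope_noiseless = grade_model(records, "raw").slope_per_grade

    # constructed multiplicative effect of +293 % per grade step
    b_log = math.log(3.93)
    records = [EyeRecord(f"p{i}", "OD", "uveitis", _GRADES[i % 6],
                         max(0, round(math.exp(2.5 + b_log * grade_to_step(_GRADES[i % 6])) - 1)),
                         age_years=50.0, sex="F")
               for i in range(30)]
    pct_change = grade_model(records, "log1p").pct_change_per_grade

    # parameter recovery from the mixed model's own generative process
    target_slope = 10.0
    slopes = []
    for _ in range(n_reps):
        recs = []
        for i in range(30):
            b = rng.normal(0, 4.0)
            g = _GRADES[int(rng.integers(0, 6))]
            age = float(rng.uniform(10, 70))
            sex = "FM"[int(rng.integers(0, 2))]
            eyes = ["OD", "OS"] if rng.random() < 0.6 else ["OD"]
            for eye in eyes:
                mu = 30 + target_slope * grade_to_step(g) + b + rng.normal(0, 3.0)
                recs.append(EyeRecord(f"p{i}", eye, "uveitis", g,
                                      max(0, round(mu)), age_years=age, sex=sex))
        slopes.append(grade_model(recs, "raw").slope_per_grade)
    slopes = np.array(slopes)
    mc_se = float(slopes.std(ddof=1) / np.sqrt(n_reps))
    return {
        "icc_identity": float(icc_identity),
        "anova_max_abs_diff": float(max_anova_diff),
        "slope_noiseless": float(slope_noiseless),
        "pct_change_constructed": float(pct_change),
        "recovery_target_slope": target_slope,
        "recovery_mean_slope": float(slopes.mean()),
        "recovery_mc_se": mc_se,
        "recovery_n_reps": n_reps,
    }


def group_separation_power(seed: int, n_reps: int = 200,
                           n_uveitis: int = 40, n_control: int = 20) -> dict:
    """Detection of a quiet-uveitis vs control difference (medians 2 vs 0).

    Counts are Poisson with rates chosen so the group medians and IQRs
    match clinically quiet uveitic eyes (median 2, IQR 0-4) and healthy
    controls (median 0, IQR 0-1); the rejection rate at alpha 0.05 over
    simulated cohorts is reported.
    """
    rng = _rng(seed)
    rejections = 0
    for _ in range(n_reps):
        recs = []
        for i in range(n_uveitis):
            recs.append(EyeRecord(f"u{i}", "OD", "uveitis", 0, int(rng.poisson(2.4)),
                                  age_years=float(rng.uniform(10, 70)),
                                  sex="FM"[int(rng.integers(0, 2))]))
        for i in range(n_control):
            recs.append(EyeRecord(f"c{i}", "OD", "control", 0, int(rng.poisson(0.6)),
                                  age_years=float(rng.uniform(10, 70)),
                                  sex="FM"[int(rng.integers(0, 2))]))
        _, p = compare_groups(recs)
        rejections += int(p < 0.05)
    return {
        "n_reps": n_reps,
        "rejection_rate": 100.0 * rejections / n_reps,
    }


def determinism_check(seed: int) -> dict:
    """Byte-identical phantom renders and identical result JSON."""
    spec = PhantomSpec(focus_count=20, seed=seed % (2 ** 31))
    digests = []
    for _ in range(2):
        scan, _ = generate_phantom(spec)
        buf = io.BytesIO()
        iio.imwrite(buf, scan.pixels, extension=".png")
        digests.append(hashlib.sha256(buf.getvalue()).hexdigest())
    scan, _ = generate_phantom(spec)
    results = []
    for _ in range(2):
        result, _ = count_scan(scan)
        payload = {"count": result.count,
                   "threshold": result.binarization_threshold,
                   "foci": [asdict(f) for f in result.foci]}
        results.append(hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest())
    return {
        "phantom_bytes_identical": int(digests[0] == digests[1]),
        "result_json_identical": int(results[0] == results[1]),
    }
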