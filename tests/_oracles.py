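"""Independent reference implementations used only by the tests.

These deliberately re-derive results through a different route than the
package: the Triangle threshold by an exact brute-force chord-distance
search with arbitrary-precision arithmetic, and connected components by a
breadth-first flood fill.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction

import numpy as np


def triangle_bruteforce(hist: np.ndarray) -> int:
    """Exhaustive max-chord-distance search over all histogram bins.

    Same geometric dialect as the pipeline (longer-tail side, ties bright;
    distance ties resolved toward the peak) but evaluated bin by bin with
    exact rational squared distances.
    """
    hist = [int(v) for v in hist]
    nz = [i for i, v in enumerate(hist) if v > 0]
    lo, hi = nz[0], nz[-1]
    peak = max(range(len(hist)), key=lambda i: (hist[i], -i))
    if lo == hi:
        return lo
    tail = lo if (peak - lo) > (hi - peak) else hi
    if abs(tail - peak) <= 1:
        return peak
    x1, y1 = peak, hist[peak]
    x2, y2 = tail, hist[tail]
    denom = (x2 - x1) ** 2 + (y2 - y1) ** 2
    step = 1 if tail > peak else -1
    best_d2 = Fraction(-1)
    best_b = peak
    for b in range(peak + step, tail, step):
        cross = (x2 - x1) * (hist[b] - y1) - (y2 - y1) * (b - x1)
        d2 = Fraction(cross * cross, denom)
        if d2 > best_d2:  # strict: first (closest-to-peak) wins ties
            best_d2 = d2
            best_b = b
    return best_b


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> set[frozenset]:
    """Connected components as a set of pixel-index frozensets (BFS)."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
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
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                comps.add(frozenset(comp))
    return comps


def scipy_label_components(mask: np.ndarray, connectivity: int = 8) -> set[frozenset]:
    """Partition induced by scipy's labeling, in the same set-of-sets form."""
    from scipy import ndimage

    struct = np.ones((3, 3), bool) if connectivity == 8 else \
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    labels, n = ndimage.label(mask, structure=struct)
    comps = set()
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        comps.add(frozenset(zip(rows.tolist(), cols.tolist())))
    return comps
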