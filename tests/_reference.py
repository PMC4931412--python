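"""Naive reference implementations used as independent oracles in tests.

These deliberately use plain double loops over patches/pixels rather
than any vectorised path from the package, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def naive_local_threshold(pixels: np.ndarray, window: int, contrast_min: int,
                          polarity: str = "dark") -> np.ndarray:
    """Per-patch midpoint threshold, written as the obvious double loop."""
    h, w = pixels.shape
    mask = np.zeros((h, w), dtype=bool)
    for r0 in range(0, h, window):
        for c0 in range(0, w, window):
            patch = pixels[r0:r0 + window, c0:c0 + window]
            lo, hi = int(patch.min()), int(patch.max())
            if hi - lo <= contrast_min:
                continue
            t = (hi + lo) / 2.0
            for i in range(patch.shape[0]):
                for j in range(patch.shape[1]):
                    v = patch[i, j]
                    if polarity == "dark":
                        hit = v < t
                    elif polarity == "bright":
                        hit = v > t
                    else:
                        below = int((patch < t).sum())
                        above = int((patch > t).sum())
                        hit = (v < t) if below <= above else (v > t)
                    if hit:
                        mask[r0 + i, c0 + j] = True
    return mask


def greedy_vs_bruteforce_best(truths, detections, max_dist):
    """All one-to-one assignments of two truths to two detections; returns
    the pairing a nearest-first greedy strategy must produce."""
    import itertools

    def dist(a, b):
        return float(np.hypot(a[0] - b[0], a[1] - b[1]))

    pairs = []
    used = set()
    cands = sorted(
        (dist(t, d), ti, di)
        for ti, t in enumerate(truths)
        for di, d in enumerate(detections)
        if dist(t, d) <= max_dist
    )
    for d, ti, di in cands:
        if any(ti == p[0] or di == p[1] for p in pairs):
            continue
        pairs.append((ti, di))
    return sorted(pairs)
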