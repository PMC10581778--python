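"""Independent brute-force oracles used by the test suite."""

from __future__ import annotations

import numpy as np


def brute_force_segmented_rss(x, y, k, min_seg_points=5):
    """Exhaustive, unoptimized segmented least squares over the observed grid.

    Independent oracle: for every admissible breakpoint (or ordered pair) at
    observed x values, builds the explicit continuous hinge design matrix
    and solves with lstsq; returns the minimum residual sum of squares.
    Segment membership: left segment x <= b, right segment x > b.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # standardize x for conditioning; RSS is invariant under the affine map
    xs = (xs - xs.mean()) / xs.std()
    n = len(xs)
    u = np.unique(xs)

    def rss_for(knots):
        cols = [np.ones_like(xs), xs] + [np.maximum(xs - b, 0.0) for b in knots]
        A = np.vstack(cols).T
        beta, *_ = np.linalg.lstsq(A, ys, rcond=None)
        r = ys - A @ beta
        return float(r @ r)

    def n_le(b):
        return int(np.searchsorted(xs, b, side="right"))

    if k == 0:
        return rss_for([])
    best = np.inf
    if k == 1:
        for b in u:
            if n_le(b) >= min_seg_points and n - n_le(b) >= min_seg_points:
                best = min(best, rss_for([b]))
        return best
    for i, b1 in enumerate(u):
        if n_le(b1) < min_seg_points:
            continue
        for b2 in u[i + 1 :]:
            if n_le(b2) - n_le(b1) < min_seg_points:
                continue
            if n - n_le(b2) < min_seg_points:
                continue
            best = min(best, rss_for([b1, b2]))
    return best
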