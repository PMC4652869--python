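"""Independent scalar oracles used to cross-check the vectorised library code.

Everything here is deliberately written in plain Python loops over scalars
(exhaustive all-pairs distances, explicit weight formula, hand-rolled
box counting) so that agreement with the numpy implementations is a real
two-implementation check rather than a tautology.  The only numpy calls are
elementwise ``np.exp`` (whose scalar and array paths are bit-identical) and
array construction.
"""

from __future__ import annotations

import numpy as np


def brute_force_forecast(library, library_targets, queries, k):
    """Scalar reference kNN cross-map forecaster.

    For every query row: accumulate squared distances to every library row
    coordinate by coordinate, pick the ``k`` closest rows (ties toward the
    lower library index), form ``exp(-(D - D_min))`` weights normalised over
    the neighbours, and combine the neighbours' target values.  Returns
    ``(neighbor_indices, squared_distances, weights, forecasts)`` as lists of
    lists / floats, matching the vectorised implementation bit for bit.
    """
    L = [[float(v) for v in row] for row in np.atleast_2d(library)]
    Q = [[float(v) for v in row] for row in np.atleast_2d(queries)]
    y = [float(v) for v in library_targets]
    all_idx, all_sq, all_w, all_fc = [], [], [], []
    for q in Q:
        dists = []
        for t, l in enumerate(L):
            s = 0.0
            for a, b in zip(q, l):
                d = a - b
                s = s + d * d
            dists.append((s, t))
        dists.sort(key=lambda p: (p[0], p[1]))
        nbrs = dists[:k]
        shift = nbrs[0][0]
        es = [float(np.exp(-(s - shift))) for s, _ in nbrs]
        den = es[0]
        for e in es[1:]:
            den = den + e
        ws = [e / den for e in es]
        fc = ws[0] * y[nbrs[0][1]]
        for w, (_, t) in zip(ws[1:], nbrs[1:]):
            fc = fc + w * y[t]
        all_idx.append([t for _, t in nbrs])
        all_sq.append([s for s, _ in nbrs])
        all_w.append(ws)
        all_fc.append(fc)
    return all_idx, all_sq, all_w, all_fc


def box_counting_dimension(points, scales):
    """Box-counting dimension of a low-dimensional point cloud.

    Counts occupied boxes of side ``eps`` for each scale and returns the
    least-squares slope of ``log N(eps)`` against ``log (1/eps)``.
    """
    pts = np.asarray(points, dtype=float)
    lo = pts.min(axis=0)
    counts = []
    for eps in scales:
        cells = {tuple(np.floor((p - lo) / eps).astype(int)) for p in pts}
        counts.append(len(cells))
    x = np.log(1.0 / np.asarray(scales, dtype=float))
    yv = np.log(np.asarray(counts, dtype=float))
    return float(np.polyfit(x, yv, 1)[0])


def fit_loglength_slope(lengths, values):
    """Least-squares slope of embeddedness against log library length."""
    x = np.log(np.asarray(lengths, dtype=float))
    return float(np.polyfit(x, np.asarray(values, dtype=float), 1)[0])
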