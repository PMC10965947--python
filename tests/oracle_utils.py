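"""Independent brute-force oracles used by the test suite.

Each function here re-derives a quantity from first principles by a route
deliberately different from the package implementation: exhaustive
enumeration instead of KD-trees, exact rational arithmetic instead of
floating-point formulas, crossing-number geometry instead of shapely.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def brute_force_match(ref_xy, pred_xy, radius):
    """Closest-first one-to-one matching by full enumeration.

    Enumerates every reference-prediction pair within the radius, then
    repeatedly scans for the globally smallest remaining distance (ties by
    (reference rank, prediction rank) under lexicographic (y, x) point
    order) and accepts it if both members are free.

    Returns the accepted pair set as frozenset of (ref index, pred index).
    """
    ref_xy = np.asarray(ref_xy, dtype=float)
    pred_xy = np.asarray(pred_xy, dtype=float)

    def lex_rank(xy):
        order = sorted(range(len(xy)), key=lambda i: (xy[i][1], xy[i][0]))
        rank = [0] * len(xy)
        for r, i in enumerate(order):
            rank[i] = r
        return rank

    rrank = lex_rank(ref_xy)
    prank = lex_rank(pred_xy)
    candidates = []
    for i in range(len(ref_xy)):
        for j in range(len(pred_xy)):
            d = math.hypot(ref_xy[i][0] - pred_xy[j][0], ref_xy[i][1] - pred_xy[j][1])
            if d <= radius:
                candidates.append((d, rrank[i], prank[j], i, j))
    accepted = []
    ref_free = set(range(len(ref_xy)))
    pred_free = set(range(len(pred_xy)))
    remaining = list(candidates)
    while remaining:
        best = min(remaining, key=lambda c: (c[0], c[1], c[2]))
        remaining.remove(best)
        _, _, _, i, j = best
        if i in ref_free and j in pred_free:
            accepted.append((i, j))
            ref_free.discard(i)
            pred_free.discard(j)
    return frozenset(accepted)


def even_odd_inside(px, py, ring, eps=1e-9):
    """Even-odd (crossing number) point-in-polygon; boundary counts inside."""
    n = len(ring)
    # Boundary check: distance to each segment.
    for k in range(n):
        x1, y1 = ring[k]
        x2, y2 = ring[(k + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        t = 0.0 if seg2 == 0 else max(0.0, min(1.0, ((px - x1) * dx + (py - y1) * dy) / seg2))
        cx, cy = x1 + t * dx, y1 + t * dy
        if math.hypot(px - cx, py - cy) <= eps:
            return True
    inside = False
    for k in range(n):
        x1, y1 = ring[k]
        x2, y2 = ring[(k + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def weighted_kappa_exact(table, linear=True):
    """Weighted Cohen's kappa on an integer contingency table, in exact rationals.

    ``table[i][j]`` counts cases rated i by rater A and j by rater B.
    Linear agreement weights ``w_ij = 1 - |i-j|/(k-1)``; chance agreement
    from the product of marginals. Returns a ``Fraction``.
    """
    k = len(table)
    n = sum(sum(row) for row in table)
    w = [
        [
            Fraction(1) - Fraction(abs(i - j), k - 1) if linear and k > 1 else Fraction(int(i == j))
            for j in range(k)
        ]
        for i in range(k)
    ]
    po = sum(w[i][j] * Fraction(table[i][j], n) for i in range(k) for j in range(k))
    pa = [Fraction(sum(table[i]), n) for i in range(k)]
    pb = [Fraction(sum(table[i][j] for i in range(k)), n) for j in range(k)]
    pe = sum(w[i][j] * pa[i] * pb[j] for i in range(k) for j in range(k))
    return (po - pe) / (1 - pe)


def icc_2_1_manual(matrix):
    """ICC(2,1) by an explicit two-way ANOVA table computed step by step.

    Returns (icc, msr, msc, mse) using plain Python loops and sums — an
    arithmetic route independent of the vectorized implementation.
    """
    rows = [list(map(float, r)) for r in matrix]
    n = len(rows)
    k = len(rows[0])
    total = sum(v for r in rows for v in r)
    grand = total / (n * k)
    row_means = [sum(r) / k for r in rows]
    col_means = [sum(rows[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((v - grand) ** 2 for r in rows for v in r)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return icc, msr, msc, mse


def f1_by_point_enumeration(counts):
    """Per-class F1 recomputed from enumerated point-level outcomes.

    ``counts`` is a 4x4 integer confusion array over
    (neg, pos, other, background). The events are expanded into an explicit
    list of (reference label, prediction label) outcomes; per-class TP, FP
    and FN are then counted by iterating over that list, and F1 computed as
    2TP / (2TP + FP + FN). Returns a dict class-index -> F1 (or None when
    undefined).
    """
    events = []
    for i in range(4):
        for j in range(4):
            events.extend([(i, j)] * int(counts[i][j]))
    out = {}
    for c in range(3):
        tp = sum(1 for r, p in events if r == c and p == c)
        fp = sum(1 for r, p in events if p == c and r != c)
        fn = sum(1 for r, p in events if r == c and p != c)
        denom = 2 * tp + fp + fn
        out[c] = None if denom == 0 else 2 * tp / denom
    return out
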