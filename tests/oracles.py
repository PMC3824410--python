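"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (O(m^2) loops, exhaustive maxima) and
shares no code with the package.
"""

import numpy as np


def bh_stepup_bruteforce(p):
    """Benjamini-Hochberg q-values by the literal step-up definition:
    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = []
        for rank_j, jdx in enumerate(order, start=1):
            if rank_j >= rank_i:
                candidates.append(p[jdx] * m / rank_j)
        q[idx] = min(1.0, min(candidates))
    return q


def ks_two_sample_bruteforce(x, y):
    """Two-sample KS statistic as the exhaustive max CDF gap over all jump
    points of either sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gaps = []
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        gaps.append(abs(fx - fy))
    return max(gaps)


def ks_one_sample_uniform_bruteforce(x):
    """One-sample KS statistic against Uniform[0,1]: the sup over jump points
    of |F_n - t|, evaluated just before and at each jump."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    d = 0.0
    for i, t in enumerate(x, start=1):
        d = max(d, abs(i / n - t), abs((i - 1) / n - t))
    return d


def silhouette_bruteforce(points, labels):
    """Per-point silhouette widths by direct definition with plain loops."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = len(points)
    uniq = sorted(set(labels.tolist()))
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        own_others = [j for j in range(n) if labels[j] == own and j != i]
        if not own_others:
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in own_others])
        b = min(
            np.mean(
                [np.linalg.norm(points[i] - points[j]) for j in range(n) if labels[j] == lab]
            )
            for lab in uniq
            if lab != own
        )
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return s
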