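"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately written with plain Python loops and no shared code with the
package implementations they validate.
"""

import itertools
import math


def tfce_brute(z, E=0.5, H=2.0, dh=0.01):
    """Double loop over threshold heights and contiguous supra-threshold
    runs, both signs."""
    z = list(map(float, z))
    m = len(z)
    out = [0.0] * m
    for sign in (1.0, -1.0):
        zz = [sign * v for v in z]
        zmax = max(zz)
        if zmax <= 0:
            continue
        n_steps = int(math.floor(zmax / dh + 1e-12))
        for i in range(1, n_steps + 1):
            h = i * dh
            sup = [v >= h for v in zz]
            for j in range(m):
                if not sup[j]:
                    continue
                lo = j
                while lo > 0 and sup[lo - 1]:
                    lo -= 1
                hi = j
                while hi < m - 1 and sup[hi + 1]:
                    hi += 1
                out[j] += (hi - lo + 1) ** E * h**H * dh
    return out


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def mannwhitney_exact_p(a, b):
    """Two-sided exact p by full enumeration of label assignments."""
    a, b = list(a), list(b)
    m, n = len(a), len(b)
    ranks = _midranks(a + b)
    mu = m * n / 2.0
    u_obs = sum(ranks[:m]) - m * (m + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for combo in itertools.combinations(range(m + n), m):
        u = sum(ranks[i] for i in combo) - m * (m + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def _binom_pmf(k, n, p):
    if p <= 0.0:
        return 1.0 if k == 0 else 0.0
    if p >= 1.0:
        return 1.0 if k == n else 0.0
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def barnard_brute_p(table, grid_step=0.001):
    """Exhaustive-outcome, nuisance-grid oracle for Barnard's test
    (pooled Wald statistic, columns fixed)."""

    def wald(x1, x2, c1, c2):
        pool = (x1 + x2) / (c1 + c2)
        var = pool * (1.0 - pool) * (1.0 / c1 + 1.0 / c2)
        if var <= 0:
            return 0.0
        return (x1 / c1 - x2 / c2) / math.sqrt(var)

    (a, b), (c, d) = table
    c1, c2 = a + c, b + d
    if c1 == 0 or c2 == 0:
        return 1.0
    t_obs = abs(wald(a, b, c1, c2))
    rejecting = [
        (x1, x2)
        for x1 in range(c1 + 1)
        for x2 in range(c2 + 1)
        if abs(wald(x1, x2, c1, c2)) >= t_obs - 1e-12
    ]
    best = 0.0
    steps = int(round(1.0 / grid_step))
    for g in range(1, steps):
        pi = g * grid_step
        tail = sum(
            _binom_pmf(x1, c1, pi) * _binom_pmf(x2, c2, pi) for x1, x2 in rejecting
        )
        best = max(best, tail)
    return min(1.0, best)


def medoid_brute(curves):
    """Brute-force medoid index by summed mean point-to-point distance."""
    best_i, best_val = -1, float("inf")
    for i, ci in enumerate(curves):
        total = 0.0
        for cj in curves:
            total += sum(
                math.dist(p, q) for p, q in zip(ci.tolist(), cj.tolist())
            ) / len(ci)
        if total < best_val:
            best_i, best_val = i, total
    return best_i
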