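"""Independent brute-force reference implementations used as test oracles.

Every function here is written in the most literal, loop-heavy way possible
and shares no code with the package: definitional step-up BH, explicit
hypergeometric enumeration for Fisher tails, a textbook DP Levenshtein,
scalar-loop ambient statistics, double-loop energy distance, and an
exhaustive scan for the dynamic read threshold.
"""

from __future__ import annotations

import math

import numpy as np


def bh_bruteforce(p: list[float]) -> list[float]:
    """O(m^2) step-up definition: q_i = min over p_(j) >= p_i of
    p_(j) * m / rank(j), clipped to 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for pos, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1)
            for j in range(pos, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """P(top-left cell = a) for fixed margins (r1, r2 rows; c1 first col)."""
    return (math.comb(r1, a) * math.comb(r2, c1 - a)) / math.comb(r1 + r2, c1)


def fisher_p_enumeration(a: int, b: int, c: int, d: int,
                         alternative: str = "two-sided") -> float:
    """Exact Fisher p by explicit enumeration of the hypergeometric support."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = hypergeom_pmf(a, r1, r2, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom_pmf(x, r1, r2, c1)
        if alternative == "two-sided":
            if px <= p_obs * (1 + 1e-12):
                total += px
        elif alternative == "greater":
            if x >= a:
                total += px
        elif alternative == "less":
            if x <= a:
                total += px
    return min(1.0, total)


def levenshtein_dp(s: str, t: str) -> int:
    """Textbook dynamic-programming edit distance."""
    n, m = len(s), len(t)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (s[i - 1] != t[j - 1]),
            )
        prev = cur
    return prev[m]


def collapse_oracle(umis: list[tuple[str, int]],
                    max_ed: int = 2) -> dict[str, int]:
    """Greedy count-descending directional merge, scalar reference."""
    ordered = sorted(umis, key=lambda x: (-x[1], x[0]))
    reps: list[str] = []
    out: dict[str, int] = {}
    for umi, n in ordered:
        for rep in reps:
            if levenshtein_dp(umi, rep) <= max_ed:
                out[rep] += n
                break
        else:
            reps.append(umi)
            out[umi] = n
    return out


def ambient_scores_scalar(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scalar-loop p_g / MSE_i / E[MSE_i] evaluation."""
    n_cells, G = X.shape
    total = X.sum()
    p = [X[:, g].sum() / total for g in range(G)]
    mse = np.zeros(n_cells)
    emse = np.zeros(n_cells)
    for i in range(n_cells):
        n_i = X[i].sum()
        acc = 0.0
        eacc = 0.0
        for g in range(G):
            acc += (X[i, g] - p[g] * n_i) ** 2
            eacc += n_i * p[g] * (1 - p[g])
        mse[i] = acc / G
        emse[i] = eacc / G
    return np.array(p), mse, emse


def energy_distance_loops(X: np.ndarray, Y: np.ndarray,
                          squared: bool = True) -> float:
    """Double-loop e-distance with self-pairs excluded within groups."""
    def d(u, v):
        s = float(((u - v) ** 2).sum())
        return s if squared else math.sqrt(s)

    nx, ny = len(X), len(Y)
    between = sum(d(x, y) for x in X for y in Y) / (nx * ny)
    wx = sum(d(X[i], X[j]) for i in range(nx) for j in range(nx) if i != j)
    wy = sum(d(Y[i], Y[j]) for i in range(ny) for j in range(ny) if i != j)
    return 2 * between - wx / (nx * (nx - 1)) - wy / (ny * (ny - 1))


def dynamic_threshold_scan(read_counts: list[int], max_loss: float) -> int:
    """Exhaustive scan over every candidate threshold."""
    total = sum(read_counts)
    best = 1
    for k in range(1, max(read_counts) + 2):
        lost = sum(r for r in read_counts if r < k)
        if lost / total <= max_loss:
            best = k
    return best
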