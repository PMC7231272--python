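"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: per-offset rescoring with Python
loops, exact tail sums from log-factorials, full permutation enumeration,
subset enumeration for k-cores.  None of it shares code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_scan(seq: str, log_odds: np.ndarray, threshold: float
                     ) -> list[tuple[int, str, float]]:
    """Exhaustive per-offset scoring on both strands; skips windows with N."""
    L = log_odds.shape[0]
    hits = []
    for strand in "+-":
        for off in range(len(seq) - L + 1):
            window = seq[off:off + L]
            if strand == "-":
                window = revcomp(window)
            if "N" in window:
                continue
            score = sum(log_odds[i, _IDX[b]] for i, b in enumerate(window))
            if score >= threshold:
                hits.append((off, strand, score))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def fisher_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the hypergeometric law of the 2x2 table's margins."""
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n_total, row1)
    total = 0
    for x in range(a, min(row1, col1) + 1):
        if col1 - x <= n_total - row1 >= 0 and row1 - x >= 0:
            total += math.comb(col1, x) * math.comb(n_total - col1, row1 - x)
    return total / denom


def binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct term summation of the binomial pmf in log space."""
    if k <= 0:
        return 1.0
    if p <= 0:
        return 0.0
    log_p, log_q = math.log(p), math.log1p(-p)
    total = 0.0
    for x in range(k, n + 1):
        log_term = (math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
                    + x * log_p + (n - x) * log_q)
        term = math.exp(log_term)
        total += term
        if x > n * p and term < 1e-18 * max(total, 1e-300):
            break
    return min(total, 1.0)


def mannwhitney_exact(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free data)."""
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yj in ys if xi > yj)

    u_obs = u_stat(x, y)
    mu = nx * ny / 2.0
    count = total = 0
    for combo in itertools.combinations(range(nx + ny), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(nx + ny) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return float(u_obs), count / total


def mcode_weight_subsets(adjacency: dict) -> dict:
    """Node weights by subset enumeration over each closed neighbourhood.

    k_max is the largest k for which some subset of N[v] induces minimum
    degree >= k; the weight is k_max times the closed-neighbourhood density
    (0 when no subset achieves k >= 2).
    """
    weights = {}
    for v, nbrs in adjacency.items():
        nodes = sorted(set(nbrs) | {v})
        n = len(nodes)
        edges = [(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1:]
                 if y in adjacency[x]]
        k_max = 0
        for r in range(2, n + 1):
            for subset in itertools.combinations(nodes, r):
                sset = set(subset)
                degs = [sum(1 for y in adjacency[x] if y in sset) for x in subset]
                k_max = max(k_max, min(degs))
        if k_max < 2:
            weights[v] = 0.0
        else:
            density = 2 * len(edges) / (n * (n - 1)) if n > 1 else 0.0
            weights[v] = k_max * density
    return weights
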