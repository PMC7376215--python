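"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: direct-definition BH,
exact-fraction hypergeometric tails, golden-section NB likelihood
maximization, naive average-linkage agglomeration, and direct enumeration
of the induced-transcript rule.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.optimize import minimize_scalar


def bh_direct(pvalues: np.ndarray) -> np.ndarray:
    """O(m^2) Benjamini-Hochberg from the definition q_i = min_{p_k >= p_i} p_k*m/rank_k."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = np.empty(m)
    for i in range(m):
        q[i] = min(ranked[k] * m / (k + 1) for k in range(i, m))
        q[i] = min(q[i], 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def hypergeom_upper_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational arithmetic."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(total)


def nb_loglik_group(q: float, y: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """NB log-likelihood of one group's counts at group mean parameter q (Var = mu + alpha mu^2)."""
    mu = s * q
    if alpha < 1e-12:
        return float(np.sum(y * np.log(mu) - mu))
    r = 1.0 / alpha
    return float(
        sum(
            math.lgamma(yi + r) - math.lgamma(r)
            + yi * math.log(mui / (mui + r))
            + r * math.log(r / (mui + r))
            for yi, mui in zip(y, mu)
        )
    )


def brute_force_log2fc(
    y: np.ndarray, size_factors: np.ndarray, alpha: float, indicator: np.ndarray
) -> float:
    """MLE log2 fold change by per-group scalar likelihood maximization.

    The two-level NB GLM factorizes into independent per-group mean
    parameters, each maximized here by bounded scalar search.
    """
    qs = []
    for level in (0, 1):
        mask = indicator == level
        yg, sg = y[mask], size_factors[mask]
        naive = max(float(np.mean(yg / sg)), 1e-6)
        res = minimize_scalar(
            lambda q: -nb_loglik_group(q, yg, sg, alpha),
            bounds=(naive / 100.0, naive * 100.0 + 1.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        qs.append(res.x)
    return float(np.log2(qs[1] / qs[0]))


def average_linkage_merges(points: np.ndarray) -> list[float]:
    """Naive agglomerative average linkage; returns sorted merge heights."""
    clusters: list[list[int]] = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, 0, 1)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean(
                        [
                            np.linalg.norm(points[i] - points[j])
                            for i in clusters[a]
                            for j in clusters[b]
                        ]
                    )
                )
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def induced_rule_enumeration(
    exposed: dict[str, float], control: dict[str, float], ratio_threshold: float
) -> set[str]:
    """Direct enumeration of the induced-transcript rule over all transcripts."""
    out = set()
    for tid, lfc in exposed.items():
        if tid not in control:
            out.add(tid)
        elif (2.0**lfc) / (2.0 ** control[tid]) > ratio_threshold:
            out.add(tid)
    return out
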