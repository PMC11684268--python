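"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the
libraries) they validate: exact rational hypergeometric enumeration for
Fisher/ORA p-values, a literal step-up loop for BH, a naive running-sum
loop for the GSEA enrichment score, and boolean-matrix powers for graph
neighborhoods.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table margins, by exact enumeration."""
    N = a + b + c + d
    n = a + b
    K = a + c
    total = Fraction(0)
    for x in range(a, min(n, K) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


def bh_step_up(p: list[float]) -> list[float]:
    """Literal Benjamini-Hochberg definition: sort, scale, cummin from the top."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = min(running, 1.0)
    return adj


def running_sum_es(features, scores, gene_set, exponent: float):
    """Naive weighted running sum; returns (ES, full running sum list)."""
    gene_set = set(gene_set)
    hits = [f in gene_set for f in features]
    n_hit = sum(hits)
    N = len(features)
    weights = [abs(s) ** exponent if h else 0.0 for s, h in zip(scores, hits)]
    total = sum(weights)
    run, cur = [], 0.0
    for h, w in zip(hits, weights):
        if h:
            cur += (w / total) if total > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (N - n_hit)
        run.append(cur)
    es = max(run, key=abs)
    return es, run


def nodes_within_hops(adjacency: np.ndarray, start: int, radius: int) -> set[int]:
    """Reachable node indices within ``radius`` hops via boolean matrix powers."""
    current = np.zeros(len(adjacency), dtype=bool)
    current[start] = True
    reach = current.copy()
    for _ in range(radius):
        reach |= (adjacency.T @ reach) > 0
    reach[start] = False
    return set(np.where(reach)[0])
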