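"""Independent brute-force oracles used to pin down expected values.

These are deliberately written without reference to the package internals
(no Biopython, no sklearn): quadratic DP for local alignment, shortest
ancestor paths for DAG semantic weights, and pair counting for AUC.
"""

import itertools

import numpy as np


def sw_dp(a: str, b: str, match: float = 2.0, mismatch: float = -1.0,
          gap: float = -1.0) -> float:
    """Smith-Waterman best local alignment score, plain quadratic DP."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + sub,
                          H[i - 1][j] + gap,
                          H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best


def semantic_weights_oracle(parent_edges, disease, theta=0.5):
    """Contribution of every ancestor term via shortest upward paths.

    With a constant decay theta < 1, the max-over-children recursion
    equals theta ** (shortest number of child->parent steps from the
    disease to the term), which we compute by breadth-first search.
    """
    up = {}
    for c, p in parent_edges:
        up.setdefault(c, set()).add(p)
    dist = {disease: 0}
    frontier = [disease]
    while frontier:
        nxt = []
        for node in frontier:
            for p in up.get(node, ()):
                if p not in dist:
                    dist[p] = dist[node] + 1
                    nxt.append(p)
        frontier = nxt
    return {t: theta ** d for t, d in dist.items()}


def semantic_similarity_oracle(parent_edges, d1, d2, theta=0.5):
    w1 = semantic_weights_oracle(parent_edges, d1, theta)
    w2 = semantic_weights_oracle(parent_edges, d2, theta)
    shared = set(w1) & set(w2)
    denom = sum(w1.values()) + sum(w2.values())
    return sum(w1[t] + w2[t] for t in shared) / denom


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))
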