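"""Reliable-negative selection by positive-unlabelled learning.

Only positive piRNA-disease pairs are ever curated; every other pair is
unlabelled, not negative.  Three classic PU strategies pick pairs that are
safe to treat as negatives during training:

* spy       -- hide a fraction of positives among the unlabelled; pairs
               scoring below every spy are reliable negatives,
* bagging   -- many bootstrap forests score out-of-bag unlabelled pairs;
               the middle cluster of averaged scores is returned,
* two-step  -- iterative relabelling against the score range of the
               current positives.

The combined selector takes the union of the three.  A pair is featurized
as the concatenation of its piRNA's fused-similarity row and its
disease's fused-similarity row (length m + n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .config import RunConfig


@dataclass
class ReliableNegativeSet:
    """Index pairs judged safe to use as negatives, with per-method provenance."""

    pairs: set
    provenance: dict = field(default_factory=dict)   # pair -> set of method names

    def __post_init__(self) -> None:
        self.pairs = {tuple(p) for p in self.pairs}
        if not self.provenance:
            self.provenance = {p: set() for p in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    @classmethod
    def from_pairs(cls, pairs, method: str) -> "ReliableNegativeSet":
        pairs = {tuple(p) for p in pairs}
        return cls(pairs=pairs, provenance={p: {method} for p in pairs})


class PairFeatureMap:
    """Features of pair (i, j): [S_p row i || S_d row j], length m + n."""

    def __init__(self, S_p: np.ndarray, S_d: np.ndarray):
        self.S_p = np.asarray(S_p, dtype=float)
        self.S_d = np.asarray(S_d, dtype=float)

    def rows(self, pairs: Sequence[tuple]) -> np.ndarray:
        pairs = list(pairs)
        if not pairs:
            return np.empty((0, self.S_p.shape[1] + self.S_d.shape[1]))
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        if ii.min() < 0 or ii.max() >= self.S_p.shape[0] \
                or jj.min() < 0 or jj.max() >= self.S_d.shape[0]:
            raise IndexError("pair index out of range")
        return np.hstack([self.S_p[ii], self.S_d[jj]])


def pair_features(S_p: np.ndarray, S_d: np.ndarray,
                  pairs: Sequence[tuple]) -> np.ndarray:
    """Feature matrix for the given pairs (one row per pair)."""
    return PairFeatureMap(S_p, S_d).rows(pairs)


def _fit_rf(X: np.ndarray, y: np.ndarray, n_estimators: int,
            seed: int) -> RandomForestClassifier:
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1)
    rf.fit(X, y)
    return rf


def _proba(rf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    return rf.predict_proba(X)[:, list(rf.classes_).index(1)]


# ---------------------------------------------------------------------------
# spy


def spy_select(positives: Sequence[tuple], unlabelled: Sequence[tuple],
               feats: PairFeatureMap, config: RunConfig,
               seed: int = 0) -> ReliableNegativeSet:
    """Spy technique: unlabelled pairs scoring below every spy's posterior.

    A random ``spy_frac`` of the positives is hidden among the unlabelled
    pool; a random forest is trained with the remaining positives against
    the whole pool (spies included), and the lowest spy posterior becomes
    the selection threshold.  The spies are only hidden inside this
    function; the caller's positive set is untouched.
    """
    positives, unlabelled = list(positives), list(unlabelled)
    if not unlabelled:
        return ReliableNegativeSet.from_pairs([], "spy")
    n_spies = math.ceil(config.spy_frac * len(positives))
    if n_spies == 0 or n_spies >= len(positives):
        raise ValueError(
            f"spy_frac={config.spy_frac} gives {n_spies} spies out of "
            f"{len(positives)} positives; adjust spy_frac")
    rng = np.random.default_rng(seed)
    spy_idx = rng.choice(len(positives), size=n_spies, replace=False)
    spy_mask = np.zeros(len(positives), dtype=bool)
    spy_mask[spy_idx] = True
    spies = [p for p, s in zip(positives, spy_mask) if s]
    rest = [p for p, s in zip(positives, spy_mask) if not s]

    X = np.vstack([feats.rows(rest), feats.rows(unlabelled), feats.rows(spies)])
    y = np.concatenate([np.ones(len(rest)),
                        np.zeros(len(unlabelled) + len(spies))])
    rf = _fit_rf(X, y, config.rf_estimators, seed)
    post_unl = _proba(rf, feats.rows(unlabelled))
    post_spy = _proba(rf, feats.rows(spies))
    threshold = post_spy.min()
    chosen = [p for p, s in zip(unlabelled, post_unl) if s < threshold]
    return ReliableNegativeSet.from_pairs(chosen, "spy")


# ---------------------------------------------------------------------------
# PU bagging


def _kmeans_1d(values: np.ndarray, k: int = 3, iters: int = 100) -> np.ndarray:
    """Deterministic 1-D k-means with quantile initialization; returns labels
    0..k-1 ordered by increasing centroid."""
    centroids = np.quantile(values, [(2 * i + 1) / (2 * k) for i in range(k)])
    labels = np.zeros(len(values), dtype=int)
    for _ in range(iters):
        d = np.abs(values[:, None] - centroids[None, :])
        new = d.argmin(axis=1)
        if (new == labels).all() and _ > 0:
            break
        labels = new
        for c in range(k):
            if (labels == c).any():
                centroids[c] = values[labels == c].mean()
    order = np.argsort(centroids)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]


def middle_cluster(pairs: Sequence[tuple], scores: np.ndarray) -> list:
    """Partition scores into three 1-D clusters and return the middle one.

    If the scores are degenerate (fewer than three distinct values, or an
    empty middle cluster), fall back to the lowest-score tertile and warn.
    """
    pairs = list(pairs)
    scores = np.asarray(scores, dtype=float)
    if len(pairs) < 3 or len(np.unique(scores)) < 3:
        warnings.warn("degenerate score distribution; returning lowest tertile")
        order = np.argsort(scores, kind="stable")
        return [pairs[i] for i in order[: max(1, len(pairs) // 3)]]
    labels = _kmeans_1d(scores, k=3)
    mid = [p for p, lab in zip(pairs, labels) if lab == 1]
    if not mid:
        warnings.warn("empty middle cluster; returning lowest tertile")
        order = np.argsort(scores, kind="stable")
        return [pairs[i] for i in order[: max(1, len(pairs) // 3)]]
    return mid


def bagging_select(positives: Sequence[tuple], unlabelled: Sequence[tuple],
                   feats: PairFeatureMap, config: RunConfig,
                   seed: int = 0) -> ReliableNegativeSet:
    """PU bagging: average out-of-bag forest scores, keep the middle cluster.

    Per round, ``n_bags`` bootstrap forests are each trained on all
    positives versus an equally-sized random draw of unlabelled pairs and
    score the pairs left out of their draw; scores are averaged within and
    then across ``bag_rounds`` rounds.
    """
    positives, unlabelled = list(positives), list(unlabelled)
    if len(unlabelled) < len(positives):
        raise ValueError("PU bagging needs at least as many unlabelled as positives")
    rng = np.random.default_rng(seed)
    X_pos = feats.rows(positives)
    X_unl = feats.rows(unlabelled)
    n_u, n_p = len(unlabelled), len(positives)
    round_means = []
    for r in range(config.bag_rounds):
        total = np.zeros(n_u)
        count = np.zeros(n_u)
        for b in range(config.n_bags):
            draw = rng.choice(n_u, size=n_p, replace=False)
            oob = np.setdiff1d(np.arange(n_u), draw)
            X = np.vstack([X_pos, X_unl[draw]])
            y = np.concatenate([np.ones(n_p), np.zeros(n_p)])
            rf = _fit_rf(X, y, config.bag_estimators,
                         seed=int(rng.integers(2 ** 31)))
            if oob.size:
                total[oob] += _proba(rf, X_unl[oob])
                count[oob] += 1
        never = count == 0
        if never.any():
            warnings.warn(f"{int(never.sum())} unlabelled pairs never out-of-bag; "
                          "imputing mean score")
            mean_scored = ((total[~never] / count[~never]).mean()
                           if (~never).any() else 0.5)
            total[never] = mean_scored
            count[never] = 1
        round_means.append(total / count)
    avg = np.mean(round_means, axis=0)
    chosen = middle_cluster(unlabelled, avg)
    return ReliableNegativeSet.from_pairs(chosen, "bagging")


# ---------------------------------------------------------------------------
# two-step


def two_step_select(positives: Sequence[tuple], unlabelled: Sequence[tuple],
                    feats: PairFeatureMap, config: RunConfig,
                    seed: int = 0) -> ReliableNegativeSet:
    """Two-step: iterative relabelling against the positive score range.

    All unlabelled pairs start labelled negative.  Each iteration trains a
    forest on the current labelling, scores everything, promotes unlabelled
    pairs scoring above the highest current-positive score (sticky: they
    never return to the output) and (re)labels those below the lowest
    current-positive score as negative.  After the final iteration, the
    pairs still labelled negative are the reliable negatives.
    """
    positives, unlabelled = list(positives), list(unlabelled)
    if not positives or not unlabelled:
        raise ValueError("two-step needs non-empty positive and unlabelled sets")
    X_pos = feats.rows(positives)
    X_unl = feats.rows(unlabelled)
    n_u = len(unlabelled)
    is_neg = np.ones(n_u, dtype=bool)       # current labelling of unlabelled
    promoted = np.zeros(n_u, dtype=bool)
    rng = np.random.default_rng(seed)
    for it in range(config.two_step_iters):
        X = np.vstack([X_pos, X_unl])
        y = np.concatenate([np.ones(len(positives)), (~is_neg).astype(float)])
        if y.all() or not y.any():
            break
        rf = _fit_rf(X, y, config.two_step_estimators,
                     seed=int(rng.integers(2 ** 31)))
        s_pos = _proba(rf, X_pos)
        cur_pos_scores = [s_pos]
        s_unl = _proba(rf, X_unl)
        if promoted.any():
            cur_pos_scores.append(s_unl[promoted])
        hi = max(s.max() for s in cur_pos_scores)
        lo = min(s.min() for s in cur_pos_scores)
        newly_promoted = (s_unl > hi) & ~promoted
        promoted |= newly_promoted
        is_neg[newly_promoted] = False
        demote = (s_unl < lo) & ~promoted
        is_neg[demote] = True
    final = is_neg & ~promoted
    if not final.any():
        warnings.warn("two-step relabelled every unlabelled pair positive")
    chosen = [p for p, keep in zip(unlabelled, final) if keep]
    return ReliableNegativeSet.from_pairs(chosen, "two_step")


# ---------------------------------------------------------------------------
# combination and dispatch


def combine_union(sets: Sequence[ReliableNegativeSet]) -> ReliableNegativeSet:
    """Set union of reliable-negative sets with merged provenance."""
    pairs: set = set()
    prov: dict = {}
    for s in sets:
        pairs |= s.pairs
        for p, methods in s.provenance.items():
            prov.setdefault(p, set()).update(methods)
    return ReliableNegativeSet(pairs=pairs, provenance=prov)


PUL_METHODS = ("none", "spy", "bagging", "two_step", "combined")


def select_negatives(method: str, positives, unlabelled, feats: PairFeatureMap,
                     config: RunConfig, seed: int = 0) -> ReliableNegativeSet:
    """Dispatch to one selector, their union, or 'none' (all unlabelled)."""
    if method not in PUL_METHODS:
        raise ValueError(f"unknown PU method {method!r}; choose from {PUL_METHODS}")
    if method == "none":
        return ReliableNegativeSet.from_pairs(unlabelled, "none")
    if method == "spy":
        return spy_select(positives, unlabelled, feats, config, seed)
    if method == "bagging":
        return bagging_select(positives, unlabelled, feats, config, seed)
    if method == "two_step":
        return two_step_select(positives, unlabelled, feats, config, seed)
    parts = [
        spy_select(positives, unlabelled, feats, config, seed),
        bagging_select(positives, unlabelled, feats, config, seed + 1),
        two_step_select(positives, unlabelled, feats, config, seed + 2),
    ]
    rns = combine_union(parts)
    overlap = rns.pairs & {tuple(p) for p in positives}
    if overlap:       # defensive; selectors only ever draw from unlabelled
        raise AssertionError("reliable negatives overlap known positives")
    return rns
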