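"""Cross-validation protocol, metrics and pipeline drivers.

Known positives and unlabelled pairs are each partitioned into five
seeded folds.  Within a fold, every training-time quantity -- the GIP
similarity matrices, the heterogeneous graph, the pair features used for
PU selection, and the training labels -- is computed from the adjacency
with the fold's test positives masked to zero, so no test information can
leak into training.  Metrics are ROC-AUC, area under the precision-recall
curve, and the rank index (mean normalized descending rank of the true
test positives among all test pairs; lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import RunConfig
from .io import AssociationDataset, DiseaseOntology
from .model import ModelInputs, prepare_inputs, train
from .pul import PairFeatureMap, select_negatives
from .seqembed import KmerVocab, tokenize_kmers, train_kmer_embeddings
from .similarity import (SimilarityMatrix, build_hetero, disease_similarity,
                         pirna_similarity, semantic_similarity, seq_similarity)


# ---------------------------------------------------------------------------
# folds


@dataclass
class FoldSplit:
    fold_id: int
    train_positives: list
    test_positives: list
    train_unlabelled: list
    test_unlabelled: list
    A_train: np.ndarray        # adjacency with test positives zeroed

    @property
    def test_pairs(self) -> list:
        return self.test_positives + self.test_unlabelled


def _chunks(items: list, k: int) -> list:
    """Split into k near-equal contiguous chunks."""
    sizes = [len(items) // k + (1 if i < len(items) % k else 0) for i in range(k)]
    out, start = [], 0
    for s in sizes:
        out.append(items[start:start + s])
        start += s
    return out


def split_5fold(dataset: AssociationDataset, seed: int = 0,
                n_folds: int = 5) -> list:
    """Seeded shuffle-and-partition of positives and unlabelled pairs."""
    pos = dataset.positive_pairs()
    unl = dataset.unlabelled_pairs()
    if len(pos) < n_folds or len(unl) < n_folds:
        raise ValueError(f"need at least {n_folds} positive and unlabelled pairs")
    rng = np.random.default_rng(seed)
    pos = [pos[i] for i in rng.permutation(len(pos))]
    unl = [unl[i] for i in rng.permutation(len(unl))]
    pos_chunks = _chunks(pos, n_folds)
    unl_chunks = _chunks(unl, n_folds)
    folds = []
    for f in range(n_folds):
        test_pos = pos_chunks[f]
        test_unl = unl_chunks[f]
        train_pos = [p for c in pos_chunks[:f] + pos_chunks[f + 1:] for p in c]
        train_unl = [p for c in unl_chunks[:f] + unl_chunks[f + 1:] for p in c]
        A_train = dataset.A.copy()
        for i, j in test_pos:
            A_train[i, j] = 0
        folds.append(FoldSplit(fold_id=f + 1, train_positives=train_pos,
                               test_positives=test_pos,
                               train_unlabelled=train_unl,
                               test_unlabelled=test_unl, A_train=A_train))
    return folds


# ---------------------------------------------------------------------------
# metrics


def rank_index(scores: np.ndarray, test_pairs: Sequence[tuple],
               test_positives: Sequence[tuple]) -> float:
    """Mean normalized descending rank of the positives among test pairs.

    Ranks are 1-based with average tie-ranks; the result is
    (1/|S+|) * sum over positives of rank / |S_test|.
    """
    test_pairs = [tuple(p) for p in test_pairs]
    test_positives = [tuple(p) for p in test_positives]
    if not test_positives:
        raise ValueError("empty positive test set")
    missing = set(test_positives) - set(test_pairs)
    if missing:
        raise ValueError(f"test positives not in test pairs: {sorted(missing)[:5]}")
    s = np.array([scores[i, j] for i, j in test_pairs], dtype=float)
    ranks = rankdata(-s, method="average")
    where = {p: k for k, p in enumerate(test_pairs)}
    r = np.array([ranks[where[p]] for p in test_positives])
    return float(r.mean() / len(test_pairs))


def auc_aupr(scores: np.ndarray, labels: np.ndarray) -> tuple:
    """ROC-AUC and area under the precision-recall curve."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


def top_percent_flags(scores: np.ndarray, pirna_ids: Sequence[str],
                      q: float) -> set:
    """piRNA ids in the top ceil(q*m) descending score ranks for one disease."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    k = int(np.ceil(q * len(scores)))
    order = np.argsort(-scores, kind="stable")
    return {pirna_ids[i] for i in order[:k]}


# ---------------------------------------------------------------------------
# pipeline pieces


@dataclass
class FoldArtifacts:
    """Everything trained inside one fold (for tests and inspection)."""

    S_p: SimilarityMatrix
    S_d: SimilarityMatrix
    reliable_negatives: object
    inputs: ModelInputs


def build_vocab(dataset: AssociationDataset, config: RunConfig) -> KmerVocab:
    corpus = [tokenize_kmers(p.sequence, config.kmer_k) for p in dataset.pirnas]
    return train_kmer_embeddings(corpus, d_w=config.word_dim,
                                 window=config.w2v_window,
                                 epochs=config.w2v_epochs,
                                 negative=config.w2v_negative,
                                 seed=config.seed)


def fold_artifacts(dataset: AssociationDataset, ontology: DiseaseOntology,
                   A_train: np.ndarray, config: RunConfig, vocab: KmerVocab,
                   seq_sim: SimilarityMatrix,
                   sem_sim: SimilarityMatrix) -> FoldArtifacts:
    """Fold-specific similarities, features and model inputs from A_train only."""
    S_p = pirna_similarity(dataset.pirnas, A_train, seq_sim=seq_sim)
    S_d = disease_similarity(ontology, dataset.diseases, A_train, sem_sim=sem_sim)
    hetero = build_hetero(S_p, A_train, S_d)
    inputs = prepare_inputs(dataset.pirnas, vocab, hetero, S_d.M, config)
    return FoldArtifacts(S_p=S_p, S_d=S_d, reliable_negatives=None, inputs=inputs)


@dataclass
class MetricReport:
    auc: float
    aupr: float
    rank_index: float
    per_fold: list = field(default_factory=list)   # dicts per fold
    variance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"auc": self.auc, "aupr": self.aupr,
                "rank_index": self.rank_index, "per_fold": self.per_fold,
                "variance": self.variance}


def run_cv(dataset: AssociationDataset, ontology: DiseaseOntology,
           config: RunConfig, pul_method: str = "combined",
           seed: int | None = None) -> MetricReport:
    """5-fold cross-validated evaluation of the full pipeline.

    Per fold: recompute GIP similarities from the masked training
    adjacency, select reliable negatives from the fold's training pool,
    train the model end to end, then score all test pairs.  Metrics per
    fold are averaged over the last ``report_window`` training epochs.
    """
    seed = config.seed if seed is None else seed
    vocab = build_vocab(dataset, config)
    seq_sim = seq_similarity(dataset.pirnas, config.sw_match, config.sw_mismatch,
                             config.sw_gap)
    sem_sim = semantic_similarity(ontology, dataset.diseases, config.theta)
    per_fold = []
    for fold in split_5fold(dataset, seed=seed, n_folds=config.cv_folds):
        art = fold_artifacts(dataset, ontology, fold.A_train, config, vocab,
                             seq_sim, sem_sim)
        feats = PairFeatureMap(art.S_p.M, art.S_d.M)
        rns = select_negatives(pul_method, fold.train_positives,
                               fold.train_unlabelled, feats, config,
                               seed=seed + 17 * fold.fold_id)
        result = train(art.inputs, fold.train_positives, sorted(rns.pairs),
                       config, seed=seed + fold.fold_id,
                       snapshot_last=config.report_window)
        labels = np.concatenate([np.ones(len(fold.test_positives)),
                                 np.zeros(len(fold.test_unlabelled))])
        vals = {"auc": [], "aupr": [], "rank_index": []}
        for S in result.score_snapshots:
            s = np.array([S[i, j] for i, j in fold.test_pairs])
            a, ap = auc_aupr(s, labels)
            vals["auc"].append(a)
            vals["aupr"].append(ap)
            vals["rank_index"].append(
                rank_index(S, fold.test_pairs, fold.test_positives))
        per_fold.append({k: float(np.mean(v)) for k, v in vals.items()})
    agg = {k: [f[k] for f in per_fold] for k in ("auc", "aupr", "rank_index")}
    return MetricReport(
        auc=float(np.mean(agg["auc"])),
        aupr=float(np.mean(agg["aupr"])),
        rank_index=float(np.mean(agg["rank_index"])),
        per_fold=per_fold,
        variance={k: float(np.var(v)) for k, v in agg.items()},
    )


def sweep_spy(dataset: AssociationDataset, ontology: DiseaseOntology,
              config: RunConfig, fracs: Sequence[float],
              pul_method: str = "combined") -> dict:
    """run_cv at each spy fraction; returns {frac: MetricReport}."""
    from dataclasses import replace

    return {f: run_cv(dataset, ontology, replace(config, spy_frac=f), pul_method)
            for f in fracs}


# ---------------------------------------------------------------------------
# planted-recovery experiment (single held-out evaluation per seed)


@dataclass
class RecoveryResult:
    auc: float                  # hidden positives vs true negatives
    aupr: float
    rank_index: float           # hidden positives among all unlabelled pairs
    hidden_selected_rate: float     # hidden positives picked as "negatives"
    negative_selected_rate: float   # true negatives picked as negatives
    n_reliable_negatives: int


def run_recovery(dataset: AssociationDataset, truth: np.ndarray,
                 ontology: DiseaseOntology, config: RunConfig,
                 pul_method: str = "combined",
                 seed: int | None = None) -> RecoveryResult:
    """Full pipeline on the observed positives; scored on hidden truth.

    ``truth`` is the complete planted association matrix; entries positive
    in truth but zero in ``dataset.A`` are the hidden positives.  The
    model never sees the truth: similarities, PU selection and training
    all use the observed adjacency only.
    """
    seed = config.seed if seed is None else seed
    truth = np.asarray(truth)
    vocab = build_vocab(dataset, config)
    seq_sim = seq_similarity(dataset.pirnas, config.sw_match, config.sw_mismatch,
                             config.sw_gap)
    sem_sim = semantic_similarity(ontology, dataset.diseases, config.theta)
    art = fold_artifacts(dataset, ontology, dataset.A, config, vocab,
                         seq_sim, sem_sim)
    positives = dataset.positive_pairs()
    unlabelled = dataset.unlabelled_pairs()
    feats = PairFeatureMap(art.S_p.M, art.S_d.M)
    rns = select_negatives(pul_method, positives, unlabelled, feats, config,
                           seed=seed)
    result = train(art.inputs, positives, sorted(rns.pairs), config, seed=seed)
    S = result.model.predict()

    hidden = [(i, j) for i, j in unlabelled if truth[i, j] == 1]
    true_neg = [(i, j) for i, j in unlabelled if truth[i, j] == 0]
    s_hidden = np.array([S[i, j] for i, j in hidden])
    s_neg = np.array([S[i, j] for i, j in true_neg])
    auc, aupr = auc_aupr(np.concatenate([s_hidden, s_neg]),
                         np.concatenate([np.ones(len(hidden)),
                                         np.zeros(len(true_neg))]))
    ri = rank_index(S, unlabelled, hidden)
    hid_rate = (sum(1 for p in hidden if p in rns.pairs) / len(hidden)
                if hidden else 0.0)
    neg_rate = (sum(1 for p in true_neg if p in rns.pairs) / len(true_neg)
                if true_neg else 0.0)
    return RecoveryResult(auc=auc, aupr=aupr, rank_index=ri,
                          hidden_selected_rate=hid_rate,
                          negative_selected_rate=neg_rate,
                          n_reliable_negatives=len(rns))
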