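# Methods

## Problem setting

Curated piRNA–disease resources list a few thousand experimentally
supported associations over thousands of piRNAs and a few dozen diseases;
typically 5–8% of all pairs are labelled positive and nothing is ever
labelled negative. `pirdap` treats prediction as bipartite link ranking on
a heterogeneous graph under positive-unlabelled (PU) supervision.

## Similarity construction

**Sequence similarity.** Smith–Waterman local alignment with a linear gap
penalty, normalized as SW(i,j)/√(SW(i,i)·SW(j,j)) so self-similarity is 1
for any positive match score. The literature for this model family does
not standardize the scoring scheme; the defaults are match +2,
mismatch −1, gap −1 on the DNA alphabet (U is normalized to T at load
time), all exposed in `RunConfig`. Alignment is delegated to Biopython's
`PairwiseAligner` in local mode; the test suite pins it against an
independent quadratic-DP oracle.

**GIP kernel.** exp(−λ‖p_i−p_j‖²) over binary interaction profiles with
the data-adaptive bandwidth λ = 1/mean‖p_k‖². The kernel is undefined on
an all-zero profile matrix and raises rather than guessing. Inside
cross-validation the profiles come from the *masked* training adjacency
and are recomputed per fold.

**Semantic similarity.** Wang-style DAG similarity on the disease
ontology: the disease itself has weight 1 and each ancestor the decayed
maximum θ·w over its children within the disease's ancestor closure,
θ = 0.5. With a constant decay this equals θ^(shortest upward distance),
which is how the independent test oracle computes it. Diseases missing
from the ontology fall back to a Kronecker-delta row with a warning so
fusion still works. Fusion with the GIP component is the arithmetic mean
in both domains; no sparsification or alternative kernels are applied.

## Sequence embedding

Sequences are tokenized into overlapping 3-mers (a 24-nt piRNA gives 22
tokens). The 3-mer vocabulary has at most 64 entries, so skip-gram with
negative sampling is implemented directly in numpy (window 5, 5 negative
samples, 5 epochs, linearly decaying learning rate from 0.025,
deterministic fixed symmetric window). Word-vector dimension defaults to
64. The TextCNN applies kernel sizes 1/3/5 with 128 filters each, ReLU, a
global max-pool per filter, and a linear map to the 128-dimensional piRNA
embedding. Sequences are right-padded with zero vectors to the batch
maximum (and at least the largest kernel); padded windows pool to 0 and
cannot dominate a ReLU feature map. The TextCNN is trained end to end
with the downstream model by default (`train_textcnn=False` freezes
randomly initialized filters, giving a random-projection encoder for
ablations).

## Model

The initial embedding H⁰ stacks the piRNA sequence features, linearly
projected to the disease-block width n (the disease rows are the fused
S_d rows, which fixes their width), over those S_d rows. Two graph
convolutions H^{l+1} = σ(D^{−1/2} A_h D^{−1/2} H^l W^l) follow, where D is
the degree matrix of the heterogeneous adjacency A_h (its unit-diagonal
similarity blocks guarantee positive degrees, so no extra self-loops are
added) and σ is ReLU, applied after the final layer too by default
(`final_relu` disables it). Width 64 per layer; two layers — deeper
stacks over-smooth a two-block graph. Cross-attention uses 2 heads with
d_k = 32, post-norm residuals (LayerNorm ε = 1e−5, learned affine), and
the score matrix is F_p F_dᵀ, mapped through a logistic function when a
probability is needed.

Training minimizes binary cross-entropy with logits over the labelled
pairs (known positives, PU-selected negatives) with Adam at lr 1e−3 for
200 epochs, full-batch. Everything runs on a small reverse-mode autograd
(`pirdap.nn`) whose operations are finite-difference checked in the test
suite; runs are bit-deterministic given a seed.

## PU learning

Pair (i,j) is featurized as [S_p(i,·) ‖ S_d(j,·)] (length m+n).

* **Spy**: ceil(5%) of positives are hidden among the unlabelled; a
  500-tree random forest is trained on the remaining positives vs the
  whole pool, and unlabelled pairs scoring below the weakest spy are
  returned. The spy split is internal; the caller's positive set is never
  mutated.
* **PU bagging**: per round, 30 bootstrap forests are trained on all
  positives vs an equal-size random draw of unlabelled pairs and score
  their out-of-bag pairs; scores are averaged within and across 5 rounds.
  The averaged scores are split into three clusters by deterministic 1-D
  k-means (quantile initialization) and the *middle* cluster is returned,
  as this model family prescribes; pairs never out-of-bag get the mean
  score with a warning, and degenerate score distributions fall back to
  the lowest tertile, flagged.
* **Two-step**: all unlabelled start labelled negative; each of 5
  iterations trains a forest on the current labelling, promotes pairs
  scoring above the highest current-positive score (sticky — promoted
  pairs never re-enter the output) and labels pairs below the lowest
  positive score negative; the pairs still negative at the end are
  returned.
* **Combined**: the set union with merged per-method provenance.

Only the spy forest's size (500 trees) is prescribed by the model family;
the bagging classifiers are described there as deliberately small, so the
per-bag and two-step forests default to 100 trees (`bag_estimators`,
`two_step_estimators`).

**Known property of two-step.** With forest posteriors evaluated on their
own training points, positives saturate near 1 and training-negative
unlabelled pairs fall below the minimum positive posterior, so neither
threshold ever fires and two-step returns essentially the whole
unlabelled pool. This was verified under sticky relabelling, full
relabelling and out-of-bag-calibrated variants, and appears intrinsic to
the max/min rule rather than to this implementation. Consequently the
*combined* union is only as selective as two-step: on planted data, spy
and bagging individually pick hidden true positives at well below half
the rate of true negatives, but the union does not. Use `spy` or
`bagging` when selectivity of the negative set matters.

## Evaluation protocol

Positives and unlabelled pairs are independently shuffled (seeded) and
split into five near-equal folds. Within a fold, the test positives are
zeroed in the adjacency before *anything* training-side is computed — GIP
similarities, the heterogeneous graph, H⁰, pair features and PU
selection — which the leakage test enforces by recomputation. Metrics
are ROC-AUC, average-precision AUPR and the rank index
(1/|S⁺|)Σ r_a/|S_test| with 1-based average tie-ranks over all test
pairs; per-fold metrics average the last 5 training epochs
(`report_window`), then mean and variance are taken across folds. The
`sweep_spy` driver repeats the protocol across spy fractions. The
per-disease top-q% flagging rule used in case-study style screens is
`top_percent_flags` (invariant to monotone score transforms).

## Synthetic data

The generator emulates the three real inputs: i.i.d. random DNA sequences
with lengths uniform on 24–35 nt; a random rooted ontology DAG (each
non-root term takes 1–2 parents among earlier terms); and a planted
association matrix. Associations are planted from a nonnegative low-rank
model (|N(0,1)| factors, rank 2, Gaussian score noise sd 0.1): the top
8% of latent scores are the truth, 70% of the truth is revealed as the
observed matrix and the rest become hidden positives in the unlabelled
pool. A uniform-random mode serves as a null control. Defaults (m=200,
n=15) keep a full pipeline run in the low minutes on one CPU while
preserving the sparsity regime of the curated databases.

What passing on synthetic data does *not* show: real piRNA sequences have
biased composition and shared biogenesis signatures, real ontologies are
deeper and unbalanced, and real association matrices have hub structure
beyond low rank. The planted experiments validate the machinery and its
statistical behaviour, not clinical performance.

## Numerical choices and limitations

Double precision throughout; similarity matrices are validated
(symmetry, unit diagonal, [0,1]) and clipped only for round-off. Ranking
ties take average ranks. Max-pool gradients break ties toward the first
argmax. The k-means clustering in bagging is deterministic by
construction. All RNGs are numpy `default_rng` seeded from `RunConfig` or
function arguments; forests run single-threaded for reproducibility.
Known limitations: O(m²) alignment cost for the sequence-similarity
matrix; full-batch training holds the dense (m+n)² graph in memory;
disease-name → ontology-term mapping is caller-provided.
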