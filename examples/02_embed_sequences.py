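"""Embed piRNA sequences: 3-mer tokens -> skip-gram vectors -> TextCNN.

The printed cosine similarities show that the learned features respect
sequence composition: a sequence is closer to a single-base mutant of
itself than to an unrelated sequence.
"""

import numpy as np

from pirdap import (PirnaRecord, embed_sequences, init_textcnn_weights,
                    tokenize_kmers, train_kmer_embeddings)
from pirdap.synthetic import SyntheticSpec, gen_sequences

records = gen_sequences(SyntheticSpec(m=50, seed=1))
base = records[0].sequence
mutant = base[:10] + ("A" if base[10] != "A" else "C") + base[11:]
records = records + [PirnaRecord("mutant", mutant)]

corpus = [tokenize_kmers(r.sequence, 3) for r in records]
print(f"example tokens of {records[0].id}: {corpus[0][:5]} ...")

vocab = train_kmer_embeddings(corpus, d_w=32, seed=0)
print(f"skip-gram vocabulary: {len(vocab.tokens)} 3-mers, dim {vocab.dim}")

weights = init_textcnn_weights(vocab.dim, n_filters=64, embed_dim=64, seed=0)
F = embed_sequences(records, vocab, weights)
print(f"TextCNN features: {F.shape[0]} sequences x {F.shape[1]} dims")


def cos(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


print(f"cos(base, 1-base mutant)      = {cos(F[0], F[-1]):.4f}")
print(f"cos(base, unrelated sequence) = {cos(F[0], F[1]):.4f}")
# the mutant shares almost all windows with the base, so its pooled
# convolutional feature map is nearly identical
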