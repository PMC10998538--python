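import numpy as np
import pytest

from pirdap.config import RunConfig
from pirdap.model import (AssociationModel, AttentionParams, ModelInputs,
                          attention_weights, encode_pair, gcn_layer,
                          init_attention_params, multi_head,
                          normalize_adjacency, prepare_inputs,
                          scaled_dot_attention, score, train)
from pirdap.nn import Tensor
from pirdap.similarity import build_hetero, pirna_similarity, disease_similarity
from pirdap.evaluation import build_vocab
from pirdap.synthetic import SyntheticSpec, generate

from oracles import auc_mann_whitney


class TestGcnLayer:
    def test_identity_adjacency_relu_clips(self):
        H = np.array([[1.0, -1.0], [2.0, 0.0]])
        out = gcn_layer(np.eye(2), H, np.eye(2))
        assert np.array_equal(out, [[1, 0], [2, 0]])

    def test_hand_normalized_product(self):
        A_h = np.ones((2, 2))
        H = np.array([[2.0, 0.0], [0.0, 2.0]])
        out = gcn_layer(A_h, H, np.eye(2))
        assert np.allclose(out, np.ones((2, 2)))  # D = diag(2,2)

    def test_zero_weight_zero_output(self):
        out = gcn_layer(np.eye(3), np.ones((3, 2)), np.zeros((2, 4)))
        assert np.allclose(out, 0.0)

    def test_zero_degree_rejected(self):
        A = np.zeros((2, 2))
        with pytest.raises(ValueError, match="zero-degree"):
            gcn_layer(A, np.ones((2, 1)), np.ones((1, 1)))

    def test_normalized_spectral_radius_at_most_one(self, small_study):
        ds, onto, _ = small_study
        S_p = pirna_similarity(ds.pirnas, ds.A)
        S_d = disease_similarity(onto, ds.diseases, ds.A)
        h = build_hetero(S_p, ds.A, S_d)
        eig = np.linalg.eigvalsh(normalize_adjacency(h.A_h))
        assert np.abs(eig).max() <= 1.0 + 1e-10


class TestAttention:
    def test_single_key_returns_value_row(self):
        Q = np.random.default_rng(0).normal(size=(4, 3))
        K = np.array([[1.0, 0.0, 2.0]])
        V = np.array([[5.0, -1.0]])
        out = scaled_dot_attention(Q, K, V, d_k=3)
        assert np.allclose(out, np.tile(V, (4, 1)))

    def test_equal_logits_average_values(self):
        Q = np.zeros((2, 2))
        K = np.zeros((2, 2))
        V = np.array([[1.0, 3.0], [5.0, 7.0]])
        out = scaled_dot_attention(Q, K, V, d_k=2)
        assert np.allclose(out, np.tile(V.mean(axis=0), (2, 1)))

    def test_weight_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        W = attention_weights(rng.normal(size=(5, 4)), rng.normal(size=(7, 4)), 4)
        assert W.shape == (5, 7)
        assert np.allclose(W.sum(axis=1), 1.0)
        assert (W > 0).all()

    def test_nonpositive_dk_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.eye(2), np.eye(2), np.eye(2), 0)


class TestMultiHead:
    def test_single_head_identity_maps(self):
        rng = np.random.default_rng(2)
        Q, K, V = (rng.normal(size=(4, 3)) for _ in range(3))
        params = AttentionParams(W_Q=[np.eye(3)], W_K=[np.eye(3)],
                                 W_V=[np.eye(3)], W_O=np.eye(3),
                                 gamma=np.ones(3), beta=np.zeros(3))
        assert np.allclose(multi_head(Q, K, V, params),
                           scaled_dot_attention(Q, K, V, 3))

    def test_two_identical_heads_collapse_to_one(self):
        rng = np.random.default_rng(3)
        Q, K, V = (rng.normal(size=(5, 4)) for _ in range(3))
        Wq, Wk, Wv = (rng.normal(size=(4, 4)) for _ in range(3))
        one = AttentionParams(W_Q=[Wq], W_K=[Wk], W_V=[Wv], W_O=np.eye(4),
                              gamma=np.ones(4), beta=np.zeros(4))
        two = AttentionParams(W_Q=[Wq, Wq], W_K=[Wk, Wk], W_V=[Wv, Wv],
                              W_O=np.vstack([np.eye(4), np.eye(4)]) / 2,
                              gamma=np.ones(4), beta=np.zeros(4))
        assert np.allclose(multi_head(Q, K, V, one),
                           multi_head(Q, K, V, two))

    def test_output_rows_match_queries(self):
        rng = np.random.default_rng(4)
        params = init_attention_params(6, 2, rng)
        out = multi_head(rng.normal(size=(9, 6)), rng.normal(size=(4, 6)),
                         rng.normal(size=(4, 6)), params)
        assert out.shape == (9, 6)


class TestEncodePair:
    def test_zero_attention_reduces_to_layer_norm(self):
        rng = np.random.default_rng(5)
        d = 4
        H_p, H_d = rng.normal(size=(6, d)), rng.normal(size=(3, d))
        params = init_attention_params(d, 2, rng)
        for w in (*params.W_V, params.W_O):
            w.data[...] = 0.0
        fp, fd = encode_pair(H_p, H_d, params, params)
        expected = Tensor(H_p).layer_norm().data
        assert np.allclose(fp, expected)

    def test_shapes_preserved(self):
        rng = np.random.default_rng(6)
        d = 6
        H_p, H_d = rng.normal(size=(8, d)), rng.normal(size=(5, d))
        fp, fd = encode_pair(H_p, H_d, init_attention_params(d, 2, rng),
                             init_attention_params(d, 2, rng))
        assert fp.shape == (8, d) and fd.shape == (5, d)

    def test_rows_standardized_before_affine(self):
        rng = np.random.default_rng(7)
        d = 8
        params_p = init_attention_params(d, 2, rng)
        params_d = init_attention_params(d, 2, rng)
        # identity affine exposes the raw layer-norm output
        fp, _ = encode_pair(rng.normal(size=(5, d)), rng.normal(size=(4, d)),
                            params_p, params_d)
        assert np.allclose(fp.mean(axis=-1), 0.0, atol=1e-8)
        assert np.allclose(fp.var(axis=-1), 1.0, atol=1e-3)


class TestScore:
    def test_inner_products(self):
        F_p = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        F_d = np.array([[1.0, 0.0], [2.0, 2.0]])
        assert np.allclose(score(F_p, F_d), F_p @ F_d.T)

    def test_orthogonal_zero_unit_one(self):
        S = score(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert S[0, 0] == 0.0 and S[0, 1] == 1.0


def _toy_inputs(m=10, n=5, seed=0, cfg=None):
    spec = SyntheticSpec(m=m, n=n, density=0.15, seed=seed)
    ds, onto, truth = generate(spec)
    cfg = cfg or RunConfig(epochs=40, word_dim=8, n_filters=8, embed_dim=16,
                           gcn_dim=8, w2v_epochs=1)
    vocab = build_vocab(ds, cfg)
    S_p = pirna_similarity(ds.pirnas, ds.A)
    S_d = disease_similarity(onto, ds.diseases, ds.A)
    inputs = prepare_inputs(ds.pirnas, vocab, build_hetero(S_p, ds.A, S_d),
                            S_d.M, cfg)
    return ds, inputs, cfg


class TestTrain:
    def test_loss_decreases_on_toy(self):
        ds, inputs, cfg = _toy_inputs()
        pos = ds.positive_pairs()
        neg = ds.unlabelled_pairs()[: len(pos)]
        res = train(inputs, pos, neg, cfg, seed=0)
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_separable_toy_reaches_training_auc_one(self):
        ds, inputs, cfg = _toy_inputs()
        pos = ds.positive_pairs()
        neg = ds.unlabelled_pairs()[: 2 * len(pos)]
        res = train(inputs, pos, neg, RunConfig(**{**cfg.to_dict(),
                                                  "epochs": 300,
                                                  "kernel_sizes": (1, 3, 5)}),
                    seed=0)
        S = res.model.predict()
        scores = [S[i, j] for i, j in pos] + [S[i, j] for i, j in neg]
        labels = [1] * len(pos) + [0] * len(neg)
        assert auc_mann_whitney(scores, labels) == 1.0

    def test_same_seed_identical_loss(self):
        ds, inputs, cfg = _toy_inputs()
        pos = ds.positive_pairs()
        neg = ds.unlabelled_pairs()[: len(pos)]
        r1 = train(inputs, pos, neg, cfg, seed=3)
        r2 = train(inputs, pos, neg, cfg, seed=3)
        assert r1.loss_trace == r2.loss_trace

    def test_empty_positives_rejected(self):
        ds, inputs, cfg = _toy_inputs()
        with pytest.raises(ValueError, match="positive"):
            train(inputs, [], ds.unlabelled_pairs()[:4], cfg)

    def test_overlapping_sets_rejected(self):
        ds, inputs, cfg = _toy_inputs()
        pos = ds.positive_pairs()
        with pytest.raises(ValueError, match="overlap"):
            train(inputs, pos, pos[:1], cfg)

    def test_textcnn_matches_reference_forward(self):
        """The autograd TextCNN equals the plain-numpy encoder weights-for-weights."""
        from pirdap.seqembed import (TextCNNWeights, pad_tokens, textcnn_encode,
                                     tokenize_kmers)

        ds, inputs, cfg = _toy_inputs()
        model = AssociationModel(inputs, cfg, seed=1)
        feats = model.sequence_features().data
        w = TextCNNWeights(
            conv_W={s: model.conv_W[s].data for s in cfg.kernel_sizes},
            conv_b={s: model.conv_b[s].data for s in cfg.kernel_sizes},
            proj_W=model.proj_W.data, proj_b=model.proj_b.data)
        vocab = build_vocab(ds, cfg)
        L = inputs.token_windows[1].shape[1]  # common padded token length
        ref = np.stack([
            textcnn_encode(pad_tokens(
                vocab.encode(tokenize_kmers(r.sequence, cfg.kmer_k)), L), w)
            for r in ds.pirnas])
        assert np.allclose(feats, ref, atol=1e-10)
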