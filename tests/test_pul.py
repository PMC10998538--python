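import numpy as np
import pytest

from pirdap.config import RunConfig
from pirdap.pul import (PairFeatureMap, ReliableNegativeSet, bagging_select,
                        combine_union, middle_cluster, pair_features,
                        select_negatives, spy_select, two_step_select)


@pytest.fixture
def separable():
    """Positives live at feature value 1, negatives at 0; trivially separable.

    Pairs are drawn on a 20 x 2 grid: disease 0 pairs are positive,
    disease 1 pairs unlabelled-and-truly-negative.
    """
    m, n = 20, 2
    S_p = np.eye(m) * 0 + np.eye(m)
    rng = np.random.default_rng(0)
    # piRNA rows: first feature strongly separates the classes
    S_p = np.clip(np.eye(m) + rng.random((m, m)) * 0.01, 0, 1)
    S_p = (S_p + S_p.T) / 2
    np.fill_diagonal(S_p, 1.0)
    S_d = np.array([[1.0, 0.0], [0.0, 1.0]])
    feats = PairFeatureMap(S_p, S_d)
    positives = [(i, 0) for i in range(m)]
    unlabelled = [(i, 1) for i in range(m)]
    return positives, unlabelled, feats


class TestPairFeatures:
    def test_concatenation_order(self):
        S_p = np.array([[1.0, 0.5], [0.5, 1.0]])
        S_d = np.array([[1.0, 0.0], [0.0, 1.0]])
        F = pair_features(S_p, S_d, [(0, 1)])
        assert np.array_equal(F[0], [1.0, 0.5, 0.0, 1.0])

    def test_vector_length_m_plus_n(self):
        F = pair_features(np.eye(3), np.eye(4), [(0, 0), (2, 3)])
        assert F.shape == (2, 7)

    def test_shared_pirna_prefix(self):
        S_p, S_d = np.eye(2), np.eye(2)
        F = pair_features(S_p, S_d, [(0, 0), (0, 1)])
        assert np.array_equal(F[0][:2], F[1][:2])

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            pair_features(np.eye(2), np.eye(2), [(5, 0)])


class TestSpy:
    def test_empty_unlabelled_gives_empty_set(self, fast_config):
        feats = PairFeatureMap(np.eye(3), np.eye(2))
        out = spy_select([(0, 0), (1, 1)], [], feats, fast_config)
        assert len(out) == 0

    def test_separable_selects_all_unlabelled(self, separable, fast_config):
        positives, unlabelled, feats = separable
        out = spy_select(positives, unlabelled, feats, fast_config, seed=0)
        assert out.pairs == set(unlabelled)

    def test_posterior_invariant_below_every_spy(self, separable, fast_config):
        """Re-run the classifier construction and confirm the threshold rule."""
        import math
        from sklearn.ensemble import RandomForestClassifier

        positives, unlabelled, feats = separable
        out = spy_select(positives, unlabelled, feats, fast_config, seed=4)
        # replicate spy split and classifier to inspect posteriors
        rng = np.random.default_rng(4)
        n_spies = math.ceil(fast_config.spy_frac * len(positives))
        spy_idx = rng.choice(len(positives), size=n_spies, replace=False)
        mask = np.zeros(len(positives), bool)
        mask[spy_idx] = True
        spies = [p for p, s in zip(positives, mask) if s]
        rest = [p for p, s in zip(positives, mask) if not s]
        X = np.vstack([feats.rows(rest), feats.rows(unlabelled),
                       feats.rows(spies)])
        y = np.concatenate([np.ones(len(rest)),
                            np.zeros(len(unlabelled) + len(spies))])
        rf = RandomForestClassifier(n_estimators=fast_config.rf_estimators,
                                    random_state=4, n_jobs=1).fit(X, y)
        pos_col = list(rf.classes_).index(1)
        t = rf.predict_proba(feats.rows(spies))[:, pos_col].min()
        post = rf.predict_proba(feats.rows(unlabelled))[:, pos_col]
        assert out.pairs == {p for p, s in zip(unlabelled, post) if s < t}

    def test_unlabelled_like_positives_selects_little_on_average(self):
        """When unlabelled pairs look exactly like positives, the mean selected
        fraction stays near the spy-quantile level, far below one."""
        from pirdap.config import RunConfig

        cfg = RunConfig(rf_estimators=60)
        rng = np.random.default_rng(1)
        m = 240
        S_p = np.clip(rng.random((m, m)), 0, 1)
        S_p = (S_p + S_p.T) / 2
        np.fill_diagonal(S_p, 1.0)
        feats = PairFeatureMap(S_p, np.eye(1))
        # positives and unlabelled drawn from the same i.i.d. feature rows
        positives = [(i, 0) for i in range(m // 2)]
        unlabelled = [(i, 0) for i in range(m // 2, m)]
        fracs = [len(spy_select(positives, unlabelled, feats, cfg, seed=s))
                 / len(unlabelled) for s in range(5)]
        assert np.mean(fracs) < 0.5

    def test_inputs_not_mutated(self, separable, fast_config):
        positives, unlabelled, feats = separable
        before = list(positives)
        spy_select(positives, unlabelled, feats, fast_config, seed=0)
        assert positives == before  # spies restored / never removed


class TestBagging:
    def test_middle_cluster_of_three_modes(self):
        rng = np.random.default_rng(0)
        pairs = [(i, 0) for i in range(30)]
        scores = np.concatenate([
            0.9 + 0.01 * rng.random(10),
            0.5 + 0.01 * rng.random(10),
            0.1 + 0.01 * rng.random(10)])
        mid = middle_cluster(pairs, scores)
        assert set(mid) == set(pairs[10:20])

    def test_degenerate_scores_fall_back_with_warning(self):
        pairs = [(i, 0) for i in range(9)]
        with pytest.warns(UserWarning, match="degenerate"):
            out = middle_cluster(pairs, np.full(9, 0.5))
        assert len(out) == 3

    def test_output_subset_of_unlabelled(self, separable, fast_config):
        positives, unlabelled, feats = separable
        out = bagging_select(positives, unlabelled, feats, fast_config, seed=0)
        assert out.pairs <= set(unlabelled)
        assert not out.pairs & set(positives)

    def test_requires_enough_unlabelled(self, separable, fast_config):
        positives, unlabelled, feats = separable
        with pytest.raises(ValueError):
            bagging_select(positives, unlabelled[:3], feats, fast_config)


class TestTwoStep:
    def test_separable_keeps_true_negatives(self, separable, fast_config):
        positives, unlabelled, feats = separable
        out = two_step_select(positives, unlabelled, feats, fast_config, seed=0)
        assert out.pairs == set(unlabelled)

    def test_promoted_pairs_never_returned(self, fast_config):
        """Hidden positives scoring above every known positive are excluded."""
        rng = np.random.default_rng(2)
        m = 30
        S_p = (lambda X: np.clip((X + X.T) / 2, 0, 1))(rng.random((m, m)))
        np.fill_diagonal(S_p, 1.0)
        # make piRNAs 0..9 the 'positive-looking' block
        S_p[:10, :10] = np.clip(S_p[:10, :10] + 0.5, 0, 1)
        np.fill_diagonal(S_p, 1.0)
        S_d = np.eye(2)
        feats = PairFeatureMap(S_p, S_d)
        positives = [(i, 0) for i in range(2, 10)]
        unlabelled = [(0, 1), (1, 1)] + [(i, 1) for i in range(10, m)]
        out = two_step_select(positives, unlabelled, feats, fast_config, seed=0)
        assert out.pairs <= set(unlabelled)
        assert not out.pairs & set(positives)

    def test_empty_inputs_rejected(self, fast_config):
        feats = PairFeatureMap(np.eye(2), np.eye(2))
        with pytest.raises(ValueError):
            two_step_select([], [(0, 0)], feats, fast_config)


class TestPlantedSelectivity:
    def test_spy_and_bagging_prefer_true_negatives(self):
        """Hidden positives planted in the unlabelled pool are selected as
        negatives at a rate strictly below planted true negatives."""
        from pirdap.similarity import disease_similarity, pirna_similarity
        from pirdap.synthetic import SyntheticSpec, generate

        cfg = RunConfig(rf_estimators=100, bag_estimators=30, n_bags=10,
                        bag_rounds=2)
        ds, onto, truth = generate(SyntheticSpec(m=80, n=10, density=0.1,
                                                 reveal_frac=0.6, seed=2))
        S_p = pirna_similarity(ds.pirnas, ds.A)
        S_d = disease_similarity(onto, ds.diseases, ds.A)
        feats = PairFeatureMap(S_p.M, S_d.M)
        pos, unl = ds.positive_pairs(), ds.unlabelled_pairs()
        hidden = {p for p in unl if truth[p] == 1}
        tneg = {p for p in unl if truth[p] == 0}
        for sel in (spy_select(pos, unl, feats, cfg, seed=0),
                    bagging_select(pos, unl, feats, cfg, seed=1)):
            hid_rate = len(sel.pairs & hidden) / len(hidden)
            neg_rate = len(sel.pairs & tneg) / len(tneg)
            assert hid_rate < neg_rate


class TestUnionAndDispatch:
    def test_union_merges_pairs_and_provenance(self):
        a = ReliableNegativeSet.from_pairs([(0, 0)], "spy")
        b = ReliableNegativeSet.from_pairs([(0, 0), (1, 1)], "bagging")
        c = ReliableNegativeSet.from_pairs([(2, 2)], "two_step")
        u = combine_union([a, b, c])
        assert u.pairs == {(0, 0), (1, 1), (2, 2)}
        assert u.provenance[(0, 0)] == {"spy", "bagging"}
        assert len(u) >= max(len(a), len(b), len(c))

    def test_union_with_empty_is_identity(self):
        a = ReliableNegativeSet.from_pairs([(1, 2)], "spy")
        u = combine_union([a, ReliableNegativeSet.from_pairs([], "bagging")])
        assert u.pairs == a.pairs

    def test_unknown_method_rejected(self, separable, fast_config):
        positives, unlabelled, feats = separable
        with pytest.raises(ValueError, match="unknown PU method"):
            select_negatives("sp", positives, unlabelled, feats, fast_config)

    def test_none_returns_all_unlabelled(self, separable, fast_config):
        positives, unlabelled, feats = separable
        out = select_negatives("none", positives, unlabelled, feats, fast_config)
        assert out.pairs == set(unlabelled)

    @pytest.mark.parametrize("method", ["spy", "bagging", "two_step", "combined"])
    def test_never_returns_a_known_positive(self, method, fast_config):
        rng = np.random.default_rng(9)
        m, n = 25, 3
        S_p = (lambda X: np.clip((X + X.T) / 2, 0, 1))(rng.random((m, m)))
        np.fill_diagonal(S_p, 1.0)
        S_d = np.clip((lambda X: (X + X.T) / 2)(rng.random((n, n))), 0, 1)
        np.fill_diagonal(S_d, 1.0)
        feats = PairFeatureMap(S_p, S_d)
        all_pairs = [(i, j) for i in range(m) for j in range(n)]
        picks = rng.permutation(len(all_pairs))
        positives = [all_pairs[k] for k in picks[:20]]
        unlabelled = [all_pairs[k] for k in picks[20:]]
        out = select_negatives(method, positives, unlabelled, feats,
                               fast_config, seed=11)
        assert not out.pairs & set(positives)
        assert out.pairs <= set(unlabelled)
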