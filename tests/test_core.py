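"""The SIS classifier core: encoding, weights, MWD ranking, scoring, NNA, LOOCV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sistf.core import (
    SCORE_SCALE,
    SISModel,
    SISResults,
    WeightTable,
    classify_nna,
    default_k_grid,
    encode,
    estimate_weights,
    loocv,
    rank_features_mwd,
    score,
    similarity,
)
from sistf.datatypes import CATEGORIES, AnnotatedGeneSet
from sistf.errors import ConfigurationError, ConsistencyError, InputError

from _oracles import naive_mwd, naive_score, naive_similarity, naive_weights


def _weight_table(W, ids=None):
    """Assemble a WeightTable around a given weight matrix (counts unused)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    ids = tuple(ids or (f"PF{i:05d}" for i in range(n)))
    dummy = np.ones((n, 4), dtype=np.int64)
    return WeightTable(ids, dummy, np.ones(4, dtype=np.int64), dummy.sum(1),
                       W.copy(), W.copy(), W)


class TestEncoding:
    def test_indicator_bits_follow_sorted_feature_order(self):
        gs = AnnotatedGeneSet.from_mapping(
            {"g": {"PF00046", "GO:0003700"}, "h": {"PF00104", "GO:0003700", "PF00046"}}
        )
        assert gs.feature_space.ids == ("GO:0003700", "PF00046", "PF00104")
        ids, mat = encode(gs)
        assert mat[ids.index("g")].tolist() == [1, 1, 0]
        assert mat[ids.index("h")].tolist() == [1, 1, 1]

    def test_column_sums_equal_feature_counts(self, small_planted):
        _, geneset, _, _ = small_planted
        ids, mat = encode(geneset)
        counts = geneset.feature_counts()
        for i, f in enumerate(geneset.feature_space):
            assert mat[:, i].sum() == counts[f]

    def test_feature_outside_space_is_an_error(self):
        gs = AnnotatedGeneSet.from_mapping({"g": {"PF00001"}})
        with pytest.raises(ConsistencyError):
            AnnotatedGeneSet(gs.genes, AnnotatedGeneSet.from_mapping({"x": {"PF00002"}}).feature_space)


class TestWeights:
    def test_hand_worked_joint_probability(self):
        # feature A in 2 of 4 TFS samples and nowhere else: P=0.5, IC=1, w=1
        bits = [[1, 1], [1, 1], [0, 1], [0, 1],   # TFS
                [0, 1], [0, 1], [0, 1], [0, 1]]   # MEM x2, ENZ, OTS x3
        labels = [frozenset({"TFS"})] * 4 + [frozenset({"MEM"})] * 2 + \
                 [frozenset({"ENZ"})] + [frozenset({"OTS"})]
        wt = estimate_weights(np.array(bits), labels, ["A", "B"])
        j = CATEGORIES.index("TFS")
        assert wt.P[0, j] == pytest.approx(0.5)
        assert wt.IC[0, j] == pytest.approx(1.0)
        assert wt.W[0, j] == pytest.approx(1.0)
        # absent feature: w = 0 exactly
        assert wt.W[0, CATEGORIES.index("MEM")] == 0.0

    def test_category_exclusive_universal_feature_capped(self):
        bits = [[1, 1], [0, 1], [0, 1], [0, 1]]
        labels = [frozenset({c}) for c in CATEGORIES]
        wt = estimate_weights(np.array(bits), labels, ["A", "B"], w_max=1e6)
        assert wt.P[0, 0] == 1.0
        assert wt.W[0, 0] == 1e6

    def test_empty_category_is_a_configuration_error(self):
        bits = np.array([[1], [1]])
        labels = [frozenset({"TFS"}), frozenset({"MEM"})]
        with pytest.raises(ConfigurationError):
            estimate_weights(bits, labels, ["A"])

    def test_zero_count_feature_is_a_consistency_error(self):
        bits = np.array([[1, 0]])
        with pytest.raises(ConsistencyError):
            estimate_weights(bits, [frozenset(CATEGORIES)], ["A", "B"])

    def test_multilabel_samples_count_in_every_category(self):
        bits = np.array([[1]] * 4)
        labels = [frozenset({"TFS", "MEM"}), frozenset({"MEM"}),
                  frozenset({"ENZ"}), frozenset({"OTS"})]
        wt = estimate_weights(bits, labels, ["A"])
        assert wt.n_j.tolist() == [1, 2, 1, 1]
        assert wt.C[0].tolist() == [1, 2, 1, 1]
        assert wt.c_i[0] == 5

    def test_brute_force_oracle_agreement_random_multilabel(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            m = int(rng.integers(8, 40))
            n = int(rng.integers(2, 20))
            bits = (rng.random((m, n)) < 0.4).astype(np.uint8)
            bits[:, rng.integers(n)] = 1   # no zero-count features
            labels = []
            for s in range(m):
                k = int(rng.integers(1, 3))
                labels.append(frozenset(rng.choice(CATEGORIES, size=k, replace=False)))
            for c in range(4):             # every category present
                labels[c] = labels[c] | {CATEGORIES[c]}
            wt = estimate_weights(bits, labels, [f"F{i:03d}" for i in range(n)])
            C, n_j, c_i, P, W = naive_weights([r.tolist() for r in bits], labels)
            assert wt.C.tolist() == C
            assert wt.n_j.tolist() == n_j
            for i in range(n):
                for j in range(4):
                    assert wt.W[i, j] == pytest.approx(W[i][j], rel=1e-12, abs=1e-300)


class TestMWDRanking:
    def test_hand_worked_examples(self):
        wt = _weight_table([[1.0, 0.1, 0.1, 0.1],    # MWD 0.9, kept
                            [0.4, 0.2, 0.2, 0.2],    # pruned: 0.4 < 0.6
                            [0.3, 0.3, 0.3, 0.3]])   # symmetric: pruned
        r = rank_features_mwd(wt)
        assert r.ranked_feature_ids == ["PF00000"]
        assert r.mwd[0] == pytest.approx(0.9)
        assert sorted(wt.feature_ids[i] for i in r.pruned) == ["PF00001", "PF00002"]

    def test_ties_break_by_feature_id(self):
        wt = _weight_table([[1.0, 0.0, 0.0, 0.0], [1.0, 0.0, 0.0, 0.0]], ids=("B", "A"))
        assert rank_features_mwd(wt).ranked_feature_ids == ["A", "B"]

    def test_matches_naive_oracle_on_random_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            W = rng.random((n, 4)) * rng.choice([0, 1], size=(n, 4))
            ids = [f"F{i:03d}" for i in range(n)]
            r = rank_features_mwd(_weight_table(W, ids))
            ref_ids, ref_mwd, ref_pruned = naive_mwd(W.tolist(), ids)
            assert r.ranked_feature_ids == ref_ids
            assert sorted(r.feature_ids[i] for i in r.pruned) == sorted(ref_pruned)
            np.testing.assert_allclose(r.mwd, ref_mwd, rtol=1e-12)


class TestSimilarityAndScore:
    def test_cosine_identities(self):
        assert similarity([1, 1, 0], [1, 1, 0]) == 1.0
        assert similarity([1, 0, 0], [0, 1, 1]) == 0.0
        assert similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)
        with pytest.raises(InputError):
            similarity([0, 0], [1, 0])

    def test_score_hand_examples(self):
        wt = _weight_table([[0.8, 0.0, 0.0, 0.0], [0.3, 0.0, 0.0, 0.0], [0.1, 0.0, 0.0, 0.0]])
        # disjoint supports: zero regardless of weights
        assert score([1, 0, 0], [0, 1, 1], wt, "TFS") == 0.0
        # identical single shared feature: 1 x 0.8 (to quantization resolution)
        assert score([1, 0, 0], [1, 0, 0], wt, "TFS") == pytest.approx(0.8, abs=2 / SCORE_SCALE)
        # combine: sim 0.5 x weight 0.8
        assert score([1, 1, 0], [1, 0, 1], wt, "TFS") == pytest.approx(0.4, abs=2 / SCORE_SCALE)

    @settings(max_examples=150, derandomize=True)
    @given(st.data())
    def test_symmetry_bounds_and_oracle_agreement(self, data):
        n = data.draw(st.integers(2, 12))
        vec = st.lists(st.integers(0, 1), min_size=n, max_size=n)
        a = data.draw(vec.filter(lambda v: sum(v) > 0))
        b = data.draw(vec.filter(lambda v: sum(v) > 0))
        W = np.array(data.draw(
            st.lists(st.lists(st.floats(0, 10), min_size=4, max_size=4),
                     min_size=n, max_size=n)))
        wt = _weight_table(W)
        s_ab = similarity(a, b)
        assert s_ab == similarity(b, a)
        assert 0.0 <= s_ab <= 1.0 + 1e-15
        assert (s_ab == 1.0) == (a == b)
        for cat in CATEGORIES:
            sc = score(a, b, wt, cat)
            assert sc == naive_score(a, b, W.tolist(), cat)  # bit-identical
            assert sc >= 0.0
            shared_cap = sum(W[k, CATEGORIES.index(cat)] for k in range(n) if a[k] and b[k])
            assert sc <= shared_cap + (n + 1) / SCORE_SCALE  # quantization headroom
        assert similarity(a, b) == pytest.approx(naive_similarity(a, b), rel=1e-12)


class TestNNAClassification:
    def _model_bits(self):
        train = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]], dtype=np.uint8)
        ids = ["a", "b", "c"]
        labels = [frozenset({"TFS"}), frozenset({"MEM"}), frozenset({"ENZ"})]
        return train, ids, labels

    def test_identical_query_returns_its_twin(self):
        train, ids, labels = self._model_bits()
        wt = _weight_table([[1.0, 0.1, 0.1, 0.1]] * 3)
        pred = classify_nna(np.array([1, 1, 0]), train, ids, labels, wt)
        assert pred.category == "TFS" and pred.neighbor_id == "a" and pred.tf_flag

    def test_all_zero_scores_is_unclassifiable(self):
        train, ids, labels = self._model_bits()
        wt = _weight_table(np.zeros((3, 4)))
        pred = classify_nna(np.array([1, 1, 1]), train, ids, labels, wt)
        assert pred.category is None and not pred.tf_flag

    def test_tie_breaks_by_category_order_then_id(self):
        train = np.array([[1, 0], [1, 0]], dtype=np.uint8)
        labels = [frozenset({"MEM"}), frozenset({"TFS"})]
        wt = _weight_table([[0.5, 0.5, 0.5, 0.5], [0.5, 0.5, 0.5, 0.5]])
        pred = classify_nna(np.array([1, 0]), train, ["a", "b"], labels, wt)
        assert pred.category == "TFS"          # TFS outranks MEM on exact ties
        assert pred.neighbor_id == "b"
        # among equal-scoring neighbors of the same category: smallest id
        labels2 = [frozenset({"TFS"}), frozenset({"TFS"})]
        pred2 = classify_nna(np.array([1, 0]), train, ["a", "b"], labels2, wt)
        assert pred2.neighbor_id == "a"

    def test_exclude_id_removes_self_match(self):
        train, ids, labels = self._model_bits()
        wt = _weight_table([[1.0, 0.1, 0.1, 0.1]] * 3)
        pred = classify_nna(np.array([1, 1, 0]), train, ids, labels, wt, exclude_id="a")
        assert pred.neighbor_id != "a"

    def test_unsorted_training_ids_rejected(self):
        train, _, labels = self._model_bits()
        wt = _weight_table(np.ones((3, 4)))
        with pytest.raises(InputError):
            classify_nna(np.array([1, 0, 0]), train, ["c", "b", "a"], labels, wt)


class TestLoocvAndModel:
    def test_separable_fixture_reaches_perfect_accuracy(self, separable_planted):
        _, geneset, truth, sig = separable_planted
        res = SISModel(geneset, truth).fit()
        assert res.best_row["accuracy"] == 1.0
        # with every planted signature selected, all four categories resolve
        full = res.curve.loc[res.curve["k"] == len(res.ranking)].iloc[0]
        assert full["fourway_accuracy"] == 1.0
        # every planted signature feature survives pruning
        planted = {f for fs in sig.values() for f in fs}
        assert planted <= set(res.ranking.ranked_feature_ids)

    def test_k_zero_means_everything_unclassifiable(self, small_planted):
        _, geneset, truth, _ = small_planted
        model = SISModel(geneset, truth)
        wt = estimate_weights(model.matrix, model.labels, model.feature_ids)
        ranking = rank_features_mwd(wt)
        cv = loocv(model.matrix, model.gene_ids, model.labels, wt, ranking, k_grid=[0])
        row = cv.curve.iloc[0]
        assert row["sensitivity"] == 0.0 and row["TP"] == 0
        assert cv.predictions["category"].isna().all()

    def test_empty_k_grid_rejected(self, small_planted):
        _, geneset, truth, _ = small_planted
        model = SISModel(geneset, truth)
        wt = estimate_weights(model.matrix, model.labels, model.feature_ids)
        with pytest.raises(ConfigurationError):
            loocv(model.matrix, model.gene_ids, model.labels, wt,
                  rank_features_mwd(wt), k_grid=[])

    def test_default_k_grid_ladder(self):
        assert default_k_grid(10) == (1, 2, 4, 8, 10)
        assert default_k_grid(8) == (1, 2, 4, 8)
        assert default_k_grid(1) == (1,)

    def test_predict_on_training_tfs_flags_them(self, separable_planted):
        _, geneset, truth, _ = separable_planted
        model = SISModel(geneset, truth)
        res = model.fit()
        preds = res.predict(geneset).set_index("gene_id")
        tfs = [g for g, c in truth.items() if c == frozenset({"TFS"})]
        assert preds.loc[tfs, "tf_flag"].all()
        non_tfs = [g for g in truth if g not in tfs]
        assert not preds.loc[non_tfs, "tf_flag"].any()
        # with the full feature set selected, every category is recovered
        res_full = model.fit(k_grid=[len(res.ranking)])
        preds_full = res_full.predict(geneset).set_index("gene_id")
        for gid, cats in truth.items():
            assert preds_full.loc[gid, "category"] in cats

    def test_predict_empty_queryset_and_unknown_features(self, separable_planted):
        _, geneset, truth, _ = separable_planted
        res = SISModel(geneset, truth).fit()
        assert len(res.predict({})) == 0
        out = res.predict({"novel": {"PF99999"}})
        assert out.iloc[0]["category"] is None and not out.iloc[0]["tf_flag"]

    def test_threaded_loocv_is_bit_identical(self, small_planted):
        _, geneset, truth, _ = small_planted
        r1 = SISModel(geneset, truth).fit(threads=1)
        r3 = SISModel(geneset, truth).fit(threads=3)
        assert r1.best_k == r3.best_k
        assert r1.curve.equals(r3.curve)
        assert r1.loocv_predictions.equals(r3.loocv_predictions)

    def test_model_save_load_roundtrip(self, tmp_path, small_planted):
        _, geneset, truth, _ = small_planted
        res = SISModel(geneset, truth).fit()
        res.save(tmp_path / "model")
        loaded = SISResults.load(tmp_path / "model")
        assert loaded.best_k == res.best_k
        assert loaded.selected_feature_ids == res.selected_feature_ids
        np.testing.assert_array_equal(loaded.weights.W, res.weights.W)
        p1 = res.predict(geneset)
        p2 = loaded.predict(geneset)
        assert p1.equals(p2)

    def test_summary_mentions_key_quantities(self, small_planted):
        _, geneset, truth, _ = small_planted
        res = SISModel(geneset, truth).fit()
        text = res.summary()
        assert "LOOCV" in text and str(res.best_k) in text
        assert "sensitivity" in text and "MCC" in text

    def test_monotone_degradation_with_leak(self):
        """More feature leakage between categories never helps accuracy."""
        from sistf.fixtures import SignatureSpec, generate_geneset

        accs = []
        for leak in (0.0, 0.15, 0.45):
            seed_accs = []
            for seed in (1, 2, 3):
                spec = SignatureSpec(n_genes_per_category=12,
                                     n_signature_features_per_category=3,
                                     n_noise_features=6,
                                     signature_presence_prob=0.9, leak_prob=leak,
                                     seed=seed)
                gs, truth, _ = generate_geneset(spec)
                res = SISModel(gs, truth).fit()
                seed_accs.append(res.best_row["accuracy"])
            accs.append(np.mean(seed_accs))
        assert accs[0] >= accs[1] >= accs[2] - 0.02
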