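import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmfuf import (
    make_cv1_plan,
    make_cv2_plan,
    repeat_cv,
    run_cv,
    score_binary,
    score_comprehensive,
    tune_latent_factors,
)
from tmfuf.data_io import DrugSet, InteractionMatrix
from conftest import auc_pairwise_oracle, aupr_threshold_oracle


def all_pairs(m):
    return {(i, j) for i in range(m) for j in range(i + 1, m)}


class TestCvPlans:
    @pytest.mark.parametrize("K,expected", [(10, 10), (3, 3), (2, 2), (5, 5)])
    def test_cv1_round_count(self, K, expected):
        assert len(make_cv1_plan(30, K, 0).rounds) == expected

    @pytest.mark.parametrize("K,expected", [(10, 55), (3, 6), (5, 15)])
    def test_cv2_round_count(self, K, expected):
        assert len(make_cv2_plan(30, K, 0).rounds) == expected

    def test_fold_sizes_near_equal_and_cover(self):
        plan = make_cv1_plan(23, 5, 3)
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(plan.folds)) == list(range(23))

    def test_cv1_toy_geometry(self):
        """K=3 over 9 drugs: 6 train drugs, 3 test drugs, 18 test pairs/round."""
        plan = make_cv1_plan(9, 3, 0)
        for rnd in plan.rounds:
            assert len(rnd.train_drugs) == 6
            assert len(rnd.test_group_a) == 3
            assert len(rnd.test_pairs()) == 18

    def test_cv1_test_sets_cover_all_between_fold_pairs(self):
        """Each cross-fold pair is tested in exactly the rounds of its two
        endpoint folds, so the union covers all between-fold pairs and the
        held-out drug groups are disjoint across rounds."""
        plan = make_cv1_plan(12, 3, 1)
        between = {
            (min(int(i), int(j)), max(int(i), int(j)))
            for a in range(3) for b in range(a + 1, 3)
            for i in plan.folds[a] for j in plan.folds[b]
        }
        tests = [r.test_pairs() for r in plan.rounds]
        assert set.union(*tests) == between
        from collections import Counter

        counts = Counter(p for t in tests for p in t)
        assert all(c == 2 for c in counts.values())
        groups = [set(r.test_group_a.tolist()) for r in plan.rounds]
        assert not (groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2])

    @pytest.mark.parametrize("scheme", ["cv1", "cv2"])
    @pytest.mark.parametrize("m,K", [(9, 3), (30, 5), (17, 4), (10, 5)])
    def test_pair_partition_exhaustive(self, scheme, m, K):
        """train/test/blind pair sets are disjoint and cover all pairs; no
        test drug appears in a train pair."""
        maker = make_cv1_plan if scheme == "cv1" else make_cv2_plan
        plan = maker(m, K, 7)
        universe = all_pairs(m)
        for rnd in plan.rounds:
            tr, te, bl = rnd.train_pairs(), rnd.test_pairs(), rnd.blind_pairs(m)
            assert tr | te | bl == universe
            assert not (tr & te or tr & bl or te & bl)
            test_drugs = set(rnd.test_group_a) | set(rnd.test_group_b)
            assert all(i not in test_drugs and j not in test_drugs for i, j in tr)

    def test_cv2_within_is_fold_interior_complement_of_cv1(self):
        """within-group CV2 test pairs = pairs inside each fold, exactly the
        pairs CV1 never tests inside that fold."""
        seed, m, K = 5, 12, 3
        cv1, cv2 = make_cv1_plan(m, K, seed), make_cv2_plan(m, K, seed)
        for k in range(K):
            fold = set(cv1.folds[k].tolist())
            interior = {(i, j) for i, j in all_pairs(m) if i in fold and j in fold}
            assert cv2.rounds[k].test_pairs() == interior
            assert not cv1.rounds[k].test_pairs() & interior

    def test_reproducible_from_seed(self):
        p1, p2 = make_cv2_plan(20, 4, 11), make_cv2_plan(20, 4, 11)
        assert all(np.array_equal(a, b) for a, b in zip(p1.folds, p2.folds))

    def test_too_few_drugs_rejected(self):
        with pytest.raises(ValueError):
            make_cv1_plan(3, 5, 0)


class TestScoreBinary:
    @pytest.mark.parametrize(
        "labels,scores,expected_auc",
        [
            ([1, 0], [0.9, 0.1], 1.0),
            ([1, 0], [0.1, 0.9], 0.0),
            ([1, 1, 0, 0], [4, 2, 3, 1], 0.75),
        ],
    )
    def test_known_rankings(self, labels, scores, expected_auc):
        assert score_binary(labels, scores).auc == pytest.approx(expected_auc)

    def test_aupr_matches_exhaustive_threshold_oracle(self):
        labels, scores = [1, 1, 0, 0], [4.0, 2.0, 3.0, 1.0]
        res = score_binary(labels, scores)
        assert res.aupr == pytest.approx(aupr_threshold_oracle(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="undefined metric"):
            score_binary([1, 1], [0.2, 0.3])

    @given(
        labels=st.lists(st.integers(0, 1), min_size=2, max_size=12),
        raw=st.lists(st.integers(-3, 3), min_size=12, max_size=12),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_pairwise_oracle(self, labels, raw):
        """AUC equals the O(n^2) Wilcoxon oracle (ties count one half) on all
        short lists, including heavy ties; AUPR equals the threshold oracle."""
        scores = raw[: len(labels)]
        if len(set(labels)) < 2:
            return
        res = score_binary(labels, scores)
        assert res.auc == pytest.approx(auc_pairwise_oracle(labels, scores))
        assert res.aupr == pytest.approx(aupr_threshold_oracle(labels, scores))

    @given(
        shift=st.floats(-5, 5),
        scale=st.floats(0.01, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_auc_invariant_under_monotone_transform(self, shift, scale):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.normal(size=30)
        base = score_binary(labels, scores).auc
        transformed = score_binary(labels, np.exp(scale * scores) + shift).auc
        assert transformed == pytest.approx(base)


class TestScoreComprehensive:
    def test_sign_flip_perfect_ranking(self):
        res = score_comprehensive([1, -1, 0], [2.0, -1.5, 0.1])
        assert res.auc == 1.0
        assert res.n_pos == 2 and res.n_neg == 1

    def test_sign_flip_inverted_ranking(self):
        assert score_comprehensive([1, -1, 0], [-2.0, 1.5, 0.1]).auc == 0.0

    def test_all_zero_scores_tie_to_half(self):
        # zero scores stay tied through the sign flip
        assert score_comprehensive([1, -1, 0, 0], [0.0, 0.0, 0.0, 0.0]).auc == 0.5

    def test_equal_nonzero_scores_break_ties_via_flip(self):
        # the flip negates the degressive score, so equal nonzero scores
        # are no longer tied: positives {0.3, -0.3} vs negatives {0.3, 0.3}
        assert score_comprehensive([1, -1, 0, 0], [0.3, 0.3, 0.3, 0.3]).auc == 0.25

    def test_invalid_labels(self):
        with pytest.raises(ValueError, match="labels"):
            score_comprehensive([2, 0], [0.1, 0.2])


class TestRunCv:
    def test_planted_noiseless_auc_well_above_chance(self, planted):
        res = run_cv(planted.A, planted.F, make_cv1_plan(60, 5, 0),
                     {"r": 3, "L": 10}, "comprehensive")
        assert res["auc"] > 0.8
        assert res["n_scored_rounds"] == 5
        assert 0 <= res["aupr"] <= 1

    def test_shuffled_labels_give_chance_auc(self, planted):
        """Destroying the label-feature association yields AUC ~ 0.5."""
        rng = np.random.default_rng(0)
        m = planted.A.n_drugs
        iu = np.triu_indices(m, k=1)
        aucs = []
        for _ in range(3):
            vals = planted.A.values[iu].copy()
            rng.shuffle(vals)
            null = np.zeros((m, m), dtype=np.int8)
            null[iu] = vals
            null += null.T
            A_null = InteractionMatrix(null, planted.A.drugs)
            res = run_cv(A_null, planted.F, make_cv1_plan(m, 5, 0),
                         {"r": 3, "L": 10}, "comprehensive")
            aucs.append(res["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_conventional_protocol_on_binary_network(self, planted):
        res = run_cv(planted.A, planted.F, make_cv1_plan(60, 5, 0),
                     {"r": "auto", "L": 10}, "conventional")
        assert res["protocol"] == "conventional"
        assert res["auc"] > 0.7

    def test_cv2_runs_all_round_kinds(self, planted):
        plan = make_cv2_plan(60, 3, 0)
        res = run_cv(planted.A, planted.F, plan, {"r": 3, "L": 10}, "comprehensive")
        assert res["n_rounds"] == 6
        assert res["auc"] > 0.5

    def test_reproducibility_same_seed_same_metrics(self, planted):
        r1 = run_cv(planted.A, planted.F, make_cv1_plan(60, 4, 9), {"L": 5})
        r2 = run_cv(planted.A, planted.F, make_cv1_plan(60, 4, 9), {"L": 5})
        assert r1["auc"] == r2["auc"] and r1["aupr"] == r2["aupr"]

    def test_repeat_cv_reports_dispersion(self, planted):
        res = repeat_cv(planted.A, planted.F, "cv1", 5, 3, seed=0,
                        hyperparams={"r": 3, "L": 10})
        assert len(res["auc_per_repeat"]) == 3
        assert res["auc_sd"] >= 0 and res["auc_sem"] <= res["auc_sd"] + 1e-12


class TestTuning:
    def test_single_element_grid(self, planted):
        assert tune_latent_factors(planted.A, planted.F, grid=[5], K=3, seed=0) == 5

    def test_planted_tuning_prefers_small_L(self, planted):
        best, table = tune_latent_factors(
            planted.A, planted.F, grid=[1, 5, 10, 20], K=3, seed=0, full_output=True
        )
        aucs = dict(table)
        assert best <= 10
        assert aucs[best] >= aucs[1]

    def test_empty_grid_rejected(self, planted):
        with pytest.raises(ValueError, match="non-empty"):
            tune_latent_factors(planted.A, planted.F, grid=[], K=3, seed=0)
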