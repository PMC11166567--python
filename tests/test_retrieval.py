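import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphmap import (
    NullDistributionCache,
    RankList,
    RetrievalScore,
    activity_filter,
    average_precision,
    bh_adjust,
    cosine_similarity,
    permutation_p,
    summarize_task,
    task_cross_modality,
    task_replicate_detection,
    task_sister_matching,
)
from morphmap.retrieval import average_precision_from_relevance
from conftest import ap_by_definition, build_table


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([1.0, 2.0, -3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        assert cosine_similarity([1, 0], [0, 5]) == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([-1.0, 2.0, -3.0])
        expected = a.dot(b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cosine_similarity(a, b) == pytest.approx(expected)
        assert cosine_similarity(a, b, "absolute") == pytest.approx(abs(expected))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity([0, 0], [1, 1])


class TestAveragePrecision:
    def test_perfect_retrieval_scores_one(self):
        rl = RankList("q", np.array([0.9, 0.8, 0.3, 0.2, 0.1]),
                      np.array([1, 1, 0, 0, 0], bool))
        assert average_precision(rl) == pytest.approx(1.0)

    def test_positives_at_ranks_one_and_three(self):
        # AP = 1/2 * 1 + 1/2 * 2/3 = 5/6 by hand enumeration
        rl = RankList("q", np.array([0.9, 0.5, 0.4, 0.3, 0.2]),
                      np.array([1, 0, 1, 0, 0], bool))
        assert average_precision(rl) == pytest.approx(5 / 6)

    def test_matches_definition_oracle_on_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            labels = np.zeros(n, bool)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
            sims = rng.normal(size=n)
            rl = RankList("q", sims, labels)
            assert average_precision(rl) == pytest.approx(
                ap_by_definition(rl.sorted_relevance())
            )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.booleans(), min_size=2, max_size=12).filter(
        lambda ls: any(ls) and not all(ls)))
    def test_equals_oracle_for_any_label_placement(self, labels):
        assert average_precision_from_relevance(np.array(labels)) == pytest.approx(
            ap_by_definition(labels)
        )

    def test_ap_is_one_iff_positives_precede_negatives(self):
        for labels in itertools.product([0, 1], repeat=6):
            if not any(labels) or all(labels):
                continue
            ap = average_precision_from_relevance(np.array(labels, bool))
            first_neg = labels.index(0)
            expected_perfect = all(l == 0 for l in labels[first_neg:])
            assert (ap == pytest.approx(1.0)) == expected_perfect

    def test_ties_broken_by_stable_order(self):
        rl = RankList("q", np.array([0.5, 0.5, 0.5]), np.array([0, 1, 0], bool))
        assert average_precision(rl) == pytest.approx(1 / 2)

    def test_rank_list_needs_both_label_kinds(self):
        with pytest.raises(ValueError, match="no relevant"):
            RankList("q", np.array([1.0, 0.5]), np.array([0, 0], bool))
        with pytest.raises(ValueError, match="no non-relevant"):
            RankList("q", np.array([1.0, 0.5]), np.array([1, 1], bool))


class TestPermutationP:
    def test_small_case_converges_to_exact_enumeration(self):
        # m=1, n=3: null AP support {1, 1/2, 1/3}, each with prob 1/3
        cache = NullDistributionCache(n_perm=30_000, seed=1)
        null = cache.null_aps(1, 3)
        for value, prob in [(1.0, 1 / 3), (0.5, 2 / 3), (1 / 3, 1.0)]:
            frac = (null >= value - 1e-12).mean()
            assert frac == pytest.approx(prob, abs=0.02)
        assert cache.p_value(1.0, 1, 3) == pytest.approx(1 / 3, abs=0.02)

    def test_perfect_ap_with_one_positive_in_100(self):
        # P(null AP = 1) = 1/100 by symmetry
        p = permutation_p(1.0, m=1, n=100, n_perm=999, seed=2)
        assert 0.005 <= p <= 0.02

    def test_ap_at_null_median_has_p_about_half(self):
        cache = NullDistributionCache(n_perm=9_999, seed=3)
        null = cache.null_aps(2, 20)
        assert cache.p_value(float(np.median(null)), 2, 20) == pytest.approx(0.5, abs=0.05)

    def test_null_shared_and_deterministic(self):
        a = NullDistributionCache(n_perm=1000, seed=4).null_aps(3, 30)
        b = NullDistributionCache(n_perm=1000, seed=4).null_aps(3, 30)
        np.testing.assert_array_equal(a, b)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            NullDistributionCache(n_perm=0)
        with pytest.raises(ValueError):
            NullDistributionCache(n_perm=10).null_aps(5, 5)


class TestBHAdjust:
    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_manual_step_up_oracle(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-4, 1, size=37)
        # manual BH: q_(i) = min_{j >= i} p_(j) * n / j
        order = np.argsort(p)
        n = len(p)
        q_sorted = [p[order[i]] * n / (i + 1) for i in range(n)]
        for i in range(n - 2, -1, -1):
            q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
        expected = np.empty(n)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-4, 1, size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestSummarizeTask:
    def test_single_class_geometric_mean(self):
        scores = [
            RetrievalScore("q1", "c", 0.8, 0.01, 0.04),
            RetrievalScore("q2", "c", 0.6, 0.01, 0.04),
        ]
        summ = summarize_task(scores)
        assert summ.per_class["combined_q"].iloc[0] == pytest.approx(0.04)
        assert summ.per_class["map"].iloc[0] == pytest.approx(0.7)
        assert summ.fraction_retrieved == 1.0

    def test_fraction_retrieved_counts_classes_below_threshold(self):
        scores = [
            RetrievalScore("q1", "a", 0.9, 0.005, 0.01),
            RetrievalScore("q2", "b", 0.4, 0.3, 0.2),
        ]
        assert summarize_task(scores).fraction_retrieved == 0.5

    def test_matches_pandas_free_group_by_oracle(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(60):
            rows.append(
                RetrievalScore(
                    f"q{i}", f"c{i % 7}", float(rng.uniform()),
                    float(rng.uniform(0.001, 1)), float(rng.uniform(0.001, 1)),
                )
            )
        summ = summarize_task(rows)
        by_class: dict[str, list[RetrievalScore]] = {}
        for s in rows:
            by_class.setdefault(s.class_id, []).append(s)
        for cid, members in by_class.items():
            expected_map = sum(s.ap for s in members) / len(members)
            expected_q = math.exp(
                sum(math.log(s.q_value) for s in members) / len(members)
            )
            row = summ.per_class.set_index("class_id").loc[cid]
            assert row["map"] == pytest.approx(expected_map)
            assert row["combined_q"] == pytest.approx(expected_q)


class TestTasks:
    @staticmethod
    def _strong_table(seed=0, n_plates=3):
        # well-separated perturbations: easy replicate retrieval
        rng = np.random.default_rng(seed)
        table = build_table(
            n_plates=n_plates,
            perturbations={f"cpd{i}": 1 for i in range(6)},
            n_negcon=8,
            n_features=20,
            seed=seed,
        )
        df = table.data
        feats = rng.normal(size=(len(df), 20)) * 0.05
        for i, pert in enumerate(df["Metadata_perturbation"].unique()):
            if pert == "DMSO":
                continue
            direction = np.zeros(20)
            direction[i % 20] = 3.0
            feats[(df["Metadata_perturbation"] == pert).to_numpy()] += direction
        return table.with_features(feats, table.feature_names)

    def test_replicate_detection_retrieves_strong_effects(self):
        summ = task_replicate_detection(self._strong_table(), n_perm=999, seed=0)
        assert summ.fraction_retrieved == 1.0
        assert (summ.scores["q_value"] >= summ.scores["p_value"] - 1e-12).all()

    def test_mixed_condition_table_rejected(self):
        table = self._strong_table()
        df = table.data.copy()
        df.loc[0, "Metadata_cell_type"] = "A549"
        from morphmap import ProfileTable

        with pytest.raises(ValueError, match="single condition"):
            task_replicate_detection(ProfileTable(df), n_perm=99)

    def test_table_without_negcon_rejected(self):
        table = self._strong_table()
        sub = table.subset(control_type="trt")
        with pytest.raises(ValueError, match="negative-control"):
            task_replicate_detection(sub, n_perm=99)

    def test_activity_filter_keeps_only_significant_perturbations(self):
        table = self._strong_table()
        summ = task_replicate_detection(table, n_perm=999, seed=0)
        active = activity_filter(table, summ)
        kept = set(active.data["Metadata_perturbation"])
        assert kept == set(summ.retrieved_classes())

    def test_sister_matching_rejects_orf(self):
        with pytest.raises(ValueError, match="ORF"):
            task_sister_matching(self._strong_table(), "orf")

    def test_sister_matching_finds_shared_target_compounds(self):
        rng = np.random.default_rng(3)
        n_cpd = 32  # 16 genes x 2 sister compounds
        perts = {f"cpd{i:02d}": 1 for i in range(n_cpd)}
        targets = {f"cpd{i:02d}": f"G{i // 2}" for i in range(n_cpd)}
        table = build_table(
            n_plates=2, perturbations=perts, n_negcon=4, n_features=40,
            seed=3, targets=targets,
        )
        df = table.data
        feats = 0.05 * rng.normal(size=(len(df), 40))
        for i in range(n_cpd):
            direction = np.zeros(40)
            direction[2 * (i // 2)] = 2.0
            sign = 1 if i % 2 == 0 else -1  # sisters may oppose: absolute mode
            feats[(df["Metadata_perturbation"] == f"cpd{i:02d}").to_numpy()] += sign * direction
        table = table.with_features(feats, table.feature_names)
        summ = task_sister_matching(table, "compound", n_perm=999, seed=1)
        assert summ.fraction_retrieved == 1.0
        assert set(summ.per_class["class_id"]) == {f"G{i}" for i in range(n_cpd // 2)}

    def test_cross_modality_sign_invariance_under_absolute_mode(self):
        rng = np.random.default_rng(4)
        n = 40
        cpd = build_table(
            n_plates=2, perturbations={f"cpd{i:02d}": 1 for i in range(n)},
            n_features=50, seed=4, targets={f"cpd{i:02d}": f"G{i}" for i in range(n)},
        )
        gen = build_table(
            n_plates=2, perturbations={f"orf{i:02d}": 1 for i in range(n)},
            n_features=50, seed=5, modality="orf",
            targets={f"orf{i:02d}": f"G{i}" for i in range(n)},
        )
        directions = rng.normal(size=(n, 50)) * 2
        for i in range(n):
            for t, key in ((cpd, "cpd"), (gen, "orf")):
                mask = (t.data["Metadata_perturbation"] == f"{key}{i:02d}").to_numpy()
                t.data.loc[mask, t.feature_names] += directions[i]
        flipped = gen.with_features(-gen.features, gen.feature_names)
        a = task_cross_modality(cpd, gen, n_perm=999, seed=2)
        b = task_cross_modality(cpd, flipped, n_perm=999, seed=2)
        pd.testing.assert_frame_equal(a.per_class, b.per_class)
        assert a.fraction_retrieved == 1.0
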