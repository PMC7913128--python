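"""Model selection, clustering, relevance, global desirability, overlaps."""

import numpy as np
import pandas as pd
import pytest

from moscreen.consensus import (
    ModelPopulation,
    category_counts,
    cluster_correlation,
    cluster_models,
    global_desirability,
    relevance_profile,
    select_models,
    target_relevance,
    top_overlap,
)
from moscreen.desirability import ProbabilityMatrix, desirability_scores


def pop_from(masks, fits, threshold=-1.0):
    return ModelPopulation(np.array(masks, bool), np.array(fits, float),
                           threshold)


class TestSelectModels:
    masks = [[1, 0, 1], [1, 1, 1], [0, 1, 1]]

    def test_inclusive_boundary(self):
        kept = select_models(self.masks, [0.10, 0.15, 0.20], threshold=0.15)
        assert len(kept) == 2
        assert (kept.fitnesses >= 0.15).all()

    def test_threshold_below_everything_keeps_all(self):
        kept = select_models(self.masks, [0.1, 0.2, 0.3], threshold=-1)
        assert len(kept) == 3

    def test_duplicates_retained(self):
        kept = select_models([[1, 0, 1]] * 4, [0.2] * 4, threshold=0.15)
        assert len(kept) == 4

    def test_empty_selection_raises_with_hint(self):
        with pytest.raises(ValueError, match="lower the threshold"):
            select_models(self.masks, [0.1, 0.1, 0.1], threshold=0.5)


class TestClusterModels:
    def test_k_one_single_cluster(self):
        models = pop_from([[1, 0], [0, 1], [1, 1]], [0.2] * 3)
        assign = cluster_models(models, k=1)
        assert set(assign.labels) == {1}

    def test_two_identical_groups_separate_perfectly(self):
        masks = [[1, 1, 0, 0]] * 5 + [[0, 0, 1, 1]] * 4
        models = pop_from(masks, [0.2] * 9)
        assign = cluster_models(models, k=2)
        a = set(assign.labels[:5])
        b = set(assign.labels[5:])
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_deterministic(self, rng):
        masks = rng.integers(0, 2, size=(20, 8))
        models = pop_from(masks, [0.2] * 20)
        l1 = cluster_models(models, k=4).labels
        l2 = cluster_models(models, k=4).labels
        assert np.array_equal(l1, l2)

    def test_k_larger_than_population_rejected(self):
        models = pop_from([[1, 0]], [0.2])
        with pytest.raises(ValueError):
            cluster_models(models, k=5)


class TestRelevance:
    def test_direct_formula(self):
        masks = np.array([[1, 0], [1, 0], [1, 1], [0, 1]], bool)
        s = relevance_profile(masks)
        assert s[0] == pytest.approx(0.75)  # 3 of 4 models
        assert s[1] == pytest.approx(0.5)

    def test_bounds(self):
        masks = np.array([[1, 0], [1, 0]], bool)
        s = relevance_profile(masks)
        assert s.tolist() == [1.0, 0.0]

    def test_counting_oracle_random_fixture(self, rng):
        masks = rng.integers(0, 2, size=(20, 6)).astype(bool)
        s = relevance_profile(masks)
        brute = [sum(masks[j, i] for j in range(20)) / 20 for i in range(6)]
        assert np.allclose(s, brute)

    def test_aggregation_consistency_across_clusters(self, rng):
        # size-weighted cluster relevances recompose the global frequency
        masks = rng.integers(0, 2, size=(30, 5)).astype(bool)
        models = pop_from(masks, [0.2] * 30)
        assign = cluster_models(models, k=3)
        total = np.zeros(5)
        for c in assign.cluster_ids:
            idx = assign.members(c)
            total += relevance_profile(masks[idx]) * len(idx)
        assert np.allclose(total / 30, relevance_profile(masks))


class TestGlobalDesirability:
    def library(self):
        rng = np.random.default_rng(7)
        P = rng.random((12, 4))
        return ProbabilityMatrix(
            P, tuple(f"d{i}" for i in range(12)),
            ("t0", "t1", "t2", "o0"),
            np.array(["target"] * 3 + ["off_target"], dtype=object),
        )

    def test_single_model_cluster_equals_its_desirability(self):
        lib = self.library()
        masks = [[1, 1, 0, 1]]
        models = pop_from(masks, [0.3])
        assign = cluster_models(models, k=1)
        gd = global_desirability(lib, models, assign)
        d, _, _ = desirability_scores(lib, np.array(masks[0], bool))
        assert np.allclose(gd["C1"].to_numpy(), d)

    def test_mean_of_two_models(self):
        lib = self.library()
        masks = [[1, 1, 0, 1], [0, 1, 1, 1]]
        models = pop_from(masks, [0.3, 0.2])
        assign = cluster_models(models, k=1)
        gd = global_desirability(lib, models, assign)
        d0, _, _ = desirability_scores(lib, np.array(masks[0], bool))
        d1, _, _ = desirability_scores(lib, np.array(masks[1], bool))
        assert np.allclose(gd["C1"].to_numpy(), (d0 + d1) / 2)

    def test_brute_force_double_loop_oracle(self, rng):
        lib = self.library()
        masks = []
        while len(masks) < 10:
            m = rng.integers(0, 2, size=4)
            if m[:3].any() and m[3]:
                masks.append(m)
        models = pop_from(masks, [0.2] * 10)
        assign = cluster_models(models, k=3)
        gd = global_desirability(lib, models, assign)
        for c in assign.cluster_ids:
            idx = assign.members(c)
            for i, cid in enumerate(lib.compound_ids):
                acc = []
                for j in idx:
                    d, _, _ = desirability_scores(lib,
                                                  models.masks[j])
                    acc.append(d[i])
                assert gd.at[cid, f"C{c}"] == pytest.approx(np.mean(acc))

    def test_gd_between_min_and_max_model_desirability(self, rng):
        lib = self.library()
        masks = [[1, 0, 1, 1], [1, 1, 1, 1], [0, 1, 0, 1]]
        models = pop_from(masks, [0.2] * 3)
        assign = cluster_models(models, k=1)
        gd = global_desirability(lib, models, assign)
        ds = np.array([
            desirability_scores(lib, np.array(m, bool))[0] for m in masks
        ])
        assert (gd["C1"].to_numpy() >= ds.min(axis=0) - 1e-12).all()
        assert (gd["C1"].to_numpy() <= ds.max(axis=0) + 1e-12).all()

    def test_invalid_mask_skipped_with_warning(self):
        lib = self.library()
        masks = [[1, 1, 0, 1], [1, 1, 0, 0]]  # second has no off-target
        models = pop_from(masks, [0.3, 0.3])
        assign = cluster_models(models, k=1)
        with pytest.warns(UserWarning, match="invalid"):
            gd = global_desirability(lib, models, assign)
        d0, _, _ = desirability_scores(lib, np.array(masks[0], bool))
        assert np.allclose(gd["C1"].to_numpy(), d0)


class TestTopOverlap:
    def test_identical_rankings(self):
        gd = pd.DataFrame(
            {"C1": [0.9, 0.5, 0.1], "C2": [0.9, 0.5, 0.1]},
            index=["a", "b", "c"],
        )
        ov = top_overlap(gd, top_n=2)
        assert ov.union_size == 2 and ov.intersection_size == 2
        assert ov.venn_counts == {("C1", "C2"): 2}

    def test_disjoint_rankings(self):
        gd = pd.DataFrame(
            {
                "C1": [4, 3, 0, 0, 0, 0],
                "C2": [0, 0, 4, 3, 0, 0],
                "C3": [0, 0, 0, 0, 4, 3],
            },
            index=list("abcdef"), dtype=float,
        )
        ov = top_overlap(gd, top_n=2)
        assert ov.union_size == 6 and ov.intersection_size == 0
        assert ov.top_lists["C1"] == ["a", "b"]

    def test_intersection_contained_in_every_top_list(self, rng):
        gd = pd.DataFrame(
            rng.random((40, 4)), index=[f"d{i}" for i in range(40)],
            columns=[f"C{i}" for i in range(1, 5)],
        )
        ov = top_overlap(gd, top_n=10)
        for col, ids in ov.top_lists.items():
            assert ov.intersection <= set(ids)
        assert sum(ov.venn_counts.values()) == ov.union_size


class TestClusterCorrelation:
    def test_identical_vectors(self, rng):
        v = rng.random(30)
        gd = pd.DataFrame({"C1": v, "C2": v.copy()})
        mat, mean, lo, hi = cluster_correlation(gd)
        assert mean == pytest.approx(1.0)
        assert np.allclose(mat.to_numpy(), 1.0)

    def test_anti_correlated_vectors(self, rng):
        v = rng.random(30)
        gd = pd.DataFrame({"C1": v, "C2": -v})
        _, mean, lo, hi = cluster_correlation(gd)
        assert mean == pytest.approx(-1.0)

    def test_symmetric_psd_with_unit_diagonal(self, rng):
        gd = pd.DataFrame(rng.random((50, 4)),
                          columns=["C1", "C2", "C3", "C4"])
        mat, mean, lo, hi = cluster_correlation(gd)
        a = mat.to_numpy()
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)
        assert np.linalg.eigvalsh(a).min() > -1e-10
        assert lo <= mean <= hi

    def test_zero_variance_rejected(self):
        gd = pd.DataFrame({"C1": [0.5, 0.5], "C2": [0.1, 0.9]})
        with pytest.raises(ValueError, match="variance"):
            cluster_correlation(gd)


class TestCategoryCounts:
    def test_empty(self):
        assert category_counts([], {}) == {}

    def test_shared_code_counts_per_drug(self):
        table = {"a": ["N02"], "b": ["N02"], "c": ["N02", "C01"]}
        counts = category_counts(["a", "b", "c"], table)
        assert counts == {"N02": 3, "C01": 1}

    def test_hand_tally_fixture(self):
        table = {
            "d1": ["A"], "d2": ["A", "B"], "d3": ["C"], "d4": ["B"],
            "d5": ["A"], "d6": ["D", "A"], "d7": ["C"], "d8": ["B"],
        }
        drugs = ["d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "dX", "dY"]
        counts = category_counts(drugs, table)
        assert counts == {"A": 4, "B": 3, "C": 2, "D": 1, "unannotated": 2}
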