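"""AUC, correlation, importance, consensus, EI classes and niche overlap."""

import numpy as np
import pytest

from mitoniche.evaluate import (
    EI_CLASSES,
    ConsensusSpec,
    auc,
    classify_ei,
    consensus,
    niche_dynamics,
    niche_overlap,
    permutation_importance,
    point_biserial,
    rescale01,
    write_overlap_csv,
)
from mitoniche.raster import SuitabilityRaster


def raster(values, scale="rescaled01"):
    v = np.asarray(values, dtype=float)
    return SuitabilityRaster(v, scale, np.ones(v.shape, dtype=bool))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_all_ties(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_pair_enumeration(self):
        # pairs: (.9,.85)+ (.9,.7)+ (.8,.85)- (.8,.7)+  -> 3/4
        assert auc([0.9, 0.8], [0.85, 0.7]) == pytest.approx(0.75)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        sp, sb = rng.normal(1, 1, 50), rng.normal(0, 1, 80)
        assert auc(np.exp(sp), np.exp(sb)) == pytest.approx(auc(sp, sb))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        sp = rng.normal(0.5, 1, 60)
        sb = rng.normal(0.0, 1, 90)
        y = np.r_[np.ones(60), np.zeros(90)]
        s = np.r_[sp, sb]
        assert auc(sp, sb) == pytest.approx(roc_auc_score(y, s))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestPointBiserial:
    def test_scores_equal_labels(self):
        assert point_biserial([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_hand_computed_case(self):
        scores = np.array([0.9, 0.7, 0.4, 0.2])
        labels = np.array([1, 1, 0, 0])
        expected = np.corrcoef(scores, labels)[0, 1]
        from scipy.stats import pointbiserialr

        assert point_biserial(scores, labels) == pytest.approx(expected)
        assert point_biserial(scores, labels) == pytest.approx(
            pointbiserialr(labels, scores).statistic
        )

    def test_null_near_zero_at_large_n(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=1000)
        labels = rng.permutation(np.r_[np.ones(500), np.zeros(500)])
        assert abs(point_biserial(scores, labels)) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            point_biserial([1.0, 1.0], [0, 1])


class TestPermutationImportance:
    def test_driving_variable_ranked_first(self, recovery_run):
        imp = permutation_importance(
            recovery_run.maxent, recovery_run.stack, recovery_run.test_points,
            recovery_run.background, seed=0, repeats=2,
        )
        ranked = sorted(imp["auc_drop"], key=imp["auc_drop"].get, reverse=True)
        assert ranked[0] == "bio1"  # the strongest response variable
        assert sum(imp["percent_contribution"].values()) == pytest.approx(100.0)

    def test_irrelevant_variable_has_small_drop(self, recovery_run):
        imp = permutation_importance(
            recovery_run.maxent, recovery_run.stack, recovery_run.test_points,
            recovery_run.background, seed=0, repeats=2,
        )
        # bio5 plays no role in the species response
        assert imp["auc_drop"]["bio5"] < 0.05

    def test_ranking_stable_across_repeat_counts(self, recovery_run):
        args = (recovery_run.maxent, recovery_run.stack,
                recovery_run.test_points, recovery_run.background)
        r1 = permutation_importance(*args, seed=3, repeats=1)
        r2 = permutation_importance(*args, seed=3, repeats=5)
        rank = lambda d: sorted(d, key=d.get, reverse=True)[:2]
        assert rank(r1["auc_drop"]) == rank(r2["auc_drop"])


class TestRescale01:
    def test_examples(self):
        out = rescale01(raster([[2.0, 4.0, 6.0]], scale="raw"))
        assert np.allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_idempotent_when_bounds_attained(self):
        r = raster([[0.0, 0.3, 1.0]])
        assert np.allclose(rescale01(r).values, r.values)

    def test_bounds_always_zero_and_one(self):
        rng = np.random.default_rng(3)
        r = raster(rng.uniform(5, 9, (4, 4)), scale="raw")
        out = rescale01(r).values
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_raster_rejected(self):
        with pytest.raises(ValueError):
            rescale01(raster([[0.5, 0.5]]))


class TestConsensus:
    def test_identical_rasters_unchanged(self):
        r = raster([[0.2, 0.8]])
        out = consensus([r, r], [0.9, 0.6])
        assert np.allclose(out.values, r.values)

    def test_weighted_average_of_constants(self):
        out = consensus([raster([[1.0]]), raster([[0.0]])], [0.9, 0.6])
        assert out.values[0, 0] == pytest.approx(0.6)  # 0.9 / 1.5

    def test_weights_normalised(self):
        assert ConsensusSpec([0.9, 0.6]).weights.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ConsensusSpec([0.0, 0.5])

    def test_bounded_by_members(self):
        rng = np.random.default_rng(4)
        a, b = raster(rng.uniform(0, 1, (5, 5))), raster(rng.uniform(0, 1, (5, 5)))
        out = consensus([a, b], [0.8, 0.7]).values
        assert (out <= np.maximum(a.values, b.values) + 1e-12).all()
        assert (out >= np.minimum(a.values, b.values) - 1e-12).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            consensus([raster([[0.1]]), raster([[0.1, 0.2]])], [0.9, 0.9])


class TestClassifyEi:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, "unsuitable"),
            (0.1, "marginal"),
            (0.19, "marginal"),
            (0.2, "high"),
            (0.35, "high"),
            (0.49, "high"),
            (0.5, "optimal"),
            (1.0, "optimal"),
        ],
    )
    def test_printed_thresholds(self, value, label):
        cls = classify_ei(raster([[value]]))
        assert EI_CLASSES[cls.classes[0, 0]] == label

    def test_dense_grid_partition_exhaustive_exclusive(self):
        vals = np.linspace(0, 1, 2001).reshape(1, -1)
        cls = classify_ei(raster(vals))
        assert set(np.unique(cls.classes)) <= {0, 1, 2, 3}
        # class boundaries in order, no gaps: monotone class codes along values
        assert (np.diff(cls.classes[0]) >= 0).all()
        fractions = [cls.fraction(lab) for lab in EI_CLASSES]
        assert sum(fractions) == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_ei(raster([[0.5, 1.5]], scale="raw"))


class TestNicheOverlap:
    def test_identical_rasters(self):
        r = raster([[0.0, 0.4], [0.8, 0.1]])
        res = niche_overlap(r, r)
        assert np.allclose(res.overlap_raster.values, r.values)
        assert not res.a_only.any() and not res.b_only.any()

    def test_disjoint_suitable_regions(self):
        a = raster([[0.9, 0.0]])
        b = raster([[0.0, 0.9]])
        res = niche_overlap(a, b)
        assert not res.both_suitable.any()
        assert res.fractions["a_only"] == pytest.approx(0.5)

    def test_hand_built_3x3_masks(self):
        a = raster([[0.6, 0.0, 0.3], [0.0, 0.5, 0.0], [0.2, 0.0, 0.0]])
        b = raster([[0.0, 0.0, 0.4], [0.7, 0.5, 0.0], [0.2, 0.0, 0.9]])
        res = niche_overlap(a, b, threshold=0.0)
        assert res.both_suitable.tolist() == [
            [False, False, True], [False, True, False], [True, False, False]]
        assert res.a_only.tolist() == [
            [True, False, False], [False, False, False], [False, False, False]]
        assert res.b_only.tolist() == [
            [False, False, False], [True, False, False], [False, False, True]]

    def test_min_method_symmetric_and_masks_partition_union(self):
        rng = np.random.default_rng(5)
        a, b = raster(rng.uniform(0, 1, (6, 6))), raster(rng.uniform(0, 1, (6, 6)))
        r1 = niche_overlap(a, b)
        r2 = niche_overlap(b, a)
        assert np.allclose(r1.overlap_raster.values, r2.overlap_raster.values)
        union = r1.both_suitable | r1.a_only | r1.b_only
        assert not (r1.both_suitable & r1.a_only).any()
        assert not (r1.a_only & r1.b_only).any()
        assert union.sum() == (r1.both_suitable.sum() + r1.a_only.sum()
                               + r1.b_only.sum())

    def test_subtract_equals_min(self):
        rng = np.random.default_rng(6)
        a, b = raster(rng.uniform(0, 1, (5, 5))), raster(rng.uniform(0, 1, (5, 5)))
        assert np.allclose(
            niche_overlap(a, b, method="subtract").overlap_raster.values,
            niche_overlap(a, b, method="min").overlap_raster.values,
        )

    def test_overlap_csv(self, tmp_path):
        res = niche_overlap(raster([[0.9, 0.0]]), raster([[0.9, 0.9]]))
        write_overlap_csv(res, tmp_path / "o.csv")
        text = (tmp_path / "o.csv").read_text()
        assert "both_suitable,1,0.5" in text


class TestNicheDynamics:
    def test_identical_ranges_full_stability(self):
        rng = np.random.default_rng(7)
        avail = rng.normal(size=(500, 3))
        occupied = avail[:100]
        res = niche_dynamics(occupied, occupied, avail, bins=10)
        assert res == pytest.approx(
            {"expansion": 0.0, "unfilling": 0.0, "stability": 1.0,
             "n_analogous_bins": res["n_analogous_bins"]}
        )

    def test_disjoint_available_region_full_expansion(self):
        avail = np.vstack([np.full((100, 2), 0.0), np.full((100, 2), 10.0)])
        avail += np.random.default_rng(8).normal(scale=0.1, size=avail.shape)
        native = avail[:50]
        invaded = avail[150:]
        res = niche_dynamics(native, invaded, avail, bins=4)
        assert res["expansion"] == 1.0 and res["stability"] == 0.0
        assert res["unfilling"] == 1.0

    def test_two_bin_hand_count(self):
        # available space splits into a low and a high bin; native occupies
        # both, invaded only the high bin -> expansion 0, stability 1,
        # unfilling 1/2
        avail = np.array([[0.0], [0.0], [1.0], [1.0]] * 10)
        native = np.array([[0.0], [1.0]])
        invaded = np.array([[1.0]])
        res = niche_dynamics(native, invaded, avail, bins=2)
        assert res["expansion"] == 0.0
        assert res["stability"] == 1.0
        assert res["unfilling"] == pytest.approx(0.5)

    def test_expansion_plus_stability_is_one(self):
        rng = np.random.default_rng(9)
        avail = rng.normal(size=(400, 4))
        native = avail[rng.choice(400, 80)]
        invaded = avail[rng.choice(400, 80)]
        res = niche_dynamics(native, invaded, avail, bins=8)
        assert res["expansion"] + res["stability"] == pytest.approx(1.0)
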