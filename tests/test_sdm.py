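"""Occurrence handling, BIOCLIM envelope and MaxEnt fitting."""

import numpy as np
import pytest
from scipy.stats import chisquare

from mitoniche.raster import ClimateStack, GridTransform
from mitoniche.sdm import (
    OccurrenceSet,
    _tail_score,
    build_feature_map,
    dedup_occurrences,
    fit_bioclim,
    fit_maxent,
    moment_condition_gaps,
    predict_bioclim,
    predict_maxent,
    read_occurrences_csv,
    sample_background,
    train_test_split,
    write_occurrences_csv,
)


def centers(stack, cells):
    return np.array([stack.transform.center_of(r, c, stack.nrows) for r, c in cells])


class TestDedup:
    def test_exact_duplicates_removed(self, tiny_stack):
        pts = centers(tiny_stack, [(1, 1), (1, 1), (2, 2)])
        occ = dedup_occurrences(pts, tiny_stack)
        assert len(occ) == 2

    def test_one_per_cell(self, tiny_stack):
        # two distinct coordinates inside the same 1-degree cell
        base = centers(tiny_stack, [(4, 4)])[0]
        pts = np.array([base, base + 0.2])
        assert len(dedup_occurrences(pts, tiny_stack)) == 2
        assert len(dedup_occurrences(pts, tiny_stack, one_per_cell=True)) == 1

    def test_nodata_points_dropped(self):
        mask = np.ones((10, 10), dtype=bool)
        mask[5, 5] = False
        stack = ClimateStack(["v"], np.ones((1, 10, 10)), GridTransform(0, 0, 1), mask)
        pts = centers(stack, [(5, 5), (2, 2)])
        occ = dedup_occurrences(pts, stack)
        assert len(occ) == 1

    def test_all_unusable_raises(self, tiny_stack):
        with pytest.raises(ValueError, match="no usable"):
            dedup_occurrences(np.array([[-500.0, -500.0]]), tiny_stack)


class TestSplit:
    def test_75_25(self):
        occ = OccurrenceSet("s", np.column_stack([np.arange(100), np.arange(100)]))
        train, test = train_test_split(occ, 0.75, seed=0)
        assert (len(train), len(test)) == (75, 25)

    def test_four_points_floor_rule(self):
        occ = OccurrenceSet("s", np.column_stack([np.arange(4), np.arange(4)]))
        train, test = train_test_split(occ, 0.75, seed=0)
        assert (len(train), len(test)) == (3, 1)

    def test_deterministic_disjoint_exhaustive(self):
        occ = OccurrenceSet("s", np.column_stack([np.arange(37), np.arange(37)]))
        t1 = train_test_split(occ, seed=5)
        t2 = train_test_split(occ, seed=5)
        assert np.array_equal(t1[0].points, t2[0].points)
        assert np.array_equal(t1[1].points, t2[1].points)
        joined = np.vstack([t1[0].points, t1[1].points])
        assert len(np.unique(joined, axis=0)) == 37

    def test_too_few_points(self):
        occ = OccurrenceSet("s", np.array([[0, 0], [1, 1], [2, 2]]))
        with pytest.raises(ValueError):
            train_test_split(occ, seed=0)


class TestBackground:
    def test_distinct_cells_exclude_presences(self, tiny_stack):
        occ = OccurrenceSet("s", centers(tiny_stack, [(0, 0), (1, 1)]))
        bg = sample_background(tiny_stack, n=50, exclude=occ, seed=0)
        cells = tiny_stack.cell_of_points(bg)
        assert len(np.unique(cells, axis=0)) == 50
        forbidden = {(0, 0), (1, 1)}
        assert not forbidden & {tuple(c) for c in cells}

    def test_insufficient_cells_raises(self, tiny_stack):
        with pytest.raises(ValueError, match="insufficient"):
            sample_background(tiny_stack, n=101, seed=0)

    def test_uniform_over_repeats(self, tiny_stack):
        counts = np.zeros(100)
        for rep in range(200):
            bg = sample_background(tiny_stack, n=20, seed=rep)
            cells = tiny_stack.cell_of_points(bg)
            counts[cells[:, 0] * 10 + cells[:, 1]] += 1
        assert chisquare(counts).pvalue > 0.01


class TestBioclim:
    def test_summary_statistics(self):
        env = fit_bioclim(np.arange(1, 6, dtype=float)[:, None], ["v"])
        assert env.min[0] == 1 and env.max[0] == 5 and env.mean[0] == 3

    def test_constant_variable_sd_zero_ok(self):
        x = np.ones((6, 1))
        env = fit_bioclim(x, ["v"])
        assert env.sd[0] == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_bioclim(np.ones((4, 1)))

    def test_tail_score_examples(self):
        sample = np.arange(1.0, 6.0)  # {1..5}
        # 2 * min(P(X<=2), P(X>=2)) = 2 * min(0.4, 0.8) = 0.8
        assert _tail_score(np.array([2.0]), sample)[0] == pytest.approx(0.8)
        # the median saturates the score
        assert _tail_score(np.array([3.0]), sample)[0] == pytest.approx(1.0)

    def _env_stack(self, values):
        grid = np.asarray(values, dtype=float).reshape(1, 1, -1)
        mask = np.ones(grid.shape[1:], dtype=bool)
        return ClimateStack(["v"], grid, GridTransform(0, 0, 1), mask)

    def test_percentile_prediction(self):
        env = fit_bioclim(np.arange(1, 6, dtype=float)[:, None], ["v"])
        stack = self._env_stack([2.0, 3.0, 6.0, 0.5])
        pred = predict_bioclim(env, stack)
        vals = pred.values[0]
        assert vals[0] == pytest.approx(0.8)
        assert vals[1] == pytest.approx(1.0)  # presence median scores 1
        assert vals[2] == 0.0  # above the presence maximum
        assert vals[3] == 0.0  # below the presence minimum

    def test_min_over_variables(self):
        pres = np.column_stack([np.arange(1, 6, dtype=float),
                                np.arange(1, 6, dtype=float)])
        env = fit_bioclim(pres, ["a", "b"])
        grid = np.stack([np.full((1, 1), 3.0), np.full((1, 1), 2.0)])
        stack = ClimateStack(["a", "b"], grid, GridTransform(0, 0, 1),
                             np.ones((1, 1), dtype=bool))
        pred = predict_bioclim(env, stack)
        assert pred.values[0, 0] == pytest.approx(0.8)  # min(1.0, 0.8)

    def test_meansd_mode_rectangular(self):
        env = fit_bioclim(np.arange(1, 6, dtype=float)[:, None], ["v"])
        stack = self._env_stack([3.0, 30.0])
        pred = predict_bioclim(env, stack, mode="meansd", k=2.0)
        assert pred.values[0, 0] == 1.0 and pred.values[0, 1] == 0.0

    def test_missing_variable_rejected(self, tiny_stack):
        env = fit_bioclim(np.ones((5, 1)), ["not-there"])
        with pytest.raises(ValueError):
            predict_bioclim(env, tiny_stack)

    def test_affine_invariance(self, stack):
        rng = np.random.default_rng(0)
        pres_cells = stack.valid_cells()[rng.choice(10000, 40, replace=False)]
        pres = stack.values_at_cells(pres_cells)
        env = fit_bioclim(pres, stack.names)
        pred = predict_bioclim(env, stack)
        grids = stack.grids.copy()
        grids[0] = 3.5 * grids[0] - 200.0
        pres2 = pres.copy()
        pres2[:, 0] = 3.5 * pres2[:, 0] - 200.0
        stack2 = ClimateStack(stack.names, grids, stack.transform, stack.mask)
        pred2 = predict_bioclim(fit_bioclim(pres2, stack.names), stack2)
        assert np.allclose(pred.values[stack.mask], pred2.values[stack.mask])


class TestMaxent:
    def test_no_signal_gives_near_uniform_model(self, tiny_stack):
        env = tiny_stack.env_table()
        rng = np.random.default_rng(1)
        pres = env[rng.choice(len(env), 40, replace=False)]
        m = fit_maxent(pres, env, variables=tiny_stack.names)
        # L1 shrinkage keeps weights essentially at zero without signal
        assert np.abs(m.weights).max() < 0.35
        raw = m.raw_at(env)
        assert raw.max() / raw.min() < 3.0

    def test_two_cell_analytic_solution(self):
        # background on {-1, +1}: quadratic feature is constant (dead), the
        # linear feature is its own standardisation, and the Gibbs mean is
        # tanh(lambda); with presence mean m the L1 optimum is atanh(m - beta)
        bg = np.array([[-1.0], [1.0]] * 50)
        pres = np.array([[1.0]] * 8 + [[-1.0]] * 2)
        m_pres = pres.mean()
        beta = 0.05 * pres.std()
        model = fit_maxent(pres, bg, variables=["f"])
        lam_expected = np.arctanh(m_pres - beta)
        assert model.weights[0] == pytest.approx(lam_expected, abs=1e-4)
        assert abs(model.weights[1]) < 1e-8  # dead quadratic feature

    def test_moment_condition_audit(self, recovery_run):
        # KKT post-condition: fitted background moments stay within the L1
        # budget of the training presence means, for every feature
        model = recovery_run.maxent
        train_env = recovery_run.stack.extract(recovery_run.train_points)
        gaps = moment_condition_gaps(model, train_env)
        assert gaps.shape == model.beta.shape
        assert np.all(gaps <= model.beta + 1e-5)

    def test_scaling_invariance(self, stack):
        rng = np.random.default_rng(2)
        cells = stack.valid_cells()[rng.choice(10000, 60, replace=False)]
        pres = stack.values_at_cells(cells)
        bg_cells = stack.valid_cells()[rng.choice(10000, 500, replace=False)]
        bg = stack.values_at_cells(bg_cells)
        m1 = fit_maxent(pres, bg, variables=stack.names)
        pres2, bg2 = pres.copy(), bg.copy()
        pres2[:, 0] *= 40.0
        bg2[:, 0] *= 40.0
        m2 = fit_maxent(pres2, bg2, variables=stack.names)
        assert np.allclose(m1.raw_at(bg), m2.raw_at(bg2), rtol=1e-5)

    def test_raw_sums_to_one_over_background(self, tiny_stack):
        env = tiny_stack.env_table()
        rng = np.random.default_rng(3)
        pres = env[rng.choice(len(env), 30, replace=False)]
        m = fit_maxent(pres, env, variables=tiny_stack.names)
        pred = predict_maxent(m, tiny_stack, scale="raw")
        assert pred.values[tiny_stack.mask].sum() == pytest.approx(1.0)

    def test_uniform_model_raw_is_one_over_n(self, tiny_stack):
        env = tiny_stack.env_table()
        fmap = build_feature_map(env, tiny_stack.names)
        from mitoniche.sdm import MaxentModel

        m = MaxentModel(fmap, np.zeros(fmap.n_features), np.full(fmap.n_features, 0.01),
                        env)
        pred = predict_maxent(m, tiny_stack, scale="raw")
        assert np.allclose(pred.values[tiny_stack.mask], 1.0 / env.shape[0])

    def test_cloglog_in_unit_interval(self, recovery_run):
        pred = predict_maxent(recovery_run.maxent, recovery_run.stack,
                              scale="cloglog")
        v = pred.values[recovery_run.stack.mask]
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_monotone_in_positively_weighted_variable(self):
        # species prefers high v: suitability must increase with v
        rng = np.random.default_rng(4)
        bg = np.column_stack([rng.uniform(0, 10, 400), rng.normal(size=400)])
        pres = np.column_stack([rng.uniform(7, 10, 60), rng.normal(size=60)])
        m = fit_maxent(pres, bg, variables=["v", "w"])
        grid_v = np.linspace(1.0, 9.0, 20)
        env = np.column_stack([grid_v, np.zeros(20)])
        raw = m.raw_at(env)
        assert raw[-1] > raw[0]

    def test_sign_recovery_for_log_linear_species(self):
        # presence density proportional to exp(2 * v): lambda_v should be
        # positive and dominate the weights of the irrelevant variables
        rng = np.random.default_rng(5)
        bg = np.column_stack([rng.uniform(-1, 1, 2000),
                              rng.uniform(-1, 1, 2000),
                              rng.uniform(-1, 1, 2000)])
        w = np.exp(2.0 * bg[:, 0])
        pres = bg[rng.choice(len(bg), 300, p=w / w.sum())]
        m = fit_maxent(pres, bg, variables=["v", "a", "b"])
        lam = dict(zip(m.feature_map.feature_names, m.weights))
        assert lam["v"] > 0
        assert lam["v"] > abs(lam["a"]) and lam["v"] > abs(lam["b"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_maxent(np.empty((0, 2)), np.ones((5, 2)))


class TestOccurrenceCsv:
    def test_round_trip(self, tmp_path):
        sets = [
            OccurrenceSet("a", np.array([[1.5, 2.5], [3.0, 4.0]])),
            OccurrenceSet("b", np.array([[0.0, 0.0]])),
        ]
        write_occurrences_csv(sets, tmp_path / "occ.csv")
        got = read_occurrences_csv(tmp_path / "occ.csv")
        assert set(got) == {"a", "b"}
        assert np.allclose(got["a"].points, sets[0].points)
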