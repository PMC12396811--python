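"""Tests of joint densities, regulation-strength series, Wasserstein distances
and trend classification."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor

from branchdyn import (assign_windows, joint_density,
                       regulation_strength_series, trend_classification,
                       wasserstein_1d, wasserstein_matrix)
from branchdyn.errors import DegenerateDataError, InvalidParameterError
from branchdyn.scenarios import regulation_ramp_dataset


class TestJointDensity:
    def test_peak_near_origin_for_standard_normals(self):
        # the single-sample KDE argmax scatters by ~0.1 at n=5000, so check
        # its average location over a few seeds (grid fine enough that the
        # spacing does not dominate)
        peaks = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            xs, ys, dens = joint_density(rng.normal(0, 1, 5000),
                                         rng.normal(0, 1, 5000), grid=256)
            i, j = np.unravel_index(np.argmax(dens), dens.shape)
            peaks.append((xs[i], ys[j]))
        mean_peak = np.mean(peaks, axis=0)
        assert abs(mean_peak[0]) < 0.1 and abs(mean_peak[1]) < 0.1

    def test_total_mass_one(self):
        rng = np.random.default_rng(1)
        xs, ys, dens = joint_density(rng.gamma(5, 2, 3000), rng.gamma(8, 1, 3000))
        mass = dens.sum() * (xs[1] - xs[0]) * (ys[1] - ys[0])
        assert abs(mass - 1.0) < 1e-3

    def test_perfect_correlation_concentrates_on_diagonal(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 5, 4000)
        xs, ys, dens = joint_density(a, a, grid=128)
        bw = len(a) ** (-1 / 6) * a.std(ddof=1)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        # kernel smoothing spreads the diagonal by sqrt(2) * bw; mass beyond
        # three of those widths should be negligible
        off = np.abs(X - Y) > 3 * np.sqrt(2) * bw
        cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
        assert dens[off].sum() * cell < 0.01

    def test_zero_variance_axis_falls_back(self):
        rng = np.random.default_rng(3)
        xs, ys, dens = joint_density(rng.normal(0, 1, 500), np.full(500, 2.0))
        mass = dens.sum() * (xs[1] - xs[0]) * (ys[1] - ys[0])
        assert abs(mass - 1.0) < 1e-2


class TestRegulationStrength:
    def test_ramped_coupling_labelled_increasing(self):
        matrix, ann = regulation_ramp_dataset(seed=4001)
        ws = assign_windows(ann, overlap_fraction=0.5,
                            branches=["pre", "branch_point", "branch1"])
        trend = regulation_strength_series(matrix, ann, ws, "Reg", "Tgt", seed=1)
        assert trend.label == "increasing"
        assert trend.rho > 0.6

    def test_independent_target_has_calibrated_null_importance(self):
        matrix, ann = regulation_ramp_dataset(seed=4002, coupled=False)
        ws = assign_windows(ann, overlap_fraction=0.5)
        trend = regulation_strength_series(matrix, ann, ws, "Reg", "Tgt", seed=2)
        n_candidates = matrix.n_genes - 1
        assert np.mean(trend.importances) <= 2 / n_candidates

    def test_importances_sum_to_one_within_window(self):
        matrix, ann = regulation_ramp_dataset(seed=4003)
        ws = assign_windows(ann, windows_per_segment=2, branches=["pre"])
        rows = matrix.cell_index(ws[0].cell_ids)
        pred = [g for g in matrix.gene_ids if g != "Tgt"]
        X = matrix.values[np.ix_(rows, [matrix.gene_ids.index(g) for g in pred])]
        y = matrix.values[rows, matrix.gene_ids.index("Tgt")]
        forest = RandomForestRegressor(100, max_features="sqrt", random_state=0)
        forest.fit(X.astype(float), y.astype(float))
        assert forest.feature_importances_.sum() == pytest.approx(1.0)


class TestWasserstein:
    def test_identity(self):
        x = np.random.default_rng(0).gamma(3, 2, 500)
        assert wasserstein_1d(x, x.copy()) == 0.0

    def test_translation_property_exact(self):
        x = np.random.default_rng(1).poisson(10, 400).astype(float)
        assert wasserstein_1d(x, x + 7.5) == pytest.approx(7.5, abs=1e-12)

    def test_uniform_closed_form(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(0, 1, 5000)
        v = rng.uniform(0, 2, 5000)
        # W1(U(0,1), U(0,2)) = 1/2; MC standard error ~ 1/sqrt(n)
        assert abs(wasserstein_1d(u, v) - 0.5) < 3 * (1 / np.sqrt(5000))

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            u, v, w = (rng.gamma(rng.uniform(1, 10), rng.uniform(0.5, 3), 200)
                       for _ in range(3))
            duv, dvw, duw = wasserstein_1d(u, v), wasserstein_1d(v, w), wasserstein_1d(u, w)
            assert duv >= 0 and duv == wasserstein_1d(v, u)
            assert duw <= duv + dvw + 1e-9

    def test_matrix_symmetry_and_zero_diagonal(self, small_dataset):
        matrix, ann = small_dataset
        wm = wasserstein_matrix(matrix, ann, ["shift00", "flat00"],
                                group_by="branch", min_cells=10)
        np.testing.assert_allclose(wm.values, wm.values.T)
        np.testing.assert_allclose(np.diag(wm.values), 0.0)

    def test_matched_laws_have_near_zero_distance(self):
        # genes A and B differ everywhere except stage 3, where their laws
        # coincide: that entry should sit far below the matrix median
        from branchdyn import (SimulationConfig, StageSchedule, StageSpec,
                               TwoStateParams, simulate_branching_dataset)
        shared = TwoStateParams(3.0, 1.0, 20.0)
        laws_a = [TwoStateParams(1.0, 5.0, 30.0), TwoStateParams(2.0, 2.0, 20.0), shared]
        laws_b = [TwoStateParams(5.0, 1.0, 50.0), TwoStateParams(8.0, 1.0, 45.0), shared]
        sched = StageSchedule([
            StageSpec(i + 1, "pre", 400, {"A": laws_a[i], "B": laws_b[i]})
            for i in range(3)
        ])
        matrix, ann = simulate_branching_dataset(SimulationConfig(sched, seed=6))
        wm = wasserstein_matrix(matrix, ann, ["A", "B"], group_by="stage")
        frame = wm.to_frame()
        same = frame.loc["A|stage=3", "B|stage=3"]
        median = np.median(wm.values[np.triu_indices_from(wm.values, k=1)])
        assert same < 0.1 * median


class TestTrendClassification:
    @pytest.mark.parametrize("series,expected,rho", [
        ([1, 2, 3, 4, 5], "increasing", 1.0),
        ([5, 4, 3, 2, 1], "decreasing", -1.0),
        ([1, 1, 1, 1], "constant", 0.0),
    ])
    def test_canonical_series(self, series, expected, rho):
        label, r = trend_classification(series)
        assert label == expected
        assert r == pytest.approx(rho)

    def test_affine_invariance_of_monotone_labels(self):
        series = np.array([0.1, 0.3, 0.2, 0.5, 0.6, 0.9])
        base = trend_classification(series)
        scaled = trend_classification(3.0 * series + 10.0)
        assert base == scaled

    def test_small_flat_wiggle_is_constant(self):
        label, _ = trend_classification([10.0, 10.2, 9.9, 10.1, 10.0, 9.95])
        assert label == "constant"

    def test_too_short_series_raises(self):
        with pytest.raises(InvalidParameterError):
            trend_classification([1, 2, 3])
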