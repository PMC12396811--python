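"""Tests of the synthetic branching-data generator."""

import numpy as np
import pytest
from scipy.special import betaln

from branchdyn import (GammaMixtureSpec, SimulationConfig, StageSchedule,
                       StageSpec, TwoStateParams, sample_gamma_mixture,
                       simulate_branching_dataset, simulate_two_state_counts)
from branchdyn.errors import ConfigError, InvalidParameterError


def beta_poisson_moments(k_on, k_off, k_syn):
    """Closed-form stationary mean/variance of the telegraph model
    (independent of the sampler): X ~ Poisson(k_syn p), p ~ Beta(k_on, k_off)."""
    ep = k_on / (k_on + k_off)
    varp = k_on * k_off / ((k_on + k_off) ** 2 * (k_on + k_off + 1))
    mean = k_syn * ep
    var = mean + k_syn**2 * varp
    return mean, var


def brute_force_beta_poisson_variance(k_on, k_off, k_syn, k_max=500):
    """Variance by summation of the Beta-Poisson pmf, each entry obtained by
    trapezoid integration in v with p = v^2 (regularizes the p -> 0 endpoint)."""
    v = np.linspace(1e-9, 1.0, 20001)
    p = v**2
    with np.errstate(divide="ignore"):  # log1p(-1) at the p=1 endpoint
        log_beta_dens = ((k_on - 1) * np.log(p) + (k_off - 1) * np.log1p(-p)
                         - betaln(k_on, k_off))
    ks = np.arange(k_max + 1)
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, k_max + 1)))])
    pmf = np.array([
        np.trapezoid(np.exp(k * np.log(k_syn * p) - k_syn * p - log_fact[k]
                            + log_beta_dens) * 2 * v, v)
        for k in ks
    ])
    assert abs(pmf.sum() - 1.0) < 1e-6
    mean = np.dot(ks, pmf)
    return np.dot((ks - mean) ** 2, pmf)


class TestTwoStateCounts:
    def test_constitutive_limit_mean(self):
        # k_off -> 0: promoter almost always ON, counts ~ Poisson(k_syn)
        counts = simulate_two_state_counts(TwoStateParams(1.0, 1e-6, 30.0), 50_000, 1)
        assert abs(counts.mean() - 30.0) / 30.0 < 0.02

    def test_symmetric_switching_mean(self):
        counts = simulate_two_state_counts(TwoStateParams(1.0, 1.0, 50.0), 50_000, 2)
        assert abs(counts.mean() - 25.0) / 25.0 < 0.02

    def test_variance_matches_brute_force_pmf(self):
        counts = simulate_two_state_counts(TwoStateParams(0.5, 10.0, 100.0), 50_000, 3)
        var_oracle = brute_force_beta_poisson_variance(0.5, 10.0, 100.0)
        assert abs(counts.var() - var_oracle) / var_oracle < 0.05

    @pytest.mark.parametrize("k_on,k_off,k_syn", [(0.5, 10.0, 100.0), (2.0, 2.0, 30.0),
                                                  (5.0, 1.0, 20.0)])
    def test_moments_within_monte_carlo_error(self, k_on, k_off, k_syn):
        n = 100_000
        counts = simulate_two_state_counts(TwoStateParams(k_on, k_off, k_syn), n, 4)
        mean, var = beta_poisson_moments(k_on, k_off, k_syn)
        se_mean = np.sqrt(var / n)
        assert abs(counts.mean() - mean) < 3 * se_mean
        # sample-variance SE from the empirical fourth moment
        m4 = np.mean((counts - counts.mean()) ** 4)
        se_var = np.sqrt(max(m4 - counts.var() ** 2, 0.0) / n)
        assert abs(counts.var() - var) < 3 * se_var

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            TwoStateParams(-1.0, 1.0, 10.0)
        with pytest.raises(InvalidParameterError):
            simulate_two_state_counts(TwoStateParams(1, 1, 10), 0, 0)

    def test_seed_determinism(self):
        p = TwoStateParams(1.0, 2.0, 40.0)
        a = simulate_two_state_counts(p, 1000, 42)
        b = simulate_two_state_counts(p, 1000, 42)
        np.testing.assert_array_equal(a, b)


class TestGammaMixtureSampler:
    def test_single_shifted_component_mean_and_support(self):
        # unimodal branch-point law: all samples above loc, mean = loc + shape/rate
        comp = [(1.0, 2.898, 1.5106, 15.481)]
        x = sample_gamma_mixture(comp, 100_000, 5)
        assert x.min() > 15.481
        expected = 15.481 + 2.898 / 1.5106
        assert abs(x.mean() - expected) / expected < 0.02

    def test_degenerate_weights_match_single_component(self):
        two = sample_gamma_mixture([(1.0, 5.0, 2.0, 0.0), (0.0, 50.0, 1.0, 0.0)],
                                   20_000, 6)
        one = sample_gamma_mixture([(1.0, 5.0, 2.0, 0.0)], 20_000, 7)
        from scipy.stats import ks_2samp
        assert ks_2samp(two, one).pvalue > 0.01

    def test_two_separated_components_show_two_peaks(self):
        x = sample_gamma_mixture([(0.5, 100.0, 10.0, 0.0), (0.5, 900.0, 30.0, 0.0)],
                                 50_000, 8)
        hist, edges = np.histogram(x, bins=80)
        centers = 0.5 * (edges[:-1] + edges[1:])
        local_max = centers[1:-1][(hist[1:-1] > hist[:-2]) & (hist[1:-1] > hist[2:])]
        # modes at (shape-1)/rate = 9.9 and 29.97
        assert np.any(np.abs(local_max - 9.9) < 1.5)
        assert np.any(np.abs(local_max - 29.97) < 1.5)

    def test_weight_sum_violation_raises(self):
        with pytest.raises(InvalidParameterError):
            sample_gamma_mixture([(0.6, 1, 1, 0), (0.5, 1, 1, 0)], 10, 0)


def _schedule(branches, n_cells=60):
    gene = {"g": TwoStateParams(1.0, 5.0, 50.0)}
    return StageSchedule([StageSpec(i + 1, b, n_cells, dict(gene))
                          for i, b in enumerate(branches)])


class TestBranchingDataset:
    SEVEN = ["pre", "pre", "pre", "pre", "branch_point", "branch1", "branch2"]

    def test_cell_counts_match_schedule(self):
        m, ann = simulate_branching_dataset(SimulationConfig(self._sched(), seed=0))
        assert m.n_cells == 420
        assert (ann.frame.groupby("stage").size() == 60).all()

    def _sched(self):
        return _schedule(self.SEVEN)

    def test_byte_identical_under_same_seed(self):
        cfg = SimulationConfig(self._sched(), seed=9)
        m1, a1 = simulate_branching_dataset(cfg)
        m2, a2 = simulate_branching_dataset(cfg)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert a1.frame.equals(a2.frame)

    def test_pseudotime_increases_along_each_branch(self):
        _, ann = simulate_branching_dataset(SimulationConfig(self._sched(), seed=1))
        for branch in ("pre", "branch1", "branch2"):
            t = ann.cells_on(branch)["pseudotime"].to_numpy()
            assert np.all(np.diff(t) >= 0)
        pre_max = ann.cells_on("pre")["pseudotime"].max()
        for branch in ("branch1", "branch2"):
            assert ann.cells_on(branch)["pseudotime"].min() > pre_max

    def test_inconsistent_topology_rejected(self):
        with pytest.raises(ConfigError):
            _schedule(["branch1", "pre", "branch2"])
        with pytest.raises(ConfigError):
            _schedule(["pre", "branch_point", "branch1"])  # missing branch2

    @pytest.mark.parametrize("branch,expected_m", [
        ("pre", 2), ("branch_point", 1), ("branch1", 2), ("branch2", 3)])
    def test_programmed_modality_recovered_downstream(self, modality_dataset,
                                                      branch, expected_m):
        # the generator's per-stage laws survive the whole path down to
        # modality selection on the pooled segment counts
        from branchdyn import FitOptions, pool_branch_counts, select_modality
        matrix, ann = modality_dataset
        counts = pool_branch_counts(matrix, ann, "Gata3", branch)
        assert select_modality(counts, FitOptions(seed=0)).m == expected_m

    def test_mixture_genes_respect_cell_size_scaling(self):
        spec = GammaMixtureSpec([(1.0, 400.0, 20.0, 0.0)])  # mean 20, tight
        sched = StageSchedule([StageSpec(1, "pre", 400, {"g": spec})])
        cfg = SimulationConfig(sched, cell_size_sigma=0.5, seed=3)
        m, _ = simulate_branching_dataset(cfg)
        # size variation inflates the spread well beyond the base law's CV of 5%
        assert m.values.std() / m.values.mean() > 0.25
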