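"""Gamma and Gamma-mixture models for windowed mRNA count distributions.

The stationary mRNA law of a bursty two-state gene is (in the bursty regime)
a Gamma distribution ``p(x) = rate^shape / Gamma(shape) * x^(shape-1)
* exp(-rate*x)``; multimodal windows are modelled as convex combinations of
two or three (optionally location-shifted) Gamma components.  Parameters are
identified by minimizing the Kullback-Leibler divergence from the windowed
empirical count distribution to the model, with the continuous density
discretized by integrating over ``[m - 1/2, m + 1/2)`` at each observed
integer ``m``.

Conventions
-----------
The *rate* parameterization is used throughout: a component's mean is
``loc + shape/rate`` and its variance ``shape/rate**2``.  In the two-state
model the shape equals ``k_on`` (burst frequency per mRNA lifetime) and the
rate equals ``k_off/k_syn`` (inverse burst size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammainc, logsumexp

from .errors import DegenerateDataError, InvalidParameterError
from .windows import EmpiricalDistribution, empirical_distribution

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class GammaComponent:
    """One mixture component: weight, shape, rate (inverse scale) and location shift."""

    weight: float
    shape: float
    rate: float
    loc: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0 + 1e-12):
            raise InvalidParameterError(f"weight must lie in [0, 1], got {self.weight}")
        if self.shape <= 0 or self.rate <= 0:
            raise InvalidParameterError("shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.loc + self.shape / self.rate

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2

    @property
    def skewness(self) -> float:
        return 2.0 / np.sqrt(self.shape)

    @property
    def excess_kurtosis(self) -> float:
        return 6.0 / self.shape

    @property
    def peak(self) -> float:
        """Mode of the component density: loc + (shape-1)/rate for shape > 1, else loc."""
        return self.loc + (self.shape - 1.0) / self.rate if self.shape > 1.0 else self.loc


@dataclass
class GammaMixtureFit:
    """A fitted Gamma mixture plus the achieved KL value and optimizer metadata."""

    components: list
    kl: float = np.nan
    converged: bool = True
    n_starts: int = 0
    seed: int | None = None
    loglik: float = np.nan
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise InvalidParameterError("fit needs at least one component")
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise InvalidParameterError(f"component weights must sum to 1, got {w}")
        if np.isfinite(self.kl) and self.kl < -1e-12:
            raise InvalidParameterError("KL value cannot be negative")

    @property
    def m(self) -> int:
        return len(self.components)

    @property
    def n_parameters(self) -> int:
        """Free parameters: (m-1) weights + per-component shape, rate and any nonzero loc."""
        k = (self.m - 1) + 2 * self.m
        k += sum(1 for c in self.components if c.loc != 0.0)
        return k

    def bic(self) -> float:
        return self.n_parameters * np.log(max(self.n_samples, 1)) - 2.0 * self.loglik


@dataclass
class DistributionStats:
    """Closed-form per-component moments plus mixture-level peak positions."""

    peaks: list
    component_peaks: list
    means: list
    variances: list
    skewnesses: list
    excess_kurtoses: list
    mixture_mean: float
    mixture_variance: float


@dataclass
class ModalityCall:
    """Result of model selection among 1-, 2- and 3-component mixtures."""

    m: int
    fits: dict = field(repr=False)
    bics: dict = field(default_factory=dict)

    @property
    def fit(self) -> GammaMixtureFit:
        return self.fits[self.m]


@dataclass
class FitOptions:
    """Options for the KL multi-start optimizer."""

    n_starts: int = 10
    seed: int = 0
    use_loc: bool = False
    maxiter: int = 300
    bic_tie_margin: float = 2.0  # prefer the smaller m when ΔBIC is below this


# ---------------------------------------------------------------------------
# Density evaluation
# ---------------------------------------------------------------------------

def mixture_pdf(x, fit: GammaMixtureFit) -> np.ndarray:
    """Mixture density at real-valued points ``x`` (0 below every component's loc)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    for c in fit.components:
        out += c.weight * stats.gamma.pdf(x, a=c.shape, loc=c.loc, scale=1.0 / c.rate)
    return out


def mixture_cdf(x, fit: GammaMixtureFit) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    for c in fit.components:
        # regularized lower incomplete Gamma; much cheaper than the frozen
        # scipy distribution in the KL optimizer's inner loop
        out += c.weight * gammainc(c.shape, np.maximum(c.rate * (x - c.loc), 0.0))
    return out


def _discretized_probs(support: np.ndarray, fit: GammaMixtureFit) -> np.ndarray:
    """P(m) at each integer support point via the continuity correction
    ∫_{m-1/2}^{m+1/2} pdf dx (lower limit clipped at 0)."""
    lo = np.maximum(support - 0.5, 0.0)
    hi = support + 0.5
    # treat m = 0 as [0, 1/2)
    lo = np.where(support == 0, -np.inf, lo)
    return np.clip(mixture_cdf(hi, fit) - np.where(np.isneginf(lo), 0.0, mixture_cdf(lo, fit)), 0.0, 1.0)


def kl_divergence(data: EmpiricalDistribution, fit: GammaMixtureFit) -> float:
    """KL(data || discretized model), renormalized over the observed support.

    Model probabilities below 1e-12 at observed support points are floored
    (and logged) rather than raised as errors.
    """
    p = np.asarray(data.probabilities, dtype=float)
    q = _discretized_probs(np.asarray(data.support, dtype=float), fit)
    total = q.sum()
    if total <= 0:
        logger.debug("model places no mass on the data support; flooring")
        q = np.full_like(q, _PROB_FLOOR)
    else:
        q = q / total
    n_floored = int(np.sum(q < _PROB_FLOOR))
    if n_floored:
        logger.debug("floored %d model probabilities at %.0e", n_floored, _PROB_FLOOR)
    q = np.maximum(q, _PROB_FLOOR)
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))))


def discretized_loglik(counts, fit: GammaMixtureFit) -> float:
    """Log-likelihood of integer counts under the discretized (unrenormalized) model."""
    data = counts if isinstance(counts, EmpiricalDistribution) else empirical_distribution(
        np.rint(np.asarray(counts)).astype(np.int64))
    q = np.maximum(_discretized_probs(np.asarray(data.support, dtype=float), fit), _PROB_FLOOR)
    freq = np.asarray(data.probabilities) * data.n
    return float(np.dot(freq, np.log(q)))


# ---------------------------------------------------------------------------
# KL fitting
# ---------------------------------------------------------------------------

def _pack(weights, shapes, rates, loc_z=None):
    # unconstrained vector: (m-1) weight logits (last fixed at 0), log shapes,
    # log rates, then (if loc is enabled) one loc logit per component
    parts = [np.log(weights[:-1] / weights[-1]), np.log(shapes), np.log(rates)]
    if loc_z is not None:
        parts.append(np.asarray(loc_z, dtype=float))
    return np.concatenate(parts)


def _unpack(z, m, loc_cap=None):
    logits = np.concatenate([z[: m - 1], [0.0]])
    weights = np.exp(logits - logsumexp(logits))
    shapes = np.exp(np.clip(z[m - 1: 2 * m - 1], -20, 20))
    rates = np.exp(np.clip(z[2 * m - 1: 3 * m - 1], -20, 20))
    if loc_cap is None:
        locs = np.zeros(m)
    else:
        # loc bounded to [0, loc_cap] (loc_cap = min of the samples)
        locs = loc_cap / (1.0 + np.exp(-np.clip(z[3 * m - 1: 4 * m - 1], -30, 30)))
    return weights, shapes, rates, locs


def _moment_match(samples: np.ndarray) -> tuple[float, float]:
    mu = samples.mean()
    var = samples.var()
    if var <= 0 or mu <= 0:
        return 1.0, 1.0
    return max(mu * mu / var, 1e-3), max(mu / var, 1e-6)


def _initial_split(samples: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quantile-split moment matching: order samples, cut into m groups,
    method-of-moments per group."""
    s = np.sort(samples)
    groups = np.array_split(s, m)
    weights, shapes, rates = [], [], []
    for g in groups:
        w = len(g) / len(s)
        a, r = _moment_match(g)
        weights.append(max(w, 1e-3))
        shapes.append(a)
        rates.append(r)
    weights = np.asarray(weights)
    return weights / weights.sum(), np.asarray(shapes), np.asarray(rates)


def fit_mixture(samples, m: int, options: FitOptions | None = None) -> GammaMixtureFit:
    """Fit an m-component Gamma mixture by multi-start KL minimization.

    Samples are rounded to integers and summarized as an empirical
    distribution; the objective is the continuity-corrected KL divergence.
    Deterministic for a given ``options.seed``.
    """
    options = options or FitOptions()
    if m not in (1, 2, 3):
        raise InvalidParameterError(f"m must be 1, 2 or 3, got {m}")
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2 or np.any(samples < 0):
        raise DegenerateDataError("need >= 2 nonnegative samples")
    if np.ptp(samples) == 0:
        raise DegenerateDataError(
            "all samples identical; a point mass cannot be fit — use m=1 point-mass handling"
        )
    counts = np.rint(samples).astype(np.int64)
    data = empirical_distribution(counts)
    loc_cap = float(samples.min()) if (options.use_loc and samples.min() > 0) else None

    # precompute the integration edges and observed probabilities once; the
    # objective below equals kl_divergence(data, fit) but avoids per-call
    # object construction in the optimizer's inner loop
    support = np.asarray(data.support, dtype=float)
    p_obs = np.asarray(data.probabilities, dtype=float)
    log_p = np.log(p_obs)
    entropy_term = float(np.dot(p_obs, log_p))
    hi = support + 0.5
    lo = np.maximum(support - 0.5, 0.0)

    def objective(z):
        weights, shapes, rates, locs = _unpack(z, m, loc_cap)
        q = np.zeros_like(support)
        for w, a, r, l in zip(weights, shapes, rates, locs):
            q += w * (gammainc(a, np.maximum(r * (hi - l), 0.0))
                      - gammainc(a, np.maximum(r * (lo - l), 0.0)))
        total = q.sum()
        if not np.isfinite(total) or total <= 0:
            return 1e6
        q = np.maximum(q / total, _PROB_FLOOR)
        val = entropy_term - float(np.dot(p_obs, np.log(q)))
        return val if np.isfinite(val) else 1e6

    w0, a0, r0 = _initial_split(samples, m)
    loc_z0 = np.full(m, -3.0) if loc_cap is not None else None
    rng = np.random.default_rng(options.seed)
    best = None
    stale = 0
    for start in range(max(options.n_starts, 1)):
        if start == 0:
            z0 = _pack(w0, a0, r0, loc_z0)
        else:
            jitter_a = a0 * np.exp(rng.normal(0, 0.4, size=m))
            jitter_r = r0 * np.exp(rng.normal(0, 0.4, size=m))
            jw = w0 * np.exp(rng.normal(0, 0.5, size=m))
            jl = loc_z0 + rng.normal(0, 1.0, size=m) if loc_z0 is not None else None
            z0 = _pack(jw / jw.sum(), jitter_a, jitter_r, jl)
        res = optimize.minimize(objective, z0, method="L-BFGS-B",
                                options={"maxiter": options.maxiter})
        if best is None or res.fun < best.fun - 1e-8:
            best = res
            stale = 0
        else:
            stale += 1
            # additional starts stopped improving; the optimum is stable
            if start >= 3 and stale >= 3:
                break
    weights, shapes, rates, locs = _unpack(best.x, m, loc_cap)
    order = np.argsort(locs + shapes / rates)  # sort components by mean for stable reporting
    comps = [GammaComponent(float(weights[i]), float(shapes[i]), float(rates[i]),
                            float(locs[i]))
             for i in order]
    fit = GammaMixtureFit(comps, kl=float(best.fun), converged=bool(best.success),
                          n_starts=max(options.n_starts, 1), seed=options.seed,
                          n_samples=int(samples.size))
    fit.loglik = discretized_loglik(data, fit)
    return fit


def select_modality(samples, options: FitOptions | None = None) -> ModalityCall:
    """Choose between 1-, 2- and 3-component Gamma mixtures by BIC.

    KL (like likelihood) always improves with m, so the Bayesian information
    criterion on the discretized log-likelihood penalizes the extra
    parameters; near-ties (ΔBIC below ``bic_tie_margin``) go to the simpler
    model.
    """
    options = options or FitOptions()
    fits, bics = {}, {}
    for m in (1, 2, 3):
        fits[m] = fit_mixture(samples, m, options)
        bics[m] = fits[m].bic()
    best_m = min(bics, key=bics.get)
    for m in (1, 2, 3):
        if m < best_m and bics[m] - bics[best_m] < options.bic_tie_margin:
            best_m = m
            break
    return ModalityCall(best_m, fits, bics)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _mixture_peaks(fit: GammaMixtureFit, n_grid: int = 4096) -> list[float]:
    """Local maxima of the mixture density: coarse grid scan + bounded refinement."""
    lo = min(c.loc for c in fit.components)
    hi = max(stats.gamma.ppf(0.999, a=c.shape, loc=c.loc, scale=1.0 / c.rate)
             for c in fit.components)
    if hi <= lo:
        hi = lo + 1.0
    grid = np.linspace(lo + 1e-9, hi, n_grid)
    dens = mixture_pdf(grid, fit)
    peaks = []
    interior = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))[0] + 1
    for i in interior:
        res = optimize.minimize_scalar(lambda x: -mixture_pdf(x, fit)[0],
                                       bounds=(grid[i - 1], grid[i + 1]), method="bounded")
        peaks.append(float(res.x))
    if dens[0] > dens[1]:  # boundary mode (shape <= 1 component at its loc)
        peaks.insert(0, float(grid[0]))
    # merge refined peaks that collapsed to the same point
    merged: list[float] = []
    tol = (hi - lo) / n_grid
    for p in sorted(peaks):
        if not merged or p - merged[-1] > 2 * tol:
            merged.append(p)
    return merged


def mixture_stats(fit: GammaMixtureFit) -> DistributionStats:
    """Closed-form per-component moments and numerically located mixture peaks."""
    means = [c.mean for c in fit.components]
    variances = [c.variance for c in fit.components]
    weights = np.array([c.weight for c in fit.components])
    mixture_mean = float(np.dot(weights, means))
    mixture_var = float(np.dot(weights, np.asarray(variances) +
                               (np.asarray(means) - mixture_mean) ** 2))
    return DistributionStats(
        peaks=_mixture_peaks(fit),
        component_peaks=[c.peak for c in fit.components],
        means=means,
        variances=variances,
        skewnesses=[c.skewness for c in fit.components],
        excess_kurtoses=[c.excess_kurtosis for c in fit.components],
        mixture_mean=mixture_mean,
        mixture_variance=mixture_var,
    )


def fit_report(fit: GammaMixtureFit, gene: str = "", branch: str = "",
               window: int | None = None) -> dict:
    """JSON-serializable per-gene/window fit report."""
    s = mixture_stats(fit)
    return {
        "gene": gene,
        "branch": branch,
        "window": window,
        "m": fit.m,
        "components": [
            {"weight": c.weight, "shape": c.shape, "rate": c.rate, "loc": c.loc}
            for c in fit.components
        ],
        "kl": fit.kl,
        "bic": fit.bic(),
        "stats": {
            "peaks": s.peaks,
            "means": s.means,
            "variances": s.variances,
            "skewness": s.skewnesses,
            "excess_kurtosis": s.excess_kurtoses,
        },
    }
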