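"""Synthetic branching scRNA-seq data from stage-dependent two-state kinetics.

The generator emulates a developmental trajectory with a pre-branch trunk, a
branch point and two post-branch segments.  Each gene has, per stage, either
two-state (telegraph) transcription kinetics — whose stationary count law is
Beta-Poisson: burst fraction ``p ~ Beta(k_on, k_off)``, count
``~ Poisson(k_syn * p)`` — or an explicit Gamma-mixture specification for
stages where a trimodal (or other multimodal) law is wanted, since a single
two-state gene cannot produce trimodality.  Per-cell size factors are drawn
log-normal, median-normalized to 1, and multiply the Poisson rate.

All randomness is controlled by explicit integer seeds; identical
configurations produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError
from .io import BRANCH_LABELS, CountMatrix, TrajectoryAnnotation

__all__ = [
    "TwoStateParams",
    "GammaMixtureSpec",
    "StageSpec",
    "StageSchedule",
    "SimulationConfig",
    "simulate_two_state_counts",
    "sample_gamma_mixture",
    "simulate_branching_dataset",
    "couple_target_to_regulator",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Rates of the two-state (telegraph) transcription model.

    k_on / k_off are the OFF->ON / ON->OFF promoter switching rates, k_syn the
    transcription rate while ON, delta the mRNA degradation rate.  All rates
    are expressed per unit degradation time; delta is 1 by convention.
    Burst size is ``k_syn / k_off`` and burst frequency is ``k_on``.
    """

    k_on: float
    k_off: float
    k_syn: float
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_syn", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {v!r}")

    @property
    def mean(self) -> float:
        """Stationary mean count, k_syn/delta * k_on/(k_on+k_off)."""
        return self.k_syn / self.delta * self.k_on / (self.k_on + self.k_off)

    @property
    def burst_size(self) -> float:
        return self.k_syn / self.k_off

    @property
    def burst_frequency(self) -> float:
        return self.k_on


@dataclass(frozen=True)
class GammaMixtureSpec:
    """Explicit Gamma-mixture law for a gene at one stage.

    ``components`` is a list of (weight, shape, rate, loc) tuples; weights sum
    to 1.  Used for stages whose distribution the two-state model cannot
    express (e.g. trimodal).
    """

    components: tuple

    def __init__(self, components) -> None:
        comps = tuple((float(w), float(a), float(r), float(l)) for (w, a, r, l) in components)
        _validate_mixture(comps)
        object.__setattr__(self, "components", comps)


def _validate_mixture(components) -> None:
    if not components:
        raise InvalidParameterError("mixture needs at least one component")
    weights = np.array([c[0] for c in components])
    if np.any(weights < 0):
        raise InvalidParameterError("mixture weights must be nonnegative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(f"mixture weights must sum to 1, got {weights.sum()!r}")
    for _, shape, rate, _ in components:
        if shape <= 0 or rate <= 0:
            raise InvalidParameterError("mixture shapes and rates must be positive")


@dataclass(frozen=True)
class StageSpec:
    """One stage cluster: id, branch label, cell count and per-gene law."""

    stage: int
    branch: str
    n_cells: int
    genes: dict  # gene id -> TwoStateParams | GammaMixtureSpec

    def __post_init__(self) -> None:
        if self.branch not in BRANCH_LABELS:
            raise ConfigError(f"unknown branch label {self.branch!r}")
        if self.n_cells < 1:
            raise ConfigError("cells per stage must be >= 1")


@dataclass(frozen=True)
class StageSchedule:
    """Ordered list of stages forming the pre -> branch_point -> {branch1, branch2} topology."""

    stages: tuple

    def __init__(self, stages) -> None:
        stages = tuple(stages)
        if not stages:
            raise ConfigError("schedule has no stages")
        rank = {"pre": 0, "branch_point": 1, "branch1": 2, "branch2": 2}
        ranks = [rank[s.branch] for s in stages]
        if ranks != sorted(ranks):
            raise ConfigError(
                "inconsistent topology: stages must be ordered pre -> branch_point -> post-branch"
            )
        labels = {s.branch for s in stages}
        if ("branch1" in labels) != ("branch2" in labels):
            raise ConfigError("inconsistent topology: both post-branch segments are required")
        gene_sets = [frozenset(s.genes) for s in stages]
        if len(set(gene_sets)) != 1:
            raise ConfigError("every stage must specify the same gene set")
        object.__setattr__(self, "stages", stages)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.stages[0].genes)

    @property
    def n_cells(self) -> int:
        return sum(s.n_cells for s in self.stages)

    def stage_intervals(self) -> dict:
        """Pseudotime sub-interval [t_lo, t_hi) of each stage.

        Trunk stages (pre + branch_point) tile [0, t_split]; each post-branch
        segment independently tiles (t_split, 1].  Widths are equal along each
        path.
        """
        trunk = [s for s in self.stages if s.branch in ("pre", "branch_point")]
        b1 = [s for s in self.stages if s.branch == "branch1"]
        b2 = [s for s in self.stages if s.branch == "branch2"]
        depth = len(trunk) + max(len(b1), len(b2), 1)
        t_split = len(trunk) / depth if (b1 or b2) else 1.0
        intervals = {}
        for k, s in enumerate(trunk):
            w = t_split / max(len(trunk), 1)
            intervals[s.stage] = (k * w, (k + 1) * w)
        for branch_stages in (b1, b2):
            for k, s in enumerate(branch_stages):
                w = (1.0 - t_split) / len(branch_stages)
                intervals[s.stage] = (t_split + k * w, t_split + (k + 1) * w)
        return intervals


@dataclass
class SimulationConfig:
    """Full generator configuration; the seed fixes all randomness."""

    schedule: StageSchedule
    cell_size_sigma: float = 0.1  # sd of log cell size; 0 disables size variation
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_size_sigma < 0:
            raise ConfigError("cell_size_sigma must be >= 0")


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def simulate_two_state_counts(params: TwoStateParams, n_cells: int, seed: int,
                              sizes: np.ndarray | None = None) -> np.ndarray:
    """Sample stationary counts of a two-state gene for ``n_cells`` cells.

    Uses the exact stationary compound draw: p ~ Beta(k_on, k_off),
    count ~ Poisson(size * k_syn/delta * p).  This is the telegraph model's
    stationary law; no time integration is needed.
    """
    if int(n_cells) < 1:
        raise InvalidParameterError(f"n_cells must be >= 1, got {n_cells}")
    rng = np.random.default_rng(seed)
    p = rng.beta(params.k_on, params.k_off, size=int(n_cells))
    lam = params.k_syn / params.delta * p
    if sizes is not None:
        lam = np.asarray(sizes) * lam
    return rng.poisson(lam).astype(np.int64)


def sample_gamma_mixture(components, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` real-valued samples from a (shifted) Gamma mixture.

    ``components`` is a list of (weight, shape, rate, loc); rate is the
    inverse scale, so a component's mean is ``loc + shape/rate``.
    """
    comps = [(float(w), float(a), float(r), float(l)) for (w, a, r, l) in components]
    _validate_mixture(comps)
    if int(n) < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    weights = np.array([c[0] for c in comps])
    assignment = rng.choice(len(comps), size=int(n), p=weights)
    out = np.empty(int(n))
    for i, (_, shape, rate, loc) in enumerate(comps):
        mask = assignment == i
        out[mask] = loc + rng.gamma(shape, 1.0 / rate, size=int(mask.sum()))
    return out


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def simulate_branching_dataset(config: SimulationConfig):
    """Generate a (CountMatrix, TrajectoryAnnotation) pair from a schedule.

    Cells are emitted stage by stage in trajectory order, with pseudotime
    drawn uniformly (then sorted) on each stage's sub-interval of [0, 1], so
    pseudotime increases along each branch.  Counts of two-state genes are
    Poisson(size * k_syn * p) with p ~ Beta(k_on, k_off); Gamma-mixture genes
    are sampled from the mixture, scaled by cell size and rounded.
    """
    schedule = config.schedule
    gene_ids = schedule.gene_ids
    intervals = schedule.stage_intervals()
    root = np.random.SeedSequence(config.seed)
    # one child stream per (stage, purpose) keeps gene draws independent
    streams = root.spawn(len(schedule.stages) + 1)
    size_rng = np.random.default_rng(streams[-1])

    n_total = schedule.n_cells
    sizes = np.exp(size_rng.normal(0.0, config.cell_size_sigma, size=n_total)) \
        if config.cell_size_sigma > 0 else np.ones(n_total)
    sizes = sizes / np.median(sizes)  # median-normalized to 1

    counts = np.zeros((n_total, len(gene_ids)), dtype=np.int64)
    rows = []
    offset = 0
    for si, stage in enumerate(schedule.stages):
        rng = np.random.default_rng(streams[si])
        n = stage.n_cells
        t_lo, t_hi = intervals[stage.stage]
        t = np.sort(rng.uniform(t_lo, t_hi, size=n))
        s = sizes[offset:offset + n]
        for gi, gene in enumerate(gene_ids):
            law = stage.genes[gene]
            if isinstance(law, TwoStateParams):
                p = rng.beta(law.k_on, law.k_off, size=n)
                counts[offset:offset + n, gi] = rng.poisson(s * law.k_syn / law.delta * p)
            elif isinstance(law, GammaMixtureSpec):
                x = _sample_mixture_rng(law.components, n, rng)
                counts[offset:offset + n, gi] = np.maximum(np.rint(s * x), 0).astype(np.int64)
            else:
                raise ConfigError(f"unsupported law for gene {gene!r}: {type(law).__name__}")
        for j in range(n):
            rows.append((f"cell_{offset + j:05d}", t[j], stage.stage, stage.branch))
        offset += n

    matrix = CountMatrix(counts, [r[0] for r in rows], gene_ids)
    annotation = TrajectoryAnnotation(
        pd.DataFrame(rows, columns=["cell_id", "pseudotime", "stage", "branch"])
    )
    return matrix, annotation


def _sample_mixture_rng(components, n: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([c[0] for c in components])
    assignment = rng.choice(len(components), size=n, p=weights)
    out = np.empty(n)
    for i, (_, shape, rate, loc) in enumerate(components):
        mask = assignment == i
        out[mask] = loc + rng.gamma(shape, 1.0 / rate, size=int(mask.sum()))
    return out


def config_from_dict(spec: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (YAML/JSON config file).

    Each stage entry carries ``stage``, ``branch``, ``n_cells`` and a
    ``genes`` mapping whose values are either two-state rate dicts
    (``{k_on, k_off, k_syn[, delta]}``) or ``{"mixture": [[w, shape, rate,
    loc], ...]}`` entries.
    """
    stages = []
    for s in spec.get("stages", []):
        genes = {}
        for gene, law in s["genes"].items():
            if "mixture" in law:
                genes[gene] = GammaMixtureSpec(law["mixture"])
            else:
                genes[gene] = TwoStateParams(**law)
        stages.append(StageSpec(int(s["stage"]), s["branch"], int(s["n_cells"]), genes))
    return SimulationConfig(StageSchedule(stages),
                            cell_size_sigma=float(spec.get("cell_size_sigma", 0.1)),
                            seed=int(spec.get("seed", 0)))


def couple_target_to_regulator(matrix: CountMatrix, annotation: TrajectoryAnnotation,
                               regulator: str, target: str, strength,
                               seed: int, baseline: float = 2.0) -> CountMatrix:
    """Redraw a target gene as Poisson(baseline + b(t) * regulator count).

    ``strength`` maps pseudotime in [0, 1] to the coupling coefficient b(t),
    so a ramped ``strength`` produces a regulation signal that grows along the
    trajectory.  Returns a new CountMatrix; the input is not modified.
    """
    rng = np.random.default_rng(seed)
    t = annotation.frame.set_index("cell_id").loc[matrix.cell_ids, "pseudotime"].to_numpy()
    b = np.array([float(strength(ti)) for ti in t])
    if np.any(b < 0):
        raise InvalidParameterError("coupling strength must be nonnegative")
    x_reg = matrix.gene(regulator).astype(float)
    new_target = rng.poisson(baseline + b * x_reg)
    values = matrix.values.copy()
    values[:, matrix.gene_ids.index(target)] = new_target
    return CountMatrix(values, matrix.cell_ids, matrix.gene_ids)
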