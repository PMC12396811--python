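"""Gene-pair analyses along the trajectory: joint densities, tree-ensemble
regulation-strength series, 1-Wasserstein distance matrices and trend labels.

The regulation-strength series follows the GENIE3 idea in miniature: within
each pseudotime window a random-forest regression predicts the target gene's
expression from all other genes, and the regulator's share of the forest's
total variance reduction (its normalized feature importance) is the
regulation strength for that window.  Repeating this along the windows gives
a trend of regulatory strength over pseudotime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .errors import DegenerateDataError, InvalidParameterError
from .io import CountMatrix, TrajectoryAnnotation

logger = logging.getLogger(__name__)

__all__ = ["RegulationTrend", "WassersteinMatrix", "joint_density",
           "regulation_strength_series", "wasserstein_1d", "wasserstein_matrix",
           "trend_classification"]


@dataclass
class RegulationTrend:
    """Per-window regulator -> target importances with a monotonicity label."""

    regulator: str
    target: str
    window_indices: list
    importances: list
    rho: float
    label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "regulator": self.regulator, "target": self.target,
            "window_index": self.window_indices, "importance": self.importances,
        })


@dataclass
class WassersteinMatrix:
    """Symmetric nonnegative matrix of pairwise 1-Wasserstein distances."""

    labels: list
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def joint_density(samples_a, samples_b, grid: int = 64):
    """Gaussian-kernel joint density of two genes on a regular grid.

    Bandwidths follow Scott's rule per axis.  Returns (xs, ys, density) where
    density integrates to 1 over the grid (cell area x sum = 1 up to edge
    truncation).  A zero-variance axis falls back to a 1D density times a
    point mass on the degenerate axis.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InvalidParameterError("need two equal-length vectors of >= 2 samples")
    n = a.size
    scott = n ** (-1.0 / 6.0)

    def axis_grid(v, bw):
        # 4 bandwidths of padding keeps truncated kernel mass ~1e-4
        pad = 4.0 * bw if bw > 0 else max(1e-3, 0.05 * max(abs(v.mean()), 1.0))
        return np.linspace(v.min() - pad, v.max() + pad, grid)

    bw_a = scott * a.std(ddof=1)
    bw_b = scott * b.std(ddof=1)
    degenerate = bw_a == 0 or bw_b == 0
    if degenerate:
        logger.warning("zero-variance axis in joint_density; using 1D fallback")
    xs = axis_grid(a, bw_a)
    ys = axis_grid(b, bw_b)

    def kernel_1d(v, g, bw):
        if bw == 0:  # point mass on the nearest grid node
            out = np.zeros((v.size, g.size))
            out[np.arange(v.size), np.argmin(np.abs(g[None, :] - v[:, None]), axis=1)] = 1.0
            return out / (g[1] - g[0])
        return np.exp(-0.5 * ((g[None, :] - v[:, None]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))

    ka = kernel_1d(a, xs, bw_a)  # (n, grid)
    kb = kernel_1d(b, ys, bw_b)
    dens = ka.T @ kb / n  # (grid, grid), axis 0 = xs
    return xs, ys, dens


def regulation_strength_series(matrix: CountMatrix, annotation: TrajectoryAnnotation,
                               windows, regulator: str, target: str,
                               n_trees: int = 100, seed: int = 0,
                               rho_threshold: float = 0.6, alpha: float = 0.05
                               ) -> RegulationTrend:
    """Windowed random-forest importance of one regulator for one target.

    Within each window, a forest of ``n_trees`` (sqrt feature subsampling,
    seed fixed per window) predicts the target from all other genes; the
    regulator's normalized importance is recorded.  The ordered series is
    then labelled by :func:`trend_classification`.
    """
    if matrix.n_genes < 2:
        raise InvalidParameterError("need at least 2 genes")
    target_j = matrix.gene_ids.index(target)
    predictors = [g for g in matrix.gene_ids if g != target]
    reg_pos = predictors.index(regulator)
    pred_idx = [matrix.gene_ids.index(g) for g in predictors]

    indices, importances = [], []
    for k, w in enumerate(windows):
        rows = matrix.cell_index(w.cell_ids)
        X = matrix.values[np.ix_(rows, pred_idx)].astype(float)
        y = matrix.values[rows, target_j].astype(float)
        if np.ptp(y) == 0:
            logger.warning("window %d: constant target %s; importances set to 0",
                           w.index, target)
            importances.append(0.0)
            indices.append(w.index)
            continue
        forest = RandomForestRegressor(n_estimators=n_trees, max_features="sqrt",
                                       random_state=(seed + 131 * k) % (2**31))
        forest.fit(X, y)
        importances.append(float(forest.feature_importances_[reg_pos]))
        indices.append(w.index)
    label, rho = trend_classification(importances, rho_threshold, alpha) \
        if len(importances) >= 4 else ("non-monotone", np.nan)
    return RegulationTrend(regulator, target, indices, importances, rho, label)


def wasserstein_1d(u, v) -> float:
    """1-Wasserstein distance between two empirical samples.

    Equals the integral of the absolute difference of the empirical quantile
    functions (equivalently of the empirical CDFs).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size == 0 or v.size == 0:
        raise DegenerateDataError("both samples must be nonempty")
    return float(stats.wasserstein_distance(u, v))


def wasserstein_matrix(matrix: CountMatrix, annotation: TrajectoryAnnotation,
                       genes, group_by: str = "stage", min_cells: int = 10
                       ) -> WassersteinMatrix:
    """Pairwise W1 distances among (gene, group) expression distributions.

    ``group_by`` is "stage" or "branch"; groups with fewer than ``min_cells``
    cells are excluded with a log entry.
    """
    if group_by not in ("stage", "branch"):
        raise InvalidParameterError("group_by must be 'stage' or 'branch'")
    frame = annotation.frame
    samples: dict[str, np.ndarray] = {}
    for g in genes:
        col = matrix.gene(g)
        for group, sub in frame.groupby(group_by, sort=True):
            if len(sub) < min_cells:
                logger.warning("group %s=%r excluded (%d cells < %d)",
                               group_by, group, len(sub), min_cells)
                continue
            samples[f"{g}|{group_by}={group}"] = col[matrix.cell_index(sub["cell_id"])]
    labels = sorted(samples)
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = wasserstein_1d(samples[labels[i]], samples[labels[j]])
            values[i, j] = values[j, i] = d
    return WassersteinMatrix(labels, values)


def trend_classification(series, rho_threshold: float = 0.6,
                         alpha: float = 0.05) -> tuple[str, float]:
    """Label an ordered series increasing / decreasing / constant / non-monotone.

    Uses the Spearman rank correlation of the series against its index:
    "increasing" (rho >= threshold, significant), "decreasing" (rho <=
    -threshold, significant), "constant" (|rho| below threshold with a
    relative range under 10%, or an all-tied series), else "non-monotone".
    """
    series = np.asarray(series, dtype=float)
    if series.size < 4:
        raise InvalidParameterError("trend classification needs >= 4 points")
    if not 0.0 < rho_threshold < 1.0:
        raise InvalidParameterError("rho_threshold must lie in (0, 1)")
    if np.ptp(series) == 0:
        return "constant", 0.0
    rho, p = stats.spearmanr(series, np.arange(series.size))
    scale = max(abs(series.mean()), 1e-12)
    rel_range = np.ptp(series) / scale
    if rho >= rho_threshold and p < alpha:
        return "increasing", float(rho)
    if rho <= -rho_threshold and p < alpha:
        return "decreasing", float(rho)
    if abs(rho) < rho_threshold and rel_range < 0.10:
        return "constant", float(rho)
    return "non-monotone", float(rho)
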