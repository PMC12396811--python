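"""Pseudotime windows along branch segments and windowed empirical distributions.

Every "pseudotime point" downstream is really a pseudotime window: cells of
one branch segment are sorted by pseudotime and partitioned into
equal-frequency windows (optionally overlapping, for smooth trend series).
Equal-frequency rather than equal-width splitting keeps window occupancies
balanced when cells are unevenly distributed along pseudotime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, WindowingError
from .io import BRANCH_LABELS, CountMatrix, TrajectoryAnnotation

__all__ = ["ExpressionWindow", "EmpiricalDistribution", "assign_windows",
           "empirical_distribution", "windows_table", "pool_branch_counts"]


@dataclass(frozen=True)
class ExpressionWindow:
    """A pseudotime window on one branch segment."""

    index: int
    branch: str
    t_lo: float
    t_hi: float
    cell_ids: tuple

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_lo + self.t_hi)


@dataclass(frozen=True)
class EmpiricalDistribution:
    """Discrete empirical law: sorted distinct support values and relative frequencies."""

    support: np.ndarray
    probabilities: np.ndarray
    n: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise DegenerateDataError("probabilities must be nonnegative and sum to 1")
        if self.n < 1:
            raise DegenerateDataError("sample size must be >= 1")

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))


def empirical_distribution(counts) -> EmpiricalDistribution:
    """Relative frequencies over the distinct observed count values."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise DegenerateDataError("cannot form a distribution from an empty vector")
    if np.any(counts < 0):
        raise DegenerateDataError("counts must be nonnegative")
    support, freq = np.unique(counts, return_counts=True)
    return EmpiricalDistribution(support, freq / counts.size, int(counts.size))


def _segment_windows(sub: pd.DataFrame, branch: str, n_windows: int,
                     min_cells: int, overlap: float, start_index: int) -> list[ExpressionWindow]:
    n = len(sub)
    if n < min_cells:
        raise WindowingError(
            f"segment {branch!r} has {n} cells, fewer than min_cells={min_cells}"
        )
    n_windows = max(1, min(n_windows, n // max(min_cells, 1)) or 1)
    t = sub["pseudotime"].to_numpy()
    ids = sub["cell_id"].to_numpy()
    if n_windows == 1:
        starts, length = np.array([0]), n
    else:
        # window length L and step chosen so consecutive windows share
        # `overlap` of their members and the last window ends at n
        length = n / (1.0 + (n_windows - 1) * (1.0 - overlap))
        step = length * (1.0 - overlap)
        starts = np.round(np.arange(n_windows) * step).astype(int)
        length = int(round(length))
    out = []
    for k, s in enumerate(starts):
        e = min(int(s) + int(round(length)), n) if n_windows > 1 else n
        if k == n_windows - 1:
            e = n
        members = ids[s:e]
        if len(members) < min_cells:
            raise WindowingError(
                f"segment {branch!r}: window {k} would hold {len(members)} cells "
                f"(< min_cells={min_cells}); reduce windows_per_segment"
            )
        t_lo = float(t[s])
        t_hi = float(t[e - 1])
        if t_hi <= t_lo:
            t_hi = np.nextafter(t_lo, np.inf)
        out.append(ExpressionWindow(start_index + k, branch, t_lo, t_hi, tuple(members)))
    return out


def assign_windows(annotation: TrajectoryAnnotation, windows_per_segment: int | None = None,
                   min_cells: int = 10, overlap_fraction: float = 0.0,
                   branches=None) -> list[ExpressionWindow]:
    """Partition each branch segment into equal-frequency pseudotime windows.

    With ``overlap_fraction`` 0 the windows of a segment partition its cells
    with occupancies differing by at most 1; with overlap f in (0, 1)
    consecutive windows share a fraction f of their members (sliding window),
    which smooths per-window trend series.  ``windows_per_segment`` defaults
    to one window per ~40 cells (at least 2 where possible).
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise WindowingError("overlap_fraction must lie in [0, 1)")
    present = [b for b in BRANCH_LABELS if (annotation.frame["branch"] == b).any()]
    if branches is not None:
        present = [b for b in present if b in set(branches)]
    windows: list[ExpressionWindow] = []
    for branch in present:
        sub = annotation.cells_on(branch)
        w = windows_per_segment or max(2, len(sub) // 40)
        if overlap_fraction == 0.0 and windows_per_segment is not None:
            # exact equal-frequency split (occupancy difference <= 1)
            n = len(sub)
            if n < min_cells:
                raise WindowingError(
                    f"segment {branch!r} has {n} cells, fewer than min_cells={min_cells}"
                )
            w_eff = max(1, min(w, n // max(min_cells, 1)) or 1)
            chunks = np.array_split(np.arange(n), w_eff)
            t = sub["pseudotime"].to_numpy()
            ids = sub["cell_id"].to_numpy()
            for k, idx in enumerate(chunks):
                if len(idx) < min_cells:
                    raise WindowingError(
                        f"segment {branch!r}: window {k} would hold {len(idx)} cells "
                        f"(< min_cells={min_cells})"
                    )
                t_lo, t_hi = float(t[idx[0]]), float(t[idx[-1]])
                if t_hi <= t_lo:
                    t_hi = np.nextafter(t_lo, np.inf)
                windows.append(ExpressionWindow(len(windows), branch, t_lo, t_hi,
                                                tuple(ids[idx])))
        else:
            windows.extend(_segment_windows(sub, branch, w, min_cells,
                                            overlap_fraction, len(windows)))
    return windows


def windows_table(windows) -> pd.DataFrame:
    """Summary table: window_index, branch, t_lo, t_hi, n_cells."""
    return pd.DataFrame(
        [(w.index, w.branch, w.t_lo, w.t_hi, w.n_cells) for w in windows],
        columns=["window_index", "branch", "t_lo", "t_hi", "n_cells"],
    )


def pool_branch_counts(matrix: CountMatrix, annotation: TrajectoryAnnotation,
                       gene: str, branch: str) -> np.ndarray:
    """Counts of one gene pooled over all cells of one branch segment.

    Distribution comparisons "before branch" / "at branch point" / "after
    branch" pool whole stage clusters rather than single windows.
    """
    cells = annotation.cells_on(branch)["cell_id"].tolist()
    if not cells:
        raise WindowingError(f"no cells on segment {branch!r}")
    return matrix.gene(gene)[matrix.cell_index(cells)]
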