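"""Marker-gene screening: highly-variable-gene ranking intersected with a
significant pre/post-branch distribution shift.

A marker gene must (1) rank within the top ``hvg_threshold`` genes by
mean-binned standardized dispersion (a variance-stabilized HVG scheme) and
(2) show a significant change in its count distribution from the pre-branch
segment to at least one post-branch segment (two-sample Kolmogorov-Smirnov,
Benjamini-Hochberg corrected across all gene x branch tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnnotationError, DegenerateDataError
from .io import CountMatrix, TrajectoryAnnotation
from .windows import pool_branch_counts

__all__ = ["MarkerOptions", "rank_hvg", "branch_shift_test", "select_markers"]


@dataclass
class MarkerOptions:
    hvg_threshold: int = 30
    fdr_level: float = 0.05
    n_bins: int = 20
    min_cells: int = 10
    call_modality: bool = False  # fit modality for flagged markers (slower)
    seed: int = 0


def rank_hvg(matrix: CountMatrix, threshold: int = 30, n_bins: int = 20) -> pd.DataFrame:
    """Rank genes by mean-binned standardized dispersion.

    Counts are per-cell total-normalized (to the median total); per-gene
    dispersion (variance/mean on the normalized linear scale, the classic
    mean-variance-plot statistic) is z-scored within quantile bins of the
    gene mean; genes are ranked by descending z-score with ties broken by
    gene id.  Returns a frame with columns gene, hvg_score, hvg_rank,
    hvg_pass.
    """
    if matrix.n_cells < 2:
        raise DegenerateDataError("HVG ranking needs at least 2 cells")
    totals = matrix.values.sum(axis=1).astype(float)
    totals[totals == 0] = 1.0
    norm = matrix.values / totals[:, None] * np.median(totals)
    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # quantile bins on the mean, z-score dispersion within each bin; cap the
    # bin count so each bin holds >= ~10 genes (a z-score within a 2-3 gene
    # bin is noise)
    n_bins = int(np.clip(matrix.n_genes // 10, 1, n_bins))
    bins = pd.qcut(mean, q=n_bins, labels=False, duplicates="drop")
    score = np.zeros_like(disp)
    for b in np.unique(bins):
        mask = bins == b
        sd = disp[mask].std(ddof=0)
        score[mask] = (disp[mask] - disp[mask].mean()) / sd if sd > 0 else 0.0
    df = pd.DataFrame({"gene": matrix.gene_ids, "hvg_score": score})
    df = df.sort_values(["hvg_score", "gene"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["hvg_rank"] = np.arange(1, len(df) + 1)
    if matrix.n_genes < threshold:
        warnings.warn(
            f"only {matrix.n_genes} genes (< threshold {threshold}); all genes pass HVG",
            stacklevel=2)
        df["hvg_pass"] = True
    else:
        df["hvg_pass"] = df["hvg_rank"] <= threshold
    return df


def branch_shift_test(pre, post, min_cells: int = 10):
    """Two-sample Kolmogorov-Smirnov test between pre- and post-branch counts."""
    pre = np.asarray(pre)
    post = np.asarray(post)
    if pre.size < min_cells or post.size < min_cells:
        raise DegenerateDataError(
            f"groups too small for the shift test: {pre.size}, {post.size} (< {min_cells})"
        )
    res = stats.ks_2samp(pre, post, method="asymp")
    return float(res.statistic), float(res.pvalue)


def select_markers(matrix: CountMatrix, annotation: TrajectoryAnnotation,
                   options: MarkerOptions | None = None) -> pd.DataFrame:
    """Full marker screen: HVG criterion AND a significant branch shift.

    The KS test compares the pre-branch pooled counts of each gene against
    each post-branch segment; p-values are Benjamini-Hochberg corrected
    across all gene x branch tests, and a gene passes the shift criterion if
    significant on at least one branch.
    """
    options = options or MarkerOptions()
    branches = set(annotation.frame["branch"])
    if "pre" not in branches:
        raise AnnotationError("annotation has no pre-branch segment")
    post_branches = [b for b in ("branch1", "branch2") if b in branches]
    if not post_branches:
        raise AnnotationError("annotation has no post-branch segment")

    hvg = rank_hvg(matrix, options.hvg_threshold, options.n_bins).set_index("gene")

    records = []
    for gene in matrix.gene_ids:
        pre = pool_branch_counts(matrix, annotation, gene, "pre")
        for b in post_branches:
            post = pool_branch_counts(matrix, annotation, gene, b)
            stat, p = branch_shift_test(pre, post, options.min_cells)
            records.append((gene, b, stat, p))
    tests = pd.DataFrame(records, columns=["gene", "branch", "ks_stat", "p"])
    _, qvals, _, _ = multipletests(tests["p"], alpha=options.fdr_level, method="fdr_bh")
    tests["q"] = qvals

    rows = []
    for gene in matrix.gene_ids:
        sub = tests[tests["gene"] == gene]
        best = sub.loc[sub["q"].idxmin()]
        shift_pass = bool((sub["q"] < options.fdr_level).any())
        row = {
            "gene": gene,
            "hvg_rank": int(hvg.loc[gene, "hvg_rank"]),
            "hvg_pass": bool(hvg.loc[gene, "hvg_pass"]),
            "ks_stat": float(best["ks_stat"]),
            "p": float(best["p"]),
            "q": float(best["q"]),
            "shift_pass": shift_pass,
            "is_marker": bool(hvg.loc[gene, "hvg_pass"]) and shift_pass,
        }
        rows.append(row)
    report = pd.DataFrame(rows)

    if options.call_modality:
        from .distributions import FitOptions, select_modality
        for col, branch in (("modality_pre", "pre"),
                            ("modality_branch1", "branch1"),
                            ("modality_branch2", "branch2")):
            calls = []
            for gene in report["gene"]:
                if not report.loc[report["gene"] == gene, "is_marker"].iloc[0] \
                        or branch not in branches:
                    calls.append(pd.NA)
                    continue
                counts = pool_branch_counts(matrix, annotation, gene, branch)
                try:
                    calls.append(select_modality(counts, FitOptions(seed=options.seed)).m)
                except DegenerateDataError:
                    calls.append(pd.NA)
            report[col] = calls
    return report
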