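"""Readers and writers for count matrices, trajectory annotations and result bundles.

The on-disk formats are deliberately plain: Matrix Market (``.mtx``) with
``genes.tsv``/``cells.tsv`` label files or a dense CSV/TSV for counts, and a
four-column CSV (``cell_id,pseudotime,stage,branch``) for the trajectory
annotation.  In memory, counts live in a :class:`CountMatrix` (cells x genes,
nonnegative integers) and the trajectory in a :class:`TrajectoryAnnotation`
backed by a pandas DataFrame.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import AnnotationError, FormatError

logger = logging.getLogger(__name__)

#: Allowed branch labels, in trajectory order.  The topology is fixed:
#: pre -> branch_point -> {branch1, branch2}.
BRANCH_LABELS = ("pre", "branch_point", "branch1", "branch2")


@dataclass
class CountMatrix:
    """Cells x genes nonnegative integer expression counts with string ids."""

    values: np.ndarray  # shape (n_cells, n_genes), integer dtype
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise FormatError("count matrix must be 2-dimensional")
        if np.any(self.values < 0):
            raise FormatError("count matrix contains negative entries")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded, atol=1e-6):
                warnings.warn("non-integer counts coerced to integers", stacklevel=2)
            self.values = rounded.astype(np.int64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        """Return the count vector of one gene across all cells."""
        try:
            j = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None
        return self.values[:, j]

    def cell_index(self, cell_ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in cell_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class TrajectoryAnnotation:
    """Per-cell pseudotime, stage cluster and branch label.

    ``frame`` columns: cell_id (str), pseudotime (float in [0, 1]),
    stage (int), branch (one of :data:`BRANCH_LABELS`).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["cell_id", "pseudotime", "stage", "branch"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise AnnotationError(f"annotation missing columns: {missing}")
        df = self.frame[required].copy()
        df["cell_id"] = df["cell_id"].astype(str)
        df["pseudotime"] = pd.to_numeric(df["pseudotime"], errors="coerce")
        if df["pseudotime"].isna().any():
            bad = df.loc[df["pseudotime"].isna(), "cell_id"].tolist()
            raise AnnotationError(f"non-finite pseudotime for cells: {bad[:5]}")
        if not np.all(np.isfinite(df["pseudotime"].to_numpy())):
            raise AnnotationError("pseudotime must be finite")
        unknown = sorted(set(df["branch"]) - set(BRANCH_LABELS))
        if unknown:
            raise AnnotationError(
                f"unknown branch labels {unknown}; allowed: {list(BRANCH_LABELS)}"
            )
        df["stage"] = df["stage"].astype(int)
        self.frame = df.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return self.frame["cell_id"].tolist()

    def cells_on(self, branch: str) -> pd.DataFrame:
        """Rows for one branch segment, sorted by pseudotime (stable)."""
        sub = self.frame[self.frame["branch"] == branch]
        return sub.sort_values("pseudotime", kind="stable").reset_index(drop=True)

    def validate_against(self, matrix: CountMatrix) -> None:
        extra = sorted(set(self.cell_ids) - set(matrix.cell_ids))
        if extra:
            raise AnnotationError(
                f"annotation refers to cells absent from the count matrix: {extra[:5]}"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_label_file(path: Path) -> list[str]:
    labels = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    if not labels:
        raise FormatError(f"empty label file: {path}")
    return labels


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from MTX (+ genes.tsv/cells.tsv) or dense CSV/TSV.

    For MTX input, orientation is normalized to cells x genes using the label
    files: a matrix stored genes x cells is transposed when the label lengths
    disambiguate.  Dense CSV/TSV must have a header row of gene names and a
    first column of cell ids.
    """
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else path.suffix.lstrip("."))
    if fmt == "mtx":
        genes_path = path.parent / "genes.tsv"
        cells_path = path.parent / "cells.tsv"
        for p in (path, genes_path, cells_path):
            if not p.exists():
                raise FormatError(f"missing file: {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_label_file(genes_path)
        cells = _read_label_file(cells_path)
        if mat.shape == (len(cells), len(genes)):
            pass
        elif mat.shape == (len(genes), len(cells)):
            mat = mat.T
        else:
            raise FormatError(
                f"{path}: shape {mat.shape} matches neither "
                f"{len(cells)} cells x {len(genes)} genes nor its transpose"
            )
        return CountMatrix(mat, cells, genes)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return CountMatrix(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])
    raise FormatError(f"unsupported count format: {fmt!r}")


def read_annotation(path: str | Path, matrix: CountMatrix | None = None) -> TrajectoryAnnotation:
    """Read a trajectory annotation CSV with header cell_id,pseudotime,stage,branch."""
    df = pd.read_csv(path)
    ann = TrajectoryAnnotation(df)
    if matrix is not None:
        ann.validate_against(matrix)
    return ann


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_counts(matrix: CountMatrix, out_dir: str | Path, format: str = "mtx") -> list[Path]:
    """Write a CountMatrix; returns the list of files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        mtx = out_dir / "counts.mtx"
        scipy.io.mmwrite(mtx, scipy.sparse.csr_matrix(matrix.values))
        (out_dir / "genes.tsv").write_text("".join(g + "\n" for g in matrix.gene_ids))
        (out_dir / "cells.tsv").write_text("".join(c + "\n" for c in matrix.cell_ids))
        return [mtx, out_dir / "genes.tsv", out_dir / "cells.tsv"]
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        p = out_dir / f"counts.{format}"
        matrix.to_frame().to_csv(p, sep=sep)
        return [p]
    raise FormatError(f"unsupported count format: {format!r}")


def write_annotation(annotation: TrajectoryAnnotation, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    annotation.frame.to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_reports(results: dict, out_dir: str | Path, *, force: bool = False,
                  config_snapshot: dict | None = None) -> dict:
    """Write a bundle of result tables/objects and a checksum manifest.

    ``results`` maps file names to pandas DataFrames (written as CSV/TSV by
    extension) or JSON-serializable objects (written as JSON).  Always writes
    ``run_config.json`` (the config snapshot) and ``manifest.json`` listing
    every produced file with its sha256 checksum.  Refuses to overwrite
    existing result files unless ``force``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []

    def _target(name: str) -> Path:
        p = out_dir / name
        if p.exists() and not force:
            raise FileExistsError(f"refusing to overwrite {p} (use force=True)")
        return p

    snap = _target("run_config.json")
    snap.write_text(json.dumps(config_snapshot or {}, indent=2, sort_keys=True, default=str) + "\n")
    produced.append(snap)

    for name, obj in sorted(results.items()):
        p = _target(name)
        if isinstance(obj, pd.DataFrame):
            sep = "\t" if p.suffix == ".tsv" else ","
            obj.to_csv(p, sep=sep, index=False)
        else:
            p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
        produced.append(p)
        logger.info("wrote %s", p)

    manifest = {
        "files": {p.name: _sha256(p) for p in produced},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
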