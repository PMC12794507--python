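"""Core data model and file I/O.

The canonical in-memory container is :class:`CountMatrix`: a genes × cells
nonnegative matrix (sparse or dense) with unique gene/cell identifiers and a
cell-metadata table carrying the experimental design (batch, donor, timepoint,
condition, cell type).  Genes-as-rows is the Matrix Market single-cell
convention and is never transposed implicitly; the TSV reader accepts either
orientation via an explicit flag.

Gene identifiers are matched case-sensitively throughout: gene symbols differ
by case across species and silent case-folding would corrupt cross-species
signature transfer.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

META_COLUMNS = ("batch", "donor", "timepoint", "condition", "cell_type")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CountMatrix:
    """Genes × cells expression matrix with cell metadata.

    Parameters
    ----------
    values
        Nonnegative matrix, genes as rows.  Stored as CSR when sparse.
    gene_ids, cell_ids
        Unique identifiers, in matrix order.
    cell_meta
        Table indexed by cell id; expected columns include
        ``batch, donor, timepoint, condition, cell_type`` (extra columns pass
        through untouched).
    """

    values: sp.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
        else:
            self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"matrix has {n_genes} gene rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"matrix has {n_cells} cell columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell ids")
        if self.values_min() < 0:
            raise FormatError("negative values in count matrix")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            missing = set(self.cell_ids) - set(self.cell_meta.index.astype(str))
            if missing:
                raise FormatError(
                    f"cell_meta missing {len(missing)} of {n_cells} cells "
                    f"(e.g. {sorted(missing)[:3]})"
                )
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
            self.cell_meta.index.name = "cell_id"

    # -- basic queries -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def values_min(self) -> float:
        if sp.issparse(self.values):
            return float(self.values.data.min()) if self.values.nnz else 0.0
        return float(self.values.min()) if self.values.size else 0.0

    def dense(self) -> np.ndarray:
        """Genes × cells dense array (copies when sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(
            self.values[idx, :], [self.gene_ids[i] for i in idx], list(self.cell_ids),
            self.cell_meta.copy(),
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            self.values[:, idx], list(self.gene_ids),
            [self.cell_ids[i] for i in idx], self.cell_meta.iloc[idx].copy(),
        )

    def gene_means(self) -> np.ndarray:
        return np.asarray(self.values.mean(axis=1)).ravel()

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()


@dataclass
class GeneSet:
    """A named, ordered gene list with optional nonnegative weights."""

    name: str
    genes: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.genes):
                raise ValueError("weights length differs from gene list length")
            if (self.weights < 0).any():
                raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


# ---------------------------------------------------------------------------
# count-matrix I/O
# ---------------------------------------------------------------------------

def read_count_matrix(
    path: str | Path,
    fmt: str = "mtx",
    *,
    meta_path: str | Path | None = None,
    genes_as_rows: bool = True,
) -> CountMatrix:
    """Read a count matrix from disk.

    ``fmt="mtx"`` expects a Matrix Market coordinate file (genes as rows) with
    ``features.tsv`` / ``barcodes.tsv`` sidecars next to it; ``fmt="tsv"``
    expects a dense table with gene ids in the first column (or cell ids when
    ``genes_as_rows=False`` — the orientation is never guessed).
    """
    path = Path(path)
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        base = path.parent
        features = _read_single_column(base / "features.tsv")
        barcodes = _read_single_column(base / "barcodes.tsv")
        if mat.shape[0] != len(features):
            raise FormatError(
                f"matrix has {mat.shape[0]} rows but features.tsv has "
                f"{len(features)} entries"
            )
        if mat.shape[1] != len(barcodes):
            raise FormatError(
                f"matrix has {mat.shape[1]} columns but barcodes.tsv has "
                f"{len(barcodes)} entries"
            )
        values: sp.spmatrix | np.ndarray = sp.csr_matrix(mat)
        gene_ids, cell_ids = features, barcodes
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if not genes_as_rows:
            df = df.T
        values = df.to_numpy(dtype=float)
        gene_ids = [str(i) for i in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'mtx' or 'tsv'")

    data = values.data if sp.issparse(values) else values
    if not np.allclose(data, np.round(data)):
        warnings.warn(
            "matrix contains non-integer values; proceeding (normalized data "
            "is accepted downstream)",
            stacklevel=2,
        )

    meta = None
    if meta_path is None and fmt == "mtx":
        candidate = path.parent / "metadata.tsv"
        meta_path = candidate if candidate.exists() else None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
    cm = CountMatrix(values, gene_ids, cell_ids, meta)
    logger.info("read %s: %d genes x %d cells", path, cm.n_genes, cm.n_cells)
    return cm


def write_count_matrix(cm: CountMatrix, outdir: str | Path, fmt: str = "mtx") -> Path:
    """Write a :class:`CountMatrix`; inverse of :func:`read_count_matrix`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        mat = cm.values if sp.issparse(cm.values) else sp.coo_matrix(cm.values)
        scipy.io.mmwrite(outdir / "matrix.mtx", mat)
        _write_single_column(outdir / "features.tsv", cm.gene_ids)
        _write_single_column(outdir / "barcodes.tsv", cm.cell_ids)
        cm.cell_meta.to_csv(outdir / "metadata.tsv", sep="\t")
        written = outdir / "matrix.mtx"
    elif fmt == "tsv":
        df = pd.DataFrame(cm.dense(), index=cm.gene_ids, columns=cm.cell_ids)
        written = outdir / "matrix.tsv"
        df.to_csv(written, sep="\t")
        cm.cell_meta.to_csv(outdir / "metadata.tsv", sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    logger.info("wrote %s (%d genes x %d cells)", written, cm.n_genes, cm.n_cells)
    return written


def _read_single_column(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"required sidecar {path} not found")
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _write_single_column(path: Path, items: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for item in items:
            fh.write(f"{item}\n")


# ---------------------------------------------------------------------------
# GMT gene-set I/O
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read GMT (name, description, genes...) into a list of :class:`GeneSet`.

    Order is preserved; duplicated genes within a line are dropped with a
    warning; an empty set is an error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and at "
                    f"least one gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"gene set {name!r} contains duplicated genes; deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, unique))
    logger.info("read %d gene sets from %s", len(sets), path)
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path,
                    description: str = "crossmod") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")
    return path


def write_json(obj: object, path: str | Path) -> Path:
    """Write a JSON result file (numpy scalars converted transparently)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o: object) -> object:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
    return path
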