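"""Expression matrix container and IO.

Bulk RNA-Seq and scRNA-Seq expression live in a common genes x samples
container so that downstream featurization can treat the two modalities
uniformly. Normalisation follows the usual TPM/CPM conventions: with gene
lengths, counts are length-corrected before per-million scaling (TPM);
without lengths, plain counts-per-million is used, which is the appropriate
unit for UMI-based single-cell counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

Modality = Literal["bulk", "single_cell"]
TransformState = Literal["raw", "per_million", "log"]

#: one-way transform pipeline raw -> per_million -> log
_STATE_ORDER = ("raw", "per_million", "log")


class ExpressionMatrixError(ValueError):
    """Raised for malformed or inconsistent expression input."""


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers (rows).
    sample_ids : list of str
        Unique sample or cell-barcode identifiers (columns).
    values : ndarray of shape (n_genes, n_samples)
        Non-negative expression values.
    modality : {"bulk", "single_cell"}
    transform_state : {"raw", "per_million", "log"}
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    modality: Modality
    transform_state: TransformState = "raw"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ExpressionMatrixError("values must be a 2D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionMatrixError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ExpressionMatrixError(f"duplicate {name} identifier: {dup!r}")
        if np.isnan(self.values).any():
            raise ExpressionMatrixError("matrix contains NaN values")
        if (self.values < 0).any():
            raise ExpressionMatrixError("matrix contains negative values")
        if self.modality not in ("bulk", "single_cell"):
            raise ExpressionMatrixError(f"unknown modality {self.modality!r}")
        if self.transform_state not in _STATE_ORDER:
            raise ExpressionMatrixError(
                f"unknown transform_state {self.transform_state!r}"
            )
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_vector(self, gene_id: str) -> np.ndarray:
        """Expression values of one gene across all samples."""
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene identifier: {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` in the given order."""
        rows = [self._index[g] for g in gene_ids]
        return replace(self, gene_ids=list(gene_ids), values=self.values[rows])

    def to_tsv(self, path: str | Path) -> None:
        """Write as dense TSV (header = sample ids, first column = gene ids)."""
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.to_csv(path, sep="\t", index_label="gene_id")


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_dense_matrix(
    path: str | Path,
    orientation: Literal["genes_in_rows", "genes_in_columns"] = "genes_in_rows",
    modality: Modality = "bulk",
) -> ExpressionMatrix:
    """Read a dense delimited expression table.

    The delimiter is inferred from the file extension (``.csv`` -> comma,
    otherwise tab). The output is always genes x samples regardless of the
    on-disk orientation; ``transform_state`` is ``raw``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if orientation == "genes_in_columns":
        df = df.T
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    for name, ids in (("gene", gene_ids), ("sample", sample_ids)):
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ExpressionMatrixError(
                f"duplicate {name} identifier in {path.name}: {dup!r}"
            )
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError:
        # locate the offending cell for the error message
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ExpressionMatrixError(
                        f"non-numeric cell at gene {gene_ids[i]!r}, "
                        f"sample {sample_ids[j]!r}: {cell!r}"
                    ) from None
        raise
    m = ExpressionMatrix(gene_ids, sample_ids, values, modality, "raw")
    _log_shape(path.name, m)
    return m


def read_sparse_triplet(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate matrix with gene/barcode sidecars.

    Follows the 10x-style exchange convention: the coordinate file is
    1-based genes x cells; sidecars hold one identifier per line. Entries
    absent from the triplet body are zero.
    """
    matrix_path = Path(matrix_path)
    try:
        sparse = mmread(str(matrix_path))
    except Exception as exc:  # malformed header or out-of-bounds index
        raise ExpressionMatrixError(
            f"cannot read MatrixMarket file {matrix_path.name}: {exc}"
        ) from exc
    values = np.asarray(sparse.todense() if hasattr(sparse, "todense") else sparse,
                        dtype=np.float64)
    genes = _read_id_column(genes_path)
    barcodes = _read_id_column(barcodes_path)
    if len(genes) != values.shape[0]:
        raise ExpressionMatrixError(
            f"gene sidecar lists {len(genes)} ids but matrix declares "
            f"{values.shape[0]} rows"
        )
    if len(barcodes) != values.shape[1]:
        raise ExpressionMatrixError(
            f"barcode sidecar lists {len(barcodes)} ids but matrix declares "
            f"{values.shape[1]} columns"
        )
    m = ExpressionMatrix(genes, barcodes, values, "single_cell", "raw")
    _log_shape(matrix_path.name, m)
    return m


def _read_id_column(path: str | Path) -> list[str]:
    with open(path) as fh:
        # 10x-style sidecars may carry extra tab-separated columns; the id is first
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def _log_shape(name: str, m: ExpressionMatrix) -> None:
    zero_frac = float(np.mean(m.values == 0)) if m.values.size else 0.0
    logger.info(
        "read %s: %d genes x %d samples (%s), zero fraction %.3f",
        name, m.n_genes, m.n_samples, m.modality, zero_frac,
    )


def normalize_per_million(
    matrix: ExpressionMatrix,
    gene_lengths: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Scale each sample to one million.

    With ``gene_lengths`` this is TPM: counts are divided by gene length
    before per-million scaling. Without lengths it is counts-per-million.
    All-zero sample columns are left at zero with a warning.
    """
    if matrix.transform_state != "raw":
        raise ExpressionMatrixError(
            f"normalize_per_million requires raw input, got "
            f"{matrix.transform_state!r}"
        )
    v = matrix.values.copy()
    if gene_lengths is not None:
        lengths = np.empty(matrix.n_genes)
        for i, g in enumerate(matrix.gene_ids):
            l = float(gene_lengths[g])
            if l <= 0:
                raise ExpressionMatrixError(f"non-positive length for gene {g!r}: {l}")
            lengths[i] = l
        v = v / lengths[:, None]
    col_sums = v.sum(axis=0)
    zero_cols = col_sums == 0
    if zero_cols.any():
        logger.warning("%d all-zero sample(s) left unscaled", int(zero_cols.sum()))
    safe = np.where(zero_cols, 1.0, col_sums)
    v = v / safe * 1e6
    v[:, zero_cols] = 0.0
    return replace(matrix, values=v, transform_state="per_million")


def log_transform(
    matrix: ExpressionMatrix,
    base: float = 10.0,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Apply ``log_base(value + pseudocount)`` entrywise."""
    if matrix.transform_state == "log":
        raise ExpressionMatrixError("matrix is already log-transformed")
    if base <= 1:
        raise ExpressionMatrixError(f"log base must exceed 1, got {base}")
    if pseudocount < 0:
        raise ExpressionMatrixError("pseudocount must be non-negative")
    if pseudocount == 0 and (matrix.values == 0).any():
        raise ExpressionMatrixError(
            "pseudocount 0 with zero expression values would produce -inf"
        )
    v = np.log(matrix.values + pseudocount) / np.log(base)
    return replace(matrix, values=v, transform_state="log")


def align_gene_universe(
    bulk: ExpressionMatrix, sc: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Restrict both matrices to their shared, non-silent gene universe.

    Genes must be present in both matrices and expressed (not all-zero) in
    both; silent genes carry no joint-expression signal and would yield
    degenerate histograms.
    """
    sc_set = set(sc.gene_ids)
    shared = [g for g in bulk.gene_ids if g in sc_set]
    kept = [
        g for g in shared
        if bulk.gene_vector(g).any() and sc.gene_vector(g).any()
    ]
    if not kept:
        raise ExpressionMatrixError(
            "no shared expressed genes between bulk and single-cell matrices"
        )
    n_dropped = len(shared) - len(kept)
    if n_dropped:
        logger.info("dropped %d shared but silent gene(s)", n_dropped)
    return bulk.subset_genes(kept), sc.subset_genes(kept), kept
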