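"""Cell-level QC gate, log-normalization, and per-cluster marker statistics.

Boundary handling is deliberate: cells at exactly 200 or 5000 detected
features, or exactly 25% mitochondrial counts, are kept — the exclusion
rules are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite

from .errors import ComputationError, EmptyResultError, InputError, ParameterError

DEFAULT_SCALE = 10_000.0


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer count matrix."""

    matrix: sparse.spmatrix
    genes: np.ndarray
    barcodes: np.ndarray
    mito_prefixes: tuple[str, ...] = ("mt-",)

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ParameterError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} cells"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ParameterError("count matrix contains negative entries")
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("gene names are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ParameterError("cell barcodes are not unique")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def features_per_cell(self) -> np.ndarray:
        """Number of genes with nonzero counts, per cell."""
        m = self.matrix.copy()
        m.eliminate_zeros()
        return np.asarray(m.getnnz(axis=0))

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def mito_gene_mask(self) -> np.ndarray:
        return np.array(
            [any(str(g).startswith(p) for p in self.mito_prefixes) for g in self.genes]
        )

    def mito_fraction(self) -> np.ndarray:
        total = self.counts_per_cell().astype(float)
        mito = np.asarray(self.matrix[self.mito_gene_mask()].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / total, 0.0)
        return frac

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.matrix[:, keep], self.genes, self.barcodes[keep], self.mito_prefixes
        )


def qc_filter(
    m: CountMatrix,
    min_features: int = 200,
    max_features: int = 5000,
    max_mito: float = 0.25,
) -> tuple[CountMatrix, dict]:
    """Drop cells with fewer than `min_features` or more than `max_features`
    detected genes, or more than `max_mito` mitochondrial count fraction.

    All three exclusions are strict, so cells exactly at a bound are kept.
    Returns the filtered matrix and a report with per-rule failure counts.
    """
    if m.n_cells == 0:
        raise ParameterError("count matrix has no cells")
    feats = m.features_per_cell()
    mito = m.mito_fraction()
    low = feats < min_features
    high = feats > max_features
    hot = mito > max_mito
    keep = ~(low | high | hot)
    report = {
        "n_input": int(m.n_cells),
        "n_kept": int(keep.sum()),
        "n_low_features": int(low.sum()),
        "n_high_features": int(high.sum()),
        "n_high_mito": int(hot.sum()),
        "min_features": min_features,
        "max_features": max_features,
        "max_mito": max_mito,
    }
    if not keep.any():
        raise EmptyResultError("no cells survive QC filtering")
    return m.subset_cells(np.flatnonzero(keep)), report


def lognormalize(m: CountMatrix, scale: float = DEFAULT_SCALE) -> sparse.csr_matrix:
    """ln(1 + count / cell_total * scale), per entry.

    Per cell the identity sum(expm1(x)) == scale holds exactly, which the
    tests use as a conservation check. Cells with zero total counts are an
    error naming the offending barcode (run qc_filter first).
    """
    totals = m.counts_per_cell().astype(float)
    if np.any(totals == 0):
        bad = m.barcodes[np.flatnonzero(totals == 0)[0]]
        raise ComputationError(f"cell {bad!r} has zero total counts; apply qc_filter first")
    out = m.matrix.tocsc().astype(float)
    for j in range(out.shape[1]):
        sl = slice(out.indptr[j], out.indptr[j + 1])
        out.data[sl] = np.log1p(out.data[sl] / totals[j] * scale)
    return out.tocsr()


def marker_stats(
    normed: sparse.spmatrix | np.ndarray,
    cluster_labels,
    target_cluster,
    gene_names=None,
) -> pd.DataFrame:
    """Per-gene marker statistics for one cluster versus all others.

    Columns: gene, log2fc (log2 of pseudocount-1-shifted de-logged means),
    pct_in, pct_out (fraction of cells with nonzero expression), p
    (two-sided Wilcoxon rank-sum), p_adj (Bonferroni, capped at 1).
    """
    dense = np.asarray(
        normed.todense() if sparse.issparse(normed) else normed, dtype=float
    )
    labels = np.asarray(cluster_labels)
    if dense.shape[1] != len(labels):
        raise ParameterError("cluster labels do not match the number of cells")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ParameterError("need >= 2 clusters")
    in_mask = labels == target_cluster
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ParameterError("need >= 2 cells inside and outside the target cluster")
    if target_cluster not in uniq:
        raise ParameterError(f"cluster {target_cluster!r} not present")

    n_genes = dense.shape[0]
    if gene_names is None:
        gene_names = [f"gene{i}" for i in range(n_genes)]
    x_in = dense[:, in_mask]
    x_out = dense[:, ~in_mask]
    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)

    pvals = np.empty(n_genes)
    for g in range(n_genes):
        a, b = x_in[g], x_out[g]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[g] = 1.0
            continue
        pvals[g] = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    return pd.DataFrame(
        {
            "gene": list(gene_names),
            "log2fc": log2fc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "p": pvals,
            "p_adj": np.minimum(1.0, pvals * n_genes),
        }
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts_mtx(
    matrix_path, genes_path, barcodes_path, mito_prefixes=("mt-",)
) -> CountMatrix:
    """Read a genes x cells MTX triplet (matrix, gene names, barcodes)."""
    for p in (matrix_path, genes_path, barcodes_path):
        if not Path(p).exists():
            raise InputError(f"missing input file: {p}")
    matrix = sparse.csr_matrix(mmread(str(matrix_path)))
    genes = pd.read_csv(genes_path, header=None)[0].to_numpy()
    barcodes = pd.read_csv(barcodes_path, header=None)[0].to_numpy()
    return CountMatrix(matrix, genes, barcodes, tuple(mito_prefixes))


def write_counts_mtx(m: CountMatrix, out_dir) -> dict:
    """Write matrix.mtx, genes.csv, barcodes.csv into `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), sparse.coo_matrix(m.matrix))
    pd.Series(m.genes).to_csv(out / "genes.csv", index=False, header=False)
    pd.Series(m.barcodes).to_csv(out / "barcodes.csv", index=False, header=False)
    return {
        "matrix": str(out / "matrix.mtx"),
        "genes": str(out / "genes.csv"),
        "barcodes": str(out / "barcodes.csv"),
    }


def read_counts_csv(path, mito_prefixes=("mt-",)) -> CountMatrix:
    """Read a dense genes x cells CSV with gene names as the index column."""
    if not Path(path).exists():
        raise InputError(f"missing input file: {path}")
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        sparse.csr_matrix(df.to_numpy()),
        df.index.to_numpy(),
        df.columns.to_numpy(),
        tuple(mito_prefixes),
    )
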