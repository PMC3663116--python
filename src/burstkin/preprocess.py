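"""Count-matrix ingestion, per-cell scale normalization and expression filtering.

Counts enter as a genes x cells integer matrix (TSV or MatrixMarket) with a
companion gene-length table.  Per-cell normalization factors combine library
size with a trimmed-mean-of-M-values (TMM) scale factor and are rescaled to
geometric mean 1, so that a "normalized read count" x_ij / t_j is on the
scale of the raw counts.  Genes whose maximum normalized count falls below a
cutoff (default 50) are treated as too lowly expressed for kinetic inference
— at low counts technical variability dominates the biological signal — and
are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "compute_norm_factors",
    "normalized_counts",
    "filter_genes",
    "length_offsets",
]

DEFAULT_EXPRESSION_CUTOFF = 50.0


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts with gene lengths and per-cell scale factors.

    Attributes
    ----------
    counts : (G, J) int array
        Read counts x_ij.
    gene_ids, cell_ids : lists of str
    gene_lengths : (G,) float array
        Transcript lengths in bp.
    norm_factors : (J,) float array or None
        Per-cell scale factors t_j with geometric mean 1; None until
        :func:`compute_norm_factors` has been run (all-ones on ingestion).
    """

    counts: np.ndarray
    gene_ids: tuple[str, ...]
    gene_lengths: np.ndarray
    cell_ids: tuple[str, ...]
    norm_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be integers")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        g, j = c.shape
        if len(self.gene_ids) != g or len(self.gene_lengths) != g:
            raise ValueError("gene annotation length does not match count rows")
        if len(self.cell_ids) != j:
            raise ValueError("cell annotation length does not match count columns")
        if np.any(np.asarray(self.gene_lengths) <= 0):
            raise ValueError("gene lengths must be positive")
        if self.norm_factors is not None and len(self.norm_factors) != j:
            raise ValueError("one normalization factor per cell required")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


def _read_lengths(lengths_path: str | Path) -> dict[str, float]:
    tbl = pd.read_csv(lengths_path, sep="\t", header=None, comment="#")
    if tbl.shape[1] < 2:
        raise ValueError(f"{lengths_path}: expected two columns (gene_id, length_bp)")
    # tolerate an optional header row
    first = tbl.iloc[0, 1]
    try:
        float(first)
    except (TypeError, ValueError):
        tbl = tbl.iloc[1:]
    return {str(g): float(v) for g, v in zip(tbl.iloc[:, 0], tbl.iloc[:, 1])}


def read_counts(
    path: str | Path,
    lengths_path: str | Path,
    fmt: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> CountMatrix:
    """Read a genes x cells count matrix plus its gene-length table.

    Parameters
    ----------
    path
        TSV (gene_id column + one column per cell, header row) or
        MatrixMarket coordinate file.
    lengths_path
        Two-column TSV: gene_id, transcript length in bp.
    fmt
        "tsv" or "mtx"; inferred from the file extension when None.
    genes_path, cells_path
        Row / column identifier files (one id per line), required for mtx.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix.lower() in {".mtx", ".mm"} else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        values = df.to_numpy()
    elif fmt == "mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("mtx input requires genes_path and cells_path id files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat)
        gene_ids = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        cell_ids = [ln.strip() for ln in Path(cells_path).read_text().splitlines() if ln.strip()]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    counts = np.asarray(values)
    if not np.issubdtype(counts.dtype, np.integer):
        rounded = np.rint(counts)
        bad = np.nonzero(np.abs(counts - rounded).sum(axis=1) > 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-integer counts for gene {gene_ids[bad[0]]!r}"
            )
        counts = rounded.astype(np.int64)
    counts = counts.astype(np.int64)
    neg = np.nonzero((counts < 0).any(axis=1))[0]
    if neg.size:
        raise ValueError(f"{path}: negative counts for gene {gene_ids[neg[0]]!r}")

    lengths = _read_lengths(lengths_path)
    missing = [g for g in gene_ids if g not in lengths]
    if missing:
        raise ValueError(
            f"{lengths_path}: no length entry for gene {missing[0]!r}"
            + (f" (and {len(missing) - 1} more)" if len(missing) > 1 else "")
        )
    glen = np.array([lengths[g] for g in gene_ids], dtype=float)
    return CountMatrix(
        counts=counts,
        gene_ids=tuple(gene_ids),
        gene_lengths=glen,
        cell_ids=tuple(cell_ids),
        norm_factors=None,
    )


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write the count matrix as TSV (inverse of :func:`read_counts`)."""
    df = pd.DataFrame(cm.counts, index=list(cm.gene_ids), columns=list(cm.cell_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# TMM scale normalization
# ---------------------------------------------------------------------------


def _tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """Weighted trimmed mean of M-values between one cell and the reference.

    Genes expressed in both cells contribute a log2 expression ratio (M) and
    an average log2 abundance (A); the most extreme 30% of M values and 5%
    of A values are trimmed, and the remainder averaged with inverse
    delta-method variance weights.
    """
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return 1.0
    o = obs[mask] / lib_obs
    r = ref[mask] / lib_ref
    log_ratio = np.log2(o / r)
    abs_expr = 0.5 * (np.log2(o) + np.log2(r))
    var = (lib_obs - obs[mask]) / (lib_obs * obs[mask]) + (lib_ref - ref[mask]) / (
        lib_ref * ref[mask]
    )
    n = log_ratio.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(log_ratio)
    rank_s = rankdata(abs_expr)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    keep &= np.isfinite(log_ratio) & np.isfinite(var) & (var > 0)
    if not keep.any():
        return 1.0
    f = np.sum(log_ratio[keep] / var[keep]) / np.sum(1.0 / var[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def compute_norm_factors(cm: CountMatrix) -> CountMatrix:
    """Per-cell scale factors t_j = library size x TMM factor, geomean 1.

    The reference cell is the one whose 75th count-fraction percentile is
    closest to the across-cell mean of that percentile.  Raises if any cell
    has all-zero counts (its factor would be undefined).
    """
    counts = cm.counts.astype(float)
    lib = counts.sum(axis=0)
    zero_cells = [cm.cell_ids[j] for j in np.nonzero(lib == 0)[0]]
    if zero_cells:
        raise ValueError(f"cells with all-zero counts: {', '.join(zero_cells)}")
    if cm.n_cells < 2:
        raise ValueError("normalization requires at least 2 cells")
    q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(cm.n_cells)])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    tmm = np.array(
        [
            _tmm_factor(counts[:, j], counts[:, ref], lib[j], lib[ref])
            for j in range(cm.n_cells)
        ]
    )
    t = lib * tmm
    t = t / np.exp(np.mean(np.log(t)))  # geometric mean 1
    return replace(cm, norm_factors=t)


def normalized_counts(cm: CountMatrix) -> np.ndarray:
    """Scale-normalized counts x_ij / t_j (no gene-length adjustment)."""
    if cm.norm_factors is None:
        raise ValueError("norm_factors not computed; run compute_norm_factors first")
    return cm.counts / cm.norm_factors[None, :]


def filter_genes(cm: CountMatrix, cutoff: float = DEFAULT_EXPRESSION_CUTOFF) -> CountMatrix:
    """Drop genes whose maximum normalized count is below ``cutoff``.

    A gene is kept iff max_j x_ij / t_j >= cutoff; gene order is preserved.
    """
    norm = normalized_counts(cm)
    keep = norm.max(axis=1) >= cutoff
    return replace(
        cm,
        counts=cm.counts[keep],
        gene_ids=tuple(g for g, k in zip(cm.gene_ids, keep) if k),
        gene_lengths=cm.gene_lengths[keep],
    )


def length_offsets(cm: CountMatrix) -> np.ndarray:
    """Gene-length offsets t_i = length / median length over current genes.

    Rescaling by the median keeps the transcription-rate parameter on the
    scale of normalized read counts rather than counts-per-bp.
    """
    med = float(np.median(cm.gene_lengths))
    return cm.gene_lengths / med
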