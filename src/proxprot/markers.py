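"""Single-cell RNA-seq support: cell filtering, specificity tests,
subsampling-equalized differential expression, expression bounds, and
marker-gene selection.

The central procedure is :func:`subsampled_de`, a differential-expression
test between two groups of cells that first equalizes both the number of
cells (subsampling without replacement) and the mean number of transcripts
per cell (binomial thinning of the deeper group) so that detection-rate
differences driven by sequencing depth cannot masquerade as expression
differences, then applies a per-gene two-sided Mann-Whitney U test on
size-factor-normalized counts with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite

from .quant import bh_adjust


@dataclass
class UMICountMatrix:
    """Genes x cells integer UMI counts with per-cell labels.

    counts : scipy.sparse.csr_matrix (genes x cells) of nonnegative ints.
    genes : array of gene symbols (unique).
    barcodes : array of cell barcodes (unique).
    cell_labels : pandas.Series of cluster / cell-type labels per barcode.
    """

    counts: sparse.csr_matrix
    genes: np.ndarray
    barcodes: np.ndarray
    cell_labels: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.genes = np.asarray(self.genes)
        self.barcodes = np.asarray(self.barcodes)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("counts shape must be (n_genes, n_cells)")
        if (self.counts.data < 0).any():
            raise ValueError("UMI counts must be nonnegative")
        if self.cell_labels is not None:
            self.cell_labels = self.cell_labels.reindex(self.barcodes)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMIs (unique transcripts) per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def cells_with_label(self, label: str) -> np.ndarray:
        if self.cell_labels is None:
            raise ValueError("matrix has no cell labels")
        return self.barcodes[(self.cell_labels == label).to_numpy()]

    def subset_cells(self, barcodes: np.ndarray) -> "UMICountMatrix":
        idx = _barcode_indices(self.barcodes, barcodes)
        labels = None if self.cell_labels is None else self.cell_labels.iloc[idx]
        return UMICountMatrix(
            counts=self.counts[:, idx],
            genes=self.genes,
            barcodes=self.barcodes[idx],
            cell_labels=labels,
        )


def _barcode_indices(all_barcodes: np.ndarray, wanted: np.ndarray) -> np.ndarray:
    pos = pd.Index(all_barcodes).get_indexer(wanted)
    if (pos < 0).any():
        missing = np.asarray(wanted)[pos < 0]
        raise KeyError(f"unknown cell barcodes: {missing[:5].tolist()}")
    return pos


def read_umi_mtx(
    directory: str | Path, labels_path: str | Path | None = None
) -> UMICountMatrix:
    """Read a UMI matrix from an MTX triplet directory.

    Expects ``matrix.mtx`` (genes x cells), ``genes.tsv`` and
    ``barcodes.tsv`` (one entry per line, first column used); an optional
    labels TSV has columns barcode, label.
    """
    directory = Path(directory)
    counts = sparse.csr_matrix(mmread(directory / "matrix.mtx"))
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].to_numpy()
    barcodes = pd.read_csv(
        directory / "barcodes.tsv", sep="\t", header=None
    )[0].to_numpy()
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t")
        labels = pd.Series(
            lab["label"].to_numpy(), index=lab["barcode"].to_numpy()
        )
    return UMICountMatrix(counts=counts, genes=genes, barcodes=barcodes,
                          cell_labels=labels)


def write_umi_mtx(m: UMICountMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), sparse.coo_matrix(m.counts))
    pd.Series(m.genes).to_csv(
        directory / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(m.barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if m.cell_labels is not None:
        pd.DataFrame(
            {"barcode": m.barcodes, "label": m.cell_labels.to_numpy()}
        ).to_csv(directory / "labels.tsv", sep="\t", index=False)


def filter_cells_min_umi(m: UMICountMatrix, min_umi: int = 1000) -> UMICountMatrix:
    """Remove cells with fewer than ``min_umi`` unique transcripts.

    A cell with exactly ``min_umi`` transcripts is kept. The gene axis is
    unchanged.
    """
    keep = m.cell_totals() >= min_umi
    if not keep.any():
        raise ValueError(f"no cells with >= {min_umi} transcripts")
    return m.subset_cells(m.barcodes[keep])


def binomial_specificity(m: UMICountMatrix, cluster: str, gene: str) -> float:
    """Upper-tail binomial test for cluster-specific expression of a gene.

    Let k = number of in-cluster cells expressing the gene (count > 0),
    n = cluster size, and p_out = the out-of-cluster expressing fraction
    floored at 1/(n_out + 1) to avoid a degenerate zero probability.
    Returns P(X >= k) for X ~ Binomial(n, p_out); small values indicate
    the gene is expressed in a larger fraction of the cluster than chance
    given its prevalence elsewhere.
    """
    if m.cell_labels is None:
        raise ValueError("matrix has no cell labels")
    in_mask = (m.cell_labels == cluster).to_numpy()
    if not in_mask.any():
        raise ValueError(f"unknown or empty cluster {cluster!r}")
    if in_mask.all():
        raise ValueError("no cells outside the cluster")
    gidx = np.flatnonzero(m.genes == gene)
    if gidx.size == 0:
        raise ValueError(f"unknown gene {gene!r}")
    expressing = np.asarray((m.counts[gidx[0]] > 0).todense()).ravel()
    n = int(in_mask.sum())
    k = int(expressing[in_mask].sum())
    n_out = int((~in_mask).sum())
    p_out = max(expressing[~in_mask].mean(), 1.0 / (n_out + 1))
    return float(stats.binom.sf(k - 1, n, p_out))


def _thin_counts(
    counts: sparse.csr_matrix, p: float, rng: np.random.Generator
) -> sparse.csr_matrix:
    """Binomially thin every entry with retention probability ``p``."""
    out = sparse.csc_matrix(counts).copy()
    out.data = rng.binomial(out.data.astype(np.int64), p)
    out.eliminate_zeros()
    return sparse.csr_matrix(out)


def _size_factors(totals: np.ndarray, dense: np.ndarray, method: str) -> np.ndarray:
    if method == "library":
        sf = totals / totals.mean()
    elif method == "median-ratio":
        # geometric mean reference over genes detected in every cell
        detected = (dense > 0).all(axis=1)
        if detected.sum() < 2:
            sf = totals / totals.mean()
        else:
            ref = np.exp(np.log(dense[detected]).mean(axis=1))
            sf = np.median(dense[detected] / ref[:, None], axis=0)
            sf = sf / sf.mean()
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    if (sf <= 0).any():
        raise ValueError("nonpositive size factor (empty cell?)")
    return sf


def subsampled_de(
    m: UMICountMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    seed: int,
    size_factor_method: str = "library",
) -> pd.DataFrame:
    """Subsampling-equalized differential expression, group_a vs group_b.

    Procedure: (i) the larger group is downsampled without replacement to
    the smaller group's cell count; (ii) the group with the higher mean
    transcripts per cell is binomially thinned so the group means match;
    (iii) counts are size-factor normalized; (iv) per-gene two-sided
    Mann-Whitney U p-values; (v) BH across genes. log2 fold change is
    computed from pseudocounted (+1) normalized group means. All
    randomness is driven by ``seed``; subsampling operates on barcodes in
    sorted order, so cell order never affects the result.

    Returns a DataFrame indexed by gene with columns mean_a, mean_b,
    log2fc, p, q.
    """
    rng = np.random.default_rng(seed)
    ga = np.sort(np.asarray(group_a))
    gb = np.sort(np.asarray(group_b))
    if ga.size < 2 or gb.size < 2:
        raise ValueError("each group needs >=2 cells")

    n = min(ga.size, gb.size)
    if ga.size > n:
        ga = rng.choice(ga, size=n, replace=False)
    if gb.size > n:
        gb = rng.choice(gb, size=n, replace=False)

    A = m.subset_cells(ga).counts
    B = m.subset_cells(gb).counts
    mean_a, mean_b = A.sum() / n, B.sum() / n
    if mean_a > mean_b:
        A = _thin_counts(A, mean_b / mean_a, rng)
    elif mean_b > mean_a:
        B = _thin_counts(B, mean_a / mean_b, rng)

    dense_a = np.asarray(A.todense(), dtype=float)
    dense_b = np.asarray(B.todense(), dtype=float)
    pooled = np.hstack([dense_a, dense_b])
    totals = pooled.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cell with zero transcripts after thinning")
    # one set of size factors over the pooled cells keeps both groups on a
    # common counts-per-mean-depth scale
    sf = _size_factors(totals, pooled, size_factor_method)
    norm = pooled / sf[None, :]
    norm_a, norm_b = norm[:, :n], norm[:, n:]

    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                norm_a,
                norm_b,
                axis=1,
                alternative="two-sided",
                method="asymptotic",
                use_continuity=False,
            )
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # all-tied genes: no evidence either way

    ma = norm_a.mean(axis=1)
    mb = norm_b.mean(axis=1)
    out = pd.DataFrame(
        {
            "mean_a": ma,
            "mean_b": mb,
            "log2fc": np.log2(ma + 1.0) - np.log2(mb + 1.0),
            "p": p,
            "q": bh_adjust(p),
        },
        index=pd.Index(m.genes, name="gene"),
    )
    return out


@dataclass(frozen=True)
class ExpressionBounds:
    """Mean +/- SD of the per-gene mean expression distribution."""

    lower: float
    upper: float
    scale: str = "log"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def mean_expression(m: UMICountMatrix, scale: str = "log") -> pd.Series:
    """Per-gene mean normalized expression over cells.

    Counts are library-size normalized to the mean cell depth; on the
    (default) log scale the per-cell values are log2(x + 1) before
    averaging. Genes with zero total count are dropped.
    """
    totals = m.cell_totals().astype(float)
    if (totals <= 0).any():
        raise ValueError("cell with zero transcripts")
    dense = np.asarray(m.counts.todense(), dtype=float)
    norm = dense / totals[None, :] * totals.mean()
    if scale == "log":
        vals = np.log2(norm + 1.0).mean(axis=1)
    elif scale == "linear":
        vals = norm.mean(axis=1)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    expressed = dense.sum(axis=1) > 0
    return pd.Series(vals[expressed], index=pd.Index(m.genes[expressed], name="gene"))


def expression_bounds(m: UMICountMatrix, scale: str = "log") -> ExpressionBounds:
    """Lower/upper expression bounds (mean -/+ SD over expressed genes).

    The lower bound is a conservative threshold for calling a gene
    expressed in the profiled cell type.
    """
    means = mean_expression(m, scale=scale)
    if len(means) < 2:
        raise ValueError("need >=2 genes with nonzero expression")
    mu, sd = float(means.mean()), float(means.std(ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate expression distribution (SD=0)", RuntimeWarning,
                      stacklevel=2)
    return ExpressionBounds(lower=mu - sd, upper=mu + sd, scale=scale)


def select_markers(
    de: pd.DataFrame, min_log2fc: float = 3.0, max_q: float = 0.01
) -> pd.DataFrame:
    """Select marker genes with >2**min_log2fc-fold specificity.

    Strict inequalities, as in the selection rule log2FC > 3 and
    FDR < 0.01 (i.e. >8-fold specificity). Returns the qualifying rows of
    ``de`` sorted by gene for order-independence.
    """
    keep = (de["log2fc"] > min_log2fc) & (de["q"] < max_q)
    return de.loc[keep].sort_index()
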