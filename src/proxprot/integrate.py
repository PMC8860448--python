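"""Cross-compartment and cross-preparation synthesis.

Marker-protein localization calls (somatodendritic vs axonal), concordance
between slice-derived and synaptosome-derived axonal proteomes, replicate
correlation matrices, z-score hierarchical clustering, and sample PCA.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA


def classify_marker_localization(
    marker_genes: list[str],
    filtered_proteins: pd.Index,
    protein_genes: pd.Series,
    de_vm_vs_str: pd.DataFrame,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Assign each marker gene's protein to a compartment.

    A marker protein present in the filtered proteome is called
    ``VM_enriched`` (somatodendritic) or ``STR_enriched`` (axonal) when the
    VM-APEX2+ vs STR-APEX2+ comparison is significant (q < q_max) with the
    corresponding fold-change sign (positive log2fc = higher in VM);
    otherwise ``unbiased``. Returns one row per marker gene with columns
    present_in_filtered, compartment, q_vm_vs_str, log2fc_vm_vs_str,
    protein_id.
    """
    gene_to_protein = {}
    for pid, gene in protein_genes.items():
        gene_to_protein.setdefault(gene, pid)

    rows = []
    filtered = set(filtered_proteins)
    for gene in marker_genes:
        pid = gene_to_protein.get(gene)
        present = pid is not None and pid in filtered
        q = lfc = np.nan
        compartment = "unbiased"
        if present and pid in de_vm_vs_str.index:
            q = float(de_vm_vs_str.at[pid, "q"])
            lfc = float(de_vm_vs_str.at[pid, "log2fc"])
            if q < q_max and lfc > 0:
                compartment = "VM_enriched"
            elif q < q_max and lfc < 0:
                compartment = "STR_enriched"
        rows.append(
            {
                "gene": gene,
                "protein_id": pid,
                "present_in_filtered": present,
                "compartment": compartment if present else "unbiased",
                "q_vm_vs_str": q,
                "log2fc_vm_vs_str": lfc,
            }
        )
    columns = [
        "gene", "protein_id", "present_in_filtered", "compartment",
        "q_vm_vs_str", "log2fc_vm_vs_str",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("gene")


def concordance_synaptosome(
    reference_proteins: pd.Index,
    de_syn: pd.DataFrame,
    means_slice: pd.Series,
    means_syn: pd.Series,
    q_max: float = 0.15,
) -> dict[str, float]:
    """Concordance of the slice-filtered axonal proteome in synaptosomes.

    A reference protein is concordant when the synaptosome APEX2+ vs
    control comparison shows log2fc > 0 and q < q_max; proteins absent
    from ``de_syn`` count as non-concordant. Pearson r is computed over
    the reference proteins' mean log2 abundances in the two preparations.
    """
    ref = pd.Index(reference_proteins)
    in_de = ref.intersection(de_syn.index)
    sub = de_syn.loc[in_de]
    n_concordant = int(((sub["log2fc"] > 0) & (sub["q"] < q_max)).sum())
    shared = ref.intersection(means_slice.index).intersection(means_syn.index)
    if len(shared) >= 2:
        r = float(np.corrcoef(means_slice[shared], means_syn[shared])[0, 1])
    else:
        r = np.nan
    return {
        "n_reference": int(len(ref)),
        "n_concordant": n_concordant,
        "pearson_r": r,
    }


def replicate_correlations(
    log_abund: pd.DataFrame, samples: list[str]
) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of the given sample columns.

    Zero-variance columns produce NaN entries and a warning.
    """
    if len(samples) < 2:
        raise ValueError("need >=2 samples")
    sub = log_abund[list(samples)]
    if (sub.std(ddof=0) == 0).any():
        warnings.warn("zero-variance sample column; correlations undefined",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.to_numpy(), rowvar=False)
    return pd.DataFrame(corr, index=samples, columns=samples)


def zscore_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (mean 0, population SD 1); constant rows dropped."""
    vals = m.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-variance row(s) excluded from z-scoring",
            RuntimeWarning,
            stacklevel=2,
        )
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals[:, :].std(
        axis=1, ddof=0, keepdims=True
    )
    return pd.DataFrame(z, index=m.index[keep], columns=m.columns)


def zscore_cluster(
    m: pd.DataFrame,
) -> tuple[list, list, np.ndarray | None, np.ndarray | None]:
    """Z-score rows, then average-linkage Euclidean clustering of both axes.

    Returns (row_order, col_order, row_linkage, col_linkage); the orders
    are leaf orders of the dendrograms. A single remaining row passes
    through unclustered.
    """
    z = zscore_rows(m)
    if z.shape[0] < 1 or z.shape[1] < 2:
        raise ValueError("need >=1 usable row and >=2 columns")
    if z.shape[0] == 1:
        return list(z.index), list(z.columns), None, None
    row_link = hierarchy.linkage(pdist(z.to_numpy()), method="average")
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    if z.shape[1] > 2:
        col_link = hierarchy.linkage(pdist(z.to_numpy().T), method="average")
        col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    else:
        col_link, col_order = None, list(z.columns)
    return row_order, col_order, row_link, col_link


def pca_samples(log_abund: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA over samples (samples = observations, proteins = features).

    Returns (coordinates, explained-variance fractions); fractions are
    non-increasing and sum to at most 1.
    """
    if log_abund.shape[1] < 3:
        raise ValueError("need >=3 samples")
    X = log_abund.to_numpy(dtype=float).T
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=log_abund.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
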