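"""Synthetic proximity-labeling proteomics and UMI data with known truth.

The proteomics generator emulates the design of a per-region APEX2+ vs
no-enzyme-control pulldown experiment: log-normal base intensities, a
planted set of APEX2-specific proteins (shared across regions or specific
to one region, optionally with a preferred region for higher abundance),
abundant non-enriched background binders (the endogenously biotinylated
carboxylases and other nonspecific binders every pulldown captures), and
logistic detection dropout at low intensity. The UMI generator draws cells
multinomially from type-specific gene-probability vectors with planted
high-fold marker genes in a target cell type.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .io import GeneSetCollection, IntensityMatrix
from .markers import UMICountMatrix

_DEFAULT_REPLICATES: dict[tuple[str, str], int] = {
    ("VM", "APEX2"): 4,
    ("VM", "CONTROL"): 4,
    ("MFB", "APEX2"): 4,
    ("MFB", "CONTROL"): 4,
    ("STR", "APEX2"): 4,
    ("STR", "CONTROL"): 4,
    ("STR_SYN", "APEX2"): 2,
    ("STR_SYN", "CONTROL"): 4,
}


@dataclass
class ProteomicsSimConfig:
    """Study-design parameters of the proteomics simulation.

    Defaults mirror the emulated experiment: four biological replicates per
    region and condition (two APEX2+ synaptosome replicates), a log2
    enrichment effect of 3 (8-fold, echoing the marker-specificity
    criterion), replicate noise of 0.5 log2 units, and logistic dropout
    that loses quantifications as intensities approach the detection limit.
    """

    n_proteins: int = 2500
    n_background: int = 500
    n_enriched_shared: int = 800
    n_enriched_region: dict[str, int] = field(
        default_factory=lambda: {"VM": 150, "MFB": 80, "STR": 250}
    )
    #: of the shared enriched proteins, how many are more abundant in VM/STR
    n_region_preference: dict[str, int] = field(
        default_factory=lambda: {"VM": 150, "STR": 250}
    )
    effect: float = 3.0
    preference_bias: float = 2.0
    base_log2_mean: float = 12.5
    base_log2_sd: float = 0.8
    background_log2_shift: float = 5.0
    noise_sd: float = 0.5
    dropout_midpoint: float = 14.0
    dropout_slope: float = 0.4
    replicates: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(_DEFAULT_REPLICATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            self.n_background
            + self.n_enriched_shared
            + sum(self.n_enriched_region.values())
        )
        if planted > self.n_proteins:
            raise ValueError("planted categories exceed n_proteins")
        if sum(self.n_region_preference.values()) > self.n_enriched_shared:
            raise ValueError("region preferences exceed shared enriched count")
        if any(n < 2 for n in self.replicates.values() if n is not None):
            raise ValueError("need >=2 replicates per sample group")


@dataclass
class ScRNASimConfig:
    """Parameters of the UMI-count simulation."""

    n_genes: int = 2000
    cell_types: dict[str, float] = field(
        default_factory=lambda: {
            "DA": 0.12,
            "MidbrainNeuron": 0.38,
            "Astro": 0.20,
            "Oligo": 0.10,
            "SPN": 0.15,
            "StriatalInterneuron": 0.05,
        }
    )
    striatal_types: tuple[str, ...] = ("SPN", "StriatalInterneuron")
    target_type: str = "DA"
    n_cells: int = 1200
    depth_log_mean: float = float(np.log(2500.0))
    depth_log_sd: float = 0.35
    n_markers: int = 20
    marker_fold: float = 16.0
    #: marker base weight relative to the mean gene weight (keeps planted
    #: markers well detected outside the target type so fold changes are
    #: estimable)
    marker_base_weight: float = 3.0
    type_jitter_sd: float = 0.3
    gene_names: np.ndarray | None = None
    marker_genes: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cell_types.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"cell-type proportions must sum to 1, got {total}")
        if self.target_type not in self.cell_types:
            raise ValueError("target_type must be one of cell_types")


def _gene_symbol(i: int) -> str:
    return f"G{i:05d}"


def gen_proteomics(
    cfg: ProteomicsSimConfig,
) -> tuple[IntensityMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a proximity-labeling pulldown experiment.

    Returns (intensity matrix, sample annotations, truth table). The truth
    table is indexed by protein id with columns gene, is_background,
    enriched_in (comma-joined region list, '' when not enriched) and
    preferred_region ('' when none). Proteins enriched in STR are also
    enriched in STR_SYN samples (synaptosomes are prepared from striatum).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    protein_ids = np.array([f"P{i:05d}" for i in range(n)])
    genes = np.array([_gene_symbol(i) for i in range(n)])

    # planted categories occupy the leading rows; assignment is part of the
    # deterministic design, abundances are random
    is_background = np.zeros(n, dtype=bool)
    is_background[: cfg.n_background] = True
    enriched_in = np.array([""] * n, dtype=object)
    preferred = np.array([""] * n, dtype=object)

    start = cfg.n_background
    shared = slice(start, start + cfg.n_enriched_shared)
    enriched_in[shared] = "VM,MFB,STR"
    pstart = start
    for region, count in cfg.n_region_preference.items():
        preferred[pstart : pstart + count] = region
        pstart += count
    start += cfg.n_enriched_shared
    for region, count in cfg.n_enriched_region.items():
        enriched_in[start : start + count] = region
        preferred[start : start + count] = region
        start += count

    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n)
    base[is_background] += cfg.background_log2_shift

    annot_rows = []
    columns: dict[str, np.ndarray] = {}
    for (region, condition), n_rep in cfg.replicates.items():
        eff_region = "STR" if region == "STR_SYN" else region
        prep = "synaptosome" if region == "STR_SYN" else "slice"
        enriched_here = np.array(
            [eff_region in e.split(",") if e else False for e in enriched_in]
        )
        for rep in range(1, n_rep + 1):
            sid = f"{region}_{condition}_{rep}"
            x = base + rng.normal(0.0, cfg.noise_sd, size=n)
            if condition == "APEX2":
                x = x + np.where(enriched_here, cfg.effect, 0.0)
                x = x + np.where(
                    enriched_here & (preferred == eff_region),
                    cfg.preference_bias,
                    0.0,
                )
            # logistic detection probability in log2 intensity
            p_detect = 1.0 / (
                1.0 + np.exp(-(x - cfg.dropout_midpoint) / cfg.dropout_slope)
            )
            detected = rng.random(n) < p_detect
            columns[sid] = np.where(detected, 2.0**x, 0.0)
            annot_rows.append(
                {
                    "sample_id": sid,
                    "region": region,
                    "condition": condition,
                    "replicate": rep,
                    "prep": prep,
                }
            )

    values = pd.DataFrame(columns, index=pd.Index(protein_ids, name="protein_id"))
    matrix = IntensityMatrix(
        values=values,
        gene_symbols=pd.Series(genes, index=values.index, name="genes"),
    )
    annot = pd.DataFrame(annot_rows)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_background": is_background,
            "enriched_in": enriched_in,
            "preferred_region": preferred,
        },
        index=values.index,
    )
    return matrix, annot, truth


def gen_scrnaseq(cfg: ScRNASimConfig) -> tuple[UMICountMatrix, pd.DataFrame]:
    """Simulate a droplet-style UMI count matrix with planted markers.

    Cells are drawn multinomially from per-type gene probability vectors;
    planted marker genes receive ``marker_fold``-times higher probability
    mass in the target type. Per-cell depths are log-normal; every cell's
    column sum equals its drawn depth exactly. Returns (matrix, per-gene
    truth with columns is_marker, marker_fold).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = (
        np.asarray(cfg.gene_names)
        if cfg.gene_names is not None
        else np.array([_gene_symbol(i) for i in range(cfg.n_genes)])
    )
    n_genes = len(genes)

    base_w = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    if cfg.marker_genes is not None:
        marker_idx = pd.Index(genes).get_indexer(np.asarray(cfg.marker_genes))
        if (marker_idx < 0).any():
            raise ValueError("marker_genes not all present in gene_names")
    else:
        marker_idx = rng.choice(n_genes, size=cfg.n_markers, replace=False)
    base_w[marker_idx] = cfg.marker_base_weight * base_w.mean()

    type_names = list(cfg.cell_types)
    probs = {}
    for t in type_names:
        w = base_w * rng.lognormal(0.0, cfg.type_jitter_sd, size=n_genes)
        # planted markers keep their exact base weight in every type so the
        # planted fold is the true fold, not fold x jitter
        w[marker_idx] = base_w[marker_idx]
        if t == cfg.target_type:
            w[marker_idx] *= cfg.marker_fold
        probs[t] = w / w.sum()

    proportions = np.array([cfg.cell_types[t] for t in type_names])
    type_of_cell = rng.choice(len(type_names), size=cfg.n_cells, p=proportions)
    depths = np.maximum(
        1,
        np.round(
            rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, size=cfg.n_cells)
        ).astype(int),
    )

    cols = [
        rng.multinomial(depths[c], probs[type_names[type_of_cell[c]]])
        for c in range(cfg.n_cells)
    ]
    counts = sparse.csr_matrix(np.column_stack(cols).astype(np.int64))

    barcodes = np.array([f"CELL{c:05d}" for c in range(cfg.n_cells)])
    labels = pd.Series(
        [type_names[i] for i in type_of_cell], index=barcodes, name="label"
    )
    matrix = UMICountMatrix(
        counts=counts, genes=genes, barcodes=barcodes, cell_labels=labels
    )
    is_marker = np.zeros(n_genes, dtype=bool)
    is_marker[marker_idx] = True
    truth = pd.DataFrame(
        {
            "is_marker": is_marker,
            "marker_fold": np.where(is_marker, cfg.marker_fold, 1.0),
        },
        index=pd.Index(genes, name="gene"),
    )
    return matrix, truth


def gen_study(
    seed: int,
    prot_cfg: ProteomicsSimConfig | None = None,
    sc_cfg: ScRNASimConfig | None = None,
) -> dict:
    """Generate a linked proteomics + single-cell study.

    The UMI matrix uses the proteome's gene symbols, and planted marker
    genes are drawn preferentially from axon-side (STR-preferring) enriched
    proteins so that marker-localization calls have a known answer.
    Returns a dict with keys intensity, annotations, prot_truth, umi,
    sc_truth, marker_truth_side.
    """
    rng = np.random.default_rng(seed)
    prot_cfg = prot_cfg or ProteomicsSimConfig(seed=int(rng.integers(2**31)))
    intensity, annot, prot_truth = gen_proteomics(prot_cfg)

    genes = prot_truth["gene"].to_numpy()
    # markers come from proteins enriched in every region (these survive both
    # cascades) with a planted regional abundance preference
    shared = prot_truth["enriched_in"] == "VM,MFB,STR"
    str_side = prot_truth.index[shared & (prot_truth["preferred_region"] == "STR")]
    vm_side = prot_truth.index[shared & (prot_truth["preferred_region"] == "VM")]
    n_markers = (sc_cfg.n_markers if sc_cfg else ScRNASimConfig.n_markers)
    n_str = int(round(0.75 * n_markers))
    marker_proteins = np.concatenate(
        [
            rng.choice(np.asarray(str_side), size=min(n_str, len(str_side)),
                       replace=False),
            rng.choice(np.asarray(vm_side), size=min(n_markers - n_str, len(vm_side)),
                       replace=False),
        ]
    )
    marker_genes = prot_truth.loc[marker_proteins, "gene"].to_numpy()
    marker_side = pd.Series(
        prot_truth.loc[marker_proteins, "preferred_region"].to_numpy(),
        index=marker_genes,
    )

    if sc_cfg is None:
        sc_cfg = ScRNASimConfig(
            n_genes=len(genes),
            gene_names=genes,
            marker_genes=marker_genes,
            seed=int(rng.integers(2**31)),
        )
    else:
        sc_cfg.gene_names = genes
        sc_cfg.n_genes = len(genes)
        sc_cfg.marker_genes = marker_genes
    umi, sc_truth = gen_scrnaseq(sc_cfg)

    return {
        "intensity": intensity,
        "annotations": annot,
        "prot_truth": prot_truth,
        "umi": umi,
        "sc_truth": sc_truth,
        "marker_truth_side": marker_side,
        "prot_cfg": prot_cfg,
        "sc_cfg": sc_cfg,
    }


def truth_gene_sets(prot_truth: pd.DataFrame, seed: int = 0) -> GeneSetCollection:
    """Gene sets derived from the planted truth, for exercising ORA.

    Builds an axonal set (genes of STR-side proteins), a somatodendritic
    set (VM-side), a background-binder set, and one random decoy set.
    """
    rng = np.random.default_rng(seed)
    axonal = prot_truth.loc[
        prot_truth["preferred_region"] == "STR", "gene"
    ].tolist()
    somadend = prot_truth.loc[
        prot_truth["preferred_region"] == "VM", "gene"
    ].tolist()
    background = prot_truth.loc[prot_truth["is_background"], "gene"].tolist()
    decoy = rng.choice(
        prot_truth["gene"].to_numpy(), size=min(100, len(prot_truth)), replace=False
    ).tolist()
    sets = {
        "axonal_truth": frozenset(axonal),
        "somatodendritic_truth": frozenset(somadend),
        "background_binders": frozenset(background),
        "random_decoy": frozenset(decoy),
    }
    return GeneSetCollection(
        sets={k: v for k, v in sets.items() if v},
        descriptions={k: "synthetic truth-derived set" for k in sets},
    )
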