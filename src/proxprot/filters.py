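"""Compartment filtering cascades for VM (somatodendritic) and striatum (axonal).

Proteins quantified in APEX2+ pulldowns are filtered to the set plausibly
derived from the targeted neurons, combining per-region APEX2+ vs control
enrichment statistics with single-cell RNA-seq evidence that the encoding
gene is expressed in (and not anti-specific to) the targeted cell type.

Ventral midbrain (VM) cascade:
  1. significant enrichment (q < q_enrich, log2fc > 0) in VM APEX2+ vs control;
  2. (a) mean single-cell expression above the lower expression bound, OR
     (b) significant enrichment in all three regions (VM, MFB, STR);
  3. removal when the gene shows very low specificity for the targeted
     neurons (significantly higher in the non-target reference population).

Striatum cascade:
  1. significant enrichment in STR APEX2+ vs control;
  2. (a) significant enrichment in VM or MFB, OR
     (b) log2fc > lfc_mfb_vm in both VM and MFB APEX2+ vs control, OR
     (c) high single-cell expression (above the upper bound) and positive
         specificity vs either reference population;
  3. (a) expression above the lower bound, OR (b) enrichment in all three
     regions;
  4. removal on very low specificity vs either reference population.

Genes absent from the single-cell data fail expression rules (logged, not
an error) but can still pass via the all-three-regions routes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering cascades.

    q_enrich : FDR cut for "significant enrichment" (default 0.05).
    lfc_mfb_vm : log2 fold-change cut of striatum rule 2b (default 1.0).
    q_specificity : FDR cut used on the single-cell specificity DE.
    lfc_specificity_low : log2fc at or below which a gene (significant at
        q_specificity) counts as "very low specificity" (default -1.0).
    expression_lower / expression_upper : bounds on mean single-cell
        expression (mean -/+ SD of the per-gene distribution).
    """

    q_enrich: float = 0.05
    lfc_mfb_vm: float = 1.0
    q_specificity: float = 0.05
    lfc_specificity_low: float = -1.0
    expression_lower: float = 0.0
    expression_upper: float = 0.0

    def __post_init__(self) -> None:
        for name in ("q_enrich", "q_specificity"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.expression_lower > self.expression_upper:
            raise ValueError("expression_lower must be <= expression_upper")


def _enriched(de: pd.DataFrame, q_max: float) -> pd.Series:
    """Boolean per protein: significant with positive fold change."""
    return (de["q"] < q_max) & (de["log2fc"] > 0)


def _gene_lookup(
    genes: pd.Series, table: pd.Series, default: float
) -> pd.Series:
    """Map proteins to a per-gene quantity; absent genes get ``default``."""
    vals = genes.map(table)
    n_absent = int(vals.isna().sum())
    if n_absent:
        logger.info(
            "%d protein(s) with genes absent from single-cell table; "
            "treated as failing expression/specificity rules",
            n_absent,
        )
    return vals.fillna(default)


def _specificity_flags(
    genes: pd.Series, spec_de: pd.DataFrame | None, cfg: FilterConfig
) -> tuple[pd.Series, pd.Series]:
    """(is_specific, is_very_low) per protein from one specificity DE table.

    ``spec_de`` is indexed by gene symbol with columns log2fc (target
    neurons minus reference cells) and q. Genes absent from the table are
    neither specific nor very-low.
    """
    if spec_de is None:
        false = pd.Series(False, index=genes.index)
        return false, false.copy()
    q = _gene_lookup(genes, spec_de["q"], default=1.0)
    lfc = _gene_lookup(genes, spec_de["log2fc"], default=0.0)
    specific = (q < cfg.q_specificity) & (lfc > 0)
    very_low = (q < cfg.q_specificity) & (lfc <= cfg.lfc_specificity_low)
    return specific, very_low


def filter_vm(
    de_vm: pd.DataFrame,
    de_mfb: pd.DataFrame,
    de_str: pd.DataFrame,
    genes: pd.Series,
    expr: pd.Series,
    spec_mid: pd.DataFrame | None,
    cfg: FilterConfig,
) -> pd.DataFrame:
    """Evaluate the VM cascade; returns a per-protein boolean rule trail.

    Parameters
    ----------
    de_vm, de_mfb, de_str : per-region APEX2+ vs control DE tables sharing
        one protein index.
    genes : protein -> representative gene symbol.
    expr : per-gene mean single-cell expression (the scale on which the
        bounds of ``cfg`` were computed).
    spec_mid : specificity DE (target neurons vs other midbrain cells),
        indexed by gene, columns log2fc and q; None disables rule 3.
    """
    _check_universe(de_vm, de_mfb, de_str, genes)
    rule1 = _enriched(de_vm, cfg.q_enrich)
    expr_vals = _gene_lookup(genes, expr, default=-float("inf"))
    rule2a = expr_vals >= cfg.expression_lower
    rule2b = (
        _enriched(de_vm, cfg.q_enrich)
        & _enriched(de_mfb, cfg.q_enrich)
        & _enriched(de_str, cfg.q_enrich)
    )
    _, very_low = _specificity_flags(genes, spec_mid, cfg)

    trail = pd.DataFrame(
        {
            "vm_rule1": rule1,
            "vm_rule2a": rule2a,
            "vm_rule2b": rule2b,
            "vm_rule3_removed": very_low,
        },
        index=de_vm.index,
    )
    trail["pass_vm"] = (
        trail["vm_rule1"]
        & (trail["vm_rule2a"] | trail["vm_rule2b"])
        & ~trail["vm_rule3_removed"]
    )
    return trail


def filter_str(
    de_vm: pd.DataFrame,
    de_mfb: pd.DataFrame,
    de_str: pd.DataFrame,
    genes: pd.Series,
    expr: pd.Series,
    spec_mid: pd.DataFrame | None,
    spec_str: pd.DataFrame | None,
    cfg: FilterConfig,
) -> pd.DataFrame:
    """Evaluate the striatum cascade; returns a per-protein rule trail.

    ``spec_mid`` / ``spec_str`` are the specificity DE tables of the target
    neurons vs other midbrain cells and vs striatal cells, respectively.
    """
    _check_universe(de_vm, de_mfb, de_str, genes)
    rule1 = _enriched(de_str, cfg.q_enrich)
    rule2a = _enriched(de_vm, cfg.q_enrich) | _enriched(de_mfb, cfg.q_enrich)
    rule2b = (de_vm["log2fc"] > cfg.lfc_mfb_vm) & (
        de_mfb["log2fc"] > cfg.lfc_mfb_vm
    )
    expr_vals = _gene_lookup(genes, expr, default=-float("inf"))
    spec_mid_pos, very_low_mid = _specificity_flags(genes, spec_mid, cfg)
    spec_str_pos, very_low_str = _specificity_flags(genes, spec_str, cfg)
    rule2c = (expr_vals >= cfg.expression_upper) & (
        spec_mid_pos | spec_str_pos
    )
    rule3a = expr_vals >= cfg.expression_lower
    rule3b = (
        _enriched(de_vm, cfg.q_enrich)
        & _enriched(de_mfb, cfg.q_enrich)
        & _enriched(de_str, cfg.q_enrich)
    )
    rule4 = very_low_mid | very_low_str

    trail = pd.DataFrame(
        {
            "str_rule1": rule1,
            "str_rule2a": rule2a,
            "str_rule2b": rule2b,
            "str_rule2c": rule2c,
            "str_rule3a": rule3a,
            "str_rule3b": rule3b,
            "str_rule4_removed": rule4,
        },
        index=de_str.index,
    )
    trail["pass_str"] = (
        trail["str_rule1"]
        & (trail["str_rule2a"] | trail["str_rule2b"] | trail["str_rule2c"])
        & (trail["str_rule3a"] | trail["str_rule3b"])
        & ~trail["str_rule4_removed"]
    )
    return trail


def _check_universe(
    de_vm: pd.DataFrame, de_mfb: pd.DataFrame, de_str: pd.DataFrame, genes: pd.Series
) -> None:
    if not (
        de_vm.index.equals(de_mfb.index)
        and de_vm.index.equals(de_str.index)
        and de_vm.index.equals(genes.index)
    ):
        raise ValueError("DE tables and gene map must share one protein index")


def combine_union(
    vm_trail: pd.DataFrame, str_trail: pd.DataFrame
) -> tuple[dict[str, pd.Index], dict[str, int]]:
    """Partition the union of passing proteins into vm_only/str_only/both.

    Returns (partition, counts); the three parts are disjoint and their
    sizes sum to the size of the union.
    """
    if not vm_trail.index.equals(str_trail.index):
        raise ValueError("trails must share one protein index")
    pv = vm_trail["pass_vm"]
    ps = str_trail["pass_str"]
    partition = {
        "vm_only": vm_trail.index[pv & ~ps],
        "str_only": vm_trail.index[~pv & ps],
        "both": vm_trail.index[pv & ps],
    }
    counts = {k: len(v) for k, v in partition.items()}
    counts["union"] = counts["vm_only"] + counts["str_only"] + counts["both"]
    return partition, counts


def region_enriched_sets(
    partition: dict[str, pd.Index],
    de_vm_vs_str: pd.DataFrame,
    q_max: float = 0.05,
) -> dict[str, pd.Index]:
    """Region-enriched sets and the inputs to over-representation analysis.

    ``de_vm_vs_str`` is the VM APEX2+ vs STR APEX2+ comparison computed on
    the shared ("both") proteins; positive log2fc means higher in VM.
    The ORA inputs are region_only ∪ region_enriched (disjoint by
    construction, so their sizes add exactly).
    """
    both = partition["both"]
    de = de_vm_vs_str.loc[de_vm_vs_str.index.intersection(both)]
    vm_enriched = de.index[(de["q"] < q_max) & (de["log2fc"] > 0)]
    str_enriched = de.index[(de["q"] < q_max) & (de["log2fc"] < 0)]
    return {
        "vm_enriched": vm_enriched,
        "str_enriched": str_enriched,
        "vm_go_input": partition["vm_only"].union(vm_enriched),
        "str_go_input": partition["str_only"].union(str_enriched),
    }
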