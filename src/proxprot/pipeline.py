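"""End-to-end orchestration: normalize -> DE -> filter -> markers -> integrate -> ORA.

:func:`analyze` runs the full analysis on in-memory inputs and returns all
intermediate tables plus a machine-readable report of every threshold,
seed, and stage count. :func:`run_pipeline` drives it from a YAML config
(either a synthetic study or file paths) and optionally writes all outputs
as TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import enrich, filters, integrate, markers as sc, quant, simulate
from .io import (
    GeneSetCollection,
    IntensityMatrix,
    read_gmt,
    read_intensity_table,
    samples_matching,
)
from .markers import UMICountMatrix, read_umi_mtx

logger = logging.getLogger(__name__)

REGION_ORDER = ("VM", "MFB", "STR", "STR_SYN")


def _apex_vs_control(
    log_abund: pd.DataFrame, annot: pd.DataFrame, region: str
) -> pd.DataFrame:
    ga = samples_matching(annot, region=region, condition="APEX2")
    gb = samples_matching(annot, region=region, condition="CONTROL")
    return quant.differential(log_abund, ga, gb)


def analyze(
    intensity: IntensityMatrix,
    annot: pd.DataFrame,
    umi: UMICountMatrix,
    da_label: str = "DA",
    striatal_labels: tuple[str, ...] = (),
    exclude_labels: tuple[str, ...] = (),
    gene_sets: GeneSetCollection | None = None,
    q_enrich: float = 0.05,
    lfc_mfb_vm: float = 1.0,
    q_specificity: float = 0.05,
    lfc_specificity_low: float = -1.0,
    marker_min_log2fc: float = 3.0,
    marker_max_q: float = 0.01,
    concordance_q: float = 0.15,
    min_umi: int = 1000,
    seed: int = 0,
) -> dict:
    """Run the complete compartment-proteomics analysis.

    Returns a dict of stage outputs plus ``report``, a JSON-serializable
    summary with per-region enriched counts, the filter partition, ORA
    input sizes, marker-localization tallies, and concordance.
    """
    report: dict = {
        "thresholds": {
            "q_enrich": q_enrich,
            "lfc_mfb_vm": lfc_mfb_vm,
            "q_specificity": q_specificity,
            "lfc_specificity_low": lfc_specificity_low,
            "marker_min_log2fc": marker_min_log2fc,
            "marker_max_q": marker_max_q,
            "concordance_q": concordance_q,
            "min_umi": min_umi,
        },
        "seed": seed,
    }

    # --- proteomics normalization and per-region enrichment ---
    log_abund = quant.normalize_log2(intensity)
    regions = [r for r in REGION_ORDER if r in set(annot["region"])]
    de: dict[str, pd.DataFrame] = {
        r: _apex_vs_control(log_abund, annot, r) for r in regions
    }
    report["n_proteins"] = int(log_abund.shape[0])
    report["enriched_counts"] = {
        r: quant.count_enriched(de[r], q_max=q_enrich, direction="up")
        for r in regions
    }
    logger.info("per-region enriched counts: %s", report["enriched_counts"])

    # --- single-cell support: expression bounds, specificity, markers ---
    umi = umi.subset_cells(
        umi.barcodes[~umi.cell_labels.isin(exclude_labels).to_numpy()]
    )
    umi = sc.filter_cells_min_umi(umi, min_umi=min_umi)
    labels = umi.cell_labels
    da_cells = umi.cells_with_label(da_label)
    striatal_mask = labels.isin(striatal_labels).to_numpy()
    midbrain_other = umi.barcodes[
        (~striatal_mask) & (labels != da_label).to_numpy()
    ]
    striatal_cells = umi.barcodes[striatal_mask]

    da_matrix = umi.subset_cells(da_cells)
    bounds = sc.expression_bounds(da_matrix)
    expr = sc.mean_expression(da_matrix)
    report["n_cells_used"] = int(umi.n_cells)
    report["n_da_cells"] = int(len(da_cells))
    report["expression_bounds"] = {"lower": bounds.lower, "upper": bounds.upper}

    spec_mid = sc.subsampled_de(umi, da_cells, midbrain_other, seed=seed)
    spec_str = (
        sc.subsampled_de(umi, da_cells, striatal_cells, seed=(seed + 1) % 2**31)
        if len(striatal_cells) >= 2
        else None
    )
    marker_table = sc.select_markers(
        spec_mid, min_log2fc=marker_min_log2fc, max_q=marker_max_q
    )
    report["n_marker_genes"] = int(len(marker_table))

    # --- filtering cascades and union ---
    fcfg = filters.FilterConfig(
        q_enrich=q_enrich,
        lfc_mfb_vm=lfc_mfb_vm,
        q_specificity=q_specificity,
        lfc_specificity_low=lfc_specificity_low,
        expression_lower=bounds.lower,
        expression_upper=bounds.upper,
    )
    genes = intensity.gene_symbols
    vm_trail = filters.filter_vm(
        de["VM"], de["MFB"], de["STR"], genes, expr, spec_mid, fcfg
    )
    str_trail = filters.filter_str(
        de["VM"], de["MFB"], de["STR"], genes, expr, spec_mid, spec_str, fcfg
    )
    partition, counts = filters.combine_union(vm_trail, str_trail)
    report["filter_partition"] = counts

    # --- VM vs STR comparison on the shared proteins ---
    vm_apex = samples_matching(annot, region="VM", condition="APEX2")
    str_apex = samples_matching(annot, region="STR", condition="APEX2")
    de_vm_vs_str = quant.differential(
        log_abund.loc[partition["both"]], vm_apex, str_apex
    )
    sets = filters.region_enriched_sets(partition, de_vm_vs_str, q_max=q_enrich)
    report["region_enriched"] = {
        "vm_enriched": len(sets["vm_enriched"]),
        "str_enriched": len(sets["str_enriched"]),
        "vm_go_input": len(sets["vm_go_input"]),
        "str_go_input": len(sets["str_go_input"]),
    }

    # --- marker-protein localization ---
    # localization uses the same VM-APEX2+ vs STR-APEX2+ comparison but over
    # the whole filtered union, so markers passing only one region's cascade
    # still receive a compartment call
    union_index = partition["vm_only"].union(partition["str_only"]).union(
        partition["both"]
    )
    de_vm_vs_str_union = quant.differential(
        log_abund.loc[union_index], vm_apex, str_apex
    )
    localization = integrate.classify_marker_localization(
        list(marker_table.index), union_index, genes, de_vm_vs_str_union,
        q_max=q_enrich,
    )
    tally = localization.loc[
        localization["present_in_filtered"], "compartment"
    ].value_counts()
    report["marker_localization"] = {
        "n_markers": int(len(localization)),
        "n_present": int(localization["present_in_filtered"].sum()),
        "VM_enriched": int(tally.get("VM_enriched", 0)),
        "STR_enriched": int(tally.get("STR_enriched", 0)),
        "unbiased": int(tally.get("unbiased", 0)),
    }

    # --- slice vs synaptosome concordance ---
    concordance = None
    if "STR_SYN" in de:
        str_filtered = str_trail.index[str_trail["pass_str"]]
        syn_apex = samples_matching(annot, region="STR_SYN", condition="APEX2")
        concordance = integrate.concordance_synaptosome(
            str_filtered,
            de["STR_SYN"],
            means_slice=log_abund[str_apex].mean(axis=1),
            means_syn=log_abund[syn_apex].mean(axis=1),
            q_max=concordance_q,
        )
        report["concordance"] = concordance

    # --- sample PCA on the filtered union ---
    pca_samples = [
        s
        for s in log_abund.columns
        if annot.set_index("sample_id").loc[s, "condition"] in ("APEX2", "CONTROL")
    ]
    coords, var_frac = integrate.pca_samples(
        log_abund.loc[union_index, pca_samples]
    )
    report["pca_variance_fractions"] = [float(v) for v in var_frac[:5]]

    # --- over-representation analysis of the axonal ORA input ---
    ora = None
    if gene_sets is not None:
        universe = set(genes.loc[union_index])
        query = set(genes.loc[sets["str_go_input"]]) & universe
        ora = enrich.hypergeom_ora(query, gene_sets, universe)
        report["ora_top_terms"] = (
            ora.head(3).reset_index()[["term", "q"]].to_dict("records")
        )

    return {
        "log_abund": log_abund,
        "de": de,
        "de_vm_vs_str": de_vm_vs_str,
        "de_vm_vs_str_union": de_vm_vs_str_union,
        "expr": expr,
        "bounds": bounds,
        "spec_mid": spec_mid,
        "spec_str": spec_str,
        "marker_table": marker_table,
        "vm_trail": vm_trail,
        "str_trail": str_trail,
        "partition": partition,
        "sets": sets,
        "localization": localization,
        "concordance": concordance,
        "pca_coords": coords,
        "ora": ora,
        "report": report,
    }


def run_synthetic(seed: int = 0, **overrides) -> dict:
    """Generate a linked synthetic study and analyze it end to end."""
    study = simulate.gen_study(seed)
    gene_sets = simulate.truth_gene_sets(study["prot_truth"], seed=seed)
    sc_cfg = study["sc_cfg"]
    result = analyze(
        study["intensity"],
        study["annotations"],
        study["umi"],
        da_label=sc_cfg.target_type,
        striatal_labels=sc_cfg.striatal_types,
        gene_sets=gene_sets,
        seed=seed,
        **overrides,
    )
    result["study"] = study
    return result


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the pipeline from a YAML config (path or pre-parsed dict).

    Config keys: either ``synthetic: {seed: int}`` or ``inputs:`` with
    paths (intensity, annotations, umi_dir, labels, gmt) plus optional
    ``thresholds:`` overrides (keyword names of :func:`analyze`) and
    ``da_label`` / ``striatal_labels`` / ``exclude_labels``.
    """
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    thresholds = dict(config.get("thresholds", {}))
    seed = int(config.get("seed", 0))

    if "synthetic" in config:
        seed = int(config["synthetic"].get("seed", seed))
        result = run_synthetic(seed=seed, **thresholds)
    else:
        inputs = config["inputs"]
        intensity, annot = read_intensity_table(
            inputs["intensity"], inputs["annotations"]
        )
        umi = read_umi_mtx(inputs["umi_dir"], labels_path=inputs.get("labels"))
        gene_sets = read_gmt(inputs["gmt"]) if inputs.get("gmt") else None
        result = analyze(
            intensity,
            annot,
            umi,
            da_label=config.get("da_label", "DA"),
            striatal_labels=tuple(config.get("striatal_labels", ())),
            exclude_labels=tuple(config.get("exclude_labels", ())),
            gene_sets=gene_sets,
            seed=seed,
            **thresholds,
        )

    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for region, table in result["de"].items():
        table.to_csv(outdir / f"de_{region}.tsv", sep="\t")
    result["de_vm_vs_str"].to_csv(outdir / "de_vm_vs_str.tsv", sep="\t")
    trail = result["vm_trail"].join(result["str_trail"])
    trail.to_csv(outdir / "filter_trail.tsv", sep="\t")
    result["marker_table"].to_csv(outdir / "markers.tsv", sep="\t")
    result["localization"].to_csv(outdir / "marker_localization.tsv", sep="\t")
    result["pca_coords"].to_csv(outdir / "pca_samples.tsv", sep="\t")
    if result["ora"] is not None:
        result["ora"].to_csv(outdir / "ora.tsv", sep="\t")
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result["report"], fh, indent=2)
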