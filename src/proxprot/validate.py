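"""Calibration and recovery experiments on synthetic data.

These experiments quantify the statistical behavior of the pipeline under
known ground truth: conservation of the total-intensity normalization,
false-positive calibration of the proteomics and single-cell differential
tests under pure nulls, and recovery of planted enrichment effects and
marker genes. They are used by the test suite and by the reproduction
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import markers as sc
from . import quant, simulate
from .io import samples_matching


def normalization_conservation_error(seed: int = 0, n_matrices: int = 20) -> float:
    """Max relative error of sum(2^a - 1) = 1e6 over random matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        n, m = int(rng.integers(5, 200)), int(rng.integers(2, 10))
        vals = rng.lognormal(8, 2, size=(n, m))
        vals[rng.random(vals.shape) < 0.3] = 0.0
        vals[0] += 1.0  # keep every column total positive
        df = pd.DataFrame(
            vals,
            index=[f"P{i}" for i in range(n)],
            columns=[f"S{j}" for j in range(m)],
        )
        genes = pd.Series([f"G{i}" for i in range(n)], index=df.index)
        from .io import IntensityMatrix

        a = quant.normalize_log2(IntensityMatrix(values=df, gene_symbols=genes))
        sums = (2.0**a - 1.0).sum(axis=0).to_numpy()
        worst = max(worst, float(np.abs(sums - 1e6).max() / 1e6))
    return worst


def _null_config(seed: int) -> simulate.ProteomicsSimConfig:
    """Default study conditions with the planted effect switched off."""
    return simulate.ProteomicsSimConfig(
        n_proteins=2000,
        n_background=400,
        n_enriched_shared=640,
        n_enriched_region={"VM": 120, "MFB": 64, "STR": 200},
        n_region_preference={"VM": 120, "STR": 200},
        effect=0.0,
        preference_bias=0.0,
        replicates={
            ("VM", "APEX2"): 4,
            ("VM", "CONTROL"): 4,
            ("STR", "APEX2"): 4,
            ("STR", "CONTROL"): 4,
        },
        seed=seed,
    )


def proteomics_null_fraction(n_seeds: int = 20, seed0: int = 0) -> float:
    """Mean fraction of proteins flagged (q<0.05) with no planted effect.

    2000 proteins, 16 samples (two regions x 4 APEX2 + 4 control) per seed.
    """
    fracs = []
    for s in range(n_seeds):
        m, annot, _ = simulate.gen_proteomics(_null_config(seed0 + s))
        la = quant.normalize_log2(m)
        for region in ("VM", "STR"):
            de = quant.differential(
                la,
                samples_matching(annot, region=region, condition="APEX2"),
                samples_matching(annot, region=region, condition="CONTROL"),
            )
            fracs.append((de["q"] < 0.05).mean())
    return float(np.mean(fracs))


def sc_null_fraction(n_seeds: int = 20, seed0: int = 0) -> float:
    """Mean fraction of genes flagged (q<0.01) under a shared-multinomial null.

    Two groups of 500 cells drawn from one cell type (identical gene
    probabilities), 2000 genes per seed.
    """
    fracs = []
    for s in range(n_seeds):
        cfg = simulate.ScRNASimConfig(
            n_genes=2000,
            n_cells=1000,
            cell_types={"A": 1.0},
            striatal_types=(),
            target_type="A",
            n_markers=0,
            seed=seed0 + s,
        )
        m, _ = simulate.gen_scrnaseq(cfg)
        de = sc.subsampled_de(
            m, m.barcodes[:500], m.barcodes[500:], seed=seed0 + s
        )
        fracs.append((de["q"] < 0.01).mean())
    return float(np.mean(fracs))


def planted_recovery(seed: int = 0) -> dict[str, float]:
    """Recovery of planted enriched proteins under the default study design.

    A planted protein counts as recovered when it is called enriched
    (q<0.05, log2fc>0, APEX2+ vs control) in at least one region it was
    planted in; the empirical FDR is the fraction of all proteins called
    enriched in any region that were not planted at all.
    """
    cfg = simulate.ProteomicsSimConfig(seed=seed)
    m, annot, truth = simulate.gen_proteomics(cfg)
    la = quant.normalize_log2(m)
    hits = {}
    for region in ("VM", "MFB", "STR"):
        de = quant.differential(
            la,
            samples_matching(annot, region=region, condition="APEX2"),
            samples_matching(annot, region=region, condition="CONTROL"),
        )
        hits[region] = (de["q"] < 0.05) & (de["log2fc"] > 0)
    planted = truth["enriched_in"] != ""
    recovered = sum(
        any(hits[r][pid] for r in truth.at[pid, "enriched_in"].split(","))
        for pid in truth.index[planted]
    )
    any_hit = hits["VM"] | hits["MFB"] | hits["STR"]
    n_false = int((any_hit & ~planted).sum())
    n_called = int(any_hit.sum())
    return {
        "sensitivity": recovered / int(planted.sum()),
        "fdr": n_false / n_called if n_called else 0.0,
        "n_planted": int(planted.sum()),
        "n_called": n_called,
    }


def marker_selection_rate(
    n_seeds: int = 20, seed0: int = 0, fold: float = 16.0, n_markers: int = 3
) -> float:
    """Fraction of planted >=16-fold markers selected, averaged over seeds."""
    rates = []
    for s in range(n_seeds):
        cfg = simulate.ScRNASimConfig(
            n_genes=1000,
            n_cells=600,
            cell_types={"DA": 0.3, "Other": 0.7},
            striatal_types=(),
            target_type="DA",
            n_markers=n_markers,
            marker_fold=fold,
            seed=seed0 + s,
        )
        m, truth = simulate.gen_scrnaseq(cfg)
        da = m.cells_with_label("DA")
        rest = np.setdiff1d(m.barcodes, da)
        de = sc.subsampled_de(m, da, rest, seed=seed0 + s + 10_000)
        selected = set(sc.select_markers(de).index)
        planted = set(truth.index[truth["is_marker"]])
        rates.append(len(planted & selected) / len(planted))
    return float(np.mean(rates))


def cascade_mismatch_count() -> int:
    """Filter cascades vs direct evaluation of their boolean formulas.

    Exhausts every combination of per-region significance, fold-change,
    expression-level and specificity inputs for a single protein and counts
    disagreements between the cascade implementation and an independent
    evaluation of the rule logic (0 = exact agreement).
    """
    import itertools

    from . import filters

    cfg = filters.FilterConfig(expression_lower=1.0, expression_upper=3.0)
    idx = pd.Index(["P"], name="protein_id")
    genes = pd.Series(["G"], index=idx)
    spec_tables = {
        "verylow": pd.DataFrame({"log2fc": [-2.0], "q": [0.001]}, index=["G"]),
        "neutral": pd.DataFrame({"log2fc": [0.1], "q": [0.9]}, index=["G"]),
        "positive": pd.DataFrame({"log2fc": [2.0], "q": [0.001]}, index=["G"]),
    }
    expr_tables = {
        "absent": pd.Series(dtype=float),
        "below": pd.Series({"G": 0.5}),
        "mid": pd.Series({"G": 2.0}),
        "high": pd.Series({"G": 3.5}),
    }

    def de(sig, lfc_high=False):
        lfc = 1.5 if (sig or lfc_high) else 0.2
        return pd.DataFrame({"q": [0.01 if sig else 0.5], "log2fc": [lfc]},
                            index=idx)

    mismatches = 0
    combos = itertools.product(
        [False, True], [False, True], [False, True], [False, True],
        [False, True], expr_tables, spec_tables, spec_tables,
    )
    for (vm_sig, mfb_sig, str_sig, vm_hi, mfb_hi, expr_level,
         s_mid, s_str) in combos:
        de_vm, de_mfb, de_str = de(vm_sig, vm_hi), de(mfb_sig, mfb_hi), de(str_sig)
        vm = filters.filter_vm(
            de_vm, de_mfb, de_str, genes, expr_tables[expr_level],
            spec_tables[s_mid], cfg,
        ).iloc[0]
        st = filters.filter_str(
            de_vm, de_mfb, de_str, genes, expr_tables[expr_level],
            spec_tables[s_mid], spec_tables[s_str], cfg,
        ).iloc[0]
        ge_lower = expr_level in ("mid", "high")
        ge_upper = expr_level == "high"
        all_three = vm_sig and mfb_sig and str_sig
        vm_expected = vm_sig and (ge_lower or all_three) and s_mid != "verylow"
        str_expected = (
            str_sig
            and (vm_sig or mfb_sig
                 or ((vm_sig or vm_hi) and (mfb_sig or mfb_hi))
                 or (ge_upper and "positive" in (s_mid, s_str)))
            and (ge_lower or all_three)
            and s_mid != "verylow" and s_str != "verylow"
        )
        mismatches += int(bool(vm["pass_vm"]) != vm_expected)
        mismatches += int(bool(st["pass_str"]) != str_expected)
    return mismatches
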