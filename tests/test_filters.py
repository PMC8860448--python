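import itertools

import numpy as np
import pandas as pd

from proxprot import filters

CFG = filters.FilterConfig(expression_lower=1.0, expression_upper=3.0)


def de_table(index, q, lfc):
    return pd.DataFrame({"q": q, "log2fc": lfc}, index=index)


def build_inputs(
    *,
    vm_sig=False,
    mfb_sig=False,
    str_sig=False,
    vm_lfc_high=False,
    mfb_lfc_high=False,
    expr_level="absent",  # absent | below | mid | high
    spec_mid="neutral",  # verylow | neutral | positive
    spec_str="neutral",
):
    """One-protein DE/expression/specificity inputs realizing a rule combo."""
    idx = pd.Index(["P"], name="protein_id")
    genes = pd.Series(["G"], index=idx)

    def de(sig, lfc_high):
        lfc = 1.5 if (sig or lfc_high) else 0.2
        return de_table(idx, [0.01 if sig else 0.5], [lfc])

    de_vm = de(vm_sig, vm_lfc_high)
    de_mfb = de(mfb_sig, mfb_lfc_high)
    de_str = de(str_sig, False)
    expr = {
        "absent": pd.Series(dtype=float),
        "below": pd.Series({"G": 0.5}),
        "mid": pd.Series({"G": 2.0}),
        "high": pd.Series({"G": 3.5}),
    }[expr_level]
    spec = {
        "verylow": pd.DataFrame({"log2fc": [-2.0], "q": [0.001]}, index=["G"]),
        "neutral": pd.DataFrame({"log2fc": [0.1], "q": [0.9]}, index=["G"]),
        "positive": pd.DataFrame({"log2fc": [2.0], "q": [0.001]}, index=["G"]),
    }
    return dict(
        de_vm=de_vm,
        de_mfb=de_mfb,
        de_str=de_str,
        genes=genes,
        expr=expr,
        spec_mid=spec[spec_mid],
        spec_str=spec[spec_str],
    )


class TestVMCascade:
    def test_pass_via_expression(self):
        inp = build_inputs(vm_sig=True, expr_level="mid")
        trail = filters.filter_vm(
            inp["de_vm"], inp["de_mfb"], inp["de_str"], inp["genes"],
            inp["expr"], inp["spec_mid"], CFG,
        )
        assert bool(trail["pass_vm"].iloc[0])

    def test_enrichment_gate_is_hard(self):
        inp = build_inputs(vm_sig=False, expr_level="high", mfb_sig=True,
                           str_sig=True)
        trail = filters.filter_vm(
            inp["de_vm"], inp["de_mfb"], inp["de_str"], inp["genes"],
            inp["expr"], inp["spec_mid"], CFG,
        )
        assert not bool(trail["pass_vm"].iloc[0])

    def test_pass_via_all_three_regions_despite_low_expression(self):
        inp = build_inputs(vm_sig=True, mfb_sig=True, str_sig=True,
                           expr_level="below")
        trail = filters.filter_vm(
            inp["de_vm"], inp["de_mfb"], inp["de_str"], inp["genes"],
            inp["expr"], inp["spec_mid"], CFG,
        )
        assert bool(trail["vm_rule2b"].iloc[0])
        assert bool(trail["pass_vm"].iloc[0])

    def test_very_low_specificity_removal(self):
        inp = build_inputs(vm_sig=True, expr_level="mid", spec_mid="verylow")
        trail = filters.filter_vm(
            inp["de_vm"], inp["de_mfb"], inp["de_str"], inp["genes"],
            inp["expr"], inp["spec_mid"], CFG,
        )
        assert not bool(trail["pass_vm"].iloc[0])


class TestStrCascade:
    def test_pass_via_vm_enrichment(self):
        inp = build_inputs(str_sig=True, vm_sig=True, expr_level="mid")
        trail = filters.filter_str(
            inp["de_vm"], inp["de_mfb"], inp["de_str"], inp["genes"],
            inp["expr"], inp["spec_mid"], inp["spec_str"], CFG,
        )
        assert bool(trail["pass_str"].iloc[0])

    def test_pass_via_fold_change_route(self):
        inp = build_inputs(str_sig=True, vm_lfc_high=True, mfb_lfc_high=True,
                           expr_level="mid")
        trail = filters.filter_str(
            inp["de_vm"], inp["de_mfb"], inp["de_str"], inp["genes"],
            inp["expr"], inp["spec_mid"], inp["spec_str"], CFG,
        )
        assert bool(trail["str_rule2b"].iloc[0])
        assert bool(trail["pass_str"].iloc[0])

    def test_fail_when_no_second_region_evidence(self):
        inp = build_inputs(str_sig=True, expr_level="mid")
        trail = filters.filter_str(
            inp["de_vm"], inp["de_mfb"], inp["de_str"], inp["genes"],
            inp["expr"], inp["spec_mid"], inp["spec_str"], CFG,
        )
        assert not bool(trail["pass_str"].iloc[0])


def test_cascades_match_bruteforce_boolean_formulas():
    """Exhaustive rule combinations agree with directly evaluated logic."""
    levels = dict(
        vm_sig=[False, True],
        mfb_sig=[False, True],
        str_sig=[False, True],
        vm_lfc_high=[False, True],
        mfb_lfc_high=[False, True],
        expr_level=["absent", "below", "mid", "high"],
        spec_mid=["verylow", "neutral", "positive"],
        spec_str=["verylow", "neutral", "positive"],
    )
    keys = list(levels)
    for combo in itertools.product(*levels.values()):
        kw = dict(zip(keys, combo))
        inp = build_inputs(**kw)
        vm = filters.filter_vm(
            inp["de_vm"], inp["de_mfb"], inp["de_str"], inp["genes"],
            inp["expr"], inp["spec_mid"], CFG,
        ).iloc[0]
        st = filters.filter_str(
            inp["de_vm"], inp["de_mfb"], inp["de_str"], inp["genes"],
            inp["expr"], inp["spec_mid"], inp["spec_str"], CFG,
        ).iloc[0]

        # independent evaluation of the cascade logic from the combo itself
        expr_ge_lower = kw["expr_level"] in ("mid", "high")
        expr_ge_upper = kw["expr_level"] == "high"
        all_three = kw["vm_sig"] and kw["mfb_sig"] and kw["str_sig"]
        vm_expected = (
            kw["vm_sig"]
            and (expr_ge_lower or all_three)
            and kw["spec_mid"] != "verylow"
        )
        str_expected = (
            kw["str_sig"]
            and (
                kw["vm_sig"]
                or kw["mfb_sig"]
                or ((kw["vm_sig"] or kw["vm_lfc_high"])
                    and (kw["mfb_sig"] or kw["mfb_lfc_high"]))
                or (expr_ge_upper
                    and ("positive" in (kw["spec_mid"], kw["spec_str"])))
            )
            and (expr_ge_lower or all_three)
            and kw["spec_mid"] != "verylow"
            and kw["spec_str"] != "verylow"
        )
        assert bool(vm["pass_vm"]) == vm_expected, kw
        assert bool(st["pass_str"]) == str_expected, kw


def random_trails(rng, n=200):
    idx = pd.Index([f"P{i}" for i in range(n)])
    vm = pd.DataFrame({"pass_vm": rng.random(n) < 0.4}, index=idx)
    st = pd.DataFrame({"pass_str": rng.random(n) < 0.4}, index=idx)
    return vm, st


class TestCombineUnion:
    def test_empty_trails(self):
        vm = pd.DataFrame({"pass_vm": []}, dtype=bool)
        st = pd.DataFrame({"pass_str": []}, dtype=bool)
        _, counts = filters.combine_union(vm, st)
        assert counts == {"vm_only": 0, "str_only": 0, "both": 0, "union": 0}

    def test_matches_set_algebra(self, rng):
        vm, st = random_trails(rng)
        partition, counts = filters.combine_union(vm, st)
        v = set(vm.index[vm["pass_vm"]])
        s = set(st.index[st["pass_str"]])
        assert set(partition["vm_only"]) == v - s
        assert set(partition["str_only"]) == s - v
        assert set(partition["both"]) == v & s
        assert counts["union"] == len(v | s)


class TestRegionEnrichedSets:
    def test_no_de_hits_reduces_to_region_only(self, rng):
        vm, st = random_trails(rng, n=50)
        partition, _ = filters.combine_union(vm, st)
        de = de_table(partition["both"], np.ones(len(partition["both"])),
                      np.zeros(len(partition["both"])))
        sets = filters.region_enriched_sets(partition, de)
        assert set(sets["vm_go_input"]) == set(partition["vm_only"])
        assert set(sets["str_go_input"]) == set(partition["str_only"])

    def test_go_input_sizes_decompose_additively(self, rng):
        vm, st = random_trails(rng)
        partition, _ = filters.combine_union(vm, st)
        nb = len(partition["both"])
        de = de_table(partition["both"], rng.random(nb), rng.normal(0, 2, nb))
        sets = filters.region_enriched_sets(partition, de)
        assert len(sets["vm_go_input"]) == len(partition["vm_only"]) + len(
            sets["vm_enriched"]
        )
        assert len(sets["str_go_input"]) == len(partition["str_only"]) + len(
            sets["str_enriched"]
        )


def test_relaxing_q_threshold_never_shrinks_pass_sets(rng):
    n = 300
    idx = pd.Index([f"P{i}" for i in range(n)])
    genes = pd.Series([f"G{i}" for i in range(n)], index=idx)
    mk = lambda: de_table(idx, rng.random(n), rng.normal(0.5, 1.5, n))
    de_vm, de_mfb, de_str = mk(), mk(), mk()
    expr = pd.Series(rng.normal(2, 1, n), index=genes.to_numpy())
    spec = pd.DataFrame(
        {"log2fc": rng.normal(0, 1.5, n), "q": rng.random(n)},
        index=genes.to_numpy(),
    )
    passes = []
    for q in (0.01, 0.05, 0.2):
        cfg = filters.FilterConfig(
            q_enrich=q, expression_lower=1.0, expression_upper=3.0
        )
        vm = filters.filter_vm(de_vm, de_mfb, de_str, genes, expr, spec, cfg)
        passes.append(set(vm.index[vm["pass_vm"]]))
    assert passes[0] <= passes[1] <= passes[2]


def test_trail_invariant_structure(synthetic_run):
    """Pass flags always satisfy the cascade's boolean structure."""
    vm = synthetic_run["vm_trail"]
    st = synthetic_run["str_trail"]
    assert (
        vm["pass_vm"]
        == vm["vm_rule1"]
        & (vm["vm_rule2a"] | vm["vm_rule2b"])
        & ~vm["vm_rule3_removed"]
    ).all()
    assert (
        st["pass_str"]
        == st["str_rule1"]
        & (st["str_rule2a"] | st["str_rule2b"] | st["str_rule2c"])
        & (st["str_rule3a"] | st["str_rule3b"])
        & ~st["str_rule4_removed"]
    ).all()
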