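import numpy as np
import pandas as pd
import pytest

from proxprot import integrate


def avg_linkage_bruteforce(points):
    """O(n^3) average-linkage agglomeration returning merge heights."""
    clusters = {i: [i] for i in range(len(points))}
    dist = lambda a, b: float(np.linalg.norm(points[a] - points[b]))
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                d = np.mean(
                    [dist(a, b) for a in clusters[i] for b in clusters[j]]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return heights


class TestReplicateCorrelations:
    def test_duplicated_column_perfectly_correlated(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [5.0, 1, 2]})
        corr = integrate.replicate_correlations(m, ["a", "b", "c"])
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_anticorrelated_vectors(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
        corr = integrate.replicate_correlations(m, ["a", "b"])
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_column_warns(self):
        m = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.warns(RuntimeWarning):
            corr = integrate.replicate_correlations(m, ["a", "b"])
        assert np.isnan(corr.loc["a", "b"])


class TestZscoreCluster:
    def test_rows_standardized(self, rng):
        m = pd.DataFrame(rng.normal(5, 3, size=(10, 6)))
        z = integrate.zscore_rows(m)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(z.to_numpy().std(axis=1), 1.0, atol=1e-10)

    def test_identical_rows_merge_at_height_zero(self):
        m = pd.DataFrame(
            [[1.0, 2, 3, 4], [2.0, 4, 6, 8], [9.0, 1, 5, 2]],
            index=["r0", "r1", "r2"],
        )
        # r0 and r1 are identical after z-scoring
        _, _, link, _ = integrate.zscore_cluster(m)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_linkage_heights_match_bruteforce(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(6, 4)))
        z = integrate.zscore_rows(m)
        _, _, link, _ = integrate.zscore_cluster(m)
        expected = avg_linkage_bruteforce(z.to_numpy())
        assert np.allclose(sorted(link[:, 2]), sorted(expected), atol=1e-10)

    def test_row_permutation_invariance(self, rng):
        m = pd.DataFrame(
            rng.normal(0, 1, size=(8, 5)), index=[f"r{i}" for i in range(8)]
        )
        order1, _, _, _ = integrate.zscore_cluster(m)
        perm = m.sample(frac=1, random_state=3)
        order2, _, _, _ = integrate.zscore_cluster(perm)
        # same leaf sets at every dendrogram height -> same flat structure;
        # compare as multisets of adjacent pairs is overly strict, so compare
        # cophenetic-equivalent grouping via sorted leaf order heights
        assert sorted(order1) == sorted(order2)


class TestPCA:
    def test_two_duplicated_groups_rank_one(self):
        base = np.arange(10.0)
        m = pd.DataFrame(
            {
                "a1": base, "a2": base, "a3": base,
                "b1": base + 5, "b2": base + 5, "b3": base + 5,
            }
        )
        coords, var = integrate.pca_samples(m)
        assert var[0] == pytest.approx(1.0, abs=1e-9)
        a = coords.loc[["a1", "a2", "a3"], "PC1"]
        b = coords.loc[["b1", "b2", "b3"], "PC1"]
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_variance_fractions_non_increasing(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(20, 8)))
        _, var = integrate.pca_samples(m)
        assert np.all(np.diff(var) <= 1e-12)
        assert var.sum() <= 1.0 + 1e-9

    def test_matches_eigendecomposition(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(20, 8)))
        coords, var = integrate.pca_samples(m)
        X = m.to_numpy().T
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        explained = var * eigvals.sum() / eigvals.sum()  # fractions
        assert np.allclose(var, eigvals[: len(var)] / eigvals.sum(), atol=1e-9)
        # coordinates have the eigenvalue variances
        assert np.allclose(
            coords.to_numpy().var(axis=0, ddof=1), eigvals[: len(var)],
            atol=1e-9,
        )

    def test_row_permutation_invariance(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(15, 6)))
        c1, v1 = integrate.pca_samples(m)
        perm = m.sample(frac=1, random_state=2)
        c2, v2 = integrate.pca_samples(perm)
        assert np.allclose(v1, v2, atol=1e-10)
        assert np.allclose(np.abs(c1.to_numpy()), np.abs(c2.to_numpy()),
                           atol=1e-8)


class TestConcordance:
    def de(self, lfc, q):
        return pd.DataFrame(
            {"log2fc": lfc, "q": q},
            index=[f"P{i}" for i in range(len(lfc))],
        )

    def test_no_positive_fold_changes_means_zero(self):
        de = self.de([-1.0, -0.5, 0.0], [0.01, 0.01, 0.01])
        res = integrate.concordance_synaptosome(
            de.index, de, pd.Series(dtype=float), pd.Series(dtype=float)
        )
        assert res["n_concordant"] == 0

    def test_duplicated_abundances_correlate_perfectly(self, rng):
        de = self.de([1.0] * 10, [0.01] * 10)
        means = pd.Series(rng.normal(5, 1, 10), index=de.index)
        res = integrate.concordance_synaptosome(de.index, de, means, means.copy())
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["n_concordant"] == 10

    def test_absent_proteins_count_as_nonconcordant(self):
        de = self.de([1.0], [0.01])
        ref = pd.Index(["P0", "MISSING"])
        res = integrate.concordance_synaptosome(
            ref, de, pd.Series(dtype=float), pd.Series(dtype=float)
        )
        assert res["n_reference"] == 2
        assert res["n_concordant"] == 1

    def test_monotone_in_q_threshold(self, rng):
        de = self.de(rng.normal(0.5, 1, 100), rng.random(100))
        counts = [
            integrate.concordance_synaptosome(
                de.index, de, pd.Series(dtype=float), pd.Series(dtype=float),
                q_max=q,
            )["n_concordant"]
            for q in (0.05, 0.15, 0.5, 1.0)
        ]
        assert counts == sorted(counts)


class TestMarkerLocalization:
    def make_de(self, lfc, q, pids):
        return pd.DataFrame({"log2fc": lfc, "q": q}, index=pids)

    def test_empty_marker_set(self):
        de = self.make_de([1.0], [0.01], ["P0"])
        out = integrate.classify_marker_localization(
            [], pd.Index(["P0"]), pd.Series({"P0": "G0"}), de
        )
        assert out.empty

    def test_sign_convention_mirrors_under_de_negation(self):
        pids = ["P0", "P1", "P2"]
        genes = pd.Series({"P0": "g0", "P1": "g1", "P2": "g2"})
        de = self.make_de([2.0, -2.0, 0.1], [0.01, 0.01, 0.9], pids)
        fwd = integrate.classify_marker_localization(
            ["g0", "g1", "g2"], pd.Index(pids), genes, de
        )
        neg = de.copy()
        neg["log2fc"] = -neg["log2fc"]
        rev = integrate.classify_marker_localization(
            ["g0", "g1", "g2"], pd.Index(pids), genes, neg
        )
        swap = {"VM_enriched": "STR_enriched", "STR_enriched": "VM_enriched",
                "unbiased": "unbiased"}
        assert list(rev["compartment"]) == [
            swap[c] for c in fwd["compartment"]
        ]

    def test_compartment_requires_significance(self):
        genes = pd.Series({"P0": "g0"})
        de = self.make_de([3.0], [0.2], ["P0"])
        out = integrate.classify_marker_localization(
            ["g0"], pd.Index(["P0"]), genes, de
        )
        assert out.loc["g0", "compartment"] == "unbiased"

    def test_planted_axon_bias_is_recovered(self):
        """Markers planted with a 4-fold axonal bias are called axonal."""
        from proxprot import quant, simulate
        from proxprot.io import samples_matching

        # the 4-fold bias is planted in a small fraction of proteins so the
        # compositional (total-intensity) shift stays small, as in a real
        # experiment where most of the proteome is unbiased
        cfg = simulate.ProteomicsSimConfig(
            n_proteins=600,
            n_background=50,
            n_enriched_shared=300,
            n_enriched_region={},
            n_region_preference={"STR": 40},
            preference_bias=2.0,
            dropout_midpoint=-100.0,  # clean quantification for this check
            replicates={("VM", "APEX2"): 6, ("STR", "APEX2"): 6},
            seed=21,
        )
        m, annot, truth = simulate.gen_proteomics(cfg)
        la = quant.normalize_log2(m)
        de = quant.differential(
            la,
            samples_matching(annot, region="VM", condition="APEX2"),
            samples_matching(annot, region="STR", condition="APEX2"),
        )
        marker_pids = truth.index[truth["preferred_region"] == "STR"][:30]
        marker_genes = truth.loc[marker_pids, "gene"].tolist()
        out = integrate.classify_marker_localization(
            marker_genes, truth.index, m.gene_symbols, de
        )
        frac = (out["compartment"] == "STR_enriched").mean()
        assert frac >= 0.9
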