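"""Axis selection, karyotype genotyping, polarization, local PCA, blocks."""

import numpy as np
import pandas as pd
import pytest

import svkaryo as sk
from svkaryo import sv_karyotype as svk
from svkaryo import windows as win
from svkaryo import ancestry as anc


def hwe_exact_pvalue(n_het, n_hom0, n_hom1):
    """Exact two-sided HWE test (conditional on allele counts)."""
    from math import lgamma

    n = n_het + n_hom0 + n_hom1
    n_a = 2 * n_hom0 + n_het  # minor-ish allele count
    n_a = min(n_a, 2 * n - n_a)

    def logprob(h):
        hom_a = (n_a - h) // 2
        hom_b = n - h - hom_a
        return (
            lgamma(n + 1) - lgamma(hom_a + 1) - lgamma(h + 1) - lgamma(hom_b + 1)
            + h * np.log(2) + lgamma(n_a + 1) + lgamma(2 * n - n_a + 1) - lgamma(2 * n + 1)
        )

    hs = [h for h in range(n_a % 2, n_a + 1, 2) if (n_a - h) // 2 + h <= n]
    probs = np.exp([logprob(h) for h in hs])
    probs /= probs.sum()
    obs = probs[hs.index(n_het if n_het in hs else hs[0])]
    return float(probs[probs <= obs + 1e-12].sum())


class TestAxisSelection:
    def test_sv_chromosome_has_three_clusters_on_pc1(self, study):
        _, gm, _ = study
        res = svk.chrom_pca(gm, "chr03")
        het = win.individual_het(gm, "chr03")
        assert svk.select_sv_axis(res, het) == 0

    def test_collinear_chromosome_yields_none(self, study):
        _, gm, _ = study
        for chrom in ("chr01", "chr04"):
            res = svk.chrom_pca(gm, chrom)
            het = win.individual_het(gm, chrom)
            assert svk.select_sv_axis(res, het) is None

    def test_stronger_geographic_split_pushes_sv_to_pc2(self):
        # strong two-way geographic drift dominates PC1; the karyotype
        # clusters (equal frequency in every lineage) land on PC2
        cfg = sk.SimConfig(
            n_per_group={"C": 30, "S": 30, "M": 30},
            n_chroms=1, sites_per_chrom=3000, chrom_length_bp=500_000, seed=17,
            fst_targets={"CM": 0.28, "CS": 0.28, "SM": 0.01},
            sv_specs=[sk.SVSpec("chr01", 150_000, 300_000, hap_divergence=0.0015,
                                karyotype_freqs={"C": 0.5, "S": 0.5, "M": 0.5})],
        )
        gm, truth = sk.simulate_study(cfg)
        res = svk.chrom_pca(gm, "chr01")
        het = win.individual_het(gm, "chr01")
        assert svk.select_sv_axis(res, het) == 1


class TestGenotyping:
    def test_perfect_calls_on_separated_clusters(self, study, truth_profiles):
        _, gm, truth = study
        res = svk.chrom_pca(gm, "chr08")
        het = win.individual_het(gm, "chr08")
        axis = svk.select_sv_axis(res, het)
        calls, _ = svk.polarize(
            svk.genotype_karyotypes(res, axis, het_by_sample=het), truth_profiles)
        tk = dict(zip(truth.karyotypes["chr08"]["sample"],
                      truth.karyotypes["chr08"]["karyotype"]))
        called = calls[calls["genotype"] != "unassigned"]
        assert (called["genotype"] == called["sample"].map(tk)).all()
        assert len(called) / len(calls) > 0.95

    def test_heterokaryote_recall(self, study, truth_profiles):
        _, gm, truth = study
        hits = total = 0
        for chrom in ("chr03", "chr07", "chr15"):
            res = svk.chrom_pca(gm, chrom)
            het = win.individual_het(gm, chrom)
            axis = svk.select_sv_axis(res, het)
            calls, _ = svk.polarize(
                svk.genotype_karyotypes(res, axis, het_by_sample=het), truth_profiles)
            tk = dict(zip(truth.karyotypes[chrom]["sample"],
                          truth.karyotypes[chrom]["karyotype"]))
            het_true = calls["sample"].map(tk) == "01"
            hits += (calls.loc[het_true, "genotype"] == "01").sum()
            total += het_true.sum()
        assert hits / total >= 0.95

    def test_midway_sample_unassigned(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-10, 0.3, 30), rng.normal(0, 0.3, 30),
                            rng.normal(10, 0.3, 30), [-5.0]])
        res = {"coords": x.reshape(-1, 1), "samples": [f"s{i}" for i in range(91)]}
        calls = svk.genotype_karyotypes(res, 0, threshold=0.90)
        assert calls.loc[calls["sample"] == "s90", "genotype"].iloc[0] == "unassigned"
        assert (calls["genotype"][:90] != "unassigned").all()

    def test_degenerate_mixture_all_unassigned(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)  # single blob: outer components starve
        x[0] = 30.0
        res = {"coords": x.reshape(-1, 1), "samples": [f"s{i}" for i in range(40)]}
        calls = svk.genotype_karyotypes(res, 0)
        assert (calls["genotype"] == "unassigned").all()

    def test_hardy_weinberg_in_panmictic_population(self):
        # random pairing of haplotypes must leave genotype counts in HWE
        pvals = []
        for seed in range(5):
            cfg = sk.SimConfig(
                n_per_group={"S": 80}, n_chroms=1, sites_per_chrom=1500,
                chrom_length_bp=400_000, seed=100 + seed,
                sv_specs=[sk.SVSpec("chr01", 100_000, 300_000, hap_divergence=0.001,
                                    karyotype_freqs={"C": 0.5, "S": 0.5, "M": 0.5})],
            )
            gm, truth = sk.simulate_study(cfg)
            k = truth.karyotypes["chr01"]["karyotype"]
            counts = pd.Series(list(k)).value_counts()
            pvals.append(hwe_exact_pvalue(
                int(counts.get("01", 0)), int(counts.get("00", 0)), int(counts.get("11", 0))))
        assert sum(p > 0.01 for p in pvals) >= 4


class TestPolarize:
    def _calls(self, genos):
        return pd.DataFrame({"sample": [f"s{i}" for i in range(len(genos))],
                             "genotype": genos, "confidence": 1.0, "axis_used": 0})

    def _profiles(self, classes):
        return pd.DataFrame({"sample": [f"s{i}" for i in range(len(classes))],
                             "ternary_class": classes})

    def test_southern_cluster_becomes_00(self):
        calls = self._calls(["11", "11", "00", "01"])
        prof = self._profiles(["S", "S", "M", "MCS"])
        out, rec = svk.polarize(calls, prof)
        assert rec["swapped"] and rec["polarized"]
        assert out["genotype"].tolist() == ["00", "00", "11", "01"]

    def test_no_southern_samples_flagged_unpolarized(self):
        calls = self._calls(["00", "11"])
        out, rec = svk.polarize(calls, self._profiles(["C", "M"]))
        assert not rec["polarized"]
        assert out["genotype"].tolist() == ["00", "11"]  # stable labels

    def test_relabeling_input_clusters_invariant(self):
        swap = {"00": "11", "11": "00"}
        calls = self._calls(["00", "00", "11", "01"])
        prof = self._profiles(["S", "S", "C", "M"])
        out1, _ = svk.polarize(calls, prof)
        flipped = calls.copy()
        flipped["genotype"] = flipped["genotype"].map(lambda g: swap.get(g, g))
        out2, _ = svk.polarize(flipped, prof)
        assert out1["genotype"].tolist() == out2["genotype"].tolist()

    def test_study_polarization_matches_truth(self, study, truth_profiles):
        _, gm, truth = study
        for chrom in ("chr03", "chr10"):
            res = svk.chrom_pca(gm, chrom)
            het = win.individual_het(gm, chrom)
            axis = svk.select_sv_axis(res, het)
            calls, rec = svk.polarize(
                svk.genotype_karyotypes(res, axis, het_by_sample=het), truth_profiles)
            assert rec["polarized"]
            tk = dict(zip(truth.karyotypes[chrom]["sample"],
                          truth.karyotypes[chrom]["karyotype"]))
            called = calls[calls["genotype"] == "00"]
            agree = (called["sample"].map(tk) == "00").mean()
            assert agree > 0.95


class TestLocalPCA:
    def test_distance_matrix_symmetric_zero_diag(self, study):
        _, gm, _ = study
        lf = svk.local_pca(gm, "chr05")
        assert np.allclose(lf.distances, lf.distances.T)
        assert np.allclose(np.diag(lf.distances), 0.0)

    def test_sv_windows_cluster_against_truth(self, study):
        from sklearn.metrics import silhouette_score

        _, gm, truth = study
        lf = svk.local_pca(gm, "chr03")
        reg = truth.sv_regions["chr03"]
        lab = ((lf.windows["start"] < reg["end"]) &
               (lf.windows["end"] > reg["start"])).to_numpy()
        assert silhouette_score(lf.mds, lab) > 0
        assert (lf.sv_windows == lab).mean() > 0.9

    def test_null_chromosome_has_no_sv_cluster(self, study):
        _, gm, _ = study
        lf = svk.local_pca(gm, "chr06")
        assert lf.sv_windows.sum() == 0


class TestBlocks:
    def _wintab(self, n):
        return pd.DataFrame({"chrom": "c", "start": np.arange(n) * 5000,
                             "end": (np.arange(n) + 1) * 5000})

    def test_no_flags_empty(self):
        assert svk.delimit_blocks(self._wintab(10), np.zeros(10, bool)) == []

    def test_single_run_with_gaps_merged(self):
        flags = np.zeros(20, bool)
        flags[[3, 4, 6, 8]] = True  # gaps of 1 window tolerated
        blocks = svk.delimit_blocks(self._wintab(20), flags, max_gap=2)
        assert blocks == [(15000, 45000)]

    def test_two_svs_split_when_gap_exceeded(self):
        flags = np.zeros(30, bool)
        flags[2:6] = True
        flags[15:20] = True
        blocks = svk.delimit_blocks(self._wintab(30), flags, max_gap=2)
        assert blocks == [(10000, 30000), (75000, 100000)]

    def test_breakpoint_recovery_within_one_window(self, study, study_pops):
        cfg, gm, truth = study
        lens = {c: cfg.chrom_length_bp for c in cfg.chrom_names()}
        tab = win.quantile_flags(win.window_stats(
            gm, study_pops["C"], study_pops["S"], chrom_lengths=lens))
        chrom = "chr08"
        wtab, flags = svk.subset_window_flags(tab, chrom)
        lf = svk.local_pca(gm, chrom)
        blocks = svk.delimit_blocks(wtab, flags, local_field=lf, max_gap=2)
        assert len(blocks) == 1
        reg = truth.sv_regions[chrom]
        s, e = blocks[0]
        assert abs(s - reg["start"]) <= 5000
        assert abs(e - reg["end"]) <= 5000


class TestFreqTables:
    def test_all_00_cluster(self):
        calls = pd.DataFrame({"sample": ["a", "b"], "genotype": ["00", "00"],
                              "confidence": 1.0, "axis_used": 0})
        prof = pd.DataFrame({"sample": ["a", "b"], "ternary_class": ["S", "S"]})
        tab = svk.freq_tables(calls, prof)
        row = tab.iloc[0]
        assert (row["f00"], row["f01"], row["f11"]) == (1.0, 0.0, 0.0)
        assert row["hap0_freq"] == 1.0

    def test_frequencies_sum_to_one_and_exclude_unassigned(self, study, truth_profiles):
        _, gm, truth = study
        k = truth.karyotypes["chr07"]
        calls = pd.DataFrame({"sample": k["sample"], "genotype": k["karyotype"],
                              "confidence": 1.0, "axis_used": 0})
        calls.loc[:4, "genotype"] = "unassigned"
        tab = svk.freq_tables(calls, truth_profiles)
        sums = tab[["f00", "f01", "f11"]].sum(axis=1)
        np.testing.assert_allclose(sums[tab["n_called"] > 0], 1.0)
        assert tab["n_unassigned"].sum() == 5

    def test_configured_southern_00_frequency_recovered(self):
        # binomial draw around a configured 0.77 southern 00-haplotype freq
        cfg = sk.SimConfig(
            n_per_group={"C": 10, "S": 60, "M": 10, "MCS": 10},
            n_chroms=1, sites_per_chrom=1500, chrom_length_bp=400_000, seed=5,
            sv_specs=[sk.SVSpec("chr01", 100_000, 300_000, hap_divergence=0.001,
                                karyotype_freqs={"C": 0.2, "S": 0.77, "M": 0.1})],
        )
        gm, truth = sk.simulate_study(cfg)
        prof = anc.classify_profiles(truth.q_matrix(), gm.samples)
        k = truth.karyotypes["chr01"]
        calls = pd.DataFrame({"sample": k["sample"], "genotype": k["karyotype"],
                              "confidence": 1.0, "axis_used": 0})
        tab = svk.freq_tables(calls, prof).set_index("cluster")
        n = tab.loc["S", "n_called"]
        se = np.sqrt(0.77 * 0.23 / (2 * n))
        assert tab.loc["S", "hap0_freq"] == pytest.approx(0.77, abs=3 * se + 0.5 / n)


class TestThirdHaplotype:
    def test_detected_only_on_three_haplotype_sv(self, study, truth_profiles):
        _, gm, truth = study
        results = {}
        for chrom in ("chr10", "chr08"):
            res = svk.chrom_pca(gm, chrom)
            het = win.individual_het(gm, chrom)
            axis = svk.select_sv_axis(res, het)
            calls, _ = svk.polarize(
                svk.genotype_karyotypes(res, axis, het_by_sample=het), truth_profiles)
            reg = truth.sv_regions[chrom]
            results[chrom] = (calls, svk.third_haplotype_scan(
                gm, calls, chrom, block=(reg["start"], reg["end"])))
        assert results["chr10"][1]["detected"]
        assert not results["chr08"][1]["detected"]

    def test_sub_karyotype_concordance(self, study, truth_profiles):
        _, gm, truth = study
        chrom = "chr10"
        res = svk.chrom_pca(gm, chrom)
        het = win.individual_het(gm, chrom)
        axis = svk.select_sv_axis(res, het)
        calls, _ = svk.polarize(
            svk.genotype_karyotypes(res, axis, het_by_sample=het), truth_profiles)
        reg = truth.sv_regions[chrom]
        rep = svk.third_haplotype_scan(gm, calls, chrom, block=(reg["start"], reg["end"]))
        sub = rep["calls"].set_index("sample")["sub_genotype"]
        full = dict(zip(truth.karyotypes[chrom]["sample"],
                        truth.karyotypes[chrom]["karyotype_full"]))
        truth_sub = pd.Series({s: full[s] for s in sub.index})
        # cluster labels may be mirrored; take the better of both polarities
        flip = {"11": "22", "22": "11", "12": "12"}
        direct = (sub == truth_sub).mean()
        mirrored = (sub.map(flip) == truth_sub).mean()
        assert max(direct, mirrored) >= 0.95

    def test_insufficient_data_report(self, study):
        _, gm, _ = study
        calls = pd.DataFrame({"sample": gm.samples[:3], "genotype": ["01", "00", "01"],
                              "confidence": 1.0, "axis_used": 0})
        rep = svk.third_haplotype_scan(gm, calls, "chr10")
        assert rep["status"] == "insufficient data"
        assert not rep["detected"]


class TestSvScanDriver:
    def test_end_to_end_scan(self, study, study_pops, truth_profiles):
        cfg, gm, truth = study
        lens = {c: cfg.chrom_length_bp for c in cfg.chrom_names()}
        tabs = {}
        for name, (a, b) in {"CS": ("C", "S"), "SM": ("S", "M")}.items():
            tabs[name] = win.quantile_flags(win.window_stats(
                gm, study_pops[a], study_pops[b], chrom_lengths=lens))
        out = svk.sv_scan(gm, truth_profiles, tabs, ["chr03", "chr01"])
        assert out["chr03"]["status"] == "ok"
        assert out["chr03"]["polarization"]["polarized"]
        assert out["chr03"]["block"] is not None
        assert out["chr01"]["status"] == "no axis"
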