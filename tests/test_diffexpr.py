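"""NB Wald test calibration, dispersion estimation, BH correctness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mirnet as mn
from mirnet.diffexpr import estimate_dispersions


def bh_brute_force(p):
    """Direct step-up definition: padj_i = min over j with p_j >= p_i of
    min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = min(running, 1.0)
    return adj


class TestDispersions:
    def test_hand_computed_value(self):
        """Groups [5,10,15] and [8,10,12]: pooled var 14.5, mean 10 ->
        alpha = (14.5 - 10)/100 = 0.045."""
        normalized = pd.DataFrame(
            [[5.0, 10.0, 15.0, 8.0, 10.0, 12.0]], index=["m"], columns=list("abcdef")
        )
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
        alpha = estimate_dispersions(normalized, groups)
        assert alpha["m"] == pytest.approx(0.045)

    def test_underdispersed_hits_floor(self):
        normalized = pd.DataFrame(
            [[10.0, 10.0, 10.0, 10.0]], index=["m"], columns=list("abcd")
        )
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        assert estimate_dispersions(normalized, groups)["m"] == pytest.approx(1e-8)

    def test_simulation_recovery(self):
        """Data at alpha=0.1, n=200/group: median estimate in [0.05, 0.2]."""
        cfg = mn.SimConfig(
            n_mirnas=400, group_sizes={"dnPD": 200, "CTR": 200}, dispersion=0.1, seed=2
        )
        counts, sheet, _ = mn.generate_cohort(cfg)
        norm = mn.size_factors(mn.filter_expressed(counts))
        alpha = estimate_dispersions(norm.normalized, sheet["group"])
        expressed = norm.normalized.mean(axis=1) > 5
        assert 0.05 <= alpha[expressed].median() <= 0.2

    def test_single_sample_group_rejected(self):
        normalized = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=list("abc"))
        groups = pd.Series(["g1", "g1", "g2"], index=list("abc"))
        with pytest.raises(ValueError):
            estimate_dispersions(normalized, groups)


class TestWaldTest:
    def test_null_rejection_rate_and_uniformity(self, null_cohort):
        counts, sheet, _ = null_cohort
        spec = mn.ContrastSpec("t", {"dnPD"}, {"CTR"})
        res = mn.run_contrasts(counts, sheet, [spec])["t"]
        p = res["pvalue"].dropna()
        assert len(p) > 800
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_effect_recovery(self):
        """Planted log2FC of +/-1 recovered with small bias at n=30/group."""
        cfg = mn.SimConfig(
            n_mirnas=1000,
            group_sizes={"dnPD": 30, "CTR": 30},
            dispersion=0.1,
            de_spec={"dnPD": (0.2, 1.0)},
            seed=5,
        )
        counts, sheet, truth = mn.generate_cohort(cfg)
        res = mn.run_contrasts(counts, sheet, [mn.ContrastSpec("t", {"dnPD"}, {"CTR"})])["t"]
        de = truth.de_log2fc["dnPD"]
        planted = de.index[(de != 0) & (res["baseMean"] > 5)]
        bias = (res.loc[planted, "log2fc"] - de[planted]).mean()
        assert abs(bias) < 0.1

    def test_label_swap_antisymmetry(self, null_cohort):
        counts, sheet, _ = null_cohort
        sub = mn.filter_expressed(counts).iloc[:100]
        fwd = mn.run_contrasts(sub, sheet, [mn.ContrastSpec("f", {"dnPD"}, {"CTR"})])["f"]
        rev = mn.run_contrasts(sub, sheet, [mn.ContrastSpec("r", {"CTR"}, {"dnPD"})])["r"]
        ok = fwd["converged"] & rev["converged"]
        assert ok.mean() > 0.9
        assert np.allclose(fwd.loc[ok, "log2fc"], -rev.loc[ok, "log2fc"], atol=1e-4)
        assert np.allclose(fwd.loc[ok, "pvalue"], rev.loc[ok, "pvalue"], atol=1e-6)

    def test_fdr_control_mixed_simulation(self):
        """Empirical FDR of DEM calling <= 1.5x nominal on a 10% non-null mix."""
        cfg = mn.SimConfig(
            n_mirnas=2000,
            group_sizes={"dnPD": 30, "CTR": 30},
            dispersion=0.1,
            de_spec={"dnPD": (0.1, 1.5)},
            seed=13,
        )
        counts, sheet, truth = mn.generate_cohort(cfg)
        res = mn.run_contrasts(counts, sheet, [mn.ContrastSpec("t", {"dnPD"}, {"CTR"})])["t"]
        dems = mn.call_dems(res)
        true_de = set(truth.de_log2fc.index[truth.de_log2fc["dnPD"] != 0])
        fdr = len(dems - true_de) / max(len(dems), 1)
        assert len(dems) > 50
        assert fdr <= 1.5 * 0.05


class TestAdjustBH:
    def test_hand_example(self):
        out = mn.adjust_bh([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(out, [0.04, 0.04, 0.05, 0.05])

    def test_single_and_degenerate(self):
        assert mn.adjust_bh([0.03])[0] == pytest.approx(0.03)
        assert (mn.adjust_bh([1.0, 1.0, 1.0]) == 1.0).all()

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_definition(self, pvals):
        ours = mn.adjust_bh(pvals).to_numpy()
        assert np.allclose(ours, bh_brute_force(pvals))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.random(200)
        assert np.allclose(
            mn.adjust_bh(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_missing_values_excluded_from_denominator(self):
        out = mn.adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], bh_brute_force([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mn.adjust_bh([1.5])


class TestCallDems:
    def test_strictly_below_threshold(self):
        res = pd.DataFrame({"padj": [0.05, 0.049, np.nan]}, index=["a", "b", "c"])
        assert mn.call_dems(res) == {"b"}

    def test_empty_result(self):
        assert mn.call_dems(pd.DataFrame({"padj": []})) == set()


class TestRunContrasts:
    def test_planted_phenotype_specificity(self):
        """A miRNA planted only in dnPD shows up in dnPD contrasts and not in
        CENT vs CTR, with good power at |log2FC| = 1.5, n = 30/group."""
        cfg = mn.SimConfig(
            n_mirnas=500,
            group_sizes={"dnPD": 30, "CTR": 30, "CENT": 30},
            dispersion=0.1,
            de_spec={"dnPD": (0.1, 1.5)},
            seed=23,
        )
        counts, sheet, truth = mn.generate_cohort(cfg)
        specs = [
            mn.ContrastSpec("dnPD_vs_CTR", {"dnPD"}, {"CTR"}),
            mn.ContrastSpec("CENT_vs_CTR", {"CENT"}, {"CTR"}),
        ]
        results = mn.run_contrasts(counts, sheet, specs)
        de = truth.de_log2fc["dnPD"]
        planted = set(de.index[de != 0])
        dn_dems = mn.call_dems(results["dnPD_vs_CTR"])
        cent_dems = mn.call_dems(results["CENT_vs_CTR"])
        power = len(dn_dems & planted) / len(planted)
        assert power >= 0.8
        assert len(cent_dems & planted) <= 0.1 * len(planted)

    def test_pooled_reference_is_union(self, small_cohort):
        counts, sheet, _ = small_cohort
        spec = mn.ContrastSpec("pool", {"dnPD"}, {"CTR"})
        mask = spec.select(sheet)
        assert set(sheet.loc[mask.index, "group"]) == {"dnPD", "CTR"}

    def test_duplicate_names_rejected(self, small_cohort):
        counts, sheet, _ = small_cohort
        spec = mn.ContrastSpec("x", {"dnPD"}, {"CTR"})
        with pytest.raises(ValueError):
            mn.run_contrasts(counts, sheet, [spec, spec])

    def test_site_restriction_empty_contrast(self, small_cohort):
        counts, sheet, _ = small_cohort
        spec = mn.ContrastSpec("x", {"dnPD"}, {"CTR"}, {"CTR": "MARS"})
        with pytest.raises(ValueError, match="empty"):
            mn.run_contrasts(counts, sheet, [spec])
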