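"""Differential expression: filter, TMM, dispersion, NB GLM-LRT, calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats, special

from nasctx.core import CountMatrix, ValidationError
from nasctx.diffexpr import (
    classify_de,
    estimate_dispersion,
    filter_expressed,
    nb_lrt,
    run_de,
    tmm_factors,
)

from conftest import make_count_matrix, simulate_nb_matrix


class TestFilterExpressed:
    def test_retained_when_all_samples_exceed_cutoff(self):
        cm = make_count_matrix(np.array([[11, 11, 11, 11]]), ["A"] * 4)
        assert filter_expressed(cm).features == ["g1"]

    def test_dropped_when_fraction_below_seventy_percent(self):
        counts = np.array([[11, 0, 0, 0, 0, 0, 0, 0]])
        cm = make_count_matrix(counts, ["A"] * 4 + ["B"] * 4)
        assert filter_expressed(cm).features == []

    def test_cutoff_is_strictly_greater_than(self):
        # exactly 10 counts does not pass ">10"
        cm = make_count_matrix(np.array([[10, 10, 10, 10]]), ["A"] * 4)
        assert filter_expressed(cm).features == []

    def test_one_qualifying_group_suffices(self):
        counts = np.array([[50, 60, 55, 45, 0, 0, 0, 0]])
        cm = make_count_matrix(counts, ["A"] * 4 + ["B"] * 4)
        assert filter_expressed(cm).features == ["g1"]

    def test_all_zero_matrix_empties(self):
        cm = make_count_matrix(np.zeros((5, 4), dtype=int), ["A", "A", "B", "B"])
        assert filter_expressed(cm).features == []


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 4))
        cm = make_count_matrix(counts, ["A", "A", "B", "B"])
        nf = tmm_factors(cm)
        np.testing.assert_allclose(nf.factors, 1.0, atol=1e-9)

    def test_pure_depth_shift_absorbed_into_effective_sizes(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(np.exp(rng.uniform(np.log(20), np.log(500), 800)))
        counts = np.column_stack([base, 2 * base, base, 2 * base])
        cm = make_count_matrix(counts, ["A", "A", "B", "B"])
        nf = tmm_factors(cm)
        eff = nf.effective_lib_sizes.to_numpy()
        ratio = eff[1] / eff[0]
        assert ratio == pytest.approx(2.0, rel=0.01)
        np.testing.assert_allclose(nf.factors, 1.0, atol=0.01)

    def test_factors_invariant_to_gene_order(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(50, size=(300, 3)) + 1
        cm = make_count_matrix(counts, ["A", "A", "B"])
        perm = rng.permutation(300)
        cm_perm = CountMatrix(cm.counts.iloc[perm], cm.groups)
        np.testing.assert_allclose(
            tmm_factors(cm).factors.to_numpy(), tmm_factors(cm_perm).factors.to_numpy()
        )

    def test_geometric_mean_is_one(self):
        cm = simulate_nb_matrix(500, 3, phi=0.1, seed=3)
        nf = tmm_factors(cm)
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger_reference_values(self):
        # frozen oracle: edgeR::calcNormFactors(method="TMM") on this exact
        # matrix returns (1.143932, 1.136779, 0.6820417, 1.12749)
        rng = np.random.default_rng(11)
        G = 500
        mu = np.exp(rng.uniform(np.log(5), np.log(800), G))
        depth = np.array([1.0, 2.0, 0.6, 1.4])
        counts = rng.poisson(mu[:, None] * depth[None, :])
        counts[:50, 2] = rng.poisson(mu[:50] * depth[2] * 8)
        cm = make_count_matrix(counts, ["A", "A", "B", "B"])
        nf = tmm_factors(cm)
        np.testing.assert_allclose(
            nf.factors.to_numpy(),
            [1.143932, 1.136779, 0.6820417, 1.12749],
            rtol=1e-5,
        )

    def test_all_zero_sample_rejected(self):
        counts = np.array([[5, 0], [3, 0]])
        cm = make_count_matrix(counts, ["A", "B"])
        with pytest.raises(ValidationError):
            tmm_factors(cm)


class TestDispersion:
    def test_poisson_counts_give_tiny_common_dispersion(self):
        cm = simulate_nb_matrix(2_000, 4, phi=0.0, seed=4)
        disp = estimate_dispersion(cm, tmm_factors(cm))
        assert disp.attrs["common_dispersion"] <= 0.01

    def test_recovers_planted_dispersion(self):
        cm = simulate_nb_matrix(2_000, 4, phi=0.1, seed=5)
        disp = estimate_dispersion(cm, tmm_factors(cm))
        assert 0.07 <= disp.attrs["common_dispersion"] <= 0.13

    def test_duplicating_samples_does_not_increase_estimate(self):
        cm = simulate_nb_matrix(500, 3, phi=0.1, seed=6)
        common = estimate_dispersion(cm, tmm_factors(cm)).attrs["common_dispersion"]
        doubled = pd.concat(
            [cm.counts, cm.counts.add_suffix("_dup")], axis=1
        )
        groups = dict(cm.groups)
        groups.update({f"{s}_dup": g for s, g in cm.groups.items()})
        cm2 = CountMatrix(doubled, groups)
        common2 = estimate_dispersion(cm2, tmm_factors(cm2)).attrs["common_dispersion"]
        assert common2 <= common * 1.05

    def test_single_sample_design_rejected(self):
        cm = make_count_matrix(np.array([[5], [9]]), ["A"])
        with pytest.raises(ValidationError):
            estimate_dispersion(cm, tmm_factors(cm))


class TestNbLrt:
    def test_identical_groups_are_null(self):
        counts = np.tile([[100], [200], [40]], (1, 6))
        cm = make_count_matrix(counts, ["A"] * 3 + ["B"] * 3)
        res = nb_lrt(cm, tmm_factors(cm), 0.05, ("B", "A"))
        np.testing.assert_allclose(res["log2_fc"], 0.0, atol=1e-6)
        assert (res["p_raw"] > 0.99).all()

    def test_recovers_planted_fourfold_change(self):
        # 200 features with a true log2FC of 2 at mean 200, embedded in a
        # null background so normalization has a stable reference
        lfc = np.zeros(2_000)
        lfc[:200] = 2.0
        cm = simulate_nb_matrix(2_000, 4, phi=0.05, seed=7, mean_range=(200, 200), lfc=lfc)
        res = nb_lrt(cm, tmm_factors(cm), 0.05, ("B", "A"))
        planted = res["log2_fc"].iloc[:200]
        assert abs(np.median(planted) - 2.0) < 0.3
        assert np.median(np.abs(planted - 2.0)) < 0.3

    def test_group_swap_negates_log2fc_and_preserves_p(self):
        cm = simulate_nb_matrix(100, 4, phi=0.1, seed=8)
        nf = tmm_factors(cm)
        ba = nb_lrt(cm, nf, 0.1, ("B", "A"))
        ab = nb_lrt(cm, nf, 0.1, ("A", "B"))
        np.testing.assert_allclose(ba["log2_fc"], -ab["log2_fc"], atol=1e-6)
        np.testing.assert_allclose(ba["p_raw"], ab["p_raw"], atol=1e-9)

    def test_chi2_p_agrees_with_parametric_bootstrap(self):
        # tiny case: one feature, 4 vs 4; the chi-square reference of the
        # LRT statistic should match a null parametric bootstrap
        rng = np.random.default_rng(9)
        phi = 0.08
        y = np.array([[220, 180, 260, 190, 140, 150, 130, 170]])
        cm = make_count_matrix(y, ["A"] * 4 + ["B"] * 4)
        nf = tmm_factors(cm)
        obs = nb_lrt(cm, nf, phi, ("B", "A"))
        stat_obs = obs["lr_stat"].iloc[0]
        # bootstrap under the fitted null (common mean)
        mu0 = y.mean()
        r = 1.0 / phi
        B = 3_000
        boot = rng.negative_binomial(r, r / (r + mu0), size=(B, 8))
        hits = 0
        for i in range(B):
            cmb = make_count_matrix(boot[i : i + 1], ["A"] * 4 + ["B"] * 4)
            res_b = nb_lrt(cmb, tmm_factors(cmb), phi, ("B", "A"))
            if res_b["lr_stat"].iloc[0] >= stat_obs - 1e-12:
                hits += 1
        p_boot = (hits + 1) / (B + 1)
        assert abs(obs["p_raw"].iloc[0] - p_boot) < 3 * np.sqrt(p_boot * (1 - p_boot) / B) + 0.01

    def test_scale_invariance_of_calls(self):
        cm = simulate_nb_matrix(300, 4, phi=0.05, seed=10,
                                lfc=np.where(np.arange(300) < 30, 2.0, 0.0))
        res1 = classify_de(nb_lrt(cm, tmm_factors(cm),
                                  estimate_dispersion(cm, tmm_factors(cm)), ("B", "A")))
        scaled = cm.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        cm2 = CountMatrix(scaled, cm.groups)
        res2 = classify_de(nb_lrt(cm2, tmm_factors(cm2),
                                  estimate_dispersion(cm2, tmm_factors(cm2)), ("B", "A")))
        agree = (res1["status"] == res2["status"]).mean()
        assert agree > 0.97
        eff1 = tmm_factors(cm).effective_lib_sizes.iloc[0]
        eff2 = tmm_factors(cm2).effective_lib_sizes.iloc[0]
        assert eff2 / eff1 == pytest.approx(3.0, rel=0.02)


class TestClassifyDe:
    def test_bh_adjustment_by_hand(self):
        res = pd.DataFrame(
            {"log2_fc": [1, 1, 1, 1], "p_raw": [0.01, 0.02, 0.03, 0.04]},
            index=list("abcd"),
        )
        out = classify_de(res)
        np.testing.assert_allclose(out["fdr"], [0.04, 0.04, 0.04, 0.04])

    def test_lfc_boundary_is_inclusive_at_0p7(self):
        res = pd.DataFrame(
            {"log2_fc": [0.69, 0.70, -0.70], "p_raw": [1e-6, 1e-6, 1e-6]},
            index=list("abc"),
        )
        out = classify_de(res)
        assert list(out["status"]) == ["not_DE", "up", "down"]

    def test_fdr_boundary_is_exclusive(self):
        res = pd.DataFrame({"log2_fc": [2.0], "p_raw": [0.01]}, index=["a"])
        out = classify_de(res, fdr_cut=0.01)
        assert out["status"].iloc[0] == "not_DE"

    def test_empty_input_gives_empty_output(self):
        res = pd.DataFrame(columns=["log2_fc", "p_raw"])
        out = classify_de(res)
        assert len(out) == 0 and "status" in out.columns


class TestRunDe:
    def test_pipeline_calls_only_planted_features(self):
        lfc = np.zeros(800)
        lfc[:40] = 3.0
        lfc[40:80] = -3.0
        cm = simulate_nb_matrix(800, 4, phi=0.05, seed=11,
                                mean_range=(100, 400), lfc=lfc)
        res = run_de(cm, ("B", "A"))
        called = set(res.index[res["status"] != "not_DE"])
        planted = {f"g{i + 1}" for i in range(80)}
        assert len(called & planted) / 80 >= 0.9
        assert len(called - planted) <= 4
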