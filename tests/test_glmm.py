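import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from allelescope.glmm import (
    MixedLogisticRegression,
    build_design,
    donor_concordance,
    fit_all_donors,
    fit_all_glmm,
    fit_glmm,
    fit_per_donor,
    multiple_testing_summary,
    normalize_expression,
    normalize_expression_matrix,
    odds_multiplier,
)
from allelescope.io import ExpressionMatrix
from allelescope.simulate import simulate_glmm_design

# Reference fits of the identical datasets (regenerated from the seeds
# below) computed with R lme4::glmer, family=binomial, nAGQ=9 — an
# independent implementation of the same marginal-likelihood problem.
LME4 = {
    # seed 3: generating sigma_u = 0, beta_expr = 0.01
    ("seed3", "base"): dict(
        beta0=-0.01348154457, se0=0.022765543167,
        beta_expr=0.01281272104, se_expr=0.002190549063,
        sigma_u=0.03565415, loglik=-16598.88,
    ),
    # seed 7: generating sigma_u = 0.5, beta_expr = 0.01
    ("seed7", "base"): dict(
        beta0=-0.057062018417, se0=0.09158092539,
        beta_expr=0.009221225566, se_expr=0.00225134455,
        sigma_u=0.3092778, loglik=-16372.43,
    ),
    # seed 5: beta_expr=0.01, beta_dia=0.3, beta_int=0.005, sigma_u=0.5
    ("seed5", "m2"): dict(
        beta_expr=0.012586213, se_expr=0.0018488232,
        beta_dia=0.397853273, se_dia=0.2659685145,
        sigma_u=0.4583107, loglik=-15811.25,
    ),
    ("seed5", "m3"): dict(
        beta_int=0.0073691722, se_int=0.0037216232,
        sigma_u=0.4581393, loglik=-15809.29,
    ),
}


def _design(tag):
    if tag == "seed3":
        return simulate_glmm_design(seed=3, beta_expr=0.01, sigma_u=0.0)
    if tag == "seed7":
        return simulate_glmm_design(seed=7, beta_expr=0.01, sigma_u=0.5)
    return simulate_glmm_design(
        seed=5, beta_expr=0.01, beta_dia=0.3, beta_int=0.005, sigma_u=0.5
    )


class TestNormalizeExpression:
    def test_min_max_scaling(self):
        np.testing.assert_allclose(normalize_expression([0, 5, 10]), [0, 50, 100])

    def test_constant_vector_dropped(self):
        with pytest.raises(ValueError, match="zero range"):
            normalize_expression([2, 2, 2])

    def test_negative_rejected_and_max_maps_to_100(self):
        with pytest.raises(ValueError, match="negative"):
            normalize_expression([-1, 2])
        rng = np.random.default_rng(0)
        v = rng.random(50) * 7
        assert normalize_expression(v).max() == pytest.approx(100.0)

    def test_matrix_normalization_drops_constant_genes(self):
        m = np.array([[0.0, 2.0], [5.0, 2.0], [10.0, 2.0]])
        em = ExpressionMatrix(m, ["a", "b", "c"], ["g1", "g2"])
        norm, dropped = normalize_expression_matrix(em)
        assert dropped == ["g2"]
        np.testing.assert_allclose(
            np.asarray(norm.matrix.todense()).ravel(), [0, 50, 100]
        )


class TestBuildDesign:
    meta = pd.DataFrame(
        {
            "barcode": ["b1", "b2"],
            "sample_id": ["s1", "s2"],
            "cell_type": ["PT", "PT"],
            "condition": ["control", "disease"],
        }
    )
    expr = ExpressionMatrix(
        np.array([[10.0, 0.0], [90.0, 100.0]]), ["b1", "b2"], ["g1", "g2"]
    )

    def _calls(self, n_ref, n_alt, barcode="b1"):
        rows = [("chr1", 100 + i, 200 + i, barcode, "ref", "pk1") for i in range(n_ref)]
        rows += [("chr1", 300 + i, 400 + i, barcode, "alt", "pk1") for i in range(n_alt)]
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "barcode", "call", "peak_id"]
        )

    def test_rows_and_outcome_sum(self):
        links = pd.DataFrame({"peak_id": ["pk1"], "gene_id": ["g1"]})
        d = build_design(self._calls(6, 7), links, self.expr, self.meta)
        assert len(d) == 13
        assert d["y"].sum() == 7
        assert set(d["x_expr"]) == {10.0}

    def test_two_linked_genes_share_y_differ_x(self):
        links = pd.DataFrame({"peak_id": ["pk1", "pk1"], "gene_id": ["g1", "g2"]})
        calls = pd.concat([self._calls(2, 3, "b1"), self._calls(1, 1, "b2")])
        d = build_design(calls, links, self.expr, self.meta)
        by_gene = {g: sub for g, sub in d.groupby("gene_id")}
        assert len(by_gene["g1"]) == len(by_gene["g2"]) == 7
        assert by_gene["g1"]["y"].sum() == by_gene["g2"]["y"].sum()
        assert set(by_gene["g2"]["x_expr"]) == {0.0, 100.0}
        assert set(d.loc[d["dia"] == 1, "barcode"]) == {"b2"}

    def test_empty_links_give_empty_design(self):
        links = pd.DataFrame({"peak_id": [], "gene_id": []})
        d = build_design(self._calls(3, 3), links, self.expr, self.meta)
        assert len(d) == 0


@pytest.mark.parametrize(
    "tag,model", [("seed3", "base"), ("seed7", "base"), ("seed5", "m2"), ("seed5", "m3")]
)
def test_glmm_matches_lme4_oracle(tag, model):
    """Estimates, SEs, sigma_u and log-likelihood agree with lme4 glmer
    (nAGQ=9) on identical data."""
    fit = fit_glmm(_design(tag), model)
    ref = LME4[(tag, model)]
    assert fit.converged
    assert fit.loglik == pytest.approx(ref["loglik"], abs=0.02)
    assert fit.sigma_u == pytest.approx(ref["sigma_u"], abs=2e-3)
    for term, key in [
        ("beta0", "beta0"), ("beta_expr", "beta_expr"),
        ("beta_dia", "beta_dia"), ("beta_int", "beta_int"),
    ]:
        if key in ref:
            assert fit.estimate[term] == pytest.approx(ref[key], abs=5e-4)
    for term, key in [
        ("beta0", "se0"), ("beta_expr", "se_expr"),
        ("beta_dia", "se_dia"), ("beta_int", "se_int"),
    ]:
        if key in ref:
            assert fit.se[term] == pytest.approx(ref[key], rel=2e-3)


def test_laplace_close_to_agq():
    d = _design("seed7")
    f9 = fit_glmm(d, "base", n_quad=9)
    f1 = fit_glmm(d, "base", n_quad=1)
    assert f1.estimate["beta_expr"] == pytest.approx(
        f9.estimate["beta_expr"], rel=5e-3
    )
    assert f1.sigma_u == pytest.approx(f9.sigma_u, rel=0.05)


def test_sigma_zero_boundary_matches_plain_logistic():
    d = _design("seed3")
    fit = fit_glmm(d, "base")
    X = sm.add_constant(d["x_expr"].to_numpy())
    ref = sm.Logit(d["y"].to_numpy(), X).fit(disp=False)
    assert abs(fit.estimate["beta0"] - ref.params[0]) < 1e-4
    assert abs(fit.estimate["beta_expr"] - ref.params[1]) < 1e-4
    assert fit.sigma_u < 0.1


def test_pinned_sigma_zero_is_exactly_plain_logistic():
    d = _design("seed3")
    est = MixedLogisticRegression(fix_sigma=0.0).fit(
        d[["x_expr"]].to_numpy(), d["y"].to_numpy(), d["sample_id"].to_numpy()
    )
    X = sm.add_constant(d["x_expr"].to_numpy())
    ref = sm.Logit(d["y"].to_numpy(), X).fit(disp=False)
    assert abs(est.intercept_ - ref.params[0]) < 1e-8
    assert abs(est.coef_[0] - ref.params[1]) < 1e-8
    np.testing.assert_allclose(est.bse_, ref.bse, rtol=1e-6)


def test_per_donor_equals_pinned_mixed_fit():
    d = _design("seed3")
    one = d[d["sample_id"] == "S01"]
    donor = fit_per_donor(one)
    est = MixedLogisticRegression(fix_sigma=0.0).fit(
        one[["x_expr"]].to_numpy(), one["y"].to_numpy(), np.zeros(len(one))
    )
    assert abs(donor.beta_expr - est.coef_[0]) < 1e-6
    assert abs(donor.se - est.bse_[1]) < 1e-6


def test_nesting_of_maximized_likelihoods():
    d = _design("seed5")
    ll = {m: fit_glmm(d, m).loglik for m in ("base", "m2", "m3")}
    assert ll["base"] <= ll["m2"] + 1e-6 <= ll["m3"] + 2e-6


def test_label_flip_negates_coefficients():
    d = simulate_glmm_design(
        seed=21, n_samples=6, n_fragments_per_sample=500,
        beta_expr=0.02, sigma_u=0.4,
    )
    f = fit_glmm(d, "base")
    flipped = d.copy()
    flipped["y"] = 1 - flipped["y"]
    g = fit_glmm(flipped, "base")
    assert g.estimate["beta0"] == pytest.approx(-f.estimate["beta0"], abs=1e-4)
    assert g.estimate["beta_expr"] == pytest.approx(
        -f.estimate["beta_expr"], abs=1e-6
    )


def test_degenerate_outcome_rejected():
    d = _design("seed3").copy()
    d["y"] = 1
    with pytest.raises(ValueError, match="degenerate"):
        fit_glmm(d, "base")


def test_interaction_recovery_power():
    """m3 detects a planted disease x expression interaction."""
    hits = 0
    n_rep = 20
    for i in range(n_rep):
        d = simulate_glmm_design(
            seed=5000 + i, beta_expr=0.005, beta_dia=0.2, beta_int=0.015,
            sigma_u=0.3,
        )
        f = fit_glmm(d, "m3")
        hits += f.wald_p["beta_int"] < 0.05
    assert hits / n_rep > 0.8


def test_wald_type_one_error_calibrated():
    """With beta_expr = 0, the Wald test rejects ~5% of the time."""
    n_rep = 400
    rej = 0
    for i in range(n_rep):
        d = simulate_glmm_design(
            seed=9000 + i, n_samples=8, n_fragments_per_sample=150,
            beta_expr=0.0, sigma_u=0.5,
        )
        if d["y"].nunique() < 2:
            continue
        f = fit_glmm(d, "base", n_quad=5)
        rej += f.wald_p["beta_expr"] < 0.05
    frac = rej / n_rep
    assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestSummaries:
    def _donor_frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample_id", "peak_id", "gene_id", "beta0", "beta_expr",
                     "se", "wald_p", "separation", "n_obs"],
        )

    def test_concordant_and_discordant_pairs(self):
        fits = self._donor_frame(
            [
                ("s1", "pk1", "g1", 0, 0.5, 0.1, 0.01, False, 100),
                ("s2", "pk1", "g1", 0, 0.4, 0.1, 0.02, False, 100),
                ("s1", "pk2", "g1", 0, 0.5, 0.1, 0.01, False, 100),
                ("s2", "pk2", "g1", 0, -0.4, 0.1, 0.02, False, 100),
                ("s1", "pk3", "g1", 0, 0.5, 0.1, 0.50, False, 100),
            ]
        )
        s = donor_concordance(fits)
        assert s["n_nominal_any"] == 2
        assert s["n_nominal_multi"] == 2
        assert s["n_sign_concordant"] == 1
        assert s["frac_sign_concordant"] == pytest.approx(0.5)

    def test_shared_effect_cohort_concordance_beats_null(self):
        designs = [
            simulate_glmm_design(
                seed=300 + i, n_samples=6, n_fragments_per_sample=800,
                beta_expr=0.02, sigma_u=0.3, peak_id=f"pk{i}", gene_id="g",
            )
            for i in range(12)
        ]
        donor = fit_all_donors(pd.concat(designs))
        s = donor_concordance(donor)
        assert s["n_nominal_multi"] >= 5
        # binomial test against chance sign agreement
        from scipy.stats import binomtest

        p = binomtest(
            s["n_sign_concordant"], s["n_nominal_multi"], 0.5, "greater"
        ).pvalue
        assert p < 0.05

    def test_multiple_testing_summary_arithmetic(self):
        fits = pd.DataFrame(
            {
                "wald_p_beta_expr": [0.001, 0.2, 0.03, 0.9],
                "converged": [True] * 4,
            }
        )
        s = multiple_testing_summary(fits)
        assert s["n_total"] == 4 and s["n_nominal"] == 2
        assert s["frac_nominal"] == pytest.approx(0.5)
        assert multiple_testing_summary(pd.DataFrame())["n_total"] == 0


def test_odds_multiplier_interpretation():
    # 0.01 log-odds per 1% expression -> e^0.1 for a 10% increase
    assert odds_multiplier(0.01, 10) == pytest.approx(np.exp(0.1))


def test_fit_all_glmm_over_cohort_designs():
    designs = pd.concat(
        [
            simulate_glmm_design(
                seed=40 + i, n_samples=4, n_fragments_per_sample=200,
                beta_expr=0.02, sigma_u=0.2, peak_id=f"pk{i}", gene_id="g",
            )
            for i in range(3)
        ]
    )
    tab = fit_all_glmm(designs, "base", n_quad=5)
    assert len(tab) == 3
    assert set(tab["peak_id"]) == {"pk0", "pk1", "pk2"}
    assert tab["converged"].all()
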