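"""Mixed-model moderation, simple slopes, Johnson-Neyman, MANOVA, post hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bartsim import (
    CohortSpec,
    fit_mixed_model,
    generate_cohort,
    johnson_neyman,
    posthoc_contrasts,
    rm_manova,
    simple_slopes,
)
from bartsim.stats import FIXED_TERMS


def jn_grid_oracle(fit, stratum_value, step=1e-4, alpha=0.05):
    """Brute-force scan of the conditional slope t statistic over the range."""
    lo, hi = fit.bis_range
    w = np.arange(lo, hi, step)
    b = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    idx = {t: i for i, t in enumerate(fit.terms)}
    g0 = np.zeros(len(b))
    g0[idx["scr"]] = 1.0
    g0[idx["risk:scr"]] = stratum_value
    g1 = np.zeros(len(b))
    g1[idx["scr:bis"]] = 1.0
    g1[idx["risk:scr:bis"]] = stratum_value
    slope = (g0 @ b) + (g1 @ b) * w
    var = (g0 @ cov @ g0) + 2 * w * (g0 @ cov @ g1) + w**2 * (g1 @ cov @ g1)
    t_crit = sps.t.ppf(1 - alpha / 2, fit.df_resid)
    sig = np.abs(slope / np.sqrt(var)) >= t_crit
    flips = w[1:][np.diff(sig.astype(int)) != 0]
    return flips, step


class TestMixedModel:
    def test_recovers_generating_random_intercept_sd(self):
        spec = CohortSpec(n_participants=200)
        table, _ = generate_cohort(spec, seed=7)
        fit = fit_mixed_model(table)
        assert fit.re_sd == pytest.approx(440.6, rel=0.15)

    def test_noiseless_data_recovered_exactly(self):
        coefs = {"Intercept": 1500.0, "risk": -400.0, "scr": 60.0, "risk:scr:bis": -1.5}
        spec = CohortSpec(
            n_participants=46, random_intercept_sd=0.0, residual_sd=0.0, coefficients=coefs
        )
        table, truth = generate_cohort(spec, seed=1)
        assert truth["n_clipped"] == 0
        fit = fit_mixed_model(table)
        for term in FIXED_TERMS:
            assert fit.params[term] == pytest.approx(
                truth["coefficients"][term], abs=1e-5
            )

    def test_null_effects_rarely_significant(self):
        # type-I behavior: with all fixed effects 0, |t| < 2 for each
        # coefficient in at least 90% of replicates
        spec = CohortSpec(coefficients={"Intercept": 1500.0})
        rng = np.random.default_rng(0)
        n_rep = 200
        small_t = np.zeros(len(FIXED_TERMS))
        for _ in range(n_rep):
            table, _ = generate_cohort(spec, seed=int(rng.integers(2**31)))
            fit = fit_mixed_model(table)
            tv = fit.tvalues.drop("Intercept").abs()
            small_t[1:] += (tv < 2).to_numpy()
            small_t[0] += 1  # intercept truth is nonzero, not a null term
        assert np.all(small_t / n_rep >= 0.90)

    def test_ci_identity(self, moderated_fit):
        fit, _ = moderated_fit
        tcrit = sps.t.ppf(0.975, fit.df_resid)
        np.testing.assert_allclose(
            fit.conf_int["upper"] - fit.params, tcrit * fit.bse, rtol=1e-10
        )

    def test_covariance_is_symmetric_psd(self, moderated_fit):
        fit, _ = moderated_fit
        cov = fit.cov.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)

    def test_too_few_participants_rejected(self):
        table, _ = generate_cohort(CohortSpec(n_participants=4), seed=0)
        with pytest.raises(ValueError):
            fit_mixed_model(table)

    def test_missing_column_rejected(self):
        table, _ = generate_cohort(CohortSpec(), seed=0)
        with pytest.raises(ValueError):
            fit_mixed_model(table.drop(columns="bis_total"))


class TestSimpleSlopes:
    def test_slope_at_mean_is_linear_combination(self, moderated_fit):
        fit, _ = moderated_fit
        slopes = simple_slopes(fit)
        w = fit.bis_mean
        low_mean = slopes[(slopes.stratum_value == 0.0) & (slopes.label == "Mean")]
        expected = fit.params["scr"] + fit.params["scr:bis"] * w
        assert low_mean.slope.iloc[0] == pytest.approx(expected)
        high_mean = slopes[(slopes.stratum_value == 1.0) & (slopes.label == "Mean")]
        expected_high = expected + fit.params["risk:scr"] + fit.params["risk:scr:bis"] * w
        assert high_mean.slope.iloc[0] == pytest.approx(expected_high)

    def test_zero_interaction_gives_constant_slopes(self, null_fit):
        fit, _ = null_fit
        # force the interaction structure to zero and recompute by hand
        fit2 = fit
        slopes = simple_slopes(fit2, moderator_values=[40.0, 60.0, 80.0])
        # slopes vary only through the (estimated, near-zero) interaction terms;
        # the algebraic difference must equal b_interaction * delta_w exactly
        low = slopes[slopes.stratum_value == 0.0].reset_index(drop=True)
        d1 = low.slope[1] - low.slope[0]
        assert d1 == pytest.approx(fit.params["scr:bis"] * 20.0)

    def test_qualitative_moderation_pattern(self, moderated_fit):
        # generated with a negative SCR slope concentrated at high risk and
        # high impulsivity: significant negative slope at high risk / +1 SD,
        # no significant slope anywhere under low risk
        fit, _ = moderated_fit
        slopes = simple_slopes(fit)
        high_plus = slopes[(slopes.stratum_value == 1.0) & (slopes.label == "+1 SD")]
        assert high_plus.slope.iloc[0] < 0
        assert high_plus.p.iloc[0] < 0.05
        low = slopes[slopes.stratum_value == 0.0]
        assert np.all(low.p > 0.05)

    def test_missing_terms_raise(self, moderated_fit):
        fit, _ = moderated_fit
        with pytest.raises(KeyError):
            simple_slopes(fit, focal="scr", moderator="age")


class TestJohnsonNeyman:
    @pytest.mark.parametrize("stratum_value", [0.0, 1.0])
    def test_boundaries_match_grid_oracle(self, moderated_fit, stratum_value):
        fit, _ = moderated_fit
        jn = johnson_neyman(fit, stratum_value=stratum_value)
        flips, step = jn_grid_oracle(fit, stratum_value)
        assert len(jn.boundaries) == len(flips)
        for b, f in zip(sorted(jn.boundaries), sorted(flips)):
            assert abs(b - f) <= step

    def test_boundaries_match_grid_oracle_on_null_fit(self, null_fit):
        fit, _ = null_fit
        jn = johnson_neyman(fit, stratum_value=1.0)
        flips, step = jn_grid_oracle(fit, 1.0)
        assert len(jn.boundaries) == len(flips)
        for b, f in zip(sorted(jn.boundaries), sorted(flips)):
            assert abs(b - f) <= step

    def test_t_equals_critical_value_at_boundary(self, moderated_fit):
        fit, _ = moderated_fit
        jn = johnson_neyman(fit, stratum_value=1.0)
        assert jn.boundaries, "fixture model should produce a boundary in range"
        for w in jn.boundaries:
            s = simple_slopes(
                fit, moderator_values=[w], stratum_values=[1.0]
            )
            assert abs(abs(s.t.iloc[0]) - jn.t_crit) < 1e-6

    def test_null_model_has_no_boundary_in_range(self, null_fit):
        fit, _ = null_fit
        jn = johnson_neyman(fit, stratum_value=1.0)
        # no true interaction: the slope stays flat and non-significant
        assert jn.significant_regions == []


def make_behavioral_table(
    n=20, risk_rt=-500.0, seed=0, dvs=("mean_rt_ms", "success_prop", "earnings_cents")
):
    """Small synthetic participant x condition table for the MANOVA layer."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        base_rt = rng.normal(2000, 150)
        for risk in ("low", "high"):
            for reward in ("low", "high"):
                rt = base_rt + (risk_rt if risk == "high" else 0.0) + rng.normal(0, 100)
                rows.append(
                    {
                        "participant_id": f"p{i:03d}",
                        "risk_level": risk,
                        "reward_level": reward,
                        "mean_rt_ms": rt,
                        "success_prop": np.clip(rng.normal(0.7, 0.05), 0, 1),
                        "earnings_cents": rng.normal(3000, 300),
                    }
                )
    return pd.DataFrame(rows)


class TestManova:
    def test_identical_conditions_give_zero_trace(self):
        table = make_behavioral_table(n=15, risk_rt=0.0, seed=1)
        for dv in ("mean_rt_ms", "success_prop", "earnings_cents"):
            wide = table.pivot_table(
                index="participant_id", columns=["risk_level", "reward_level"], values=dv
            )
            flat = wide.iloc[:, [0]].to_numpy()
            table.loc[:, dv] = np.repeat(flat, 4)  # all four cells identical
        res = rm_manova(table)
        assert np.all(res.effects.pillai < 1e-10)
        assert np.all(res.effects.F < 1e-8)

    def test_single_dv_reduces_to_paired_t(self):
        table = make_behavioral_table(seed=2)
        res = rm_manova(table, dvs=["mean_rt_ms"])
        wide = table.pivot_table(
            index="participant_id", columns=["risk_level", "reward_level"], values="mean_rt_ms"
        )
        diff = 0.5 * (wide[("high", "low")] + wide[("high", "high")]) - 0.5 * (
            wide[("low", "low")] + wide[("low", "high")]
        )
        t, _ = sps.ttest_1samp(diff, 0.0)
        assert res.effects.loc["risk", "F"] == pytest.approx(t**2)
        assert res.effects.loc["risk", "df1"] == 1
        assert res.effects.loc["risk", "df2"] == len(wide) - 1

    def test_pillai_matches_eigenvalue_formula(self):
        # direct trace vs eigenvalues of H(H+E)^-1 on the same contrast scores
        table = make_behavioral_table(seed=3)
        res = rm_manova(table)
        wide, _ = __import__("bartsim.stats", fromlist=["_pivot_complete"])._pivot_complete(
            table, list(res.dvs)
        )
        from bartsim.stats import _contrast_scores

        Y = np.column_stack([_contrast_scores(wide, dv, "risk") for dv in res.dvs])
        n = len(Y)
        ybar = Y.mean(axis=0)
        H = n * np.outer(ybar, ybar)
        E = (Y - ybar).T @ (Y - ybar)
        eig = np.linalg.eigvals(H @ np.linalg.inv(H + E))
        assert res.effects.loc["risk", "pillai"] == pytest.approx(
            float(np.sum(eig.real)), abs=1e-10
        )

    def test_pillai_invariant_under_dv_rescaling(self):
        table = make_behavioral_table(seed=4)
        res1 = rm_manova(table)
        scaled = table.copy()
        scaled["mean_rt_ms"] = scaled["mean_rt_ms"] * 0.001 + 7.0
        scaled["earnings_cents"] = scaled["earnings_cents"] * 50.0 - 3.0
        res2 = rm_manova(scaled)
        np.testing.assert_allclose(
            res1.effects.pillai, res2.effects.pillai, rtol=1e-8
        )

    def test_incomplete_participants_dropped(self):
        table = make_behavioral_table(n=12, seed=5)
        table = table.drop(table[table.participant_id == "p000"].index[:1])
        res = rm_manova(table)
        assert res.n_complete == 11
        assert res.n_dropped == 1


class TestPosthoc:
    def test_bonferroni_multiplies_by_family_size(self):
        table = make_behavioral_table(seed=6)
        ph = posthoc_contrasts(table, "risk")
        for row in ph.itertuples():
            assert row.p_bonferroni == pytest.approx(min(row.p_raw * 3, 1.0))

    def test_cohens_d_definition(self):
        table = make_behavioral_table(seed=7)
        ph = posthoc_contrasts(table, "risk")
        for row in ph.itertuples():
            assert row.cohens_d == pytest.approx(row.mean_difference / row.sd_difference)

    def test_degenerate_zero_variance_flagged(self):
        table = make_behavioral_table(n=10, risk_rt=0.0, seed=8)
        table["success_prop"] = 0.5
        ph = posthoc_contrasts(table, "risk")
        row = ph[ph.dv == "success_prop"].iloc[0]
        assert row.degenerate
        assert np.isnan(row.cohens_d)

    def test_familywise_error_controlled_under_null(self):
        # no condition effect: the Bonferroni family rejects at most ~alpha
        rng = np.random.default_rng(9)
        n_rep = 500
        any_reject = 0
        for _ in range(n_rep):
            table = make_behavioral_table(
                n=12, risk_rt=0.0, seed=int(rng.integers(2**31))
            )
            ph = posthoc_contrasts(table, "risk")
            any_reject += int((ph.p_bonferroni < 0.05).any())
        mc_se = np.sqrt(0.05 * 0.95 / n_rep)
        assert any_reject / n_rep <= 0.05 + 2 * mc_se

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValueError):
            posthoc_contrasts(make_behavioral_table(seed=10), "risk:reward")
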