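"""Matched case-control analysis: conditional-logistic machinery,
splines, interactions, sub-site heterogeneity, sensitivity filters."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.discrete.conditional_models import ConditionalLogit

from bilimr.serology import (
    SeparationError,
    SplineSpec,
    clogit_fit,
    genotype_exposure_check,
    interaction_test,
    liver_exclusion,
    liver_indices,
    restricted_cubic_spline,
    spline_nonlinearity,
    standardize_log_exposure,
    subsite_heterogeneity,
)
from bilimr.simulate import CohortConfig, gen_matched_cohort

from conftest import pairs_from_diffs


class TestStandardize:
    def test_hand_computed_z_scores(self):
        df = pairs_from_diffs([0.0])  # two members
        df = pd.concat([df, df.iloc[[0]].assign(pair_id=1)], ignore_index=True)
        df = df.iloc[:3].copy()
        df["exposure"] = [np.e, np.e**2, np.e**3]
        out = standardize_log_exposure(df, sd_scope="pooled")
        np.testing.assert_allclose(out["z_log_exposure"], [-1.0, 0.0, 1.0],
                                   atol=1e-12)

    def test_scale_invariance(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=20, seed=1))
        a = standardize_log_exposure(cohort)
        doubled = cohort.assign(exposure=2 * cohort["exposure"])
        b = standardize_log_exposure(doubled)
        np.testing.assert_allclose(a["z_log_exposure"], b["z_log_exposure"],
                                   atol=1e-12)

    def test_constant_exposure_errors(self):
        df = pairs_from_diffs([1.0, 2.0])
        df["exposure"] = 5.0
        with pytest.raises(ValueError, match="zero SD"):
            standardize_log_exposure(df)

    def test_nonpositive_exposure_names_pair(self):
        df = pairs_from_diffs([1.0, 2.0])
        df.loc[2, "exposure"] = -1.0
        with pytest.raises(ValueError, match="pair 1"):
            standardize_log_exposure(df)

    def test_sex_specific_moments(self):
        men = gen_matched_cohort(CohortConfig.for_sex("men", n_pairs=100, seed=2))
        women = gen_matched_cohort(CohortConfig.for_sex("women", n_pairs=100, seed=3))
        women["pair_id"] += 1000
        out = standardize_log_exposure(pd.concat([men, women], ignore_index=True))
        for sex in ("men", "women"):
            z = out.loc[out["sex"] == sex, "z_log_exposure"]
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestClogit:
    def test_three_pair_closed_form(self):
        # score equation 2 - 3*sigmoid(beta) = 0  =>  beta = ln 2
        res = clogit_fit(pairs_from_diffs([1.0, 1.0, -1.0]), exposure_col="z")
        assert res.beta == pytest.approx(np.log(2), abs=1e-8)
        assert res.or_per_sd == pytest.approx(2.0, abs=1e-6)
        assert res.n_pairs_used == 3

    def test_balanced_differences_give_null(self):
        res = clogit_fit(pairs_from_diffs([0.7, -0.7, 0.7, -0.7]), exposure_col="z")
        assert res.beta == pytest.approx(0.0, abs=1e-10)

    def test_matches_independent_conditional_likelihood_oracle(self):
        # direct maximization of prod exp(b x_case)/(exp(b x_case)+exp(b x_ctrl))
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(7)
        diffs = rng.normal(0.3, 1.0, 9)
        res = clogit_fit(pairs_from_diffs(diffs), exposure_col="z")

        def nll(b):
            return float(np.sum(np.logaddexp(0.0, -b * diffs)))

        oracle = minimize_scalar(nll, bounds=(-10, 10), method="bounded",
                                 options={"xatol": 1e-10})
        assert res.beta == pytest.approx(oracle.x, abs=1e-4)

    def test_matches_statsmodels_conditional_logit(self):
        cohort = gen_matched_cohort(CohortConfig(
            n_pairs=150, causal_logor_per_sd=0.3,
            covariate_effects={"bmi": 0.05}, seed=9))
        std = standardize_log_exposure(cohort)
        res = clogit_fit(std, covariates=["bmi", "height"])
        df = std.sort_values(["pair_id", "is_case"])
        X = df[["z_log_exposure", "bmi", "height"]].to_numpy(float)
        sm_fit = ConditionalLogit(
            df["is_case"].astype(int).to_numpy(), X,
            groups=df["pair_id"].to_numpy()).fit(disp=0)
        np.testing.assert_allclose(
            [res.params["z_log_exposure"], res.params["bmi"], res.params["height"]],
            sm_fit.params, atol=5e-5)
        np.testing.assert_allclose(
            [res.bse["z_log_exposure"], res.bse["bmi"], res.bse["height"]],
            sm_fit.bse, atol=1e-4)

    def test_pair_constant_covariate_is_absorbed(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=80, seed=4))
        std = standardize_log_exposure(cohort)
        base = clogit_fit(std, covariates=["bmi"])
        shifted = std.copy()
        # add a pair-level constant to bmi: matching absorbs it
        shifts = {pid: s for pid, s in zip(
            shifted["pair_id"].unique(),
            np.random.default_rng(0).normal(0, 5, shifted["pair_id"].nunique()))}
        shifted["bmi"] = shifted["bmi"] + shifted["pair_id"].map(shifts)
        after = clogit_fit(shifted, covariates=["bmi"])
        assert after.beta == pytest.approx(base.beta, abs=1e-9)
        assert after.params["bmi"] == pytest.approx(base.params["bmi"], abs=1e-9)

    def test_wald_ci_is_exp_beta_pm_196_se(self):
        res = clogit_fit(pairs_from_diffs([1.0, 1.0, -1.0, 0.5]), exposure_col="z")
        assert res.ci_low == pytest.approx(
            np.exp(res.beta - 1.959964 * res.se), abs=1e-12)
        assert res.ci_high == pytest.approx(
            np.exp(res.beta + 1.959964 * res.se), abs=1e-12)

    def test_complete_separation_raises_with_covariate_name(self):
        with pytest.raises(SeparationError, match="z"):
            clogit_fit(pairs_from_diffs([1.0, 2.0, 0.5, 1.5]), exposure_col="z")

    def test_zero_informative_pairs_errors(self):
        with pytest.raises(ValueError, match="informative"):
            clogit_fit(pairs_from_diffs([0.0, 0.0]), exposure_col="z")

    def test_missing_categorical_becomes_own_level(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=300, missing_rate=0.1, seed=6))
        std = standardize_log_exposure(cohort)
        res = clogit_fit(std, covariates=["smoking"])
        assert any(name == "smoking[missing]" for name in res.params)


class TestSpline:
    def test_basis_zero_at_and_below_first_knot(self):
        knots = (1.0, 3.0, 6.0)
        x = np.array([-2.0, 0.5, 1.0])
        np.testing.assert_array_equal(restricted_cubic_spline(x, knots), 0.0)

    def test_basis_linear_beyond_last_knot(self):
        knots = (1.0, 3.0, 6.0)
        x = np.linspace(7, 20, 40)
        second_diff = np.diff(restricted_cubic_spline(x, knots), 2)
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)

    def test_knots_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            SplineSpec((3.0, 1.0, 6.0))

    def test_planted_quadratic_effect_is_detected(self):
        cohort = gen_matched_cohort(CohortConfig(
            n_pairs=658, causal_logor_per_sd=0.0,
            causal_logor_quadratic=0.4, seed=12))
        std = standardize_log_exposure(cohort)
        _, p, _ = spline_nonlinearity(std, scale="log")
        assert p < 0.01

    def test_curve_is_zero_at_reference(self):
        cohort = gen_matched_cohort(CohortConfig(
            n_pairs=200, causal_logor_per_sd=0.2, seed=13))
        std = standardize_log_exposure(cohort)
        curve, _, _ = spline_nonlinearity(std)
        ref = np.percentile(std["exposure"], 10)
        at_ref = np.interp(ref, curve["exposure"], curve["log_or"])
        assert at_ref == pytest.approx(0.0, abs=1e-6)


class TestInteraction:
    def test_opposite_sign_stratum_effects_are_detected(self):
        rejections = 0
        reps = 25
        for r in range(reps):
            a = gen_matched_cohort(CohortConfig(
                n_pairs=329, causal_logor_per_sd=np.log(1.19), seed=3000 + r))
            b = gen_matched_cohort(CohortConfig(
                n_pairs=329, causal_logor_per_sd=np.log(0.86), seed=4000 + r))
            a["grp"] = "a"
            b["grp"] = "b"
            b["pair_id"] += 1000
            both = standardize_log_exposure(pd.concat([a, b], ignore_index=True))
            res = interaction_test(both, "grp", cutpoint="categories")
            rejections += res.p_heterogeneity < 0.05
        assert rejections / reps > 0.5

    def test_null_modifier_p_is_roughly_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(77)
        ps = []
        for r in range(150):
            cohort = gen_matched_cohort(CohortConfig(
                n_pairs=120, causal_logor_per_sd=0.2, seed=6000 + r))
            cohort["grp"] = np.repeat(
                rng.choice(["a", "b"], size=120), 2)
            std = standardize_log_exposure(cohort)
            res = interaction_test(std, "grp", cutpoint="categories")
            ps.append(res.p_heterogeneity)
        assert kstest(ps, "uniform").pvalue > 0.005

    def test_stratum_estimates_match_separate_fits(self):
        cohort = gen_matched_cohort(CohortConfig(
            n_pairs=200, causal_logor_per_sd=0.3, seed=15))
        std = standardize_log_exposure(cohort)
        res = interaction_test(std, "smoking", cutpoint="categories")
        cases = std[std["is_case"]].set_index("pair_id")
        for lev, fit in res.strata.items():
            ids = cases.index[cases["smoking"] == lev]
            direct = clogit_fit(std[std["pair_id"].isin(ids)])
            assert fit.beta == pytest.approx(direct.beta, abs=1e-10)

    def test_constant_modifier_errors(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=30, seed=16))
        cohort["const"] = "x"
        std = standardize_log_exposure(cohort)
        with pytest.raises(ValueError, match="constant"):
            interaction_test(std, "const", cutpoint="categories")


class TestSubsites:
    def test_two_site_toy_matches_brute_force_likelihood(self):
        # competing-risks conditional likelihood factorizes over case sites
        diffs_colon = [0.8, 1.2, -0.4, 0.6]
        diffs_rectum = [-0.5, -0.9, 0.3]
        df_parts = []
        for i, d in enumerate(diffs_colon + diffs_rectum):
            site = "proximal" if i < 4 else "rectum"
            df_parts.append(pd.DataFrame({
                "pair_id": [i, i], "is_case": [True, False], "sex": "men",
                "exposure": [1.0, 1.0], "z": [d, 0.0], "subsite": site}))
        df = pd.concat(df_parts, ignore_index=True)
        res = subsite_heterogeneity(df, grouping="colon-vs-rectum",
                                    exposure_col="z")

        def nll(b, diffs):
            return np.sum(np.logaddexp(0, -b * np.asarray(diffs)))

        grid = np.linspace(-5, 5, 200001)
        b_colon = grid[np.argmin([nll(b, diffs_colon) for b in grid])]
        b_rectum = grid[np.argmin([nll(b, diffs_rectum) for b in grid])]
        assert res.strata["colon"].beta == pytest.approx(b_colon, abs=1e-3)
        assert res.strata["rectum"].beta == pytest.approx(b_rectum, abs=1e-3)

    def test_overlapping_colon_counts_toward_colon_only(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=400, seed=18))
        std = standardize_log_exposure(cohort)
        colon_rectum = subsite_heterogeneity(std, grouping="colon-vs-rectum")
        prox_dist = subsite_heterogeneity(std, grouping="proximal-vs-distal")
        cases = std[std["is_case"]]
        n_overlap = (cases["subsite"] == "overlapping-colon").sum()
        n_colon_cr = colon_rectum.strata["colon"].n_pairs_used
        n_pd = sum(s.n_pairs_used for s in prox_dist.strata.values())
        assert n_colon_cr >= n_pd  # overlapping cases excluded from prox/dist
        assert n_overlap > 0

    def test_label_permutation_leaves_pooled_estimate_unchanged(self):
        cohort = gen_matched_cohort(CohortConfig(
            n_pairs=150, causal_logor_per_sd=0.25, seed=19))
        std = standardize_log_exposure(cohort)
        pooled_before = clogit_fit(std).beta
        rng = np.random.default_rng(0)
        perm = std.copy()
        site_by_pair = perm.groupby("pair_id")["subsite"].first()
        shuffled = pd.Series(rng.permutation(site_by_pair.to_numpy()),
                             index=site_by_pair.index)
        perm["subsite"] = perm["pair_id"].map(shuffled)
        assert clogit_fit(perm).beta == pooled_before
        assert subsite_heterogeneity(perm).p_heterogeneity > 0  # still runs

    def test_unknown_grouping_errors(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=30, seed=20))
        std = standardize_log_exposure(cohort)
        with pytest.raises(ValueError, match="grouping"):
            subsite_heterogeneity(std, grouping="foo")


class TestLiverFilters:
    def test_index_arithmetic(self):
        idx = liver_indices(400.0, 50.0, 50.0)
        assert idx.btr == pytest.approx(8.0)
        assert idx.fischer == pytest.approx(4.0)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError, match="denominator"):
            liver_indices(400.0, 0.0, 0.0)

    def test_zero_thresholds_exclude_nothing(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=40, seed=21))
        filtered, log = liver_exclusion(cohort, btr_min=0.0, fischer_min=0.0)
        assert len(filtered) == len(cohort)
        assert len(log) == 0

    def test_pair_dropped_when_either_member_below_threshold(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=40, seed=22))
        # push one control below the BTR threshold
        idx = cohort.index[(cohort["pair_id"] == 7) & (~cohort["is_case"])][0]
        cohort.loc[idx, "bcaa"] = 10.0
        filtered, log = liver_exclusion(cohort, btr_min=4.4, fischer_min=1.8)
        assert 7 not in set(filtered["pair_id"])
        assert 7 in set(log["pair_id"])

    def test_record_level_zero_denominator(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=10, seed=23))
        cohort.loc[4, ["tyrosine", "phenylalanine"]] = 0.0
        with pytest.raises(ValueError, match="pair"):
            liver_exclusion(cohort)


class TestGenotypeExposure:
    def test_planted_variance_share_is_recovered(self):
        # per-allele effect sized so the lead variant explains ~20% of
        # log-exposure variance in controls at the validation sample size
        b = np.sqrt(0.20 / (2 * 0.35 * 0.65))
        r2s = []
        for r in range(20):
            cohort = gen_matched_cohort(CohortConfig(
                n_pairs=808, lead_snp_maf=0.35, lead_snp_beta_sd=b,
                seed=7000 + r))
            controls = cohort[~cohort["is_case"]]
            r2s.append(genotype_exposure_check(controls).r2)
        assert np.mean(r2s) == pytest.approx(0.20, abs=0.02)

    def test_null_effect_r2_matches_chance_expectation(self):
        r2s = []
        for r in range(100):
            cohort = gen_matched_cohort(CohortConfig(
                n_pairs=400, lead_snp_beta_sd=0.0, seed=8000 + r))
            r2s.append(genotype_exposure_check(cohort[~cohort["is_case"]]).r2)
        # E[R^2] under the null is ~ 1/(n-1)
        assert np.mean(r2s) == pytest.approx(1 / 399, rel=0.5)

    def test_location_invariance(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=100, seed=25))
        controls = cohort[~cohort["is_case"]]
        a = genotype_exposure_check(controls)
        scaled = controls.assign(exposure=controls["exposure"] * np.exp(2.0))
        bshift = genotype_exposure_check(scaled)
        assert bshift.slope == pytest.approx(a.slope, abs=1e-12)
        assert bshift.r2 == pytest.approx(a.r2, abs=1e-12)

    def test_constant_genotype_errors(self):
        cohort = gen_matched_cohort(CohortConfig(n_pairs=20, seed=26))
        cohort["lead_genotype"] = 1
        with pytest.raises(ValueError, match="constant genotype"):
            genotype_exposure_check(cohort[~cohort["is_case"]])
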