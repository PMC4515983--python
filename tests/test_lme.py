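"""Mixed-effects model fitting: closed-form ML, changepoint estimation,
likelihood-ratio statistics, bootstrap SD, atrophy rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from mtlshape import lme
from mtlshape.synthetic import (
    Cohort,
    CohortParams,
    EffectParams,
    MarkerMatrix,
    generate_cohort,
    generate_markers,
)


def _manual_cohort(groups, ages_per_subject, onsets=None, sexes=None, licvs=None):
    """Hand-built cohort for exact-value tests."""
    subj_rows, scan_rows = [], []
    for i, (g, ages) in enumerate(zip(groups, ages_per_subject)):
        sid = f"m{i:02d}"
        onset = np.nan if g == "control" else (onsets[i] if onsets else ages[-1] + 2.0)
        sex = sexes[i] if sexes else 0
        licv = licvs[i] if licvs else 14.0
        subj_rows.append((sid, g, sex, licv, onset))
        for j, a in enumerate(ages):
            scan_rows.append((sid, f"{sid}_t{j}", float(a)))
    return Cohort(
        pd.DataFrame(subj_rows, columns=["subject_id", "group", "sex", "log_icv", "onset_age"]),
        pd.DataFrame(scan_rows, columns=["subject_id", "scan_id", "scan_age"]),
    )


class TestCrossSectional:
    def test_noiseless_group_offset_recovered(self):
        cohort = _manual_cohort(["control"] * 4 + ["symptomatic"] * 4,
                                [[60.0]] * 8)
        values = np.array([[0.0] * 4 + [-0.2] * 4])
        mk = MarkerMatrix(values, cohort.scans["scan_id"].tolist())
        fit = lme.fit_cross_sectional(mk, cohort, include_age=False)
        assert fit.coef_named("group")[0] == pytest.approx(-0.2, abs=1e-12)
        # constant sex and log-ICV columns flagged, not crashed on
        assert "sex" in fit.dropped and "log_icv" in fit.dropped

    def test_single_group_drops_group_column(self):
        cohort = _manual_cohort(["control"] * 6, [[55.0 + i] for i in range(6)],
                                sexes=[0, 1, 0, 1, 0, 1],
                                licvs=[14.0, 14.1, 13.9, 14.2, 14.05, 13.95])
        rng = np.random.default_rng(0)
        mk = MarkerMatrix(rng.normal(size=(2, 6)), cohort.scans["scan_id"].tolist())
        fit = lme.fit_cross_sectional(mk, cohort)
        assert "group" in fit.dropped
        assert np.isnan(fit.coef_named("group")).all()
        # remaining fit equals plain covariate OLS
        dz, Y = lme.build_design(mk, cohort.first_scans(), "cs", ("control", "symptomatic"))
        keep = [i for i, c in enumerate(dz.columns1) if c != "group"]
        theta = np.linalg.lstsq(dz.X1[:, keep], Y, rcond=None)[0]
        got = fit.coef[[fit.columns.index(dz.columns1[i]) for i in keep]]
        assert np.allclose(got, theta, atol=1e-10)

    def test_loglik_matches_numerical_maximization(self):
        # direct Nelder-Mead over (theta, log sigma2) as the independent oracle
        cohort = generate_cohort(
            CohortParams(n_control=10, n_preclinical=0, n_symptomatic=10,
                         scans_per_subject_mean=(1, 1, 1)), seed=31)
        eff = EffectParams(n_vertices=3, affected_vertex_fraction=1.0, beta=-0.1,
                           sigma2=0.01, rho=0.0)
        mk = generate_markers(cohort, eff, seed=32)
        fit = lme.fit_cross_sectional(mk, cohort)
        dz, Y = lme.build_design(mk, cohort.first_scans(), "cs", ("control", "symptomatic"))
        n = dz.n_obs
        for v in range(3):
            y = Y[:, v]

            def negll(params):
                th, ls2 = params[:-1], params[-1]
                r = y - dz.X1 @ th
                return 0.5 * (n * (np.log(2 * np.pi) + ls2) + (r @ r) / np.exp(ls2))

            th0 = np.linalg.lstsq(dz.X1, y, rcond=None)[0]
            res = minimize(negll, np.concatenate([th0, [np.log(y.var())]]),
                           method="Nelder-Mead",
                           options={"maxiter": 20000, "xatol": 1e-12, "fatol": 1e-14})
            assert fit.loglik[v] == pytest.approx(-res.fun, abs=1e-6)


class TestLongitudinal:
    def test_rho_zero_reduces_to_ols(self):
        cohort = generate_cohort(
            CohortParams(n_control=12, n_preclinical=0, n_symptomatic=8,
                         scans_per_subject_mean=(3, 3, 3)), seed=41)
        eff = EffectParams(n_vertices=2, affected_vertex_fraction=1.0, beta=-0.05,
                           sigma2=0.01, rho=0.0)
        mk = generate_markers(cohort, eff, seed=42)
        fit = lme.fit_longitudinal(mk, cohort, rho_grid=np.array([0.0]))
        dz, Y = lme.build_design(mk, cohort, "long", ("control", "symptomatic"))
        theta = np.linalg.lstsq(dz.X1, Y, rcond=None)[0]
        assert np.allclose(fit.coef, theta, atol=1e-8)

    def test_single_subject_perfect_line(self):
        cohort = _manual_cohort(["control"], [[60.0, 62.0, 64.0, 66.0]])
        ages = cohort.scans["scan_age"].to_numpy()
        mk = MarkerMatrix((0.5 - 0.01 * ages)[None, :], cohort.scans["scan_id"].tolist())
        fit = lme.fit_longitudinal(mk, cohort)
        assert fit.degenerate[0]  # residuals identically zero
        assert fit.coef_named("age")[0] == pytest.approx(-0.01, abs=1e-9)

    def test_single_scan_data_flags_rho_fixed(self, cs_cohort):
        eff = EffectParams(n_vertices=2, affected_vertex_fraction=0.0, sigma2=0.01)
        mk = generate_markers(cs_cohort, eff, seed=43)
        fit = lme.fit_longitudinal(mk, cs_cohort)
        assert fit.rho_fixed_zero
        assert (fit.rho == 0).all()

    def test_null_reduction_matches_cross_sectional(self, cs_cohort):
        # single-scan data: the longitudinal null design [1, a, d, i] with rho
        # pinned at 0 is exactly the cross-sectional null model
        eff = EffectParams(n_vertices=3, affected_vertex_fraction=0.0, sigma2=0.01)
        mk = generate_markers(cs_cohort, eff, seed=44)
        f_long = lme.fit_longitudinal(mk, cs_cohort, null=True)
        f_cs = lme.fit_cross_sectional(mk, cs_cohort, null=True)
        assert np.allclose(f_long.loglik, f_cs.loglik, atol=1e-10)
        assert np.allclose(f_long.coef, f_cs.coef, atol=1e-10, equal_nan=True)

    def test_slope_recovery_within_two_se(self):
        hits_a = hits_b = 0
        n_seeds = 60
        for s in range(n_seeds):
            # shared entry and onset: the pre-changepoint intercept shift is a
            # pure group offset, so group_age carries exactly the extra slope
            cohort = generate_cohort(
                CohortParams(n_control=30, n_preclinical=0, n_symptomatic=30,
                             entry_age_mean=(60, 60, 60), entry_age_sd=(0, 0, 0),
                             scans_per_subject_mean=(3, 3, 3),
                             onset_offset_mean=1.0, onset_offset_sd=0.0), seed=500 + s)
            eff = EffectParams(n_vertices=1, affected_vertex_fraction=1.0,
                               alpha_prime=-0.01, beta=0.0, beta_prime=-0.03,
                               delta_true=20.0, sigma2=0.01, rho=0.5)
            mk = generate_markers(cohort, eff, seed=600 + s)
            fit = lme.fit_longitudinal(mk, cohort, compute_se=True)
            hits_a += abs(fit.coef_named("age")[0] + 0.01) <= 2 * fit.se_named("age")[0]
            hits_b += (abs(fit.coef_named("group_age")[0] + 0.03)
                       <= 2 * fit.se_named("group_age")[0])
        assert hits_a >= 0.9 * n_seeds
        assert hits_b >= 0.9 * n_seeds


class TestChangepoint:
    def test_noiseless_break_recovered_exactly(self):
        onsets = {f"m{i:02d}": 70.0 for i in range(12)}
        groups = ["control"] * 4 + ["symptomatic"] * 8
        ages = [[58.0, 61.0, 64.0, 67.0, 70.0]] * 12
        cohort = _manual_cohort(groups, ages, onsets=[70.0] * 12)
        design = cohort.scan_design()
        a = design["scan_age"].to_numpy()
        g = (design["group"] != "control").to_numpy()
        cp = 70.0 - 6.0
        y = -0.005 * a - 0.03 * np.clip(a - cp, 0, None) * g
        mk = MarkerMatrix(np.vstack([y, y]), cohort.scans["scan_id"].tolist())
        fit = lme.fit_changepoint(mk, cohort, np.arange(0, 12.01, 0.5))
        assert fit.delta == 6.0

    def test_flat_profile_when_no_switch(self):
        cohort = _manual_cohort(["control"] * 3 + ["symptomatic"] * 3,
                                [[60.0, 62.0, 64.0]] * 6, onsets=[66.0] * 6)
        a = cohort.scan_design()["scan_age"].to_numpy()
        y = 0.2 - 0.004 * a  # beta' = 0: no regime change anywhere
        mk = MarkerMatrix(y[None, :], cohort.scans["scan_id"].tolist())
        fit = lme.fit_changepoint(mk, cohort, np.arange(0, 10.01, 0.5))
        assert fit.profile.max() - fit.profile.min() < 1e-9
        assert fit.delta == 0.0  # ties break toward smaller Delta

    def test_delta_grid_required(self, small_markers, small_cohort):
        with pytest.raises(lme.ModelUsageError, match="empty"):
            lme.fit_changepoint(small_markers, small_cohort, np.array([]))

    def test_controls_only_rejected(self):
        cohort = _manual_cohort(["control"] * 4, [[60.0, 62.0]] * 4)
        mk = MarkerMatrix(np.zeros((1, 8)), cohort.scans["scan_id"].tolist())
        with pytest.raises(lme.ModelUsageError, match="onset"):
            lme.fit_changepoint(mk, cohort, np.arange(0, 5, 1.0))

    def test_switch_regressor_vanishes_at_changepoint(self, small_markers, small_cohort):
        # continuity: the fitted mean is the same on both sides of the break
        fit = lme.fit_changepoint(small_markers, small_cohort, np.arange(0, 8.01, 1.0))
        dz, _ = lme.build_design(small_markers, small_cohort, "changepoint",
                                 delta=fit.delta)
        design = small_cohort.scan_design()
        w = dz.X1[:, dz.columns1.index("post_cp_age")]
        at_cp = np.isclose(design["scan_age"], design["onset_age"] - fit.delta)
        assert np.allclose(w[at_cp], 0.0)


class TestLRStatistic:
    def test_alt_equals_null_gives_zero(self, small_markers, small_cohort):
        alt = lme.fit_cross_sectional(small_markers, small_cohort)
        null = lme.fit_cross_sectional(small_markers, small_cohort, null=True)
        s = lme.lr_statistic(alt, null)
        assert (s >= -1e-8).all()
        same = lme.lr_statistic(alt, lme.LMEFit(
            alt.coef, alt.se, alt.sigma2, alt.rho, alt.loglik, alt.columns,
            "cs-null", alt.n_obs, alt.dropped, alt.degenerate))
        assert np.allclose(same, 0.0, atol=1e-12)

    def test_non_nested_rejected(self, small_markers, small_cohort):
        alt = lme.fit_cross_sectional(small_markers, small_cohort)
        with pytest.raises(lme.ModelUsageError, match="nested"):
            lme.lr_statistic(alt, alt)

    def test_null_distribution_is_chi2(self):
        # 2 S_v ~ chi2(1) under H0 for the cross-sectional group test
        cohort = generate_cohort(
            CohortParams(n_control=200, n_preclinical=0, n_symptomatic=200,
                         entry_age_mean=(60, 60, 60),
                         scans_per_subject_mean=(1, 1, 1)), seed=71)
        eff = EffectParams(n_vertices=300, affected_vertex_fraction=0.0, sigma2=0.01)
        mk = generate_markers(cohort, eff, seed=72)
        s = lme.lr_statistic(lme.fit_cross_sectional(mk, cohort),
                             lme.fit_cross_sectional(mk, cohort, null=True))
        ks = stats.kstest(2 * s, stats.chi2(df=1).cdf).statistic
        assert ks < 0.05


class TestDeltaSD:
    def test_noiseless_bootstrap_sd_is_zero(self):
        onsets = [70.0] * 10
        cohort = _manual_cohort(["control"] * 4 + ["symptomatic"] * 6,
                                [[58.0, 62.0, 66.0, 70.0]] * 10, onsets=onsets)
        design = cohort.scan_design()
        a = design["scan_age"].to_numpy()
        g = (design["group"] != "control").to_numpy()
        y = -0.005 * a - 0.03 * np.clip(a - 64.0, 0, None) * g
        mk = MarkerMatrix(y[None, :], cohort.scans["scan_id"].tolist())
        sd, reps = lme.estimate_delta_sd(mk, cohort, np.arange(0, 10.01, 1.0),
                                         n_boot=50, seed=3)
        assert sd == 0.0
        assert (reps == 6.0).all()

    def test_same_seed_same_sd(self, small_markers, small_cohort):
        grid = np.arange(0, 8.01, 1.0)
        sd1, r1 = lme.estimate_delta_sd(small_markers, small_cohort, grid,
                                        n_boot=50, seed=9)
        sd2, r2 = lme.estimate_delta_sd(small_markers, small_cohort, grid,
                                        n_boot=50, seed=9)
        assert sd1 == sd2
        assert np.array_equal(r1, r2)

    def test_too_few_replicates_rejected(self, small_markers, small_cohort):
        with pytest.raises(lme.ModelUsageError):
            lme.estimate_delta_sd(small_markers, small_cohort, n_boot=10, seed=0)

    def test_bootstrap_sd_calibrated_against_monte_carlo(self):
        # bootstrap SD should sit within a factor of 2 of the across-cohort SD
        grid = np.arange(3.0, 11.01, 0.5)
        rho_grid = np.concatenate([[0.0], np.geomspace(0.1, 20, 6)])
        params = CohortParams(n_control=20, n_preclinical=10, n_symptomatic=10,
                              scans_per_subject_mean=(3, 3, 3))
        eff = EffectParams(n_vertices=4, affected_vertex_fraction=1.0, beta=0.0,
                           beta_prime=-0.03, delta_true=7.0, sigma2=0.01, rho=0.5)
        mc = []
        for s in range(15):
            c = generate_cohort(params, seed=800 + s)
            m = generate_markers(c, eff, seed=900 + s)
            mc.append(lme.fit_changepoint(m, c, grid, rho_grid=rho_grid,
                                          refine=False).delta)
        mc_sd = np.std(mc, ddof=1)
        c = generate_cohort(params, seed=800)
        m = generate_markers(c, eff, seed=900)
        boot_sd, _ = lme.estimate_delta_sd(m, c, grid, n_boot=60, seed=1,
                                           rho_grid=rho_grid)
        assert boot_sd <= 2.0 * mc_sd + 1e-12
        assert boot_sd >= mc_sd / 2.0 - 1e-12


class TestAtrophyRates:
    def _cohort(self):
        return _manual_cohort(["control"] * 2 + ["symptomatic"],
                              [[60, 61, 62, 63], [60, 61], [60, 61, 62, 63]],
                              onsets=[np.nan, np.nan, 64.0])

    def test_exact_linear_decline(self):
        cohort = self._cohort()
        rows = []
        for sid, grp in cohort.scans.groupby("subject_id", sort=False):
            ages = grp["scan_age"].to_numpy()
            v0 = 1000.0
            rows.append(pd.DataFrame({
                "subject_id": sid, "scan_age": ages,
                "volume": v0 * (1 - 0.01 * (ages - ages[0])),
            }))
        volumes = pd.concat(rows, ignore_index=True)
        rates = lme.fit_atrophy_rates(volumes, cohort, min_scans=3)
        ctrl = rates.loc[rates["group"] == "control"]
        # the 2-scan subject is excluded: one control contributes
        assert int(ctrl["n_subjects"].iloc[0]) == 1
        assert ctrl["atrophy_rate_pct_per_year"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_volume_zero_rate(self):
        cohort = self._cohort()
        volumes = cohort.scans.assign(volume=500.0)[["subject_id", "scan_age", "volume"]]
        rates = lme.fit_atrophy_rates(volumes, cohort, min_scans=3)
        assert np.allclose(rates["atrophy_rate_pct_per_year"], 0.0, atol=1e-12)

    def test_no_eligible_subjects_rejected(self):
        cohort = self._cohort()
        volumes = cohort.scans.assign(volume=500.0)[["subject_id", "scan_age", "volume"]]
        with pytest.raises(ValueError, match="no subjects"):
            lme.fit_atrophy_rates(volumes, cohort, min_scans=10)

    def test_negative_volume_rejected(self):
        cohort = self._cohort()
        volumes = cohort.scans.assign(volume=-1.0)[["subject_id", "scan_age", "volume"]]
        with pytest.raises(ValueError, match="positive"):
            lme.fit_atrophy_rates(volumes, cohort)
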