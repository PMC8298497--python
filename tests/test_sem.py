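"""The multi-group SEM engine: moments, ML fit, SEs, indices, nested tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from edsem import (
    CohortConfig,
    GroupData,
    SemParams,
    SemSpec,
    baseline_fit,
    chi_square_difference,
    count_df,
    fit_indices,
    fit_ml,
    generate_phenotypes,
    model_implied_moments,
    standardized_solution,
)
from edsem.sem import _Layout
from edsem.simulate import DEFAULT_EFFECT_BETAS

GROUPS = ("HC", "ADHD-I", "ADHD-C/H")
LOADINGS = np.array([0.909, 0.603, 0.546, 0.428])


def _spec(outcome="topo", equal=False):
    return SemSpec(
        indicators=("x1", "x2", "x3", "x4"),
        groups=GROUPS,
        outcome=outcome,
        reference_group="ADHD-I",
        equal_regressions=equal,
    )


def _params(spec, lam, psi, theta, beta=None, zeta=None):
    m = len(lam)
    return SemParams(
        loadings=np.asarray(lam, dtype=float),
        latent_variance={g: psi[g] for g in spec.groups},
        residual_variances={g: np.asarray(theta[g], dtype=float) for g in spec.groups},
        intercepts={g: np.zeros(m) for g in spec.groups},
        regression=None if beta is None else dict(beta),
        outcome_residual=None if zeta is None else dict(zeta),
        outcome_intercept=None if beta is None else {g: 0.0 for g in spec.groups},
    )


def _data_from_moments(spec, params, ns):
    moments = model_implied_moments(spec, params)
    return GroupData(
        spec.variables,
        spec.groups,
        dict(ns),
        {g: moments[g][1] for g in spec.groups},
        {g: moments[g][0] for g in spec.groups},
    )


def _random_proper_params(spec, rng):
    m = len(spec.indicators)
    lam = rng.uniform(0.3, 0.95, size=m)
    psi = {g: 1.0 if g == spec.reference_group else rng.uniform(0.3, 1.5) for g in spec.groups}
    theta = {g: rng.uniform(0.25, 1.2, size=m) for g in spec.groups}
    beta = zeta = None
    if spec.outcome:
        beta = {g: rng.uniform(-0.8, 0.8) for g in spec.groups}
        zeta = {g: rng.uniform(0.3, 1.2) for g in spec.groups}
    return _params(spec, lam, psi, theta, beta, zeta)


class TestImpliedMoments:
    def test_zero_loadings_zero_regression_diagonal(self):
        spec = _spec()
        params = _params(
            spec,
            [0, 0, 0, 0],
            {g: 1.0 for g in GROUPS},
            {g: [1, 2, 3, 4] for g in GROUPS},
            beta={g: 0.0 for g in GROUPS},
            zeta={g: 0.5 for g in GROUPS},
        )
        sigma, mu = model_implied_moments(spec, params)["HC"]
        assert np.allclose(sigma, np.diag([1, 2, 3, 4, 0.5]))
        assert np.allclose(mu, 0)

    def test_unit_loadings_compound_symmetry(self):
        spec = _spec(outcome=None)
        params = _params(
            spec, [1, 1, 1, 1], {g: 1.0 for g in GROUPS}, {g: [1, 1, 1, 1] for g in GROUPS}
        )
        sigma, _ = model_implied_moments(spec, params)["HC"]
        assert np.allclose(sigma, np.ones((4, 4)) + np.eye(4))

    def test_study_loading_fixture_against_matrix_oracle(self):
        # independent dense-matrix-arithmetic oracle for the full 5x5 Sigma
        spec = _spec()
        theta = 1.0 - LOADINGS**2
        params = _params(
            spec,
            LOADINGS,
            {g: 1.0 for g in GROUPS},
            {g: theta for g in GROUPS},
            beta={g: 0.8 for g in GROUPS},
            zeta={g: 0.36 for g in GROUPS},
        )
        sigma, _ = model_implied_moments(spec, params)["ADHD-I"]
        lam_star = np.concatenate([LOADINGS, [0.8]])  # latent -> all observed
        oracle = np.outer(lam_star, lam_star) + np.diag(np.concatenate([theta, [0.36]]))
        assert np.allclose(sigma, oracle, atol=1e-12)

    def test_reference_variance_enforced(self):
        spec = _spec(outcome=None)
        params = _params(
            spec, LOADINGS, {"HC": 0.3, "ADHD-I": 2.0, "ADHD-C/H": 0.34},
            {g: np.ones(4) for g in GROUPS},
        )
        with pytest.raises(ValueError):
            model_implied_moments(spec, params)


class TestDegreesOfFreedom:
    def test_free_and_constrained_three_group_model(self):
        assert count_df(_spec()) == 21
        assert count_df(_spec(equal=True)) == 23
        assert count_df(_spec(equal=True)) - count_df(_spec()) == 2

    def test_measurement_model(self):
        assert count_df(_spec(outcome=None)) == 12

    def test_moments_minus_parameters_identity(self):
        for spec in [_spec(), _spec(equal=True), _spec(outcome=None)]:
            lay = _Layout(spec)
            p = spec.n_observed
            moments = len(spec.groups) * (p * (p + 1) // 2 + p)
            assert count_df(spec) == moments - lay.n_free

    def test_unidentified_spec_rejected(self):
        spec = SemSpec(indicators=("a", "b"), groups=("g1",))
        with pytest.raises(ValueError, match="identified"):
            count_df(spec)


class TestZeroDiscrepancyFixedPoint:
    @pytest.mark.parametrize("with_outcome", [True, False])
    def test_exact_moments_recover_parameters(self, with_outcome, rng):
        spec = _spec() if with_outcome else _spec(outcome=None)
        lay = _Layout(spec)
        for _ in range(10):
            truth = _random_proper_params(spec, rng)
            data = _data_from_moments(spec, truth, {g: 400 for g in spec.groups})
            fit = fit_ml(spec, data, compute_se=False)
            assert fit.converged
            assert fit.statistic < 1e-6
            err = np.max(np.abs(lay.to_vector(fit.params) - lay.to_vector(truth)))
            assert err < 1e-6


class TestFitML:
    def test_simulated_recovery_large_n(self):
        """Estimates land within Monte-Carlo distance of the generating values."""
        cfg = CohortConfig(group_sizes={"HC": 5000, "ADHD-I": 5000, "ADHD-C/H": 5000})
        pheno = generate_phenotypes(cfg, seed=11, outcome_nodes={"topo": DEFAULT_EFFECT_BETAS})
        spec = SemSpec(cfg.indicators, cfg.groups, outcome="topo", reference_group="ADHD-I")
        data = GroupData.from_frame(
            pheno.rename(columns={"topo": "topo"}), spec.variables, groups=cfg.groups
        )
        fit = fit_ml(spec, data)
        assert fit.converged
        est = fit.estimates
        for ind, lam in zip(cfg.indicators, cfg.loadings):
            row = est[(est.parameter == f"lambda[{ind}]")].iloc[0]
            assert row.estimate == pytest.approx(lam, abs=3.5 * row.se)
        std = standardized_solution(fit)
        b = std[(std.parameter == "beta") & (std.group == "ADHD-C/H")]["value"].iloc[0]
        assert b == pytest.approx(0.844, abs=0.03)

    def test_asymptotic_bias_small(self):
        cfg = CohortConfig(group_sizes={g: 20_000 for g in GROUPS})
        pheno = generate_phenotypes(cfg, seed=3, outcome_nodes={"topo": DEFAULT_EFFECT_BETAS})
        spec = SemSpec(cfg.indicators, cfg.groups, outcome="topo", reference_group="ADHD-I")
        data = GroupData.from_frame(pheno, spec.variables, groups=cfg.groups)
        fit = fit_ml(spec, data, compute_se=False)
        truth = cfg.true_params(DEFAULT_EFFECT_BETAS)
        lay = _Layout(spec)
        assert np.max(np.abs(lay.to_vector(fit.params) - lay.to_vector(truth))) < 0.02

    def test_likelihood_identity(self, rng):
        """N*F equals -2(logL_model - logL_saturated) from normal densities."""
        cfg = CohortConfig(group_sizes={"HC": 60, "ADHD-I": 40, "ADHD-C/H": 50})
        pheno = generate_phenotypes(cfg, seed=7)
        spec = SemSpec(cfg.indicators, cfg.groups, reference_group="ADHD-I")
        data = GroupData.from_frame(pheno, spec.variables, groups=cfg.groups)
        fit = fit_ml(spec, data, compute_se=False)
        moments = model_implied_moments(spec, fit.params)
        ll_model = ll_sat = 0.0
        for g in cfg.groups:
            block = pheno.loc[pheno.group == g, list(spec.variables)].to_numpy()
            sigma, mu = moments[g]
            ll_model += stats.multivariate_normal.logpdf(block, mu, sigma).sum()
            xbar = block.mean(axis=0)
            s = np.cov(block, rowvar=False, ddof=0)
            ll_sat += stats.multivariate_normal.logpdf(block, xbar, s).sum()
        assert fit.statistic == pytest.approx(-2.0 * (ll_model - ll_sat), abs=1e-8)

    def test_missing_values_rejected(self):
        cfg = CohortConfig()
        pheno = generate_phenotypes(cfg, seed=1)
        pheno.loc[0, "k10_distress"] = np.nan
        spec = SemSpec(cfg.indicators, cfg.groups, reference_group="ADHD-I")
        with pytest.raises(ValueError, match="missing"):
            GroupData.from_frame(pheno, spec.variables, groups=cfg.groups)

    def test_too_small_group_rejected(self):
        cfg = CohortConfig(group_sizes={"HC": 50, "ADHD-I": 4, "ADHD-C/H": 25})
        pheno = generate_phenotypes(cfg, seed=1)
        spec = SemSpec(cfg.indicators, cfg.groups, reference_group="ADHD-I")
        with pytest.raises(ValueError, match="ADHD-I"):
            GroupData.from_frame(pheno, spec.variables, groups=cfg.groups)


class TestStandardErrors:
    def test_z_and_p_columns(self):
        cfg = CohortConfig()
        pheno = generate_phenotypes(cfg, seed=21)
        spec = SemSpec(cfg.indicators, cfg.groups, reference_group="ADHD-I")
        fit = fit_ml(spec, GroupData.from_frame(pheno, spec.variables, groups=cfg.groups))
        est = fit.estimates.dropna(subset=["se"])
        assert np.allclose(est.z, est.estimate / est.se)
        assert np.allclose(est.p_value, 2 * stats.norm.sf(np.abs(est.z)))
        # normal-quantile anchor points
        assert 2 * stats.norm.sf(1.96) == pytest.approx(0.05, abs=1e-3)
        assert 2 * stats.norm.sf(0.0) == 1.0

    def test_wald_coverage(self):
        """95% Wald intervals cover the generating loading about 95% of the time.

        Coverage is evaluated over proper solutions: replicates where a
        residual variance collapses to the boundary (Heywood case) are
        excluded, since Wald theory does not apply on the boundary.
        """
        import warnings as _warnings

        cfg = CohortConfig(group_sizes={"HC": 250, "ADHD-I": 250, "ADHD-C/H": 250})
        spec = SemSpec(cfg.indicators, cfg.groups, reference_group="ADHD-I")
        covered, proper = 0, 0
        n_rep = 200
        for rep in range(n_rep):
            pheno = generate_phenotypes(cfg, seed=1000 + rep)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                fit = fit_ml(spec, GroupData.from_frame(pheno, spec.variables, groups=cfg.groups))
            if fit.heywood or not fit.converged:
                continue
            row = fit.estimates[fit.estimates.parameter == "lambda[k10_distress]"].iloc[0]
            if not np.isfinite(row.se):
                continue
            proper += 1
            if abs(row.estimate - 0.909) < 1.959964 * row.se:
                covered += 1
        assert proper > 0.8 * n_rep
        # binomial 3.5-sigma band around the nominal level
        assert covered / proper == pytest.approx(0.95, abs=0.055)


class TestStandardizedSolution:
    def test_already_standardized_metric_unchanged(self):
        spec = _spec(outcome=None)
        theta = 1.0 - LOADINGS**2
        params = _params(spec, LOADINGS, {g: 1.0 for g in GROUPS}, {g: theta for g in GROUPS})
        data = _data_from_moments(spec, params, {g: 100 for g in GROUPS})
        fit = fit_ml(spec, data, compute_se=False)
        std = standardized_solution(fit)
        for ind, lam in zip(spec.indicators, LOADINGS):
            vals = std[std.parameter == f"lambda[{ind}]"]["value"]
            assert np.allclose(vals, lam, atol=1e-5)

    def test_rescaling_invariance(self):
        cfg = CohortConfig()
        pheno = generate_phenotypes(cfg, seed=5, outcome_nodes={"topo": DEFAULT_EFFECT_BETAS})
        spec = SemSpec(cfg.indicators, cfg.groups, outcome="topo", reference_group="ADHD-I")
        data = GroupData.from_frame(pheno, spec.variables, groups=cfg.groups)
        fit = fit_ml(spec, data, compute_se=False)
        scaled = pheno.copy()
        scaled["k10_distress"] *= 7.3
        scaled["topo"] *= 0.2
        fit2 = fit_ml(
            spec, GroupData.from_frame(scaled, spec.variables, groups=cfg.groups),
            compute_se=False,
        )
        a = standardized_solution(fit).sort_values(["parameter", "group"])["value"].to_numpy()
        b = standardized_solution(fit2).sort_values(["parameter", "group"])["value"].to_numpy()
        assert np.allclose(a, b, atol=1e-5)

    def test_direct_ratio_example(self):
        # unstandardized loading 2 with implied indicator sd 2.21 -> 2/2.21
        spec = SemSpec(indicators=("a", "b", "c"), groups=("g",))
        theta_a = 2.21**2 - 4.0
        params = SemParams(
            loadings=np.array([2.0, 1.0, 1.0]),
            latent_variance={"g": 1.0},
            residual_variances={"g": np.array([theta_a, 1.0, 1.0])},
            intercepts={"g": np.zeros(3)},
        )
        data = _data_from_moments(spec, params, {"g": 50})
        fit = fit_ml(spec, data, compute_se=False)
        std = standardized_solution(fit)
        val = std[(std.parameter == "lambda[a]")]["value"].iloc[0]
        assert val == pytest.approx(2.0 / 2.21, abs=1e-5)


class TestFitIndices:
    def test_perfect_fit(self, rng):
        spec = _spec()
        params = _random_proper_params(spec, rng)
        data = _data_from_moments(spec, params, {g: 200 for g in GROUPS})
        fit = fit_ml(spec, data, compute_se=False)
        idx = fit_indices(fit)
        assert idx["cfi"] == pytest.approx(1.0)
        assert idx["rmsea"] == pytest.approx(0.0, abs=1e-6)
        assert idx["srmr"] == pytest.approx(0.0, abs=1e-6)

    def test_baseline_closed_form_equals_numeric_minimum(self, rng):
        """The independence-model MLE really is the diagonal of S."""
        cfg = CohortConfig(group_sizes={"HC": 40, "ADHD-I": 30, "ADHD-C/H": 30})
        pheno = generate_phenotypes(cfg, seed=13)
        data = GroupData.from_frame(pheno, cfg.indicators, groups=cfg.groups)
        base = baseline_fit(data)
        p = len(data.variables)
        N = data.n_total

        # the independence discrepancy separates per (group, variable): minimise
        # each 1-D term log d + s_jj/d numerically and assemble the total
        total = 0.0
        for g in data.groups:
            s = data.covs[g]
            _, logdet_s = np.linalg.slogdet(s)
            per_var = 0.0
            for j in range(p):
                s_jj = s[j, j]
                res = optimize.minimize_scalar(
                    lambda d, s_jj=s_jj: np.log(d) + s_jj / d,
                    bounds=(1e-8, 1e4),
                    method="bounded",
                    options={"xatol": 1e-12},
                )
                per_var += res.fun
            total += (data.ns[g] / N) * (per_var - logdet_s - p)
        assert base.statistic == pytest.approx(N * total, abs=1e-5)
        assert base.df == 3 * p * (p - 1) // 2  # 18 for four variables, three groups

    def test_baseline_df_for_five_variables(self):
        cfg = CohortConfig()
        pheno = generate_phenotypes(cfg, seed=2, outcome_nodes={"t": DEFAULT_EFFECT_BETAS})
        data = GroupData.from_frame(pheno, (*cfg.indicators, "t"), groups=cfg.groups)
        assert baseline_fit(data).df == 30


class TestChiSquareDifference:
    def test_equal_generating_model_gives_near_zero(self):
        spec = _spec()
        params = _params(
            spec,
            LOADINGS,
            {"HC": 0.3, "ADHD-I": 1.0, "ADHD-C/H": 0.34},
            {g: 1.0 - LOADINGS**2 for g in GROUPS},
            beta={g: 0.5 for g in GROUPS},
            zeta={g: 0.6 for g in GROUPS},
        )
        data = _data_from_moments(spec, params, {"HC": 91, "ADHD-I": 31, "ADHD-C/H": 25})
        free = fit_ml(spec, data, compute_se=False)
        constrained = fit_ml(spec.constrained(), data, compute_se=False)
        diff = chi_square_difference(free, constrained)
        assert diff["delta_df"] == 2
        assert diff["delta_chi2"] == pytest.approx(0.0, abs=1e-5)
        assert diff["p_value"] == pytest.approx(1.0, abs=1e-5)

    def test_constrained_never_fits_better(self):
        cfg = CohortConfig()
        spec = SemSpec(cfg.indicators, cfg.groups, outcome="topo", reference_group="ADHD-I")
        for seed in range(5):
            pheno = generate_phenotypes(
                cfg, seed=seed, outcome_nodes={"topo": DEFAULT_EFFECT_BETAS}
            )
            data = GroupData.from_frame(pheno, spec.variables, groups=cfg.groups)
            free = fit_ml(spec, data, compute_se=False)
            constrained = fit_ml(spec.constrained(), data, compute_se=False)
            assert constrained.statistic >= free.statistic - 1e-6 * data.n_total

    def test_non_nested_rejected(self):
        cfg = CohortConfig()
        pheno = generate_phenotypes(cfg, seed=1, outcome_nodes={"topo": DEFAULT_EFFECT_BETAS})
        spec = SemSpec(cfg.indicators, cfg.groups, outcome="topo", reference_group="ADHD-I")
        data = GroupData.from_frame(pheno, spec.variables, groups=cfg.groups)
        free = fit_ml(spec, data, compute_se=False)
        with pytest.raises(ValueError, match="nested"):
            chi_square_difference(free, free)
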