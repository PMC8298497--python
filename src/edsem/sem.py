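"""Multi-group linear latent-variable structural equation models.

Implements the model family used throughout the package: m observed
indicators loading on a single latent factor (loadings shared across
groups), optionally one observed outcome regressed on the latent with a
group-specific (or equality-constrained) slope.  Per group the model has
free indicator/outcome intercepts and residual variances; the latent mean
is zero everywhere and the latent variance is fixed to 1 in a reference
group and free elsewhere.

Estimation is normal-theory maximum likelihood on group means and
covariances (covariance divisor ``n_g``), minimising

    F = sum_g (n_g/N) [ log|Sigma_g| + tr(S_g Sigma_g^-1) - log|S_g| - p
                        + (xbar_g - mu_g)' Sigma_g^-1 (xbar_g - mu_g) ]

with test statistic T = N * F, which is the likelihood-ratio chi-square
against the saturated model.  Because every mean is a free intercept, the
mean structure is saturated and the intercept MLEs are the sample means;
the optimiser therefore only searches the covariance parameters, with
analytic gradients and log-transformed variances.

Standard errors come from the observed information (numerical Hessian of
the negative log-likelihood at the optimum); the completely standardized
solution, CFI/SRMR/RMSEA fit indices, and nested-model chi-square
difference tests round out the engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SemSpec",
    "SemParams",
    "GroupData",
    "SemFit",
    "model_implied_moments",
    "fit_ml",
    "count_df",
    "standardized_solution",
    "fit_indices",
    "baseline_fit",
    "chi_square_difference",
]

_GTOL = 1e-6
_HEYWOOD_TOL = 1e-7


# ---------------------------------------------------------------------------
# specification and data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SemSpec:
    """Declarative description of one multi-group latent-variable model.

    Parameters
    ----------
    indicators:
        Names of the observed indicators of the latent factor (>= 3 for an
        identified factor when a single group is analysed without further
        constraints; >= 2 is accepted and identification is checked via the
        degree-of-freedom count).
    groups:
        Ordered group labels.
    outcome:
        Optional observed outcome regressed on the latent factor.
    reference_group:
        Group whose latent variance is fixed to 1 (scale of the factor).
    equal_regressions:
        If True the latent-to-outcome slope is constrained equal across
        groups (the "fixed regression" comparison model).
    """

    indicators: tuple[str, ...]
    groups: tuple[str, ...]
    outcome: str | None = None
    reference_group: str | None = None
    equal_regressions: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.indicators) < 2:
            raise ValueError("need at least 2 indicators")
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError("duplicate indicator names")
        if len(self.groups) < 1:
            raise ValueError("need at least one group")
        if self.reference_group is None:
            object.__setattr__(self, "reference_group", self.groups[0])
        if self.reference_group not in self.groups:
            raise ValueError(f"reference group {self.reference_group!r} not among groups")
        if self.outcome is not None and self.outcome in self.indicators:
            raise ValueError("outcome must not also be an indicator")
        if self.equal_regressions and self.outcome is None:
            raise ValueError("equal_regressions requires an outcome")

    @property
    def variables(self) -> tuple[str, ...]:
        """Observed variables in model order (indicators, then outcome)."""
        return self.indicators + ((self.outcome,) if self.outcome else ())

    @property
    def n_observed(self) -> int:
        return len(self.variables)

    def constrained(self) -> "SemSpec":
        """The nested comparison model with the regression slope shared."""
        if self.outcome is None:
            raise ValueError("no outcome to constrain")
        return replace(self, equal_regressions=True)


@dataclass
class SemParams:
    """Full parameter set for a :class:`SemSpec`.

    ``loadings`` are shared across groups; everything else is per group
    (the reference group's ``latent_variance`` must be 1).
    """

    loadings: np.ndarray
    latent_variance: dict[str, float]
    residual_variances: dict[str, np.ndarray]
    intercepts: dict[str, np.ndarray]
    regression: dict[str, float] | None = None
    outcome_residual: dict[str, float] | None = None
    outcome_intercept: dict[str, float] | None = None


@dataclass
class GroupData:
    """Per-group sample size, mean vector and covariance (divisor n_g)."""

    variables: tuple[str, ...]
    groups: tuple[str, ...]
    ns: dict[str, int]
    means: dict[str, np.ndarray]
    covs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        p = len(self.variables)
        for g in self.groups:
            if self.ns[g] < p + 1:
                raise ValueError(
                    f"group {g!r}: n={self.ns[g]} but need at least {p + 1} "
                    f"observations for {p} variables"
                )
            s = np.asarray(self.covs[g], dtype=float)
            if s.shape != (p, p) or not np.allclose(s, s.T):
                raise ValueError(f"group {g!r}: covariance must be symmetric {p}x{p}")
            if np.linalg.eigvalsh(s)[0] <= 0:
                raise ValueError(f"group {g!r}: sample covariance is singular")
            self.covs[g] = s
            self.means[g] = np.asarray(self.means[g], dtype=float)

    @property
    def n_total(self) -> int:
        return sum(self.ns.values())

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        variables: Sequence[str],
        group_col: str = "group",
        groups: Sequence[str] | None = None,
    ) -> "GroupData":
        """Build moments from subject-level data (listwise complete rows)."""
        variables = tuple(variables)
        if frame[list(variables)].isna().any().any():
            raise ValueError("missing values in model variables; exclude incomplete cases first")
        if groups is None:
            groups = tuple(pd.unique(frame[group_col]))
        else:
            groups = tuple(groups)
        ns, means, covs = {}, {}, {}
        for g in groups:
            block = frame.loc[frame[group_col] == g, list(variables)].to_numpy(dtype=float)
            ns[g] = block.shape[0]
            means[g] = block.mean(axis=0)
            covs[g] = np.cov(block, rowvar=False, ddof=0)
        return cls(variables, groups, ns, means, covs)

    def restrict_groups(self, groups: Sequence[str]) -> "GroupData":
        groups = tuple(groups)
        return GroupData(
            self.variables,
            groups,
            {g: self.ns[g] for g in groups},
            {g: self.means[g].copy() for g in groups},
            {g: self.covs[g].copy() for g in groups},
        )


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------

class _Layout:
    """Index map between the free covariance-parameter vector and SemParams.

    Vector order: loadings (identity scale), free latent variances (log),
    residual variances by group (log), regression slopes (identity),
    outcome residual variances (log).
    """

    def __init__(self, spec: SemSpec):
        self.spec = spec
        m = len(spec.indicators)
        g_labels = spec.groups
        self.m = m
        self.free_psi_groups = tuple(g for g in g_labels if g != spec.reference_group)
        names: list[tuple[str, str | None]] = []
        names += [("lambda", ind) for ind in spec.indicators]
        names += [("psi", g) for g in self.free_psi_groups]
        for g in g_labels:
            names += [("theta", f"{ind}|{g}") for ind in spec.indicators]
        if spec.outcome is not None:
            if spec.equal_regressions:
                names += [("beta", None)]
            else:
                names += [("beta", g) for g in g_labels]
            names += [("zeta", g) for g in g_labels]
        self.names = names
        self.size = len(names)
        # only the latent variances are log-parameterized; residual variances
        # stay on the identity scale so Heywood (negative) solutions are
        # representable and flagged rather than truncated at zero
        self.log_scale = np.array([kind == "psi" for kind, _ in names])
        # slices
        i = 0
        self.sl_lam = slice(i, i + m); i += m
        self.sl_psi = slice(i, i + len(self.free_psi_groups)); i += len(self.free_psi_groups)
        self.sl_theta = {}
        for g in g_labels:
            self.sl_theta[g] = slice(i, i + m); i += m
        if spec.outcome is not None:
            nb = 1 if spec.equal_regressions else len(g_labels)
            self.sl_beta = slice(i, i + nb); i += nb
            self.sl_zeta = slice(i, i + len(g_labels)); i += len(g_labels)
        else:
            self.sl_beta = self.sl_zeta = None
        assert i == self.size

    # number of free parameters including the saturated mean structure
    @property
    def n_free(self) -> int:
        spec = self.spec
        n_means = len(spec.groups) * spec.n_observed
        return self.size + n_means

    def to_params(self, x: np.ndarray, data: GroupData | None = None) -> SemParams:
        """Natural-scale vector -> SemParams (intercepts from data if given)."""
        spec = self.spec
        lam = np.asarray(x[self.sl_lam], dtype=float)
        psi = {spec.reference_group: 1.0}
        for g, v in zip(self.free_psi_groups, x[self.sl_psi]):
            psi[g] = float(v)
        theta = {g: np.asarray(x[self.sl_theta[g]], dtype=float) for g in spec.groups}
        beta = zeta = iota = None
        m = self.m
        if spec.outcome is not None:
            bvals = x[self.sl_beta]
            if spec.equal_regressions:
                beta = {g: float(bvals[0]) for g in spec.groups}
            else:
                beta = {g: float(b) for g, b in zip(spec.groups, bvals)}
            zeta = {g: float(z) for g, z in zip(spec.groups, x[self.sl_zeta])}
        if data is not None:
            nu = {g: data.means[g][:m].copy() for g in spec.groups}
            if spec.outcome is not None:
                iota = {g: float(data.means[g][m]) for g in spec.groups}
        else:
            nu = {g: np.zeros(m) for g in spec.groups}
            if spec.outcome is not None:
                iota = {g: 0.0 for g in spec.groups}
        return SemParams(lam, psi, theta, nu, beta, zeta, iota)

    def to_vector(self, params: SemParams) -> np.ndarray:
        spec = self.spec
        x = np.empty(self.size)
        x[self.sl_lam] = params.loadings
        x[self.sl_psi] = [params.latent_variance[g] for g in self.free_psi_groups]
        for g in spec.groups:
            x[self.sl_theta[g]] = params.residual_variances[g]
        if spec.outcome is not None:
            if spec.equal_regressions:
                x[self.sl_beta] = [params.regression[spec.groups[0]]]
            else:
                x[self.sl_beta] = [params.regression[g] for g in spec.groups]
            x[self.sl_zeta] = [params.outcome_residual[g] for g in spec.groups]
        return x

    def transform(self, x_nat: np.ndarray) -> np.ndarray:
        y = x_nat.copy()
        y[self.log_scale] = np.log(np.maximum(y[self.log_scale], 1e-300))
        return y

    def untransform(self, y: np.ndarray) -> np.ndarray:
        x = y.copy()
        x[self.log_scale] = np.exp(np.clip(x[self.log_scale], -40.0, 40.0))
        return x


def count_df(spec: SemSpec) -> int:
    """Model degrees of freedom: observed moments minus free parameters.

    Each group contributes p(p+1)/2 covariance moments and p means.  For the
    three-group model with four indicators and a group-specific regression
    this is 60 - 39 = 21; constraining the regression equal gives 23.
    """
    layout = _Layout(spec)
    p = spec.n_observed
    moments = len(spec.groups) * (p * (p + 1) // 2 + p)
    df = moments - layout.n_free
    if df < 0:
        raise ValueError(
            f"model not identified: {layout.n_free} free parameters for {moments} moments"
        )
    return df


# ---------------------------------------------------------------------------
# model-implied moments
# ---------------------------------------------------------------------------

def _implied_sigma_mu(spec: SemSpec, params: SemParams, g: str) -> tuple[np.ndarray, np.ndarray]:
    lam = np.asarray(params.loadings, dtype=float)
    m = lam.size
    psi = params.latent_variance[g]
    theta = np.asarray(params.residual_variances[g], dtype=float)
    if spec.outcome is None:
        sigma = psi * np.outer(lam, lam) + np.diag(theta)
        mu = np.asarray(params.intercepts[g], dtype=float)
        return sigma, mu
    beta = params.regression[g]
    zeta = params.outcome_residual[g]
    p = m + 1
    sigma = np.empty((p, p))
    sigma[:m, :m] = psi * np.outer(lam, lam) + np.diag(theta)
    sigma[:m, m] = sigma[m, :m] = beta * psi * lam
    sigma[m, m] = beta * beta * psi + zeta
    mu = np.concatenate([params.intercepts[g], [params.outcome_intercept[g]]])
    return sigma, mu


def model_implied_moments(
    spec: SemSpec, params: SemParams
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group model-implied covariance matrix and mean vector."""
    lam = np.asarray(params.loadings, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite loadings")
    if abs(params.latent_variance[spec.reference_group] - 1.0) > 1e-12:
        raise ValueError("reference-group latent variance must be fixed to 1")
    out = {}
    for g in spec.groups:
        sigma, mu = _implied_sigma_mu(spec, params, g)
        if not (np.all(np.isfinite(sigma)) and np.all(np.isfinite(mu))):
            raise ValueError(f"non-finite implied moments in group {g!r}")
        out[g] = (sigma, mu)
    return out


# ---------------------------------------------------------------------------
# ML discrepancy and analytic gradient (covariance structure only)
# ---------------------------------------------------------------------------

class _Objective:
    """F(x) and its gradient over the free covariance parameters.

    The saturated mean structure is concentrated out (intercepts = sample
    means), so only the covariance part of the discrepancy is evaluated.
    """

    def __init__(self, spec: SemSpec, data: GroupData):
        if tuple(data.variables) != spec.variables:
            raise ValueError(
                f"data variables {data.variables} do not match model order {spec.variables}"
            )
        self.spec = spec
        self.layout = _Layout(spec)
        self.data = data
        self.N = data.n_total
        self.w = {g: data.ns[g] / self.N for g in spec.groups}
        self.logdet_s = {}
        for g in spec.groups:
            sign, logdet = np.linalg.slogdet(data.covs[g])
            if sign <= 0:
                raise ValueError(f"group {g!r}: sample covariance not positive definite")
            self.logdet_s[g] = logdet

    def value_grad_natural(self, x_nat: np.ndarray) -> tuple[float, np.ndarray]:
        spec, lay = self.spec, self.layout
        m = lay.m
        p = spec.n_observed
        has_out = spec.outcome is not None
        lam = x_nat[lay.sl_lam]
        psi_all = {spec.reference_group: 1.0}
        for g, v in zip(lay.free_psi_groups, x_nat[lay.sl_psi]):
            psi_all[g] = v
        if has_out:
            bvals = x_nat[lay.sl_beta]
            beta_all = (
                {g: bvals[0] for g in spec.groups}
                if spec.equal_regressions
                else dict(zip(spec.groups, bvals))
            )
            zeta_all = dict(zip(spec.groups, x_nat[lay.sl_zeta]))
        F = 0.0
        grad = np.zeros(lay.size)
        for gi, g in enumerate(spec.groups):
            psi = psi_all[g]
            theta = x_nat[lay.sl_theta[g]]
            sigma = psi * np.outer(lam, lam) + np.diag(theta)
            if has_out:
                beta, zeta = beta_all[g], zeta_all[g]
                full = np.empty((p, p))
                full[:m, :m] = sigma
                full[:m, m] = full[m, :m] = beta * psi * lam
                full[m, m] = beta * beta * psi + zeta
                sigma = full
            s = self.data.covs[g]
            try:
                c = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                # trial step left the positive-definite region; F diverges at
                # the boundary, so a large finite value makes the line search
                # retreat (an infinity would abort it)
                return 1e12, grad
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            sinv = np.linalg.inv(sigma)
            F += self.w[g] * (logdet + np.sum(sinv * s) - self.logdet_s[g] - p)
            # A = Sinv (Sigma - S) Sinv, symmetric
            a = sinv - sinv @ s @ sinv
            a_ind = a[:m, :m]
            alam = a_ind @ lam
            w = self.w[g]
            # loadings (shared)
            gl = 2.0 * psi * alam
            if has_out:
                gl = gl + 2.0 * beta * psi * a[:m, m]
            grad[lay.sl_lam] += w * gl
            # free latent variance
            if g != spec.reference_group:
                idx = lay.free_psi_groups.index(g)
                gp = lam @ alam
                if has_out:
                    gp += 2.0 * beta * (a[m, :m] @ lam) + beta * beta * a[m, m]
                grad[lay.sl_psi.start + idx] += w * gp
            # residual variances
            grad[lay.sl_theta[g]] += w * np.diag(a)[:m]
            if has_out:
                gb = 2.0 * psi * (a[m, :m] @ lam) + 2.0 * beta * psi * a[m, m]
                if spec.equal_regressions:
                    grad[lay.sl_beta.start] += w * gb
                else:
                    grad[lay.sl_beta.start + gi] += w * gb
                grad[lay.sl_zeta.start + gi] += w * a[m, m]
        return F, grad

    def value_grad(self, y: np.ndarray) -> tuple[float, np.ndarray]:
        """Objective in the transformed (log-variance) space."""
        x = self.layout.untransform(y)
        F, g_nat = self.value_grad_natural(x)
        g = g_nat.copy()
        g[self.layout.log_scale] *= x[self.layout.log_scale]
        return F, g


def _start_values(spec: SemSpec, data: GroupData) -> np.ndarray:
    """Natural-scale starting vector: principal-axis loadings, halved variances.

    The loading start is the first eigenvector of the pooled indicator
    covariance scaled by the root of its eigenvalue — this keeps the search
    away from the all-zero-loading saddle point of the discrepancy.
    """
    lay = _Layout(spec)
    m = lay.m
    x = np.empty(lay.size)
    pooled = np.zeros((m, m))
    for g in spec.groups:
        pooled += data.ns[g] * data.covs[g][:m, :m]
    pooled /= data.n_total
    pooled_var = np.diag(pooled)
    sd = np.sqrt(pooled_var)
    corr = pooled / np.outer(sd, sd)
    evals, evecs = np.linalg.eigh(corr)
    v1 = evecs[:, -1]
    if v1.sum() < 0:
        v1 = -v1
    lam0 = v1 * np.sqrt(max(evals[-1], 1e-8)) * sd
    # keep every start loading away from zero so no coordinate begins flat
    floor = 0.1 * sd
    lam0 = np.where(np.abs(lam0) < floor, floor, lam0)
    x[lay.sl_lam] = lam0
    x[lay.sl_psi] = 1.0
    for g in spec.groups:
        x[lay.sl_theta[g]] = np.maximum(0.5 * np.diag(data.covs[g])[:m], 1e-4)
    if spec.outcome is not None:
        betas = []
        for g in spec.groups:
            cov_out = data.covs[g][m, 0]
            betas.append(cov_out / max(lam0[0], 1e-8))
        if spec.equal_regressions:
            x[lay.sl_beta] = [float(np.mean(betas))]
        else:
            x[lay.sl_beta] = betas
        x[lay.sl_zeta] = [max(0.5 * data.covs[g][m, m], 1e-4) for g in spec.groups]
    return x


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class SemFit:
    """Result of a maximum-likelihood fit."""

    spec: SemSpec
    data: GroupData = field(repr=False)
    params: SemParams = field(repr=False)
    discrepancy: float
    statistic: float
    df: int
    p_value: float
    converged: bool
    n_iter: int
    grad_norm: float
    heywood: list[str] = field(default_factory=list)
    estimates: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_total(self) -> int:
        return self.data.n_total


def _parameter_table(
    spec: SemSpec,
    layout: _Layout,
    x_nat: np.ndarray,
    se_cov: np.ndarray | None,
    data: GroupData,
    params: SemParams,
) -> pd.DataFrame:
    rows = []
    for (kind, label), est in zip(layout.names, x_nat):
        se = np.nan if se_cov is None else se_cov[len(rows)]
        group = None
        name = kind
        if kind == "lambda":
            name = f"lambda[{label}]"
        elif kind == "psi":
            group = label
        elif kind == "theta":
            ind, group = label.split("|")
            name = f"theta[{ind}]"
        elif kind in ("beta", "zeta"):
            group = label
        rows.append((name, group, float(est), se))
    # fixed reference latent variance, for completeness
    rows.append(("psi", spec.reference_group, 1.0, np.nan))
    # saturated mean parameters with analytic SEs: cov(mean) = Sigma_hat / n_g
    moments = model_implied_moments(spec, params)
    m = layout.m
    for g in spec.groups:
        sigma, _ = moments[g]
        se_mu = np.sqrt(np.diag(sigma) / data.ns[g])
        for j, ind in enumerate(spec.indicators):
            rows.append((f"nu[{ind}]", g, float(data.means[g][j]), float(se_mu[j])))
        if spec.outcome is not None:
            rows.append(("iota", g, float(data.means[g][m]), float(se_mu[m])))
    tab = pd.DataFrame(rows, columns=["parameter", "group", "estimate", "se"])
    with np.errstate(divide="ignore", invalid="ignore"):
        tab["z"] = tab["estimate"] / tab["se"]
    tab["p_value"] = 2.0 * stats.norm.sf(np.abs(tab["z"]))
    return tab


def _observed_information_se(obj: _Objective, x_nat: np.ndarray) -> np.ndarray:
    """SEs of the covariance parameters from the observed information.

    The information is (N/2) times the Hessian of F in natural-scale
    parameters, evaluated by central differences of the analytic gradient.
    """
    n = x_nat.size
    hess = np.empty((n, n))
    for i in range(n):
        h = 1e-5 * max(1.0, abs(x_nat[i]))
        xp, xm = x_nat.copy(), x_nat.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = obj.value_grad_natural(xp)
        _, gm = obj.value_grad_natural(xm)
        hess[i] = (gp - gm) / (2.0 * h)
    hess = (hess + hess.T) / 2.0
    info = 0.5 * obj.N * hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        bad = [obj.layout.names[i] for i in np.flatnonzero(np.abs(info).sum(axis=1) < 1e-10)]
        raise np.linalg.LinAlgError(
            f"singular observed information; flat directions for parameters {bad}"
        )
    diag = np.diag(cov)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    return se


def _scale_factors(lay: _Layout, scales: np.ndarray) -> np.ndarray:
    """Per-parameter back-transform factors for observed-variable rescaling."""
    spec = lay.spec
    factor = np.ones(lay.size)
    factor[lay.sl_lam] = scales[: lay.m]
    for g in spec.groups:
        factor[lay.sl_theta[g]] = scales[: lay.m] ** 2
    if spec.outcome is not None:
        s_out = scales[lay.m]
        factor[lay.sl_beta] = s_out
        factor[lay.sl_zeta] = s_out**2
    return factor


def fit_ml(
    spec: SemSpec,
    data: GroupData,
    start: SemParams | None = None,
    compute_se: bool = True,
    max_restarts: int = 3,
) -> SemFit:
    """Fit the model by multivariate-normal maximum likelihood.

    Internally every observed variable is rescaled to pooled unit variance
    (ML is exactly equivariant under diagonal rescaling, so estimates are
    transformed back afterwards); this keeps the optimisation conditioning
    and the convergence check independent of the data's units.  Feeding
    moments that are exactly model-implied recovers the generating
    parameters with T = 0 (up to optimiser tolerance).  Non-convergence
    after deterministic restarts is reported via ``fit.converged``;
    Heywood (nonpositive) residual variances are listed in ``fit.heywood``.
    """
    lay_nat = _Layout(spec)
    p = spec.n_observed
    pooled_var = sum(data.ns[g] * np.diag(data.covs[g]) for g in data.groups) / data.n_total
    scales = np.sqrt(pooled_var)
    inv = 1.0 / scales
    data_std = GroupData(
        data.variables,
        data.groups,
        dict(data.ns),
        {g: data.means[g] * inv for g in data.groups},
        {g: data.covs[g] * np.outer(inv, inv) for g in data.groups},
    )
    factor = _scale_factors(lay_nat, scales)
    if start is not None:
        start = lay_nat.to_params(lay_nat.to_vector(start) / factor, data_std)
    fit = _fit_ml_raw(spec, data_std, start, compute_se, max_restarts)
    # map the standardized-metric solution back to the data's units
    x_nat = lay_nat.to_vector(fit.params) * factor
    params = lay_nat.to_params(x_nat, data)
    table = fit.estimates
    if table is not None:
        k = lay_nat.size
        table = table.copy()
        table.loc[: k - 1, "estimate"] = x_nat
        table.loc[: k - 1, "se"] = table.loc[: k - 1, "se"].to_numpy() * factor
        # mean parameters: recompute from the unscaled data
        table = _recompute_mean_rows(table, spec, lay_nat, data, params)
    return SemFit(
        spec=spec,
        data=data,
        params=params,
        discrepancy=fit.discrepancy,
        statistic=fit.statistic,
        df=fit.df,
        p_value=fit.p_value,
        converged=fit.converged,
        n_iter=fit.n_iter,
        grad_norm=fit.grad_norm,
        heywood=fit.heywood,
        estimates=table,
    )


def _recompute_mean_rows(
    table: pd.DataFrame,
    spec: SemSpec,
    lay: _Layout,
    data: GroupData,
    params: SemParams,
) -> pd.DataFrame:
    moments = model_implied_moments(spec, params)
    m = lay.m
    for g in spec.groups:
        sigma, _ = moments[g]
        se_mu = np.sqrt(np.diag(sigma) / data.ns[g])
        for j, ind in enumerate(spec.indicators):
            mask = (table.parameter == f"nu[{ind}]") & (table.group == g)
            table.loc[mask, ["estimate", "se"]] = [data.means[g][j], se_mu[j]]
        if spec.outcome is not None:
            mask = (table.parameter == "iota") & (table.group == g)
            table.loc[mask, ["estimate", "se"]] = [data.means[g][m], se_mu[m]]
    with np.errstate(divide="ignore", invalid="ignore"):
        table["z"] = table["estimate"] / table["se"]
    table["p_value"] = 2.0 * stats.norm.sf(np.abs(table["z"]))
    return table


def _fit_ml_raw(
    spec: SemSpec,
    data: GroupData,
    start: SemParams | None = None,
    compute_se: bool = True,
    max_restarts: int = 3,
) -> SemFit:
    """ML fit in the data's own metric (no internal rescaling)."""
    obj = _Objective(spec, data)
    lay = obj.layout
    if start is not None:
        starts = [lay.to_vector(start)]
    else:
        # two deterministic basins: principal-axis loadings, and flat 0.7*sd
        x0 = _start_values(spec, data)
        x_alt = x0.copy()
        pooled_sd = np.sqrt(
            sum(data.ns[g] * np.diag(data.covs[g])[: lay.m] for g in spec.groups)
            / data.n_total
        )
        x_alt[lay.sl_lam] = 0.7 * pooled_sd
        starts = [x0, x_alt]
    # deterministic perturbations appended in case no start converges
    for k in range(max_restarts):
        scale = 1.35 + 0.35 * k
        x_try = starts[0].copy()
        x_try[lay.sl_lam] *= scale
        x_try[lay.log_scale] = np.maximum(x_try[lay.log_scale] / scale, 1e-4)
        starts.append(x_try)

    best = None  # (not converged, F, gnorm, x_hat, nit); tuple order = preference
    for attempt, x_try in enumerate(starts):
        res = optimize.minimize(
            obj.value_grad,
            lay.transform(x_try),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9},
        )
        x_hat = lay.untransform(res.x)
        _, g_nat = obj.value_grad_natural(x_hat)
        gnorm = float(np.max(np.abs(g_nat)))
        cand = (gnorm >= _GTOL, res.fun, gnorm, x_hat, res.nit)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if attempt >= 1 and not best[0]:
            break  # a converged solution exists after trying both main starts
    _, F, gnorm, x_hat, nit = best
    converged = bool(np.isfinite(F)) and gnorm < _GTOL

    # sign convention: flip the factor so that the loadings are net positive
    if np.sum(x_hat[lay.sl_lam]) < 0:
        x_hat = x_hat.copy()
        x_hat[lay.sl_lam] *= -1.0
        if lay.sl_beta is not None:
            x_hat[lay.sl_beta] *= -1.0

    params = lay.to_params(x_hat, data)
    heywood = []
    for g in spec.groups:
        small = params.residual_variances[g] < _HEYWOOD_TOL
        heywood += [f"theta[{ind}]|{g}" for ind, s in zip(spec.indicators, small) if s]
        if spec.outcome is not None:
            if params.outcome_residual[g] < _HEYWOOD_TOL:
                heywood.append(f"zeta|{g}")
    if heywood:
        warnings.warn(f"Heywood case: nonpositive residual variances {heywood}", stacklevel=2)

    df = count_df(spec)
    T = obj.N * F
    p_value = float(stats.chi2.sf(T, df)) if df > 0 else 1.0
    se = None
    if compute_se and converged:
        try:
            se = _observed_information_se(obj, x_hat)
        except np.linalg.LinAlgError as err:
            warnings.warn(str(err), stacklevel=2)
    table = _parameter_table(spec, lay, x_hat, se, data, params)
    return SemFit(
        spec=spec,
        data=data,
        params=params,
        discrepancy=float(F),
        statistic=float(T),
        df=df,
        p_value=p_value,
        converged=converged,
        n_iter=int(nit),
        grad_norm=gnorm,
        heywood=heywood,
        estimates=table,
    )


# ---------------------------------------------------------------------------
# standardized solution, fit indices, nested tests
# ---------------------------------------------------------------------------

def standardized_solution(fit: SemFit) -> pd.DataFrame:
    """Completely standardized loadings and regression slopes, per group.

    Loadings are rescaled by sqrt(psi_g)/sd(indicator); the regression by
    sqrt(psi_g)/sd(outcome); all sds are model-implied.  Invariant to any
    rescaling of the observed variables.
    """
    spec, params = fit.spec, fit.params
    moments = model_implied_moments(spec, params)
    rows = []
    m = len(spec.indicators)
    for g in spec.groups:
        sigma, _ = moments[g]
        sd = np.sqrt(np.diag(sigma))
        if np.any(sd <= 0):
            raise ValueError(f"group {g!r}: zero implied variance")
        s_psi = np.sqrt(params.latent_variance[g])
        for j, ind in enumerate(spec.indicators):
            rows.append((f"lambda[{ind}]", g, params.loadings[j] * s_psi / sd[j]))
        if spec.outcome is not None:
            rows.append(("beta", g, params.regression[g] * s_psi / sd[m]))
        rows.append(("psi", g, params.latent_variance[g]))
    return pd.DataFrame(rows, columns=["parameter", "group", "value"])


def standardized_z_p(fit: SemFit) -> pd.DataFrame:
    """Standardized estimates joined with the raw-parameter z and p values.

    The z statistic is the quotient of the unstandardized estimate and its
    standard error; the standardized value is reported alongside it, which
    is how multi-group SEM results tables are conventionally printed.
    """
    std = standardized_solution(fit)
    est = fit.estimates.copy()
    est["key"] = est["parameter"] + "|" + est["group"].fillna("")
    lut_z = dict(zip(est["key"], est["z"]))
    lut_p = dict(zip(est["key"], est["p_value"]))
    out = std.copy()
    shared = {f"lambda[{ind}]" for ind in fit.spec.indicators}
    if fit.spec.equal_regressions:
        shared.add("beta")
    keys = [
        p + "|" + ("" if p in shared else g)
        for p, g in zip(out["parameter"], out["group"])
    ]
    out["z"] = [lut_z.get(k, np.nan) for k in keys]
    out["p_value"] = [lut_p.get(k, np.nan) for k in keys]
    return out


def baseline_fit(data: GroupData) -> SemFit:
    """Independence baseline: group-specific variances and means only.

    The MLE is closed-form (diagonal of each sample covariance), giving
    T = N * sum_g w_g (sum_j log s_jj - log|S_g|); the same value is reached
    by numerically minimising the engine's discrepancy over a diagonal model.
    """
    p = len(data.variables)
    N = data.n_total
    F = 0.0
    for g in data.groups:
        s = data.covs[g]
        sign, logdet = np.linalg.slogdet(s)
        F += (data.ns[g] / N) * (float(np.sum(np.log(np.diag(s)))) - logdet)
    moments = len(data.groups) * (p * (p + 1) // 2 + p)
    df = moments - 2 * p * len(data.groups)
    spec = SemSpec(indicators=data.variables[:2], groups=data.groups)  # placeholder spec
    dummy = SemParams(np.zeros(2), {g: 1.0 for g in data.groups},
                      {g: np.ones(2) for g in data.groups},
                      {g: np.zeros(2) for g in data.groups})
    T = N * F
    return SemFit(
        spec=spec,
        data=data,
        params=dummy,
        discrepancy=float(F),
        statistic=float(T),
        df=df,
        p_value=float(stats.chi2.sf(T, df)),
        converged=True,
        n_iter=0,
        grad_norm=0.0,
    )


def fit_indices(fit: SemFit, baseline: SemFit | None = None) -> dict[str, float]:
    """CFI, SRMR and RMSEA for a fitted model.

    CFI compares excess misfit against an independence baseline with free
    group-specific variances and means.  RMSEA carries the sqrt(G)
    multi-group scaling.  SRMR averages, over groups, the RMS of residual
    moments standardized by the sample standard deviations (mean residuals
    are identically zero here because the mean structure is saturated, but
    they count toward the number of moments).
    """
    if baseline is None:
        baseline = baseline_fit(fit.data)
    T, df, N = fit.statistic, fit.df, fit.n_total
    tb, dfb = baseline.statistic, baseline.df
    G = len(fit.data.groups)
    excess = max(T - df, 0.0)
    denom = max(tb - dfb, T - df, 0.0)
    cfi = 1.0 - (excess / denom if denom > 0 else 0.0)
    rmsea = float("nan") if df == 0 else np.sqrt(G) * np.sqrt(excess / (df * N))
    # SRMR
    moments = model_implied_moments(fit.spec, fit.params)
    p = len(fit.data.variables)
    srmr_groups = []
    for g in fit.data.groups:
        s = fit.data.covs[g]
        sigma, mu = moments[g]
        sd = np.sqrt(np.diag(s))
        scale = np.outer(sd, sd)
        iu = np.triu_indices(p)
        res_cov = ((s - sigma) / scale)[iu]
        res_mean = (fit.data.means[g] - mu) / sd
        resid = np.concatenate([res_cov, res_mean])
        srmr_groups.append(np.sqrt(np.mean(resid**2)))
    return {"cfi": float(cfi), "srmr": float(np.mean(srmr_groups)), "rmsea": float(rmsea)}


def chi_square_difference(fit_free: SemFit, fit_constrained: SemFit) -> dict[str, float]:
    """Likelihood-ratio test of the equality-constrained model against the free one."""
    sf, sc = fit_free.spec, fit_constrained.spec
    nested = (
        sf.indicators == sc.indicators
        and sf.outcome == sc.outcome
        and sf.groups == sc.groups
        and not sf.equal_regressions
        and sc.equal_regressions
    )
    if not nested:
        raise ValueError("constrained model is not nested in the free model")
    if fit_free.data is not fit_constrained.data:
        for g in sf.groups:
            if not (
                fit_free.data.ns[g] == fit_constrained.data.ns[g]
                and np.allclose(fit_free.data.covs[g], fit_constrained.data.covs[g])
            ):
                raise ValueError("the two fits use different data")
    delta = fit_constrained.statistic - fit_free.statistic
    if delta < -1e-6 * fit_free.n_total:
        warnings.warn(
            f"constrained chi-square below free chi-square by {-delta:.3e}; "
            "treating as 0 (convergence tolerance)",
            stacklevel=2,
        )
    delta = max(delta, 0.0)
    ddf = fit_constrained.df - fit_free.df
    return {
        "delta_chi2": float(delta),
        "delta_df": int(ddf),
        "p_value": float(stats.chi2.sf(delta, ddf)) if ddf > 0 else 1.0,
    }
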