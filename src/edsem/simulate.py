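"""Synthetic cohorts with the statistical structure the analysis assumes.

The study data (147 young adults: 91 healthy controls, 31 ADHD-I, 25
ADHD-C/H, with four questionnaire scales and resting-state graphs) are not
public, so this module generates stand-ins: a latent emotion-dysregulation
score per subject, questionnaire indicators loading on it, an optional
directly generated topology outcome per node, and parcellated time series
whose target-node clustering tracks the latent score.

Defaults encode the study's reported world: group sizes 91/31/25,
standardized loadings (0.909, 0.603, 0.546, 0.428), group latent variances
(0.300, 1, 0.340) with ADHD-I as the reference, the density-integrated
clustering regression pattern (0.091, -0.279, 0.844), and 266 timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import MotionSummary, SubjectTimeSeries
from .sem import SemParams, SemSpec

GROUPS: tuple[str, ...] = ("HC", "ADHD-I", "ADHD-C/H")
REFERENCE_GROUP = "ADHD-I"
INDICATORS: tuple[str, ...] = ("k10_distress", "sdq_emotional", "sdq_conduct", "cprs_lability")

#: completely standardized loadings of the four retained indicators
DEFAULT_LOADINGS: tuple[float, ...] = (0.909, 0.603, 0.546, 0.428)
#: latent variance per group, standardized to 1 in the reference group
DEFAULT_LATENT_VARIANCES: dict[str, float] = {"HC": 0.300, "ADHD-I": 1.0, "ADHD-C/H": 0.340}
#: standardized latent-to-topology regression slopes for the effect node
#: (density-integrated clustering of the right insula)
DEFAULT_EFFECT_BETAS: dict[str, float] = {"HC": 0.091, "ADHD-I": -0.279, "ADHD-C/H": 0.844}
DEFAULT_GROUP_SIZES: dict[str, int] = {"HC": 91, "ADHD-I": 31, "ADHD-C/H": 25}
DEFAULT_TIMEPOINTS = 266


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic cohort.

    All latent-model quantities are in the completely standardized metric of
    the reference group: indicator residual variances default to
    ``1 - loading**2`` and the outcome is generated with unit total variance
    in every group, so the requested regression slopes are the standardized
    slopes.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    loadings: tuple[float, ...] = DEFAULT_LOADINGS
    latent_variances: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_VARIANCES)
    )
    effect_betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_BETAS))
    indicators: tuple[str, ...] = INDICATORS
    residual_variances: tuple[float, ...] | None = None  # default 1 - loading^2
    reference_group: str = REFERENCE_GROUP
    n_timepoints: int = DEFAULT_TIMEPOINTS
    n_parcels: int = 70
    target_node: str = "parcel_01"
    # coupling and background density are set by a calibration run (see the
    # methods note): with 70 parcels and 266 timepoints these defaults give a
    # correlation of ~0.5 between the pipeline-estimated density-integrated
    # clustering of the target node and the true latent score at n = 150
    coupling: float = 4.0  # logistic slope for neighbour-edge probability vs latent
    base_density: float = 0.05  # density of the background truth graph
    ar_coef: float = 0.0  # temporal autocorrelation of the noise, off by default

    def __post_init__(self) -> None:
        if self.residual_variances is None:
            self.residual_variances = tuple(1.0 - l * l for l in self.loadings)
        if len(self.residual_variances) != len(self.loadings):
            raise ValueError("residual_variances must match loadings")
        if len(self.indicators) != len(self.loadings):
            raise ValueError("indicators must match loadings")
        if any(v <= 0 for v in self.latent_variances.values()):
            raise ValueError("latent variances must be positive")
        if any(abs(b) >= 1 for b in self.effect_betas.values()):
            raise ValueError("standardized regression slopes must satisfy |beta| < 1")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("each group needs at least 2 subjects")
        if abs(self.latent_variances[self.reference_group] - 1.0) > 1e-12:
            raise ValueError("reference-group latent variance must be 1")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_sizes)

    def spec(self, outcome: str | None = None) -> SemSpec:
        return SemSpec(
            indicators=self.indicators,
            groups=self.groups,
            outcome=outcome,
            reference_group=self.reference_group,
        )

    def true_params(self, outcome_betas: dict[str, float] | None = None) -> SemParams:
        """Generating values as a :class:`SemParams` (intercepts all zero)."""
        m = len(self.loadings)
        lam = np.asarray(self.loadings, dtype=float)
        theta = np.asarray(self.residual_variances, dtype=float)
        params = SemParams(
            loadings=lam,
            latent_variance=dict(self.latent_variances),
            residual_variances={g: theta.copy() for g in self.groups},
            intercepts={g: np.zeros(m) for g in self.groups},
        )
        if outcome_betas is not None:
            # unstandardized slope so that the outcome has unit variance and
            # the standardized slope equals the requested value
            params.regression = {
                g: outcome_betas[g] / np.sqrt(self.latent_variances[g]) for g in self.groups
            }
            params.outcome_residual = {
                g: 1.0 - outcome_betas[g] ** 2 for g in self.groups
            }
            params.outcome_intercept = {g: 0.0 for g in self.groups}
        return params


def study_proportion_sizes(n_total: int) -> dict[str, int]:
    """Split ``n_total`` subjects across groups in the study's 91:31:25 ratio
    (largest-remainder rounding so the sizes sum exactly to ``n_total``)."""
    total_ref = sum(DEFAULT_GROUP_SIZES.values())
    exact = {g: n_total * n / total_ref for g, n in DEFAULT_GROUP_SIZES.items()}
    sizes = {g: int(np.floor(v)) for g, v in exact.items()}
    leftover = n_total - sum(sizes.values())
    for g in sorted(exact, key=lambda g: exact[g] - sizes[g], reverse=True)[:leftover]:
        sizes[g] += 1
    return sizes


def generate_phenotypes(
    config: CohortConfig,
    seed: int,
    outcome_nodes: dict[str, dict[str, float]] | None = None,
    outcome_standardized: bool = True,
) -> pd.DataFrame:
    """Subject table: group, latent score, indicators, optional outcomes.

    Per subject, eta ~ Normal(0, psi_g); indicator_j = loading_j * eta +
    Normal(0, theta_j).  If ``outcome_nodes`` maps node names to per-group
    slopes, one outcome column per node is added (column name = node).  With
    ``outcome_standardized`` (default) the slopes are *completely
    standardized* values and the outcome has unit total variance per group;
    note that with unequal group latent variances, equal standardized slopes
    imply *unequal* raw regression slopes.  With
    ``outcome_standardized=False`` the slopes are the raw regression
    coefficients on the latent (t = beta_g * eta + Normal(0, 1)), which is
    the scale on which the equality constraint of the chi-square difference
    test operates — use this to generate an exactly beta-equal null world.
    The true latent score is returned in column ``eta`` for validation.
    """
    rng = np.random.default_rng(seed)
    lam = np.asarray(config.loadings, dtype=float)
    theta_sd = np.sqrt(np.asarray(config.residual_variances, dtype=float))
    rows = []
    for g in config.groups:
        n = config.group_sizes[g]
        psi = config.latent_variances[g]
        eta = rng.normal(0.0, np.sqrt(psi), size=n)
        eps = rng.normal(0.0, 1.0, size=(n, lam.size)) * theta_sd
        indicators = eta[:, None] * lam + eps
        block = pd.DataFrame(indicators, columns=list(config.indicators))
        block.insert(0, "group", g)
        block.insert(1, "eta", eta)
        if outcome_nodes:
            for node, betas in outcome_nodes.items():
                if outcome_standardized:
                    b_std = betas[g]
                    noise = rng.normal(0.0, np.sqrt(1.0 - b_std**2), size=n)
                    block[node] = b_std * eta / np.sqrt(psi) + noise
                else:
                    block[node] = betas[g] * eta + rng.normal(0.0, 1.0, size=n)
        rows.append(block)
    table = pd.concat(rows, ignore_index=True)
    table.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(len(table))])
    return table


def _truth_graph(
    config: CohortConfig, eta: float, psi: float, rng: np.random.Generator
) -> nx.Graph:
    """Background random graph plus latent-coupled triangles around the target.

    The target node gets a fixed neighbourhood; edges *among* its neighbours
    are switched on with probability logistic(coupling * eta/sd(eta)), so the
    target's clustering coefficient increases monotonically with the latent
    score.
    """
    n = config.n_parcels
    parcels = [f"parcel_{i:02d}" for i in range(1, n + 1)]
    g = nx.Graph()
    g.add_nodes_from(parcels)
    target = config.target_node
    others = [p for p in parcels if p != target]
    # fixed-size neighbourhood; kept small because the positive-definiteness
    # cap on the covariance scale shrinks with the neighbourhood's spectral
    # radius, diluting the per-edge correlations the pipeline must detect
    k_nbrs = max(6, int(0.12 * n))
    nbrs = others[:k_nbrs]
    for p in nbrs:
        g.add_edge(target, p)
    # latent-coupled edges among the target's neighbours
    z = config.coupling * eta / np.sqrt(psi)
    p_edge = 1.0 / (1.0 + np.exp(-z))
    for i in range(len(nbrs)):
        for j in range(i + 1, len(nbrs)):
            if rng.random() < p_edge:
                g.add_edge(nbrs[i], nbrs[j])
    # background wiring among the remaining pairs
    rest = [p for p in others if p not in nbrs]
    for i in range(len(rest)):
        for j in range(i + 1, len(rest)):
            if rng.random() < config.base_density:
                g.add_edge(rest[i], rest[j])
    for p in rest:
        for q in nbrs:
            if rng.random() < config.base_density:
                g.add_edge(p, q)
    return g


def generate_timeseries_cohort(
    config: CohortConfig,
    seed: int,
) -> tuple[list[SubjectTimeSeries], list[MotionSummary], pd.DataFrame, dict[str, nx.Graph]]:
    """Phenotypes plus per-subject time series and ground-truth graphs.

    Each subject's time series are draws from N(0, c*A + I) where A is the
    adjacency matrix of the subject's truth graph; c is reduced automatically
    if needed to keep the covariance positive definite.  Pearson correlations
    of the series are therefore elevated exactly on the truth edges, so
    thresholding recovers the planted topology up to sampling noise.
    Motion summaries are all below the exclusion threshold by default.
    """
    rng = np.random.default_rng(seed)
    phenotypes = generate_phenotypes(config, seed=int(rng.integers(2**31)))
    series: list[SubjectTimeSeries] = []
    motion: list[MotionSummary] = []
    truth: dict[str, nx.Graph] = {}
    parcels = tuple(f"parcel_{i:02d}" for i in range(1, config.n_parcels + 1))
    for row in phenotypes.itertuples(index=False):
        g_truth = _truth_graph(config, row.eta, config.latent_variances[row.group], rng)
        a = nx.to_numpy_array(g_truth, nodelist=parcels)
        c = 0.6
        lam_max = float(np.linalg.eigvalsh(a)[-1])
        if lam_max > 0 and c * lam_max >= 0.95:
            c = 0.95 / lam_max
        cov = c * a + np.eye(config.n_parcels)
        chol = np.linalg.cholesky(cov)
        noise = rng.standard_normal((config.n_parcels, config.n_timepoints))
        if config.ar_coef:
            for t in range(1, config.n_timepoints):
                noise[:, t] += config.ar_coef * noise[:, t - 1]
        data = chol @ noise
        series.append(SubjectTimeSeries(row.subject_id, data, parcels))
        motion.append(MotionSummary(row.subject_id, float(rng.uniform(0.02, 0.20))))
        truth[row.subject_id] = g_truth
    return series, motion, phenotypes, truth


def toy_graph_fixtures() -> dict[str, nx.Graph]:
    """Named small graphs used across the test suites.

    ``example4`` is the 4-node graph with edges {01, 02, 12, 13} whose node 1
    has clustering and local efficiency exactly 1/3.
    """
    example4 = nx.Graph([(0, 1), (0, 2), (1, 2), (1, 3)])
    two_edges = nx.Graph([(0, 1), (2, 3)])
    return {
        "K3": nx.complete_graph(3),
        "K4": nx.complete_graph(4),
        "K5": nx.complete_graph(5),
        "star4": nx.star_graph(3),  # centre 0 plus 3 leaves
        "P3": nx.path_graph(3),
        "P4": nx.path_graph(4),
        "C4": nx.cycle_graph(4),
        "C5": nx.cycle_graph(5),
        "example4": example4,
        "two_edges": two_edges,
    }
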