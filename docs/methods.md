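# Methods

This note documents the models, conventions and numerical choices behind
`edsem`, in the spirit of the methods documentation of packages like
statsmodels or msprime: enough detail to reproduce or audit every number
the library computes.

## 1. Connectivity graphs

**Correlation and transform.** For each subject the parcels × timepoints
matrix yields pairwise Pearson correlations; a parcel with zero variance is
an error (named in the message), not a silent NaN. The connectivity weight
is `|atanh(r)|`; since `|atanh(r)| = atanh(|r|)` the order of absolute value
and transform is immaterial (asserted numerically in the tests).
Correlations are clipped to `±(1 − 1e-7)` before `atanh` so collinear
parcels — which synthetic data can produce — give a large finite weight
rather than infinity. Self-correlations are excluded everywhere.

**Density thresholding.** At density `d` on `n` nodes exactly
`k = round(d·n(n−1)/2)` edges are kept (round half away from zero; the
discretisation is not dictated by the statistics, only by the need to be
exact and consistent). Pairs are ranked by weight descending with ties
broken by lexicographic node-pair order; because every density slices the
same ranking, graphs are *nested* across densities even under heavy ties.
A request yielding zero edges is an error. Default densities are the seven
equally spaced values 0.10–0.40.

**Selection rules.** Subjects are retained iff RMS framewise displacement
≤ 0.25 mm (the boundary is assigned to retention; FD is an input, not
computed, since realignment-parameter conventions vary). Nodes are parcels
with anatomical overlap strictly greater than 0.30 ("more than 30%").
Thresholding operates by default on the matrix restricted to the selected
nodes (`threshold_scope="selected"`); thresholding the full matrix first
and restricting afterwards is available (`"all"`), in which case per-graph
edge counts become data dependent.

## 2. Nodal topology measures

Definitions on simple undirected binary graphs, with conventions for
disconnected graphs chosen to match the standard graph library:

- clustering `C_i = 2T_i/(k_i(k_i−1))`, zero for degree < 2;
- local efficiency = global efficiency of the neighbour-induced subgraph
  (mean over neighbour pairs of inverse within-subgraph distance,
  `1/∞ = 0`), zero for degree < 2;
- nodal efficiency `E_i = (1/(n−1)) Σ_{j≠i} 1/d(i,j)`, unreachable pairs
  contribute zero;
- betweenness: Brandes accumulation with equal weight over multiple
  shortest paths, endpoints not counted, normalised by `(n−1)(n−2)/2`;
- closeness: component-scaled (Wasserman–Faust)
  `((r−1)/(n−1))·((r−1)/Σd)` with `r` the reachable-set size; zero for
  isolates;
- eigenvector centrality: entrywise-nonnegative dominant eigenvector of
  the adjacency matrix, L2-normalised. Computed by power iteration on
  `A + I` from a uniform start — the shift leaves the dominant eigenvector
  unchanged and guarantees convergence on bipartite components, where plain
  iteration on `A` oscillates. The stopping rule converts the iterate
  change into an error forecast (change divided by `1 − ρ`, with ρ the
  estimated geometric rate), target 1e-10, cap 10 000 iterations,
  non-convergence is an error with diagnostics. On disconnected graphs
  mass concentrates on the component with the largest spectral radius; when
  two components tie, any unit nonnegative vector in the dominant
  eigenspace is a valid answer (the test oracle checks eigenspace
  membership, which is the well-posed form of the comparison).

**Density integration** is the plain mean across the (equally spaced)
density levels; at equal spacing the normalised integral reduces to this.

The study's verbal description of closeness ("how many of the possible
direct connections exist") actually describes degree; the standard
closeness definition is implemented and the discrepancy documented here,
not resolved. Whether the original analysis normalised betweenness and
closeness is unknown; normalisation only rescales, and the SEM's
completely standardized solution is invariant to it.

## 3. The SEM engine

**Model family.** One latent factor, `m` indicators with loadings shared
across groups, optional observed outcome regressed on the latent with a
group-specific (or equality-constrained) slope; all intercepts and residual
variances group-specific; latent mean 0 everywhere; latent variance fixed
to 1 in a reference group (ADHD-I by default, the group the study reports
with standardized variance exactly 1) and free elsewhere. For three groups
and four indicators this gives 39 free parameters against 60 moments —
df = 21 free, df = 23 with the slope shared, Δdf = 2.

**Estimation.** Normal-theory ML on group means and covariances with
covariance divisor `n_g` and `T = N·F` (the convention of the SEM software
the field uses, so df and χ² line up). Because every mean is a free
intercept the mean structure is saturated: the intercept MLEs are the
sample means exactly, the mean term of `F` vanishes at the optimum, and the
optimiser searches only the covariance parameters. The intercepts still
count as free parameters in the df bookkeeping. Before optimisation every
observed variable is rescaled to pooled unit variance and estimates are
transformed back afterwards — ML is exactly equivariant under diagonal
rescaling, so this changes nothing statistically while making conditioning
and the convergence check unit-free (and the standardized solution
scale-invariant to numerical precision, which is tested).

**Optimiser.** L-BFGS-B on a vector with latent variances
log-parameterised and everything else on the identity scale, analytic
gradients throughout
(`dF = Σ_g w_g tr[Σ_g^{-1}(Σ_g − S_g)Σ_g^{-1} dΣ_g]`). Residual variances
are deliberately *not* log-parameterised: Heywood solutions (nonpositive
residual variances) are representable, flagged in `fit.heywood` and warned
about, never silently truncated — matching standard SEM practice. A trial
step outside the positive-definite region returns a large finite penalty
so the line search retreats (`F` itself diverges at the boundary).
Two deterministic starts are tried — principal-axis loadings from the
pooled *correlation* matrix (the covariance version is dominated by
high-variance noise indicators), and flat `0.7·sd` loadings — plus scaled
perturbations if neither converges; the best converged solution wins.
Convergence: max-abs natural-scale gradient < 1e-6. The loading-vector
sign is normalised to a net-positive factor. On hard small-sample
configurations (six indicators, n = 147, weak loadings) about 2–3% of
replicates still fail to converge or sit on a boundary; the scan records
such cells rather than aborting.

**Standard errors** come from the observed information: the numerical
Hessian (central differences of the analytic gradient) of `(N/2)·F` at the
optimum, inverted; intercept SEs are the analytic `sqrt(Σ̂_jj/n_g)`
(information is block-diagonal between mean and covariance parameters at
the MLE). `z = estimate/SE` with two-sided normal p-values. Wald coverage
is verified by simulation over proper solutions; on the boundary
(Heywood) Wald theory does not apply and such replicates are excluded from
the coverage check.

**Standardized solution.** Loadings are multiplied by `sqrt(psi_g)` and
divided by the model-implied indicator SD; the regression slope by
`sqrt(psi_g)/sd(outcome)`. With the generator's defaults the standardized
loadings in the reference group equal the raw loadings, which is the
convention used when reporting recovery of the study's printed values.

**Fit indices.** Baseline for CFI: the independence model with
group-specific variances and means; its MLE is closed-form (the diagonal of
each sample covariance), which a test verifies against a numerical
minimisation of the same discrepancy. `CFI = 1 − max(T−df,0)/max(T_b−df_b,
T−df, 0)`; `RMSEA = sqrt(G)·sqrt(max(T−df,0)/(df·N))` (the multi-group
scaling); SRMR is the unweighted mean over groups of the RMS of residual
moments standardized by sample SDs, counting the mean residuals (which are
identically zero here) in the denominator.

**χ² difference test.** `Δχ² = T_constrained − T_free` (clamped at zero
within convergence tolerance, warned if meaningfully negative), `Δdf` from
the df difference, p from the χ² distribution. Nesting is verified
structurally. Whether the original analysis scaled by `N` or `N−G` is not
documented; `N` is used, matching the cited software's default.

## 4. Group analysis

Indicator selection fits the multi-group CFA to all candidates and retains
indicators with loading `p < α` (α = 0.05), then refits; fewer than three
retained indicators is an error (the factor would be under-identified).

The scan fits, per node × measure, the free-slope and shared-slope models
on the density-integrated outcome. FDR families: all integrated-level
difference-test p-values form one Benjamini–Hochberg family; the
per-density p-values of a given node × measure form their own family.
Gatekeeping: per-density results are computed and logged for every cell but
flagged significant only where the integrated-level test survives — by
default on the FDR-adjusted p (`gate_on_adjusted=False` switches to raw).
Post-hoc two-group models (each pair, Δdf = 1, p × 3 Bonferroni) run where
the integrated omnibus is significant. Non-convergent cells are recorded
with `converged=False` and NaN statistics; the scan continues. The
robustness check on overall connectivity strength is a Kruskal–Wallis test
(the field's default rank-based omnibus; the original analysis names no test),
cross-checked against a permutation oracle in the tests.

## 5. Synthetic cohorts

`generate_phenotypes` draws, per subject, `eta ~ N(0, psi_g)` and
indicators `lambda_j·eta + N(0, theta_j)` in the completely standardized
metric of the reference group (defaults: loadings 0.909/0.603/0.546/0.428,
`theta = 1 − lambda²`, psi = 0.300/1/0.340, group sizes 91/31/25). Outcome
columns can be generated with *standardized* slopes (unit outcome variance
per group; note equal standardized slopes imply unequal raw slopes when
latent variances differ) or with *raw* slopes
(`outcome_standardized=False`), which is the scale the equality-constraint
test operates on and therefore the correct null world for calibration
studies. The default effect pattern 0.091/−0.279/0.844 is the study's
density-integrated clustering row. Raw questionnaire scores are not
modelled (the study reports only sum-score means/SDs); everything lives in
the standardized metric.

`generate_timeseries_cohort` builds, per subject, a ground-truth binary
graph: the target node has a fixed neighbourhood (`max(6, 0.12·n)` nodes);
edges *among* the neighbours switch on with probability
`logistic(coupling·eta/sd(eta))`, so the target's true clustering increases
monotonically with the latent score (r ≈ 0.9 at the defaults); background
pairs connect with probability `base_density = 0.05`. Time series of 266
timepoints are drawn from `N(0, c·A + I)` with `c = 0.6` reduced
automatically per subject to `0.95/λ_max(A)` to keep the covariance
positive definite. This PD cap is the binding constraint on the design:
the achievable on-edge correlation scales as `1/λ_max`, so the
neighbourhood is kept small and the background sparse. A calibration run
(150 subjects, 70 parcels, seed 1) with these defaults gives a correlation
of ≈ 0.55 between the pipeline-estimated density-integrated clustering of
the target node and the true latent score; across seeds the value varies
roughly between 0.4 and 0.6, the ceiling being Pearson estimation noise at
266 timepoints, not the coupling. Noise is white in time by default
(`ar_coef` adds optional AR(1) colour); the analysis consumes only Pearson
correlations, which this model exercises fully. No haemodynamics, motion
artefacts or site effects are simulated — a green pipeline test
establishes statistical, not physiological, fidelity.

## 6. What the acceptance computations establish

The study's subject-level results are not reproducible without its
(non-public) data. The recovery studies therefore establish a weaker but
checkable claim: cohorts *generated from* the printed estimates give them
back, through this implementation, at the stated precision — mean
standardized loadings within ±0.02, the healthy-control latent variance
within ±0.03, the ADHD-C/H slope within ±0.03; the difference test holds
its nominal level (checked at n = 500/group, where the asymptotic χ²
reference is accurate; at the study's own n = 147 the type-I rate is
mildly inflated, ≈ 0.07 — a known property of likelihood-ratio tests at
small samples, worth remembering when interpreting the original p-values);
and a planted effect with the study's slope pattern is the top FDR hit in
≥ 90% of scans at 4× the study's sample size.

## 7. Known limitations

- Only the one-factor(+outcome) model family is supported — no general SEM
  syntax, no categorical indicators, no missing-data FIML, no
  Satorra–Bentler corrections, no mediation models.
- Weighted-graph metric variants and community detection are out of scope;
  so is any fMRI preprocessing (the pipeline starts at parcellated series).
- The time-series generator's covariance construction cannot produce
  realistically dense, strongly correlated networks (see the PD cap
  above); it is adequate for validating the pipeline's statistics, not for
  emulating empirical connectomes.
- Roughly 2–3% of small-sample fits on weak-structure data end
  non-converged or at a Heywood boundary; downstream code must (and does)
  treat such cells explicitly.
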