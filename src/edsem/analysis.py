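"""The study's inference pipeline on top of the SEM engine.

Indicator selection by multi-group CFA, the node x measure SEM scan with
chi-square difference tests (group-specific vs shared latent-to-topology
regression), density-integrated gatekeeping, Benjamini-Hochberg FDR,
post-hoc pairwise two-group models with Bonferroni correction, and the
overall-connectivity robustness check.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import INTEGRATED
from .sem import (
    GroupData,
    SemFit,
    SemSpec,
    baseline_fit,
    chi_square_difference,
    fit_indices,
    fit_ml,
    standardized_z_p,
)

DEFAULT_ALPHA = 0.05
_PAIR_COUNT = 3  # Bonferroni factor: number of group pairs


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class CfaSelection:
    """Outcome of the indicator-selection CFA."""

    retained: list[str]
    dropped: list[str]
    loadings: pd.DataFrame  # indicator, estimate, z, p_value, retained
    initial_fit: SemFit = field(repr=False)
    final_fit: SemFit = field(repr=False)


def select_indicators(
    phenotypes: pd.DataFrame,
    candidates: list[str],
    groups: tuple[str, ...],
    reference_group: str,
    alpha: float = DEFAULT_ALPHA,
    group_col: str = "group",
) -> CfaSelection:
    """Retain indicators whose shared loading is significant in a multi-group CFA.

    A CFA with loadings shared across groups and the latent variance fixed
    to 1 in the reference group is fitted to all candidates; indicators with
    loading p >= alpha are discarded and the model is refitted on the
    retained set.  Fewer than 3 retained indicators leave the latent factor
    under-identified and raise an error.
    """
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate indicators")
    spec = SemSpec(indicators=tuple(candidates), groups=groups, reference_group=reference_group)
    data = GroupData.from_frame(phenotypes, spec.variables, group_col, groups)
    initial = fit_ml(spec, data)
    est = initial.estimates
    rows = []
    for ind in candidates:
        row = est.loc[est["parameter"] == f"lambda[{ind}]"].iloc[0]
        rows.append((ind, row["estimate"], row["z"], row["p_value"]))
    table = pd.DataFrame(rows, columns=["indicator", "estimate", "z", "p_value"])
    table["retained"] = table["p_value"] < alpha
    retained = list(table.loc[table["retained"], "indicator"])
    dropped = [c for c in candidates if c not in retained]
    if len(retained) < 3:
        raise ValueError(
            f"only {len(retained)} indicators retained; latent factor under-identified"
        )
    final_spec = SemSpec(indicators=tuple(retained), groups=groups, reference_group=reference_group)
    final_data = GroupData.from_frame(phenotypes, final_spec.variables, group_col, groups)
    final = fit_ml(final_spec, final_data)
    return CfaSelection(retained, dropped, table, initial, final)


def _fit_cell(
    spec_free: SemSpec,
    frame: pd.DataFrame,
    outcome: str,
    group_col: str,
    compute_se: bool,
) -> dict:
    """Free and shared-regression fits plus difference test for one scan cell."""
    data = GroupData.from_frame(frame, spec_free.variables, group_col, spec_free.groups)
    free = fit_ml(spec_free, data, compute_se=compute_se)
    constrained = fit_ml(spec_free.constrained(), data, compute_se=False)
    diff = chi_square_difference(free, constrained)
    indices = fit_indices(free, baseline_fit(data))
    out = {
        "chi2": free.statistic,
        "df": free.df,
        "p_model": free.p_value,
        "cfi": indices["cfi"],
        "srmr": indices["srmr"],
        "rmsea": indices["rmsea"],
        "delta_chi2": diff["delta_chi2"],
        "delta_df": diff["delta_df"],
        "p_diff": diff["p_value"],
        "converged": free.converged and constrained.converged,
    }
    if compute_se:
        std = standardized_z_p(free)
        for g in spec_free.groups:
            brow = std.loc[(std["parameter"] == "beta") & (std["group"] == g)].iloc[0]
            key = g.replace("/", "").replace("-", "_")
            out[f"beta_{key}"] = brow["value"]
            out[f"z_{key}"] = brow["z"]
            out[f"p_{key}"] = brow["p_value"]
    return out, free


def run_node_scan(
    metrics: pd.DataFrame,
    phenotypes: pd.DataFrame,
    indicators: list[str],
    nodes: list | None = None,
    measures: list[str] | None = None,
    densities: list[float] | None = None,
    groups: tuple[str, ...] | None = None,
    reference_group: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    gate_on_adjusted: bool = True,
    posthoc: bool = True,
    compute_se: bool = True,
    group_col: str = "group",
) -> pd.DataFrame:
    """The node x measure SEM scan with integrated-level gatekeeping.

    For every node x measure the density-integrated value is the outcome of
    a three-group model fitted twice (group-specific vs shared regression);
    the chi-square difference p-values form one FDR family across all
    integrated cells.  Per-density results are then computed for every cell
    and logged, but flagged significant only where the integrated-level test
    survives (FDR-adjusted by default); each cell's per-density p-values are
    FDR-adjusted as their own family.  Post-hoc pairwise two-group models
    (Bonferroni x3) run where the integrated omnibus is significant.

    ``metrics`` is the long table from :func:`edsem.metrics.metric_table`;
    ``phenotypes`` has one row per subject with the indicator columns.
    Non-convergent cells are reported with ``converged = False`` rather than
    aborting the scan.
    """
    if nodes is None:
        nodes = list(pd.unique(metrics["node"]))
    if measures is None:
        measures = list(pd.unique(metrics["measure"]))
    if groups is None:
        groups = tuple(pd.unique(phenotypes[group_col]))
    if reference_group is None:
        reference_group = groups[0]
    pheno = phenotypes.set_index("subject_id")
    spec_free = SemSpec(
        indicators=tuple(indicators),
        groups=groups,
        outcome="_topology",
        reference_group=reference_group,
    )

    wide = metrics.pivot_table(
        index="subject_id", columns=["node", "measure", "density"], values="value", sort=False
    )

    def cell_frame(node, measure, density):
        col = wide[(node, measure, density)]
        frame = pheno.loc[col.index, [group_col, *indicators]].copy()
        frame["_topology"] = col.to_numpy()
        return frame.reset_index()

    # pass 1: density-integrated level, one FDR family across cells
    integrated_rows = []
    free_fits = {}
    for node, measure in itertools.product(nodes, measures):
        try:
            res, free = _fit_cell(spec_free, cell_frame(node, measure, INTEGRATED),
                                  "_topology", group_col, compute_se)
            free_fits[(node, measure)] = free
        except Exception as err:  # pragma: no cover - defensive per-cell guard
            warnings.warn(f"scan cell ({node}, {measure}) failed: {err}", stacklevel=2)
            res = {"converged": False, "p_diff": np.nan, "reason": str(err)}
        integrated_rows.append({"node": node, "measure": measure, "density": INTEGRATED, **res})
    integrated = pd.DataFrame(integrated_rows)
    ok = integrated["p_diff"].notna()
    integrated["p_diff_fdr"] = np.nan
    integrated.loc[ok, "p_diff_fdr"] = fdr_adjust(integrated.loc[ok, "p_diff"])
    gate_col = "p_diff_fdr" if gate_on_adjusted else "p_diff"
    integrated["significant"] = integrated[gate_col] < alpha

    # pass 2: per-density results, own FDR family per cell, gated significance
    density_rows = []
    if densities:
        for row in integrated.itertuples(index=False):
            gate_open = bool(row.significant)
            cell = []
            for d in densities:
                try:
                    res, _ = _fit_cell(spec_free, cell_frame(row.node, row.measure, d),
                                       "_topology", group_col, compute_se)
                except Exception as err:  # pragma: no cover
                    warnings.warn(
                        f"scan cell ({row.node}, {row.measure}, {d}) failed: {err}",
                        stacklevel=2,
                    )
                    res = {"converged": False, "p_diff": np.nan, "reason": str(err)}
                cell.append({"node": row.node, "measure": row.measure, "density": d, **res})
            cell_df = pd.DataFrame(cell)
            okc = cell_df["p_diff"].notna()
            cell_df["p_diff_fdr"] = np.nan
            cell_df.loc[okc, "p_diff_fdr"] = fdr_adjust(cell_df.loc[okc, "p_diff"])
            cell_df["significant"] = gate_open & (cell_df[gate_col] < alpha)
            density_rows.append(cell_df)

    result = pd.concat([integrated, *density_rows], ignore_index=True)

    # post-hoc pairwise models where the integrated omnibus survives
    if posthoc:
        pair_cols = {}
        for row in integrated.loc[integrated["significant"]].itertuples(index=False):
            frame = cell_frame(row.node, row.measure, INTEGRATED)
            pairs = posthoc_pairwise(
                frame, indicators, "_topology", groups, reference_group, group_col
            )
            for pair_row in pairs.itertuples(index=False):
                key = f"posthoc[{pair_row.pair}]"
                pair_cols.setdefault(key, {})[(row.node, row.measure, INTEGRATED)] = (
                    pair_row.p_bonferroni
                )
        for key, values in pair_cols.items():
            result[key] = [
                values.get((r.node, r.measure, r.density), np.nan)
                for r in result.itertuples(index=False)
            ]
    return result


def posthoc_pairwise(
    frame: pd.DataFrame,
    indicators: list[str],
    outcome: str,
    groups: tuple[str, ...],
    reference_group: str,
    group_col: str = "group",
) -> pd.DataFrame:
    """Two-group regression-equality tests for every group pair, Bonferroni x3.

    Each pair's model is the two-group analogue of the omnibus model; the
    chi-square difference test has one degree of freedom and its p-value is
    multiplied by the number of pairs (capped at 1).
    """
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        pair_groups = (ga, gb)
        ref = reference_group if reference_group in pair_groups else ga
        spec = SemSpec(
            indicators=tuple(indicators),
            groups=pair_groups,
            outcome=outcome,
            reference_group=ref,
        )
        sub = frame.loc[frame[group_col].isin(pair_groups)]
        data = GroupData.from_frame(sub, spec.variables, group_col, pair_groups)
        free = fit_ml(spec, data, compute_se=False)
        constrained = fit_ml(spec.constrained(), data, compute_se=False)
        diff = chi_square_difference(free, constrained)
        rows.append(
            {
                "pair": f"{ga} vs {gb}",
                "delta_chi2": diff["delta_chi2"],
                "delta_df": diff["delta_df"],
                "p_value": diff["p_value"],
                "p_bonferroni": min(diff["p_value"] * _PAIR_COUNT, 1.0),
                "converged": free.converged and constrained.converged,
            }
        )
    return pd.DataFrame(rows)


def overall_connectivity_test(
    mean_connectivity: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> dict[str, float]:
    """Rank-based omnibus test (Kruskal-Wallis) of group differences in
    overall connectivity strength — the robustness check that group effects
    in topology are not mere differences in connectivity magnitude."""
    values = np.asarray(mean_connectivity, dtype=float)
    labels = np.asarray(groups)
    samples = []
    for g in pd.unique(labels):
        sample = values[labels == g]
        if sample.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        samples.append(sample)
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    stat, p = stats.kruskal(*samples)
    return {"statistic": float(stat), "p_value": float(p), "n_groups": len(samples)}
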