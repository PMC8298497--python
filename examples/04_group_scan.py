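"""The node x measure scan with FDR control and post-hoc pairwise models.

One effect node (the study's integrated-clustering slope pattern) is hidden
among null nodes; the scan fits free- and shared-slope models per node,
FDR-adjusts the difference-test p-values, and runs Bonferroni-corrected
two-group post-hoc models where the omnibus test survives.
"""

import pandas as pd

from edsem import CohortConfig, generate_phenotypes, run_node_scan, select_indicators
from edsem.simulate import DEFAULT_EFFECT_BETAS, GROUPS

cfg = CohortConfig(group_sizes={"HC": 364, "ADHD-I": 124, "ADHD-C/H": 100})  # 4x study n
nodes = ["insula_R", "null_a", "null_b", "null_c", "null_d", "null_e"]
betas = {"insula_R": DEFAULT_EFFECT_BETAS}
betas.update({n: {g: 0.0 for g in GROUPS} for n in nodes[1:]})
pheno = generate_phenotypes(cfg, seed=8, outcome_nodes=betas)

# indicator selection by multi-group CFA (all four scales load significantly)
sel = select_indicators(pheno, list(cfg.indicators), cfg.groups, "ADHD-I")
print("retained indicators:", sel.retained)

metrics = pd.DataFrame(
    [
        (sid, node, "clustering", "integrated", val)
        for node in nodes
        for sid, val in zip(pheno.subject_id, pheno[node])
    ],
    columns=["subject_id", "node", "measure", "density", "value"],
)

result = run_node_scan(
    metrics, pheno, sel.retained, groups=cfg.groups, reference_group="ADHD-I"
)
cols = ["node", "p_diff", "p_diff_fdr", "significant", "beta_HC", "beta_ADHD_I", "beta_ADHD_CH"]
print("\nintegrated-level scan results:")
print(result[cols].round(4).to_string(index=False))
# Only the effect node should survive FDR; its standardized slopes recover
# the generating 0.091 / -0.279 / 0.844 pattern.

posthoc_cols = [c for c in result.columns if c.startswith("posthoc")]
if posthoc_cols:
    print("\npost-hoc pairwise p-values (Bonferroni-corrected), significant cells:")
    print(result.loc[result.significant, ["node", *posthoc_cols]].round(4).to_string(index=False))
    # The study's pattern: ADHD-C/H differs from both HC and ADHD-I, while
    # HC vs ADHD-I is not significant.
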