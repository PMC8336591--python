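"""The conventional comparator: GLM interaction contrast + enrichment.

On the same simulated 3vs3 study as the cross-cohort example, run the
gene-set-level GLM+EGS pipeline: TMM-normalized log-CPM, within-pair
log-ratios, moderated two-sample t between cohorts, BH over genes, then
Fisher enrichment of the DEGs over the four sets.  At this sample size the
comparator typically finds nothing — the contrast the cross-cohort method
is designed to win.
"""

from internof1 import (
    SimulationConfig,
    generate_dataset,
    glm_egs,
    paired_interaction_test,
    sim_filter,
)

dataset = generate_dataset(SimulationConfig(n_genes=8000, cohort_size=3, seed=42))
matrix = sim_filter(dataset.counts, dataset.all_pairs(), mode="glm")

result = paired_interaction_test(matrix, dataset.cohort_a, dataset.cohort_b)
n_degs = len(result.degs(0.05))
print(f"interaction contrast: {n_degs} DEGs at q < 0.05 "
      f"(residual df {result.df_residual:.0f}, prior df {result.df_prior:.1f})")

table = glm_egs(result, dataset.collection, deg_q=0.05, fdr_level=0.05)
print(table.round(4).to_string(index=False))
print(
    "\nWith 3 subjects per cohort the moderated interaction test has almost\n"
    "no power, so the enrichment stage usually receives no DEGs and no set\n"
    "is declared enriched — compare with example 02 on identical data."
)
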