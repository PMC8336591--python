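"""Single-subject pathway profiling from one paired transcriptome.

Simulates a small two-cohort study, then analyses ONE subject's
tumor/normal pair: mixture-model DEG calling on |log2FC| followed by
Fisher-exact gene-set enrichment with the continuity-corrected log odds
ratio Q as the effect size.
"""

import numpy as np

from internof1 import (
    SimulationConfig,
    call_degs,
    compute_log2fc,
    fit_mixture,
    generate_dataset,
    profile_to_frame,
    sim_filter,
    subject_profile,
)

dataset = generate_dataset(SimulationConfig(n_genes=8000, cohort_size=3, seed=42))
matrix = sim_filter(dataset.counts, dataset.all_pairs(), mode="s3")
subject = dataset.cohort_a.subjects[0]

fc = compute_log2fc(matrix, subject)
fit = fit_mixture(np.abs(fc.log2fc))
degs = call_degs(fc, fit, posterior_threshold=0.99)
stats = subject_profile(degs, dataset.collection, subject_id=subject.subject_id)

print(f"subject {subject.subject_id}: {int(degs.is_deg.sum())} DEGs "
      f"of {len(degs.genes)} genes "
      f"(null scale {fit.sds[0]:.2f}, DE mean {fit.means[1]:.2f})")
print(profile_to_frame(stats).round(4).to_string(index=False))
print(
    "\nQ > 0 with small fet_q marks a set overrepresented for this subject's\n"
    "DEGs; the two seeded sets should stand out while the control sets stay\n"
    "near the null."
)
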