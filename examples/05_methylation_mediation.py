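"""eQTM -> DMC -> conditional-mediation cascade on planted triplets.

A complete-mediation triplet routes the disease signal entirely through a
CpG: case status shifts methylation, and the gene's expression follows the
beta value. Conditioning the disease-expression model on the CpG should
collapse the effect (attenuation near 1, adjusted p large).
"""

import pandas as pd

from triaxis.de import log_cpm_transform
from triaxis.methylation import conditional_mediation, dmc_scan
from triaxis.synthetic import (CohortDesign, generate_cohort, generate_counts,
                               generate_methylation, mediation_effects)

design = CohortDesign(seed=5)
samples, _ = generate_cohort(design)
effects = mediation_effects(n_complete=2, n_none=2, slope=2.0,
                            cpg_case_shift=-0.3, direct_log2fc=0.6)
counts = generate_counts(design, effects, samples)
beta = generate_methylation(design, effects, samples)
logcpm = pd.DataFrame(log_cpm_transform(counts.to_numpy(float)),
                      index=counts.index, columns=counts.columns)

cpgs = [t.cpg_id for t in effects.eqtm_truth]
dmc = dmc_scan(beta.loc[cpgs], samples, latent_k="auto").set_index("cpg_id")
print("differential methylation (beta-scale case - control effect):")
print(dmc[["effect", "p", "significant"]].round(4).to_string())
print("\nonly the mediating CpGs carry the planted -0.3 shift.\n")

for t in effects.eqtm_truth:
    res = conditional_mediation(t.gene_id, t.cpg_id, logcpm, beta, samples)
    print(f"{t.gene_id} ({t.mediation:8s}): log2FC "
          f"{res.log2fc_unadj:+.3f} (p={res.p_unadj:.2g}) -> "
          f"{res.log2fc_adj:+.3f} (p={res.p_adj:.2g}), "
          f"attenuation {res.attenuation:.2f} -> {res.verdict}")
print("\ncomplete triplets attenuate toward zero; none-type genes keep "
      "their direct disease effect.")
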