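"""Replication enrichment against an external meta-analysis table.

Harmonizes gene identifiers (duplicates resolved to the row with the most
contributing studies k), counts the double-significant overlap, and tests
its enrichment with an upper-tail hypergeometric test.
"""

import warnings

from triaxis.de import DesignSpec, run_differential_expression
from triaxis.replication import replication_report
from triaxis.synthetic import (CohortDesign, default_effects, generate_cohort,
                               generate_counts, synthetic_replication_table)

design = CohortDesign(seed=6)
samples, _ = generate_cohort(design)
effects = default_effects(seed=6)
counts = generate_counts(design, effects, samples)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    deg = run_differential_expression(counts, samples, DesignSpec())

external = synthetic_replication_table(effects, list(counts.index), seed=6)
rep = replication_report(deg, external)

print(f"genes tested in both analyses: {rep.n_total}")
print(f"internal DEGs (q<0.05) among matched: {rep.n_internal_sig}")
print(f"external significant: {rep.n_external_sig}; "
      f"overlap: {rep.n_overlap}")
print(f"hypergeometric enrichment p = {rep.enrichment_p:.3g}")
print(f"direction concordance in the overlap: {rep.concordance:.2f}")
print(f"nominal replications (external p<0.05, same sign): {rep.n_nominal}")
print("\na tiny enrichment p with high concordance indicates the internal "
      "hit list replicates externally far beyond chance.")
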