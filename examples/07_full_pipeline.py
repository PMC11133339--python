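"""Run the whole analysis end to end on a synthetic bundle.

Writes the bundle to a temporary directory, runs
filter -> DEG -> modules -> risk -> eQTM/DMC/mediation -> replication, and
prints the per-stage record counts from the run manifest.

Equivalent shell usage:
    triaxis simulate --out bundle/ --seed 7
    triaxis run --config pipeline.yaml --base-dir bundle/
"""

import tempfile
import warnings

from triaxis.pipeline import PipelineConfig, run_pipeline
from triaxis.synthetic import CohortDesign, default_effects, write_bundle

with tempfile.TemporaryDirectory() as tmp:
    design = CohortDesign(seed=7)
    write_bundle(design, default_effects(seed=7), tmp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(PipelineConfig(seed=7), base_dir=tmp)

m = res["manifest"]
print("stages completed:", " -> ".join(m["stages"]))
for k, v in m["counts"].items():
    print(f"  {k:<22} {v}")

risk = res["risk"]
print("\ncumulative risk ORs (1..3 risk modules):",
      {k: round(v[0], 2) for k, v in risk.odds_ratios.items()})
print("rerunning with the same config and inputs reproduces every output "
      "byte for byte.")
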