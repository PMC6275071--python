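"""Run the full configured pipeline on bundled synthetic fixtures.

Generates steering records and toy complexes, reconstructs the PMF from
two independent runs, decomposes an interface, and computes every
trajectory statistic, writing tidy CSV/JSON outputs plus a manifest of
SHA-256 hashes.  Re-running the same configuration is bit-identical.
"""

import json
from pathlib import Path

from unbindkit.pipeline import demo_config, run_pipeline

outdir = Path("scratch/pipeline_demo")
config = demo_config(str(outdir), seed=1)
manifest = run_pipeline(config)

print(f"stages completed: {list(manifest['stages'])}")
print(f"outputs written under {outdir}:")
for rel in sorted(manifest["hashes"]):
    print(f"  {rel}  sha256:{manifest['hashes'][rel][:12]}")

report = json.loads((outdir / "pmf_convergence.json").read_text())
print(f"\nPMF two-run convergence: max deviation "
      f"{report['max_abs_deviation']:.4f} kcal/mol "
      f"-> convergent: {report['convergent']}")
# The manifest hashes are the reproducibility contract: the same config
# and seed yield byte-identical outputs on any machine.
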