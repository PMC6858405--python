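"""End-to-end analysis: curation, correlations, signal, ANCOVA, WF model.

Equivalent to `bacrate report --estimates ... --traits ... --tree ...`.
"""

import json
import tempfile
from pathlib import Path

from bacrate.pipeline import RunConfig, run_pipeline

DATA = Path(__file__).resolve().parent.parent / "data" / "synthetic_benchmark"

with tempfile.TemporaryDirectory() as td:
    config = RunConfig(
        estimates_path=str(DATA / "rate_estimates.csv"),
        traits_path=str(DATA / "species_traits.csv"),
        tree_path=str(DATA / "species_tree.nwk"),
        mutation_rates_path=str(DATA / "mutation_rates.csv"),
        outdir=td,
        outlier_species=["Buchnera_aphidicola"],
        signal_permutations=199,
        seed=0,
    )
    report = run_pipeline(config)
    print("sampling time:", json.dumps(report["sampling_time"], indent=2))
    print("power:", json.dumps(report["power"], indent=2))
    print("WF model:", json.dumps(report["wf_model"], indent=2))
    print("\ncorrelation table rows:", len(report["correlations"]))
    for row in report["correlations"][:6]:
        print(f"  {row['covariate']:<12s} {row['method']:<4s} {row['variant']:<12s} "
              f"r = {row['r']:+.3f} (n = {row['n']})")
    print("\nwritten tables:", sorted(p.name for p in Path(td).iterdir()))
print("Every statistic carries its n and the exclusion audit lives in "
      "summary.json; rerunning with the same seed reproduces the tables "
      "byte-for-byte.")
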