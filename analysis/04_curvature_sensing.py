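#!/usr/bin/env python
"""Buckled-membrane curvature-sensing analysis.

Peptides diffusing on the buckled bilayer are emulated by position samples
whose curvature bias scales with (programmed) insertion depth: shallow
peptides prefer positive mean curvature, deep ones negative.  The pipeline
fits each leaflet's surface, histograms sampled vs accessible curvature,
reweights, and reports the mean sensed curvature per peptide and membrane,
the upper/lower-leaflet agreement diagnostic, and the depth–curvature
Pearson correlation per membrane (expected strongly negative).
"""

import argparse
import json
from pathlib import Path

from memsense.io import write_table
from memsense.pipeline import run_sensing_analysis


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-samples", type=int, default=20000)
    args = parser.parse_args()

    root = Path(__file__).resolve().parents[1]
    results = root / "results"
    results.mkdir(exist_ok=True)

    report = run_sensing_analysis({"seed": args.seed, "n_samples": args.n_samples})
    write_table(report["table"], results / "sensing_summary.csv", {"seed": args.seed})
    with open(results / "sensing_correlations.json", "w") as fh:
        json.dump(report["correlations"], fh, indent=2)
    report["manifest"].write(results / "sensing_manifest.json")

    print(report["table"].to_string(index=False))
    print("\ndepth–curvature correlations per membrane:")
    for mem, cor in report["correlations"].items():
        print(f"  {mem}: r = {cor['pearson_r']:.3f} (p = {cor['p_value']:.2e})")
    converged = sum(bool(e["converged"]) for e in report["summary"].entries)
    print(f"\n{converged}/{len(report['summary'].entries)} peptide×membrane entries pass the "
          "leaflet-agreement convergence check; deeper peptides sense more negative curvature.")


if __name__ == "__main__":
    main()
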