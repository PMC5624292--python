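#!/usr/bin/env python
"""Landscape distance models: great-circle (IBD), least-cost path (LCP)
and commute/resistance (IBR) matrices between the five patches, plus the
explicit least-cost corridors and their land-use composition.

Reads the products of 01_simulate_landscape.py; writes matrices and
per-pair corridor traces under results/landscape/.
"""

import sys

from landgen.pipeline import RunConfig, run_landscape
from landgen.synthetic import read_scenario

SEED = 20260921


def main() -> None:
    scenario = read_scenario("results/synthetic/scenario.json")
    cfg = RunConfig(fasta="results/synthetic/haplotypes.fasta",
                    labels="results/synthetic/labels.tsv",
                    raster="results/synthetic/landscape.asc",
                    conductance=scenario.conductance,
                    out_dir="results/landscape", seed=SEED)
    res = run_landscape(cfg)
    for name, unit in (("geo", "km"), ("lcp", "cost units"),
                       ("ibr", "expected steps")):
        print(f"\n{name.upper()} distances ({unit}):")
        print(res[name].round(1).to_string())
    print("\ncorridor land-use composition (fraction of path cells):")
    legend = scenario.legend
    for (a, b), path in res["corridors"].items():
        comp = ", ".join(f"{legend.get(c, c)}: {f:.2f}"
                         for c, f in sorted(path.class_composition.items(),
                                            key=lambda kv: -kv[1]))
        print(f"  {a}-{b} ({len(path.cells)} cells): {comp}")


if __name__ == "__main__":
    sys.exit(main())
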