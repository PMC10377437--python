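#!/usr/bin/env python
"""Simulate the study cohorts and write them (plus truth sidecars) to disk.

Three cohorts are produced:
  * discovery        n=2000, US-EHR-like marginals, planted TE-history main
                     effect and NEPxRDW / LYPxRDW quadrant interactions
  * treatment        n=3000 with ~4% ruxolitinib switchers, for the
                     period-aligned incidence-rate comparison
  * validation       n=300, registry-like marginals (higher TE-history
                     prevalence, lower RDW), same planted thresholds

Every downstream driver regenerates these deterministically from the same
seed, so the CSVs are a convenience export, not a pipeline dependency.
"""

import argparse
from pathlib import Path

from pvrisk import synthgen
from pvrisk.cohort import write_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    configs = {
        "discovery": synthgen.GeneratorConfig(n_patients=2000, seed=args.seed, label="discovery"),
        "treatment": synthgen.GeneratorConfig(
            n_patients=3000, seed=args.seed + 1, label="treatment", switcher_fraction=0.04
        ),
        "validation": synthgen.validation_config(n_patients=300, seed=args.seed + 2),
    }
    for name, cfg in configs.items():
        cohort = synthgen.generate_cohort(cfg)
        write_cohort(cohort, args.out_dir / f"{name}.csv")
        synthgen.write_sidecar(cfg, args.out_dir / f"{name}_planted.json")
        n_sw = sum(p.is_switcher for p in cohort)
        print(f"{name}: {len(cohort)} patients ({n_sw} switchers) -> {args.out_dir}/{name}.csv")


if __name__ == "__main__":
    main()
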