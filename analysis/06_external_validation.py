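#!/usr/bin/env python
"""Validate the fixed decision-tree thresholds on an independent cohort.

The decision trees derived on the discovery cohort (read from
results/decision_trees.json when present, otherwise the headline fixed
thresholds) are applied unchanged to a registry-like validation cohort, and
thrombosis-free survival is compared between the high- and low-risk leaves
with Kaplan-Meier curves and a log-rank test, in patients without TE history.
"""

import argparse
import json
from pathlib import Path

from pvrisk import landscape, synthgen

FALLBACK_TREES = {
    "NEP_RDW": landscape.DecisionTree("NEP", 72.05, ">=", "RDW", 14.3, "<"),
    "LYP_RDW": landscape.DecisionTree("LYP", 19.3, "<", "RDW", 14.05, "<"),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    trees = dict(FALLBACK_TREES)
    stored = args.out_dir / "decision_trees.json"
    if stored.exists():
        raw = json.loads(stored.read_text())
        trees = {
            name: landscape.DecisionTree(
                d["var1"], d["threshold1"], d["direction1"],
                d["var2"], d["threshold2"], d["direction2"],
            )
            for name, d in raw.items()
        }
        print(f"loaded thresholds from {stored}")

    cohort = synthgen.generate_validation_cohort(n_patients=300, seed=args.seed + 2)
    report = {}
    for name, tree in trees.items():
        res = landscape.validate_fixed_thresholds(tree, cohort)
        report[name] = {
            "rule": tree.rule,
            "n_per_leaf": res.n_per_leaf,
            "n_excluded_missing": res.n_excluded_missing,
            "logrank_chi2": res.logrank.chi2,
            "logrank_p": res.logrank.p,
        }
        print(f"{name}: {tree.rule}")
        print(f"  leaves {res.n_per_leaf}, log-rank chi2={res.logrank.chi2:.2f}, "
              f"p={res.logrank.p:.2e}")
        for leaf, km in res.km_curves.items():
            safe = leaf.replace(" ", "_")
            km.as_frame().to_csv(args.out_dir / f"km_{name}_{safe}.csv", index=False)

    out = args.out_dir / "validation.json"
    out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {out} and km_*.csv")


if __name__ == "__main__":
    main()
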