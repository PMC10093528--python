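"""Scaled-down L1 and L2 sweeps: regularization versus the train/test gap.

Runs one-at-a-time sweeps of the two weight penalties on the small
synthetic cohort (all other hyperparameters at base values, epochs reduced
to 60 so the unregularized setting has room to overfit) and writes
per-value aggregates and range summaries under results/.
"""

import argparse
import csv
import json
from pathlib import Path

from fnnsweep import HyperParams, SyntheticConfig, generate_dataset
from fnnsweep.sweep import GridSpec, run_single_sweep

ROOT = Path(__file__).resolve().parents[1]

GRIDS = {
    "l1": GridSpec("l1", values=(0.0, 0.001, 0.01, 0.05)),
    "l2": GridSpec("l2", values=(0.0, 0.008, 0.05, 0.1)),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--n-cases", type=int, default=800)
    ap.add_argument("--reps", type=int, default=3)
    args = ap.parse_args()

    ds = generate_dataset(SyntheticConfig(n_cases=args.n_cases, seed=args.seed,
                                          target_bayes_auc=0.75))
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    for name, spec in GRIDS.items():
        res = run_single_sweep(name, spec, HyperParams(epochs=60), ds,
                               n_reps=args.reps, base_mode="fixed",
                               seed=args.seed)
        with open(results / f"{name}_sweep.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([name, "avg_mean_train_auc", "avg_mean_test_auc",
                        "avg_percent_auc_diff"])
            for i, v in enumerate(res.values):
                w.writerow([v, res.avg_mean_train_auc[i],
                            res.avg_mean_test_auc[i],
                            res.avg_percent_auc_diff[i]])
        with open(results / f"{name}_ranges.json", "w") as fh:
            json.dump({"hyperparameter": name, "n_reps": args.reps,
                       "ranges": res.ranges}, fh, indent=2)
        print(f"{name} sweep:")
        for i, v in enumerate(res.values):
            print(f"  {name}={v:<6}: test {res.avg_mean_test_auc[i]:.3f}  "
                  f"percent_AUC_diff {res.avg_percent_auc_diff[i]:.3f}")
    print("tables -> results/l1_sweep.csv, results/l2_sweep.csv (+ range JSONs)")


if __name__ == "__main__":
    main()
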