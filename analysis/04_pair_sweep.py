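"""Interactive sweep: how learning rate and momentum jointly shape overfitting.

Cross-product sweep of a reduced learning-rate x momentum grid with the
remaining hyperparameters at base values, writing the averaged
mean_test_AUC and percent_AUC_diff surface under results/.
"""

import argparse
import csv
from pathlib import Path

from fnnsweep import HyperParams, SyntheticConfig, generate_dataset
from fnnsweep.sweep import GridSpec, run_pair_sweep

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--n-cases", type=int, default=800)
    ap.add_argument("--reps", type=int, default=2)
    args = ap.parse_args()

    ds = generate_dataset(SyntheticConfig(n_cases=args.n_cases, seed=args.seed,
                                          target_bayes_auc=0.75))
    spec_lr = GridSpec("learning_rate", values=(0.01, 0.05, 0.2))
    spec_mom = GridSpec("momentum", values=(0.1, 0.5, 0.9))
    res = run_pair_sweep(spec_lr, spec_mom, HyperParams(epochs=30), ds,
                         n_reps=args.reps, seed=args.seed)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "pair_lr_momentum.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["learning_rate", "momentum", "avg_mean_test_auc",
                    "avg_percent_auc_diff"])
        for ai, a in enumerate(res.values_a):
            for bi, b in enumerate(res.values_b):
                w.writerow([a, b, float(res.avg_mean_test_auc[ai, bi]),
                            float(res.avg_percent_auc_diff[ai, bi])])

    print("learning_rate x momentum surface (avg percent_AUC_diff):")
    header = "            " + "".join(f"m={b:<8}" for b in res.values_b)
    print(header)
    for ai, a in enumerate(res.values_a):
        row = "".join(f"{float(res.avg_percent_auc_diff[ai, bi]):<10.3f}"
                      for bi in range(len(res.values_b)))
        print(f"  lr={a:<6} {row}")
    print("table -> results/pair_lr_momentum.csv")


if __name__ == "__main__":
    main()
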