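"""Rank the swept hyperparameters by their range statistics.

Collects the range summaries written by the earlier sweep scripts
(results/*_ranges.json) and orders the hyperparameters by the range of
each metric — the averaged per-repetition maximum minus minimum — the
protocol's measure of how much a hyperparameter can move performance and
overfitting across its tested values.
"""

import csv
import json
from pathlib import Path
from types import SimpleNamespace

from fnnsweep.sweep import rank_hyperparameters

ROOT = Path(__file__).resolve().parents[1]


def main():
    results = ROOT / "results"
    sweeps = []
    for path in sorted(results.glob("*_ranges.json")):
        blob = json.loads(path.read_text())
        sweeps.append(SimpleNamespace(name=blob["hyperparameter"],
                                      ranges=blob["ranges"]))
    if not sweeps:
        raise SystemExit("no *_ranges.json found under results/ — run the "
                         "sweep scripts (02, 03) first")

    ranking = rank_hyperparameters(sweeps)
    with open(results / "ranking.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "rank", "hyperparameter", "range"])
        for metric, pairs in ranking.items():
            for rank, (name, rng) in enumerate(pairs, start=1):
                w.writerow([metric, rank, name, rng])

    for metric, pairs in ranking.items():
        print(f"{metric} range ranking:")
        for rank, (name, rng) in enumerate(pairs, start=1):
            print(f"  {rank}. {name:<15s} {rng:.4f}")
    print("table -> results/ranking.csv")


if __name__ == "__main__":
    main()
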