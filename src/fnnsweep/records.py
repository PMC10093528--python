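"""Per-model output records for grid-search runs.

Every trained hyperparameter setting produces one :class:`ModelRecord`
serialized as one CSV row under a fixed, documented header: identification
(run id, repetition, swept value), the full 11-value hyperparameter
setting, per-fold and mean train/test AUCs, the overfitting statistic and
flag, seeds, timing and software provenance.  Numeric fields are written
as full-precision decimal text (``repr``), so deserialization reproduces
them exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .evaluation import CVResult
from .fnn import HyperParams

_HP_FIELDS = (
    "output_activation", "weight_initializer", "n_hidden_layers",
    "learning_rate", "momentum", "decay", "dropout_rate", "epochs",
    "batch_size", "l1", "l2",
)

RECORD_HEADER = (
    ("run_id", "repetition", "swept_value")
    + _HP_FIELDS
    + tuple(f"fold{i}_train_auc" for i in range(5))
    + tuple(f"fold{i}_test_auc" for i in range(5))
    + ("mean_train_auc", "mean_test_auc", "percent_auc_diff", "overfit_flag",
       "seed", "wall_seconds", "software_version", "timestamp")
)

_FLOAT_FIELDS = {"learning_rate", "momentum", "decay", "dropout_rate", "l1", "l2",
                 "mean_train_auc", "mean_test_auc", "percent_auc_diff",
                 "wall_seconds", "swept_value"}
_INT_FIELDS = {"repetition", "n_hidden_layers", "epochs", "batch_size", "seed"}


@dataclass
class ModelRecord:
    run_id: str
    repetition: int
    swept_value: object
    hp: HyperParams
    result: CVResult
    seed: int
    wall_seconds: float
    software_version: str
    timestamp: str

    def to_row(self) -> list[str]:
        row = [self.run_id, repr(self.repetition), _fmt(self.swept_value)]
        row += [_fmt(getattr(self.hp, f)) for f in _HP_FIELDS]
        row += [repr(v) for v in self.result.fold_train_auc]
        row += [repr(v) for v in self.result.fold_test_auc]
        row += [repr(self.result.mean_train_auc), repr(self.result.mean_test_auc),
                repr(self.result.percent_auc_diff), str(self.result.overfit_flag),
                repr(self.seed), repr(self.wall_seconds),
                self.software_version, self.timestamp]
        return row


def _fmt(v) -> str:
    return v if isinstance(v, str) else repr(v)


def write_records(records, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RECORD_HEADER)
        for rec in records:
            w.writerow(rec.to_row())


def read_records(path) -> list[dict]:
    """Read a records CSV back into dicts with exact numeric values."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            parsed = {}
            for k, v in row.items():
                if k in _FLOAT_FIELDS or k.endswith("_auc"):
                    try:
                        parsed[k] = float(v)
                    except ValueError:  # categorical swept_value
                        parsed[k] = v
                elif k in _INT_FIELDS:
                    parsed[k] = int(v)
                elif k == "overfit_flag":
                    parsed[k] = v == "True"
                else:
                    parsed[k] = v
            out.append(parsed)
    return out
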