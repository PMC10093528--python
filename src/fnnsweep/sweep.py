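"""Repeated one-at-a-time and paired hyperparameter grid sweeps.

The protocol: give a wide range of values to one hyperparameter of
interest, hold the other ten at a single value each (their base values, or
one seeded random draw per repetition from their tested value sets), run
stratified 5-fold CV for every grid value, and repeat the whole sweep
``n_reps`` times.  Reported per-value metrics are means over repetitions
("means of means"); per-hyperparameter sensitivity is summarized by the
range statistic: the averaged per-repetition maximum minus the averaged
per-repetition minimum of each metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np

from .evaluation import CVResult, evaluate_cv
from .fnn import HyperParams, INITIALIZERS, OUTPUT_ACTIVATIONS

#: The 11 hyperparameters under study, in protocol order.
HYPERPARAM_NAMES = (
    "output_activation", "weight_initializer", "n_hidden_layers",
    "learning_rate", "momentum", "decay", "dropout_rate",
    "epochs", "batch_size", "l1", "l2",
)

_INT_PARAMS = {"n_hidden_layers", "epochs", "batch_size"}

METRICS = ("mean_train_auc", "mean_test_auc", "percent_auc_diff")


class SpecError(ValueError):
    """Invalid grid or sweep specification."""


@dataclass(frozen=True)
class GridSpec:
    """Value-range specification for one hyperparameter.

    Either a numeric range (start/stop/step, endpoints generated by index
    arithmetic and rounded to the step's decimal precision) or an explicit
    value list; a range may carry extra points via ``extras``.
    """

    name: str
    start: float | None = None
    stop: float | None = None
    step: float | None = None
    values: tuple | None = None
    extras: tuple = ()

    def __post_init__(self):
        if self.name not in HYPERPARAM_NAMES:
            raise SpecError(f"unknown hyperparameter {self.name!r}")
        if self.values is None:
            if self.start is None or self.stop is None or self.step is None:
                raise SpecError(f"grid for {self.name!r} needs start/stop/step or values")
            if self.step <= 0:
                raise SpecError(f"step must be positive, got {self.step}")
            if self.start > self.stop:
                raise SpecError(f"start {self.start} exceeds stop {self.stop}")
        elif len(self.values) == 0:
            raise SpecError(f"empty value list for {self.name!r}")


def _decimals(x: float) -> int:
    exp = Decimal(str(x)).normalize().as_tuple().exponent
    return max(0, -exp) if isinstance(exp, int) else 0


def build_grid(spec: GridSpec) -> list:
    """Materialize the ordered grid values for a spec.

    Range values are start + i*step for i = 0..count-1 with
    count = floor((stop-start)/step + eps) + 1, each rounded to the step's
    decimal precision so e.g. 0.1 + 3*0.1 yields 0.4 exactly as printed.
    Extras are merged in, the result deduplicated and sorted.
    """
    if spec.values is not None:
        vals = list(spec.values)
        if all(isinstance(v, (int, float)) for v in vals):
            vals = sorted(set(vals))
        return vals
    nd = max(_decimals(spec.start), _decimals(spec.step))
    span = float(Decimal(str(spec.stop)) - Decimal(str(spec.start)))
    count = int(math.floor(span / spec.step + 1e-9)) + 1
    vals = [round(spec.start + i * spec.step, nd) for i in range(count)]
    if spec.name in _INT_PARAMS:
        vals = [int(v) for v in vals]
    vals = sorted(set(vals) | set(spec.extras))
    return vals


#: Tested value ranges of the study protocol, one spec per hyperparameter.
#: The batch-size step is 5 (consistent with the printed count of 838
#: values from 1 to the dataset size 4186); the decay range 0-0.2 at step
#: 0.0005 materializes 401 values.
SINGLE_SWEEP_GRIDS: dict[str, GridSpec] = {
    "output_activation": GridSpec("output_activation", values=OUTPUT_ACTIVATIONS),
    "weight_initializer": GridSpec("weight_initializer", values=INITIALIZERS),
    "n_hidden_layers": GridSpec("n_hidden_layers", values=(1, 2, 3, 4)),
    "learning_rate": GridSpec("learning_rate", 0.001, 0.4, 0.001),
    "momentum": GridSpec("momentum", 0.1, 0.9, 0.1),
    "decay": GridSpec("decay", 0.0, 0.2, 0.0005),
    "dropout_rate": GridSpec("dropout_rate", 0.1, 0.9, 0.1),
    "epochs": GridSpec("epochs", 5, 2000, 25),
    "batch_size": GridSpec("batch_size", 1, 4186, 5),
    "l1": GridSpec("l1", 0.0, 0.5, 0.001),
    "l2": GridSpec("l2", 0.0, 0.7, 0.001),
}

#: Paired (interactive) sweep axes.  The momentum step is 0.1 (the printed
#: value count of 9 admits no other step over 0.1-0.9).
PAIRED_SWEEP_AXES: dict[tuple[str, str], tuple[GridSpec, GridSpec]] = {
    ("learning_rate", "momentum"): (
        GridSpec("learning_rate", 0.01, 0.2, 0.01),
        GridSpec("momentum", 0.1, 0.9, 0.1)),
    ("learning_rate", "decay"): (
        GridSpec("learning_rate", 0.01, 0.2, 0.01),
        GridSpec("decay", 0.005, 0.1, 0.005)),
    ("batch_size", "epochs"): (
        GridSpec("batch_size", 1, 1500, 50),
        GridSpec("epochs", 5, 500, 25)),
    ("l1", "l2"): (
        GridSpec("l1", 0.0, 0.01, 0.001, extras=(0.02,)),
        GridSpec("l2", 0.0, 0.01, 0.001, extras=(0.02,))),
}


@dataclass
class SweepResult:
    """Aggregated outcome of one repeated single-hyperparameter sweep."""

    name: str
    values: list
    avg_mean_train_auc: list[float]
    avg_mean_test_auc: list[float]
    avg_percent_auc_diff: list[float]
    raw: list[list[CVResult]]  # [repetition][value index]
    settings: list[list[HyperParams]]  # hp actually evaluated per unit
    seeds: list[list[int]]  # sub-seed per unit
    ranges: dict = field(default_factory=dict)  # metric -> {avg_max, avg_min, range}
    n_reps: int = 0


@dataclass
class PairSweepResult:
    """Aggregated outcome of a paired (interactive) sweep."""

    name_a: str
    name_b: str
    values_a: list
    values_b: list
    avg_mean_test_auc: np.ndarray  # |A| x |B|
    avg_percent_auc_diff: np.ndarray
    raw: list  # [repetition] -> |A| x |B| nested lists of CVResult
    settings: list = field(default_factory=list)  # same nesting as raw
    seeds: list = field(default_factory=list)
    n_reps: int = 0


def _unit_seed(master: int, tag: int, rep: int, value_idx: int) -> int:
    """Deterministic sub-seed for one (repetition, grid value) work unit."""
    ss = np.random.SeedSequence([int(master), int(tag), int(rep), int(value_idx)])
    return int(ss.generate_state(1)[0] % (2**31))


def _set_value(hp: HyperParams, name: str, value) -> HyperParams:
    if name in _INT_PARAMS:
        value = int(value)
    return hp.with_(**{name: value})


def _randomized_base(base: HyperParams, swept: str, master: int, rep: int,
                     grids: dict[str, GridSpec]) -> HyperParams:
    """One seeded random draw per non-swept hyperparameter for this repetition."""
    hp = base
    for i, name in enumerate(HYPERPARAM_NAMES):
        if name == swept:
            continue
        choices = build_grid(grids.get(name, SINGLE_SWEEP_GRIDS[name]))
        rng = np.random.default_rng(
            np.random.SeedSequence([int(master), 7919, i, int(rep)]))
        hp = _set_value(hp, name, choices[rng.integers(len(choices))])
    return hp


def compute_ranges(raw: list[list[CVResult]]) -> dict:
    """Range statistics from per-repetition model results.

    For each metric: the mean over repetitions of the per-repetition
    maximum, likewise the minimum, and their difference.
    """
    if not raw or any(len(rep) == 0 for rep in raw):
        raise ValueError("compute_ranges needs >= 1 repetition with >= 1 model each")
    out = {}
    for metric in METRICS:
        maxima = [max(getattr(r, metric) for r in rep) for rep in raw]
        minima = [min(getattr(r, metric) for r in rep) for rep in raw]
        avg_max = float(np.mean(maxima))
        avg_min = float(np.mean(minima))
        out[metric] = {"avg_max": avg_max, "avg_min": avg_min,
                       "range": avg_max - avg_min}
    return out


def run_single_sweep(name: str, spec: GridSpec, base: HyperParams, dataset,
                     n_reps: int = 30, base_mode: str = "randomized",
                     seed: int = 0, evaluator=None) -> SweepResult:
    """Repeated one-at-a-time sweep of ``name`` over ``spec``.

    For each repetition the other ten hyperparameters are held at one value
    each: their base values (``base_mode='fixed'``) or one seeded draw per
    repetition from their tested value sets (``'randomized'``, the study's
    stated protocol).  Every (repetition, grid value) unit derives its seed
    from (seed, hyperparameter, repetition, value index) only, so results
    are independent of execution order.  ``evaluator`` overrides
    :func:`fnnsweep.evaluation.evaluate_cv` (stubbing hook).
    """
    if name not in HYPERPARAM_NAMES:
        raise SpecError(f"unknown hyperparameter {name!r}")
    if spec.name != name:
        raise SpecError(f"grid spec targets {spec.name!r}, not {name!r}")
    if n_reps < 1:
        raise SpecError("n_reps must be >= 1")
    if base_mode not in ("fixed", "randomized"):
        raise SpecError(f"unknown base_mode {base_mode!r}")
    evaluate = evaluator or evaluate_cv
    values = build_grid(spec)
    tag = HYPERPARAM_NAMES.index(name)
    raw: list[list[CVResult]] = []
    settings: list[list[HyperParams]] = []
    seeds: list[list[int]] = []
    for rep in range(n_reps):
        if base_mode == "randomized":
            hp_base = _randomized_base(base, name, seed, rep, SINGLE_SWEEP_GRIDS)
        else:
            hp_base = base
        row, hp_row, seed_row = [], [], []
        for vi, value in enumerate(values):
            hp = _set_value(hp_base, name, value)
            sub = _unit_seed(seed, tag, rep, vi)
            try:
                row.append(evaluate(dataset, hp, sub))
            except ArithmeticError as e:
                raise type(e)(
                    f"repetition {rep}, {name}={value}: {e}") from None
            hp_row.append(hp)
            seed_row.append(sub)
        raw.append(row)
        settings.append(hp_row)
        seeds.append(seed_row)
    n_values = len(values)
    agg = {m: [float(np.mean([getattr(raw[r][v], m) for r in range(n_reps)]))
               for v in range(n_values)] for m in METRICS}
    return SweepResult(
        name=name, values=values,
        avg_mean_train_auc=agg["mean_train_auc"],
        avg_mean_test_auc=agg["mean_test_auc"],
        avg_percent_auc_diff=agg["percent_auc_diff"],
        raw=raw, settings=settings, seeds=seeds,
        ranges=compute_ranges(raw), n_reps=n_reps)


def run_pair_sweep(spec_a: GridSpec, spec_b: GridSpec, base: HyperParams,
                   dataset, n_reps: int = 30, seed: int = 0,
                   evaluator=None) -> PairSweepResult:
    """Interactive sweep over the cross-product of two hyperparameter grids.

    The remaining nine hyperparameters stay at their base values.
    """
    if spec_a.name == spec_b.name:
        raise SpecError(f"paired sweep needs two distinct hyperparameters, got {spec_a.name!r} twice")
    evaluate = evaluator or evaluate_cv
    va, vb = build_grid(spec_a), build_grid(spec_b)
    tag = 100 + HYPERPARAM_NAMES.index(spec_a.name) * 11 + HYPERPARAM_NAMES.index(spec_b.name)
    raw, settings, seeds = [], [], []
    for rep in range(n_reps):
        grid_rep, hp_rep, seed_rep = [], [], []
        for ai, a in enumerate(va):
            row, hp_row, seed_row = [], [], []
            for bi, b in enumerate(vb):
                hp = _set_value(_set_value(base, spec_a.name, a), spec_b.name, b)
                sub = _unit_seed(seed, tag, rep, ai * len(vb) + bi)
                row.append(evaluate(dataset, hp, sub))
                hp_row.append(hp)
                seed_row.append(sub)
            grid_rep.append(row)
            hp_rep.append(hp_row)
            seed_rep.append(seed_row)
        raw.append(grid_rep)
        settings.append(hp_rep)
        seeds.append(seed_rep)
    test = np.array([[[raw[r][ai][bi].mean_test_auc for bi in range(len(vb))]
                      for ai in range(len(va))] for r in range(n_reps)])
    pad = np.array([[[raw[r][ai][bi].percent_auc_diff for bi in range(len(vb))]
                     for ai in range(len(va))] for r in range(n_reps)])
    return PairSweepResult(
        name_a=spec_a.name, name_b=spec_b.name, values_a=va, values_b=vb,
        avg_mean_test_auc=test.mean(axis=0), avg_percent_auc_diff=pad.mean(axis=0),
        raw=raw, settings=settings, seeds=seeds, n_reps=n_reps)


def rank_hyperparameters(sweeps: list[SweepResult]) -> dict:
    """Descending ranking of hyperparameters by each metric's range.

    Ties break alphabetically by hyperparameter name.  Returns
    metric -> list of (name, range).
    """
    if len(sweeps) < 1:
        raise ValueError("need at least one sweep to rank")
    names = [s.name for s in sweeps]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate hyperparameter names in {names}")
    out = {}
    for metric in METRICS:
        pairs = [(s.name, s.ranges[metric]["range"]) for s in sweeps]
        out[metric] = sorted(pairs, key=lambda p: (-p[1], p[0]))
    return out
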