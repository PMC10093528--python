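"""Synthetic EHR-like binary-outcome cohorts with known ground truth.

Emulates the shape of a 5-year breast-cancer-metastasis table (by default
4189 patients x 31 mixed clinical features) under a logistic
data-generating model: a subset of "signal" features carries true log-odds
effects (optionally with pairwise interactions), the remainder is pure
noise, and labels are Bernoulli draws from the resulting per-case
probability.  Because the true per-case log-odds are retained, the best
achievable (Bayes) discrimination is known, which makes model capacity and
overfitting measurable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from scipy.special import expit


class ConfigError(ValueError):
    """Invalid generator configuration."""


class DatasetError(ValueError):
    """Malformed or unsupported dataset."""


#: Monte-Carlo size and internal seed used by the Bayes-AUC calibration.
_CALIB_N = 50_000
_CALIB_SEED = 20230515

#: Seed of the structural RNG that fixes the data-generating design
#: (per-column distribution parameters, signal set, effect sizes,
#: interaction pairs) for a given config shape.  Keeping the design fixed
#: while cfg.seed drives only the case-level draws makes the Bayes AUC a
#: property of the config, so effect-scale calibration transfers across
#: dataset seeds.
_STRUCT_SEED = 730418


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    feature_mix gives counts of (binary, ordinal 0-3, continuous) columns
    and must sum to n_features.  If target_bayes_auc is set, effect_scale
    is replaced by a calibrated value so that the AUC of the true log-odds
    approaches the target.
    """

    n_cases: int = 4189
    n_features: int = 31
    prevalence: float = 0.25
    n_signal_features: int = 6
    effect_scale: float = 1.0
    interaction_pairs: int = 2
    feature_mix: tuple[int, int, int] = (10, 6, 15)
    target_bayes_auc: float | None = None
    seed: int = 0
    class_column: str = "metastasis_5yr"

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_features <= 0:
            raise ConfigError("n_cases and n_features must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence must lie strictly in (0,1), got {self.prevalence}")
        if self.n_signal_features < 0 or self.n_signal_features > self.n_features:
            raise ConfigError("n_signal_features must be in [0, n_features]")
        if self.effect_scale < 0:
            raise ConfigError("effect_scale must be non-negative")
        if self.interaction_pairs < 0:
            raise ConfigError("interaction_pairs must be non-negative")
        if sum(self.feature_mix) != self.n_features:
            raise ConfigError(
                f"feature_mix {self.feature_mix} must sum to n_features={self.n_features}")
        if self.target_bayes_auc is not None and not 0.5 <= self.target_bayes_auc < 1.0:
            raise ConfigError("target_bayes_auc must lie in [0.5, 1)")


@dataclass
class Dataset:
    """Feature matrix, binary labels, names and (for synthetic data) truth.

    ``truth`` is the per-case ground-truth log-odds; it exists only for
    generated cohorts and is the oracle against which fitted models are
    calibrated.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    truth: np.ndarray | None = None
    class_column: str = "metastasis_5yr"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.features.ndim != 2:
            raise DatasetError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise DatasetError("row count of features must equal label count")
        if len(self.feature_names) != self.features.shape[1]:
            raise DatasetError("feature_names length must equal column count")
        if not np.all(np.isfinite(self.features)):
            raise DatasetError("features contain missing or non-finite values")
        if set(np.unique(self.labels)) - {0, 1}:
            raise DatasetError("labels must be binary 0/1")

    @property
    def n_cases(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def _feature_names(mix):
    nb, no, nc = mix
    return ([f"bin_{i:02d}" for i in range(nb)]
            + [f"ord_{i:02d}" for i in range(no)]
            + [f"cont_{i:02d}" for i in range(nc)])


def _draw_features(rng, struct_rng, n_cases, mix):
    """Raw columns: binary 0/1, ordinal codes 0-3, standardized continuous.

    Per-column distribution parameters (positivity rates, level
    probabilities) come from the structural RNG; only the case-level draws
    use the dataset seed.
    """
    nb, no, nc = mix
    cols = []
    for _ in range(nb):
        p = struct_rng.uniform(0.1, 0.9)
        cols.append(rng.binomial(1, p, n_cases).astype(float))
    for _ in range(no):
        probs = struct_rng.dirichlet(np.ones(4) * 2.0)
        cols.append(rng.choice(4, size=n_cases, p=probs).astype(float))
    for _ in range(nc):
        cols.append(rng.standard_normal(n_cases))
    return np.column_stack(cols) if cols else np.empty((n_cases, 0))


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _signal_indices(struct_rng, cfg: SyntheticConfig) -> np.ndarray:
    """Signal columns spread across the three feature blocks (structural)."""
    return np.sort(struct_rng.choice(cfg.n_features, size=cfg.n_signal_features,
                                     replace=False))


def _raw_score(X, sig_idx, betas, pairs, gammas):
    """Linear + interaction risk score on standardized signal columns."""
    Z = _standardize(X)
    score = Z[:, sig_idx] @ betas if len(sig_idx) else np.zeros(X.shape[0])
    for (i, j), g in zip(pairs, gammas):
        score = score + g * Z[:, i] * Z[:, j]
    return score


def _solve_intercept(score, prevalence):
    """Bisection for c with mean(sigmoid(score + c)) = prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(score + mid).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _mc_bayes_auc(cfg: SyntheticConfig, effect_scale: float) -> float:
    """Monte-Carlo AUC of the true log-odds at the given effect scale."""
    probe = SyntheticConfig(
        n_cases=_CALIB_N, n_features=cfg.n_features, prevalence=cfg.prevalence,
        n_signal_features=cfg.n_signal_features, effect_scale=effect_scale,
        interaction_pairs=cfg.interaction_pairs, feature_mix=cfg.feature_mix,
        target_bayes_auc=None, seed=_CALIB_SEED, class_column=cfg.class_column)
    ds = _generate(probe)
    from .evaluation import roc_auc
    return roc_auc(ds.labels, ds.truth)


def calibrate_effect_scale(cfg: SyntheticConfig) -> float:
    """Bisection on effect_scale toward cfg.target_bayes_auc.

    The oracle AUC is monotone in effect_scale (stronger effects separate
    the classes more), so bisection against a fixed-seed Monte-Carlo AUC
    estimate at n=50000 converges to the scale whose Bayes AUC matches the
    target.
    """
    if cfg.target_bayes_auc is None:
        raise ConfigError("calibrate_effect_scale requires target_bayes_auc")
    if cfg.n_signal_features == 0:
        raise ConfigError("cannot calibrate with zero signal features")
    target = cfg.target_bayes_auc
    lo, hi = 0.0, 1.0
    while _mc_bayes_auc(cfg, hi) < target and hi < 64:
        hi *= 2.0
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        if _mc_bayes_auc(cfg, mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _generate(cfg: SyntheticConfig) -> Dataset:
    rng = np.random.default_rng(cfg.seed)
    struct_rng = np.random.default_rng(_STRUCT_SEED)
    X = _draw_features(rng, struct_rng, cfg.n_cases, cfg.feature_mix)
    sig_idx = _signal_indices(struct_rng, cfg)
    # alternating-sign effects of comparable magnitude, scaled by effect_scale
    base = struct_rng.uniform(0.5, 1.5, size=cfg.n_signal_features)
    signs = np.where(np.arange(cfg.n_signal_features) % 2 == 0, 1.0, -1.0)
    betas = cfg.effect_scale * base * signs
    pairs, gammas = [], []
    if cfg.interaction_pairs > 0 and cfg.n_signal_features >= 2:
        for k in range(cfg.interaction_pairs):
            i, j = struct_rng.choice(sig_idx, size=2, replace=False)
            pairs.append((int(i), int(j)))
            gammas.append(0.5 * cfg.effect_scale * struct_rng.uniform(0.5, 1.5))
    score = _raw_score(X, sig_idx, betas, pairs, gammas)
    truth = score + _solve_intercept(score, cfg.prevalence)
    labels = rng.binomial(1, expit(truth))
    if labels.min() == labels.max():  # pathological draw at extreme prevalence
        labels[rng.integers(cfg.n_cases)] = 1 - labels[0]
    return Dataset(X, labels, _feature_names(cfg.feature_mix), truth=truth,
                   class_column=cfg.class_column)


def generate_dataset(cfg: SyntheticConfig) -> Dataset:
    """Generate a cohort; pure function of the config (seed included).

    Labels are Bernoulli(sigmoid(truth)) where truth = intercept (solved so
    the mean event probability matches ``prevalence``) + linear effects on
    the signal features + the configured interaction terms.  Noise features
    are independent of the labels.
    """
    if cfg.target_bayes_auc is not None:
        scale = calibrate_effect_scale(cfg)
        cfg = SyntheticConfig(**{**cfg.__dict__, "effect_scale": scale,
                                 "target_bayes_auc": None})
    return _generate(cfg)


def bayes_scores(dataset: Dataset) -> np.ndarray:
    """Ground-truth log-odds per case — the best achievable ranking score."""
    if dataset.truth is None:
        raise DatasetError("dataset has no ground truth (not synthetic?)")
    return dataset.truth


def write_dataset(dataset: Dataset, path, truth_path=None) -> None:
    """Write the cohort as a headered CSV; optional truth sidecar CSV."""
    df = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    df[dataset.class_column] = dataset.labels
    df.to_csv(path, index=False, float_format="%.17g")
    if truth_path is not None and dataset.truth is not None:
        pd.DataFrame({"true_log_odds": dataset.truth}).to_csv(
            truth_path, index=False, float_format="%.17g")


def read_dataset(path, class_column: str = "metastasis_5yr",
                 truth_path=None) -> Dataset:
    """Read a headered delimited file with a binary class column.

    Raises a parse error naming the offending column for a non-binary class
    column or missing values; an empty (header-only) file is rejected.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise DatasetError(f"empty dataset: {path} has a header but no rows")
    if class_column not in df.columns:
        raise DatasetError(f"class column {class_column!r} not found in {path}")
    labels = df[class_column]
    if labels.isna().any():
        raise DatasetError(f"missing values in class column {class_column!r}")
    bad = set(labels.unique()) - {0, 1}
    if bad:
        raise DatasetError(
            f"class column {class_column!r} must be binary 0/1, found {sorted(bad)}")
    feats = df.drop(columns=[class_column])
    for col in feats.columns:
        if feats[col].isna().any():
            row = int(feats[col].isna().idxmax())
            raise DatasetError(f"missing value at row {row}, column {col!r}")
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        truth = pd.read_csv(truth_path)["true_log_odds"].to_numpy()
    return Dataset(feats.to_numpy(dtype=float), labels.to_numpy(dtype=int),
                   list(feats.columns), truth=truth, class_column=class_column)
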