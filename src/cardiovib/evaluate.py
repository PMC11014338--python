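"""Regression metrics, split/CV protocols and aggregation conventions.

Metrics are R^2, MAE and RMSE evaluated on sample-index coordinates, with
conversion to milliseconds at the recording's sampling rate.  Aggregation
follows the reference conventions: sample standard deviation (n-1
denominator), display rounding only at report time, and feature averaging
after excluding the two hard diastolic features (RE, RF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MetricReport",
    "AggregateSummary",
    "r2",
    "mae",
    "rmse",
    "samples_to_ms",
    "metric_report",
    "summarize_runs",
    "truncate_decimals",
    "aggregate_features",
    "kfold_indices",
    "kfold_cv",
    "repeated_split_eval",
    "train_test_split_indices",
]

DEFAULT_EXCLUDE = frozenset({"RE", "RF"})


def _check_pair(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    if y.size < 2:
        raise ValueError("need at least 2 paired values")
    return y, yhat


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SSres/SStot."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: zero label variance")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def samples_to_ms(value: float | np.ndarray, sampling_rate: float):
    """Convert a quantity in samples to milliseconds."""
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    return value / sampling_rate * 1000.0


@dataclass(frozen=True)
class MetricReport:
    """Per-feature metric bundle on one split."""

    feature: str
    split: str
    r2: float
    mae_samples: float
    rmse_samples: float
    n: int
    sampling_rate: float = 2000.0

    @property
    def mae_ms(self) -> float:
        return samples_to_ms(self.mae_samples, self.sampling_rate)

    @property
    def rmse_ms(self) -> float:
        return samples_to_ms(self.rmse_samples, self.sampling_rate)


def metric_report(
    feature: str,
    split: str,
    y: np.ndarray,
    yhat: np.ndarray,
    sampling_rate: float = 2000.0,
) -> MetricReport:
    return MetricReport(
        feature=feature,
        split=split,
        r2=r2(y, yhat),
        mae_samples=mae(y, yhat),
        rmse_samples=rmse(y, yhat),
        n=len(np.asarray(y)),
        sampling_rate=sampling_rate,
    )


def summarize_runs(values: Sequence[float]) -> dict[str, float]:
    """Mean and sample standard deviation (n-1 denominator) of run values."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values to summarize")
    return {
        "mean": float(np.mean(vals)),
        "sample_sd": float(np.std(vals, ddof=1)),
    }


def truncate_decimals(value: float, decimals: int) -> float:
    """Truncate (floor toward zero) at a decimal position, for display.

    Reference summary tables print standard deviations truncated -- not
    rounded -- at five decimals; this helper reproduces that display.
    """
    factor = 10.0**decimals
    return math.trunc(value * factor) / factor


@dataclass
class AggregateSummary:
    """Per-feature values over runs/folds with their summary statistics."""

    feature: str
    values: list[float]
    exclusions: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sample_sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def aggregate_features(
    per_feature_values: Mapping[str, float],
    exclude: Iterable[str] = DEFAULT_EXCLUDE,
    display_decimals: int | None = None,
) -> float:
    """Mean over features after exclusion; rounding only at display."""
    exclude = set(exclude)
    kept = [v for k, v in per_feature_values.items() if k not in exclude]
    if not kept:
        raise ValueError("no features left after exclusion")
    value = float(np.mean(kept))
    if display_decimals is not None:
        value = round(value, display_decimals)
    return value


# ---------------------------------------------------------------------------
# split protocols


def train_test_split_indices(
    n: int, test_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_test = int(round(n * test_frac))
    if n_test == 0 or n_test == n:
        raise ValueError(f"split of {n} samples at {test_frac} leaves an empty side")
    return perm[n_test:], perm[:n_test]


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint seed-deterministic folds with sizes differing by at most 1."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


Trainer = Callable[[np.ndarray, np.ndarray, np.ndarray, str, int], np.ndarray]
"""(X_train, y_train, X_test, feature, seed) -> predictions on X_test."""


def _default_trainer(X_train, y_train, X_test, feature, seed):
    from .cnn import TrainConfig, predict, train_localizer
    from .reference import structure_for

    config = TrainConfig(seed=seed)
    model = train_localizer(
        X_train, y_train, structure_for(feature, s1_choice=1), config, feature=feature
    )
    return predict(model, X_test)["coordinate"]


def repeated_split_eval(
    dataset,
    features: Sequence[str],
    n_repeats: int = 10,
    test_frac: float = 0.3,
    seed: int = 0,
    trainer: Trainer | None = None,
    metric: str = "r2",
) -> dict[str, AggregateSummary]:
    """n_repeats independent random splits; per-feature mean +/- sample SD.

    Each repeat redraws the split *and* reseeds the trainer (new weight
    init).  Per-repeat training failures are recorded in ``extra`` rather
    than aborting the experiment.
    """
    trainer = _default_trainer if trainer is None else trainer
    metric_fn = {"r2": r2, "mae": mae, "rmse": rmse}[metric]
    out: dict[str, AggregateSummary] = {}
    for feature in features:
        X, y = dataset.arrays(feature)
        values, failures = [], []
        for rep in range(n_repeats):
            rng = np.random.default_rng((seed, rep))
            tr, te = train_test_split_indices(len(y), test_frac, rng)
            try:
                yhat = trainer(X[tr], y[tr], X[te], feature, seed + rep)
                values.append(metric_fn(y[te], yhat))
            except Exception as exc:
                failures.append(f"repeat {rep}: {exc}")
        out[feature] = AggregateSummary(
            feature=feature, values=values, extra={"failures": failures}
        )
    return out


def kfold_cv(
    dataset,
    features: Sequence[str],
    k: int = 5,
    seed: int = 0,
    trainer: Trainer | None = None,
    metric: str = "r2",
) -> dict[str, AggregateSummary]:
    """k-fold cross-validation; each fold serves once as the test set."""
    trainer = _default_trainer if trainer is None else trainer
    metric_fn = {"r2": r2, "mae": mae, "rmse": rmse}[metric]
    out: dict[str, AggregateSummary] = {}
    for feature in features:
        X, y = dataset.arrays(feature)
        folds = kfold_indices(len(y), k, np.random.default_rng(seed))
        values, failures = [], []
        for fi, test_idx in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != fi])
            try:
                yhat = trainer(X[train_idx], y[train_idx], X[test_idx], feature, seed + fi)
                values.append(metric_fn(y[test_idx], yhat))
            except Exception as exc:
                failures.append(f"fold {fi}: {exc}")
        out[feature] = AggregateSummary(
            feature=feature, values=values, extra={"failures": failures}
        )
    return out
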