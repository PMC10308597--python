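"""The metallization metric: a 1-D linear discriminant on 11 MHz features.

The impedance magnitude and phase of each bead's peak at 11 MHz are z-score
scaled (pooled statistics over both training classes) and projected onto a
two-class Fisher discriminant trained on high-metal and low-metal reference
bead sets.  The projection is oriented so that a higher score means more
metallization; the mean score over a trial's beads is the trial-level
metallization metric, and the midpoint of the projected training-class
means serves as the positive/negative decision threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError, NumericalError
from .pulses import BeadRecord

__all__ = [
    "MetricModel",
    "features_from_records",
    "fit_lda",
    "fit_scaler",
    "project",
    "train_metric",
    "trial_metric",
]

#: Channel index of the 11 MHz carrier among the default six.
FEATURE_CHANNEL = 4
FEATURE_FREQ = 11e6


@dataclass(frozen=True)
class MetricModel:
    """Trained scaler + discriminant direction + orientation."""

    feature_freq: float
    feature_means: tuple[float, float]
    feature_sds: tuple[float, float]
    w: tuple[float, float]  # unit-norm discriminant direction
    sign: int  # +-1, oriented so higher score = more metal
    class_means_projected: tuple[float, float]  # (high, low), oriented
    decision_threshold: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MetricModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            feature_freq=raw["feature_freq"],
            feature_means=tuple(raw["feature_means"]),
            feature_sds=tuple(raw["feature_sds"]),
            w=tuple(raw["w"]),
            sign=int(raw["sign"]),
            class_means_projected=tuple(raw["class_means_projected"]),
            decision_threshold=raw["decision_threshold"],
        )


def features_from_records(
    records: list[BeadRecord], channel: int = FEATURE_CHANNEL
) -> np.ndarray:
    """(n, 2) feature matrix: peak magnitude and phase change at 11 MHz."""
    if not records:
        raise ConfigError("no records to extract features from")
    return np.array([[r.dzp[channel], r.dphip[channel]] for r in records])


def fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-feature mean and standard deviation (z-score transform)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ConfigError("scaler needs a 2-D feature matrix with >= 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        raise NumericalError(
            "a feature has zero variance; z-scoring is undefined"
        )
    return means, sds


def fit_lda(
    X_high: np.ndarray,
    X_low: np.ndarray,
    feature_freq: float = FEATURE_FREQ,
) -> MetricModel:
    """Two-class Fisher discriminant on z-scored features.

    ``w`` is proportional to ``S_w^-1 (mu_high - mu_low)`` with ``S_w`` the
    pooled within-class scatter, normalized to unit length and oriented so
    the high-metal class projects higher.
    """
    X_high = np.asarray(X_high, dtype=float)
    X_low = np.asarray(X_low, dtype=float)
    if len(X_high) < 2 or len(X_low) < 2:
        raise ConfigError("both classes need at least two beads")
    pooled = np.vstack([X_high, X_low])
    means, sds = fit_scaler(pooled)
    zh = (X_high - means) / sds
    zl = (X_low - means) / sds

    mu_h, mu_l = zh.mean(axis=0), zl.mean(axis=0)
    scatter = (zh - mu_h).T @ (zh - mu_h) + (zl - mu_l).T @ (zl - mu_l)
    try:
        w = np.linalg.solve(scatter, mu_h - mu_l)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "within-class scatter is singular; regularize by adding eps*I "
            "with eps = 1e-6 * trace(S_w) to the scatter matrix"
        ) from exc
    norm = np.linalg.norm(w)
    if norm == 0 or not np.all(np.isfinite(w)):
        raise NumericalError(
            "degenerate discriminant direction (identical class means?); "
            "regularize by adding eps*I with eps = 1e-6 * trace(S_w)"
        )
    w = w / norm
    sign = 1
    if w @ mu_h < w @ mu_l:
        sign = -1
    proj_h = float(sign * (w @ mu_h))
    proj_l = float(sign * (w @ mu_l))
    return MetricModel(
        feature_freq=feature_freq,
        feature_means=tuple(means),
        feature_sds=tuple(sds),
        w=tuple(w),
        sign=sign,
        class_means_projected=(proj_h, proj_l),
        decision_threshold=0.5 * (proj_h + proj_l),
    )


def train_metric(
    high_records: list[BeadRecord], low_records: list[BeadRecord]
) -> MetricModel:
    """Fit the metric from high-metal and low-metal reference bead records."""
    return fit_lda(
        features_from_records(high_records), features_from_records(low_records)
    )


def project(records: list[BeadRecord], model: MetricModel) -> np.ndarray:
    """Per-bead metallization scores (oriented discriminant projection)."""
    X = features_from_records(records)
    if not np.all(np.isfinite(X)):
        raise ConfigError("records carry non-finite 11 MHz features")
    z = (X - np.asarray(model.feature_means)) / np.asarray(model.feature_sds)
    return model.sign * (z @ np.asarray(model.w))


def trial_metric(scores: np.ndarray) -> float:
    """Trial-level metallization metric: the mean per-bead score."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ConfigError("trial_metric requires at least one score")
    return float(scores.mean())
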