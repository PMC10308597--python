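"""Four-parameter-logistic dose-response fitting, LOD and classification.

The trial-level metallization metric measured across a dilution series is
fit with the 4PL curve

    y = d + (a - d) / (1 + (x/c)^b)

where ``a`` is the response at zero concentration, ``d`` the saturation
ceiling, ``c`` the inflection concentration (nM) and ``b`` the Hill slope.
The limit of detection is the concentration at which the fitted curve
crosses ``mean(blank) + 3 * sd(blank)``, solved in closed form by inverting
the 4PL.  Trial classification compares a trial's metric with the
discriminant decision threshold learned from the training bead sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError, NumericalError
from .metric import MetricModel

__all__ = [
    "DoseResponseFit",
    "classify_trial",
    "fit_4pl",
    "four_pl",
    "inverse_4pl",
    "lod",
]


def four_pl(x, a: float, b: float, c: float, d: float):
    """Evaluate the 4PL curve; valid at x = 0 for b > 0 (y -> a)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / c) ** b, 0.0)
    return d + (a - d) / (1.0 + ratio)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters plus diagnostics."""

    a: float  # response floor (y at x = 0)
    b: float  # Hill slope
    c: float  # inflection concentration (nM)
    d: float  # response ceiling
    residual_sd: float
    converged: bool
    message: str = ""
    lod: float = math.nan

    def predict(self, x) -> np.ndarray:
        return four_pl(x, self.a, self.b, self.c, self.d)


def fit_4pl(conc, y) -> DoseResponseFit:
    """Least-squares 4PL fit of trial metrics against concentration (nM).

    Initialization from the data: a = response at the lowest concentration,
    d = response at the highest, c = concentration nearest mid-response,
    b = 1.  Deterministic given the data.  Degenerate data (constant
    response, too few distinct concentrations) yields a flagged
    ``converged=False`` fit, never a silent failure.
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(y, dtype=float)
    if conc.shape != y.shape or conc.ndim != 1:
        raise ConfigError("conc and y must be 1-D arrays of equal length")
    if np.any(conc < 0):
        raise ConfigError("concentrations must be non-negative")
    if not np.all(np.isfinite(y)):
        raise ConfigError("responses must be finite")
    if len(np.unique(conc)) < 4:
        raise ConfigError("need at least 4 distinct concentrations")

    order = np.argsort(conc, kind="stable")
    conc_s, y_s = conc[order], y[order]
    span = y_s.max() - y_s.min()
    if span == 0:
        return DoseResponseFit(
            a=float(y_s[0]), b=math.nan, c=math.nan, d=float(y_s[0]),
            residual_sd=0.0, converged=False,
            message="constant response; 4PL is unidentifiable",
        )

    a0 = float(np.mean(y_s[conc_s == conc_s.min()]))
    d0 = float(np.mean(y_s[conc_s == conc_s.max()]))
    mid = 0.5 * (a0 + d0)
    positive = conc_s[conc_s > 0]
    c0 = float(positive[np.argmin(np.abs(y_s[conc_s > 0] - mid))])
    theta0 = np.array([a0, 1.0, c0, d0])

    def residuals(theta):
        a, b, c, d = theta
        return four_pl(conc, a, b, c, d) - y

    lower = [-np.inf, 1e-3, 1e-12, -np.inf]
    upper = [np.inf, 50.0, 1e6 * max(conc.max(), 1.0), np.inf]
    result = least_squares(
        residuals, theta0, bounds=(lower, upper), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    a, b, c, d = result.x
    dof = max(len(y) - 4, 1)
    residual_sd = float(np.sqrt(np.sum(result.fun**2) / dof))
    ok = bool(result.success) and np.all(np.isfinite(result.x)) and c > 0
    return DoseResponseFit(
        a=float(a), b=float(b), c=float(c), d=float(d),
        residual_sd=residual_sd, converged=ok,
        message="" if ok else f"fit did not converge: {result.message}",
    )


def inverse_4pl(y: float, fit: DoseResponseFit) -> float:
    """Concentration at which the fitted curve takes the value ``y``.

    Defined on the open response interval between ``a`` and ``d``.
    """
    lo, hi = sorted((fit.a, fit.d))
    if not lo < y < hi:
        raise ConfigError(
            f"response {y} outside the open fitted range ({lo:.4g}, {hi:.4g})"
        )
    return float(fit.c * ((fit.a - fit.d) / (y - fit.d) - 1.0) ** (1.0 / fit.b))


def lod(fit: DoseResponseFit, blank_scores) -> DoseResponseFit:
    """Limit of detection: curve crossing of mean(blank) + 3*sd(blank).

    Returns a copy of the fit with ``lod`` filled in (nM).  If the cutoff
    exceeds the fitted ceiling the LOD is beyond the tested range and is
    flagged as NaN with an explanatory message.
    """
    if not fit.converged:
        raise NumericalError("cannot compute an LOD from a non-converged fit")
    blanks = np.asarray(blank_scores, dtype=float)
    if blanks.size < 2:
        raise ConfigError("need at least two blank replicate scores")
    cutoff = float(blanks.mean() + 3.0 * blanks.std(ddof=1))
    lo, hi = sorted((fit.a, fit.d))
    if cutoff >= hi:
        return DoseResponseFit(
            **{**fit.__dict__, "lod": math.nan,
               "message": "LOD beyond tested range: blank cutoff exceeds the "
                          "fitted ceiling"}
        )
    if cutoff <= lo:
        # blank mean+3sd below the fitted floor: curve exceeds the cutoff
        # already at zero concentration
        return DoseResponseFit(**{**fit.__dict__, "lod": 0.0})
    return DoseResponseFit(
        **{**fit.__dict__, "lod": inverse_4pl(cutoff, fit)}
    )


def classify_trial(trial_metric_value: float, model: MetricModel) -> str:
    """'positive' iff the trial metric exceeds the decision threshold."""
    return (
        "positive"
        if trial_metric_value > model.decision_threshold
        else "negative"
    )
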