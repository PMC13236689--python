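"""Goodness-of-fit and prediction-error metrics for biomass models.

All metrics operate on observed/predicted vectors in kilograms and follow
the conventions standard in forest biometrics: R² with the total sum of
squares taken about the observed mean, AIC in its least-squares form
``2k + n[ln(2π·SSE/n) + 1]`` with the small-sample AICc correction
``2k(k+1)/(n−k−1)``, and a signed relative bias expressed in percent
(positive when observations exceed predictions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def _as_vectors(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise MetricError(f"length mismatch: {y.size} observed vs {yhat.size} predicted")
    if y.size == 0:
        raise MetricError("empty vectors")
    return y, yhat


def r_squared(y, yhat) -> float:
    """Coefficient of determination, 1 − SSE/SST with SST about the mean of y."""
    y, yhat = _as_vectors(y, yhat)
    if y.size < 2:
        raise MetricError("R² requires at least 2 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise MetricError("R² undefined: observed values have zero variance")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def adj_r_squared(r2: float, n: int, p: int) -> float:
    """Adjusted R² penalising for p predictors at sample size n."""
    if n <= p + 1:
        raise MetricError(f"adjusted R² undefined for n={n}, p={p} (need n > p+1)")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rmse(y, yhat) -> float:
    """Root mean square error in the units of y (kg)."""
    y, yhat = _as_vectors(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    """Mean absolute error in the units of y (kg)."""
    y, yhat = _as_vectors(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def aic(y, yhat, k: int, n: int | None = None) -> float:
    """Least-squares AIC: 2k + n[ln(2π·SSE/n) + 1].

    ``k`` counts the mean-structure parameters only (k = 2 for a power law:
    a and b); the error variance is not counted.
    """
    y, yhat = _as_vectors(y, yhat)
    if n is None:
        n = y.size
    if n <= k + 1:
        raise MetricError(f"AIC undefined for n={n}, k={k} (need n > k+1)")
    sse = float(np.sum((y - yhat) ** 2))
    if sse <= 0.0:
        raise MetricError("AIC undefined: zero residual sum of squares")
    return 2.0 * k + n * (math.log(2.0 * math.pi * sse / n) + 1.0)


def aicc(y, yhat, k: int, n: int | None = None) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n−k−1)."""
    y, _ = _as_vectors(y, yhat)
    if n is None:
        n = y.size
    return aic(y, yhat, k, n) + 2.0 * k * (k + 1) / (n - k - 1)


def bias_pct(y, yhat) -> float:
    """Mean relative error in percent: (100/n) Σ (yᵢ − ŷᵢ)/yᵢ.

    Positive when observations exceed predictions. Unstable when any yᵢ is
    near zero — retained without winsorising because small leaf/branch masses
    legitimately inflate this metric for those components.
    """
    y, yhat = _as_vectors(y, yhat)
    if np.any(y == 0.0):
        raise MetricError("Bias% undefined: observed value equal to zero")
    return float(100.0 * np.mean((y - yhat) / y))


@dataclass(frozen=True)
class MetricSet:
    """Bundle of evaluation metrics for one fitted model on one dataset."""

    r2: float
    adj_r2: float
    rmse: float
    mae: float
    bias_pct: float
    aic: float
    aicc: float
    n: int
    k: int
    p: int

    @classmethod
    def compute(cls, y, yhat, k: int = 2, p: int = 1) -> "MetricSet":
        y, yhat = _as_vectors(y, yhat)
        n = y.size
        r2 = r_squared(y, yhat)
        return cls(
            r2=r2,
            adj_r2=adj_r_squared(r2, n, p),
            rmse=rmse(y, yhat),
            mae=mae(y, yhat),
            bias_pct=bias_pct(y, yhat),
            aic=aic(y, yhat, k, n),
            aicc=aicc(y, yhat, k, n),
            n=n,
            k=k,
            p=p,
        )
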