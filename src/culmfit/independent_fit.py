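"""Weighted nonlinear least-squares power-law fits, y = a·x^b.

Residual variance of culm biomass grows roughly linearly with stem
diameter, so fitting uses variance weights 1/x² (generalised to the
model's own predictor when H or D²H is used). Estimation is on the
original scale — no log transform, avoiding retransformation bias — via
Levenberg–Marquardt style least squares seeded from a log–log OLS fit plus
fixed multiplicative perturbations; the best weighted objective wins, which
makes the fit deterministic given the data.

Fit statistics (RMSE, adjusted R²) are computed on unweighted residuals in
kg so they are comparable across predictors and with reported values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import metrics
from .data_model import PREDICTORS, CulmRecord, ValidationError

#: multiplicative multi-start perturbations applied to the log–log OLS seed
_START_FACTORS = ((1.0, 1.0), (1.5, 1.0), (0.5, 1.0), (1.0, 1.2), (1.0, 0.8))


class FitError(RuntimeError):
    """Optimisation failed to converge from every start."""


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted single-predictor power law for one biomass component."""

    component: str
    predictor: str
    a: float
    b: float
    weight_spec: str  # "1/x2" or "none"
    rmse: float
    adj_r2: float
    n: int
    converged: bool
    objective: float  # weighted SSE at the optimum
    ci_a: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None
    ci_seed: int | None = None

    def predict(self, x) -> np.ndarray | float:
        return predict(self, x)


def _weights(x: np.ndarray, weight_spec: str) -> np.ndarray:
    if weight_spec == "1/x2":
        return 1.0 / x**2
    if weight_spec in ("none", None):
        return np.ones_like(x)
    raise ValueError(f"unknown weight spec {weight_spec!r}")


def weighted_objective(x, y, a, b, weight_spec: str = "1/x2") -> float:
    """Σ wᵢ (yᵢ − a·xᵢ^b)² — the criterion the fit minimises."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = _weights(x, weight_spec)
    return float(np.sum(w * (y - a * x**b) ** 2))


def _solve(x, y, sqrt_w, a0, b0):
    lx = np.log(x)

    def resid(theta):
        a, b = theta
        return sqrt_w * (y - a * np.exp(b * lx))

    def jac(theta):
        a, b = theta
        xb = np.exp(b * lx)
        return np.column_stack((-sqrt_w * xb, -sqrt_w * a * xb * lx))

    return least_squares(
        resid, x0=[a0, b0], jac=jac, method="lm", xtol=1e-10, ftol=1e-12, gtol=1e-12,
        max_nfev=500 * 2,
    )


def fit_power(
    x,
    y,
    weights: str = "1/x2",
    component: str = "agb",
    predictor: str = "dbh",
    starts: Sequence[tuple[float, float]] | None = None,
) -> PowerLawFit:
    """Fit y = a·x^b by weighted NLS.

    ``weights`` is ``"1/x2"`` (default) or ``"none"``. ``starts`` overrides
    the multi-start list with explicit (a, b) pairs — used by bootstrap
    refits that warm-start from the full-data estimate.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError("x and y differ in length")
    if x.size < 3:
        raise ValidationError("power-law fit requires at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("power-law fit requires positive x and y")
    sqrt_w = np.sqrt(_weights(x, weights))

    if starts is None:
        # log-log OLS seed; robust even when the data are not exactly power-law
        b0, la0 = np.polyfit(np.log(x), np.log(y), 1)
        a0 = float(np.exp(la0))
        starts = [(a0 * fa, b0 * fb) for fa, fb in _START_FACTORS]

    best = None
    for a0, b0 in starts:
        try:
            res = _solve(x, y, sqrt_w, a0, b0)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"power-law fit failed for {component}~{predictor} from every start")

    a, b = (float(v) for v in best.x)
    yhat = a * x**b
    try:
        adj_r2 = metrics.adj_r_squared(metrics.r_squared(y, yhat), x.size, 1)
    except metrics.MetricError:  # constant y: R² undefined, fit still valid
        adj_r2 = float("nan")
    return PowerLawFit(
        component=component,
        predictor=predictor,
        a=a,
        b=b,
        weight_spec=weights if weights else "none",
        rmse=metrics.rmse(y, yhat),
        adj_r2=adj_r2,
        n=int(x.size),
        converged=bool(best.status > 0),
        objective=2.0 * float(best.cost),  # least_squares cost = 0.5·SSE_w
    )


def predict(fit: PowerLawFit, x):
    """Evaluate a·x^b; x must be positive."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa <= 0):
        raise ValidationError("predictor value must be positive")
    out = fit.a * xa**fit.b
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def bootstrap_ci(
    x,
    y,
    weights: str = "1/x2",
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Nonparametric case-resampling percentile CIs for (a, b).

    Replicate fits warm-start from the full-data estimate; non-converged
    replicates are dropped, and more than 20% failures raises.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 5:
        raise ValidationError("bootstrap CI requires at least 5 points")
    if B < 200:
        raise ValidationError("bootstrap CI requires at least 200 replicates")
    full = fit_power(x, y, weights=weights)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, x.size, size=(B, x.size))
    a_s, b_s, failures = [], [], 0
    for idx in draws:
        try:
            f = fit_power(x[idx], y[idx], weights=weights, starts=[(full.a, full.b)])
        except (FitError, ValidationError, metrics.MetricError):
            failures += 1
            continue
        if not f.converged:
            failures += 1
            continue
        a_s.append(f.a)
        b_s.append(f.b)
    if failures > 0.2 * B:
        raise FitError(f"bootstrap CI unreliable: {failures}/{B} replicate fits failed")
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    ci_a = tuple(float(v) for v in np.percentile(a_s, [lo, hi]))
    ci_b = tuple(float(v) for v in np.percentile(b_s, [lo, hi]))
    return ci_a, ci_b


def model_aicc(x, y, fit: PowerLawFit, k: int = 2) -> float:
    """AICc from the full likelihood of the fitted heteroscedastic model.

    Under the estimation model y ~ N(a·x^b, σ²x²) the exact −2·logL is
    n[ln(2π·SSEw/n) + 1] + 2Σln xᵢ with SSEw the 1/x²-weighted residual sum
    of squares; the Σln xᵢ term makes the criterion comparable across
    candidate predictors measured on different scales. For an unweighted fit
    this reduces to the ordinary least-squares AICc.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n <= k + 1:
        raise metrics.MetricError(f"AICc undefined for n={n}, k={k}")
    if fit.weight_spec == "none":
        return metrics.aicc(y, fit.predict(x), k=k)
    sse_w = weighted_objective(x, y, fit.a, fit.b, fit.weight_spec)
    if sse_w <= 0:
        raise metrics.MetricError("AICc undefined: zero residual sum of squares")
    aic = 2.0 * k + n * (np.log(2 * np.pi * sse_w / n) + 1.0) + 2.0 * float(np.sum(np.log(x)))
    return float(aic + 2.0 * k * (k + 1) / (n - k - 1))


def fit_component(
    records: Sequence[CulmRecord],
    component: str,
    predictor: str = "dbh",
    weights: str = "1/x2",
    ci: bool = False,
    B: int = 1000,
    seed: int = 0,
) -> PowerLawFit:
    """Fit one component (or 'agb') against one predictor from culm records."""
    x = np.array([r.predictor(predictor) for r in records])
    y = np.array([r.biomass(component) for r in records])
    fit = fit_power(x, y, weights=weights, component=component, predictor=predictor)
    if ci:
        ci_a, ci_b = bootstrap_ci(x, y, weights=weights, B=B, seed=seed)
        fit = replace(fit, ci_a=ci_a, ci_b=ci_b, ci_seed=seed)
    return fit


def select_predictor(
    records: Sequence[CulmRecord],
    component: str,
    predictors: Sequence[str] = PREDICTORS,
    weights: str = "1/x2",
    B: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank candidate predictors for one component by AICc.

    Returns one row per candidate with AICc, ΔAICc versus the best, and
    bootstrap out-of-bag R²/RMSE/MAE. The winner (first row) has the lowest
    AICc; exact ties break by the fixed predictor order DBH < H < D²H.
    AICc comes from :func:`model_aicc`, the full likelihood of the
    heteroscedastic fitting model, so candidates measured on different
    scales are comparable.
    """
    from .validation import IndependentFamily, bootstrap_oob  # local: avoid cycle

    if len(predictors) < 2:
        raise ValidationError("predictor selection needs at least 2 candidates")
    y = np.array([r.biomass(component) for r in records])
    rows = []
    for rank, p in enumerate(predictors):
        x = np.array([r.predictor(p) for r in records])
        try:
            f = fit_power(x, y, weights=weights, component=component, predictor=p)
        except (FitError, ValidationError) as err:
            rows.append(
                {"predictor": p, "order": rank, "failed": True, "error": str(err)}
            )
            continue
        report = bootstrap_oob(
            records,
            IndependentFamily(components=(component,), predictor=p, weights=weights),
            B=B,
            seed=seed,
        )
        summ = report.summary()
        row = {
            "predictor": p,
            "order": rank,
            "failed": False,
            "a": f.a,
            "b": f.b,
            "aicc": model_aicc(x, y, f, k=2),
            "boot_r2": summ.loc[component, "r2_mean"],
            "boot_rmse": summ.loc[component, "rmse_mean"],
            "boot_mae": summ.loc[component, "mae_mean"],
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise FitError(f"all candidate fits failed for component {component!r}")
    table = table.sort_values(["failed", "aicc", "order"], kind="stable").reset_index(drop=True)
    best = table.loc[0, "aicc"]
    table["delta_aicc"] = table["aicc"] - best
    return table
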