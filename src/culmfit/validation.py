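"""Bootstrap out-of-bag validation of fitted model families.

The protocol: draw n indices with replacement, refit the model family on
the in-bag sample, predict the out-of-bag (OOB) records — those never
drawn — and compute R², RMSE, MAE and Bias% on the OOB observed-vs-
predicted pairs; repeat B times (default 1000) and aggregate each metric
as mean ± sd over completed iterations. OOB R² uses the OOB subset's own
mean in the total sum of squares (standard out-of-sample R²). Iterations
whose OOB set is smaller than 3 records or has zero variance in some
component are skipped and counted, so B retains its interpretation as the
number of attempted resamples.

A single seeded generator drives everything: per-iteration substreams are
derived from the iteration index, so changing B never reshuffles earlier
draws. Final reported parameters always come from the full-data fit, never
from bootstrap averages.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .data_model import COMPONENTS, CulmRecord, ValidationError

_METRICS = ("r2", "rmse", "mae", "bias_pct")


class ModelFamily(Protocol):
    """A refittable model family evaluated by the bootstrap."""

    name: str
    components: tuple[str, ...]

    def fit(self, records: Sequence[CulmRecord]):
        """Fit on a sample; returns an object for :meth:`predict`."""

    def predict(self, model, records: Sequence[CulmRecord]) -> dict[str, np.ndarray]:
        """Per-component predictions (kg) for the given records."""


@dataclass(frozen=True)
class IndependentFamily:
    """Separately fitted weighted power laws per component (and AGB)."""

    components: tuple[str, ...] = ("culm", "branch", "leaf", "agb")
    predictor: str = "dbh"
    weights: str = "1/x2"
    name: str = "independent"
    starts: tuple[tuple[float, float], ...] | None = None

    def fit(self, records):
        from .independent_fit import fit_component

        return {
            c: fit_component(records, c, predictor=self.predictor, weights=self.weights)
            for c in self.components
        }

    def predict(self, model, records):
        x = np.array([r.predictor(self.predictor) for r in records])
        return {c: model[c].predict(x) for c in self.components}


@dataclass(frozen=True)
class SurFamily:
    """The additivity-constrained compatible system (components + exact-sum AGB)."""

    components: tuple[str, ...] = ("culm", "branch", "leaf", "agb")
    weights: str = "1/x2"
    name: str = "sur"
    max_cycles: int = 50

    def fit(self, records):
        from .sur_system import fit_sur

        return fit_sur(list(records), weights=self.weights, max_cycles=self.max_cycles)

    def predict(self, model, records):
        from .sur_system import predict_system

        x = np.array([r.predictor("dbh") for r in records])
        pred = predict_system(model, x)
        return {c: pred[c] for c in self.components}


@dataclass
class BootstrapReport:
    """Per-iteration OOB metrics and their mean ± sd aggregation."""

    family: str
    components: tuple[str, ...]
    iterations: pd.DataFrame  # columns: iteration, component, r2, rmse, mae, bias_pct
    completed: int
    skipped: int
    B: int
    seed: int
    n: int
    oob_fractions: np.ndarray = field(default_factory=lambda: np.array([]))

    def summary(self) -> pd.DataFrame:
        """Mean and sd per metric, one row per component."""
        if self.completed == 0:
            raise ValidationError("empty report: no completed bootstrap iterations")
        g = self.iterations.groupby("component", sort=False)
        out = {}
        for m in _METRICS:
            out[f"{m}_mean"] = g[m].mean()
            out[f"{m}_sd"] = g[m].std(ddof=1).fillna(0.0)
        return pd.DataFrame(out).reindex(list(self.components))


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    # substream keyed by iteration index: B can grow without reshuffling
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration,)))


def bootstrap_oob(
    records: Sequence[CulmRecord],
    model_spec: ModelFamily,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapReport:
    """Run the B-iteration bootstrap-OOB protocol for one model family."""
    records = list(records)
    n = len(records)
    if n < 10:
        raise ValidationError("bootstrap OOB requires at least 10 records")
    if B < 1:
        raise ValidationError("B must be at least 1")
    observed = {c: np.array([r.biomass(c) for r in records]) for c in model_spec.components}
    rows = []
    oob_fracs = []
    skipped = 0
    for it in range(B):
        rng = _iteration_rng(seed, it)
        idx = rng.integers(0, n, size=n)
        inbag = set(idx.tolist())
        oob = np.array([i for i in range(n) if i not in inbag])
        assert not inbag.intersection(oob.tolist())  # OOB rows never seen in fitting
        oob_fracs.append(oob.size / n)
        if oob.size < 3:
            skipped += 1
            continue
        degenerate = any(np.ptp(observed[c][oob]) == 0.0 for c in model_spec.components)
        if degenerate:
            skipped += 1
            continue
        try:
            model = model_spec.fit([records[i] for i in idx])
            preds = model_spec.predict(model, [records[i] for i in oob])
        except Exception:
            skipped += 1
            continue
        for c in model_spec.components:
            y = observed[c][oob]
            yhat = np.asarray(preds[c])
            rows.append(
                {
                    "iteration": it,
                    "component": c,
                    "r2": metrics.r_squared(y, yhat),
                    "rmse": metrics.rmse(y, yhat),
                    "mae": metrics.mae(y, yhat),
                    "bias_pct": metrics.bias_pct(y, yhat),
                }
            )
    completed = B - skipped
    if skipped > 0.1 * B:
        warnings.warn(
            f"{skipped}/{B} bootstrap iterations skipped for family {model_spec.name!r}"
        )
    cols = ["iteration", "component", *_METRICS]
    return BootstrapReport(
        family=model_spec.name,
        components=tuple(model_spec.components),
        iterations=pd.DataFrame(rows, columns=cols),
        completed=completed,
        skipped=skipped,
        B=B,
        seed=seed,
        n=n,
        oob_fractions=np.asarray(oob_fracs),
    )


def format_mean_sd(mean: float, sd: float, decimals: int = 3) -> str:
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def parse_mean_sd(text: str) -> tuple[float, float]:
    """Inverse of :func:`format_mean_sd` ("0.944 ± 0.021" -> (0.944, 0.021))."""
    m = re.fullmatch(r"\s*(-?[\d.]+)\s*±\s*(-?[\d.]+)\s*", text)
    if not m:
        raise ValueError(f"cannot parse mean ± sd from {text!r}")
    return float(m.group(1)), float(m.group(2))


def summarize_report(report: BootstrapReport, decimals: int = 3) -> pd.DataFrame:
    """Formatted mean ± sd rows, one per component, for reporting tables."""
    summ = report.summary()
    rows = []
    for comp in summ.index:
        rows.append(
            {
                "component": comp,
                "model_type": report.family,
                "bootstrap_r2": format_mean_sd(
                    summ.loc[comp, "r2_mean"], summ.loc[comp, "r2_sd"], decimals
                ),
                "rmse": format_mean_sd(
                    summ.loc[comp, "rmse_mean"], summ.loc[comp, "rmse_sd"], decimals
                ),
                "bias_pct": format_mean_sd(
                    summ.loc[comp, "bias_pct_mean"], summ.loc[comp, "bias_pct_sd"], decimals
                ),
                "mae": format_mean_sd(
                    summ.loc[comp, "mae_mean"], summ.loc[comp, "mae_sd"], decimals
                ),
            }
        )
    return pd.DataFrame(rows)
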