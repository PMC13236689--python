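"""Synthetic culm datasets with the statistical structure the models assume.

The generator emulates a destructive sample of managed clumping-bamboo
culms: two age cohorts with distinct size distributions, heights linked to
DBH through a noisy power law, component dry biomass following allometric
power laws in DBH with additive Gaussian errors whose standard deviation
grows proportionally with DBH (the heteroscedasticity that motivates 1/DBH²
weighting), and cross-component error correlation (the covariance structure
a seemingly-unrelated-regression system exploits). Observed AGB is the
exact sum of the three components, and fresh/subsample weights are
back-filled from drawn moisture contents so the generated table round-trips
through ``data_model.read_culm_table``.

Defaults reproduce the published study conditions for a 45-culm sample:
cohort DBH distributions and group-mean heights match the descriptive
tables, true allometric parameters equal the compatible-system estimates,
and error scales are moment-matched so component RMSEs at n = 45
approximate the reported fit RMSEs. The height-link and error-scale
constants are derived by the calibration functions below, never hand-typed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import COMPONENTS, CSV_COLUMNS, CulmRecord

# Published study conditions used as calibration anchors ---------------------

#: per age class: (dbh mean, dbh sd) in cm and mean height in m
AGE_CLASS_DBH = {2: (6.23, 1.03), 3: (3.09, 0.91)}
AGE_CLASS_MEAN_H = {2: 10.84, 3: 5.67}
DBH_MIN_CM = 1.6

#: compatible-system allometric truth: component -> (a, b), biomass = a·DBH^b
TRUE_ALLOMETRY = {"culm": (0.088, 2.163), "branch": (0.049, 1.616), "leaf": (0.044, 1.640)}

#: component fit RMSEs (kg) the error scales are moment-matched against
TARGET_RMSE = {"culm": 0.498, "branch": 0.339, "leaf": 0.205}

#: observed moisture-content ranges (%) per component, used to back-fill
#: fresh weights from generated dry biomass
MOISTURE_RANGE_PCT = {
    "culm": (45.68, 78.80),
    "branch": (44.16, 88.30),
    "leaf": (41.18, 69.38),
}

#: plot layout: plot id -> (slope degrees, aspect class)
PLOT_LAYOUT = {
    "P1": (35.0, "semi_sunny"),
    "P2": (25.0, "semi_shaded"),
    "P3": (10.0, "semi_shaded"),
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


def calibrate_height_link(
    anchors: dict[int, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Solve H = c·DBH^d through the two cohort (mean DBH, mean H) anchors.

    Two equations, two unknowns: d = ln(H₂/H₃)/ln(D₂/D₃), c = H₂/D₂^d.
    """
    if anchors is None:
        anchors = {a: (AGE_CLASS_DBH[a][0], AGE_CLASS_MEAN_H[a]) for a in (2, 3)}
    (d2, h2), (d3, h3) = anchors[2], anchors[3]
    d_h = float(np.log(h2 / h3) / np.log(d2 / d3))
    c_h = float(h2 / d2**d_h)
    return c_h, d_h


def _truncnorm(mean: float, sd: float, lower: float) -> stats.rv_continuous:
    a = (lower - mean) / sd
    return stats.truncnorm(a, np.inf, loc=mean, scale=sd)


def calibrate_error_scales(
    age_mix: float = 0.5,
    dbh_params: dict[int, tuple[float, float]] | None = None,
    dbh_min: float = DBH_MIN_CM,
    target_rmse: dict[str, float] | None = None,
) -> dict[str, float]:
    """Moment-match per-component error slopes s_c so that RMSE ≈ target.

    The error model is ε_c ~ N(0, (s_c·DBH)²), so the population RMSE is
    s_c·√E[DBH²] with the expectation taken over the truncated-normal age
    mixture. Inverting gives s_c = RMSE_target / √E[DBH²].
    """
    dbh_params = dbh_params or AGE_CLASS_DBH
    target_rmse = target_rmse or TARGET_RMSE
    e_d2 = 0.0
    for age, w in ((2, age_mix), (3, 1.0 - age_mix)):
        mean, sd = dbh_params[age]
        tn = _truncnorm(mean, sd, dbh_min)
        e_d2 += w * (tn.var() + tn.mean() ** 2)
    root = float(np.sqrt(e_d2))
    return {c: target_rmse[c] / root for c in target_rmse}


def _default_height_c() -> float:
    return calibrate_height_link()[0]


def _default_height_d() -> float:
    return calibrate_height_link()[1]


def _default_error_scales() -> dict[str, float]:
    return calibrate_error_scales()


def _default_corr() -> np.ndarray:
    r = np.full((3, 3), 0.3)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic culm-sample generator.

    Defaults define the study conditions (45 culms, even 2-/3-year age mix,
    cohort DBH distributions, published allometric truth). ``error_corr``
    is the cross-component error correlation matrix; its default off-
    diagonal of 0.3 is a placeholder for the unknown field value.
    """

    n_culms: int = 45
    age_mix: float = 0.5  # proportion of 2-year culms
    dbh_params: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(AGE_CLASS_DBH)
    )
    dbh_min: float = DBH_MIN_CM
    height_c: float = field(default_factory=_default_height_c)
    height_d: float = field(default_factory=_default_height_d)
    height_sigma: float = 0.08  # lognormal scatter of H around the link
    allometry: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TRUE_ALLOMETRY)
    )
    error_scales: dict[str, float] = field(default_factory=_default_error_scales)
    error_corr: np.ndarray = field(default_factory=_default_corr)
    biomass_floor: float = 0.01  # kg; truncates non-physical small/negative draws
    seed: int = 0

    def validate(self) -> None:
        if self.n_culms < 1:
            raise ConfigError("n_culms must be at least 1")
        if not 0.0 < self.age_mix < 1.0:
            raise ConfigError("age_mix must lie strictly between 0 and 1")
        for age, (m, s) in self.dbh_params.items():
            if s <= 0:
                raise ConfigError(f"dbh sd for age {age} must be positive")
        if self.height_sigma < 0:
            raise ConfigError("height_sigma must be non-negative")
        r = np.asarray(self.error_corr, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise ConfigError("error_corr must be a symmetric 3×3 correlation matrix")
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError as err:
            raise ConfigError("error_corr must be positive definite") from err


def generate(config: SyntheticConfig | None = None, **overrides) -> list[CulmRecord]:
    """Draw a synthetic culm sample; fully reproducible for a fixed seed."""
    config = replace(config, **overrides) if config is not None else SyntheticConfig(**overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_culms
    n2 = int(round(n * config.age_mix))
    n2 = min(max(n2, 1), n - 1)
    ages = np.array([2] * n2 + [3] * (n - n2))

    dbh = np.empty(n)
    for age in (2, 3):
        mask = ages == age
        mean, sd = config.dbh_params[age]
        tn = _truncnorm(mean, sd, config.dbh_min)
        dbh[mask] = tn.rvs(size=int(mask.sum()), random_state=rng)

    h = config.height_c * dbh**config.height_d * np.exp(
        config.height_sigma * rng.standard_normal(n)
    )

    chol = np.linalg.cholesky(np.asarray(config.error_corr, dtype=float))
    z = rng.standard_normal((n, 3)) @ chol.T
    dry = {}
    for j, c in enumerate(COMPONENTS):
        a, b = config.allometry[c]
        noise = config.error_scales[c] * dbh * z[:, j]
        dry[c] = np.maximum(a * dbh**b + noise, config.biomass_floor)

    plots = sorted(PLOT_LAYOUT)
    records = []
    for i in range(n):
        plot = plots[i % len(plots)]
        slope, aspect = PLOT_LAYOUT[plot]
        fresh_total, sub_fresh, sub_dry = {}, {}, {}
        for c in COMPONENTS:
            lo, hi = MOISTURE_RANGE_PCT[c]
            mc = rng.uniform(lo, hi)
            fresh_total[c] = dry[c][i] / (1.0 - mc / 100.0)
            frac = rng.uniform(0.05, 0.20)  # subsample mass fraction
            sub_fresh[c] = fresh_total[c] * frac
            sub_dry[c] = sub_fresh[c] * (1.0 - mc / 100.0)
        records.append(
            CulmRecord(
                culm_id=f"C{i + 1:03d}",
                plot_id=plot,
                age_class=int(ages[i]),
                slope_deg=slope,
                aspect=aspect,
                dbh_cm=float(dbh[i]),
                height_m=float(h[i]),
                fresh_total_kg=fresh_total,
                sub_fresh_kg=sub_fresh,
                sub_dry_kg=sub_dry,
            )
        )
    return records


def to_csv_frame(records: list[CulmRecord]) -> pd.DataFrame:
    """Raw-measurement table in the canonical CSV schema (no derived fields)."""
    rows = []
    for r in records:
        row = {
            "culm_id": r.culm_id,
            "plot_id": r.plot_id,
            "age_class": r.age_class,
            "slope_deg": r.slope_deg,
            "aspect": r.aspect,
            "dbh_cm": r.dbh_cm,
            "height_m": r.height_m,
        }
        for c in COMPONENTS:
            row[f"{c}_fresh_total_kg"] = r.fresh_total_kg[c]
            row[f"{c}_sub_fresh_kg"] = r.sub_fresh_kg[c]
            row[f"{c}_sub_dry_kg"] = r.sub_dry_kg[c]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_csv(records: list[CulmRecord], path) -> None:
    to_csv_frame(records).to_csv(path, index=False)
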