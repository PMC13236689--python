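"""Domain types and descriptive statistics for destructively sampled culms.

A harvested culm is recorded in the field as per-component total fresh
weights plus oven-dried subsamples; dry biomass per component is derived by
applying the subsample dry-to-fresh ratio to the total fresh weight.
Aboveground biomass (AGB) is the exact sum of the culm, branch and leaf dry
masses — an identity this module enforces at ingestion and that the
additivity-constrained model system later reproduces at the prediction
level.

Components are keyed ``"culm" | "branch" | "leaf"``; candidate size
predictors are DBH (cm), total height H (m) and the volume proxy
D²H = DBH²·H (cm²·m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPONENTS = ("culm", "branch", "leaf")
PREDICTORS = ("dbh", "h", "d2h")

#: biomass/covariate variables summarised in descriptive tables
SUMMARY_VARIABLES = ("dbh", "h", "agb", "bcu", "bbr", "ble")

ASPECT_CLASSES = ("semi_sunny", "semi_shaded")

#: canonical CSV column names (see read_culm_table's ``dialect`` to remap)
CSV_COLUMNS = (
    ["culm_id", "plot_id", "age_class", "slope_deg", "aspect", "dbh_cm", "height_m"]
    + [f"{c}_{k}" for c in COMPONENTS for k in ("fresh_total_kg", "sub_fresh_kg", "sub_dry_kg")]
)


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class ValidationError(ValueError):
    """A row violates a physical or logical invariant."""


def derive_dry_biomass(fresh_total: float, sub_fresh, sub_dry) -> float:
    """Dry biomass from total fresh weight and oven-dried subsample(s).

    Applies the subsample dry-to-fresh ratio to the component's total fresh
    weight. When several subsamples exist for one component (one per culm
    third or crown layer), the ratio is pooled as Σdry/Σfresh, weighting
    each subsample by its mass; a single subsample degenerates to the plain
    ratio.
    """
    sub_fresh = np.atleast_1d(np.asarray(sub_fresh, dtype=float))
    sub_dry = np.atleast_1d(np.asarray(sub_dry, dtype=float))
    if sub_fresh.shape != sub_dry.shape:
        raise ValidationError("subsample fresh/dry vectors differ in length")
    if fresh_total <= 0 or np.any(sub_fresh <= 0) or np.any(sub_dry <= 0):
        raise ValidationError("weights must be positive")
    tf, td = float(sub_fresh.sum()), float(sub_dry.sum())
    if td > tf:
        raise ValidationError(f"subsample dry weight {td} exceeds fresh weight {tf}")
    if tf > fresh_total:
        raise ValidationError(
            f"subsample fresh weight {tf} exceeds component total {fresh_total}"
        )
    return fresh_total * (td / tf)


def moisture_content(fresh: float, dry: float) -> float:
    """Moisture content in percent: 100·(fresh − dry)/fresh."""
    if dry <= 0 or fresh <= 0:
        raise ValidationError("weights must be positive")
    if dry > fresh:
        raise ValidationError(f"dry weight {dry} exceeds fresh weight {fresh}")
    return 100.0 * (fresh - dry) / fresh


def contrast_pct(mean_a: float, mean_b: float) -> float:
    """Percent difference of a relative to b: 100·(a − b)/b."""
    if mean_b <= 0:
        raise ValidationError("reference mean must be positive")
    return 100.0 * (mean_a - mean_b) / mean_b


def fold_increase(mean_a: float, mean_b: float) -> float:
    """Fold increase of a over b: (a − b)/b — contrast_pct on the 1× scale."""
    return contrast_pct(mean_a, mean_b) / 100.0


@dataclass(frozen=True)
class CulmRecord:
    """One destructively sampled culm with raw weights and derived biomass."""

    culm_id: str
    plot_id: str
    age_class: int
    dbh_cm: float
    height_m: float
    fresh_total_kg: Mapping[str, float]
    sub_fresh_kg: Mapping[str, float]
    sub_dry_kg: Mapping[str, float]
    slope_deg: float | None = None
    aspect: str | None = None
    # derived (populated in __post_init__)
    dry_kg: Mapping[str, float] = field(default_factory=dict)
    moisture_pct: Mapping[str, float] = field(default_factory=dict)
    agb_kg: float = float("nan")
    d2h: float = float("nan")

    def __post_init__(self):
        if self.dbh_cm <= 0:
            raise ValidationError(f"culm {self.culm_id}: DBH must be positive")
        if self.height_m <= 0:
            raise ValidationError(f"culm {self.culm_id}: height must be positive")
        if self.age_class not in (2, 3):
            raise ValidationError(f"culm {self.culm_id}: age class must be 2 or 3")
        if self.aspect is not None and self.aspect not in ASPECT_CLASSES:
            raise ValidationError(f"culm {self.culm_id}: unknown aspect {self.aspect!r}")
        dry, mc = {}, {}
        for c in COMPONENTS:
            try:
                dry[c] = derive_dry_biomass(
                    self.fresh_total_kg[c], self.sub_fresh_kg[c], self.sub_dry_kg[c]
                )
                mc[c] = moisture_content(self.fresh_total_kg[c], dry[c])
            except ValidationError as err:
                raise ValidationError(f"culm {self.culm_id}, component {c}: {err}") from err
        object.__setattr__(self, "dry_kg", dry)
        object.__setattr__(self, "moisture_pct", mc)
        object.__setattr__(self, "agb_kg", dry["culm"] + dry["branch"] + dry["leaf"])
        object.__setattr__(self, "d2h", self.dbh_cm**2 * self.height_m)

    def predictor(self, name: str) -> float:
        if name == "dbh":
            return self.dbh_cm
        if name == "h":
            return self.height_m
        if name == "d2h":
            return self.d2h
        raise KeyError(f"unknown predictor {name!r}")

    def biomass(self, component: str) -> float:
        """Dry biomass (kg) of a component, or total AGB for 'agb'."""
        if component == "agb":
            return self.agb_kg
        return self.dry_kg[component]


def read_culm_table(path, dialect: Mapping[str, str] | None = None) -> list[CulmRecord]:
    """Read a per-culm CSV into validated records.

    ``dialect`` maps canonical column names (see ``CSV_COLUMNS``) to the
    header names actually present in the file. Row order is preserved;
    slope/aspect may be blank.
    """
    df = pd.read_csv(path)
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c not in ("slope_deg", "aspect")]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            slope = row.get("slope_deg")
            aspect = row.get("aspect")
            records.append(
                CulmRecord(
                    culm_id=str(row["culm_id"]),
                    plot_id=str(row["plot_id"]),
                    age_class=int(row["age_class"]),
                    slope_deg=None if slope is None or pd.isna(slope) else float(slope),
                    aspect=None if aspect is None or pd.isna(aspect) else str(aspect),
                    dbh_cm=float(row["dbh_cm"]),
                    height_m=float(row["height_m"]),
                    fresh_total_kg={c: float(row[f"{c}_fresh_total_kg"]) for c in COMPONENTS},
                    sub_fresh_kg={c: float(row[f"{c}_sub_fresh_kg"]) for c in COMPONENTS},
                    sub_dry_kg={c: float(row[f"{c}_sub_dry_kg"]) for c in COMPONENTS},
                )
            )
        except (ValueError, TypeError) as err:
            if isinstance(err, ValidationError):
                raise ValidationError(f"row {i}: {err}") from err
            raise SchemaError(f"row {i}: unparseable value ({err})") from err
    return records


def records_to_frame(records: Sequence[CulmRecord]) -> pd.DataFrame:
    """Tidy per-culm DataFrame with raw and derived columns."""
    rows = []
    for r in records:
        row = {
            "culm_id": r.culm_id,
            "plot_id": r.plot_id,
            "age_class": r.age_class,
            "slope_deg": r.slope_deg,
            "aspect": r.aspect,
            "dbh": r.dbh_cm,
            "h": r.height_m,
            "d2h": r.d2h,
            "bcu": r.dry_kg["culm"],
            "bbr": r.dry_kg["branch"],
            "ble": r.dry_kg["leaf"],
            "agb": r.agb_kg,
        }
        for c in COMPONENTS:
            row[f"{c}_fresh_total_kg"] = r.fresh_total_kg[c]
            row[f"{c}_moisture_pct"] = r.moisture_pct[c]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics for one group of culms."""

    group_key: str | None
    group_value: object
    n: int
    stats: Mapping[str, Mapping[str, float]]  # variable -> {mean, sd, min, max}


def _sample_sd(x: np.ndarray) -> float:
    # sd defined as 0 for a single observation
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def summarize(
    records: Sequence[CulmRecord], group_by: str | None = None
) -> list[GroupSummary]:
    """Per-group mean/sd/min/max/n of DBH, H, AGB and component biomass.

    ``group_by`` is one of ``age_class``, ``slope_deg``, ``aspect`` or None
    for an overall summary. Records with a missing grouping key are skipped.
    Sample sd uses the n−1 denominator (0 for n = 1).
    """
    if not records:
        raise ValidationError("cannot summarise an empty record list")
    df = records_to_frame(records)
    if group_by is None:
        groups: Iterable[tuple[object, pd.DataFrame]] = [(None, df)]
    else:
        if group_by not in ("age_class", "slope_deg", "aspect"):
            raise KeyError(f"unknown grouping key {group_by!r}")
        df = df.dropna(subset=[group_by])
        if df.empty:
            raise ValidationError(f"no records carry a value for {group_by!r}")
        groups = df.groupby(group_by, sort=True)
    out = []
    for value, sub in groups:
        stats = {}
        for v in SUMMARY_VARIABLES:
            x = sub[v].to_numpy(dtype=float)
            stats[v] = {
                "mean": float(x.mean()),
                "sd": _sample_sd(x),
                "min": float(x.min()),
                "max": float(x.max()),
            }
        out.append(GroupSummary(group_key=group_by, group_value=value, n=len(sub), stats=stats))
    return out


def summary_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Flatten GroupSummary objects into a tidy table (one row per group)."""
    rows = []
    for s in summaries:
        row: dict = {"group_key": s.group_key, "group_value": s.group_value, "n": s.n}
        for v, st in s.stats.items():
            for stat, val in st.items():
                row[f"{v}_{stat}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_matrix(records: Sequence[CulmRecord]) -> pd.DataFrame:
    """Pearson correlations of {Bcu, Bbr, Ble, AGB} against {DBH, H, D²H}."""
    if len(records) < 3:
        raise ValidationError("correlation requires at least 3 records")
    df = records_to_frame(records)
    comps = {"bcu": "Bcu", "bbr": "Bbr", "ble": "Ble", "agb": "AGB"}
    preds = {"dbh": "DBH", "h": "H", "d2h": "D2H"}
    for col in list(comps) + list(preds):
        if math.isclose(float(df[col].var(ddof=1)), 0.0, abs_tol=1e-300):
            raise ValidationError(f"correlation undefined: column {col!r} has zero variance")
    mat = pd.DataFrame(
        {
            pname: [float(np.corrcoef(df[c], df[p])[0, 1]) for c in comps]
            for p, pname in preds.items()
        },
        index=list(comps.values()),
    )
    return mat
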