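"""Discounted QALYs and costs at the participant level.

QALYs are the trapezoidal area under the utility-time curve, in years, with
each trapezoid discounted by the year containing its midpoint.  Costs map
resource-use counts onto a unit-cost table (GBP, 2019-2020 price year) with
surgery-related components discounted by the year of surgery and recurring
items apportioned evenly over follow-up years.  Discounting follows the
trial convention: year one undiscounted, 3.5% annually thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .synthetic import UTILITY_FLOOR, UTILITY_CEILING, TrialParams, visit_columns

__all__ = [
    "UnitCostTable",
    "QALYProfile",
    "CostProfile",
    "annual_discount_factor",
    "trapezoid_weights",
    "auc_qaly",
    "participant_cost",
    "cohort_outcomes",
]

REQUIRED_ITEMS = frozenset({
    "surgery_episode", "theatre_minute", "bed_day",
    "ae_attendance", "readmission", "primary_care_visit",
})


class ConfigurationError(KeyError):
    """A required unit-cost item is absent from the table."""


class UnitCostTable:
    """Resource item -> unit cost in GBP (2019-2020 price year).

    The bundled default table is an illustrative synthetic fixture with
    realistic NHS-scale magnitudes; it is not a published reference-cost
    schedule.
    """

    def __init__(self, costs: dict[str, float]):
        missing = REQUIRED_ITEMS - set(costs)
        if missing:
            raise ConfigurationError(
                f"unit-cost table missing items: {sorted(missing)}")
        bad = [k for k, v in costs.items() if v < 0]
        if bad:
            raise ValueError(f"negative unit costs for: {bad}")
        self._costs = dict(costs)

    def __getitem__(self, item: str) -> float:
        try:
            return self._costs[item]
        except KeyError:
            raise ConfigurationError(f"no unit cost for item {item!r}") from None

    def items(self):
        return self._costs.items()

    def scaled(self, factor: float) -> "UnitCostTable":
        return UnitCostTable({k: v * factor for k, v in self._costs.items()})

    @classmethod
    def from_csv(cls, path) -> "UnitCostTable":
        df = pd.read_csv(path, comment="#")
        return cls(dict(zip(df["item"], df["unit_cost_gbp"].astype(float))))

    @classmethod
    def default(cls) -> "UnitCostTable":
        ref = resources.files("gallstone_cea.data") / "unit_costs.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass(frozen=True)
class QALYProfile:
    participant_id: int
    undiscounted: float
    discounted: float
    per_interval: tuple[float, ...]  # discounted contribution per trapezoid


@dataclass(frozen=True)
class CostProfile:
    participant_id: int
    total: float
    components: dict[str, float]  # discounted GBP per resource item


def annual_discount_factor(year_index: int, rate: float) -> float:
    """Discount factor for costs/QALYs accrued during 1-based ``year_index``.

    Year one is undiscounted; year ``y`` thereafter is discounted by
    ``(1 + rate) ** -(y - 1)``.
    """
    if year_index < 1:
        raise ValueError(f"year_index must be >= 1, got {year_index}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return float((1.0 + rate) ** -(year_index - 1))


def year_of_month(month: float) -> int:
    """1-based follow-up year containing time ``month`` (months since t0)."""
    return int(np.floor(month / 12.0)) + 1


def trapezoid_weights(visit_months: np.ndarray, rate: float) -> np.ndarray:
    """Per-visit weights w such that discounted AUC-QALY = w . utilities.

    Each trapezoid's area (in years) is discounted by the year containing its
    midpoint; weights fold the half-width of each adjacent interval onto its
    end-point visits.
    """
    t = np.asarray(visit_months, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("visit_months must be strictly increasing, length >= 2")
    widths_yr = np.diff(t) / 12.0
    mids = 0.5 * (t[:-1] + t[1:])
    dfs = np.array([annual_discount_factor(year_of_month(m), rate) for m in mids])
    w = np.zeros_like(t)
    contrib = 0.5 * widths_yr * dfs
    w[:-1] += contrib
    w[1:] += contrib
    return w


def auc_qaly(visit_months, utilities, rate: float = 0.035,
             participant_id: int = 0) -> QALYProfile:
    """Trapezoidal QALYs over a utility trajectory, discounted annually.

    Utilities must be complete; impute upstream before calling.
    """
    t = np.asarray(visit_months, dtype=float)
    u = np.asarray(utilities, dtype=float)
    if t.shape != u.shape:
        raise ValueError("visit_months and utilities must have equal length")
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("visit_months must be strictly increasing, length >= 2")
    if np.any(np.isnan(u)):
        raise ValueError("utilities contain missing values; run imputation first")
    if np.any(u < UTILITY_FLOOR - 1e-12) or np.any(u > UTILITY_CEILING + 1e-12):
        raise ValueError(
            f"utilities outside instrument range [{UTILITY_FLOOR}, {UTILITY_CEILING}]")
    widths_yr = np.diff(t) / 12.0
    areas = 0.5 * (u[:-1] + u[1:]) * widths_yr
    mids = 0.5 * (t[:-1] + t[1:])
    dfs = np.array([annual_discount_factor(year_of_month(m), rate) for m in mids])
    return QALYProfile(
        participant_id=participant_id,
        undiscounted=float(areas.sum()),
        discounted=float((areas * dfs).sum()),
        per_interval=tuple(float(a) for a in areas * dfs))


def participant_cost(record, costs: UnitCostTable, rate: float = 0.035,
                     follow_up_months: float = 24.0) -> CostProfile:
    """Discounted total cost for one participant record (row or mapping).

    Surgery-episode components (episode, theatre time, bed-days) are
    discounted by the year of surgery; recurring items (readmissions, A&E,
    primary care) are apportioned evenly across follow-up years.
    """
    n_years = int(np.ceil(follow_up_months / 12.0))
    df_recur = float(np.mean([annual_discount_factor(y, rate)
                              for y in range(1, n_years + 1)]))
    comp: dict[str, float] = {}
    if bool(record["had_surgery"]):
        df_surg = annual_discount_factor(year_of_month(record["surgery_month"]), rate)
        comp["surgery_episode"] = costs["surgery_episode"] * df_surg
        comp["theatre_minute"] = record["theatre_minutes"] * costs["theatre_minute"] * df_surg
        comp["bed_day"] = record["stay_days"] * costs["bed_day"] * df_surg
    else:
        comp["surgery_episode"] = comp["theatre_minute"] = comp["bed_day"] = 0.0
    comp["readmission"] = record["readmissions"] * costs["readmission"] * df_recur
    comp["ae_attendance"] = record["ae_attendances"] * costs["ae_attendance"] * df_recur
    comp["primary_care_visit"] = (record["primary_care_visits"]
                                  * costs["primary_care_visit"] * df_recur)
    for k, v in comp.items():
        if v < 0:
            raise ValueError(f"negative cost component {k!r}: counts must be >= 0")
    return CostProfile(participant_id=int(record.get("id", 0)),
                       total=float(sum(comp.values())), components=comp)


def cohort_outcomes(data: pd.DataFrame, costs: UnitCostTable,
                    params: TrialParams, rate: float = 0.035) -> pd.DataFrame:
    """Vectorized per-participant discounted QALY and cost for a whole cohort.

    Equivalent to calling :func:`auc_qaly` / :func:`participant_cost` per row;
    used by the resampling-heavy estimation loops.
    """
    sched = np.asarray(params.visit_schedule, dtype=float)
    w = trapezoid_weights(sched, rate)
    cols = ["baseline_utility"] + visit_columns(params)
    U = data[cols].to_numpy(dtype=float)
    if np.isnan(U).any():
        raise ValueError("utilities contain missing values; run imputation first")
    qaly = U @ w

    n_years = int(np.ceil(params.follow_up_months / 12.0))
    df_recur = float(np.mean([annual_discount_factor(y, rate)
                              for y in range(1, n_years + 1)]))
    surg_year = np.where(data["had_surgery"].to_numpy(),
                         np.floor(np.nan_to_num(data["surgery_month"].to_numpy())
                                  / 12.0).astype(int) + 1, 1)
    df_surg = (1.0 + rate) ** -(surg_year - 1.0)
    bundle = (costs["surgery_episode"]
              + data["theatre_minutes"].to_numpy() * costs["theatre_minute"]
              + data["stay_days"].to_numpy() * costs["bed_day"])
    cost = (data["had_surgery"].to_numpy() * bundle * df_surg
            + (data["readmissions"].to_numpy() * costs["readmission"]
               + data["ae_attendances"].to_numpy() * costs["ae_attendance"]
               + data["primary_care_visits"].to_numpy() * costs["primary_care_visit"]
               ) * df_recur)
    return pd.DataFrame({"id": data["id"].to_numpy(),
                         "qaly": qaly, "cost": cost}, index=data.index)
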