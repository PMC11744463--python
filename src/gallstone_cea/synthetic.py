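"""Synthetic participant-level data for a two-arm gallstone-surgery trial.

Emulates the statistical structure of a pragmatic randomized trial comparing
laparoscopic cholecystectomy (LC) with conservative management (CM) for
uncomplicated symptomatic gallstones: 217 participants per arm from 20
centres, mean age 50.5 years, 71% women, 24 months of follow-up, cumulative
cholecystectomy uptake of about 70.5% (LC) and 29.5% (CM), and SF-6D-style
utility trajectories with a transient post-operative decrement.

The generator is fully seeded and ships with a closed-form oracle
(:func:`truth_summary`) returning the per-arm expected discounted cost and
QALY implied by a parameter set, so that the downstream estimation pipeline
can be checked for parameter recovery without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WaitingTimeParams",
    "ResourceParams",
    "TrialParams",
    "TruthSummary",
    "generate_cohort",
    "apply_missingness",
    "truth_summary",
    "visit_column",
    "visit_columns",
    "write_cohort",
    "read_cohort",
]

#: SF-6D instrument range for utility values.
UTILITY_FLOOR = -0.59
UTILITY_CEILING = 1.0

ARMS = ("LC", "CM")

# Fixed MAR slopes (logistic link on the probability a post-baseline utility
# is missing); the intercept is solved numerically per dataset to hit the
# requested marginal rate.  Lower baseline utility and CM allocation both
# raise the odds of nonresponse.
_MAR_SLOPE_BASELINE = -3.0
_MAR_SLOPE_CM = 0.5


class ParameterError(ValueError):
    """A trial parameter is outside its admissible range."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{name}: {msg}")


@dataclass(frozen=True)
class WaitingTimeParams:
    """Gamma-distributed months from randomization to surgery, truncated at 24."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        _check(self.shape > 0, "waiting_time_params.shape", "must be > 0")
        _check(self.scale > 0, "waiting_time_params.scale", "must be > 0")


@dataclass(frozen=True)
class ResourceParams:
    """Per-arm resource-use distribution parameters.

    Theatre minutes and hospital-stay days apply to operated participants only
    and are drawn from moment-matched gamma distributions (non-negative,
    right-skewed).  Readmission is a per-participant Bernoulli event; A&E
    attendances and primary-care visits are Poisson counts over follow-up.
    """

    theatre_minutes_mean: float
    theatre_minutes_sd: float
    stay_days_mean: float
    stay_days_sd: float
    readmission_prob: float
    ae_rate: float
    primary_care_rate: float

    def __post_init__(self) -> None:
        for f in ("theatre_minutes_mean", "theatre_minutes_sd", "stay_days_mean",
                  "stay_days_sd", "ae_rate", "primary_care_rate"):
            _check(getattr(self, f) >= 0, f"resource_params.{f}", "must be >= 0")
        _check(0 <= self.readmission_prob <= 1,
               "resource_params.readmission_prob", "must be in [0, 1]")


@dataclass(frozen=True)
class TrialParams:
    """Full parameterization of the synthetic trial.

    Defaults reproduce the observable margins of the emulated trial: arm
    sizes, demographics, surgical uptake, theatre time, length of stay,
    readmission rates and A&E attendance rates, with utility levels chosen so
    that arm-level QALY totals sit in the range typical of this population.
    """

    n_per_arm: int = 217
    n_centres: int = 20
    age_mean: float = 50.5
    age_sd: float = 13.0
    prop_female: float = 0.71
    visit_schedule: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 18.0, 24.0)
    baseline_utility_mean: float = 0.70
    baseline_utility_sd: float = 0.12
    utility_noise_sd: float = 0.08
    #: steady-state utility gain after recovery, CM arm
    surgery_benefit: float = 0.045
    #: LC minus CM post-surgery steady-state utility
    arm_utility_effect: float = 0.01
    surgery_dip_depth: float = 0.10
    surgery_dip_duration: float = 3.0
    uptake_LC: float = 0.705
    uptake_CM: float = 0.295
    waiting_time_params: dict[str, WaitingTimeParams] = field(
        default_factory=lambda: {
            "LC": WaitingTimeParams(shape=2.0, scale=2.5),
            "CM": WaitingTimeParams(shape=2.0, scale=6.0),
        })
    resource_params: dict[str, ResourceParams] = field(
        default_factory=lambda: {
            "LC": ResourceParams(72.0, 42.0, 0.63, 1.3, 0.097, 0.22, 3.0),
            "CM": ResourceParams(83.0, 49.0, 1.40, 3.4, 0.129, 0.47, 4.0),
        })
    #: s.d. of the per-centre zero-mean normal effect on log hospital durations
    centre_log_sd: float = 0.10
    unit_cost_ref: str = "default"
    missing_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_per_arm >= 1, "n_per_arm", "must be >= 1")
        _check(self.n_centres >= 1, "n_centres", "must be >= 1")
        _check(self.age_sd >= 0, "age_sd", "must be >= 0")
        _check(0 <= self.prop_female <= 1, "prop_female", "must be in [0, 1]")
        sched = tuple(float(t) for t in self.visit_schedule)
        _check(len(sched) >= 2, "visit_schedule", "needs at least two visits")
        _check(sched[0] == 0.0, "visit_schedule", "must start at month 0")
        _check(all(b > a for a, b in zip(sched, sched[1:])),
               "visit_schedule", "must be strictly increasing")
        _check(self.baseline_utility_sd >= 0, "baseline_utility_sd", "must be >= 0")
        _check(self.utility_noise_sd >= 0, "utility_noise_sd", "must be >= 0")
        _check(UTILITY_FLOOR <= self.baseline_utility_mean <= UTILITY_CEILING,
               "baseline_utility_mean", "must be within the utility range")
        _check(self.surgery_dip_depth >= 0, "surgery_dip_depth", "must be >= 0")
        _check(self.surgery_dip_duration >= 0, "surgery_dip_duration", "must be >= 0")
        _check(0 <= self.uptake_LC <= 1, "uptake_LC", "must be in [0, 1]")
        _check(0 <= self.uptake_CM <= 1, "uptake_CM", "must be in [0, 1]")
        _check(set(self.waiting_time_params) == set(ARMS),
               "waiting_time_params", "must have entries for LC and CM")
        _check(set(self.resource_params) == set(ARMS),
               "resource_params", "must have entries for LC and CM")
        _check(self.centre_log_sd >= 0, "centre_log_sd", "must be >= 0")
        _check(0 <= self.missing_rate < 1, "missing_rate", "must be in [0, 1)")

    @property
    def follow_up_months(self) -> float:
        return self.visit_schedule[-1]

    def uptake(self, arm: str) -> float:
        return self.uptake_LC if arm == "LC" else self.uptake_CM

    def steady_state_gain(self, arm: str) -> float:
        """Post-recovery utility gain over baseline for the given arm."""
        if arm == "LC":
            return self.surgery_benefit + self.arm_utility_effect
        return self.surgery_benefit

    def replace(self, **kwargs) -> "TrialParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TruthSummary:
    """Analytically implied per-arm expectations under a parameter set.

    ``true_delta_*`` are oriented CM minus LC, matching the reporting
    convention of the analysis pipeline.
    """

    expected_cost: dict[str, float]
    expected_qaly: dict[str, float]
    true_delta_cost: float
    true_delta_qaly: float
    discount_rate: float


def visit_column(month: float) -> str:
    """Column name for the utility measured at ``month`` (baseline excluded)."""
    m = int(month) if float(month).is_integer() else month
    return f"u_{m}m"


def visit_columns(params: TrialParams) -> list[str]:
    """Post-baseline utility column names, in visit order."""
    return [visit_column(t) for t in params.visit_schedule[1:]]


def _truncnorm_rvs(mean, sd, lo, hi, rng, size=None):
    if np.all(sd == 0):
        return np.broadcast_to(np.clip(mean, lo, hi), size if size else np.shape(mean)).copy()
    a = (lo - np.asarray(mean)) / sd
    b = (hi - np.asarray(mean)) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _gamma_from_moments(mean: float, sd: float):
    """Moment-matched gamma (shape, scale); degenerate at ``mean`` if sd == 0."""
    if mean == 0 or sd == 0:
        return None
    shape = (mean / sd) ** 2
    return shape, sd**2 / mean


def _truncated_wait_cdf(wt: WaitingTimeParams, t, follow_up: float):
    """CDF of months-to-surgery, gamma truncated to (0, follow_up]."""
    dist = stats.gamma(wt.shape, scale=wt.scale)
    denom = dist.cdf(follow_up)
    return np.clip(dist.cdf(np.asarray(t, dtype=float)) / denom, 0.0, 1.0)


def _sample_wait(wt: WaitingTimeParams, n: int, follow_up: float, rng) -> np.ndarray:
    dist = stats.gamma(wt.shape, scale=wt.scale)
    u = rng.uniform(size=n) * dist.cdf(follow_up)
    return dist.ppf(np.maximum(u, 1e-300))


def _latent_utility(base: np.ndarray, gain: float, dip: float,
                    operated: np.ndarray, wait: np.ndarray,
                    t: float, dip_duration: float) -> np.ndarray:
    """Piecewise-constant latent mean utility at visit month ``t``."""
    lat = base.copy()
    post = operated & (wait + dip_duration < t)
    in_dip = operated & (wait < t) & ~post
    lat[in_dip] = base[in_dip] - dip
    lat[post] = base[post] + gain
    return lat


def generate_cohort(params: TrialParams) -> pd.DataFrame:
    """Draw a complete (no-missingness) synthetic cohort.

    Returns a DataFrame with one row per participant and columns::

        id, arm, centre, age, sex, baseline_utility, u_<t>m ...,
        had_surgery, surgery_month, theatre_minutes, stay_days,
        readmissions, ae_attendances, primary_care_visits

    Deterministic given ``params`` (including ``params.seed``).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_per_arm
    total = 2 * n
    follow_up = params.follow_up_months

    centre_mult = np.exp(rng.normal(0.0, params.centre_log_sd, params.n_centres))

    df = pd.DataFrame({
        "id": np.arange(1, total + 1),
        "arm": np.repeat(ARMS, n),
        "centre": rng.integers(1, params.n_centres + 1, size=total),
    })
    df["age"] = _truncnorm_rvs(params.age_mean, params.age_sd, 18.0, 90.0, rng, total)
    df["sex"] = np.where(rng.uniform(size=total) < params.prop_female, "F", "M")
    df["baseline_utility"] = _truncnorm_rvs(
        params.baseline_utility_mean, params.baseline_utility_sd,
        UTILITY_FLOOR, UTILITY_CEILING, rng, total)

    base = df["baseline_utility"].to_numpy()
    operated = np.zeros(total, dtype=bool)
    wait = np.full(total, np.nan)
    theatre = np.zeros(total)
    stay = np.zeros(total)
    readmit = np.zeros(total, dtype=int)
    ae = np.zeros(total, dtype=int)
    gp = np.zeros(total, dtype=int)

    mult = centre_mult[df["centre"].to_numpy() - 1]
    for arm in ARMS:
        idx = np.flatnonzero(df["arm"].to_numpy() == arm)
        res = params.resource_params[arm]
        operated[idx] = rng.uniform(size=idx.size) < params.uptake(arm)
        op = idx[operated[idx]]
        wait[op] = _sample_wait(params.waiting_time_params[arm], op.size, follow_up, rng)
        for arr, mean, sd in ((theatre, res.theatre_minutes_mean, res.theatre_minutes_sd),
                              (stay, res.stay_days_mean, res.stay_days_sd)):
            g = _gamma_from_moments(mean, sd)
            if g is None:
                arr[op] = mean
            else:
                arr[op] = rng.gamma(g[0], g[1], size=op.size)
            arr[op] *= mult[op]
        readmit[idx] = (rng.uniform(size=idx.size) < res.readmission_prob).astype(int)
        ae[idx] = rng.poisson(res.ae_rate, size=idx.size)
        # every participant has some primary-care contact over 24 months when
        # the rate allows; the mean stays equal to the configured rate
        r = res.primary_care_rate
        gp[idx] = (1 + rng.poisson(r - 1.0, size=idx.size) if r >= 1.0
                   else rng.poisson(r, size=idx.size))

    gain = np.where(df["arm"].to_numpy() == "LC",
                    params.steady_state_gain("LC"), params.steady_state_gain("CM"))
    for t in params.visit_schedule[1:]:
        lat = np.empty(total)
        for arm in ARMS:
            sel = df["arm"].to_numpy() == arm
            lat[sel] = _latent_utility(base[sel], params.steady_state_gain(arm),
                                       params.surgery_dip_depth, operated[sel],
                                       wait[sel], t, params.surgery_dip_duration)
        df[visit_column(t)] = _truncnorm_rvs(
            lat, params.utility_noise_sd, UTILITY_FLOOR, UTILITY_CEILING, rng, total)

    df["had_surgery"] = operated
    df["surgery_month"] = wait
    df["theatre_minutes"] = theatre
    df["stay_days"] = stay
    df["readmissions"] = readmit
    df["ae_attendances"] = ae
    df["primary_care_visits"] = gp
    return df


def apply_missingness(data: pd.DataFrame,
                      mechanism: Literal["MCAR", "MAR"],
                      rate: float,
                      seed: int,
                      visit_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Mask post-baseline utility visits; baseline is never masked.

    Under MCAR every post-baseline entry is masked independently with
    probability ``rate``.  Under MAR the per-participant masking probability
    follows a logistic model in observed baseline utility and arm, with the
    intercept solved so the expected marginal masking fraction equals
    ``rate`` exactly for the dataset at hand.
    """
    if not 0 <= rate < 1:
        raise ParameterError("rate: must be in [0, 1)")
    if mechanism not in ("MCAR", "MAR"):
        raise ParameterError(f"mechanism: unknown mechanism {mechanism!r}")
    out = data.copy()
    if rate == 0:
        return out
    if visit_cols is None:
        visit_cols = [c for c in data.columns
                      if c.startswith("u_") and c.endswith("m")]
    rng = np.random.default_rng(seed)
    n = len(out)
    if mechanism == "MCAR":
        p = np.full(n, rate)
    else:
        z = (_MAR_SLOPE_BASELINE * (out["baseline_utility"].to_numpy() - 0.7)
             + _MAR_SLOPE_CM * (out["arm"].to_numpy() == "CM"))

        def gap(a):
            return float(np.mean(1.0 / (1.0 + np.exp(-(a + z))))) - rate

        a = optimize.brentq(gap, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-(a + z)))
    for col in visit_cols:
        mask = rng.uniform(size=n) < p
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# Closed-form truth


def _truncnorm_mean(mu, sd, lo=UTILITY_FLOOR, hi=UTILITY_CEILING):
    """E[X] for X ~ N(mu, sd) truncated to [lo, hi]; vectorized in mu."""
    mu = np.asarray(mu, dtype=float)
    if sd == 0:
        return np.clip(mu, lo, hi)
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    return stats.truncnorm.mean(a, b, loc=mu, scale=sd)


def _expected_observed_utility(params: TrialParams, arm: str, t: float) -> float:
    """E over baseline, surgery timing, and measurement noise of u(t)."""
    lo, hi = UTILITY_FLOOR, UTILITY_CEILING
    m0, s0 = params.baseline_utility_mean, params.baseline_utility_sd
    # Gauss-Legendre quadrature over the truncated baseline distribution.
    nodes, weights = np.polynomial.legendre.leggauss(80)
    u = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    if s0 > 0:
        a, b = (lo - m0) / s0, (hi - m0) / s0
        f0 = stats.truncnorm.pdf(u, a, b, loc=m0, scale=s0)
        w = weights * 0.5 * (hi - lo) * f0
    else:
        u = np.array([np.clip(m0, lo, hi)])
        w = np.array([1.0])

    if t == 0:  # baseline column carries the raw baseline value
        return float(np.sum(w * u))

    noise = params.utility_noise_sd
    uptake = params.uptake(arm)
    gain = params.steady_state_gain(arm)
    dip, d = params.surgery_dip_depth, params.surgery_dip_duration
    G = lambda x: float(_truncated_wait_cdf(
        params.waiting_time_params[arm], max(x, 0.0), params.follow_up_months))
    p_post = G(t - d) if t - d > 0 else 0.0
    p_dip = G(t) - p_post if t > 0 else 0.0
    p_pre = 1.0 - p_post - p_dip

    e_base = np.sum(w * _truncnorm_mean(u, noise))
    e_dip = np.sum(w * _truncnorm_mean(u - dip, noise))
    e_post = np.sum(w * _truncnorm_mean(u + gain, noise))
    return float((1 - uptake) * e_base
                 + uptake * (p_pre * e_base + p_dip * e_dip + p_post * e_post))


def truth_summary(params: TrialParams, unit_costs=None,
                  discount_rate: float = 0.035) -> TruthSummary:
    """Closed-form per-arm expected discounted cost and QALY under ``params``.

    The expectation integrates analytically (or by quadrature) over baseline
    utility, surgical uptake and timing, the post-operative dip, measurement
    noise truncation, and the centre-level duration multiplier; it mirrors
    exactly the discounting conventions used by the costing layer, so it is a
    valid recovery target for the estimation pipeline.
    """
    from .costing import UnitCostTable, annual_discount_factor, trapezoid_weights

    if unit_costs is None:
        unit_costs = UnitCostTable.default()

    sched = np.asarray(params.visit_schedule, dtype=float)
    w = trapezoid_weights(sched, discount_rate)
    follow_up_years = int(np.ceil(params.follow_up_months / 12.0))
    df_recurring = float(np.mean([annual_discount_factor(y, discount_rate)
                                  for y in range(1, follow_up_years + 1)]))
    # mean of the log-normal centre multiplier on hospital durations
    dur_mult = float(np.exp(params.centre_log_sd**2 / 2.0))

    qaly, cost = {}, {}
    for arm in ARMS:
        eu = np.array([_expected_observed_utility(params, arm, t) for t in sched])
        qaly[arm] = float(w @ eu)

        res = params.resource_params[arm]
        wt = params.waiting_time_params[arm]
        # discount factor of the surgery year, averaged over waiting time
        probs, efs = [], []
        prev = 0.0
        for y in range(1, follow_up_years + 1):
            cdf = float(_truncated_wait_cdf(wt, min(12.0 * y, params.follow_up_months),
                                            params.follow_up_months))
            probs.append(cdf - prev)
            efs.append(annual_discount_factor(y, discount_rate))
            prev = cdf
        df_surgery = float(np.dot(probs, efs))

        bundle = (unit_costs["surgery_episode"]
                  + res.theatre_minutes_mean * dur_mult * unit_costs["theatre_minute"]
                  + res.stay_days_mean * dur_mult * unit_costs["bed_day"])
        recurring = (res.readmission_prob * unit_costs["readmission"]
                     + res.ae_rate * unit_costs["ae_attendance"]
                     + res.primary_care_rate * unit_costs["primary_care_visit"])
        cost[arm] = float(params.uptake(arm) * bundle * df_surgery
                          + recurring * df_recurring)

    return TruthSummary(
        expected_cost=cost, expected_qaly=qaly,
        true_delta_cost=cost["CM"] - cost["LC"],
        true_delta_qaly=qaly["CM"] - qaly["LC"],
        discount_rate=discount_rate)


# ---------------------------------------------------------------------------
# Delimited-text interface

def write_cohort(data: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a cohort as CSV; missing utilities become empty fields.

    ``header_comment`` (e.g. a seed / config-hash audit line) is written as a
    leading ``#`` line that :func:`read_cohort` skips.
    """
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        data.to_csv(fh, index=False, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, comment="#")
    required = {"id", "arm", "centre", "age", "sex", "baseline_utility",
                "had_surgery", "surgery_month", "theatre_minutes", "stay_days",
                "readmissions", "ae_attendances", "primary_care_visits"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    df["had_surgery"] = df["had_surgery"].astype(bool)
    return df
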