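"""Natural-history progression law for ADPKD renal decline.

The model predicts non-linear TKV and eGFR trajectories from baseline
age, sex (via height), TKV and eGFR:

* TKV grows exponentially at a patient-specific rate ``g`` obtained by
  Mayo-style back-extrapolation from a reference height-adjusted TKV of
  150 mL/m at age zero: ``g = ln(tkv0 / (150 * height)) / age0``.
* The instantaneous eGFR decline rate is tied to current kidney volume,
  ``rate = kappa * (TKV / 1000) ** gamma`` (mL/min/1.73m^2 per year),
  so decline accelerates as cysts grow.  On treatment the rate is
  multiplied by ``1 - rho``.

Both pieces integrate in closed form: with ``a = gamma * g`` and
``kprime = kappa * (tkv0/1000) ** gamma`` the eGFR trajectory is
``egfr0 - m * (kprime / a) * (exp(a t) - 1)``, and the first crossing of
the ESRD threshold inverts analytically.  Background mortality is a
Gompertz–Makeham hazard with a calibration scale factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .cohorts import PatientBaseline
from .treatment import TreatmentPolicy, sample_discontinuation_time

__all__ = [
    "ProgressionParams",
    "MortalityParams",
    "PatientTrajectory",
    "baseline_growth_rate",
    "tkv_at",
    "egfr_decline_rate",
    "egfr_at",
    "time_to_threshold",
    "piecewise_egfr",
    "piecewise_time_to_threshold",
    "ckd_stage",
    "survival_probability",
    "survival_integral",
    "sample_death_age",
    "simulate_patient",
]

_A_TINY = 1e-10  # below this the a -> 0 linear-decline limit is used


@dataclass(frozen=True)
class ProgressionParams:
    """Free parameters of the progression law."""

    kappa: float                   # slope scale, mL/min/1.73m^2/yr at TKV = tkv_norm
    gamma: float                   # TKV exponent (dimensionless)
    httkv_ref: float = 150.0       # reference htTKV at age 0, mL/m
    tkv_norm: float = 1000.0       # normalising TKV for the slope law, mL
    esrd_threshold: float = 15.0   # eGFR below this is ESRD
    egfr_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0 < self.esrd_threshold < 60:
            raise ValueError("esrd_threshold must lie in (0, 60)")


@dataclass(frozen=True)
class MortalityParams:
    """Gompertz–Makeham background mortality.

    Hazard at age x: ``scale_multiplier * (makeham + A * exp(B x))``.
    The scale multiplier is the calibration handle; zero disables death.
    """

    makeham: float = 2e-4          # age-independent hazard, 1/yr
    gompertz_scale: float = 2.5e-5  # A, 1/yr
    gompertz_shape: float = 0.095   # B, 1/yr
    scale_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if min(self.makeham, self.gompertz_scale, self.scale_multiplier) < 0:
            raise ValueError("mortality parameters must be non-negative")
        if self.gompertz_shape <= 0:
            raise ValueError("gompertz_shape must be positive")


@dataclass
class PatientTrajectory:
    """Per-patient simulation record."""

    times: np.ndarray            # years from baseline (annual grid + event time)
    egfr_series: np.ndarray
    tkv_series: np.ndarray
    ckd_series: list[str]
    esrd_time: float | None      # years from baseline, None if not reached
    death_time: float | None     # stochastic mode only
    years_on_treatment: float
    survival_weight: float = 1.0  # P(alive at ESRD/horizon), expectation mode

    @property
    def reaches_esrd(self) -> bool:
        if self.esrd_time is None:
            return False
        return self.death_time is None or self.esrd_time <= self.death_time


def baseline_growth_rate(
    age0: float, tkv0: float, height: float, params: ProgressionParams
) -> float:
    """Patient-specific exponential TKV growth rate (1/yr)."""
    if age0 <= 0:
        raise ValueError("baseline age must be positive")
    ref = params.httkv_ref * height
    if tkv0 <= ref:
        raise ValueError(
            "baseline TKV does not exceed the age-zero reference volume; "
            "the back-extrapolated growth rate would be non-positive"
        )
    return math.log(tkv0 / ref) / age0


def tkv_at(tkv0: float, g: float, t: float) -> float:
    """TKV after ``t`` years of exponential growth."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return tkv0 * math.exp(g * t)


def egfr_decline_rate(tkv: float, params: ProgressionParams) -> float:
    """Instantaneous natural eGFR decline rate at the given TKV."""
    if tkv <= 0:
        raise ValueError("TKV must be positive")
    return params.kappa * (tkv / params.tkv_norm) ** params.gamma


def _law_constants(
    baseline: PatientBaseline, g: float, params: ProgressionParams
) -> tuple[float, float]:
    """(kprime, a): initial decline rate and its exponential growth rate."""
    kprime = params.kappa * (baseline.tkv0 / params.tkv_norm) ** params.gamma
    return kprime, params.gamma * g


def egfr_at(
    baseline: PatientBaseline,
    g: float,
    params: ProgressionParams,
    multiplier: float,
    t: float,
) -> float:
    """Closed-form eGFR after ``t`` years at a constant decline multiplier."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if not 0.0 < multiplier <= 1.0:
        raise ValueError("multiplier must lie in (0, 1]")
    kprime, a = _law_constants(baseline, g, params)
    if abs(a) < _A_TINY:
        drop = multiplier * kprime * t
    else:
        drop = multiplier * (kprime / a) * math.expm1(a * t)
    return max(baseline.egfr0 - drop, params.egfr_floor)


def time_to_threshold(
    baseline: PatientBaseline,
    g: float,
    params: ProgressionParams,
    multiplier: float = 1.0,
) -> float:
    """Years until eGFR first crosses the ESRD threshold (analytic inverse)."""
    delta = baseline.egfr0 - params.esrd_threshold
    if delta <= 0:
        raise ValueError("baseline eGFR must exceed the ESRD threshold")
    if not 0.0 < multiplier <= 1.0:
        raise ValueError("multiplier must lie in (0, 1]")
    kprime, a = _law_constants(baseline, g, params)
    if abs(a) < _A_TINY:
        return delta / (multiplier * kprime)
    return math.log1p(delta * a / (multiplier * kprime)) / a


def piecewise_egfr(
    baseline: PatientBaseline,
    g: float,
    params: ProgressionParams,
    segments: list[tuple[float, float, float]],
    t: float,
) -> float:
    """eGFR at time ``t`` under a piecewise-constant decline multiplier."""
    kprime, a = _law_constants(baseline, g, params)
    drop = 0.0
    for a0, a1, m in segments:
        hi = min(a1, t)
        if hi <= a0:
            break
        if abs(a) < _A_TINY:
            drop += m * kprime * (hi - a0)
        else:
            drop += m * (kprime / a) * (math.exp(a * hi) - math.exp(a * a0))
    return max(baseline.egfr0 - drop, params.egfr_floor)


def piecewise_time_to_threshold(
    baseline: PatientBaseline,
    g: float,
    params: ProgressionParams,
    segments: list[tuple[float, float, float]],
) -> float | None:
    """First ESRD-threshold crossing under a piecewise multiplier.

    Returns None if the threshold is not reached before the last segment
    ends (the horizon).
    """
    kprime, a = _law_constants(baseline, g, params)
    remaining = baseline.egfr0 - params.esrd_threshold
    if remaining <= 0:
        raise ValueError("baseline eGFR must exceed the ESRD threshold")
    for a0, a1, m in segments:
        if abs(a) < _A_TINY:
            seg_drop = m * kprime * (a1 - a0)
            if seg_drop >= remaining:
                return a0 + remaining / (m * kprime)
        else:
            e0, e1 = math.exp(a * a0), math.exp(a * a1)
            seg_drop = m * (kprime / a) * (e1 - e0)
            if seg_drop >= remaining:
                return math.log(e0 + remaining * a / (m * kprime)) / a
        remaining -= seg_drop
    return None


def ckd_stage(egfr: float, esrd_threshold: float = 15.0) -> str:
    """KDIGO CKD stage label for an eGFR value."""
    if egfr < 0:
        raise ValueError("eGFR must be non-negative")
    if egfr >= 90:
        return "CKD 1"
    if egfr >= 60:
        return "CKD 2"
    if egfr >= 30:
        return "CKD 3"
    if egfr >= esrd_threshold:
        return "CKD 4"
    return "ESRD"


def _cumulative_hazard(mort: MortalityParams, age_from: float, age_to: float) -> float:
    lam, A, B = mort.makeham, mort.gompertz_scale, mort.gompertz_shape
    return mort.scale_multiplier * (
        lam * (age_to - age_from) + (A / B) * (math.exp(B * age_to) - math.exp(B * age_from))
    )


def survival_probability(mort: MortalityParams, age_from: float, age_to: float) -> float:
    """P(alive at ``age_to`` | alive at ``age_from``); multiplicative over intervals."""
    if age_to < age_from or age_from < 0:
        raise ValueError("require 0 <= age_from <= age_to")
    return math.exp(-_cumulative_hazard(mort, age_from, age_to))


def survival_integral(mort: MortalityParams, age0: float, t0: float, t1: float) -> float:
    """Expected alive-years over [t0, t1] from baseline age ``age0``."""
    if t1 <= t0:
        return 0.0
    if mort.scale_multiplier == 0.0:
        return t1 - t0
    val, _ = quad(lambda u: survival_probability(mort, age0, age0 + u), t0, t1)
    return val


def sample_death_age(
    mort: MortalityParams,
    age0: float,
    rng: np.random.Generator,
    max_age: float = 120.0,
) -> float:
    """Draw a death age by inverting the conditional survival function."""
    u = rng.random()
    if mort.scale_multiplier == 0.0 or survival_probability(mort, age0, max_age) > u:
        return math.inf
    return brentq(lambda x: survival_probability(mort, age0, x) - u, age0, max_age, xtol=1e-10)


def simulate_patient(
    baseline: PatientBaseline,
    params: ProgressionParams,
    mort: MortalityParams,
    policy: TreatmentPolicy | None = None,
    mode: str = "expectation",
    rng: np.random.Generator | None = None,
    horizon_age: float = 110.0,
) -> PatientTrajectory:
    """Simulate one patient to ESRD, death or the horizon.

    ``policy=None`` gives pure natural history.  In ``expectation`` mode
    death enters as an analytic survival weight and discontinuation must
    be handled upstream (mixture enumeration); in ``stochastic`` mode a
    seeded generator draws the death age and discontinuation time.
    """
    if horizon_age <= baseline.age0:
        raise ValueError("horizon_age must exceed the baseline age")
    if mode not in ("expectation", "stochastic"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    horizon = horizon_age - baseline.age0

    g = baseline_growth_rate(baseline.age0, baseline.tkv0, baseline.height, params)

    disc_time = math.inf
    death_time: float | None = None
    if mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires a random generator")
        death_age = sample_death_age(mort, baseline.age0, rng)
        death_time = None if math.isinf(death_age) else death_age - baseline.age0
        if policy is not None and not policy.discontinuation.is_null:
            disc_time = sample_discontinuation_time(policy.discontinuation, rng)

    if policy is None:
        segments = [(0.0, horizon, 1.0)]
        on_intervals: list[tuple[float, float]] = []
    else:
        segments = policy.multiplier_segments(horizon, disc_time)
        on_intervals = policy.on_intervals(horizon, disc_time)

    esrd_time = piecewise_time_to_threshold(baseline, g, params, segments)

    # event end: first of ESRD, death, horizon
    end = horizon
    if esrd_time is not None:
        end = min(end, esrd_time)
    if death_time is not None:
        end = min(end, death_time)

    # time on treatment up to the event end
    def _on_time(until: float) -> float:
        return sum(max(0.0, min(b, until) - a) for a, b in on_intervals if a < until)

    if mode == "stochastic":
        years_on = _on_time(end)
        weight = 1.0
    else:
        # expected alive-years on treatment, truncated at ESRD
        stop = end
        years_on = sum(
            survival_integral(mort, baseline.age0, a, min(b, stop))
            for a, b in on_intervals
            if a < stop
        )
        weight = survival_probability(mort, baseline.age0, baseline.age0 + end)

    grid = np.arange(0.0, math.floor(end) + 0.5)
    times = np.unique(np.append(grid, end))
    egfr = np.array([piecewise_egfr(baseline, g, params, segments, t) for t in times])
    tkv = np.array([tkv_at(baseline.tkv0, g, t) for t in times])
    stages = [ckd_stage(e, params.esrd_threshold) for e in egfr]

    return PatientTrajectory(
        times=times,
        egfr_series=egfr,
        tkv_series=tkv,
        ckd_series=stages,
        esrd_time=esrd_time,
        death_time=death_time,
        years_on_treatment=years_on,
        survival_weight=weight,
    )
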