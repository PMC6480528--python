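"""Tolvaptan treatment-effect layer.

The drug effect is a constant proportional reduction ``rho`` of the
instantaneous eGFR decline rate: while on treatment the natural decline
is multiplied by ``1 - rho``; TKV growth is never affected.  Effect
sizes differ by eGFR measure (reciprocal serum creatinine vs CKD-EPI)
and by subgroup (overall, CKD stage at initiation, Mayo 1C–1E); the nine
published combinations ship as a CSV fixture and any other lookup is an
error rather than a silent default.

Treatment discontinuation follows published annual probabilities
(15.30/6.51/2.89% in years 1–3, 0.50% each year thereafter), is
permanent, and is placed mid-year within the discontinuation year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentEffect",
    "DiscontinuationSchedule",
    "TreatmentPolicy",
    "TrialOverride",
    "effect_table",
    "get_effect",
    "slope_multiplier",
    "percent_reduction_from_slopes",
    "sample_discontinuation_time",
    "enumerate_discontinuation_mixture",
    "apply_trial_override",
]

_MEASURES = ("reciprocal_creatinine", "ckd_epi")
_SUBGROUPS = ("overall", "ckd1", "ckd2", "ckd3", "mayo_1c_1e")


@dataclass(frozen=True)
class TreatmentEffect:
    """Proportional reduction of eGFR decline for one measure/subgroup."""

    measure: str
    subgroup: str
    rho: float

    def __post_init__(self) -> None:
        if self.measure not in _MEASURES:
            raise ValueError(f"unknown eGFR measure {self.measure!r}")
        if self.subgroup not in _SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


def effect_table() -> pd.DataFrame:
    """The shipped (measure, subgroup, rho) effect-size table."""
    with resources.files("adpkdsim.data").joinpath("treatment_effects.csv").open() as fh:
        return pd.read_csv(fh)


def get_effect(measure: str, subgroup: str = "overall") -> TreatmentEffect:
    """Look up a published effect size; unknown combinations raise KeyError."""
    table = effect_table()
    row = table[(table["measure"] == measure) & (table["subgroup"] == subgroup)]
    if row.empty:
        combos = ", ".join(f"({m}, {s})" for m, s in zip(table["measure"], table["subgroup"]))
        raise KeyError(
            f"no published effect size for measure={measure!r}, subgroup={subgroup!r}; "
            f"available: {combos}"
        )
    return TreatmentEffect(measure=measure, subgroup=subgroup, rho=float(row.iloc[0]["rho"]))


def slope_multiplier(effect: TreatmentEffect, on_treatment: bool) -> float:
    """Multiplier applied to the natural eGFR decline rate."""
    return 1.0 - effect.rho if on_treatment else 1.0


def percent_reduction_from_slopes(placebo_slope: float, active_slope: float) -> float:
    """Percent reduction in decline implied by two (negative) eGFR slopes."""
    if placebo_slope >= 0:
        raise ValueError("placebo slope must be negative (a decline)")
    if active_slope > 0:
        raise ValueError("active slope must be non-positive")
    return 100.0 * (1.0 - active_slope / placebo_slope)


@dataclass(frozen=True)
class DiscontinuationSchedule:
    """Annual probabilities of stopping treatment, by treatment-year.

    ``year4_onward`` applies every subsequent year until ESRD or death.
    An all-zero schedule means no discontinuation (the base case).
    """

    year1: float = 0.1530
    year2: float = 0.0651
    year3: float = 0.0289
    year4_onward: float = 0.0050

    def __post_init__(self) -> None:
        for p in (self.year1, self.year2, self.year3, self.year4_onward):
            if not 0.0 <= p <= 1.0:
                raise ValueError("annual discontinuation probabilities must lie in [0, 1]")

    @classmethod
    def none(cls) -> "DiscontinuationSchedule":
        return cls(0.0, 0.0, 0.0, 0.0)

    def hazard(self, year_index: int) -> float:
        """Probability of stopping during treatment-year ``year_index`` (0-based)."""
        return (self.year1, self.year2, self.year3)[year_index] if year_index < 3 else self.year4_onward

    @property
    def is_null(self) -> bool:
        return self.year1 == self.year2 == self.year3 == self.year4_onward == 0.0


def sample_discontinuation_time(
    schedule: DiscontinuationSchedule,
    rng: np.random.Generator,
    horizon: float = 100.0,
) -> float:
    """Draw a discontinuation time (treatment-years); ``inf`` means never.

    Year ``k`` is reached with the product of earlier persistence
    probabilities and stops with its annual hazard; within the stopping
    year the time is uniform.
    """
    if schedule.is_null:
        return math.inf
    for k in range(int(math.ceil(horizon))):
        if rng.random() < schedule.hazard(k):
            return k + rng.random()
    return math.inf


def enumerate_discontinuation_mixture(
    schedule: DiscontinuationSchedule, horizon: float
) -> list[tuple[float, float]]:
    """Discrete mixture over mid-year discontinuation times.

    Returns ``(time, probability)`` atoms with times at mid-year
    (k + 0.5) plus a terminal ``(inf, P(never within horizon))`` atom;
    probabilities sum to one.  Enables deterministic expectation-mode
    evaluation of the discontinuation scenario.
    """
    if horizon < 1.0:
        raise ValueError("horizon must be at least one year")
    if schedule.is_null:
        return [(math.inf, 1.0)]
    atoms: list[tuple[float, float]] = []
    persist = 1.0
    for k in range(int(math.floor(horizon))):
        h = schedule.hazard(k)
        atoms.append((k + 0.5, persist * h))
        persist *= 1.0 - h
    atoms.append((math.inf, persist))
    return atoms


@dataclass(frozen=True)
class TreatmentPolicy:
    """When treatment is on, how strong it is, and how it stops.

    ``start_time``/``stop_time`` are years from baseline.  If both
    ``stop_time`` and ``washout_gap`` are set, treatment resumes after
    the off-treatment gap (trial-extension pattern); with ``stop_time``
    alone treatment simply ends.
    """

    effect: TreatmentEffect
    discontinuation: DiscontinuationSchedule = field(default_factory=DiscontinuationSchedule.none)
    start_time: float = 0.0
    stop_time: float | None = None
    washout_gap: float | None = None

    def __post_init__(self) -> None:
        if self.stop_time is not None and self.stop_time <= self.start_time:
            raise ValueError("stop_time must exceed start_time")
        if self.washout_gap is not None:
            if self.stop_time is None:
                raise ValueError("washout_gap requires a stop_time between phases")
            if self.washout_gap < 0:
                raise ValueError("washout_gap must be non-negative")

    def on_intervals(self, horizon: float, disc_time: float = math.inf) -> list[tuple[float, float]]:
        """On-treatment intervals within [0, horizon].

        ``disc_time`` is a permanent discontinuation time measured in
        cumulative treatment-years.
        """
        raw: list[tuple[float, float]]
        if self.stop_time is None:
            raw = [(self.start_time, horizon)]
        elif self.washout_gap is not None:
            resume = self.stop_time + self.washout_gap
            raw = [(self.start_time, self.stop_time), (resume, horizon)]
        else:
            raw = [(self.start_time, self.stop_time)]
        out: list[tuple[float, float]] = []
        treated = 0.0
        for a, b in raw:
            a, b = max(a, 0.0), min(b, horizon)
            if b <= a:
                continue
            if treated + (b - a) > disc_time:
                out.append((a, a + (disc_time - treated)))
                break
            out.append((a, b))
            treated += b - a
        return [(a, b) for a, b in out if b > a]

    def multiplier_segments(
        self, horizon: float, disc_time: float = math.inf
    ) -> list[tuple[float, float, float]]:
        """Piecewise-constant decline multiplier over [0, horizon]."""
        m_on = 1.0 - self.effect.rho
        edges = [0.0]
        on = self.on_intervals(horizon, disc_time)
        for a, b in on:
            edges.extend((a, b))
        edges.append(horizon)
        edges = sorted(set(min(max(e, 0.0), horizon) for e in edges))
        segs = []
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            mult = m_on if any(lo <= mid < hi for lo, hi in on) else 1.0
            segs.append((a, b, mult))
        return segs


@dataclass(frozen=True)
class TrialOverride:
    """Observed three-year trial trajectories used in place of the model law.

    Cumulative TKV percentage changes at years 1–3 (placebo arm) and the
    constant per-arm eGFR slopes; outside the three-year window the
    progression law resumes from the overridden state.
    """

    tkv_pct_changes: tuple[float, float, float] = (5.05, 11.49, 18.85)
    placebo_slope: float = -3.812
    tolvaptan_slope: float = -2.609


def apply_trial_override(
    baseline, override: TrialOverride, arm: str, t: float
) -> tuple[float, float]:
    """(TKV, eGFR) at time ``t`` in [0, 3] under the in-trial override.

    TKV follows linear interpolation of the printed cumulative per-cent
    changes; eGFR follows the printed constant arm slope.
    """
    if not 0.0 <= t <= 3.0:
        raise ValueError("the trial override applies only for t in [0, 3] years")
    if arm == "placebo":
        slope = override.placebo_slope
    elif arm == "tolvaptan":
        slope = override.tolvaptan_slope
    else:
        raise ValueError(f"unknown arm {arm!r}")
    pct = float(np.interp(t, [0.0, 1.0, 2.0, 3.0], [0.0, *override.tkv_pct_changes]))
    tkv = baseline.tkv0 * (1.0 + pct / 100.0)
    egfr = baseline.egfr0 + slope * t
    return tkv, egfr
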