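"""Scenario runner, outcome statistics and file outputs.

A scenario pairs a treated arm against a control (natural-history) arm
on identical baselines and summarises per-arm events: fraction reaching
ESRD before death, mean time/age at ESRD onset among reachers, expected
years on treatment, and the treated-minus-control delay.  Evaluation is
either deterministic ("mean" profile mode: sex-stratified closed forms,
analytic survival weights, discontinuation handled by enumerating its
discrete mixture) or stochastic (seeded patient-level sampling).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter, exceptions

from .calibration import FittedParams, calibrate
from .cohorts import (
    CohortProfile,
    PatientBaseline,
    build_profile,
    expectation_strata,
    sample_cohort,
)
from .progression import (
    MortalityParams,
    ProgressionParams,
    baseline_growth_rate,
    ckd_stage,
    piecewise_egfr,
    piecewise_time_to_threshold,
    sample_death_age,
    survival_integral,
    survival_probability,
    tkv_at,
)
from .treatment import (
    DiscontinuationSchedule,
    TreatmentEffect,
    TreatmentPolicy,
    TrialOverride,
    apply_trial_override,
    enumerate_discontinuation_mixture,
    get_effect,
    sample_discontinuation_time,
)

__all__ = [
    "ScenarioConfig",
    "OutcomeSummary",
    "ScenarioResult",
    "KMCurve",
    "load_scenario",
    "available_scenarios",
    "run_scenario",
    "km_curve",
    "annualized_slope",
    "one_year_effect",
    "five_year_change_series",
    "write_outputs",
    "held_out_validation_table",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (profile, effect, policy, evaluation mode)."""

    profile: str = "overall"
    mode: str = "mean"                 # "mean" (expectation) | "stochastic"
    n: int | None = None               # stochastic cohort size; default profile n
    seed: int = 0
    effect_measure: str = "reciprocal_creatinine"
    subgroup: str = "overall"
    rho: float | None = None           # explicit override of the table value
    discontinuation: bool = False
    trial_override: bool = False
    horizon_age: float = 110.0
    start_time: float = 0.0
    stop_time: float | None = None
    washout_gap: float | None = None

    def __post_init__(self) -> None:
        if self.n is not None and self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if self.mode not in ("mean", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def resolve_effect(self) -> TreatmentEffect:
        eff = get_effect(self.effect_measure, self.subgroup)
        if self.rho is not None:
            eff = TreatmentEffect(eff.measure, eff.subgroup, self.rho)
        return eff

    def policy(self) -> TreatmentPolicy:
        sched = DiscontinuationSchedule() if self.discontinuation else DiscontinuationSchedule.none()
        return TreatmentPolicy(
            effect=self.resolve_effect(),
            discontinuation=sched,
            start_time=self.start_time,
            stop_time=self.stop_time,
            washout_gap=self.washout_gap,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def available_scenarios() -> list[str]:
    """Names of the scenario configs shipped with the package."""
    root = resources.files("adpkdsim.configs")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name: str) -> ScenarioConfig:
    """Load a shipped scenario config by name (e.g. ``base_case``)."""
    ref = resources.files("adpkdsim.configs").joinpath(f"{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown scenario {name!r}; shipped scenarios: " + ", ".join(available_scenarios())
        ) from None
    return ScenarioConfig(**(yaml.safe_load(text) or {}))


@dataclass(frozen=True)
class OutcomeSummary:
    """Cohort-level outcome statistics for one arm (or arm contrast)."""

    fraction_reaching_esrd: float
    mean_time_to_esrd: float           # years from baseline, among reachers
    mean_age_at_esrd: float            # years, among reachers
    mean_treatment_duration: float     # expected alive-years on treatment, all patients
    rmst_to_esrd: float                # expected ESRD-free alive-years (all patients)
    delay_vs_control: float | None = None
    esrd_prevented_fraction: float | None = None
    years_of_therapy_per_year_delayed: float | None = None


@dataclass
class KMCurve:
    """Product-limit survival-to-ESRD estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    fitted: FittedParams
    outcomes: pd.DataFrame             # per patient/stratum/atom, both arms
    control: OutcomeSummary
    treated: OutcomeSummary
    trajectories: pd.DataFrame         # annual-grid series per stratum, both arms


# ---------------------------------------------------------------------------
# arm evaluation


def _arm_record(
    patient: PatientBaseline,
    weight: float,
    params: ProgressionParams,
    mort: MortalityParams,
    policy: TreatmentPolicy | None,
    horizon: float,
    disc_time: float = math.inf,
    death_time: float | None = None,
    trial_override: TrialOverride | None = None,
    override_arm: str = "placebo",
) -> dict:
    """Event record for one patient under one arm.

    Expectation path (``death_time is None``): death enters as an
    analytic survival weight and expected alive-years on treatment.
    Stochastic path: the sampled death time censors events directly.
    """
    g = baseline_growth_rate(patient.age0, patient.tkv0, patient.height, params)
    on_intervals = [] if policy is None else policy.on_intervals(horizon, disc_time)

    if trial_override is None:
        segments = (
            [(0.0, horizon, 1.0)]
            if policy is None
            else policy.multiplier_segments(horizon, disc_time)
        )
        esrd_time = piecewise_time_to_threshold(patient, g, params, segments)
    else:
        # Printed in-trial trajectories for t in [0, 3]; the law resumes
        # from the overridden state afterwards (same growth rate g).
        slope = (
            trial_override.placebo_slope
            if override_arm == "placebo"
            else trial_override.tolvaptan_slope
        )
        cross = (params.esrd_threshold - patient.egfr0) / slope if slope < 0 else math.inf
        if cross <= 3.0:
            esrd_time = cross
        else:
            tkv3, egfr3 = apply_trial_override(patient, trial_override, override_arm, 3.0)
            resumed = dataclasses.replace(patient, tkv0=tkv3, egfr0=egfr3)
            if policy is None:
                tail = [(0.0, horizon - 3.0, 1.0)]
            else:
                tail = [
                    (max(a - 3.0, 0.0), b - 3.0, m)
                    for a, b, m in policy.multiplier_segments(horizon, disc_time)
                    if b > 3.0
                ]
            sub = piecewise_time_to_threshold(resumed, g, params, tail)
            esrd_time = None if sub is None else 3.0 + sub

    end = horizon if esrd_time is None else min(esrd_time, horizon)
    if death_time is not None:
        end_observed = min(end, death_time)
        reaches = esrd_time is not None and esrd_time <= min(death_time, horizon)
        p_reach = 1.0 if reaches else 0.0
        years_on = sum(max(0.0, min(b, end_observed) - a) for a, b in on_intervals if a < end_observed)
        duration_record = end_observed
    else:
        p_reach = (
            survival_probability(mort, patient.age0, patient.age0 + esrd_time)
            if esrd_time is not None and esrd_time <= horizon
            else 0.0
        )
        years_on = sum(
            survival_integral(mort, patient.age0, a, min(b, end))
            for a, b in on_intervals
            if a < end
        )
        duration_record = end
    rmst = (
        survival_integral(mort, patient.age0, 0.0, end)
        if death_time is None
        else duration_record
    )
    return {
        "weight": weight,
        "age0": patient.age0,
        "sex": patient.sex,
        "esrd_time": math.nan if esrd_time is None else esrd_time,
        "age_at_esrd": math.nan if esrd_time is None else patient.age0 + esrd_time,
        "p_reach": p_reach,
        "years_on_treatment": years_on,
        "duration": duration_record,
        "rmst": rmst,
    }


def _summarize(records: pd.DataFrame) -> OutcomeSummary:
    w = records["weight"].to_numpy()
    p = records["p_reach"].to_numpy()
    t = np.nan_to_num(records["esrd_time"].to_numpy())
    reach_mass = float(np.sum(w * p))
    total = float(np.sum(w))
    frac = reach_mass / total
    mean_t = float(np.sum(w * p * t) / reach_mass) if reach_mass > 0 else math.nan
    mean_age = (
        float(np.sum(w * p * (records["age0"].to_numpy() + t)) / reach_mass)
        if reach_mass > 0
        else math.nan
    )
    return OutcomeSummary(
        fraction_reaching_esrd=frac,
        mean_time_to_esrd=mean_t,
        mean_age_at_esrd=mean_age,
        mean_treatment_duration=float(np.sum(w * records["years_on_treatment"]) / total),
        rmst_to_esrd=float(np.sum(w * records["rmst"]) / total),
    )


def _trajectory_frame(
    patient: PatientBaseline,
    label: str,
    arm: str,
    params: ProgressionParams,
    policy: TreatmentPolicy | None,
    horizon: float,
) -> pd.DataFrame:
    g = baseline_growth_rate(patient.age0, patient.tkv0, patient.height, params)
    segments = (
        [(0.0, horizon, 1.0)] if policy is None else policy.multiplier_segments(horizon)
    )
    esrd = piecewise_time_to_threshold(patient, g, params, segments)
    end = horizon if esrd is None else esrd
    times = np.unique(np.append(np.arange(0.0, math.floor(end) + 0.5), end))
    on = [] if policy is None else policy.on_intervals(horizon)
    rows = []
    for t in times:
        e = piecewise_egfr(patient, g, params, segments, t)
        rows.append(
            {
                "stratum": label,
                "arm": arm,
                "t_years": t,
                "age": patient.age0 + t,
                "egfr": e,
                "tkv": tkv_at(patient.tkv0, g, t),
                "ckd_stage": ckd_stage(e, params.esrd_threshold),
                "on_treatment": any(a <= t < b for a, b in on),
            }
        )
    return pd.DataFrame(rows)


def run_scenario(
    config: ScenarioConfig, fitted: FittedParams | None = None
) -> ScenarioResult:
    """Simulate the paired treated/control scenario and summarise it."""
    if fitted is None:
        fitted = calibrate()
    params = fitted.progression()
    mort = fitted.mortality()
    profile = build_profile(config.profile)
    policy = config.policy()
    horizon = config.horizon_age - profile.mean_age
    override = TrialOverride() if config.trial_override else None

    records: list[dict] = []
    if config.mode == "mean":
        atoms = (
            enumerate_discontinuation_mixture(policy.discontinuation, horizon)
            if config.discontinuation
            else [(math.inf, 1.0)]
        )
        for si, (w, patient) in enumerate(expectation_strata(profile)):
            rec = _arm_record(
                patient, w, params, mort, None, horizon,
                trial_override=override, override_arm="placebo",
            )
            rec.update(arm="control", stratum=si, atom=math.nan)
            records.append(rec)
            for d, pd_atom in atoms:
                rec = _arm_record(
                    patient, w * pd_atom, params, mort, policy, horizon,
                    disc_time=d, trial_override=override, override_arm="tolvaptan",
                )
                rec.update(arm="treated", stratum=si, atom=d)
                records.append(rec)
    else:
        n = config.n or profile.n
        cohort = sample_cohort(profile, n, "stochastic", seed=config.seed)
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2**16 + 1])
        )
        w = 1.0 / n
        for patient in cohort:
            death_age = sample_death_age(mort, patient.age0, rng)
            death_time = None if math.isinf(death_age) else death_age - patient.age0
            disc = (
                sample_discontinuation_time(policy.discontinuation, rng)
                if config.discontinuation
                else math.inf
            )
            horizon_i = config.horizon_age - patient.age0
            dt = math.inf if death_time is None else death_time
            rec = _arm_record(
                patient, w, params, mort, None, horizon_i, death_time=dt,
                trial_override=override, override_arm="placebo",
            )
            rec.update(arm="control", stratum=patient.id, atom=math.nan)
            records.append(rec)
            rec = _arm_record(
                patient, w, params, mort, policy, horizon_i,
                disc_time=disc, death_time=dt,
                trial_override=override, override_arm="tolvaptan",
            )
            rec.update(arm="treated", stratum=patient.id, atom=disc)
            records.append(rec)

    outcomes = pd.DataFrame(records)
    control = _summarize(outcomes[outcomes["arm"] == "control"])
    treated = _summarize(outcomes[outcomes["arm"] == "treated"])

    delay = treated.mean_age_at_esrd - control.mean_age_at_esrd
    prevented = control.fraction_reaching_esrd - treated.fraction_reaching_esrd
    ratio = treated.mean_treatment_duration / delay if delay > 0 else math.nan
    treated = dataclasses.replace(
        treated,
        delay_vs_control=delay,
        esrd_prevented_fraction=prevented,
        years_of_therapy_per_year_delayed=ratio,
    )

    strata = expectation_strata(profile)
    traj = pd.concat(
        [
            _trajectory_frame(p, f"{p.sex}", arm, params, pol, horizon)
            for _, p in strata
            for arm, pol in (("control", None), ("treated", policy))
        ],
        ignore_index=True,
    )
    return ScenarioResult(
        config=config,
        fitted=fitted,
        outcomes=outcomes,
        control=control,
        treated=treated,
        trajectories=traj,
    )


# ---------------------------------------------------------------------------
# outcome operations


def km_curve(outcomes: pd.DataFrame, grid: np.ndarray | None = None) -> KMCurve:
    """Kaplan–Meier survival-to-ESRD from per-patient event records.

    Expects columns ``duration`` (years to ESRD, death or horizon),
    ``p_reach`` (event indicator or probability) and ``weight``.
    Probabilistic expectation-mode records are split into an event atom
    and a censored atom with the corresponding weights.
    """
    if outcomes.empty:
        raise ValueError("cannot build a KM curve from an empty cohort")
    durations, events, weights = [], [], []
    for _, row in outcomes.iterrows():
        p = float(row["p_reach"])
        w = float(row["weight"])
        d = float(row["duration"])
        if p > 0:
            durations.append(row["esrd_time"] if not math.isnan(row["esrd_time"]) else d)
            events.append(1)
            weights.append(w * p)
        if p < 1:
            durations.append(d)
            events.append(0)
            weights.append(w * (1 - p))
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        # fractional analytic weights are intentional in expectation mode
        warnings.simplefilter("ignore", exceptions.StatisticalWarning)
        kmf.fit(durations, event_observed=events, weights=weights, timeline=grid)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    ev = kmf.event_table.reindex(sf.index).fillna(0.0)
    return KMCurve(
        times=times,
        survival=sf.iloc[:, 0].to_numpy(),
        at_risk=ev["at_risk"].to_numpy(),
        events=ev["observed"].to_numpy(),
    )


def annualized_slope(times: np.ndarray, egfr: np.ndarray) -> float:
    """Ordinary least-squares eGFR slope (mL/min/1.73m^2 per year)."""
    times = np.asarray(times, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two points to estimate a slope")
    return float(np.polyfit(times, egfr, 1)[0])


def _mean_change(
    profile: CohortProfile,
    params: ProgressionParams,
    multiplier: float,
    t: float,
) -> float:
    """Stratified mean eGFR drop (positive number) after ``t`` years."""
    total = 0.0
    for w, patient in expectation_strata(profile):
        g = baseline_growth_rate(patient.age0, patient.tkv0, patient.height, params)
        kprime = params.kappa * (patient.tkv0 / params.tkv_norm) ** params.gamma
        a = params.gamma * g
        drop = multiplier * kprime * t if abs(a) < 1e-10 else multiplier * (kprime / a) * math.expm1(a * t)
        total += w * drop
    return total


def one_year_effect(
    fitted: FittedParams,
    profile: CohortProfile | None = None,
    rho: float | None = None,
) -> float:
    """Treatment effect on one-year mean eGFR change (treated − control).

    Defaults replicate the later-stage validation cohort with the
    CKD-EPI overall effect size (rho = 0.264); positive values mean
    preserved renal function.
    """
    if profile is None:
        profile = build_profile("reprise")
    if rho is None:
        rho = get_effect("ckd_epi", "overall").rho
    params = fitted.progression()
    return _mean_change(profile, params, 1.0, 1.0) - _mean_change(profile, params, 1.0 - rho, 1.0)


def five_year_change_series(
    fitted: FittedParams,
    profile: CohortProfile | None = None,
    rho: float | None = None,
    washout_gap: float = 0.25,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """eGFR change from baseline over a 3-yr + washout + 2-yr regimen.

    Emulates an early-treated trial-extension cohort: treatment for
    three years, an off-treatment washout gap, then treatment again to
    5.25 years.  Returns columns ``t_years``, ``egfr_change``,
    ``on_treatment``.
    """
    if profile is None:
        profile = build_profile("tempo44")
    if rho is None:
        rho = get_effect("ckd_epi", "overall").rho
    if times is None:
        times = np.arange(0.0, 3.0 + washout_gap + 2.0 + 1e-9, 0.25)
    params = fitted.progression()
    policy = TreatmentPolicy(
        effect=TreatmentEffect("ckd_epi", "overall", rho),
        start_time=0.0,
        stop_time=3.0,
        washout_gap=washout_gap,
    )
    horizon = float(times[-1]) + 1.0
    segments = policy.multiplier_segments(horizon)
    on = policy.on_intervals(horizon)
    rows = []
    for t in times:
        change = 0.0
        for w, patient in expectation_strata(profile):
            g = baseline_growth_rate(patient.age0, patient.tkv0, patient.height, params)
            change += w * (piecewise_egfr(patient, g, params, segments, t) - patient.egfr0)
        rows.append(
            {
                "t_years": float(t),
                "egfr_change": change,
                "on_treatment": any(a <= t < b for a, b in on),
            }
        )
    return pd.DataFrame(rows)


def write_outputs(result: ScenarioResult, directory: str | Path) -> dict[str, Path]:
    """Write outcomes.csv, summary.json, km.csv and trajectories.csv."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc
    if result.outcomes.empty:
        raise ValueError("scenario produced no outcome records")

    paths = {
        "outcomes": directory / "outcomes.csv",
        "summary": directory / "summary.json",
        "km": directory / "km.csv",
        "trajectories": directory / "trajectories.csv",
    }
    result.outcomes.to_csv(paths["outcomes"], index=False)
    result.trajectories.to_csv(paths["trajectories"], index=False)

    km_frames = []
    for arm in ("control", "treated"):
        curve = km_curve(result.outcomes[result.outcomes["arm"] == arm])
        km_frames.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "t": curve.times,
                    "survival": curve.survival,
                    "n_at_risk": curve.at_risk,
                    "n_events": curve.events,
                }
            )
        )
    pd.concat(km_frames, ignore_index=True).to_csv(paths["km"], index=False)

    summary = {
        "config": result.config.to_dict(),
        "fitted": {
            "kappa": result.fitted.kappa,
            "gamma": result.fitted.gamma,
            "mortality_scale": result.fitted.mortality_scale,
        },
        "control": dataclasses.asdict(result.control),
        "treated": dataclasses.asdict(result.treated),
        "delay_vs_control": result.treated.delay_vs_control,
        "esrd_prevented_fraction": result.treated.esrd_prevented_fraction,
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# held-out validation surface


def held_out_validation_table(fitted: FittedParams) -> pd.DataFrame:
    """Predicted vs published outcomes not used as calibration anchors."""
    base = run_scenario(ScenarioConfig(), fitted)
    ckd1 = run_scenario(ScenarioConfig(profile="ckd1"), fitted)
    ckd2 = run_scenario(ScenarioConfig(profile="ckd2"), fitted)
    ckd3 = run_scenario(ScenarioConfig(profile="ckd3"), fitted)
    disc = run_scenario(ScenarioConfig(discontinuation=True), fitted)

    rows = [
        ("esrd_prevented_pct", 100 * base.treated.esrd_prevented_fraction, 3.0),
        ("base_treatment_duration_yr", base.treated.mean_treatment_duration, 17.9),
        ("ckd1_natural_time_yr", ckd1.control.mean_time_to_esrd, 19.0),
        ("ckd2_natural_time_yr", ckd2.control.mean_time_to_esrd, 12.0),
        ("ckd3_natural_time_yr", ckd3.control.mean_time_to_esrd, 7.0),
        ("ckd1_delay_yr", ckd1.treated.delay_vs_control, 6.6),
        ("ckd2_delay_yr", ckd2.treated.delay_vs_control, 4.7),
        ("ckd3_delay_yr", ckd3.treated.delay_vs_control, 2.7),
        ("discontinuation_delay_yr", disc.treated.delay_vs_control, 3.8),
        ("discontinuation_duration_yr", disc.treated.mean_treatment_duration, 13.6),
        ("reprise_one_year_effect", one_year_effect(fitted), 1.26),
    ]
    frame = pd.DataFrame(rows, columns=["outcome", "predicted", "published"])
    frame["abs_difference"] = (frame["predicted"] - frame["published"]).abs()
    return frame
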