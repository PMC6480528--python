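"""Synthetic ADPKD cohort construction.

Baseline populations are described only through published trial summary
profiles (mean age, % female, mean eGFR, mean TKV).  This module turns a
named profile into simulated patients in two modes:

* ``mean`` — every patient carries the profile means (deterministic; no
  random numbers are consumed), with sex assigned so the female fraction
  matches the profile as closely as integer counts allow;
* ``stochastic`` — age and eGFR are drawn from truncated normals and TKV
  from a truncated log-normal, so that sample means converge to the
  profile means while individual heterogeneity is present.

Heights are not part of the published profiles; they are needed because
the Mayo imaging classification works on height-adjusted TKV (htTKV).
Fixed sex-specific defaults (1.63 m female / 1.76 m male) are used in
mean mode and a truncated normal in stochastic mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortProfile",
    "PatientBaseline",
    "HeightModel",
    "HeterogeneityCV",
    "MAYO_SUBCLASSES",
    "available_profiles",
    "build_profile",
    "sample_cohort",
    "assign_height",
    "mayo_subclass",
    "expectation_strata",
    "cohort_to_frame",
]

#: Reference height-adjusted TKV (mL/m) at age zero used by the Mayo
#: imaging classification back-extrapolation.
HTTKV_REF = 150.0

#: Mayo imaging subclasses ordered by annualised htTKV growth rate.
MAYO_SUBCLASSES = ("1A", "1B", "1C", "1D", "1E")

# Upper bin edges (exclusive) for subclasses 1A..1D; ties go to the
# higher class, so an exact 3%/yr patient is 1C, not 1B.
_MAYO_EDGES = (0.015, 0.03, 0.045, 0.06)


@dataclass(frozen=True)
class CohortProfile:
    """Named baseline population summary from a published trial table."""

    name: str
    n: int
    mean_age: float          # years
    pct_female: float        # percent
    mean_egfr: float         # mL/min/1.73m^2
    mean_tkv: float          # mL
    se_age: float | None = None
    se_egfr: float | None = None
    se_tkv: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if not 0.0 <= self.pct_female <= 100.0:
            raise ValueError("pct_female must lie in [0, 100]")
        if min(self.mean_age, self.mean_egfr, self.mean_tkv) <= 0:
            raise ValueError("profile means must be positive")


@dataclass(frozen=True)
class PatientBaseline:
    """One simulated patient's starting state."""

    id: int
    age0: float      # years
    sex: str         # "female" | "male"
    height: float    # metres
    tkv0: float      # mL
    egfr0: float     # mL/min/1.73m^2

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"invalid sex label {self.sex!r}")
        if not 1.2 <= self.height <= 2.2:
            raise ValueError("height outside plausible adult range [1.2, 2.2] m")

    @property
    def httkv0(self) -> float:
        """Height-adjusted TKV at baseline (mL/m)."""
        return self.tkv0 / self.height


@dataclass(frozen=True)
class HeightModel:
    """Sex-specific height defaults (m) and stochastic-draw settings."""

    female_mean: float = 1.63
    male_mean: float = 1.76
    female_sd: float = 0.06
    male_sd: float = 0.07
    lo: float = 1.40
    hi: float = 2.10

    def mean_for(self, sex: str) -> float:
        if sex == "female":
            return self.female_mean
        if sex == "male":
            return self.male_mean
        raise ValueError(f"invalid sex label {sex!r}")


@dataclass(frozen=True)
class HeterogeneityCV:
    """Coefficients of variation for stochastic cohort sampling.

    Published profiles print standard errors of means, not patient-level
    standard deviations, so these dispersions are configuration.
    """

    age: float = 0.15
    egfr: float = 0.25
    tkv: float = 0.45    # log-normal

    def __post_init__(self) -> None:
        if min(self.age, self.egfr, self.tkv) < 0:
            raise ValueError("coefficients of variation must be non-negative")


_ALIASES = {
    "overall": "TEMPO 3:4 overall",
    "tempo34": "TEMPO 3:4 overall",
    "ckd1": "CKD 1",
    "ckd2": "CKD 2",
    "ckd3": "CKD 3",
    "mayo_1c_1e": "Mayo 1C-1E",
    "tempo44": "TEMPO 4:4 early-treated",
    "reprise": "REPRISE overall",
}


def _profile_table() -> pd.DataFrame:
    with resources.files("adpkdsim.data").joinpath("cohort_profiles.csv").open() as fh:
        return pd.read_csv(fh)


def available_profiles() -> list[str]:
    """Canonical profile labels shipped with the package."""
    return list(_profile_table()["name"])


def build_profile(name: str) -> CohortProfile:
    """Return the published baseline profile with the given label.

    Short aliases (``overall``, ``ckd1`` ... ``reprise``) are accepted
    alongside the full row labels.
    """
    canonical = _ALIASES.get(name.strip().lower().replace(" ", "_"), name)
    table = _profile_table()
    row = table[table["name"] == canonical]
    if row.empty:
        raise KeyError(
            f"unknown cohort profile {name!r}; valid labels: "
            + ", ".join(table["name"])
        )
    r = row.iloc[0]

    def _opt(key: str) -> float | None:
        return None if pd.isna(r[key]) else float(r[key])

    return CohortProfile(
        name=str(r["name"]),
        n=int(r["n"]),
        mean_age=float(r["mean_age"]),
        pct_female=float(r["pct_female"]),
        mean_egfr=float(r["mean_egfr"]),
        mean_tkv=float(r["mean_tkv"]),
        se_age=_opt("se_age"),
        se_egfr=_opt("se_egfr"),
        se_tkv=_opt("se_tkv"),
    )


def assign_height(
    sex: str,
    mode: str = "fixed",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    model: HeightModel = HeightModel(),
) -> float:
    """Sex-specific height in metres (fixed default or truncated-normal draw)."""
    mean = model.mean_for(sex)
    if mode == "fixed":
        return mean
    if mode != "stochastic":
        raise ValueError(f"unknown height mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    sd = model.female_sd if sex == "female" else model.male_sd
    a, b = (model.lo - mean) / sd, (model.hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def mayo_subclass(
    age0: float, tkv0: float, height: float, httkv_ref: float = HTTKV_REF
) -> str:
    """Mayo imaging subclass (1A–1E) from the annualised htTKV growth rate.

    The rate is back-extrapolated from a reference htTKV at age zero:
    ``r = (htTKV0 / httkv_ref) ** (1 / age0) - 1``.  Bins: 1A < 1.5%/yr,
    1B 1.5–3%, 1C 3–4.5%, 1D 4.5–6%, 1E > 6%; boundary values go to the
    higher class.
    """
    if age0 <= 0:
        raise ValueError("age must be positive")
    httkv = tkv0 / height
    if httkv <= httkv_ref:
        raise ValueError(
            "height-adjusted TKV does not exceed the reference volume; the "
            "growth-rate back-extrapolation is undefined for this patient"
        )
    rate = (httkv / httkv_ref) ** (1.0 / age0) - 1.0
    # snap tolerance absorbs round-off so exact-boundary rates bin upward;
    # it is far below any physiologically meaningful perturbation
    idx = int(np.searchsorted(_MAYO_EDGES, rate + 1e-13, side="right"))
    return MAYO_SUBCLASSES[idx]


def _female_count(n: int, pct_female: float) -> int:
    return int(round(n * pct_female / 100.0))


def sample_cohort(
    profile: CohortProfile,
    n: int,
    mode: str = "mean",
    seed: int | None = None,
    cv: HeterogeneityCV = HeterogeneityCV(),
    height_model: HeightModel = HeightModel(),
    esrd_threshold: float = 15.0,
    httkv_ref: float = HTTKV_REF,
) -> list[PatientBaseline]:
    """Simulate ``n`` baseline patients matching a published profile.

    ``mean`` mode is deterministic: every patient carries the profile
    means and the fixed sex-specific height.  ``stochastic`` mode draws
    age/eGFR from truncated normals and TKV from a truncated log-normal;
    eGFR is truncated above the ESRD threshold and TKV above the
    reference kidney volume so every patient has a positive growth rate.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    n_female = _female_count(n, profile.pct_female)
    sexes = ["female"] * n_female + ["male"] * (n - n_female)

    if mode == "mean":
        return [
            PatientBaseline(
                id=i,
                age0=profile.mean_age,
                sex=sex,
                height=height_model.mean_for(sex),
                tkv0=profile.mean_tkv,
                egfr0=profile.mean_egfr,
            )
            for i, sex in enumerate(sexes)
        ]
    if mode != "stochastic":
        raise ValueError(f"unknown cohort mode {mode!r}")

    rng = np.random.default_rng(seed)
    # Shuffle sex labels so id order carries no structure.
    rng.shuffle(sexes)

    def _truncnorm(mean: float, sd: float, lo: float, hi: float, size: int):
        if sd == 0:
            return np.full(size, mean)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    ages = _truncnorm(profile.mean_age, cv.age * profile.mean_age, 18.0, 90.0, n)
    egfrs = _truncnorm(
        profile.mean_egfr, cv.egfr * profile.mean_egfr, esrd_threshold + 1.0, 150.0, n
    )
    is_female = np.array([s == "female" for s in sexes])
    heights = np.empty(n)
    for mask, mean, sd in (
        (is_female, height_model.female_mean, height_model.female_sd),
        (~is_female, height_model.male_mean, height_model.male_sd),
    ):
        k = int(mask.sum())
        if k:
            heights[mask] = _truncnorm(mean, sd, height_model.lo, height_model.hi, k)

    # Log-normal with the profile mean as its (untruncated) expectation.
    sigma2 = np.log1p(cv.tkv**2)
    mu = np.log(profile.mean_tkv) - sigma2 / 2.0
    tkvs = np.empty(n)
    pending = np.arange(n)
    while pending.size:  # redraw below-reference volumes (rare)
        draw = rng.lognormal(mu, np.sqrt(sigma2), pending.size)
        ok = draw > httkv_ref * heights[pending] * 1.05
        tkvs[pending[ok]] = draw[ok]
        pending = pending[~ok]

    return [
        PatientBaseline(
            id=i,
            age0=float(ages[i]),
            sex=sexes[i],
            height=float(heights[i]),
            tkv0=float(tkvs[i]),
            egfr0=float(egfrs[i]),
        )
        for i in range(n)
    ]


def expectation_strata(
    profile: CohortProfile, height_model: HeightModel = HeightModel()
) -> list[tuple[float, PatientBaseline]]:
    """Sex strata for deterministic expectation-mode evaluation.

    Returns ``(weight, patient)`` pairs: a female and a male stratum at
    the profile means with fixed heights, weighted by the profile's
    female fraction.  Zero-weight strata are dropped.
    """
    f = profile.pct_female / 100.0
    strata = []
    for weight, sex in ((f, "female"), (1.0 - f, "male")):
        if weight <= 0.0:
            continue
        strata.append(
            (
                weight,
                PatientBaseline(
                    id=0 if sex == "female" else 1,
                    age0=profile.mean_age,
                    sex=sex,
                    height=height_model.mean_for(sex),
                    tkv0=profile.mean_tkv,
                    egfr0=profile.mean_egfr,
                ),
            )
        )
    return strata


def cohort_to_frame(patients: Iterable[PatientBaseline]) -> pd.DataFrame:
    """Tabulate a cohort (one row per patient, with Mayo subclass)."""
    rows = []
    for p in patients:
        rows.append(
            {
                "id": p.id,
                "age0": p.age0,
                "sex": p.sex,
                "height": p.height,
                "tkv0": p.tkv0,
                "egfr0": p.egfr0,
                "mayo_subclass": mayo_subclass(p.age0, p.tkv0, p.height),
            }
        )
    return pd.DataFrame(rows)
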