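"""Lung-cancer natural history for one simulated person.

The disease model has four parts:

1. **Onset** — age of first malignant lung cancer from the two-stage clonal
   expansion (TSCE) model of carcinogenesis.  Normal cells are initiated at
   rate nu, initiated cells divide (alpha), die (beta) and convert to a
   malignant cell (mu); initiation and net promotion respond to the
   instantaneous cigarettes/day dose.  For piecewise-constant parameters the
   survival function has a closed form obtained by composing the Riccati flow
   across smoking segments, which is what this module implements; a fine-step
   ODE integration serves as an independent oracle in the test suite.
2. **Preclinical progression** — starting in TNM stage IA the cancer spends a
   Weibull-distributed sojourn time in each successive stage (IA, IB, II,
   IIIA, IIIB, IV); sojourn means/shapes are specific to stage, histology and
   sex.  A Weibull shape below 1 yields many very short sojourns, which is how
   stage "skipping" is represented.
3. **Clinical detection** — at the end of each stage's sojourn the cancer is
   diagnosed symptomatically with a stage-specific probability or progresses
   undetected; stage IV always ends in diagnosis.
4. **Survival** — upon clinical diagnosis a survival time is drawn from a
   mixture-cure exponential per (stage, histology); the person dies of lung
   cancer or earlier of other causes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

from .errors import ConfigurationError, ValidationError
from .population import (
    DEFAULT_OC_GAMMA,
    LifeTable,
    Person,
    SmokingHistory,
    sample_other_cause_death,
    smoking_multiplier,
)

__all__ = [
    "STAGES",
    "HISTOLOGIES",
    "TsceParams",
    "HistologyDistribution",
    "SojournParams",
    "ClinicalDetectionProbs",
    "SurvivalParams",
    "StageSchedule",
    "LifeHistory",
    "ModelParams",
    "tsce_hazard",
    "tsce_cumulative_hazard",
    "sample_onset_age",
    "weibull_scale_from_mean",
    "sample_sojourn",
    "simulate_disease_course",
    "sample_survival",
    "build_life_history",
    "default_model_params",
]

STAGES = ("IA", "IB", "II", "IIIA", "IIIB", "IV")
HISTOLOGIES = ("adenocarcinoma", "squamous", "other_nsclc", "sclc")


# ---------------------------------------------------------------------------
# Two-stage clonal expansion onset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TsceParams:
    """TSCE carcinogenesis parameters for one sex.

    nu0 : background initiation rate (initiated clones per year, cell-number
        scaled); mu0 : malignant conversion rate per initiated cell per year;
        g0 : background net clonal proliferation alpha - beta - mu (per year);
        division_rate : clonal division rate alpha (per year), held fixed.
    Dose response multiplies initiation and promotion:
        nu = nu0 * (1 + c_nu * cpd**p_nu),  g = g0 * (1 + c_g * cpd**p_g).
    ``lag`` shifts malignant conversion to stage-IA onset by a fixed delay.
    """

    nu0: float
    g0: float
    mu0: float
    c_nu: float = 0.0
    c_g: float = 0.0
    p_nu: float = 1.0
    p_g: float = 1.0
    lag: float = 0.0
    division_rate: float = 3.0

    def __post_init__(self) -> None:
        for name in ("nu0", "g0", "mu0", "c_nu", "c_g", "p_nu", "p_g", "lag"):
            if getattr(self, name) < 0:
                raise ValidationError(f"TSCE parameter {name} must be >= 0")
        if self.division_rate <= 0:
            raise ValidationError("division_rate must be > 0")

    def rates_at_dose(self, cpd: float) -> tuple[float, float, float, float]:
        """(nu, alpha, beta, mu) at an instantaneous dose of ``cpd``."""
        nu = self.nu0 * (1.0 + self.c_nu * cpd ** self.p_nu) if cpd > 0 else self.nu0
        g = self.g0 * (1.0 + self.c_g * cpd ** self.p_g) if cpd > 0 else self.g0
        alpha = self.division_rate
        mu = self.mu0
        beta = alpha - g - mu
        if beta < 0:
            raise ValidationError(
                "net proliferation exceeds the division rate; increase division_rate"
            )
        return nu, alpha, beta, mu


def _exposure_regimes(smoking: SmokingHistory, up_to: float):
    """Piecewise-constant (t0, t1, cpd) regimes covering [0, up_to]."""
    pts: list[tuple[float, float, float]] = []
    t = 0.0
    for (a0, a1, cpd) in smoking.segments:
        if a0 >= up_to:
            break
        if a0 > t:
            pts.append((t, min(a0, up_to), 0.0))
        pts.append((max(a0, t), min(a1, up_to), cpd))
        t = min(a1, up_to)
        if t >= up_to:
            break
    if t < up_to:
        pts.append((t, up_to, 0.0))
    return [r for r in pts if r[1] > r[0] + 1e-12]


def _riccati_roots(alpha: float, beta: float, mu: float) -> tuple[float, float]:
    """Roots q1 < 1 < q2 of alpha z^2 - (alpha+beta+mu) z + beta = 0."""
    s = alpha + beta + mu
    disc = math.sqrt(max(s * s - 4.0 * alpha * beta, 0.0))
    q2 = (s + disc) / (2.0 * alpha)
    q1 = (s - disc) / (2.0 * alpha)
    return q1, q2

def _segment_flow(y: float, d: float, nu: float, alpha: float,
                  beta: float, mu: float) -> tuple[float, float]:
    """Propagate the no-malignancy probability backward across one regime.

    ``y`` is the probability that a clone alive at the regime's *end* never
    produces a malignant cell before the target age.  Returns the probability
    for a clone present at the regime *start*, plus this regime's additive
    contribution nu * integral(1 - v) to the person-level cumulative hazard.
    The Riccati equation v' = alpha (v - q1)(v - q2) is solved exactly via the
    Moebius substitution w = (v - q1)/(v - q2).
    """
    q1, q2 = _riccati_roots(alpha, beta, mu)
    k = alpha * (q2 - q1)
    if k < 1e-12:  # degenerate double root
        # v' = alpha (v - q)^2; 1/(q - v) grows linearly.
        q = q1
        if abs(y - q) < 1e-15:
            return y, nu * (1.0 - q) * d
        inv = 1.0 / (q - y) + alpha * d
        v0 = q - 1.0 / inv
        integral = (1.0 - q) * d + math.log(abs(inv * (q - y))) / alpha
        return v0, nu * integral
    if abs(y - q2) < 1e-15:  # stationary upper root (mu == 0 with y == 1)
        return y, nu * (1.0 - q2) * d
    w0 = (y - q1) / (y - q2)
    e = math.exp(-k * d)
    we = w0 * e
    v0 = (q1 - q2 * we) / (1.0 - we)
    # integral of (1 - v) over the regime: (1-q2) d + (q2-q1) [d + ln((1-we)/(1-w0))/k]
    integral = (1.0 - q2) * d + (q2 - q1) * (d + math.log((1.0 - we) / (1.0 - w0)) / k)
    return v0, nu * integral


def tsce_cumulative_hazard(params: TsceParams, smoking: SmokingHistory, age: float) -> float:
    """Cumulative onset hazard H(age) = -ln P(no malignant cell by ``age``).

    Exact for piecewise-constant smoking exposure: the Riccati flow is
    composed backward from ``age`` across exposure regimes, accumulating each
    regime's closed-form contribution.
    """
    if age < 0:
        raise ValidationError("age must be >= 0")
    if age == 0:
        return 0.0
    H = 0.0
    y = 1.0
    for (t0, t1, cpd) in reversed(_exposure_regimes(smoking, age)):
        nu, alpha, beta, mu = params.rates_at_dose(cpd)
        if mu == 0.0 and y == 1.0:
            continue  # no malignant conversion possible; v stays 1, no hazard
        y, dH = _segment_flow(y, t1 - t0, nu, alpha, beta, mu)
        H += dH
    return max(H, 0.0)


def tsce_hazard(params: TsceParams, smoking: SmokingHistory, age: float) -> float:
    """Instantaneous onset hazard (per year) at ``age``.

    Central finite difference of the exact cumulative hazard; step 1e-3 years
    keeps the discretization error far below the 1e-4 relative tolerance the
    ODE oracle checks.
    """
    if age < 0:
        raise ValidationError("age must be >= 0")
    eps = 1e-3
    lo = max(age - eps, 0.0)
    hi = age + eps
    h = (tsce_cumulative_hazard(params, smoking, hi)
         - tsce_cumulative_hazard(params, smoking, lo)) / (hi - lo)
    return max(h, 0.0)


def sample_onset_age(
    person: Person,
    params: TsceParams,
    seed: "int | np.random.Generator",
    max_age: float = 110.0,
    cum_hazard=None,
) -> Optional[float]:
    """Inverse-CDF draw of the stage-IA onset age, or None if no onset.

    Draws E ~ Exp(1) and solves H(a) = E on [0, max_age] by root finding on
    the exact cumulative hazard; the configured lag from malignant conversion
    to stage-IA entry is added afterwards.  ``cum_hazard`` (an age -> H
    callable) overrides the TSCE cumulative hazard, e.g. for a user-supplied
    onset model.
    """
    from scipy.optimize import brentq

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cum_hazard is None:
        cum_hazard = lambda a: tsce_cumulative_hazard(params, person.smoking, a)
    target = rng.exponential()
    if target >= cum_hazard(max_age):
        return None
    a = brentq(lambda x: cum_hazard(x) - target, 0.0, max_age, xtol=1e-8)
    onset = a + params.lag
    return onset if onset < max_age else None


# ---------------------------------------------------------------------------
# Histology, sojourn times, disease course
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistologyDistribution:
    """Per-sex probabilities over the four modelled histological types."""

    male: tuple[float, float, float, float]
    female: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for sex in ("male", "female"):
            p = getattr(self, sex)
            if len(p) != len(HISTOLOGIES):
                raise ValidationError("one probability per histology required")
            if any(not (0.0 <= x <= 1.0) for x in p):
                raise ValidationError("histology probabilities outside [0, 1]")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValidationError("histology probabilities must sum to 1")

    def probs(self, sex: str) -> np.ndarray:
        return np.asarray(getattr(self, sex), dtype=float)


def weibull_scale_from_mean(mean: float, shape: float) -> float:
    """Weibull scale such that the distribution's expectation equals ``mean``.

    scale = mean / Gamma(1 + 1/shape).
    """
    if mean <= 0 or shape <= 0:
        raise ValidationError("Weibull mean and shape must be > 0")
    return mean / gamma_fn(1.0 + 1.0 / shape)


class SojournParams:
    """Weibull (mean, shape) of the preclinical sojourn per (stage, histology, sex)."""

    def __init__(self, table: dict[tuple[str, str, str], tuple[float, float]]):
        for key, (mean, shape) in table.items():
            if mean <= 0 or shape <= 0:
                raise ValidationError(f"non-positive Weibull parameter for {key}")
        self._table = dict(table)

    def get(self, stage: str, histology: str, sex: str) -> tuple[float, float]:
        try:
            return self._table[(stage, histology, sex)]
        except KeyError:
            raise ConfigurationError(
                f"no sojourn parameters for ({stage}, {histology}, {sex})"
            ) from None

    def scale_shape(self, stage: str, histology: str, sex: str) -> tuple[float, float]:
        mean, shape = self.get(stage, histology, sex)
        return weibull_scale_from_mean(mean, shape), shape

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(stage=s, histology=h, sex=x, mean=m, shape=k)
            for (s, h, x), (m, k) in sorted(self._table.items())
        ]
        return pd.DataFrame(rows, columns=["stage", "histology", "sex", "mean", "shape"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SojournParams":
        return cls({
            (str(r.stage), str(r.histology), str(r.sex)): (float(r.mean), float(r.shape))
            for r in df.itertuples(index=False)
        })

    @classmethod
    def from_csv(cls, path) -> "SojournParams":
        return cls.from_frame(pd.read_csv(path))


def sample_sojourn(
    stage: str,
    histology: str,
    sex: str,
    params: SojournParams,
    seed: "int | np.random.Generator",
) -> float:
    """One Weibull sojourn draw for the given compartment."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale, shape = params.scale_shape(stage, histology, sex)
    return float(scale * rng.weibull(shape))


@dataclass(frozen=True)
class ClinicalDetectionProbs:
    """Probability of symptomatic diagnosis at the end of each stage's sojourn."""

    probs: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.probs) != len(STAGES):
            raise ValidationError("one detection probability per stage required")
        for p in self.probs:
            if not (0.0 <= p <= 1.0):
                raise ValidationError("detection probabilities must lie in [0, 1]")
        if self.probs[-1] != 1.0:
            raise ValidationError("stage IV must always end in clinical diagnosis")

    def __getitem__(self, stage: str) -> float:
        return self.probs[STAGES.index(stage)]


class SurvivalParams:
    """Mixture-cure exponential survival after clinical diagnosis.

    For each (stage, histology): with probability ``cure`` no lung-cancer
    death is ever scheduled; otherwise the death delay is Exponential(rate).
    """

    def __init__(self, table: dict[tuple[str, str], tuple[float, float]]):
        for key, (cure, rate) in table.items():
            if not (0.0 <= cure <= 1.0):
                raise ValidationError(f"cure fraction outside [0, 1] for {key}")
            if rate <= 0:
                raise ValidationError(f"survival rate must be > 0 for {key}")
        self._table = dict(table)

    def get(self, stage: str, histology: str) -> tuple[float, float]:
        try:
            return self._table[(stage, histology)]
        except KeyError:
            raise ConfigurationError(
                f"no survival parameters for ({stage}, {histology})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(stage=s, histology=h, cure=c, rate=r)
            for (s, h), (c, r) in sorted(self._table.items())
        ]
        return pd.DataFrame(rows, columns=["stage", "histology", "cure", "rate"])


@dataclass
class StageSchedule:
    """Counterfactual (no-screening) preclinical course of one cancer."""

    onset_age: float
    entries: list[tuple[str, float]]  # (stage, entry age), strictly increasing
    clinical_dx: Optional[tuple[float, str]]  # (age, stage) of symptomatic diagnosis

    def stage_at(self, age: float) -> Optional[str]:
        """Stage occupied at ``age`` (half-open [entry, next-entry) windows).

        None before onset or at/after clinical diagnosis.
        """
        if self.clinical_dx is not None and age >= self.clinical_dx[0]:
            return None
        current = None
        for stage, entry in self.entries:
            if entry <= age:
                current = stage
            else:
                break
        return current


@dataclass
class LifeHistory:
    """One person's simulated event sequence.

    ``lc_death_age`` is the scheduled (counterfactual, pre-screening)
    lung-cancer death; the observed death is min(lc, other-cause).  Screen
    detections are appended by the trial engine.
    """

    person: Person
    oc_death_age: float
    schedule: Optional[StageSchedule] = None
    histology: Optional[str] = None
    lc_death_age: Optional[float] = None
    screen_detections: list[tuple[int, float, str]] = field(default_factory=list)
    prevented: bool = False

    @property
    def death_age(self) -> float:
        if self.lc_death_age is None:
            return self.oc_death_age
        return min(self.lc_death_age, self.oc_death_age)

    @property
    def observed_dx(self) -> Optional[tuple[float, str]]:
        """Clinical diagnosis actually observed (before death), if any."""
        if self.schedule is None or self.schedule.clinical_dx is None:
            return None
        age, stage = self.schedule.clinical_dx
        return (age, stage) if age < self.oc_death_age else None


def simulate_disease_course(
    onset_age: float,
    histology: str,
    sex: str,
    sojourns: SojournParams,
    det: ClinicalDetectionProbs,
    seed: "int | np.random.Generator",
) -> StageSchedule:
    """Sequential staged progression with per-stage clinical-detection Bernoullis."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not math.isfinite(onset_age):
        raise ValidationError("onset_age must be finite")
    entries: list[tuple[str, float]] = []
    t = onset_age
    for stage in STAGES:
        entries.append((stage, t))
        t = t + sample_sojourn(stage, histology, sex, sojourns, rng)
        if stage == "IV" or rng.random() < det[stage]:
            return StageSchedule(onset_age, entries, (t, stage))
    raise AssertionError("unreachable: stage IV always diagnoses")


def sample_survival(
    stage: str,
    histology: str,
    age_at_dx: float,
    surv: SurvivalParams,
    oc_death_age: float,
    seed: "int | np.random.Generator",
) -> Optional[float]:
    """Scheduled lung-cancer death age after clinical diagnosis (None if cured).

    The caller takes min() with the other-cause death age; a draw landing
    after ``oc_death_age`` simply means the person dies of other causes first.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cure, rate = surv.get(stage, histology)
    if rng.random() < cure:
        return None
    return float(age_at_dx + rng.exponential(1.0 / rate))


# ---------------------------------------------------------------------------
# Parameter bundle and end-to-end composition
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Everything needed to simulate one life history."""

    tsce: dict[str, TsceParams]
    histology: HistologyDistribution
    sojourn: SojournParams
    clinical_detection: ClinicalDetectionProbs
    survival: SurvivalParams
    life_table: dict[str, LifeTable]
    oc_gamma: float = DEFAULT_OC_GAMMA


def _default_sojourn_table() -> dict[tuple[str, str, str], tuple[float, float]]:
    """Default sojourn table.

    The stage IA adenocarcinoma rows carry the trial-fitted values (mean 3.56 y
    for men, 4.77 y for women, shape 0.35).  All other cells are synthetic
    stand-ins: plausible values informed by the published NLST-fitted IA
    adenocarcinoma row (1.82/2.43 y, shape 1.44), with faster progression for
    squamous/other NSCLC, very fast small-cell disease, and sub-year sojourns
    in later stages.
    """
    table: dict[tuple[str, str, str], tuple[float, float]] = {}
    ia = {
        "adenocarcinoma": {"male": (3.56, 0.35), "female": (4.77, 0.35)},
        "squamous": {"male": (1.5, 1.2), "female": (1.8, 1.2)},
        "other_nsclc": {"male": (1.3, 1.2), "female": (1.6, 1.2)},
        "sclc": {"male": (0.4, 1.0), "female": (0.45, 1.0)},
    }
    later = {  # (mean, shape) by stage, same across sexes
        "IB": {"adenocarcinoma": (1.0, 1.1), "squamous": (0.8, 1.1),
               "other_nsclc": (0.8, 1.1), "sclc": (0.25, 1.0)},
        "II": {"adenocarcinoma": (0.8, 1.1), "squamous": (0.7, 1.1),
               "other_nsclc": (0.7, 1.1), "sclc": (0.2, 1.0)},
        "IIIA": {"adenocarcinoma": (0.7, 1.1), "squamous": (0.6, 1.1),
                 "other_nsclc": (0.6, 1.1), "sclc": (0.2, 1.0)},
        "IIIB": {"adenocarcinoma": (0.6, 1.1), "squamous": (0.5, 1.1),
                 "other_nsclc": (0.5, 1.1), "sclc": (0.15, 1.0)},
        "IV": {"adenocarcinoma": (0.6, 1.1), "squamous": (0.5, 1.1),
               "other_nsclc": (0.5, 1.1), "sclc": (0.15, 1.0)},
    }
    for hist in HISTOLOGIES:
        for sex in ("male", "female"):
            table[("IA", hist, sex)] = ia[hist][sex]
            for stage in ("IB", "II", "IIIA", "IIIB", "IV"):
                table[(stage, hist, sex)] = later[stage][hist]
    return table


def _default_survival_table() -> dict[tuple[str, str], tuple[float, float]]:
    """Synthetic stand-in cure fractions / event rates after clinical diagnosis."""
    cure_by_stage = {"IA": 0.50, "IB": 0.40, "II": 0.28, "IIIA": 0.15,
                     "IIIB": 0.08, "IV": 0.02}
    rate_by_stage = {"IA": 0.35, "IB": 0.40, "II": 0.55, "IIIA": 0.75,
                     "IIIB": 1.0, "IV": 1.6}
    table = {}
    for stage in STAGES:
        for hist in HISTOLOGIES:
            cure = cure_by_stage[stage] * (0.5 if hist == "sclc" else 1.0)
            rate = rate_by_stage[stage] * (1.8 if hist == "sclc" else 1.0)
            table[(stage, hist)] = (cure, rate)
    return table


def default_model_params() -> ModelParams:
    """Stated-world default parameter bundle.

    TSCE coefficients are chosen once to give realistic lifetime risks for a
    high-exposure cohort (lifetime lung-cancer risk near 1% for never-smokers
    and 15-20% for lifelong heavy smokers); they are configuration, not
    published estimates.
    """
    tsce = {
        "male": TsceParams(nu0=0.12, g0=0.085, mu0=2.0e-6, c_nu=0.30, c_g=0.12,
                           p_nu=1.0, p_g=0.5, division_rate=3.0),
        "female": TsceParams(nu0=0.10, g0=0.085, mu0=2.0e-6, c_nu=0.30, c_g=0.12,
                             p_nu=1.0, p_g=0.5, division_rate=3.0),
    }
    histology = HistologyDistribution(
        male=(0.38, 0.26, 0.16, 0.20),
        female=(0.48, 0.16, 0.15, 0.21),
    )
    return ModelParams(
        tsce=tsce,
        histology=histology,
        sojourn=SojournParams(_default_sojourn_table()),
        # stage IV is the most common stage at symptomatic diagnosis
        clinical_detection=ClinicalDetectionProbs((0.05, 0.10, 0.20, 0.30, 0.45, 1.0)),
        survival=SurvivalParams(_default_survival_table()),
        life_table={
            "male": LifeTable.gompertz_makeham("male"),
            "female": LifeTable.gompertz_makeham("female"),
        },
    )


def build_life_history(
    person: Person,
    params: ModelParams,
    seed: "int | np.random.Generator",
) -> LifeHistory:
    """Compose onset, histology, disease course, survival and other-cause death.

    The counterfactual (no-screening) schedule is retained in full so that the
    screening engine can evaluate the stage occupied at any screen time; all
    *observed* quantities are derived by truncating at min(lc, other-cause)
    death.  A latent onset after the other-cause death is kept in the schedule
    but never observed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    oc_age = sample_other_cause_death(person, params.life_table[person.sex], rng,
                                      gamma=params.oc_gamma)
    lh = LifeHistory(person=person, oc_death_age=oc_age)
    onset = sample_onset_age(person, params.tsce[person.sex], rng)
    if onset is None:
        return lh
    hist = HISTOLOGIES[rng.choice(len(HISTOLOGIES), p=params.histology.probs(person.sex))]
    schedule = simulate_disease_course(onset, hist, person.sex, params.sojourn,
                                       params.clinical_detection, rng)
    lh.schedule = schedule
    lh.histology = hist
    dx_age, dx_stage = schedule.clinical_dx
    lh.lc_death_age = sample_survival(dx_stage, hist, dx_age, params.survival,
                                      oc_age, rng)
    return lh
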