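"""Four-round CT screening applied to simulated life histories.

Implements the screening arm of the trial: stage/histology/round-specific CT
sensitivity, the stage-specific mortality-prevention ("cure") draw upon
screen detection, interval-cancer classification, and aggregation of both
arms into trial-level counts.

Two code paths share one set of semantics:

* per-person operations (:func:`screen_person`,
  :func:`apply_mortality_prevention`) working on :class:`LifeHistory`
  objects — the reference semantics, convenient for hand-built cases; and
* an array engine (:func:`simulate_natural_histories` +
  :func:`run_trial`) that freezes every random draw into per-person arrays so
  a cohort of 10^5+ persons simulates in seconds and so calibration can
  re-screen the same natural histories under new parameters (common random
  numbers) without re-simulating disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError, ValidationError
from . import nelson
from .natural_history import (
    HISTOLOGIES,
    STAGES,
    ClinicalDetectionProbs,
    LifeHistory,
    ModelParams,
    SojournParams,
    SurvivalParams,
    TsceParams,
    tsce_cumulative_hazard,
    weibull_scale_from_mean,
)
from .population import AttendanceModel, Cohort, smoking_multiplier, sample_other_cause_death_ages

__all__ = [
    "ScreeningProtocol",
    "SensitivityParams",
    "CureProbs",
    "TrialResult",
    "NaturalHistories",
    "sensitivity",
    "screen_person",
    "apply_mortality_prevention",
    "simulate_natural_histories",
    "run_trial",
    "all_screen_average_sensitivity",
]

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}
_HIST_INDEX = {h: i for i, h in enumerate(HISTOLOGIES)}


@dataclass(frozen=True)
class ScreeningProtocol:
    """Screen times (years from randomization), attendance and follow-up."""

    round_times: tuple[float, ...] = nelson.ROUND_TIMES
    attendance: AttendanceModel = field(default_factory=AttendanceModel)
    followup_end: float = nelson.FOLLOWUP_YEARS

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.round_times, self.round_times[1:])):
            raise ValidationError("round times must be strictly increasing")
        if self.followup_end <= self.round_times[-1]:
            raise ValidationError("follow-up must extend past the last round")


class SensitivityParams:
    """Stage x histology CT sensitivity, baseline vs repeat screens.

    ``table`` mode stores explicit (baseline, repeat) probabilities per
    (stage, histology).  ``parametric`` mode stores baseline probabilities and
    a per-histology logit-scale repeat-screen boost beta_h:
    repeat = expit(logit(baseline) + beta_h); beta_h = 0 reproduces the
    baseline exactly.
    """

    def __init__(self, mode: str,
                 table: dict[tuple[str, str], tuple[float, float]] | None = None,
                 base: dict[tuple[str, str], float] | None = None,
                 beta: dict[str, float] | None = None):
        if mode not in ("table", "parametric"):
            raise ConfigurationError(f"unknown sensitivity mode {mode!r}")
        self.mode = mode
        if mode == "table":
            if table is None:
                raise ConfigurationError("table mode requires a table")
            for key, (b, r) in table.items():
                if not (0.0 <= b <= 1.0 and 0.0 <= r <= 1.0):
                    raise ValidationError(f"sensitivity outside [0, 1] for {key}")
            self.table = dict(table)
        else:
            if base is None or beta is None:
                raise ConfigurationError("parametric mode requires base and beta")
            for key, b in base.items():
                if not (0.0 <= b <= 1.0):
                    raise ValidationError(f"baseline sensitivity outside [0, 1] for {key}")
            for h, bh in beta.items():
                if bh < 0:
                    raise ValidationError("beta_h must be >= 0")
            self.base = dict(base)
            self.beta = dict(beta)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_percent_frame(cls, df: pd.DataFrame) -> "SensitivityParams":
        """Table mode from a tidy frame with percent columns baseline, repeat."""
        bad = df[(df.baseline < 0) | (df.baseline > 100)
                 | (df.repeat < 0) | (df.repeat > 100)]
        if len(bad):
            raise ValidationError("sensitivity percentages must lie in [0, 100]")
        table = {
            (str(r.stage), str(r.histology)): (float(r.baseline) / 100.0,
                                               float(getattr(r, "repeat")) / 100.0)
            for r in df.itertuples(index=False)
        }
        return cls("table", table=table)

    @classmethod
    def nelson_fitted(cls) -> "SensitivityParams":
        """Table mode loaded with the published fitted sensitivity table."""
        return cls.from_percent_frame(nelson.sensitivity_frame())

    @classmethod
    def constant(cls, p: float) -> "SensitivityParams":
        table = {(s, h): (p, p) for s in STAGES for h in HISTOLOGIES}
        return cls("table", table=table)

    # -- evaluation --------------------------------------------------------
    def value(self, stage: str, histology: str, is_repeat: bool) -> float:
        if self.mode == "table":
            try:
                b, r = self.table[(stage, histology)]
            except KeyError:
                raise ConfigurationError(
                    f"no sensitivity entry for ({stage}, {histology})") from None
            return r if is_repeat else b
        try:
            b = self.base[(stage, histology)]
        except KeyError:
            raise ConfigurationError(
                f"no baseline sensitivity for ({stage}, {histology})") from None
        bh = self.beta.get(histology, 0.0)
        if not is_repeat or bh == 0.0:
            return b
        if b <= 0.0:
            return 0.0
        if b >= 1.0:
            return 1.0
        return float(expit(logit(b) + bh))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(baseline, repeat) arrays of shape (n_stages, n_histologies)."""
        base = np.zeros((len(STAGES), len(HISTOLOGIES)))
        rep = np.zeros_like(base)
        for i, s in enumerate(STAGES):
            for j, h in enumerate(HISTOLOGIES):
                base[i, j] = self.value(s, h, False)
                rep[i, j] = self.value(s, h, True)
        return base, rep

    def to_percent_frame(self) -> pd.DataFrame:
        rows = [
            dict(histology=h, stage=s,
                 baseline=round(100.0 * self.value(s, h, False), 10),
                 repeat=round(100.0 * self.value(s, h, True), 10))
            for h in HISTOLOGIES for s in STAGES
            if self.mode == "parametric" or (s, h) in self.table
        ]
        return pd.DataFrame(rows)


def sensitivity(params: SensitivityParams, stage: str, histology: str,
                is_repeat: bool) -> float:
    """CT detection probability for a preclinical cancer at a screen."""
    return params.value(stage, histology, is_repeat)


class CureProbs:
    """Stage-specific probability that screen detection prevents the LC death."""

    def __init__(self, by_stage: dict[str, float]):
        for s, d in by_stage.items():
            if not (0.0 <= d <= 1.0):
                raise ValidationError(f"cure probability outside [0, 1] for {s}")
        self.by_stage = dict(by_stage)

    def __getitem__(self, stage: str) -> float:
        try:
            return self.by_stage[stage]
        except KeyError:
            raise ConfigurationError(f"no cure probability for stage {stage}") from None

    @classmethod
    def nelson_fitted(cls) -> "CureProbs":
        return cls(nelson.cure_probabilities())

    @classmethod
    def constant(cls, d: float) -> "CureProbs":
        return cls({s: d for s in STAGES})

    def as_array(self) -> np.ndarray:
        return np.array([self[s] for s in STAGES])


# ---------------------------------------------------------------------------
# Per-person reference operations
# ---------------------------------------------------------------------------

def screen_person(
    lh: LifeHistory,
    round_index: int,
    protocol: ScreeningProtocol,
    sens: SensitivityParams,
    seed: "int | np.random.Generator",
    attended: bool | None = None,
    is_repeat: bool | None = None,
) -> Optional[str]:
    """One CT screen for one person; returns the detected stage or None.

    Detection requires attendance, being alive and not yet clinically
    diagnosed at the screen time, a preclinical cancer present (onset at or
    before the screen, diagnosis after), and a Bernoulli success at the
    stage/histology sensitivity.  ``is_repeat`` defaults to round_index > 0;
    the trial engine instead passes repeat status relative to the person's
    first attended screen.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_age = lh.person.age_at_randomization + protocol.round_times[round_index]
    if attended is None:
        p_att = protocol.attendance.round_rates[round_index]
        attended = bool(rng.random() < p_att)
    if not attended:
        return None
    if t_age >= lh.death_age:
        return None
    if lh.schedule is None:
        return None
    stage = lh.schedule.stage_at(t_age)
    if stage is None:
        return None
    if is_repeat is None:
        is_repeat = round_index > 0
    p = sens.value(stage, lh.histology, is_repeat)
    return stage if rng.random() < p else None


def apply_mortality_prevention(
    lh: LifeHistory,
    detected_stage: str,
    cure: CureProbs,
    seed: "int | np.random.Generator",
) -> LifeHistory:
    """Cure draw after a screen detection (mutates and returns ``lh``).

    If no lung-cancer death was scheduled in the no-screening counterfactual,
    nothing changes (the detection is pure lead time or overdiagnosis).
    Otherwise, with the stage-specific prevention probability the scheduled
    lung-cancer death is cancelled and the person dies of other causes; on
    failure the life history continues exactly as if no screening occurred.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lh.lc_death_age is None:
        return lh
    if rng.random() < cure[detected_stage]:
        lh.lc_death_age = None
        lh.prevented = True
    return lh


# ---------------------------------------------------------------------------
# Array engine
# ---------------------------------------------------------------------------

@dataclass
class NaturalHistories:
    """Frozen per-person natural histories plus every random draw downstream.

    The stochastic course (stage entry ages, clinical diagnosis, survival) is
    a deterministic function of the frozen uniforms and the parameter bundle,
    so it can be recomputed under new sojourn/survival parameters without
    touching the underlying randomness (common random numbers).
    """

    age0: np.ndarray
    sex: np.ndarray        # 0 = male, 1 = female
    screen_arm: np.ndarray  # bool
    oc_age: np.ndarray
    onset: np.ndarray      # nan if never
    hist: np.ndarray       # histology index, -1 if no onset
    u_soj: np.ndarray      # (n, 6) uniforms for sojourn draws
    u_det: np.ndarray      # (n, 6) uniforms for clinical-detection Bernoullis
    u_cure_frac: np.ndarray  # (n,) uniform for the survival cure mixture
    e_surv: np.ndarray     # (n,) Exp(1) for the survival delay
    u_screen: np.ndarray   # (n, 4) uniforms for screen-detection Bernoullis
    u_cure_screen: np.ndarray  # (n,) uniform for mortality prevention
    attendance: np.ndarray  # (n, 4) bool
    # derived by compute_courses:
    entry: np.ndarray = None    # (n, 6) stage entry ages, nan past diagnosis
    dx_age: np.ndarray = None   # clinical diagnosis age (counterfactual), inf if no onset
    dx_stage: np.ndarray = None  # stage index at clinical diagnosis, -1 if none
    lc_death: np.ndarray = None  # scheduled LC death age, nan if cured/none

    @property
    def n(self) -> int:
        return len(self.age0)

    def compute_courses(self, params: ModelParams) -> None:
        """(Re)derive stage schedule, diagnosis and survival from frozen draws."""
        n = self.n
        n_stage = len(STAGES)
        scale = np.ones((n_stage, len(HISTOLOGIES), 2))
        shape = np.ones_like(scale)
        for i, s in enumerate(STAGES):
            for j, h in enumerate(HISTOLOGIES):
                for k, sex in enumerate(("male", "female")):
                    sc, sh = params.sojourn.scale_shape(s, h, sex)
                    scale[i, j, k] = sc
                    shape[i, j, k] = sh
        det = np.array([params.clinical_detection[s] for s in STAGES])
        cure = np.ones((n_stage, len(HISTOLOGIES)))
        rate = np.ones_like(cure)
        for i, s in enumerate(STAGES):
            for j, h in enumerate(HISTOLOGIES):
                c, r = params.survival.get(s, h)
                cure[i, j] = c
                rate[i, j] = r

        entry = np.full((n, n_stage), np.nan)
        dx_age = np.full(n, np.inf)
        dx_stage = np.full(n, -1, dtype=int)
        has = ~np.isnan(self.onset)
        t = np.where(has, self.onset, np.nan)
        active = has.copy()
        hist = np.where(has, self.hist, 0)
        sexi = self.sex
        for i in range(n_stage):
            entry[active, i] = t[active]
            # inverse-CDF Weibull draw from the frozen uniform
            w = scale[i, hist, sexi] * (-np.log1p(-self.u_soj[:, i])) ** (1.0 / shape[i, hist, sexi])
            t = t + w
            diag = active & ((self.u_det[:, i] < det[i]) | (i == n_stage - 1))
            dx_age[diag] = t[diag]
            dx_stage[diag] = i
            active &= ~diag
        cured = self.u_cure_frac < cure[np.maximum(dx_stage, 0), hist]
        lc = np.where(
            has & ~cured & (dx_stage >= 0),
            dx_age + self.e_surv / rate[np.maximum(dx_stage, 0), hist],
            np.nan,
        )
        self.entry = entry
        self.dx_age = dx_age
        self.dx_stage = dx_stage
        self.lc_death = lc


def simulate_natural_histories(
    cohort: Cohort,
    params: ModelParams,
    seed: int,
    condition_on_entry: bool = True,
    max_redraws: int = 200,
) -> NaturalHistories:
    """Simulate frozen natural histories for a whole cohort.

    With ``condition_on_entry`` the cohort is conditioned on trial enrolment:
    persons whose counterfactual clinical diagnosis falls before randomization
    have their cancer history redrawn (trial participants had no prior lung
    cancer diagnosis).  Other-cause death is sampled conditional on being
    alive at entry by construction.
    """
    rng = np.random.default_rng(seed)
    persons = cohort.persons
    n = len(persons)
    age0 = np.array([p.age_at_randomization for p in persons])
    sex = np.array([1 if p.sex == "female" else 0 for p in persons])
    screen_arm = np.array([p.arm == "screen" for p in persons])
    mult = np.array([smoking_multiplier(p.smoking, params.oc_gamma) for p in persons])
    sex_str = np.array(["female" if s else "male" for s in sex])
    oc_age = sample_other_cause_death_ages(age0, mult, params.life_table, sex_str, rng)

    # onset: inverse-CDF on the exact TSCE cumulative hazard
    from scipy.optimize import brentq

    def draw_onsets(idx: np.ndarray) -> np.ndarray:
        targets = rng.exponential(size=len(idx))
        out = np.full(len(idx), np.nan)
        for j, i in enumerate(idx):
            p = persons[i]
            par = params.tsce[p.sex]
            H_max = tsce_cumulative_hazard(par, p.smoking, 110.0)
            if targets[j] >= H_max:
                continue
            a = brentq(
                lambda x: tsce_cumulative_hazard(par, p.smoking, x) - targets[j],
                0.0, 110.0, xtol=1e-6,
            )
            onset = a + par.lag
            out[j] = onset if onset < 110.0 else np.nan
        return out

    all_idx = np.arange(n)
    onset = draw_onsets(all_idx)
    hist = np.full(n, -1, dtype=int)
    probs = {k: params.histology.probs(k) for k in ("male", "female")}
    has = ~np.isnan(onset)
    for sx, code in (("male", 0), ("female", 1)):
        sel = has & (sex == code)
        hist[sel] = rng.choice(len(HISTOLOGIES), size=int(sel.sum()), p=probs[sx])

    nh = NaturalHistories(
        age0=age0, sex=sex, screen_arm=screen_arm, oc_age=oc_age,
        onset=onset, hist=hist,
        u_soj=rng.random((n, len(STAGES))),
        u_det=rng.random((n, len(STAGES))),
        u_cure_frac=rng.random(n),
        e_surv=rng.exponential(size=n),
        u_screen=rng.random((n, 4)),
        u_cure_screen=rng.random(n),
        # default attendance at the published round rates; run_trial overrides
        # with the protocol's attendance model
        attendance=rng.random((n, 4)) < np.asarray(AttendanceModel().round_rates),
    )
    nh.compute_courses(params)

    if condition_on_entry:
        for _ in range(max_redraws):
            bad = np.flatnonzero(nh.dx_age < age0)
            if len(bad) == 0:
                break
            nh.onset[bad] = draw_onsets(bad)
            still = ~np.isnan(nh.onset[bad])
            for sx, code in (("male", 0), ("female", 1)):
                sel = bad[still & (sex[bad] == code)]
                nh.hist[sel] = rng.choice(len(HISTOLOGIES), size=len(sel), p=probs[sx])
            nh.hist[bad[~still]] = -1
            nh.u_soj[bad] = rng.random((len(bad), len(STAGES)))
            nh.u_det[bad] = rng.random((len(bad), len(STAGES)))
            nh.u_cure_frac[bad] = rng.random(len(bad))
            nh.e_surv[bad] = rng.exponential(size=len(bad))
            nh.compute_courses(params)
    return nh


@dataclass
class TrialResult:
    """Aggregate trial counts for both arms.

    Counts are raw simulated counts at the cohort's replication factor;
    divide by ``replication`` for trial-scale expectations.
    """

    round_times: tuple[float, ...]
    followup_end: float
    replication: int
    screen_detected: np.ndarray      # (rounds, stages, histologies)
    detectable: np.ndarray           # (rounds, stages, histologies)
    n_attended: np.ndarray           # (rounds,)
    interval_cancers: np.ndarray     # (rounds, stages): window after round r
    control_incidence: np.ndarray    # (years,)
    screened_arm_clinical: np.ndarray  # (years,)
    py_after_detection: np.ndarray   # (stages,)
    lc_deaths_after_detection: np.ndarray  # (stages,)
    lc_deaths_by_arm: np.ndarray     # (2,): [screen, control] within follow-up
    n_by_arm: np.ndarray             # (2,)
    overdiagnosed: int               # screen-detected, counterfactual dx after OC death

    @property
    def negatives(self) -> np.ndarray:
        return self.n_attended - self.screen_detected.sum(axis=(1, 2))

    def validate(self) -> None:
        if np.any(self.negatives < 0) or np.any(self.screen_detected < 0):
            raise ValidationError("negative counts in trial result")
        if np.any(self.py_after_detection < 0):
            raise ValidationError("negative person-years")

    def yield_frame(self) -> pd.DataFrame:
        """Tidy screen-detected counts (round, stage, histology, count)."""
        rows = []
        for r in range(len(self.round_times)):
            for i, s in enumerate(STAGES):
                for j, h in enumerate(HISTOLOGIES):
                    rows.append(dict(round=r + 1, stage=s, histology=h,
                                     count=int(self.screen_detected[r, i, j])))
        return pd.DataFrame(rows)

    def incidence_frame(self) -> pd.DataFrame:
        """Clinical incidence by year since randomization, per arm."""
        rows = []
        for year in range(len(self.control_incidence)):
            rows.append(dict(year=year, arm="control",
                             count=int(self.control_incidence[year])))
            rows.append(dict(year=year, arm="screen",
                             count=int(self.screened_arm_clinical[year])))
        return pd.DataFrame(rows)

    def mortality_frame(self) -> pd.DataFrame:
        """Lung-cancer deaths and person-years after screen detection, by stage."""
        return pd.DataFrame(dict(
            stage=list(STAGES),
            lc_deaths=self.lc_deaths_after_detection.astype(int),
            person_years=self.py_after_detection,
        ))


def replay_screening(
    nh: NaturalHistories,
    protocol: ScreeningProtocol,
    sens: SensitivityParams,
    cure: CureProbs,
    replication: int = 1,
    return_detail: bool = False,
):
    """Apply the screening protocol to frozen natural histories.

    Deterministic given ``nh``: every Bernoulli uses the frozen uniforms, so
    re-running with different sensitivity/cure parameters reuses the exact
    same underlying randomness.
    """
    n = nh.n
    n_rounds = len(protocol.round_times)
    base, rep = sens.as_arrays()
    cure_arr = cure.as_array()
    followup = protocol.followup_end

    detected = np.zeros(n, dtype=bool)
    det_round = np.full(n, -1)
    det_stage = np.full(n, -1)
    det_age = np.full(n, np.nan)
    attended_before = np.zeros(n, dtype=bool)

    screen_detected = np.zeros((n_rounds, len(STAGES), len(HISTOLOGIES)), dtype=int)
    detectable = np.zeros_like(screen_detected)
    n_attended = np.zeros(n_rounds, dtype=int)

    hist = np.maximum(nh.hist, 0)
    for r, t in enumerate(protocol.round_times):
        t_age = nh.age0 + t
        in_pool = (nh.screen_arm & nh.attendance[:, r] & ~detected
                   & (t_age < nh.oc_age) & (t_age < nh.dx_age))
        n_attended[r] = int(in_pool.sum())
        prec = in_pool & ~np.isnan(nh.onset) & (nh.onset <= t_age)
        stage_at = np.where(
            prec,
            np.sum(np.nan_to_num(nh.entry, nan=np.inf) <= t_age[:, None], axis=1) - 1,
            -1,
        )
        prec &= stage_at >= 0
        is_rep = attended_before
        p = np.where(is_rep, rep[stage_at, hist], base[stage_at, hist])
        hit = prec & (nh.u_screen[:, r] < p)
        np.add.at(detectable, (r, stage_at[prec], hist[prec]), 1)
        np.add.at(screen_detected, (r, stage_at[hit], hist[hit]), 1)
        detected |= hit
        det_round[hit] = r
        det_stage[hit] = stage_at[hit]
        det_age[hit] = t_age[hit]
        attended_before |= in_pool

    # mortality prevention among screen-detected with a scheduled LC death
    has_lc_death = ~np.isnan(nh.lc_death)
    prevented = detected & has_lc_death & (nh.u_cure_screen < cure_arr[np.maximum(det_stage, 0)])
    lc_final = np.where(prevented, np.nan, nh.lc_death)

    death = np.fmin(nh.oc_age, np.where(np.isnan(lc_final), np.inf, lc_final))
    tau_dx = nh.dx_age - nh.age0  # counterfactual clinical diagnosis time

    # observed clinical diagnoses: not screen-detected, before death, in follow-up
    observed_dx = (~detected) & (nh.dx_age < nh.oc_age) & (tau_dx >= 0) & (tau_dx < followup)
    years = np.arange(int(math.ceil(followup)))
    control_incidence = np.bincount(
        np.floor(tau_dx[observed_dx & ~nh.screen_arm]).astype(int),
        minlength=len(years))[:len(years)]
    screened_arm_clinical = np.bincount(
        np.floor(tau_dx[observed_dx & nh.screen_arm]).astype(int),
        minlength=len(years))[:len(years)]

    # interval cancers: screen-arm observed clinical diagnoses after >= 1
    # attended round, classified by the last round time before diagnosis
    interval = np.zeros((n_rounds, len(STAGES)), dtype=int)
    si = observed_dx & nh.screen_arm & attended_before
    window = np.searchsorted(np.asarray(protocol.round_times), tau_dx[si], side="right") - 1
    window = np.clip(window, 0, n_rounds - 1)
    np.add.at(interval, (window, nh.dx_stage[si]), 1)

    # follow-up after screen detection
    py = np.zeros(len(STAGES))
    lc_deaths_det = np.zeros(len(STAGES), dtype=int)
    sel = np.flatnonzero(detected)
    end = np.minimum(death[sel], nh.age0[sel] + followup)
    np.add.at(py, det_stage[sel], np.maximum(end - det_age[sel], 0.0))
    died_lc = (~np.isnan(lc_final[sel])
               & (lc_final[sel] < nh.oc_age[sel])
               & (lc_final[sel] - nh.age0[sel] <= followup))
    np.add.at(lc_deaths_det, det_stage[sel[died_lc]], 1)

    # arm-level LC mortality within follow-up
    lc_death_obs = (~np.isnan(lc_final) & (lc_final < nh.oc_age)
                    & (lc_final - nh.age0 <= followup))
    lc_deaths_by_arm = np.array([
        int(np.sum(lc_death_obs & nh.screen_arm)),
        int(np.sum(lc_death_obs & ~nh.screen_arm)),
    ])
    n_by_arm = np.array([int(nh.screen_arm.sum()), int((~nh.screen_arm).sum())])

    overdiagnosed = int(np.sum(detected & (nh.dx_age >= nh.oc_age)))

    result = TrialResult(
        round_times=tuple(protocol.round_times),
        followup_end=followup,
        replication=replication,
        screen_detected=screen_detected,
        detectable=detectable,
        n_attended=n_attended,
        interval_cancers=interval,
        control_incidence=control_incidence,
        screened_arm_clinical=screened_arm_clinical,
        py_after_detection=py,
        lc_deaths_after_detection=lc_deaths_det,
        lc_deaths_by_arm=lc_deaths_by_arm,
        n_by_arm=n_by_arm,
        overdiagnosed=overdiagnosed,
    )
    result.validate()
    if return_detail:
        detail = dict(detected=detected, det_round=det_round, det_stage=det_stage,
                      det_age=det_age, prevented=prevented, lc_final=lc_final,
                      attended_before=attended_before)
        return result, detail
    return result


def run_trial(
    cohort: Cohort,
    protocol: ScreeningProtocol,
    params: ModelParams,
    sens: SensitivityParams,
    cure: CureProbs,
    seed: int,
    histories: NaturalHistories | None = None,
) -> TrialResult:
    """Simulate the full two-arm trial and aggregate outcomes.

    The control arm is never screened; the screen arm is processed round by
    round in time order (a person screen-detected at round r is not screened
    again).  Pass precomputed ``histories`` to reuse natural histories across
    parameter settings (common random numbers).
    """
    if histories is None:
        histories = simulate_natural_histories(cohort, params, seed)
        histories.attendance = sample_attendance_for(histories, cohort, protocol, seed)
    return replay_screening(histories, protocol, sens, cure,
                            replication=cohort.replication_factor)


def sample_attendance_for(
    nh: NaturalHistories,
    cohort: Cohort,
    protocol: ScreeningProtocol,
    seed: int,
) -> np.ndarray:
    """Attendance flags under the protocol's attendance model (seed-shifted)."""
    from .population import sample_attendance
    return sample_attendance(cohort, protocol.attendance, seed + 104729)


def all_screen_average_sensitivity(result: TrialResult) -> pd.DataFrame:
    """All-round average sensitivity: detected / detectable, per stage x histology.

    The detectable pool counts each person-round at which an undetected
    preclinical cancer was present at an attended screen (a cancer present at
    several rounds contributes to each).  Cells with an empty pool are NaN.
    """
    det = result.screen_detected.sum(axis=0).astype(float)
    pool = result.detectable.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(pool > 0, det / pool * 100.0, np.nan)
    rows = []
    for j, h in enumerate(HISTOLOGIES):
        for i, s in enumerate(STAGES):
            rows.append(dict(histology=h, stage=s,
                             all_screen_average=avg[i, j],
                             detected=int(det[i, j]), detectable=int(pool[i, j])))
    return pd.DataFrame(rows)
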