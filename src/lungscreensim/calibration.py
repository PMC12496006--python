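"""Calibration of screening parameters against trial-level target counts.

The fit statistic is a composite log-likelihood over independent target
blocks:

* Poisson terms for yearly control-arm clinical incidence and for interval
  cancers per inter-round window (observed count k against the model-expected
  count lambda);
* a multinomial term per screening round distributing attended screens over
  {negative, positive by stage}, with cell probabilities taken from the
  model's expected proportions;
* Poisson terms for lung-cancer deaths after screen detection with the
  observed person-years as offset (lambda = model death rate x observed
  person-years).

Simulated counts are produced at a replication factor R and divided by R to
serve as expectations, so replication is purely a variance-reduction device.
The search is differential evolution (DE/rand/1/bin) on transformed scales
(logit for probabilities, log for positive parameters), with common random
numbers: natural histories are frozen once per calibration, and each
objective evaluation only re-applies screening, making the objective
quasi-deterministic in the parameters.

Feasible ranges are profile-likelihood intervals: a parameter is walked up
and down from its point estimate, others held fixed, until twice the
log-likelihood drop crosses the chi-squared(1) 97.5th percentile (5.024);
the crossing is linearly interpolated between grid points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit, gammaln, logit
from scipy.stats import chi2

from .errors import ConfigurationError, ValidationError
from .natural_history import HISTOLOGIES, STAGES, ModelParams
from .screening import (
    CureProbs,
    NaturalHistories,
    ScreeningProtocol,
    SensitivityParams,
    TrialResult,
    replay_screening,
    sample_attendance_for,
    simulate_natural_histories,
)

__all__ = [
    "CalibrationTargets",
    "FittedParams",
    "FeasibleRange",
    "DESettings",
    "composite_loglik",
    "de_optimize",
    "calibrate",
    "profile_parameter",
    "CHI2_THRESHOLD",
]

#: threshold on 2*(max loglik - loglik), the chi-squared(1) 97.5th percentile
CHI2_THRESHOLD = float(chi2.ppf(0.975, df=1))  # 5.0239

_LOGLIK_FLOOR = -1.0e12  # sentinel for expected 0 with observed > 0


@dataclass
class CalibrationTargets:
    """Observed trial-scale counts the model is fitted against.

    Any block left as None is excluded from the likelihood.
    """

    control_incidence: Optional[np.ndarray] = None   # (years,) counts
    interval_cancers: Optional[np.ndarray] = None    # (rounds,) counts
    screen_stage_counts: Optional[np.ndarray] = None  # (rounds, stages) counts
    n_attended: Optional[np.ndarray] = None           # (rounds,)
    lc_deaths_after_detection: Optional[np.ndarray] = None  # (stages,)
    py_after_detection: Optional[np.ndarray] = None         # (stages,)

    def __post_init__(self) -> None:
        for name in ("control_incidence", "interval_cancers", "screen_stage_counts",
                     "n_attended", "lc_deaths_after_detection", "py_after_detection"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(v < 0):
                    raise ValidationError(f"negative counts in {name}")
                setattr(self, name, v)
        if self.lc_deaths_after_detection is not None:
            if self.py_after_detection is None:
                raise ValidationError("deaths without person-years")
            if np.any((self.lc_deaths_after_detection > 0)
                      & (self.py_after_detection <= 0)):
                raise ValidationError("deaths observed with zero person-years")

    @classmethod
    def from_trial_result(cls, result: TrialResult) -> "CalibrationTargets":
        """Trial-scale targets from a simulated result (counts / replication)."""
        r = result.replication
        return cls(
            control_incidence=np.round(result.control_incidence / r),
            interval_cancers=np.round(result.interval_cancers.sum(axis=1) / r),
            screen_stage_counts=np.round(result.screen_detected.sum(axis=2) / r),
            n_attended=np.round(result.n_attended / r),
            lc_deaths_after_detection=np.round(result.lc_deaths_after_detection / r),
            py_after_detection=result.py_after_detection / r,
        )


def _poisson_ll(k: np.ndarray, lam: np.ndarray) -> float:
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any((lam <= 0) & (k > 0)):
        return _LOGLIK_FLOOR
    ok = lam > 0
    ll = float(np.sum(k[ok] * np.log(lam[ok]) - lam[ok] - gammaln(k[ok] + 1.0)))
    return ll


def composite_loglik(sim: TrialResult, obs: CalibrationTargets) -> float:
    """Composite log-likelihood of observed targets under simulated expectations.

    ``sim`` counts are divided by their replication factor to obtain
    trial-scale expectations.  Higher is better; the sentinel -1e12 is
    returned whenever a block has expected 0 against observed > 0.
    """
    r = sim.replication
    total = 0.0
    if obs.control_incidence is not None:
        lam = sim.control_incidence[:len(obs.control_incidence)] / r
        ll = _poisson_ll(obs.control_incidence, lam)
        if ll <= _LOGLIK_FLOOR:
            return _LOGLIK_FLOOR
        total += ll
    if obs.interval_cancers is not None:
        lam = sim.interval_cancers.sum(axis=1) / r
        ll = _poisson_ll(obs.interval_cancers, lam)
        if ll <= _LOGLIK_FLOOR:
            return _LOGLIK_FLOOR
        total += ll
    if obs.screen_stage_counts is not None:
        sim_pos = sim.screen_detected.sum(axis=2).astype(float)  # (rounds, stages)
        sim_att = sim.n_attended.astype(float)
        obs_pos = obs.screen_stage_counts
        obs_att = (obs.n_attended if obs.n_attended is not None
                   else np.ceil(obs_pos.sum(axis=1)))
        for rd in range(obs_pos.shape[0]):
            if sim_att[rd] <= 0:
                if obs_pos[rd].sum() > 0:
                    return _LOGLIK_FLOOR
                continue
            p_pos = sim_pos[rd] / sim_att[rd]
            p_neg = max(1.0 - p_pos.sum(), 0.0)
            k_pos = obs_pos[rd]
            k_neg = obs_att[rd] - k_pos.sum()
            if k_neg < 0:
                raise ValidationError("positives exceed attended screens")
            probs = np.concatenate([[p_neg], p_pos])
            ks = np.concatenate([[k_neg], k_pos])
            if np.any((probs <= 0) & (ks > 0)):
                return _LOGLIK_FLOOR
            ok = probs > 0
            total += float(
                gammaln(ks.sum() + 1.0) - np.sum(gammaln(ks + 1.0))
                + np.sum(ks[ok] * np.log(probs[ok]))
            )
    if obs.lc_deaths_after_detection is not None:
        sim_py = sim.py_after_detection / r
        sim_deaths = sim.lc_deaths_after_detection / r
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(sim_py > 0, sim_deaths / np.maximum(sim_py, 1e-300), 0.0)
        lam = rate * obs.py_after_detection
        ll = _poisson_ll(obs.lc_deaths_after_detection, lam)
        if ll <= _LOGLIK_FLOOR:
            return _LOGLIK_FLOOR
        total += ll
    return total


# ---------------------------------------------------------------------------
# Differential evolution
# ---------------------------------------------------------------------------

@dataclass
class DESettings:
    """DE/rand/1/bin controls (canonical Storn-Price defaults)."""

    np_: Optional[int] = None   # population size; default 10 x dimension
    F: float = 0.5              # differential weight
    CR: float = 0.9             # crossover rate
    generations: int = 300
    stagnation: int = 50        # early stop after this many non-improving generations
    polish: bool = True         # Nelder-Mead refinement of the DE best (calibrate only)


@dataclass
class DEResult:
    x: np.ndarray
    fun: float
    trace: list[float]          # best objective after each generation
    n_eval: int


def de_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    settings: DESettings | None = None,
    seed: int = 0,
) -> DEResult:
    """Minimize ``objective`` over a box with DE/rand/1/bin.

    Deterministic for a fixed seed; the per-generation best-value trace is
    monotone non-increasing; candidate vectors are clipped to the bounds.
    """
    settings = settings or DESettings()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ConfigurationError("bounds must be a sequence of (lower, upper)")
    if np.any(bounds[:, 0] > bounds[:, 1]):
        raise ConfigurationError("lower bound exceeds upper bound")
    dim = len(bounds)
    NP = settings.np_ if settings.np_ is not None else 10 * dim
    if NP < 4:
        raise ConfigurationError("DE needs a population of at least 4")
    rng = np.random.default_rng(seed)
    lo, hi = bounds[:, 0], bounds[:, 1]
    pop = lo + rng.random((NP, dim)) * (hi - lo)
    fit = np.array([objective(x) for x in pop])
    n_eval = NP
    trace: list[float] = []
    best = float(fit.min())
    stagnant = 0
    for _ in range(settings.generations):
        for i in range(NP):
            candidates = [j for j in (rng.permutation(NP)[:4]) if j != i][:3]
            a, b, c = pop[candidates[0]], pop[candidates[1]], pop[candidates[2]]
            mutant = np.clip(a + settings.F * (b - c), lo, hi)
            cross = rng.random(dim) < settings.CR
            cross[rng.integers(dim)] = True
            trial = np.where(cross, mutant, pop[i])
            f = objective(trial)
            n_eval += 1
            if f <= fit[i]:
                pop[i] = trial
                fit[i] = f
        new_best = float(fit.min())
        if new_best < best - 1e-12:
            best = new_best
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best)
        if stagnant >= settings.stagnation:
            break
    i_best = int(np.argmin(fit))
    return DEResult(x=pop[i_best].copy(), fun=float(fit[i_best]),
                    trace=trace, n_eval=n_eval)


# ---------------------------------------------------------------------------
# Free parameters and the calibration wrapper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreeParameter:
    """One calibratable parameter, searched on a transformed scale.

    ``name`` encodes the target:
      "sens:<stage>:<histology>:baseline" | "sens:<stage>:<histology>:repeat"
      "beta:<histology>"          (parametric repeat-screen boost, log scale)
      "cure:<stage>"
      "sojourn_mean:<stage>:<histology>:<sex>"
      "sojourn_shape:<stage>:<histology>:<sex>"
    Probabilities are searched on the logit scale, positive quantities on the
    log scale; ``bounds`` are on the natural scale.
    """

    name: str
    bounds: tuple[float, float]

    @property
    def kind(self) -> str:
        return self.name.split(":")[0]

    @property
    def transform(self) -> str:
        return "logit" if self.kind in ("sens", "cure") else "log"

    def to_internal(self, x: float) -> float:
        return float(logit(x)) if self.transform == "logit" else math.log(x)

    def to_natural(self, z: float) -> float:
        return float(expit(z)) if self.transform == "logit" else math.exp(z)

    def internal_bounds(self) -> tuple[float, float]:
        lo, hi = self.bounds
        if lo > hi:
            raise ConfigurationError(f"infeasible bounds for {self.name}")
        return self.to_internal(lo), self.to_internal(hi)


def _apply_free_params(
    values: Sequence[float],
    free: Sequence[FreeParameter],
    sens: SensitivityParams,
    cure: CureProbs,
    params: ModelParams,
) -> tuple[SensitivityParams, CureProbs, ModelParams, bool]:
    """Return copies of (sens, cure, params) with free-parameter values applied.

    The final flag says whether natural-history parameters changed (requiring
    a course recomputation).
    """
    sens_table = dict(sens.table) if sens.mode == "table" else None
    sens_base = dict(sens.base) if sens.mode == "parametric" else None
    sens_beta = dict(sens.beta) if sens.mode == "parametric" else None
    cure_d = dict(cure.by_stage)
    soj_table = dict(params.sojourn._table)
    nh_changed = False
    for fp, v in zip(free, values):
        parts = fp.name.split(":")
        if fp.kind == "sens":
            _, stage, hist, which = parts
            if sens_table is not None:
                b, r = sens_table[(stage, hist)]
                sens_table[(stage, hist)] = (v, r) if which == "baseline" else (b, v)
            else:
                if which != "baseline":
                    raise ConfigurationError(
                        "parametric mode frees baseline and beta, not repeat")
                sens_base[(stage, hist)] = v
        elif fp.kind == "beta":
            sens_beta[parts[1]] = v
        elif fp.kind == "cure":
            cure_d[parts[1]] = v
        elif fp.kind in ("sojourn_mean", "sojourn_shape"):
            _, stage, hist, sex = parts
            mean, shape = soj_table[(stage, hist, sex)]
            soj_table[(stage, hist, sex)] = ((v, shape) if fp.kind == "sojourn_mean"
                                             else (mean, v))
            nh_changed = True
        else:
            raise ConfigurationError(f"unknown free parameter {fp.name!r}")
    new_sens = (SensitivityParams("table", table=sens_table) if sens_table is not None
                else SensitivityParams("parametric", base=sens_base, beta=sens_beta))
    new_cure = CureProbs(cure_d)
    new_params = params
    if nh_changed:
        from .natural_history import SojournParams
        new_params = ModelParams(
            tsce=params.tsce, histology=params.histology,
            sojourn=SojournParams(soj_table),
            clinical_detection=params.clinical_detection,
            survival=params.survival, life_table=params.life_table,
            oc_gamma=params.oc_gamma,
        )
    return new_sens, new_cure, new_params, nh_changed


@dataclass
class FittedParams:
    names: list[str]
    values: np.ndarray            # natural scale
    internal: np.ndarray          # transformed scale
    loglik: float
    free: list[FreeParameter]
    trace: list[float] = field(default_factory=list)
    n_eval: int = 0


def make_objective(
    histories: NaturalHistories,
    protocol: ScreeningProtocol,
    params: ModelParams,
    sens: SensitivityParams,
    cure: CureProbs,
    free: Sequence[FreeParameter],
    targets: CalibrationTargets,
    replication: int,
) -> Callable[[np.ndarray], float]:
    """Negative composite log-likelihood as a function of the internal vector."""

    def objective(z: np.ndarray) -> float:
        natural = [fp.to_natural(zi) for fp, zi in zip(free, z)]
        s, c, p, nh_changed = _apply_free_params(natural, free, sens, cure, params)
        if nh_changed:
            histories.compute_courses(p)
        sim = replay_screening(histories, protocol, s, c, replication=replication)
        return -composite_loglik(sim, targets)

    return objective


def calibrate(
    cohort,
    protocol: ScreeningProtocol,
    params: ModelParams,
    sens: SensitivityParams,
    cure: CureProbs,
    free: Sequence[FreeParameter],
    targets: CalibrationTargets,
    settings: DESettings | None = None,
    seed: int = 0,
    histories: NaturalHistories | None = None,
) -> FittedParams:
    """Fit the free parameters to the targets by differential evolution.

    Natural histories are simulated once from ``seed`` and frozen across all
    objective evaluations (common random numbers); each evaluation only
    replays screening (and, when sojourn parameters are free, recomputes the
    disease course from the same frozen uniforms).
    """
    if histories is None:
        histories = simulate_natural_histories(cohort, params, seed)
        histories.attendance = sample_attendance_for(histories, cohort, protocol, seed)
    objective = make_objective(histories, protocol, params, sens, cure,
                               list(free), targets, cohort.replication_factor)
    if len(free) == 0:
        ll = -objective(np.empty(0))
        return FittedParams([], np.empty(0), np.empty(0), ll, [], [], 1)
    bounds = [fp.internal_bounds() for fp in free]
    settings = settings or DESettings()
    result = de_optimize(objective, bounds, settings, seed=seed + 1)
    if settings.polish:
        # local simplex refinement: DE localizes the basin, Nelder-Mead walks
        # down the flat quasi-deterministic objective (gradient-free because
        # counts move in discrete steps)
        from scipy.optimize import minimize
        pol = minimize(objective, result.x, method="Nelder-Mead", bounds=bounds,
                       options=dict(xatol=1e-4, fatol=1e-9,
                                    maxfev=200 * len(bounds)))
        if pol.fun <= result.fun:
            result.x = np.clip(pol.x, [b[0] for b in bounds], [b[1] for b in bounds])
            result.fun = float(pol.fun)
            result.n_eval += int(pol.nfev)
    # restore the best-fitting courses if sojourn parameters were free
    natural = np.array([fp.to_natural(z) for fp, z in zip(free, result.x)])
    _, _, p_best, nh_changed = _apply_free_params(natural, free, sens, cure, params)
    if nh_changed:
        histories.compute_courses(p_best)
    return FittedParams(
        names=[fp.name for fp in free],
        values=natural,
        internal=result.x.copy(),
        loglik=-result.fun,
        free=list(free),
        trace=result.trace,
        n_eval=result.n_eval,
    )


@dataclass
class FeasibleRange:
    """Profile-likelihood feasible range for one parameter (natural scale)."""

    name: str
    lower: float
    point: float
    upper: float
    threshold: float = CHI2_THRESHOLD
    lower_open: bool = False   # no crossing found before the bound
    upper_open: bool = False


def profile_parameter(
    objective: Callable[[np.ndarray], float],
    fitted: FittedParams,
    name: str,
    step: float = 0.05,
    max_steps: int = 200,
    threshold: float = CHI2_THRESHOLD,
) -> FeasibleRange:
    """Walk one parameter away from the optimum until the likelihood rejects it.

    ``objective`` is the minimized negative log-likelihood over the internal
    vector.  Other parameters stay at their fitted values; the walk is on the
    transformed scale in increments of ``step``, and the crossing of
    2*(loglik_hat - loglik) = threshold is linearly interpolated.  If no
    crossing occurs before the parameter's bound, the corresponding side is
    flagged open and reported at the bound.
    """
    idx = fitted.names.index(name)
    fp = fitted.free[idx]
    z_hat = fitted.internal.copy()
    f_hat = objective(z_hat)
    lo_b, hi_b = fp.internal_bounds()

    def walk(direction: int) -> tuple[float, bool]:
        z_prev = z_hat[idx]
        d_prev = 0.0
        for k in range(1, max_steps + 1):
            z_new = z_hat[idx] + direction * k * step
            clipped = min(max(z_new, lo_b), hi_b)
            z = z_hat.copy()
            z[idx] = clipped
            d = 2.0 * (objective(z) - f_hat)
            if d >= threshold:
                frac = ((threshold - d_prev) / (d - d_prev)) if d > d_prev else 1.0
                return z_prev + frac * (clipped - z_prev), False
            z_prev, d_prev = clipped, d
            if clipped != z_new:  # hit the bound without crossing
                return clipped, True
        return z_prev, True

    up, up_open = walk(+1)
    down, down_open = walk(-1)
    lower_z, upper_z = min(down, up), max(down, up)
    return FeasibleRange(
        name=name,
        lower=fp.to_natural(lower_z),
        point=fitted.values[idx],
        upper=fp.to_natural(upper_z),
        threshold=threshold,
        lower_open=down_open,
        upper_open=up_open,
    )
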