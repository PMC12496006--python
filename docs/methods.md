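# Methods

## Scope

The package reproduces the analysis pipeline used to estimate stage- and
histology-specific CT screening sensitivity, stage IA sojourn times, and
mortality-prevention probabilities from a four-round CT screening trial:
a person-level natural-history microsimulation, a trial screening engine,
a composite-likelihood calibration layer, and reporting surfaces. Because
the individual-level trial data are restricted, every input the real
analysis takes from data is emulated by a synthetic generator whose
parameters are explicit configuration.

## Onset: two-stage clonal expansion

Normal cells are initiated at rate ν (per year, cell-number absorbed into
ν), initiated cells divide at α, die at β and convert to a malignant cell at
μ; net clonal proliferation is g = α − β − μ. Smoking acts on initiation and
promotion through x = x₀(1 + c·cpdᵖ) with separate (c, p) for ν and g.

For a clone initiated at time s, the probability it produces no malignant
cell before the target age solves the Riccati equation
v′ = β + αv² − (α+β+μ)v backwards in time. With piecewise-constant
parameters (one regime per smoking segment) the flow is a Möbius transform
per regime: with q₁ < 1 < q₂ the roots of αz² − (α+β+μ)z + β = 0 and
w = (v−q₁)/(v−q₂), w decays as exp(−α(q₂−q₁)τ). The person-level cumulative
hazard H(a) = ∫₀ᵃ ν(s)(1 − v(s,a)) ds likewise integrates in closed form per
regime (a linear term plus a logarithm), so H is exact up to floating point.
The instantaneous hazard is a central finite difference of H (step 10⁻³ y,
error orders of magnitude below the 10⁻⁴ relative tolerance at which the
test suite cross-checks a stiff-ODE integration of the same equations).
Onset ages are inverse-CDF draws: E ~ Exp(1) solved against H by Brent's
method; no event if E exceeds H(110).

Degenerate regimes (μ = 0, coincident roots, v at a fixed point) are handled
by explicit limits rather than the generic formula.

**Defaults.** α = 3 /y (fixed); ν₀ = 0.12 (men) / 0.10 (women); g₀ = 0.085 /y;
μ₀ = 2·10⁻⁶ /y; c_ν = 0.30, p_ν = 1; c_g = 0.12, p_g = 0.5; lag 0. The real
analysis's coefficients live in unavailable supplementary material, so these
were chosen once to give a realistic world — a lifelong 20-cigarettes/day
smoker reaches an onset hazard of ~1.5/4.7/8 per 1000 person-years at ages
50/60/70 and ~24% cumulative risk to age 80, versus ~2% with no exposure —
and then frozen. They are configuration, validated structurally (ODE oracle,
dose monotonicity), not estimates.

## Preclinical progression and survival

Sojourn times are Weibull with the (mean, shape) parameterization; the scale
is mean/Γ(1 + 1/shape). The fitted stage IA adenocarcinoma values (mean
3.56 y men / 4.77 y women, shape 0.35) are used exactly; a shape this far
below 1 makes the distribution extremely right-skewed, which is how
effective stage-skipping (near-zero sojourns) arises. All other (stage,
histology, sex) cells are synthetic stand-ins — published only in
supplementary material — set to plausible values: ~1.3–1.8 y for other
IA histologies (shape 1.2, near the earlier-trial fit of 1.44), sub-year
means declining through IB–IV, and very fast SCLC.

At each stage end a Bernoulli with stage-specific probability decides
symptomatic diagnosis versus progression; stage IV always diagnoses.
Defaults (0.05, 0.10, 0.20, 0.30, 0.45, 1.0) make stage IV the most common
stage at clinical diagnosis, as in registry data.

Post-diagnosis survival is mixture-cure exponential per (stage, histology):
cure fraction 0.50 → 0.02 from IA to IV (halved for SCLC), event rates
0.35 → 1.6 /y. The source describes a "Poisson" stage- and
histology-specific survival curve without details; exponential-with-cure is
the minimal family consistent with a drawn survival time plus long-term
survivors, and is flagged as a package choice. One cancer per person;
recurrence is folded into relative survival.

## Synthetic cohort

The generator emulates the trial's descriptives, not its joint covariate
distribution: ages truncated-Normal(58, 5.5) on [50, 74]; smoking start age
discretized Normal(17, 3) on [10, 30]; cigarettes/day a mixture on
{10, 15, 20, 25, 30} (weights 5/15/35/25/20%); 55% current smokers, former
smokers quit Uniform(0, 10) years before entry; rejection sampling enforces
the eligibility rule (>15 cpd for >25 y or >10 cpd for >30 y, quit <10 y),
with a cap that surfaces infeasible configurations. Arms alternate
deterministically by id (a design choice removing one noise source).
Attendance is independent Bernoulli per round at the published rates, with
optional age/sex logit modifiers (off by default).

Other-cause mortality is Gompertz–Makeham (m(a) = A + B·e^{θa}; A = 2·10⁻⁴,
B = 2.5·10⁻⁵ men / 1.6·10⁻⁵ women, θ = 0.092, q forced to 1 at age 110)
standing in for national life tables, scaled per person by
exp(γ·pack-years/40) with γ = ln 2 (hazard doubles at 40 pack-years).

A green test against this world establishes that the machinery is correct
and that the stated distributions are reproduced; it does not establish
agreement with the real trial population, whose joint smoking–age–sex
distribution is unavailable. Notably the synthetic world yields a ~4%
10-year control-arm cumulative incidence and ~10 stage IA adenocarcinoma
screen detections per round at trial scale — somewhat fewer than the real
trial — which widens honestly-computed feasible ranges (see Calibration).

## Trial engine

Screens occur at exact protocol times (0, 1, 3, 5.5 y from randomization);
the stage at a screen is the stage occupied at that instant (half-open entry
windows). "Repeat" sensitivity applies from a person's second *attended*
screen (the volume-doubling-time information motivating the boost requires a
prior scan). Screen-detected persons leave the screening pool but contribute
person-years and mortality follow-up to 10 y. The detectable pool for the
all-screen average counts each person-round with an undetected preclinical
cancer at an attended screen. Cancers are conserved: each screen-arm cancer
is exactly one of screen-detected, clinical within follow-up, clinical after
follow-up, or latent at death; overdiagnosed detections (counterfactual
diagnosis after other-cause death) are counted separately. Cohorts are
conditioned on trial enrolment: histories whose counterfactual diagnosis
precedes randomization are redrawn.

The engine freezes every random draw (sojourn, detection, screening and cure
uniforms; survival exponentials) into per-person arrays, making the course a
deterministic function of parameters and enabling exact common-random-number
replays: calibration re-screens the same histories under new parameters
without re-simulating disease.

## Calibration

The fit statistic sums independent blocks: Poisson terms for yearly
control-arm incidence and interval cancers; a multinomial term per round
over {negative, positive-by-stage} with probabilities from simulated
proportions; Poisson terms for deaths after detection with observed
person-years as offset. Blocks are equally weighted (the source does not
state weights). Simulated counts at replication factor R are divided by R —
replication is a variance-reduction device, not a likelihood change.
Expected 0 against observed > 0 returns a −10¹² sentinel.

Search is DE/rand/1/bin (defaults NP = 10·dim, F = 0.5, CR = 0.9, 300
generations, early stop after 50 stagnant) on transformed scales (logit for
probabilities, log for positive parameters), followed by a bounded
Nelder–Mead polish of the DE best — the likelihood is flat near its optimum
at trial-scale counts, and the polish (the same design as scipy's DE)
localizes the optimum that DE alone brackets. Under common random numbers
self-calibration recovers generating sensitivities to well within the
published ±6-point scale.

Profiling walks one parameter from the optimum on its transformed scale
(others fixed), interpolating the crossing of 2·(ℓ̂ − ℓ) = 5.024 (χ²₁,
97.5th percentile; df = 1 chosen since the source does not state it);
a side that reaches its bound without crossing is flagged open. In the
synthetic world the trial-scale feasible range for the stage IA
adenocarcinoma baseline sensitivity is several times wider than the
published ±6 points, a direct consequence of the smaller informative yield
noted above; the tests therefore assert the structural contract (range
contains the point estimate and the generating truth) rather than the
published width.

## Numerical choices

- Ages and times are continuous years; the trial clock starts at
  randomization; no event-clock discretization.
- Annual other-cause probabilities scale as min(q·multiplier, 1); deaths are
  uniform within their year.
- Weibull draws use inverse-CDF on frozen uniforms, so recomputing courses
  under new sojourn parameters preserves each person's rank.
- β_h = 0 short-circuits to the baseline probability exactly (no
  logit/expit round-trip).
- Table exports render percentages to one decimal and round-trip
  byte-identically.

## Limitations

- All parameters published only in supplementary material (TSCE
  coefficients, non-IA-adenocarcinoma sojourns, clinical-detection and
  survival parameters, non-IA/IB cure probabilities) are synthetic
  stand-ins; quantities that depend on them are structurally, not
  numerically, comparable to the published analysis.
- No nodule-level modelling (volume doubling time, recall policies) and no
  specificity/false-positive accounting — the repeat-screen boost absorbs
  the protocol's growth information, as in the source analysis.
- Stage imputation for unknown-stage cancers, the Belgian subcohort, and
  policy/cost-effectiveness extrapolation are out of scope.
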