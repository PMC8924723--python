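# Methods

## Model structure

`ceasim` evaluates AI-assisted versus standard-of-care diagnostic
screening with discrete-time Markov models run as patient-level (or
tooth-level) Monte Carlo microsimulations over a lifetime horizon.

A model is a labelled state space with an entry age, an entry-state
distribution, an optional maximum age, and a transition kernel
`transition_fn(state, age, params, action)` returning a probability vector
per state and age. Absorbing states (death, tooth loss, blindness) are
self-loops with probability 1, checked by `validate_model` together with
row sums (tolerance 1e-9), non-negativity and the entry distribution.

Each yearly cycle applies, in fixed order:

1. **screening** — every test application due that cycle draws a result
   (positive with probability *sens* in diseased states, *1 − spec*
   otherwise), charges the test fee, and maps (result, state) to a
   clinical action;
2. **reward accrual** — the occupied state's per-cycle cost and effect,
   plus a one-time cost for the escalation-maximal action of the cycle
   (work-up, restoration, …);
3. **transition** — one draw from the (possibly action-modified) row;
   one-time event rewards attach to the realised (from, to) pair.

The fixed order makes runs reproducible; alternative orderings are
equally defensible and the choice is documented here rather than exposed
as an option. There is no half-cycle
correction: rewards accrue for the state occupied at cycle start, which
keeps the analytic oracle formulas exact and matches common
microsimulation practice. Discounting divides cycle-*t* rewards by
(1 + r)^t with cycle 0 undiscounted; both costs and effects are discounted
by default (configurable — some source models discount effects only for
certain outcomes, and the convention is not always stated).

**Fractional schedules.** A schedule of *s* tests/year delivers
⌈s·(t+1)⌉ − ⌈s·t⌉ applications in cycle *t*: 2/year gives two per cycle,
0.5/year the deterministic pattern 1, 0, 1, 0 … aligned to entry.
"Biannual" ophthalmological screening is read as every other year
(0.5/year), in deliberate contrast with dentistry's twice-yearly recall —
both are plain configuration values.

**Background mortality** is an age-indexed annual death probability
composed with disease dynamics as competing events: disease-specific
transitions happen first, background death claims a share of the
survivors. The melanoma model thereby distinguishes melanoma death from
other-cause death.

**Absorbing states and rewards.** Absorbing states accrue nothing unless
explicitly configured otherwise. A zero-reward absorber terminates the
trajectory; an absorber with a configured per-cycle reward (blindness with
a reduced utility) keeps accruing until `max_age`, which must then be
finite. This treats post-blindness life as a utility annuity and ignores
mortality differentials after blindness — a simplification to keep the
state absorbing in the strict sense.

## Randomness and common random numbers

Every (cycle, purpose) pair derives its own generator from the master seed
(`default_rng([seed, tag, cycle, application])`), so individual *i* sees
identical uniforms in both arms per cycle and purpose regardless of how
many draws the other arm consumes. This makes arm differences reflect the
intervention rather than sampling noise: with identical tests and fees the
two arms produce bit-identical trajectories, and incremental quantities
are exactly zero. The same property lets the cohort engine vectorise over
individuals (a counter-based random field rather than per-individual
generator objects) while remaining bit-reproducible given the seed.
`simulate_individual` offers a scalar path with an explicit generator and
full per-cycle trajectory records.

## Analytic oracle

`solve_cohort_analytic` propagates the occupancy vector o_{t+1} = o_t·P_t
and accumulates discounted expected rewards, exactly up to floating point.
It accepts screening only when no decision action modifies transitions;
fees and expected action costs then fold into per-state cost rates (for
*m* applications per cycle, the escalation-maximal action's cost weight is
1 − (1 − p)^m for the higher-ranked branch). Strategy-dependent branching
that rewires transitions is rejected with an explanation — that is
precisely what the microsimulation engine is for. Known-truth generators
additionally compute fundamental-matrix closed forms,
e₀ᵀ(I − d·Q)⁻¹·r, which agree with the propagation solver to 1e-9 and give
the microsimulation a reference independent of both code paths.

## Use-case models

All three builders consume a flat parameter dictionary (so that PSA
sampling and one-way sweeps can address any parameter by name) and return
the model, rewards and both strategies. The AI arm's per-application fee
is `fee_exam + fee_ai`: the clinician's examination still happens, the AI
fee is charged on top. State lists are defaults, not a closed world — the
engine accepts any valid specification.

- **Melanoma** (entry 50, configurable to 48; QALYs; USD): Healthy →
  Undetected → Detected → Remission, with melanoma death and other death
  as separate absorbers. A positive screen triggers referral (work-up
  cost); referral of a real lesion routes to the Detected/treated branch
  with its own mortality and costs.
- **Caries** (entry 12; tooth-retention-years; EUR): Sound → Initial →
  Advanced lesions, a restoration → re-restoration → extraction repair
  chain, absorbing Tooth lost (which also represents the carrier's death).
  The effect is exactly 1 per cycle with the tooth present, 0 otherwise.
  `treatment_path` switches the response to a detected initial lesion:
  `noninvasive` management slows progression (rate multiplier
  `rr_noninvasive`) at a small per-cycle cost, `invasive` restores
  immediately — under which a false positive on a sound tooth pays the
  restoration *and* enters the repair chain, so specificity buys
  retention-years.
- **Diabetic retinopathy** (entry 40; utility-weighted QALYs; BRL): No DR
  → non-proliferative → proliferative, photocoagulation after a detected
  proliferative stage lowers the blindness hazard; blindness and death
  absorb. Screening every other year by default.

## Uncertainty analysis

**Distributions.** Probabilities and utilities default to beta, costs to
gamma, both stated as (mean, 95% CI); caries progression uses a uniform
band, mirroring the evidence structure of the source literature. Fitting
first matches the mean exactly with a one-parameter concentration search,
then solves the 2×2 system ppf(2.5%, 97.5%) = CI exactly; the stated
interval is honoured exactly and the realised mean moves only as far as
the family requires (e.g. 0.190 for a beta asked to cover mean 0.2 with
the symmetric interval (0.1, 0.3)). A stated mean outside its CI is a
named error. Sampled values are clipped to declared bounds.

**PSA** uses the two-level design: `n_psa` parameter draws (default 1000)
× `n_individuals` microsimulated individuals per draw (default 1000), both
arms per draw under common random numbers. Replicate means form the CE
draws; 95% intervals are empirical 2.5/97.5 percentiles with linear
interpolation, computed over replicate means (not pooled individuals).
The mean-inside-interval property is checked and logged rather than
assumed.

**CEAC** counts, per willingness-to-pay, the fraction of draws with
positive net benefit; exact ties count 1/2 — measure-zero for continuous
draws, deterministic for degenerate test cases.

**One-way sweeps** rerun the deterministic base case over a grid (built-in
grids: discount 0–10%, AI fee 0–32) with a fixed seed, so rows differ only
through the swept value. `find_threshold` scans for sign changes of the
dominance criterion (incremental cost by default) and refines each
crossing by bisection to 0.01 grid units; multiple crossings are all
returned with a warning.

## Synthetic parameters

The published use-case evaluations keep their transition tables in
supplementary appendices that are not redistributable, so the generator
produces stand-ins that emulate their statistical shape rather than their
values. Only printed anchors are copied: the 8-unit fee per AI
application, 3% discounting, entry ages 50/12/40, and the screening
schedules. Everything else — disease probabilities around plausible
magnitudes with ±10% seeded jitter, costs, accuracies giving the AI arm a
modest edge, Gompertz-form life tables (hazard a·e^{b·age}, reaching 1 at
age 110) per setting — is generated, deterministic given the seed, and
flagged `synthetic: true`. Consequently passing tests demonstrate the
correctness of the machinery (engine, economics, uncertainty analysis) on
data with realistic structure; they say nothing about the actual
cost-effectiveness of any real AI product, which requires the real
tariffs, prevalences and transition evidence.

## Numerical choices and problem sizes

- Probability bookkeeping tolerance 1e-9; analytic horizon convergence
  when non-absorbing mass < 1e-12 (when no maximum age is set).
- Presentation rounding is half-away-from-zero at 2 decimals; internal
  arithmetic is full precision. Published conversions mix rounding and
  truncation; the package standardises and documents instead of
  reverse-engineering per-value conventions.
- Oracle-equivalence testing uses 100 seeded known-truth scenarios of
  50,000 individuals each, geometric recovery 100,000, distribution round
  trips 100,000 samples; determinism and sweep checks use smaller cohorts
  since their assertions are exact.
- Ties in `searchsorted`-based categorical sampling are measure-zero;
  uniform draws live in [0, 1).

## Known limitations

- No half-cycle correction, continuous-time semantics, or tunnel states.
- Clinicians follow test results perfectly (no adherence/behaviour noise);
  this is a deliberate base case.
- Post-blindness and post-tooth-loss pathways are collapsed into single
  absorbing states.
- PSA samples parameters independently; correlated or multivariate
  scenario analysis is out of scope, as are EVPI/EVPPI.
- One reported curiosity of the dermatology literature (mean lifetime
  QALYs near 86 from entry at mid-life) suggests a unit convention in the
  source model that the text does not resolve; `ceasim` simply reports
  discounted utility-weighted life-years from entry.
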