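# ceasim

Cost-effectiveness microsimulation of AI-assisted diagnostic screening.

`ceasim` is a health-economics modelling package for the question: *when an
AI decision-support tool with a given sensitivity/specificity and a
per-application fee replaces or augments a clinician's diagnostic call,
does the payer end up with better outcomes, lower costs, neither, or both?*
It provides a generic discrete-time Markov microsimulation engine with an
imperfect-diagnostic screening layer, three built-in use-case models —
melanoma detection (dermatology, QALYs, USD), proximal-caries detection at
the level of a single tooth (dentistry, tooth-retention-years, EUR) and
diabetic-retinopathy screening (ophthalmology, QALYs, BRL) — and the full
incremental-economics stack on top. It is written for health-economics
researchers and HTA analysts who want a scriptable, reproducible
alternative to GUI decision-tree tools.

## The model

Individuals (or teeth) move through labelled health states at yearly
cycles. Each cycle applies, in order: the screening tests due that cycle,
reward accrual for the occupied state, then one state transition. A
diagnostic test fires positive with probability *sens(s)* in diseased
states and *1 − spec(s)* in healthy ones; a decision map sends every
(result, state) pair to a clinical action (monitor, refer, non-invasive or
invasive treatment), which may reroute the transition onto a treated
branch. Every test application charges its fee-for-service. Costs *C* and
effects *E* (QALYs or tooth-retention-years) are discounted at rate *r*
(default 3%/year), cycle 0 undiscounted. Background mortality is an
age-indexed hazard composed with disease dynamics as competing events.

Two arms — AI-assisted and standard-of-care, differing only in test
accuracy and fee — are simulated under common random numbers, and compared
through:

- **ICER** = ΔC/ΔE, always reported with a dominance flag
  (cheaper-and-better ⇒ *dominant*, costlier-and-worse ⇒ *dominated*);
- **net monetary benefit** NB(λ) = λ·ΔE − ΔC at willingness-to-pay λ;
- **CEAC**: P(NB > 0) across probabilistic-sensitivity draws, per λ;
- **PSA**: parameters resampled from beta/gamma/uniform uncertainty
  distributions fitted to a mean and 95% interval, percentile CIs over
  replicate means;
- **one-way sweeps** with bisection refinement of dominance thresholds
  (e.g. the break-even AI fee);
- **PPP conversion** (2020 OECD: €0.746 and R$2.362 per US$1) and the WHO
  3×GDP-per-capita willingness-to-pay ceiling.

An analytic cohort solver (occupancy-vector propagation) computes the same
expectations exactly for screening-free configurations and serves as the
engine's oracle. The exact transition tables of the published use-case
evaluations are not redistributable, so `ceasim` ships a synthetic
parameter generator that emulates their structure (every file carries a
`synthetic: true` flag); see `docs/methods.md`.

## Worked example

```sh
$ ceasim generate --use-case dentistry --seed 7 --out caries.yaml
wrote synthetic dentistry configuration to caries.yaml

$ ceasim simulate caries.yaml --n-individuals 1000 --seed 42
ai: mean cost 1098.16 EUR, mean effect 25.445 tooth-retention-year
standard: mean cost 685.58 EUR, mean effect 25.106 tooth-retention-year
delta cost +412.58, delta effect +0.3399, ICER = 1213.96 [ratio]
```

1000 synthetic teeth are followed from age 12 over their carrier's
lifetime under both screening arms with shared random draws. In this
synthetic parameter set the AI arm retains each tooth ~0.34 discounted
years longer but costs ~€413 more (its per-visit fee is charged twice a
year for decades), so buying one extra tooth-retention-year costs ~€1214
— cost-effective only for payers whose willingness to pay per retained
tooth-year exceeds that. A fee sweep then asks when the AI arm would
*become* cheaper:

```sh
$ ceasim threshold caries.yaml --parameter fee --grid 0,8,16,24,32 \
      --n-individuals 500 --seed 42
no dominance flip for 'fee' on the grid
```

(here the incremental cost never changes sign on the grid — with this
synthetic tariff the AI arm is costlier even at fee 0). The same machinery
is available as a library: `run_arms`, `run_psa`, `ceac`, `one_way_sweep`,
`find_threshold`.

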