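# Methods

This note documents the models, defaults, and design choices behind
`knowretain`, in the spirit of the methods documentation of packages such as
statsmodels or msprime.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Measurement model

Responses are dichotomous and modelled with the Rasch (one-parameter
logistic) model: for person p and item i,

    P(X_pi = 1 | θ_p, b_i) = exp(θ_p − b_i) / (1 + exp(θ_p − b_i)),

with proficiency θ and difficulty b on a common logit scale.  Proficiency is
multidimensional only in the weak sense that each of the 14 organ-system
domains is scored separately with its own item set; no cross-system
correlation structure is modelled at scoring time.

**Calibration** (`irt.fit_item_difficulties`) is marginal maximum likelihood
under a fixed N(0,1) latent distribution, computed with the Bock–Aitkin EM
scheme on a fixed quadrature grid: 61 equally spaced nodes on [−6, 6] with
normal-density weights.  The M-step solves each item's expected score
equation by damped Newton steps.  Convergence is declared when the largest
absolute difficulty change falls below 1e−4 (at most 500 EM sweeps; a
non-convergent fit raises, carrying the last iterate).  Items answered
all-correct or all-incorrect by their responders have no finite maximum and
are excluded with a warning.  After fitting, difficulties are re-centered to
mean zero; together with the N(0,1) latent this fixes the scale's location.

Because the latent density decays like a Gaussian, the equally spaced
trapezoid-type rule converges superalgebraically here; the 61-node grid
reproduces dense-grid integrals of the posterior mean to well below 1e−4,
which the test suite verifies against a brute-force 12,001-point oracle.

**Scoring** (`irt.score_person`, `irt.score_group`) is expected a posteriori
(EAP) under the same N(0,1) prior and grid; the reported standard error is
the posterior standard deviation.  EAP was chosen over ML/WLE because it
remains finite for perfect and zero raw scores, which are routine on short
quarterly forms.  One consequence worth noting: with a unit-variance prior
and a log-concave Rasch likelihood, the posterior SD is bounded above by 1,
so with the default reliability threshold of 1.0 the filter excludes only
cells that are missing altogether.  Analysts who want an information-based
criterion that can exceed 1 (as ML-type standard errors do on short forms)
should lower `se_max`; the filter logic itself is estimator-agnostic.

Both time points are scored against the same item-bank difficulties, placing
t1 and t2 proficiencies on the bank's scale.  The pipeline defaults to the
bank as given (difficulties "retrieved from the item pool"); setting
`recalibrate: true` re-estimates each system's difficulties from the time-1
responses instead.  Cross-form equating beyond shared-bank anchoring is out
of scope.

## Transition analysis

The procedure is the classify-then-count form of latent transition analysis
(a mover-stayer tabulation), not a full measurement-error-aware latent-class
model:

1. Estimates with se strictly greater than `se_max` (default 1.0; strict
   because the rule is "larger than") become *not applicable*.
2. Within each system and time point, exactly `round(0.6 · n)` of the n kept
   examinees — rounding half to even — are classified proficient, ranked by
   θ with ties broken by ascending person id for determinism.  The 60% share
   reflects that certifying exams pass most candidates, so "proficient"
   is set above the passing margin.
3. Each person × system with both time points observed gets one of the four
   patterns (0,0), (0,1), (1,0), (1,1); pairs with a not-applicable side are
   excluded from pattern counts (exclusion counts are logged).
4. Pattern counts are tabulated per (specialty, system) stratum, then pooled
   per system within each frequency label.  A system is *effective* for a
   label when its pooled count reaches `min_n`; the label's row reports the
   unweighted mean proportion over effective systems and the across-system
   standard deviation divided by √K (K = effective system count).  The
   divide-by-K variant is available via `se_denominator: k`.  The reference
   label is reported as a single person-pooled table without an
   across-system SE, since general-practice observations are not
   system-clustered by construction.

`min_n` defaults to 30, a conventional minimum for a stable proportion at
full study scale (thousands of examinees).  Scaled-down runs should set it
proportionally (the packaged small-cohort examples use 5–10); it gates only
which systems enter a label's mean, and the effective count is always
surfaced in the report.

## Odds-ratio inference

Decline is the (1,0) pattern *among observations proficient at time 1*;
improvement is (0,1) among the initially non-proficient.  This conditioned
2×2 construction is the default because "decline" is only meaningful for
those who had something to lose; the unconditioned variant (event vs all
else) is available via `conditional_or: false`.  For groups a and b,

    OR = (a_events · b_nonevents) / (a_nonevents · b_events),

with 95% CI exp(log OR ± 1.96·√(Σ 1/cell)) and a two-sided Wald p-value.
Zero cells receive the Haldane–Anscombe 0.5 correction (all four cells) and
the result is flagged.  Pairs are oriented with the less frequently used
label in the numerator, so decline ORs above 1 mean rarely-used knowledge
declines more.  Observations pool persons across systems within a label;
person-level clustering is ignored (plain unadjusted ORs), and the run
summary carries a note to that effect.

The ordering check compares per-label mean proportions against the
hypothesized chains — maintenance (1,1): dominant > reference > relevant ≥
distant; decline (1,0): dominant < reference < relevant ≈ distant — and
reports each link as satisfied, tied (within `tie_tol`, default 0.005
proportion), violated, or unavailable.  The relevant/distant link is treated
as a near-tie expectation: either direction satisfies it.

## Synthetic cohorts

The simulator emulates the data structure the analysis assumes:

- **Item bank**: `bank_items_per_system` (default 30) items per system with
  N(difficulty_mean, difficulty_sd²) difficulties (defaults 0, 1).
- **Forms**: the initial exam as 5 blocks × 60 items and the longitudinal
  recertification assessment as 12 quarters × 25 items, sampled from the
  bank without replacement and balanced across systems
  (`simulate.build_forms`).  The cohort generator itself uses per-system
  item counts: 21 at time 1 (≈300 items over 14 systems) and 14 at time 2,
  matching a two-year longitudinal pilot of eight 25-item quarters; the
  shorter time-2 forms produce visibly larger standard errors.
- **Abilities**: θ_{p,s,1} ~ N(0, 1), matching the calibration prior so
  generated and estimated scales coincide up to estimation error;
  θ_{p,s,2} = θ_{p,s,1} + μ_label + ε with ε ~ N(0, drift_sd²).
- **Drift defaults**: dominant +0.30, reference 0.00, relevant −0.30,
  distant −0.35 logits, with drift_sd 0.30.  These are configuration chosen
  to realize the usage hypothesis with relevant and distant nearly tied —
  not empirical claims.  Because proficiency classification is
  norm-referenced within each system, only *relative* drift matters: labels
  whose drift beats the population average rise in rank.
- **Specialty mix**: 48% of examinees in multi-specialization
  (general-practice) profiles, the remainder uniform over the 59
  single-specialization profiles.

The packaged registries (14 systems, 64 specialties, example label map) are
illustrative; only the neurological-surgery profile and the general-practice
rule are fixed by the study design.

What the simulator deliberately does **not** model: correlation of abilities
across systems within a person, quarterly spacing or learning-during-
assessment effects, demographic covariates, item exposure, or non-normal
ability distributions.  Passing recovery tests therefore demonstrates that
the pipeline is correct under its own assumptions, not that those
assumptions hold for any particular real cohort.

## Numerical and degenerate-input choices

- Every stochastic routine takes an explicit seed (`numpy.random.default_rng`);
  no global state.  Equal configurations reproduce byte-identical outputs.
- `round(0.6·n)` uses banker's rounding; with share 0.6 no exact .5 ties can
  occur for integer n.
- Pattern-probability inputs to `simulate_pattern_sequences` must sum to 1
  within 1e−9; callers working from rounded published proportions should
  renormalize first.
- Empty inputs raise typed errors at the operation level
  (`TransitionError`, `ScoringError`, `InferenceError`, `DesignError`);
  the pipeline wraps any stage failure in a `PipelineError` naming the stage.
- Comparison pairs whose conditioning set is empty are reported as failures
  in the run summary rather than aborting the run.

## Problem sizes used by the test and acceptance suites

Calibration recovery uses 2,000 examinees × 20 items; the classification-
marginal check uses a 1,000-examinee cohort with shortened forms; pattern
recovery uses 10,000 multinomial draws; the null type-I-error check uses
1,000 replicate pairs of 1,000 draws; the default-drift pipeline run uses
215 examinees × 14 systems ≈ 3,000 examinee-system trajectories.  These
sizes make the full suite run in seconds on one CPU while leaving the
statistical checks well-powered.

## Known limitations

- Two time points only; no multi-wave transition chains.
- The classify-then-count procedure ignores classification error near the
  60th-percentile boundary, which attenuates transition contrasts relative
  to a latent-class treatment; this bias is shared by design with the
  procedure it implements.
- Odds ratios ignore within-person clustering across systems, so their CIs
  are anti-conservative to a degree that grows with the number of systems
  per person.
- No DIF analysis, 2PL/3PL, or polytomous support.
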