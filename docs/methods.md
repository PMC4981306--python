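# Methods

## Decision problem and model form

The model compares seven test-treat strategies for women in secondary
care with persistent overactive-bladder (OAB) or urgency-predominant
mixed urinary incontinence after failed conservative treatment. A
decision tree (not a Markov model) is appropriate because the decision
is short-term and path-dependent: what a woman receives next depends on
which treatments she has already had. The tree is rooted at the true
urodynamic condition (six categories), layered with the diagnostic
information each strategy buys, and terminates in "cured" or "remains
symptomatic" states. Health improvements, once achieved, last to the end
of the five-year horizon (no relapse), and women whose condition offers
no invasive treatment (normal bladder, low compliance only, voiding
dysfunction only) remain symptomatic at their baseline quality of life.

All branch probabilities, unit costs and utilities are *symbolic
references* into a flat parameter namespace resolved at evaluation time.
One tree structure therefore serves the base case, every deterministic
scenario and every probabilistic draw; evaluation is a recursive
expected-value rollback that broadcasts over arrays, so a 10,000-draw
probabilistic analysis is a single vectorised pass per strategy. An
independent path-enumeration evaluator exists purely as a verification
oracle (the test suite requires rollback and enumeration to agree to
1e-9), and trees export as indented outlines and DOT graphs for visual
audit.

## Parameters

Inputs are a YAML document mirroring the published input tables:

* **Cure probabilities** P(subjective cure | treatment, true condition),
  Beta-distributed. Where the source reported counts of effectively
  treated patients the counts are the shapes (e.g. Beta(50, 38), mean
  0.568, for botulinum in detrusor overactivity); elicited rows carry
  their stated 95% bounds for scenario analysis. Neurostimulation and
  the implanted neurostimulator pool stress and mixed incontinence into
  one entry. Women with untreatable conditions who are nonetheless
  treated after misdiagnosis use the most conservative elicited rate
  (0.143) for any intervention — the only stated rule for that case.
* **Pathway probabilities** (treatment preference 0.75 for botulinum
  over neurostimulation, 0.314 for botulinum before sling, voiding
  difficulty 0.086, implantation 0.67 after peripheral nerve evaluation,
  device revision/maintenance/removal), all Beta.
* **Unit costs** (GBP, 2012–13), Gamma. Rows published without an
  interval (ultrasonography £51, self-catheterisation training £84) use
  shape 1, scale = mean: the published parameterisations Gamma(1.00,
  51.07) and Gamma(1.00, 84.00) are reproduced exactly by reading the
  "variance equal to the mean" fitting note as *standard deviation*
  equal to the mean.
* **Utilities** per health state, Beta; 0.92 cured, 0.87 cured with
  botulinum-induced voiding dysfunction, baseline condition utilities
  0.600–0.744.
* **Accuracy / prevalence / history** — see the synthetic fixture below.
* **Economic settings**: 3.5%/year discount rate, 5-year horizon, 10,000
  PSA iterations, incidence 54,000/year, 10-year research horizon,
  willingness-to-pay grids 0–£100,000 (step £500) per success and
  0–£50,000 (step £250) per QALY.

Distribution fitting from a mean and 95% CI (provided for re-deriving
elicited rows) constrains the analytic mean exactly (Beta: β = α(1−m)/m;
Gamma: scale = mean/shape) and minimises the summed squared deviation of
the 2.5%/97.5% quantiles by a coarse geometric grid plus bounded
golden-section refinement of every grid basin (the objective can be
multimodal for extreme shapes); `constrain_mean=False` switches to a
joint Nelder–Mead fit of all three values, since the original fitting
convention is not fully recoverable: some published parameterisations
(e.g. the urodynamics cost) have quantiles inconsistent with their own
printed intervals. Percentile bounds are read as equal-tailed 2.5%/97.5%
quantiles throughout. Three published probability rows (sling–mixed
0.560, colposuspension–mixed 0.489, device maintenance 0.150) differ
from their distribution means (0.556, 0.488, 0.151) by more than printed
rounding; the distributions govern.

## Event-timing grid

Costs and QALYs accrue on a yearly grid; the first 12 months are
undiscounted, later years discount at (1.035)^−(t−1). Choices that were
genuinely open and the conventions adopted:

* Entry test and first treatment at year 0; a treatment given at year t
  that cures switches utility from the interval [t, t+1); failures move
  to the next step at t+1.
* Botulinum course: injections at t, t+1, t+2, taken with probability
  1 / 0.80 / 0.736 (the drop-out schedule), each costed at its year; the
  course cure probability splits over injections 34% / 52% / 14%, so
  cure timing is disaggregated by injection year. Injections that would
  fall beyond the horizon are neither given nor costed, and the cure
  probability is truncated proportionally. Failure is established a year
  after the last scheduled injection (t+3).
* Neurostimulation: the 12-session course is costed at year t;
  responders need a monthly maintenance session to the horizon, costed
  at course/12 per session (no per-session price is published) — 9
  sessions in the first year (months 4–12), 12 per year thereafter,
  discounted by the year in which they fall.
* Implant follow-up events (revision before/after 2 years, maintenance,
  removal; all at the £4,160 day-case cost) occur at the end of the
  horizon. Because the four probabilities are *marginal* estimates from
  different sources, independent Beta draws can sum above 1, so they are
  costed in expectation (probability-weighted cost events) rather than
  as mutually exclusive branches; the expected cost is identical and
  probability conservation holds for every draw.
* Voiding dysfunction after botulinum (8.6% per course) adds
  self-catheterisation training at the course year and marks the woman,
  permanently, as cured-with-side-effects if she is ever cured.

## Tests and the two-test rule

Urodynamics is the reference standard and classifies exactly (a
scenario lowers its sensitivity for detrusor overactivity, misclassified
women being managed as mixed incontinence). Ultrasound is positive at
BWT >= 5 mm — positives are managed as OAB, negatives as mixed
incontinence, since a thin wall cannot separate the syndromes. Clinical
history maps urgency-only symptoms to OAB management and mixed symptoms
to mixed-incontinence management.

At most two diagnostic tests are performed. In the conditional
strategies, women in the untested arm are managed by history; if their
*first treatment cycle* fails, the strategy's test is performed and
management switches to its result, skipping treatments already given,
with colposuspension barred once any OAB treatment has been delivered.
Women tested at entry are not re-tested (the same test would return the
same answer), and the `single_test_only` scenario disables the second
test everywhere. When a re-managed pathway reaches a treatment already
given it falls through to the next option; a woman managed as mixed who
has already had a sling proceeds directly to the colposuspension rule.

## Synthetic cohort fixture

The accuracy, prevalence and history-classification inputs of the
primary cross-sectional study are not publicly deposited. The `cohort`
module generates cohorts with the same structure — true urodynamic
diagnosis, BWT measurement, history label, baseline utility — under a
configurable generator whose defaults were fixed once, before any model
output was inspected, to the only in-text anchors available: detrusor
overactivity the most prevalent finding (mix 0.40/0.15/0.15/0.20/0.05/
0.05) and an overall mixed-history rate of 0.52. BWT is log-normal per
category (positive, right-skewed; medians 4.7/4.0/4.4/3.9/4.1/4.2 mm,
log-scale 0.25), implying sensitivity ≈ 0.40 and specificity ≈ 0.79 at
the 5 mm threshold; the reference-positive set is {detrusor
overactivity} by default, with mixed incontinence includable by flag.
The packaged default config freezes the *estimated counts* from one
generated cohort of n = 209 (the primary study's analysed sample size;
seed 101), so the model's default inputs carry realistic small-sample
uncertainty: sensitivity Beta(28, 60), specificity Beta(98, 23),
prevalence Dirichlet(88, 29, 32, 33, 12, 15), per-condition history
Betas.

The generator emulates the joint structure the model needs and nothing
more: it does not simulate bladder diaries, post-void residual
screening, recruitment funnels, or correlation between BWT and symptom
severity. Tests passing against it show that the estimation and decision
machinery recovers known ground truth, not that the fixture equals the
primary cohort — absolute outputs (e.g. £4,869 expected cost for
urodynamics-for-all; 82% probability that it is cost-effective at
£20,000/QALY; population EVPI of £24M) are fixture-conditional, though
their qualitative pattern (ultrasound strategies dominated;
history-conditional urodynamics attractive per success) matches the
published analysis, and the published ICERs re-derived from published
increments are reproduced to ~1%.

## Probabilistic analysis

Each PSA iteration draws every parameter once from its distribution and
evaluates all seven trees on that joint draw (common random parameters —
required for coherent incremental comparisons). Every parameter owns an
independent substream keyed by its name from the run seed, so enlarging
the iteration count extends rather than reshuffles the draws, and
re-running one strategy alone reproduces its column exactly. The CEAF
reports, at each willingness-to-pay, the probability that the strategy
with the highest *mean* net monetary benefit attains the per-iteration
maximum, splitting exact ties equally (an unbiased tie convention).
EVPI is E[max NMB] − max E[NMB], clipped at zero against floating
residue; population EVPI multiplies by incidence × the 10-year annuity
factor (first year undiscounted), 8.6077 at 3.5%.

## Frontier conventions

Strategies are sorted by cost; strictly dominated options (no cheaper,
no more effective, one strict) are removed, then extended dominance is
eliminated by deleting any middle strategy whose incoming ICER is not
below its outgoing ICER, leaving strictly increasing ICERs between
adjacent frontier members. Exact cost-and-effect ties are kept in the
table with all but the lexicographically first flagged, so reports are
reproducible. ICERs are kept at full precision internally and rounded to
the nearest £100 only for presentation.

## Known limitations

* NHS perspective only; no societal costs, no price-year adjustment.
* No relapse after cure, no utility decrements from surgery itself, and
  no tachyphylaxis to repeated botulinum or neurostimulation.
* The second-test rule ("after the first failed treatment cycle") is one
  reasonable reading of the two-test assumption; the outline/DOT exports
  exist so the wiring can be audited against alternatives.
* Partial EVPI (per-parameter value of information) is out of scope;
  only total EVPI is computed.
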