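# Methods

This note documents the models, parameter choices and numerical conventions
behind `lingsum`, and what the synthetic-data experiments do and do not show.

## Fuzzy sets and membership functions

Feature labels are piecewise-linear fuzzy sets: triangular, trapezoidal, and
shoulder functions (the lowest/highest label of a variable plateaus at 1 all
the way to the domain boundary, so an extreme observation is always fully
covered by the extreme label).  Degrees are double-precision floats; α-cut
comparisons use exact `>=`/`>` with no epsilon, because membership values come
from explicit formulas rather than noisy measurement.  The fuzzy connectives
are the minimum t-norm and maximum t-conorm (product / probabilistic sum are
available as configuration); negation is the standard complement `1 − μ`.

## Label induction with fuzzy c-means

Each feature's label centers are fit by one-dimensional fuzzy c-means with
fuzzifier m = 2, tolerance 1e-6 on the maximum center shift, at most 300
iterations, and a seeded farthest-point ("k-means++-style") initialisation.
The alternating optimisation is monotone: the objective trace is recorded and
asserted non-increasing in tests, and a random-restart direct minimisation of
the closed-form m = 2 objective serves as an independent oracle.  Centers are
returned sorted; the first/last labels become shoulders and interior labels
triangulars with feet at the neighbouring centers, which makes label
memberships a Ruspini partition (they sum to exactly 1) inside the center
span.

Three-level labels (low/medium/high) are used for attention features and
Bayley composites; five-level age-relative labels (far behind … far ahead) for
Bayley subscale age-equivalents.  Age-relative variables are fit on the
difference *age-equivalent − chronological age* in months, so "behind by age"
means the same thing for a 28-month-old and a 36-month-old.  Fitting on raw
subscale scores instead would confound developmental level with age; the
difference convention is the package's choice where either reading is
defensible.

Labels are induced on the **whole usable cohort** (both groups pooled), not
per group.  This matters: "low SI net dwell time" means low relative to all
children, so a group-scoped sentence can say that ASD children sit at the low
end of a shared scale.  Per-group induction would re-normalise each group to
its own range and wash out exactly the contrasts the summaries are meant to
express.

Children lacking any Bayley field are excluded from summarization (with a
logged count) rather than imputed; a missing feature value in a record
fuzzifies to an explicit MISSING sentinel, never silently to 0.

## Quantifiers

Relative quantifiers over the proportion scale [0, 1]:

| name       | membership function        | note                               |
|------------|----------------------------|------------------------------------|
| few        | trapezoid (0, 0, 0.2, 0.4) | exact dual: few(x) = most(1 − x)   |
| about half | triangle (0.3, 0.5, 0.7)   |                                    |
| most       | trapezoid (0.6, 0.8, 1, 1) |                                    |
| almost all | trapezoid (0.8, 0.95, 1, 1)| semi-fuzzy form: max{2p − 1, 0}    |

The few/most duality is kept exact deliberately — the algebraic identity
`T_few(¬S) = T_most(S)` (scalar route) is asserted to 1e-12 in tests and
justifies dropping "few" sentences as negation duals during reduction.
"Almost all" carries two gradings: its relative MF (used for scalar truth and
pointwise inclusion checks, where it must sit inside "most") and the linear
crisp-ratio form `max{2(|X₁∩X₂|/|X₁|) − 1, 0}` used as its semi-fuzzy form in
the fuzzification mechanism, with the convention Q(∅, ·) = 1.  Binary
semi-fuzzy forms for the other quantifiers apply their MF to the crisp
conditional proportion |X₁∩X₂|/|X₁|; unary forms to |X₁|/|universe|.

## Truth evaluation

Scalar route: type-I truth is `μ_Q(Σ μ_S / R)` (R = subject count for
relative quantifiers, 1 for absolute); type-II is the weighted conditional
form with the configured t-norm.  A type-II sentence whose pre-summarizer
supports no subject at all (zero denominator) is flagged undefined and
dropped downstream: a vacuous restriction carries no evidence either way.

Fuzzification route (default): the semi-fuzzy quantifier is integrated over
all non-strict α-cut levels of its fuzzy arguments.  For a discrete cohort
the non-strict cut is piecewise constant in α, so the integral is an exact
finite sum: the distinct membership values of each argument partition (0, 1]
into right-closed intervals, and the truth degree is the sum over the
interval grid of (product of widths) × Q(cut tuple).  Boundary conventions
(which end of each interval is closed) affect only measure-zero sets and not
the integral.  Internally nothing is rounded; reports print 2 decimals and
JSON 4 decimals.  Note the ∅-convention makes the mechanism return high truth
for sentences whose pre-summarizer is nearly empty in scope — such vacuous
sentences are a known property of this evaluation and survive reduction only
if nothing subsumes them.

Whole-cohort sentence sets are evaluated through two vectorized exact paths
(unary, and binary ratio-form via a two-dimensional suffix-sum over
membership levels); both are asserted equal to the generic rectangle
decomposition to 1e-12, and the generic path is itself cross-checked against
a seeded uniform-α Monte-Carlo estimator (10⁵ samples agree within 0.01 on
random instances).  Arities above 3 fall back to Monte-Carlo with the
configured sample count and seed, flagged stochastic.

## Interpretability reduction

Pipeline order: threshold → negation-dual removal → contradiction detection →
inclusion-redundancy removal → merging.  Choices worth recording:

* The truth threshold comparison is boundary-inclusive (`T ≥ 0.90`): a
  sentence exactly at the threshold is kept.
* Contradictory pairs (antonym quantifier with the same summarizer, or same
  quantifier with antonym summarizer labels, both at high truth) are
  **reported, not auto-dropped** — there is no principled resolution rule, so
  the report surfaces them for a human.
* Inclusion uses pointwise MF dominance on a 1001-point grid with tolerance
  1e-9 (quantifiers on [0, 1], summarizers on the span of both functions'
  breakpoints); the dominated (less informative) sentence is dropped.
* Merging combines sentences sharing a pre-summarizer into an "and"
  summarizer composite and sentences sharing a summarizer into an "or"
  pre-summarizer composite.  The merged truth is **re-evaluated** on the
  composite, never inherited or aggregated from the members — re-evaluation
  is the only semantics consistent with a single truth value per sentence.
  A merge is abandoned (members stay retained) if the re-evaluated truth
  drops below the threshold, which also makes reduction idempotent: only
  simple (arity-1) sentences are merge candidates, so re-reducing a reduced
  summary is a fixed point.  Bookkeeping is conservative: every input
  sentence appears exactly once across retained and dropped (merge sources
  carry reason `merged_away`).

## Synthetic cohort generator

The generator emulates the published cohort structure, not any real child:

* **Sizes and ages** — 61 ASD and 72 TD children; chronological ages are
  truncated normals on [28, 36] and [26, 36] months whose latent parameters
  (35.53 ± 1.2, 33.57 ± 2.4) realise observed means of 34.85 and 32.90 after
  truncation.
* **Attention trade-off** — each child has a log-normal attention budget
  (median 9000 ms) split between the animation and SI areas of interest by a
  Beta-distributed share (ASD mean 0.78, TD mean 0.25, concentration 16).
  Because animation time = share × budget and SI time = (1 − share) × budget,
  the shared budget induces the negative cross-AOI correlation; the trade-off
  strength ρ ∈ [−1, 0] shrinks the budget's log-sd (0.4·(1 − |ρ|), default
  ρ = −0.8) so that share variation dominates.  These settings encode a
  strong, near-categorical group preference: the hallmark sentence "most ASD
  children with high animation net dwell time have low SI net dwell time"
  evaluates to truth ≈ 0.91–0.99 across seeds, bracketing the level the
  method reports on the real cohort, while the label-reversed control stays
  at 0.  Dwell-derived features (net dwell ≤ dwell, fixation time, counts as
  Poisson with ~280 ms mean fixation, entry time earlier into the preferred
  AOI) are consistency-clamped; durations are truncated log-normals, so the
  animation dwell range covers roughly the published [590, 13051] ms span.
* **Bayley block** — composites are a correlated trivariate normal on the
  100/15 standard scale (pairwise r = 0.6; ASD mean shifted −1.5 SD);
  age-equivalents equal chronological age plus 4 months per population SD of
  the matching composite plus noise, so low composites translate into
  "behind by age" labels.
* **Degradation** — a seeded fraction of children can have the whole Bayley
  block blanked, reproducing the published join (133 tracked children, 130
  with both assessments).
* **Planted associations** — optional (group, pre-label → summ-label,
  strength) tilts implemented by quantile-region resampling, for controlled
  recovery experiments beyond the built-in attention trade-off.

What passing tests show — and do not.  The generator produces smooth,
unimodal, independently-drawn feature noise; real eye-tracking data have
session effects, floor/ceiling artefacts, device-specific event detection and
missingness that correlates with severity.  Recovery of the planted structure
therefore demonstrates that the pipeline detects the *kind* of association
the study reports at comparable sample sizes, not that it would reproduce the
study's exact truth degrees on real data (which were never deposited).

## Expert-survey scoring

Per-summary quality averages the truthfulness/relevance questions (P1, P2)
and the clarity questions (P3–P5) as `((P̄1+P̄2)/2 + (P̄3+P̄4+P̄5)/3)/2`; the
global score is the mean over summaries.  Only the five question averages and
the summary count are published, so the per-summary scores are reconstructed
by applying the cohort-level averages uniformly — the only reconstruction
consistent with the printed numbers.  Exact arithmetic on the averages
(9, 8.5, 9, 9, 10) gives 9.0417, reported elsewhere rounded to 9.05.

## Problem sizes and determinism

Default full runs evaluate ≈33k candidate sentences over 133 children in a
few seconds via the vectorized exact paths; tests use reduced feature sets
(4 attention + 2 composite + 2 age-relative features) for sub-second runs.
Every stochastic component (generator, FCM initialisation, Monte-Carlo
fallback) is driven by an explicit integer seed; identical config + seed
yields byte-identical outputs.

## Known limitations

* Quantifier MF parameters are declared defaults (configurable), not fitted
  to any external standard.
* The ∅-convention of binary semi-fuzzy quantifiers yields truth 1 for
  vacuous pre-summarizers under the fuzzification route (the scalar route
  flags them undefined instead); consumers should read group-scoped
  sentences whose pre-summarizer is rare in that group with care.
* Inclusion is checked by pointwise MF dominance on a finite grid — a
  deliberate computational surrogate for fuzzy-set inclusion.
* Arity > 2 semi-fuzzy quantifiers and OWA/Choquet truth degrees are out of
  scope; composites beyond arity 1 arise only from interpretability merging.
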