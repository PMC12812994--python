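# Methods

## Problem setting

Spontaneous reporting systems such as FAERS collect voluntary post-marketing
safety reports.  Each report carries demographics, one or more drugs with
role codes (primary suspect, secondary suspect, concomitant, interacting),
MedDRA-coded adverse events (PTs, grouped into SOCs), outcomes and dates.
The package quantifies how disproportionately a target drug co-reports with
an event relative to the rest of the database, characterizes when events
occur after therapy start, and probes robustness to a neurotoxic
concomitant.  Disproportionality is an association screen, not a causal
estimate.

## Report preparation

* **Deduplication.** FAERS cases accrue versions; one report per `case_id`
  is kept — the latest `receipt_date`, ties broken by the greatest
  `version_id` (numeric versions compare numerically).  The rule is the
  FDA-recommended convention; the operation is idempotent.
* **Dates.** Only full `YYYYMMDD` dates are parsed; year- or month-precision
  values become absent.  Partial dates exclude a record from time-to-onset
  but not from disproportionality counting, which maximizes signal counts
  while keeping latencies clean.
* **Drug matching** is exact-token after casefolding and punctuation
  stripping: a synonym matches when its tokens appear contiguously among the
  verbatim string's tokens, so `"velcade."` matches VELCADE and
  `"carfilzomib + dexamethasone"` matches carfilzomib, but substrings never
  match.  Synonym sets of different labels must be disjoint.
* **Counting unit.** A report contributes once per (drug, PT) pair even if a
  PT repeats within it.  A report whose primary suspects match two target
  drugs counts for both (logged).  The fourfold tables count b, c, d at the
  report–PT pair level; this is the package default (a report-level switch
  was considered out of scope since every downstream statistic consumes the
  same universe).

## Disproportionality statistics

Given `a, b, c, d` and `N = a+b+c+d`:

* **ROR** `= ad/bc`, CI `exp(ln ROR ± 1.96 SE)`, `SE = √(1/a+1/b+1/c+1/d)`
  (Woolf).  Tables with a zero cell get the Haldane–Anscombe +0.5 on all
  four cells, flagged in the output; this keeps rare PTs (the n = 3 class)
  computable.
* **PRR** `= [a/(a+b)]/[c/(c+d)]` with the Yates-corrected Pearson χ²
  `N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)]` (continuity correction is the
  common practice in PRR screening; it can be disabled).
* **BCPNN.** The closed-form Bate-1998 posterior: with pseudo-counts
  α₁ = β₁ = 1 on the margins, α = β = 2 on the totals, γ₁₁ = 1 on the joint
  cell and the joint prior weight γ chosen so the prior IC expectation is 0,

      IC   = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]
      IC025 = IC − 2√V(IC)

  with the matching closed-form variance.  A `prior_scale` parameter
  multiplies every pseudo-count; as it tends to 0 the IC tends to the naive
  `log₂(aN/((a+b)(a+c)))`, which is the property the tests pin down.  Note
  the Bate prior shrinks substantially when `a` is far above its
  expectation at modest counts — the posterior IC can sit well below the
  naive IC; that is a feature of the published form, not an error.
* **MGPS.** `a ~ Poisson(λE)` with `E = (a+b)(a+c)/N`; prior
  `λ ~ w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂)`.  Hyperparameters maximize the
  marginal negative-binomial mixture likelihood over all drug–event cells
  (background drugs included), via L-BFGS-B on log/logit-transformed
  parameters from five fixed starting points (DuMouchel's classic start plus
  four dispersed restarts), relative log-likelihood tolerance 1e-8.  The
  posterior is again a two-gamma mixture; EBGM `= exp(E[ln λ | a])` and EB05
  is found by bisection on the analytic mixture CDF (tests cross-check
  against numerical quadrature to 1e-6).  Fits on fewer than ~50 cells are
  allowed but warned about.
* **Signal criterion** (all four must hold; each overridable):
  `a ≥ 3` and ROR CI low > 1; PRR ≥ 2 and χ² ≥ 4; IC025 > 0; EB05 > 2.
  These are the conventional "four algorithm standards" in the
  pharmacovigilance literature.  Rankings (by report count or by ROR) are
  taken among signal-positive pairs, ties broken by the other key then PT
  name.

## Sex subgroup analysis

Default orientation: (male vs female) × (PT vs other PTs) *within* the
target drug's sex-known reports, so ROR > 1 reads "more male-dominant" —
this matches the reading of a male-excess finding; the drug-vs-others
orientation within one sex stratum is available behind a flag.  The χ²
p-value on the same table supplies −log₁₀ p.  Raw p-values are the default
(reproducing common practice); Benjamini–Hochberg adjustment is available.
The significance rule at the boundary is non-strict (p ≤ α flags).

## Time to onset

Latency = event date − earliest full-precision therapy start of the tagged
drug, in whole days; non-positive or undated latencies are dropped and
counted.  Reports contain only realized onsets, so there is no censoring and
the KM cumulative incidence equals the empirical CDF (KM is retained for
fidelity to survival-analysis practice; lifelines supplies KM and the
k-sample log-rank test).

The Weibull fit maximizes the likelihood via the profile score equation in
the shape (Brent root-finding; scale in closed form), with 95% CIs from the
observed information on (ln α, ln β) — symmetric on the log scale, matching
the two-sided intervals conventionally printed.  Classification: *early*
iff β̂ < 1 and CI upper < 1; *wear-out* iff β̂ > 1 and CI lower > 1;
otherwise *random*, including a CI endpoint exactly at 1.  Fits pool all
nervous-system PTs per drug (per-PT fits are possible by filtering the
extracted records).  Quantiles are type-7 (linear interpolation).

## Synthetic data generator

Each case draws: one primary-suspect drug uniformly from 3 targets + 20
anonymous background drugs; sex Bernoulli(0.5); `1 + Poisson(0.7)` events
from a 40-PT multinomial (uniform base over a packaged miniature PT→SOC
catalogue spanning 12 SOCs), tilted multiplicatively by planted drug–event
strengths and, for males, by sex odds multipliers; a therapy start date and
per-event dates offset by Weibull(β, α) latencies rounded up to whole
days ≥ 1; concomitant mentions (thalidomide at rate 0.10, dexamethasone
0.30); missing sex (0.20), age (0.40) and dates (0.10); and with
probability 0.05 an extra earlier-dated duplicate version differing only in
`version_id`/`receipt_date`.  Default planted strengths echo the
target-drug study conditions: peripheral neuropathy 20 and polyneuropathy
22.8 for bortezomib, hypertensive encephalopathy 18 for carfilzomib,
burning feet syndrome 16 for ixazomib; sex odds multipliers 3 (male,
bortezomib polyneuropathy) and 1/3 (ixazomib paraesthesia); onset laws
(β, α) = (0.70, 68.8), (0.61, 81.9), (0.65, 153.5) days.  Identical config +
seed give byte-identical bundles, and a `GroundTruth` record stores every
planted parameter plus exact realized counts (per-drug cases, per-pair
report counts, nervous-system onset multisets, co-mention counts).

What the generator does **not** emulate: name misspellings, correlated
country/reporter structure, non-uniform background PT frequencies, secular
reporting trends, true duplicates with altered content, or indication
fields.  Passing tests therefore demonstrate correctness of the statistical
machinery under a clean spontaneous-reporting model, not robustness to real
FAERS data quality.  Because the vocabulary is miniature (40 PTs), planted
strengths produce much higher absolute event prevalences than real data;
relative measures (ROR, PRR, IC, EBGM) are unaffected by this scaling.

Two notes on fidelity of recovery:

* Day-rounding inflates a fitted Weibull shape slightly (≈ +0.04 at
  β = 0.70, α = 68.8, where ~5% of the continuous mass falls below one
  day).  Parameter-recovery checks therefore simulate on the continuous
  scale (`sample_onset_days(..., discretize=False)`); hazard-type
  classification is insensitive to the rounding.
* A planted multiplicative tilt of r on a 1/40-probability PT yields a
  report-level ROR below r (multinomial renormalization plus the
  several-events-per-case structure); the planted pairs are detection
  targets, not exact ROR targets.

## Problem sizes used

Calibration and power suites run 100 replicate universes of 20,000 cases
(null: nothing planted; power: the default planted conditions); Weibull
recovery runs 100 replicates at n = 2,053; log-rank separation runs 100
replicates at group sizes (500, 400, 500) and the null-uniformity check 200
replicates of two 200-observation groups.  The acceptance script uses 10
planted and 5 null universes of 20,000 cases plus the reference
time-to-onset sample sizes (2,053 / 399 / 794).

## Known limitations

* No censoring or interval-censoring model; partial dates are simply
  dropped from the latency analysis.
* Pairwise MGPS only (no multi-item itemsets), no IC temporal scan, no
  regression-adjusted disproportionality.
* The miniature PT→SOC catalogue is a synthetic stand-in for a licensed
  MedDRA hierarchy; only the PT→SOC level is modelled.
* The empirical-Bayes fit is exchangeable across cells; drug- or
  class-specific priors are out of scope.
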