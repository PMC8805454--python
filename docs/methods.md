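# Methods

This package reimplements, against fully synthetic inputs, an infodemiology
analysis linking the affective dynamics of COVID-era local news headlines to
same-day mental-health-related search activity across US states. This note
records the models, the conventions chosen where the method leaves room, the
synthetic-data design, and what the validation suite does and does not show.

## Affect scoring

Words carry crowdsourced ratings of valence (pleasantness), arousal
(intensity) and dominance (control) on a 1–9 scale. Each dimension is
z-standardized over the loaded lexicon's own entries before any scoring, so
all downstream affect values are in SD units relative to the dictionary.
The raw per-dimension moments used for the transform are stored on the
`AffectLexicon` so any scoring run is auditable. When a truncated lexicon is
supplied, its own moments are used — the standardization population is
always the loaded dictionary, not a hypothetical full one.

Headline cleaning is deliberately minimal: lowercase, split on any run of
non-alphabetic characters (so "covid-19" yields "covid"), drop stop words.
No lemmatization or stemming is applied; tokens match lexicon lemmas by
exact string. The built-in stop list is a standard English function-word
list; a plain-text additions file covers domain noise (place names, media
boilerplate, proper nouns that collide with lexicon entries). Words a day
uses repeatedly count once per occurrence: daily means and SDs are
token-weighted, reflecting exposure rather than vocabulary.

## Circumplex dynamics

For each state-day, the mapped tokens form a point cloud in z-scored affect
space, summarized per 2D plane (VA, VD, AD) by three SD-type statistics:

* **flux** — SD of the scalar scores along one dimension;
* **pulse** — SD of word-vector Euclidean magnitudes (extremity);
* **spin** — SD of word-vector angular displacements from the horizontal
  axis (tone).

Conventions, fixed globally and echoed into output metadata:

* **SD denominator.** Sample SD (n−1) everywhere an SD or variance is taken
  (lexicon standardization, flux, pulse, spin, phase variance). The `ddof`
  parameter exists so sensitivity checks can flip the convention.
* **Angle definition.** The printed angle formula evaluates to
  arccos(|a_x|/‖v‖), which folds every quadrant into [0°, 90°] because the
  numerator u·v = a_x² is non-negative. Both this `literal` reading
  (default) and a `signed` |atan2(a_y, a_x)| variant on [0°, 180°] are
  implemented; the choice is a logged config field. a_x = 0 with a_y ≠ 0 is
  defined as 90° in both modes (the limit of either formula); exact zero
  vectors have no angle and are excluded from spin while still counting for
  flux and pulse.
* **Angular SD.** Spin is the ordinary linear sample SD of angles in
  degrees, not a circular SD — spin is defined as an SD calculation, and on
  the folded [0°, 90°] range a circular statistic would be inappropriate
  anyway.
* **Missing rules.** Means need ≥ 1 mapped token; flux/pulse/spin need ≥ 2
  (spin: ≥ 2 nonzero vectors in the plane). Undefined statistics propagate
  as missing values and the affected rows are excluded from model designs.

## Phase descriptives

The collection period 2020-01-23..2020-10-22 (274 days) splits into
Pre-pandemic (50 d), Early Response (26 d) and Mid-pandemic (198 d), the
last cut into three 66-day partitions; the windows tile the period exactly.
Within each window a state's daily mean affect series is summarized by its
mean, sample variance and RMSSD. RMSSD uses only calendar-adjacent day
pairs where both days are observed — a gap contributes no pair — so missing
days never conflate multi-day change with daily change. Cross-state
percentile ranks use midrank ties mapped linearly to [0, 100] (single or
all-tied inputs sit at 50 by convention). High-frequency words are word
types whose total count is ≥ 2 sample SDs above the mean type count within
the state; with uniform counts nothing is selected.

## Search-count estimation

Platform-normalized (0–100) search interest is rescaled to estimated
absolute counts through a same-day comparator term with a published
absolute volume tier: the national count is the normalized total times
COMP_SV/COMP_NormTot, and each state's share is the normalized state/total
ratio times the state's population share, floored to an integer. COMP_SV is
always the lowest value of its published tier. Days whose comparator shows
zero normalized activity are undefined under the rescale and are dropped,
not imputed. The floor is applied with a relative epsilon (1e-9) so values
that are integral up to float rounding are not pushed down a whole count;
this is a numerical guard, not a change to the flooring semantics. The 17
tracked terms partition into Depression (7), Anxiety (6) and Nonspecific
(4) clusters; All is their union, and cluster sums satisfy the partition
identity row by row.

## Negative binomial mixed models

Daily state-level cluster counts are modeled as NB2 (variance μ + μ²/θ)
with a log link, fixed effects {t, V, A, Spin_VA, Pulse_VA, Flux_V, Flux_A}
(VA set) or the 13-term VAD extension, and a Gaussian random intercept per
state. Time is days since 2020-03-24 (213 modeling days, t ∈ [0, 212]); the
alternative time transform is log(t+1), chosen as the natural reading of a
"logistic time" sensitivity check that names no formula.

Estimation maximizes the Laplace-approximated marginal likelihood: an inner
damped-Newton solve finds each state's conditional mode (the penalized
problem is concave in the intercepts, so plain Newton with step halving is
globally safe), and an outer L-BFGS-B run over (β, log θ, log σ_b) uses an
analytic gradient obtained by implicit differentiation through the modes
(envelope terms for the data part, an explicit db̂/dparam for the
log-determinant correction). Starting values are fixed and
data-determined — intercept log(mean(y)+1), all other β 0, θ = 1, σ_b = 1 —
so fits are exactly reproducible; starting the intercept at the outcome's
log mean rather than 0 keeps the quasi-Newton iteration out of the flat
region that very large counts induce around β = 0. Convergence tolerance is
1e-8 on the scaled objective. Wald inference throughout: standard errors
from the inverse of a central-finite-difference Hessian of the objective,
95% CIs as β ± 1.96·se. Features enter unstandardized, so a coefficient is
the log-count change per feature unit (z units; degrees for spin; days for
t) and (exp(β) − 1)·100 is its percent-change reading. Efron's pseudo-r²
(1 − Σ(y−ŷ)²/Σ(y−ȳ)²) is reported with conditional fitted means (random
intercept at its mode); marginal prediction grids set the random effect to
0 and hold other features at their sample means.

The implementation is validated against `glmmTMB` (family `nbinom2`) as an
independent oracle on synthetic data — coefficients, SEs, θ and σ_b agree
to well under a percent — and against `lme4::glmer` in the Poisson limit
(θ → ∞).

## Synthetic data

No original inputs (scraped headlines, live search records) are
redistributable, so a generator emulates all four inputs with known ground
truth. Its defaults are the study's conditions where stated, and a single
seed drives independent per-module substreams.

* **Lexicon**: 2,000 random alphabetic lemmas with raw ratings drawn to the
  published scale moments — valence 5.064 (1.275), arousal 4.211 (0.986),
  dominance 5.185 (0.938) — clipped to [1, 9].
* **Headlines**: 50 states × 274 days, ~12 headlines/state-day of 4–9
  content tokens. Each day's mapped words realize an affect regime: latent
  draws are standardized to the day's target mean and spread, snapped to
  nearest lexicon entries in z space, and redrawn (up to 30 attempts) if
  the realized features deviate more than the tolerance (10%); a regime
  whose best attempt still deviates grossly raises an infeasible-regime
  error. Regimes can alternatively fix an angular center and spread in the
  VA plane, giving direct control of spin and pulse. Per-state baseline
  means sit around 0.25 z; the within-day spread target (nominally 0.9 z)
  varies day to day and independently per dimension (factor N(1, 0.15)
  clipped to [0.5, 1.5]) so the flux features carry identifying variation
  rather than collapsing into collinearity. Day-to-day volatility of the
  daily means is high pre-pandemic, low in the early-response window, and
  ramps back up across the mid-pandemic partitions, reproducing the RMSSD
  "rubber-banding" course.
  Out-of-vocabulary filler (63% of content tokens) and interspersed stop
  words bring mapping rates to ≈ 33–35%.
* **Counts**: cluster counts are NB2 draws with log-mean Xβ + intercept_c +
  b_state (defaults: Spin_VA −0.008 per degree, Flux_A +0.22 per z unit,
  t −0.004/day, σ_b 0.35, θ 8; intercepts put daily state counts in the
  hundreds). Spin's generating coefficient is on the per-degree scale so
  its effect across the realized spin range (roughly ±10°) matches the
  magnitude of the reported per-unit spin effects. Per-term series are a
  multinomial split within each cluster, so cluster sums reproduce the NB
  draw exactly; the All cluster is the sum of the three disjoint clusters
  and is therefore slightly less dispersed than any single NB (its fitted θ
  exceeds the generating θ by construction).
* **Normalization**: `lossless` mode (default) sets the comparator tier
  floor to its true volume and makes state shares exactly invertible, so
  the denormalization stage is an exact round trip up to flooring —the
  validation condition for the estimator. `platform` mode instead rounds
  0–100 values to integers, scales states per capita and floors the
  comparator volume to its tier, quantifying how much signal the real
  platform's normalization destroys.

**What passing tests do not show.** The generator produces statistically
analogous inputs, not English: headlines are token bags, word choice within
a day is exchangeable, and the count model generating the data is the model
being fit. Recovery results therefore validate the estimation machinery and
the pipeline's bookkeeping, not the substantive findings on real news and
search data — with real inputs, model misspecification, platform
normalization loss, and corpus coverage all add error the synthetic study
cannot exhibit.

## Problem sizes used in validation

The parameter-recovery study refits the generating model on 20 independent
replicates of 50 states × 200 days (10,000 rows each), checking mean
absolute bias below 0.05 per coefficient and 95% Wald CI coverage within
[85%, 100%]. The oracle-equivalence suite compares flux/pulse/spin/RMSSD/
variance against explicit-loop recomputation on 1,000 random small inputs
at 1e-10. The end-to-end scripts and the acceptance script run the full
50-state, 274-day synthetic study.

## Known limitations

* The literal angle fold means spin cannot distinguish a day spanning the
  left and right half-planes from one concentrated in a single quadrant;
  the `signed` mode exists precisely to probe this, and the two modes give
  different spin values by design.
* Wald CIs and p-values ignore uncertainty in θ and σ_b beyond the joint
  Hessian, and the Laplace approximation is known to bias variance
  components slightly for very small groups; with ≥ 26 observations per
  state this is negligible here.
* The estimator of absolute search counts inherits every distortion of the
  platform's normalization; only the lossless synthetic mode makes it
  exact, and `platform` mode shows the degradation.
* Days with fewer than two mapped words drop out of the model design
  entirely rather than being imputed.
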