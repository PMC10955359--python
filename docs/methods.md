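# Methods

## Generative model

### Players and matches

A cohort of `n_male + n_female` players (defaults 51 and 45) is drawn with
independent Bernoulli behavioural types: conditional cooperator with
probability `p_coop_male = 0.614` / `p_coop_female = 0.860`, non-cooperator
otherwise. These propensities are the observed gender-specific Round-1
cooperation rates of the study the package emulates, so the type shares are
calibrated rather than free. Note the emulated study's printed counts are
internally inconsistent (its overall figures use a 94-player total while the
gender counts sum to 96); this package keeps the gender composition and
derives all totals from it, so the default cohort has 96 players and 48
matches, and its expected Round-1 cooperation is ≈72.9% before trembles
(≈70.6% at the default tremble) rather than the 74.5% a 94-player total
would imply.

Pairing is a uniform random perfect matching, gender-blind: the emulated
design says nothing about how pairs were formed, so the maximum-entropy
default is used, and each player appears in exactly one fixed pair.

Match length is the guaranteed minimum of 2 plus sequential continuation
draws: from completed round `n`, play continues with probability
`4^(1−n)` (so P(L=2)=3/4, P(L≥4)=1/64), truncated at `max_rounds_cap = 10`
— the truncated mass is below `4^-36` and is ignored. One uniform draw is
consumed per completed round from round 2 onward.

Choices follow the conditional-cooperation law: non-cooperators always
intend Take All; conditional cooperators intend Split in Round 1 and copy
the partner's previous *realized* choice thereafter. The intended choice
flips with probability `tremble` (default 0.05, symmetric, i.i.d. per
player-round). The tremble both injects realistic execution noise and
calibrates the Round-2 cooperation rate: with the default composition the
closed-form expectation is ≈51.4%, within the three-point band around the
emulated 53.2% that the acceptance suite checks. With `tremble = 0` the
whole trajectory of a pair is a deterministic function of the two types,
which the tests verify by enumerating all four type pairs.

### Raters

The recruitment fixture generates 445 raters: 422 kept with the exact
per-treatment counts (None 108, Label 101, Photo 108, Video 105) plus 11
small-screen and 12 too-fast records (disjoint, cycled over treatments) so
the exclusion arithmetic 445 − 11 − 12 = 422 is exact. Kept durations are
480 s + Gamma(2) with mean 1464 s (the emulated mean completion time);
too-fast durations are uniform below the 480 s floor. Exclusion applies the
small-screen rule first, then the duration floor, and the audit always
conserves counts.

Rater gender is Male/Female/Other with shares 48.53%/48.98%/remainder.
Belief pairs are bivariate normal censored to [0, 100] with correlation
0.503 and rater-gender-specific means (male raters 46.3/61.8 about
male/female players, female raters 42.2/66.5, others at the pooled
44.2/63.9). The belief standard deviation is not recoverable from the
emulated study's transcribed tables, so it is a free parameter defaulting
to 20 percentage points.

Strategy: with probability `lambda_optimize` (default 0.5) a guess uses the
threshold rule — Split iff the effective posterior ≥ 50%, ties to Split for
consistency with the ≥50% sufficiently-correct convention — otherwise it
probability-matches on the posterior. The effective prior is the
gender-specific belief when the treatment reveals gender and the unweighted
mean of the two beliefs otherwise. Photo/Video treatments add a binary
appearance cue that equals the player's Round-1 truth with validity 0.55
(equal across the two arms by default, reflecting the emulated null
photo-vs-video contrast); it enters the prior on the log-odds scale with
weight `cue_weight` (default 1). Validities below 0.5 (anti-diagnostic
cues) are rejected. The default λ = 0.5 places raters midway between pure
matching and pure optimisation, which reproduces first-round guessed-Split
rates in the mid-50s as in the emulated data.

Round-2 guesses apply the tit-for-tat mirror (defector → Take All;
cooperator → partner's Round-1 choice) with probability
`heuristic_adherence` (default 0.8), else fall back to the Round-1 rule on
the same information set. Because the mirror is the true generative law up
to trembles, adherence 1 on a tremble-free cohort yields 100% Round-2
correctness — an identity the tests exercise end to end.

The vectorised study simulator draws each guess from the exact Bernoulli
probability implied by these mixtures, which is distributionally identical
to the literal two-stage draws of the scalar strategy functions; all
Round-1 records are generated before Round-2 records.

## Measurement layer

Detection rates condition on the truth: `H` among Split-truth records, `R`
among Take-All-truth records, always per rater per round over that rater's
full guess set — never from rates pooled across raters, because the probit
transform does not commute with averaging. Zero/one rates clamp to 1e−5 /
1 − 1e−5 so `Z(·)` stays finite; an all-Split guesser therefore has
accuracy exactly 0 (`Z(0.99999) − Z(0.99999)`), i.e. chance. A rater-round
block with an empty truth class (impossible at the default calibration,
where both classes are present) gets NaN rates, a logged warning, and drops
from conditional summaries. The odds ratio uses the Haldane–Anscombe +0.5
on all four cells whenever any cell is zero, a standard default chosen
because the emulated study's own alternative-measure formulas are not
available. `Z(·)` is the standard normal quantile (SciPy); tests verify it
against an independent bisection oracle on an erfc-based CDF to 1e−9.

## Scoring

Belief payments use one consistent reading of a quadratic rule with a 1/6
window: `max_pay × (1 − (d/w)²)` for `d = |belief − actual|/100 ≤ w`, zero
beyond — continuous, symmetric, maximal at zero error. The dollar constants
(max $0.50 per belief, $0.02 per correct guess) are free schedule
parameters; the emulated study does not print them.

## Inference

Permutation tests use the add-one estimator
`p = (1 + #{permuted ≥ observed}) / (1 + n_perm)` (default
`n_perm = 10000`), one-sided where the claim is directional. The sign test
flips signs independently (exact under symmetry); the group test shuffles
labels with the size-weighted between-group variance of means as statistic.
Both are bit-for-bit reproducible under a fixed generator and hold their
nominal type-I error (checked at 5% over 1000 null simulations).

Recovery estimates: gender propensities from Round-1 Split shares with the
tremble correction `(share − t̂)/(1 − 2t̂)` (the raw share has bias
`t(1−2p)` ≈ 3.6 points for the female propensity at the default tremble,
which would break interval coverage); the tremble from deviation
indicators of realized choices against the type-implied intention in both
rounds; `λ` and adherence by grid-search maximum likelihood (grid step
0.01 on [0, 1], ties to the smaller value) restricted to None/Label raters,
whose guess probabilities are exact functions of the stored beliefs — in
Photo/Video the sampled cue is latent. Intervals are 95% percentile
bootstraps: over players for cohort parameters, over raters (cached
per-rater likelihood profiles) for strategy parameters; the adherence
bootstrap plugs in the full-sample λ̂, whose own uncertainty (~200 raters ×
94+ guesses) is negligible. Measured coverage at the default scale is
≈92–95% per parameter.

## Problem sizes and determinism

Default study: 96 players, 48 matches, 445 → 422 raters, 81 024 guesses.
Replication-based checks use 200 cohort replications (accuracy ordering,
Round-2 calibration), 1000 null simulations (test levels), and 100
full-pipeline replications with 200 bootstrap draws (recovery coverage) —
sizes chosen so the full suite completes in about a minute on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances. All
randomness descends from a single root seed via `numpy` `SeedSequence`
spawning, with fixed stage order (players, matches, raters, guesses, tests,
recovery), so a config plus seed reproduces every CSV byte for byte and
changing only `n_perm` leaves the simulation stages untouched.

## What the synthetic cohorts do and do not show

The generator reproduces the emulated study's *structure* (treatments,
phases, exclusion arithmetic, measurement constructs) and its printed
*aggregates* (gender propensities, belief moments and correlation,
cooperation rates within tolerance). It does not model faces, expressivity,
response times, learning across the guess sequence, or any rater
heterogeneity beyond beliefs and the shared strategy parameters; appearance
is reduced to a single binary cue with configurable validity. Passing tests
therefore validate the measurement and inference machinery and the internal
consistency of the generative model — they are not evidence about real
raters beyond what the calibration builds in. Printed per-rater means such
as H = 59.8%, R = 44.8% or bias = −0.316 are nonlinear averages over
unpublished per-rater data and serve only as qualitative anchors (the
synthetic analogues come out near 57%/49% and ≈ −0.12 at the default
calibration).
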