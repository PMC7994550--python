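# Methods

## Model and assumptions

A pressure pain threshold (PPT) observation indexed by subject *i*,
session *j*, side *k* and repetition *l* is modelled as

    PPT_ijkl = mu + a_i + b_ij + c_ik + d_ijk + e_ijkl

with mutually independent zero-mean Gaussian effects:

| term | variance | meaning | units |
|---|---|---|---|
| a_i | sigma2_subj | stable subject level | N² |
| b_ij | sigma2_sess | session-within-subject shift (day-to-day state, re-marking of the site) | N² |
| c_ik | sigma2_side | side-within-subject offset (laterality) | N² |
| d_ijk | sigma2_sss | session x side interaction | N² |
| e_ijkl | sigma2_reps | repetition residual, i.i.d. per observation | N² |

Sessions and sides are *nested* within subjects (a subject's "session 1"
shares nothing with another subject's "session 1"); sides are treated as
exchangeable random draws rather than fixed left/right effects.  The
residual is purely i.i.d.: there is no drift or sensitisation across
repetitions, which matches protocols with long inter-stimulus intervals
but not rapid-fire stimulation.

Default simulation parameters are the fitted values of the motivating
lumbar-region study (sigma2 = 222.28, 4.83, 9.72, 34.63, 45.77 N², design
20 subjects x 2 sessions x 2 sides x 10 repetitions).  The grand mean
defaults to 50 N, a typical lumbar PPT level; it only shifts the location,
never a ratio.  No truncation at zero force is applied by default — with
the default components the mean sits about 2.8 total-SDs above zero, so
negative draws are vanishingly rare; an optional resample-if-negative flag
exists for low-mean scenarios and warns when used, because it truncates
the Gaussian residual.

## REML estimation

Subjects are independent, so the marginal covariance is block-diagonal
with per-subject blocks

    V_i = s_subj 11' + s_sess Z_sess Z_sess' + s_side Z_side Z_side'
        + s_sss Z_cell Z_cell' + s_reps I .

The criterion maximised is the restricted (residual) log-likelihood in
its error-contrast form — the exact log-density of K'y for an orthonormal
basis K of contrasts orthogonal to the intercept.  That form is
basis-invariant and includes all constants, which makes it directly
checkable against a brute-force dense-matrix evaluation (tests do this to
1e-6 and better).  It differs from profiled-scale conventions of common
mixed-model software by the fixed constant log(n)/2 only.

Two evaluation paths give identical values:

* **Balanced layouts.**  Each block is a sum of Kronecker products of
  averaging projectors, so V_i diagonalises in closed form into five
  strata (between subjects; sessions, sides, session x side within
  subject; within cell) with eigenvalues that are linear in the five
  variances and degrees of freedom (I−1), I(J−1), I(K−1), I(J−1)(K−1),
  IJK(L−1).  The criterion then depends on the data only through the five
  pooled stratum sums of squares — one pass over the data, O(1) per
  evaluation, with an analytic gradient.  This is what makes thousands of
  bootstrap refits cheap.
* **Unbalanced layouts.**  Per-subject dense blocks with Cholesky
  factorisation; any pattern of missing cells is accepted as long as each
  subject retains at least one observation.

Optimisation is over log(sigma²) (non-negativity by construction):
L-BFGS-B with the analytic gradient on the balanced path, Nelder-Mead on
the dense path.  Starts are deterministic — the ANOVA/Henderson moment
estimates from the stratum mean squares plus a fixed coarse grid of
variance splits — so a fit is reproducible without any seed.  Components
driven below 10⁻³ of the sample variance are then re-tested one at a time
against an exact-zero profile fit and pinned to 0 when the criterion does
not drop by more than 10x the criterion tolerance (default 1e-8; the
parameter tolerance is 1e-6 on the log scale, both configurable).
Zero-pinned components are reported with a boundary flag — real analyses
of this design do hit the boundary, as the published zero lower confidence
bounds for the side and session variances show.

Estimability is decided from the observed levels: a single observed
session makes the session (and interaction) variance unidentifiable, a
single side likewise, and single replicates per cell confound the
interaction with the residual; such components are excluded and flagged
rather than fitted.  Exactly constant data yield all-zero variances with a
degenerate (+inf) criterion, reported as such.  Fewer than two subjects is
an error.

## ICC construction

All single-measurement ICCs follow one shared-component rule: the
denominator is the total variance; the numerator keeps each component
whose defining factors are shared between the two correlated
measurements (subject always; session, side, repetition according to the
declared differing set; the interaction only when both session and side
are shared).  The three printed coefficients of the motivating study are
regression tests of this rule, not separate formulas.

Two deliberate tensions are preserved rather than "fixed":

* The session-only ICC counts the residual as shared (same repetition
  index at both sessions).  Under the i.i.d. residual model a new session
  necessarily draws a new residual, so the simulated matched-index
  inter-session correlation converges to the session+repetition ICC
  instead — which is precisely the overoptimism argument for reporting
  the more conservative coefficient.  Both variants are exposed.
* The average-measures ICCk(session) keeps only the subject variance in
  its numerator even though the averaged sides are the same at both
  sessions; it is implemented exactly as conventionally printed (the
  published values 0.85 and 0.88 confirm that computation), and the
  difference from the single-measurement session ICC at K=L=1 is
  documented and tested rather than reconciled.

`minimal_repetitions` inverts the ICCk curve: the L→inf ceiling at fixed
K is s_subj / (s_subj + s_sess + (s_side + s_sss)/K); thresholds above it
are reported as unreachable (Python `None`).

Reporting rounds ICCs to 2 decimals and variance shares to 1 decimal;
JSON/CSV outputs keep full precision.  Qualitative labels use the Shrout
bands with boundaries at 0.10/0.40/0.60/0.80; a boundary value belongs to
the lower band (0.80 is "moderate", matching the strictly-greater phrasing
of "substantial > 0.80"), except 0.10 itself, which is "slight" because
"virtually none" is strictly below 0.10.

## Parametric bootstrap

Each iteration simulates a full dataset from the fitted components on the
stated design, refits by REML, and evaluates every requested functional;
intervals are percentile-based.  Conventions chosen where the literature
is silent:

* **Percentile variant:** inverted-CDF empirical quantiles, so interval
  endpoints are order statistics and two replicates give exactly
  [min, max].  BCa/normal approximations are not used.
* **Non-convergence:** failed refits are dropped, never imputed, and
  counted in `n_failed`.
* **Seeding:** iteration *i* uses substream *i* spawned from the master
  seed, so intervals are independent of execution order and bit-for-bit
  reproducible.  The simulator likewise spawns one substream per random
  effect, so enlarging L leaves the subject/session/side draws untouched
  (paired comparisons across designs).

The default is 1000 iterations at the 95% level, the convention of the
motivating study; tests and examples use reduced counts.

## What the synthetic generator does and does not show

The generator reproduces the nested Gaussian variance structure exactly,
so passing tests demonstrate correct estimation and construction *under
the model*: REML recovery at the information-theoretic floor, nominal
bootstrap coverage, the boundary pattern of small components.  It does not
emulate rater effects, loading-rate variation, wind-up/sensitisation
drift, floor effects near zero force, or non-Gaussian tails — agreement
with the model on synthetic data says nothing about those violations in
real algometry data.

## Problem sizes used in the checks

Chosen as the smallest sizes that make each property sharply testable:
oracle equivalence on 4–6 subjects; parameter recovery at 200 subjects x
2 x 2 x 10 over 20 seeds (median error per component is compared both
against a fraction of the total variance and against the exact sampling
floor of the balanced-design mean-squares estimator, simulated from its
chi-square representation); bootstrap behaviour at the study's own
20-subject design with 200 iterations, and interval coverage over 100
outer replicates of 200 inner iterations.  Relative error of the small
session variance is large at any realistic sample size (its sampling SD
at 200 subjects is comparable to its value); that is a property of the
design, not of the estimator, which the floor comparison makes explicit.

## Known limitations

* Sides enter as exchangeable random effects; systematic left/right
  differences would call for a fixed side effect instead.
* No covariates (sex, anxiety, testing experience) — extensions would add
  fixed effects to the mean structure.
* Single rater: inter-rater variance is outside the model.
* Percentile intervals for variance components near zero are known to be
  conservative on the low side; profile-likelihood intervals are not
  provided.
* Agreement indices (standard error of measurement, minimal detectable
  change) are deliberately out of scope; the package quantifies relative
  reliability only.
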