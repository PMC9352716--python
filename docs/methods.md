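# Methods

## Scope and design

The package implements the scoring rules and four-step analysis of a
two-group spatial-navigation study (healthy controls vs community-dwelling
Alzheimer's patients) and a synthetic-data layer that reproduces the study's
published group-level structure. The library is organised around a
statsmodels-style pair: `DisorientationStudy` (data + configuration) and the
`DisorientationResults` its `fit()` returns; the scoring modules (`vst`,
`shq`, `dnt`), the statistics engine (`stats`), the generator (`simulate`)
and the CLI (`cli`) sit beneath that surface.

## Scoring rules and their open choices

**VST.** Directional components are exact-match percent correct over the
trials present (partial trial sets are scored, with `n_trials_scored`
recorded, rather than rejected — per-trial missingness handling is not
specified by the instrument's public description). The allocentric
displacement normalizer is the map diagonal, chosen because it is the
largest realisable error and therefore bounds the score in [0, 100]; map
width is available as an alternative. Whether the canonical instrument
averages displacement per trial or sums before normalizing is not publicly
documented; the mean is used here.

**SHQ.** The wayfinding normalization behind published score magnitudes
(~0.7 for controls, ~1.2 for patients) is not recoverable from public
sources, so reference distance/duration are explicit configuration constants
defaulting to 1.0 (raw pass-through). Every downstream analysis — t/rank-sum
tests, Cohen's d, standardized regression, the logistic odds ratio per SD —
is invariant to this scale, so the default loses nothing. Only the easiest
wayfinding level feeds the analysis (harder levels were not administered to
patients); flare accuracy weights each level's stars by its number of turns,
the stated weighting, though other weightings would satisfy the same verbal
description.

**DNT.** The published description normalizes summed event counts "for the
respective total route distance and total route intersection number". Two
readings are implemented: the default `split` mode treats wrong turns as a
per-intersection proportion (the opportunity set) and hesitations as a
per-km rate, summed — consistent with the published component rows summing
to the score rows — and `combined` divides total events by intersections ×
distance. Wrong-turn detection operates on an explicit street graph: a move
from an intersection is wrong when the edge taken is not on the planned
route, not marked viable by the experimenter, and not an exempted overlap
(e.g. a cul-de-sac exit); re-entering the original route on a detour walk is
wrong unless exempted. Retreating along the edge just walked is never
flagged: turning back is recovery from an error already counted, not a new
navigation decision. After two consecutive wrong turns the data must record
a positional reset to the node before the first wrong turn; a walk that
continues without one is rejected as protocol-inconsistent. The risk
dichotomy compares the composite to 1 with tolerance 1e-9 — route scores are
exact rationals of counts, so this is effectively exact equality. A
participant with equal *nonzero* route scores also has composite = 1 and is
classified low risk; the definition is applied as stated even though that
case is arguably qualitatively different (it did not occur in the study,
where original-route scores were essentially all zero).

## Statistics

- **Normality gate:** Shapiro–Wilk per group at α = 0.05 (the study does not
  name its test; Shapiro–Wilk is standard at n < 50). A constant group is
  treated as non-normal.
- **t-test:** pooled-variance Student's t (a single reported t with no
  Welch-style df suggests the classical test).
- **Rank-sum:** W is the Mann–Whitney U of the first sample (rank sum minus
  n_x(n_x+1)/2, midranks for ties), which reproduces the magnitude range of
  the published W values (bounded by n_x·n_y = 336 for 21 vs 16). p is exact
  for small untied samples, otherwise a tie- and continuity-corrected normal
  approximation (scipy's `mannwhitneyu` supplies both regimes).
- **Effect size:** unsigned pooled-SD Cohen's d, computable from summary
  statistics alone. The published effect sizes reproduce to ±0.01 only with
  row-specific patient n — the wayfinding-distance row with n = 14 (two
  non-attempters), the duration and detour-route rows with n = 16 (even
  though one patient's detour data were excluded downstream). The package
  reproduces the rows as printed and records the inconsistency here rather
  than resolving it.
- **ANCOVA:** OLS of outcome on group + covariate; the group F is the
  squared group t with (1, n−3) df. The inverse transform (y → 1/y) is the
  skew remedy the original analysis used; it requires strictly positive
  outcomes.
- **Regression:** both variables z-scored, so β is the Pearson correlation;
  f² = R²/(1−R²); residual normality flagged by Shapiro–Wilk at 0.05. A
  perfect fit is rejected (f² undefined).
- **Logistic:** maximum-likelihood binomial fit with a Wald p. With ~15
  patients the Wald and likelihood-ratio p-values are both unstable;
  Wald is reported because that is what an odds-ratio-plus-p presentation
  implies. Complete or quasi-separation raises an explicit error.
- **Multiple testing:** none is applied anywhere, matching the original
  analysis. With six group comparisons and six regressions at α = 0.05,
  some nominally significant results are expected under the global null;
  readers of the report should treat per-row significance accordingly.

## Synthetic cohorts

**Marginals.** Each variable in each group is a *censored (clipped) normal*:
a latent normal draw clipped to the variable's support, with the latent
(μ, σ) solved (closed-form censored moments + least squares) so the clipped
draw has exactly the published group mean and SD. Censoring rather than
renormalized truncation is a deliberate choice with three reasons. First,
feasibility: several published (mean, SD) pairs are unattainable by any
renormalized truncated normal on the same support (on [0, 100] the largest
attainable SD at mean 81.49 is ≈ 17.5, against a published 21.67; similar
failures occur for heading direction, flare accuracy, and the detour score,
whose SD is twice its mean next to a hard zero bound). Second, realism:
percent-correct scores genuinely pile up at the 100% ceiling and
disorientation scores at exactly zero; a censored latent-propensity model
reproduces those point masses. Third, necessity: exact zeros on both routes
are what make composite = 1 — and hence a non-empty low-risk class —
possible; without them the logistic step would be degenerate by
construction. Zero-SD variables (controls' original-route score) are
constants.

**Dependence.** A Gaussian copula on the latent normals couples wayfinding
distance with duration (ρ = 0.8) and both with the detour-route score
(ρ = 0.55 and 0.44), emulating the one published cross-test relation
(R² ≈ 0.29 between wayfinding distance and the composite score);
ρ = 0.55 ≈ √0.29 is an assumption, not an estimate, and censoring attenuates
the observed correlation below it. All other variables are independent —
the true joint structure is unknown.

**Cohort mechanics.** Defaults are the published tables: 21 controls, 16
patients, two patients missing the wayfinding level, one missing the detour.
The map-view duration (ANCOVA covariate) is not published; controls
45 s (SD 25), patients 75 s (SD 45) on [5, 600] s are the package's
invented, plausible values. The wayfinding support floor is 0.2 — a
completed level cannot involve travelling a small fraction of the reference
path — which also keeps the inverse transform away from its singularity. A
single study seed fans out through per-participant substreams
(`SeedSequence([seed, group, index])`), so enlarging the cohort never
perturbs existing participants.

**Event-level walks.** The walk generator plants Bernoulli(p) wrong turns
per evaluated intersection and Poisson(rate × km) hesitations on a synthetic
street grid whose route intersections all have off-route branches (detour
branches are two deep, so a second consecutive wrong turn and reset can
occur). Planted wrong turns are exactly re-detected by the detection
routine — a round-trip property the tests enforce. Default profiles
(patients: p = 0.02, 0.23 hesitations/km on the detour; controls nearly
event-free) match the published component means under the split
normalization.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: real street networks and their heterogeneous route
lengths; within-participant correlation between the VST components;
disease-severity gradients; discrete trial-level structure in the cohort
table's VST columns (the score-level generator draws the score directly);
and right-skewed wayfinding distributions — the censored-normal marginals
are near-symmetric, which makes the inverse-transform ANCOVA noticeably
noisier on synthetic cohorts than it evidently was on the real data.

One fidelity consequence is worth stating plainly: the generator holds the
published flare-accuracy contrast (2.30 vs 2.12, common SD 0.54, d ≈ 0.33)
as a *true* group difference, because the published means are its
calibration targets. The original study's flare comparison was
non-significant at n = 21/16, where power for d ≈ 0.33 is ~15–20%; any
faithfully calibrated cohort large enough to estimate means precisely will
therefore declare the flare difference significant. The published flare null
is a small-sample power outcome, not an invariant of the data-generating
process, and no generator calibrated to the published table can make it
both.

## Numerical choices

- Censored-moment matching runs on (μ, log σ) with relative residuals and a
  1e-6 acceptance threshold; solutions are cached per (mean, SD, bounds).
- The latent correlation matrix is eigenvalue-checked and Cholesky-factored
  with a 1e-12 jitter.
- Rank-sum p-values switch from exact to asymptotic above 25 pooled
  observations or in the presence of ties.
- Composite/risk comparisons use the 1e-9 tolerance noted above; all file
  outputs are sorted by participant id so repeated runs are byte-identical.

## Problem sizes used in the test suite

Large-sample checks use 5,000–10,000 simulated participants for law-of-large
numbers assertions, 20 cohorts of 200/group for calibration fidelity, and
n = 1000–2000 for regression/logistic parameter recovery — sizes at which
the Monte-Carlo error of each assertion is several times smaller than its
tolerance.
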