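# Methods

## The prediction model

Central vault is modelled as an affine function of the ICL length and
three UBM-derived biometric covariates:

```
vault (μm) = β0 + β1·size + β2·STS_h + β3·LT + β4·STS_v
β = (−1369.05, +657.121, −287.408, −432.497, −137.33)
```

The coefficients are taken as given (the package validates and applies
the model; it does not refit it, except as a test oracle). Because the
model is affine, the effect of a size step is biometry-independent:
+329 μm for 12.1→12.6 mm and 13.2→13.7 mm, +394 μm for 12.6→13.2 mm
(rounded from 657.121·Δsize). Predictions are kept unrounded internally
and rounded half-away-from-zero to integer μm only at reporting
boundaries. A negative predicted vault is a legitimate numeric output of
the formula (it is unbounded below); it simply can never be in-window.

Input validation is strict rather than forgiving: sulcus-to-sulcus
diameters outside (8, 16) mm or lens thickness outside (2.5, 6) mm raise
an error naming the offending field. Silent clamping of implausible
biometry would corrupt downstream statistics invisibly.

## Size selection

All four manufactured lengths are evaluated. Sizes predicting inside the
target window (default 300–700 μm) form the feasible set, which is always
a contiguous run because predictions increase strictly with size. The
selected size is the feasible one predicting nearest the window center
(default 500 μm, the midpoint), ties broken toward the smaller size since
the severest complications accompany excessive vault. The window center
is configurable because the optimum inside the window is a clinical
judgment, not a property of the model.

When no size is feasible the boundary-nearest size is returned flagged
`in_window=False` rather than raising, so cohort pipelines can count
exclusions.

An opt-in adjustment reflects documented clinical practice for eyes with
an anteriorly positioned ciliary body (a feature associated with
higher-than-predicted vaults): when enabled and a smaller feasible size
exists, the smallest feasible size is chosen — the conservative reading —
and the result is flagged `adjusted_for_feature=True`.

## Outcome classification

Achieved vaults are classified low (< 200 μm), normal (200–800 μm
inclusive) or high (> 800 μm); the clinical definition is stated on
integers, and this is its real-valued generalisation. Prediction errors
(actual − predicted) are bucketed at ±300 μm with strict inequalities:
`overestimated` below −300, `underestimated` above +300, `within`
otherwise (so an error of exactly ±300 μm is within).

## Agreement statistics

Bland–Altman analysis of d = actual − predicted: mean, sample SD (n−1
denominator — at stratum sizes of ~200 the n vs n−1 distinction is below
printed precision, but it must be fixed for exact tests), 95% CI of the
mean = mean ± 1.96·SD/√n, and 95% limits of agreement = mean ± 1.96·SD.
The z multiplier is used for both intervals, consistent with the LoA
definition. Quartiles use linear interpolation between order statistics.
Strata with fewer than two eyes cannot contribute an SD and are skipped
with a warning. The overall row of every table pools the raw data; it is
never an average of stratum rows. Optional Bland–Altman plots (difference
vs pairwise mean, dotted mean line, dashed LoA lines) are written per
stratum; only the underlying numbers are tested.

## Fisher exact test

Feature-by-error-group 2×2 tables are tested with the exact
hypergeometric test. The two-sided p-value follows the probability-mass
convention — the sum of point probabilities not exceeding the observed
one, with a 1+1e-7 relative tolerance when comparing probabilities —
which is the dominant convention (SPSS, scipy) for "Fisher exact"; mid-p
and doubling conventions give different values and are deliberately not
offered. Point probabilities are evaluated through
`scipy.stats.hypergeom` (log-gamma based), keeping tables with totals in
the hundreds exact to double precision. The test suite pins the
implementation against exhaustive rational-arithmetic enumeration of the
support.

## Synthetic cohorts

The generator emulates the validation population: biometry drawn from
normal marginals (horizontal STS 11.54 ± 0.41 mm, vertical STS
11.96 ± 0.43 mm, LT 3.67 ± 0.23 mm, ACD 3.24 ± 0.23 mm, WTW
11.61 ± 0.38 mm) truncated to the validity ranges by rejection (under the
defaults, rejection discards well under 1% of draws). Only the
horizontal–vertical STS coupling is modelled (default ρ = 0.7, a
configurable placeholder — the true covariance structure of the
population is unreported); other variables are independent. Season labels
are drawn with weights proportional to the study's per-season eye counts.

Achieved vault is generated as

```
actual = selected prediction + noise_mean + Σ feature effects + N(0, noise_sd),  floored at 0
```

with `noise_mean = 6` μm and `noise_sd = 176` μm matching the observed
overall mean and SD of prediction error. The floor mirrors the clinically
observed vault-disappearance cases. UBM features are independent
Bernoulli draws; their vault offsets (wide ICA −250, iris concavity −250,
anterior ciliary body +250, cyst +150 μm) are **synthetic calibration,
not estimates** — only the directions of effect are clinically
documented — chosen so feature-bearing eyes preferentially populate the
large-error groups. Cohort-wide prevalences (4%, 1.5%, 4%, 2%) are
likewise choices: the source data report feature counts only within the
large-error groups.

What passing tests on these cohorts show is that the pipeline's
*arithmetic and plumbing* are correct under realistic marginals; they do
not show that the model achieves any particular accuracy on real eyes,
because the generator assumes the model is true by construction.

### Known limitation: in-band fraction

Because the four sizes are ~330–394 μm apart while the window is 400 μm
wide, the *selected* prediction is spread nearly uniformly over
300–700 μm (SD ≈ 111 μm), noticeably wider than the clinical cohort's
predicted-vault SD of ~95 μm. Combined with a Gaussian 176 μm error, the
expected fraction of synthetic vaults in the 200–800 μm band is ≈ 0.84 —
below the ~93% achievement rate reported clinically. Reproducing that
rate would require both a more concentrated predicted-vault distribution
and a leptokurtic error model (narrow core plus feature-driven tails),
neither of which is identifiable from the published summary statistics.
The generator therefore under-reproduces the headline rate by design
honesty rather than by recalibrated noise, and the corresponding
bracketing check in the acceptance suite documents this gap.

## Refitting as an oracle

`refit_linear_model` recovers the five coefficients by OLS
(`numpy.linalg.lstsq`, QR-based — numerically safer than literal normal
equations, same estimator; statsmodels provides the independent
standard-error route in tests). Zero-vault eyes are excluded before
fitting: a floored vault is a censored observation, and including such
eyes biases every coefficient (with random size assignment ~11% of eyes
censor, shifting the size coefficient by ~10 SE). On noise-free cohorts
with randomly assigned sizes the fit interpolates the generating
coefficients to 1e-6; with realistic noise and rule-based sizing
(censoring ≈ 0.7%) each coefficient lands within ordinary OLS sampling
error of its generating value.

## Pipeline and determinism

`run_validation` is deterministic given the configuration: one seed
drives biometry, features, seasons and noise through a single
`numpy.random.Generator`, and the report metadata records the seed and a
configuration hash. Rows failing biometry validation are dropped with
per-row diagnostics; a file with no valid rows is an error. Inputs
without achieved vaults produce a sizing-only report with the agreement
and feature sections marked absent. Eyes-within-subject clustering is
ignored throughout (eyes are the analysis unit); the report metadata
carries this as a known limitation.

Default problem sizes in the test suite (cohorts of 120–5000 eyes, 20
seeds for distributional checks) are chosen so distributional assertions
sit well inside binomial/CLT tolerance at those n.
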