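# Methods

## Count model

Each flow's homopolymer length (HPL) `N` is modeled as a hurdle mixture:
a Bernoulli component for the zero/positive split (probability `pi` of a
positive flow) and, conditional on a positive, a zero-truncated weighted
Poisson (ZTWP) distribution.  The weighted Poisson density is

    f_WP(n; lambda, theta) = w_n e^{-lambda} lambda^n / (W n!),
    w_n = exp(-theta (lambda - n)^2),

with normalizing constant `W = sum_{n>=0} e^{-lambda} lambda^n w_n / n!`.
The distance weights pull mass toward `n ≈ lambda`, so `theta > 0` models
the underdispersion of positive flow counts; `theta = 0` is the ordinary
Poisson and is admitted throughout as a testable limit.  `theta` is a
single global parameter; `pi` and `lambda` vary per flow through
covariates.

Series are summed until the next raw term falls below `1e-15` times the
running sum, with a hard cap of 200 terms (rates in flow data rarely
exceed ~10, and the terms decay factorially).  Zero truncation is
normalized against the sum of the *positive* raw terms rather than
`1 - f_WP(0)`, which stays accurate when the zero class carries nearly
all weighted-Poisson mass (small `lambda` with large `theta`).  Moments
are computed by enumeration over the same truncation grid, so they agree
with untruncated closed forms where those exist.  Reported probability
vectors span HPL `0..n_max` with `n_max = max(training HPL) + 3`,
floor 12, renormalized over the reported range.

## Covariates

Per flow: the flowgram value; the log2 raw intensity, optionally centered
by a read-specific baseline (median log2 raw intensity of the read's
flows with flowgram < 0.5, i.e. presumed zero flows, falling back to the
read median when fewer than 4 exist); cumulative sums of both over
strictly earlier flows; and flowgram values 1, 4 and 8 flows before and
after (same-nucleotide context sits 4 and 8 flows away in a four-flow
cycle).  Lags and leads beyond the read boundary are filled with 0.0, the
natural background flowgram.  Default predictor sets: the binomial
submodel uses {fg0, lraw0, cum_fg, fg_lag1, fg_lead1}; the Poisson
submodel additionally uses the lag/lead-4 and -8 terms.  Both sets are
configurable and the raw-intensity term can be dropped.

## Additive submodels and fitting

`logit(pi)` and `log(lambda)` are additive in centered cubic B-spline
smooths (basis dimension 10 per covariate, knots at quantiles of the
distinct training values, linear extension beyond the knot range).  The
difference penalty of order 2 is divided by Greville-abscissa spacings,
so its null space is exactly {constant, linear in the covariate}: at
infinite smoothing each smooth collapses to a straight line and the fit
matches a plain GLM on the same covariates.  Covariates with too few
distinct values degrade to an unpenalized linear term with a warning.

Both submodels are fitted by penalized IRLS.  The binomial submodel uses
the standard logistic working weights; the ZTWP submodel obtains score
and curvature in `eta = log(lambda)` by central numerical differences
(step 1e-4) of the exact ZTWP log-density, with `eta` clipped to
[-10, 5] (a warning notes when the clip is active at the optimum).  Step
halving enforces a monotone non-increasing penalized deviance; the fit
converges when the relative change falls below 1e-6 (at most 100
iterations; non-convergence is flagged but the fit is returned).
Quasi-separation — plausible here, because zero and positive flows are
nearly separable in the flowgram — triggers a ridge fallback (an extra
1e-6 on the penalty) with a warning.

A single smoothing parameter per submodel is selected by deviance-based
GCV on a log-spaced grid `1e-4..1e4`.  `theta` is estimated by profile
likelihood over the grid {0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6}, refined by
golden-section search in `log theta` (tolerance 1e-3) between the
neighbors of the grid argmax.  When the profile is still rising at the
top of the grid the bracket expands geometrically until the likelihood
turns over; without this the boundary estimate widens every per-flow
probability vector and systematically understates the quality of
confident calls.  Smoothing selection and dispersion estimation alternate
once: the penalty is chosen at a mid-grid `theta`, `theta` is profiled at
that penalty, and the final submodel is refitted.  Fits are deterministic
given data; the fitted model serializes to a versioned JSON document with
a bit-exact round trip.

## Calling and quality scores

Per flow, plugging the fitted `pi`, `lambda` and `theta` into the hurdle
density yields the probability vector over HPL `0..n_max`; the call is
the argmax, with ties broken toward the smaller HPL (conservative against
overcalls).  For the k-th base of a called homopolymer (k = 0 is the
no-base position of a zero call), scores derive from the error tails:
`QS_overcall = -10 log10 P(HPL < k)` and
`QS_undercall = -10 log10 P(HPL > k)`, with tails floored at 1e-15 before
the log.  The signed score is the rounded smaller of the two (half away
from zero), capped at 40, negative when the undercall score is strictly
smaller.  Per-base Phred scores carry the overcall score trimmed to 0..40
and travel in FASTQ (Sanger, Phred+33); signed and per-position scores go
to a TSV sidecar, since FASTQ cannot encode signs.  Probabilities below
1e-15 print at the floor in output files; raw values are used internally.

## Synthetic data

The signal-based simulator emulates the salient structure of flow data:

* reference sequences with i.i.d. geometric homopolymer lengths
  (support >= 1, default p = 0.6, mean 1.67) and each run's nucleotide
  uniform among the three differing from the previous run;
* the deterministic flow decomposition along the fixed order (default
  TACG), padded with zero flows to the cycle boundary — about half of all
  flows are zero flows under this law;
* zero flows: flowgram `|Normal(0, 0.12)|`, raw intensity
  `2^Normal(6, 0.7)` (background optical noise);
* positive flows with HPL n: flowgram `n + Normal(0, 0.12 sqrt(n))`
  floored at 0, raw intensity `1000 n^0.8 LogNormal(0, 0.3)`.

The sqrt-growth of flowgram noise and the `n^0.8` attenuation make
adjacent HPL signal distributions overlap increasingly with length, so
miscall rates rise with HPL and reach several percent by HPL 7 — the
defining error phenomenon.  Defaults are 1000 reads of ~100 bases
(~120 flows per read), a desk-scale stand-in for a training run.  One
seed drives everything; per-read substreams are derived by counter, so a
read's data do not depend on how many reads precede it.

What the simulator does *not* emulate: carry-forward/incomplete-extension
chemistry, spatial plate effects, base-composition bias, and the vendor's
preprocessing chain (its flowgram is HPL-scaled by construction).  Tests
passing on this generator therefore demonstrate correctness of the model,
fitting and scoring machinery — not accuracy on any particular instrument
run, for which the model should be retrained on reference flows.

The model-based mode draws counts exactly from a specified hurdle model
(`pi` and `lambda` functions of a covariate, global `theta`, inverse-CDF
on the truncated table) and is the ground truth for parameter-recovery
and calibration tests.

## Evaluation

Truth pairing is flow-aligned (the simulator knows every flow's reference
HPL), avoiding an embedded aligner: a call below/above the reference HPL
is an undercall/overcall, and the k-th called base of a flow is an
overcall base when k exceeds the reference HPL.  Quality-score
calibration groups called bases by integer predicted Phred score;
the observed score is `-10 log10(overcall rate)` in the group.  Both
predicted and observed scores are trimmed at the cap (40) — otherwise a
group at the cap with a single rare error could report an observed score
above 40 and spuriously appear miscalibrated — and zero-error groups are
reported at the cap with a flag.

## Problem sizes and numerical choices

The test suite exercises recovery at 50,000 model-based flows
(`theta = 0.4`, smooth `pi(x)` and `lambda(x)`) and an end-to-end run of
1000 training plus 2000 evaluation reads (~360k flows), sizes at which
the penalized fits and the dispersion profile are stable on a single
core.  Tie-breaks, floors and caps are fixed as described above; rounding
of reported scores is half-away-from-zero, which reproduces every
worked-example score cell (pure truncation would too for some cells, but
not for 7.696 -> 8).

## Known limitations

* One global `theta` cannot track noise whose width varies with HPL (the
  simulator's sqrt-law); the profile estimate settles on a compromise
  value, which is why per-group calibration is checked at a 2-unit
  tolerance rather than exactly.
* The binomial submodel is near-separable on clean data; its fitted
  probabilities in the transition region depend on the ridge fallback.
* Vendor binary formats (SFF) are not read; the documented flow-table TSV
  is the ingestion contract.
* Intercepts are global constants; flow-level variation enters only
  through covariates (anything else would be unidentifiable).
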