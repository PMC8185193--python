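# Methods

## The model chain

The package predicts the fertility cost of a radiotherapy plan in four
steps, each exposed as a separately testable function.

**1. Dose summary.** A plan's ovarian dose enters as a dose-volume
histogram (DVH). The canonical internal form is a *differential* DVH with
half-open bins `[dᵢ, dᵢ₊₁)` in Gy and relative (fractional) bin volumes;
cumulative exports are converted by successive differences, and absolute
(cm³) volumes are normalized with the total retained as a weight. Left and
right ovary are merged into a single "both ovaries" histogram, weighted by
absolute volume when known and equally otherwise (with a logged warning —
planning exports often omit structure volumes). Doses are total physical
dose; no fractionation (EQD2) correction is applied anywhere.

**2. Follicle survival.** The resting non-growing follicle (NGF) pool
survives a uniform dose *z* with percentage

    log10 g(z) = 2 − 0.15 z ,

i.e. g(0) = 100 % and a tenfold loss every 6.67 Gy; the implied median
lethal dose is (2 − log₁₀ 50)/0.15 ≈ 2.007 Gy. For a non-uniform
distribution the survival is volume-averaged over the DVH rebinned to
0.1 Gy:

    g = Σᵢ 10^(2 − 0.15·½(dᵢ + dᵢ₊₁)) · vᵢ / v_total .

Because 10^(−0.15 z) is convex, this DVH average is always at least the
point survival at the mean dose (Jensen's inequality): dose inhomogeneity
*spares* follicles relative to a uniform dose with the same mean. This is
why the analysis must run on DVHs, not on mean doses.

**3. Reserve and effective reproductive age.** The normal decline of the
NGF count with age follows

    log10 n(age) = −0.00019 · age^2.452 + 5.717

(≈ 5.2·10⁵ follicles at birth). A woman treated at age *a* retains
n(a)·g/100 follicles; her *effective reproductive age* is the closed-form
inverse

    r = ((5.717 − log10 n) / 0.00019)^(1/2.452) ,

exact to ≈ 1e-11 years in round-trip (a bisection oracle in the test suite
confirms the closed form; no root-finding is used at run time).

**4. Time to menopause.** With 50.4 years as the average age at natural
menopause, the remaining time is t = max(0, 50.4 − r). Negative predicted
times are floored to zero *per patient before any averaging*; this is what
makes cohort means and SDs collapse to exactly zero at high treatment ages
and what drives the vanishing between-arm difference there. The model has
no separate "minimum reserve at menopause" threshold — the 50.4-year
subtraction is the whole rule. The survival and reserve models use base-10
logarithms as printed above; the hormone model's natural log is unrelated.

## Paired comparison and the sign test

Both plans of each patient are evaluated identically, so each endpoint
yields one within-patient difference (IFRT − ISRT for doses; ISRT − IFRT,
a *gain*, for surviving NGF and time to menopause). Endpoints are bounded,
skewed and floored, so significance uses the exact sign test: differences
within a tolerance of zero are excluded as ties, and

    p = min(1, 2·P[Bin(m, ½) ≥ max(k, m − k)])

on the m remaining differences (k positive); m = 0 gives p = 1. The
two-sided value is the doubled larger tail, capped at one — with a
symmetric null the doubled tail equals the sum of both tails, and it is the
convention that reproduces the characteristic p-value ladder (2·(½)¹³ ≈
0.000244 for 13 unanimous pairs, 0.125 at four effective pairs, 1.0 when
everything ties). The tie tolerance is 1e-9 for dose endpoints and 0.005
years (half the two-decimal reporting unit) for time endpoints, so two
times equal after rounding count as a tie. Time endpoints at high ages lose
pairs to the zero floor, which is why their p-values rise toward 1 even
though every unfloored pair still favors the smaller target. No
multiplicity adjustment is applied across the 16 age rows.

## Hormone regression

FSH and LH (U/L) are log-transformed with the natural log and fitted
separately on a shared design: intercept; age z-scored over the cohort
(the z-scoring statistics are stored in the fit so prediction grids are
reproducible); sex coded ±½ (female positive; 0/1 dummy coding available
and recorded verbatim in the fit's coding note); the age×sex product; and
two 0/1 indicators, chemotherapy (ABVD = 1 vs 2+2 = 0) and RT field
(infradiaphragmatic = 1 vs supradiaphragmatic = 0). Putting both treatment
factors on the same 0/1 column scale makes their coefficients directly
comparable effect sizes. Fitting is least squares via statsmodels WLS with
default unit weights; a per-record weight column is accepted so any
weighting scheme can be reproduced, but none is imposed because no
canonical scheme exists for these data. Standard errors use the unbiased
residual variance and p-values the t distribution on n − p degrees of
freedom. Cohort eligibility (women < 40, men < 50 years at diagnosis) is
enforced by the record validator.

## Synthetic cohorts

The generators exist so that every pipeline stage, including the
end-to-end report, is exercisable and testable without patient-level data.
They emulate *structure*, not anatomy.

**Paired DVH cohorts.** Each organ's DVH is a two-component mixture: a
fraction *f* of the volume near the 30 Gy prescription (in-field) and the
remainder in a low-dose bath (0.2–3 Gy by default) — the minimal shape
capturing how arc-therapy plans trade a conformal high-dose region for a
widespread low-dose wash, which is exactly the feature the convex survival
curve is sensitive to. Per-patient target mean doses are drawn from
distributions calibrated so the *cohort* mean and SD equal configured
targets; defaults are ovarian mean dose 15.13 ± 6.34 Gy (IFRT) and
7.44 ± 5.64 Gy (ISRT), with analogous per-organ defaults for the other
organs at risk (maximum dose for the spinal cord). The calibrated family is
a truncated normal on [0, 1.05 × prescription] whose location and scale are
solved numerically so the moments *after* truncation hit the targets; when
the requested coefficient of variation exceeds what that family can reach
(femoral-head doses with SD ≈ mean), a gamma conditioned on the same
support is calibrated instead. The two techniques are coupled
comonotonically — one shared uniform per patient and organ mapped through
both quantile functions — which preserves both marginal distributions while
enforcing the hard constraint that the smaller target never increases the
dose (ISRT ≤ IFRT within every patient). Given the target mean *m* and the
shared bath/spike doses, *f* is solved from m = f·s + (1−f)·b, so the
per-patient mean dose is exact up to 0.1 Gy bin-midpoint snapping. A single
integer seed drives one named substream per patient, so enlarging a cohort
never reshuffles existing patients.

What the generator does *not* reproduce: real DVH shapes (mid-dose
gradients, inter-organ correlation), and consequently the cohort-mean
surviving-NGF percentages of a clinical plan set — the two-component shape
concentrates volume in the bath, so its surviving fractions run higher than
clinical values at the same mean dose. Passing tests therefore demonstrate
correctness of the analysis chain and the qualitative dose→survival→time
pattern, not agreement with any clinical cohort's table values.

**Hormone cohorts.** Covariates are drawn per configured frequencies —
51.7 % female, 50 % ABVD, 4.2 % infradiaphragmatic RT, ages uniform within
the eligibility windows — and log-scale outcomes are the design's linear
predictor under configurable generating coefficients plus Normal(0, 0.8)
residuals, exponentiated back to U/L. The 0.8 log-scale residual SD is in
the middle of the 0.5–1.6 range seen in published stratified log-hormone
SDs. Because the true weighting and exact sex coding behind published
coefficient tables are not recoverable, recovery tests target
self-consistency (refits recover the generating values within Monte-Carlo
error), not any published row.

## Numerical choices and degenerate inputs

- Rebinning apportions each input bin's mass to output bins by overlap
  length and renormalizes the overlap fractions, so total volume is
  conserved to ≤ 1e-9 and the mean dose moves by at most half a bin width.
- Differential CSV rows give the bin lower edge; bins are contiguous, and
  the final upper edge extends by the last spacing (0.1 Gy for a
  single-row organ). Cumulative grids with residual volume at the top edge
  get one extra conserving bin.
- All-zero DVHs are rejected wherever a mean, max or survival would divide
  by zero; negative doses are rejected rather than clamped; survival is
  capped at 100 % only as a guard against floating-point overshoot.
- Sign-test p-values come from the exact binomial survival function, not a
  normal approximation; single-observation and all-tie inputs give p = 1.
- Single-record strata report SD 0 with an explicit `sd_defined = False`
  flag; empty strata are emitted with n = 0 and blank statistics.
- Rank-deficient hormone designs (e.g. a single-level factor) raise an
  error naming the collinear columns rather than silently dropping terms.
- Report tables round to two decimals with a decimal point; all tests run
  on unrounded values.

## Problem sizes

The test suite and the acceptance script run the generator at the sizes the
analyses are designed for: 13 patient pairs for plan comparisons (with
2,000 pairs, ovaries only, for the calibration check), 499-record hormone
cohorts with 200 replicates for parameter recovery, 1,000 grid points for
the inversion bound, 100 random DVHs for the summation oracle, and full
enumeration of sign patterns up to m = 12. The whole suite completes in
well under a minute.
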