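# Methods

This note documents the statistical models, the numerical choices and the
known limits of the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model and cleaning

Input is a long-format table with one row per measurement
(`subject_id, date, sex, age, analyte, value`). Repeat testing is itself a
weak disease signal, so `deduplicate_first` keeps only the earliest-dated
row per `(subject_id, analyte)`; ties on the date are broken by input
order so re-runs are byte-identical. Keying on `(subject_id, analyte)`
rather than subject alone is deliberate: for panel data (one CBC per visit)
the two coincide, and per-analyte keying generalizes to mixed extracts.
Stratification is by sex with an inclusive age floor (default 18 years);
rows with unparseable sex are dropped with a logged warning rather than an
error, since stray codes are routine in hospital extracts.

Shape summaries use the population-moment estimators: skewness
`m3/m2^1.5` and **non-excess** kurtosis `m4/m2²` (3 for a Gaussian). The
non-excess convention matters: the pipeline's "is the processed data
roughly Gaussian?" judgement reads kurtosis ≈ 3, not ≈ 0. At the sample
sizes this package targets (10⁴–10⁵) the small-sample bias corrections
would change nothing past the third decimal.

One quantile rule is used everywhere (moments, Tukey fences, Freedman–
Diaconis widths): linear interpolation at rank `p(n−1)+1`, numpy's
default. The nonparametric *estimator* is the one exception — it uses the
CLSI rank convention `p(n+1)` — because that convention is part of the
method being implemented, not a house style.

## Normalization

Two transforms are supported as fitted, exactly invertible objects: the
natural log (base e; the base is a convention choice and e keeps every
inverse a plain exponential) and the one-parameter Box-Cox transform. λ is
fitted by golden-section search on the profile log-likelihood over
[−3, 3] to an absolute tolerance of 1e-4; the objective is smooth and
unimodal at these sample sizes, so nothing fancier is warranted. No
two-parameter (shifted) Box-Cox is offered: CBC-like analytes are strictly
positive and a location shift would be unidentifiable extrapolation.
λ is fitted once per stratum on the post-deduplication, pre-outlier-removal
data and reused for flagging and estimation, so all 30 matrix cells of one
stratum share a single normalization per transform kind. An `identity`
transform exists for raw-scale work; it is not part of the 2×3×5 matrix.

Round-trip identity (forward then inverse) is enforced to 1e-9 relative in
the tests for λ ∈ {−1, −0.5, 0, 0.5, 1, 2}; λ recovery on power-normal
data at n = 50,000 is within 0.15 of the generating exponent.

## Outlier rules

All three rules return positional masks so flags computed on the
normalized scale (as the matrix runner always does) can be applied to
either scale.

* **Tukey fences** (`k = 1.5`, single pass): on a Gaussian the fences sit
  at ±2.698 SD, so the expected elimination rate is 2Φ(−2.698) ≈ 0.70%.
* **Iterative mean ± 3 SD**: strict inequality (constant samples are a
  fixed point), SD with the n−1 denominator, iterated until a pass flags
  nothing; on a Gaussian it removes ~0.3–0.4%.
* **Reed–Dixon**: an extreme is dropped when its gap to the adjacent order
  statistic exceeds one third of the current range; the rule is iterated,
  examining the larger endpoint gap first and recomputing the range after
  each removal. Whether one iterates or stops after one pass is
  unobservable on large continuous unimodal samples — the extreme-gap to
  range ratio is far below ⅓ and the rule removes *nothing* (0%), which is
  exactly its documented conservatism.

This fixes the elimination-rate ordering Tukey > iterative 3SD >
Reed–Dixon (= 0) on large unimodal samples, which the tests assert at
n = 100,000. A practical corollary, pinned as an acceptance quantity: a
95% nonparametric interval computed after Tukey removal covers only ~94%
of the population.

## The five estimators

**Parametric.** `mean ± 1.96·SD` (n−1 denominator) of the retained
normalized values, limits back-transformed. 1.96 — the conventional
rounded multiplier — is used everywhere in the package, not 1.959964.

**Nonparametric.** Ranks `0.025(n+1)` and `0.975(n+1)` with linear
interpolation, clamped to the observed range; CLSI's minimum of 120
observations is enforced by default and configurable.

**Hoffmann.** Sorted normalized values against standard-normal quantiles
of Hazen plotting positions `(i − 0.5)/n`; OLS through the points whose
plotting position lies in the central window (default 25th–75th
percentile, configurable), evaluated at `z = ±1.96`. The window replaces
the traditional visual selection of the linear segment with a documented,
reproducible default; a user who wants the by-eye workflow passes a
different window.

**Bhattacharya.** Histogram with bin width `h` (user-set, or
Freedman–Diaconis rounded to one significant figure); log differences
`y_i = ln f_{i+1} − ln f_i` regressed on bin midpoints. For a Gaussian
component `y` is linear with slope `b = −h/σ²` and x-intercept
`x₀ = μ − h/2`, so `σ = √(−h/b)` and `μ = x₀ + h/2`. Automatic segment
selection scans contiguous runs of positive-count bins and keeps the
window (length ≥ 4 preferred, ≥ 3 required) with negative slope maximizing
`R²·length`; a manual `(start_bin, end_bin)` reproduces a recorded by-eye
analysis. The OLS is unweighted by default — matching the
least-squares-through-chosen-points practice of the classical tools — with
inverse-variance count weighting available as an option. Near-empty tail
bins carry a small log-count bias that can depress σ̂ by ~1%; at the
package's target n this stays well inside the 2% recovery envelope the
tests enforce.

**Kosmic.** The healthy fraction is modeled as Gaussian after a Box-Cox
transform. λ is estimated once on the central 80% of the data (robust to
tail contamination) and held fixed. A grid of truncation-quantile pairs —
lower ∈ [0.05, 0.30], upper ∈ [0.70, 0.95], step 0.01 — is searched; per
candidate interval a Gaussian is fitted by truncated-normal maximum
likelihood (Nelder–Mead on (μ, log σ); the truncated likelihood depends on
the data only through n, Σx, Σx² inside the interval, so 676 fits are
cheap) and scored by the KS distance between the truncated model CDF and
the conditional empirical CDF, **divided by the fraction of data in the
interval**. The normalization is essential: the raw KS distance always
favors narrow intervals (two free parameters fit any short CDF segment),
which lets σ̂ drift low; dividing by the data fraction prefers the widest
interval the model still explains, the same idea as the original
truncation-point cost. The best fit's `μ ± 1.96σ` is back-transformed.
Accuracy on clean power-normal data at n = 50,000 is typically within 1%
of the true limits (median over seeds) and bounded by ~2% — the
information floor of a truncated fit plus central-80% λ bias — and under
10% one-sided contamination its contaminated-side limit beats the
nonparametric one in ≥ 18/20 seeded replicates.

## Matrix wiring

For each of the 30 cells: fit the transform on the full stratum → flag
outliers on the *transformed* values → parametric/Hoffmann/Bhattacharya
consume the retained transformed values and back-transform their limits;
nonparametric/kosmic consume the retained original values. (The
alternative reading — flags on the raw scale — is noted but not adopted;
flagging on the normalized scale makes the three Gaussian-assuming rules
well-behaved for skewed analytes.) Estimator failures are recorded per
cell, never fatal to the matrix, and excluded — with an explicit
denominator — from qualification rates.

## Evaluation

`d%` is signed and relative to the reference limit; `SD_RI` is the
reference width over 3.92 (a central-95% Gaussian interval spans 3.92 SD);
`BR` is the signed limit difference over `SD_RI`; qualification is the
*strict* inequality `|BR| < 0.375`. Top-k ranking sorts ascending |BR| and
includes every combination tied with the k-th smallest value; output order
is tie-broken by label, but membership never depends on input order.

## Synthetic data

The generator emulates the structure the estimators assume: a power-normal
healthy core (so every target quantile is closed-form, and the kosmic
model is exactly right for the healthy fraction), Gaussian contamination
displaced by ≥ 3 healthy original-scale SDs (a clean separation knob), and
duplicate visits as fresh same-component draws with a later date. Presets
for the 8 CBC analytes × 2 sexes are calibrated by moment-matching the
median and IQR of typical adult physical-examination populations on the
transformed scale; the per-analyte exponents (0 for WBC, 0.2 for PLT, 1
for RBC/HCT, 1.3–1.8 for the left-skewed indices) are modelling choices
recorded in the preset table. Ages are uniform 18–79 metadata only — no
age trend is simulated — and pathological components are unimodal
Gaussians, so passing tests demonstrate recovery under the assumed mixture
model, not under arbitrary real-world shapes (multimodal pathology,
age-drifting means, analytical shifts).

## Problem sizes and determinism

Recovery tests run at the sizes where their tolerances are meaningful:
n = 100,000 for the five-estimator 2% envelope and coverage checks,
n = 50,000 for λ and kosmic recovery, n = 200,000 for moment/quantile
convergence (tolerances set at 3 order-statistic or moment standard
errors), 20 seeded replicates for the contamination comparison. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
identical specs yield byte-identical datasets, and a matrix re-run on the
same data is exactly reproducible.

## Known limitations

* The Hoffmann and Bhattacharya automations are faithful but *documented
  defaults* for steps the classical workflows performed by eye; different
  window/segment choices move the limits, which is part of what the
  30-combination comparison is for.
* The kosmic implementation follows the published idea (truncated
  power-normal, KS minimization) with its own documented grid and cost
  normalization; it is not a port of any existing tool.
* Bias metrics require strictly positive, non-degenerate reference limits;
  analytes spanning zero would need an additive offset upstream.
* One-sided heavy contamination above ~30% of the sample defeats every
  estimator here, including kosmic, whose truncation grid assumes the
  healthy mode dominates the central 40% of the data.
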