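# Methods

## Scope and data flow

`sensipod` covers the quantitative chain from raw nonanimal assay readouts to
a skin-sensitization point of departure and its comparison with in vivo
references:

1. **Endpoint derivation** (`dpra`, `keratinosens`, `hclat`, `mixtures`,
   `dose_response`): percent peptide depletion and TG 442C reactivity
   classes; KeratinoSens Imax/EC1.5 and the four-condition positivity call;
   h-CLAT CV75, the 1.2-fold dose series, EC150/EC200 and the minimum
   induction threshold; purity/weighted-MW concentration corrections for
   mixtures.
2. **In vivo reference curation** (`llna`): per-study EC3, Ryan screening of
   extrapolations, a study-quality checklist, and two aggregation approaches.
3. **Defined-approach prediction** (`ann`): the 5+2-hidden-node logistic
   feed-forward network trained by full-batch backpropagation with momentum,
   run as a 100-member random-initialization ensemble.
4. **Potency evaluation** (`potency`): raw-scale RMSE/MAE, log-scale
   benchmark metrics, GHS concordance, dose-per-area conversion and NESIL
   ratios.
5. **Synthetic ground truth** (`synthetic`) and **orchestration**
   (`pipeline`, `cli`).

## Threshold-crossing interpolation

Every derived concentration endpoint (EC1.5, CV75, EC150, EC200, EC3) is a
threshold crossing of a piecewise-linear interpolant of an ordered
concentration–response series. The in vitro endpoints are interpolated in
log₁₀ concentration — serial-dilution designs are geometric, and this is
standard TG 442D/E practice — while LLNA EC3 uses arithmetic concentration,
the long-standing LLNA convention. Both scales are available per call.

Scanning runs from the lowest concentration upward and the first event wins:
an exact hit at a tested concentration returns that concentration; a segment
straddling the threshold in the requested direction returns the interpolated
crossing. A series that is already beyond the threshold at its lowest tested
concentration returns "undefined" rather than extrapolating (conservative for
non-monotone series: the lowest crossing is the most potent interpretable
one). The implementation is validated against a brute-force dense-grid scan
of the same interpolant (10⁵ points plus the knots, so no grid cell straddles
a kink) to 0.1% relative error.

## Assay-specific choices

* **DPRA.** Positive if Avg.Lys.Cys > 6.38%, with TG 442C average-model bins
  (≤ 6.38 minimal, ≤ 22.62 low, ≤ 42.47 moderate, > 42.47 high). When the
  test article co-elutes with the lysine peptide, the TG 442C cysteine-only
  model applies (cutoff 13.89%; bins 13.89/23.09/98.24). Co-elution with the
  cysteine peptide leaves no applicable model and raises an error: the
  guideline defines no lysine-only model.
* **KeratinoSens.** A positive call requires Imax ≥ 1.5, viability > 70% at
  the lowest inducing concentration, **EC1.5 < 1000 μM**, and a
  dose-dependent increase. The < 1000 μM bound follows TG 442D. The guideline
  does not operationalize "dose-dependent"; here it holds when the tested
  concentration immediately above the EC1.5 crossing responds at least as
  strongly as the crossing itself, or when the Spearman rank trend of
  induction over non-cytotoxic concentrations is positive.
* **h-CLAT.** Positivity follows the two-independent-runs rule per marker
  with viability ≥ 50% at the qualifying concentration. Marker ECs are
  interpolated from the geometric-mean RFI across the qualifying runs (RFI is
  a ratio statistic; the geometric mean is the natural cross-run average),
  restricted to concentrations whose mean viability is ≥ 50%. MIT is the
  minimum of the defined ECs; a substance positive only below the lowest
  tested concentration is reported positive with MIT undefined.
* **Mixtures.** Weighted MW is the mole-fraction-weighted mean; a
  concentration prepared under a default-MW assumption is corrected by
  purity divided by (weighted MW / default MW). All reported concentrations
  are rounded to 3 significant figures at the reporting layer only.

## LLNA EC3 and reference aggregation

EC3 is interpolated linearly in concentration between the lowest bracketing
pair around SI 3. When no bracket exists: a rising sub-threshold curve is
extrapolated upward from the two highest points; a curve already above SI 3
at the lowest dose is extrapolated downward from the two lowest points (this
is precisely the situation the Ryan criteria police); a flat or falling
sub-threshold curve is a negative call. Extrapolated values are screened by
the Ryan criteria — lowest measured SI < 5; EC3 within 10-fold of the closest
tested concentration (the highest tested dose for upward, the lowest for
downward extrapolation); slope ratio (outer/inner slope over the three tested
concentrations nearest the extrapolation) ≤ 2 and non-negative. A study with
only two concentrations cannot be slope-screened and an extrapolated estimate
from it is rejected (conservative). Quality screening requires all eight
checklist attributes (topical application to both ears, draining-node
proliferation during induction, vehicle control, concentration/SI data,
in vivo radiolabel, no SLS enhancement, 3–4 day application); duplicate
studies are removed by the (chemical, SI-vector) key at ingestion.

**Approach 1** restricts to acetone / 4:1 acetone:olive-oil studies and takes
the lowest acceptable EC3; studies within 1.25-fold of the minimum are
treated as a tied set and reported as a range (midpoint used for metrics).
**Approach 2** averages all acceptable EC3 values with a 95% CI of
mean ± t₀.₉₇₅,ₙ₋₁ · sd/√n, lower bound censored at zero; n = 1 yields no CI;
negative studies contribute no EC3. The Student-t quantile is the default (a
normal quantile is available by configuration). On homoscedastic draws the
interval covers the true mean at the nominal 95%; on skewed lognormal
inter-study variability (CV 0.5, n = 9) the delivered coverage is ≈ 91–93%,
the familiar undercoverage of t-intervals on skewed data — the test suite
asserts the band the procedure actually delivers.

GHS classification: EC3 ≤ 2% → 1A, > 2% → 1B, negative → NC. The h-CLAT
potency category is strong at MIT ≤ 10 μg/mL, weak above.

## The neural-network defined approach

Architecture (fixed): input (2 or 3) → 5 → 2 → 1, logistic activations on
both hidden layers and the output. Inputs and the EC3 target are
log₁₀-transformed, then min–max mapped onto [0.05, 0.95] using training-set
extremes — the margin leaves the logistic output headroom to represent every
training target; the inverse transform is exact on the forward image.
Training minimizes mean squared error by full-batch gradient descent with a
momentum term (velocity = momentum·velocity − lr·gradient) for exactly
10,000 iterations. Defaults: learning rate 0.2, momentum 0.5, weights and
biases initialized uniformly on (−0.5, 0.5) from a seeded generator. These
give stable, near-converged fits at 10,000 full-batch iterations on scaled
data; at this learning rate roughly 5,000 iterations are needed before the
held-out fit stabilizes, which is why the fast test-suite configuration uses
5,000 iterations while the acceptance script runs the full configuration.
Backpropagation gradients are verified against central finite differences to
1e-6 relative error.

An ensemble trains `n_runs` (default 100) networks from per-run seeds spawned
deterministically from one master seed. The reported EC3 is the arithmetic
mean of per-run predictions on the raw percent scale (the "mean EC3"
convention), and the 95% CI is the 2.5th/97.5th percentile of the run
distribution — a distribution-free choice that needs no normality assumption
across runs. Runs producing non-finite weights are dropped; more than half
failing aborts the ensemble. Benchmarks (R², RMSE) are computed between
predicted and observed EC3 in log₁₀ space, the conventional scale for potency
models.

## Synthetic data

The generator emulates the structure of a DA training population, not assay
mechanism. True log₁₀ EC3 is uniform on [−3.0, 1.3] (≈ 0.001–20% w/v,
bracketing published isothiazolinone references). Monotone endpoint links,
calibrated so generated values bracket the observed isothiazolinone endpoint
ranges (depletions around 50%, MIT ≈ 1–12 μg/mL, Imax in low single digits):

* Avg.Lys.Cys = 100 / (1 + 10^(0.5·x)) + N(0, 3) %, clipped to (0.1, 100];
* MIT = 10^(0.5·x + 1) · 10^N(0, 0.2) μg/mL;
* Imax = 1 + 3·(1 − x/1.3) · 10^N(0, 0.2), floored at 1,

with x = log₁₀ EC3 and per-endpoint lognormal noise σ = 0.2 (log₁₀). The
75/25 train/test split is seeded. Simulated LLNA studies place the dose grid
at (0.25, 0.5, 1, 2, 4) × the nominal EC3, draw a study-level EC3 from a
*mean-preserving* lognormal (μ = −cv²/2, cv = 0.5) so the Approach-2 mean
targets the nominal value, and evaluate SI(c) = 1 + 2(c/EC3ᵢ)^h (h = 1 by
default, making interpolation exact on noiseless curves). Raw assay fixtures
are constructed so the endpoint calculators recover prescribed targets within
the dilution grid's interpolation error; infeasible targets (e.g. a MIT
outside the 1.2-fold dose window implied by CV75) are flagged, not shifted.

What passing synthetic tests shows — and does not. They establish that the
estimation machinery is unbiased and well-calibrated when the monotone link
and noise model hold: held-out RMSE_log10 ≈ 0.24 (≤ 2× the injected σ = 0.2)
and R² ≈ 0.95 on the 80-chemical population. Real assay endpoints carry
inter-laboratory variability, censoring at tested-range boundaries, and
mechanism-specific nonlinearities that the generator does not model, so these
numbers bound algorithmic, not real-world, performance. Published DA
benchmarks on real training data (R² 0.62–0.72, RMSE 0.64) are accordingly
worse than the synthetic recovery, and per-chemical predictions from the
original models are not reproducible here because their training data are not
public; the bundled published prediction tables are used as inputs to the
comparison layer instead.

## Numerical and reporting conventions

* Seeds: every stochastic component takes an explicit seed; master seeds
  spawn named child streams so adding a generator never perturbs existing
  draws. All derived seeds stay below 2³¹.
* Degenerate inputs: zero-variance scaling spans fall back to a unit span
  (constant features map to mid-range); a zero inner slope makes the Ryan
  slope ratio incomputable and the study is rejected; an empty aggregation
  raises rather than returning NaN.
* Rounding: 3 significant figures for concentrations and 2 for dose-per-area
  values at the reporting layer only; all internal arithmetic is full
  precision.
* Error metrics between predicted and reference EC3 are reported on the raw
  percent scale (the published convention for the case-study comparison) with
  log₁₀-scale alternatives available, since raw-scale metrics are dominated
  by the least potent chemical.

## Known limitations

* The DA cannot output an EC3 outside the range spanned by its training
  targets (the logistic output saturates at the scaling margins) — ensemble
  means for chemicals more potent than anything in the training set are
  biased toward the training range.
* The ensemble CI quantifies initialization variance only; it excludes
  endpoint measurement uncertainty and training-set sampling error, and is
  therefore much narrower than in vivo CIs.
* Approach-1 tie handling (1.25-fold window) and the downward-extrapolation
  screen are pragmatic operationalizations of practices that the underlying
  guidance documents describe only by example.
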