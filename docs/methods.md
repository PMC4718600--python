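# Methods

`tunefree` analyzes direction tuning curves of visual cortical neurons
measured at K = 12 equally spaced stimulus directions (30° steps), with a
small number of repeated trials per direction. It implements two routes to
the same scientific questions — *what shape does the tuning curve have, and
how does it change between experimental conditions?* — a model-based route
(parametric fits, goodness of fit, information-criterion selection) and a
model-free route (algorithmic feature extraction applied directly to the
trial-mean data points, and trial-ensemble tests).

## Data model and conventions

A dataset is a tidy table of trials: `cell_id, paradigm, condition,
direction, trial_index, rate`. Paradigms are `spatially_separate` (two
moving random-dot patterns in separate apertures) and `transparent`
(superimposed); conditions are `uni`/`uni1`/`uni2` (one stimulus),
`afix` (two stimuli, attention outside the receptive field) and `ain`
(two stimuli, attention on one of them). Composite stimuli always place the
two motion directions 120° apart, so `uni` curves are unimodal and
`afix`/`ain` curves bimodal.

Per (cell, condition, direction) the trial mean y_i, trial standard
deviation σ_i (denominator n−1) and trial count n_i form a `TuningCurve`.
Cells need at least two trials at every recorded direction; thinner cells
are rejected with an error naming the offender.

All analyses assume a per-cell circular relabeling of directions such that
the maximum trial-mean rate of the single-stimulus condition sits at 240°
(`uni2` preferred where both uni variants exist). For cells without a uni
condition, the right peak of the `afix` curve is placed at 240° instead;
which of the two bimodal peaks is "right" is reconstructed by comparing the
responses 120° on either side of the global maximum (the companion peak
lies counter-clockwise of the right peak). The offset, always a multiple of
30°, is stored so the relabeling can be undone; alignment is idempotent and
preserves the multiset of rates.

## Parametric models

Eight families, all 360°-periodic, angles in degrees, Ω = 2π/360:

* wrapped Gaussian `wG(θ) = a Σᵢ exp(−½((θ−c+360i)/b)²) + d`
* wrapped Cauchy `wC(θ) = a sinh(b) / (cosh(b) − cos Ω(θ−c)) + d`
* modified von Mises `vM(θ) = a (e^{k cos Ω(θ−c)} − e^{−k})/(e^k − e^{−k}) + d`,
  with k floored at 0.001 (k = 0 voids the normalizer)
* symmetric Beta `sβ(θ) = a (4x(1−x))^b + d`, `x = (Ω(θ−c)+π)/(2π) mod 1`
* wrapped generalized bell `wB(θ) = a (Σᵢ 1/(1+|(θ−c+360i)/b|^{2s}) − β)/(α−β) + d`
  with α, β normalizers evaluated at the peak and the antipode
* Fourier series F2, F3, F4: `a₀ + Σ₁ⁿ aᵢcos(iΩθ) + bᵢsin(iΩθ)`

Wrapped sums run over i = −4..4. The image sum is taken around the angle
difference wrapped to [−180, 180), which makes the truncated families
exactly periodic; for the Gaussian the truncation error is below 1e−9 up to
b = 120°, while the bell's power-law tails (|x|^{−2s}) converge slowly —
doubling the window moves values by up to ~10⁻³ for wide, shallow bells.
The N = 4 truncation is part of the model definition, not an approximation
to be refined.

Bimodal responses are sums of two copies of one family,
`f(θ) = g(θ, a₁,b₁,c₁,d/2) + g(θ, a₂,b₂,c₂,d/2)`, sharing the baseline
(split d/2 per component): 7 free parameters, or 9 for the bell (extra
shape exponents s₁, s₂). Fourier series keep one functional form for both
modalities.

## Fitting

The objective is χ² = Σᵢ((yᵢ − f(θᵢ))/σᵢ)², weighting by the per-direction
*trial* standard deviation (not the standard error of the mean) — the
convention under which the empirical error bars are drawn. Zero σᵢ
(identical trials) is floored at 1e−6 s⁻¹.

Non-linear families are minimized by SLSQP from a 3-point multistart over
widths corresponding to half-widths at half-maximum of 15°, 45° and 90°
(sβ exponents 100, 10.74, 2.41; von Mises k 20.34, 2.3, 0.001), followed
by a bounded trust-region least-squares polish of the best start.
Amplitudes and baseline are bounded in [0, u] with
u = min y + 1.2 (max y − min y); peak positions start at the grid argmax
(unimodal) or at 120°/240° (bimodal). Optimizer failure is reported via
`converged=False`, never by dropping the cell.

Fourier fits use the exact solution: with bᵢ = yᵢ/σᵢ and
A_im = X_m(θᵢ)/σᵢ, the coefficients are p = Σ_m (U⃗(m)·b⃗/w_m) V⃗(m) over the
singular triplets of A; singular values below the machine-precision
threshold are dropped and flagged.

### Goodness of fit

Q is the null probability of a sum of squared errors at least as large as
observed. For the linear Fourier families Q is the regularized upper
incomplete gamma function at shape (K−M)/2 and argument χ²/2 — the
χ² tail with K−M degrees of freedom. For non-linear families Q is
estimated by parametric Monte-Carlo: replicas are the fitted curve plus
Gaussian noise with the observed σᵢ, refitted with the same family
(single-start from the observed parameters), and Q is the fraction of
replicas with χ² at least the observed one. The library default is 10000
replicas; desk-scale runs (tests, the acceptance script) use 100–150,
which resolves the Q ≤ 0.1 "bad fit" threshold to ±0.01–0.007. For linear
families the Monte-Carlo route reduces to an orthogonal projection and is
fully vectorized; it serves as a calibration cross-check of the analytic
tail (agreement within ±0.02 at 10000 replicas).

Because the weights are trial standard deviations while the trial-mean
noise scales as σᵢ/√nᵢ, χ² on real-structured data is strongly deflated
and nearly every family fits nearly every cell "well" (Q > 0.1). This is a
property of the convention, reproduced deliberately: it is the regime in
which goodness of fit cannot select a model, which motivates the
model-free route.

## Model selection

AIC = K ln(SSE/K) + 2M on the *unweighted* SSE at the 12 grid points;
AICc = AIC + 2M(M+1)/(K−M−1). Per cell, ΔAIC = AIC − min AIC; the best
model has ΔAIC = 0 and models with ΔAIC ≤ 1 are contenders. Ties are
broken by fewest parameters, then a fixed family order (F2, F3, F4, sβ,
vM, wC, wG, wB). SSE = 0 returns a −10¹² sentinel. Non-converged fits are
excluded with a warning. With K = 12, the AICc correction is 10 for M = 5
but 90 for M = 9, which in practice bars 9-parameter models from winning
AICc on bimodal data.

## Model-free features

Features are scalar descriptors computed by fixed rules from discrete
samples — either the 12 trial means (direct method) or a fitted curve
sampled at 1° (model-based methods, including the per-cell best model
"bM"). Conventions: the left peak is searched in [0°, 180°), the right in
[180°, 360°); argmin/argmax ties take the smallest angle, peak ties the
sample closest to 120°/240°; InnerMinimum is the minimum strictly between
the peak angles and OuterMinimumAngle the minimum on the complementary
wrapped arc (adjacent peaks fall back to the smaller peak sample);
bandwidths walk outward from a peak in sample steps, without
interpolation, while the GlobalMinimum-subtracted rate stays at or above
X% of that peak's PeakToPeak (a constant curve yields the full support,
330° on the 12-point grid); GlobalMinimumAngle is reported in
(−120°, 240°]. Rate features obtain `normalized` variants by dividing by
the cell's maximum uni-condition rate. Direct-method angular features are
by construction multiples of 30°.

Peak skewness is a reconstruction (the original rule library is not
published in full): the weighted third standardized moment of angle over
the peak's support arc — from the inner minimum through the peak to the
outer minimum — with GlobalMinimum-subtracted rates as weights;
`minusSkewness_left` negates the left peak's value so that mirror-symmetric
curves give equal left/right values and ΔSkewness = 0. CircularVariance
(unimodal only) is 1 − |Σ vₖ e^{iΩθₖ}| / Σ vₖ on the raw rates. The
extraction routine is a single function of (samples, modality), so an
alternative skewness rule can be swapped in without touching anything else.

Cross-method agreement is summarized by population z-scores
z(F) = (mean(F)_model − mean(F)_direct)/std(F)_direct per feature.

## Statistical comparisons

Feature pairs (one value per cell, two groups) are compared with a
two-group Kruskal-Wallis rank test with tie correction — ties are heavy
because direct-method angles are 30°-quantized. For small samples the
p-value is computed by full enumeration of group assignments (up to 20000
combinations); larger samples use the χ²₁ tail. Significance is p < 0.05;
the direction of an effect follows the group medians, falling back to
means on an exact median tie. No multiple-testing correction is applied by
default (Benjamini–Hochberg is available behind a flag).

Specific effects compare the trial ensembles of two conditions per cell
and per stimulus direction with a two-sample Kolmogorov–Smirnov test,
exact for combined samples up to 25 trials, asymptotic beyond. A
direction with fewer than two trials on either side is marked untestable.
The exact KS test is conservative at equal small sample sizes because D is
discrete (at n = m = 10 the achievable level closest below 0.05 rejects
with probability ≈ 0.012); with mixed trial counts of 8–15 per side the
aggregate null false-positive rate is ≈ 0.042–0.05.

## Synthetic data

The generator emulates the structure of the recordings: 12 × 30° grid,
2–15 trials per stimulus (drawn uniformly unless fixed), unimodal `uni`
ground truths with a random preferred direction, bimodal `afix`/`ain`
ground truths with components 120° apart, and an optional attentional
gain multiplying the attended (right) peak in `ain`. Trial rates are
Gaussian around the ground-truth curve with standard deviation cv · mean;
cv defaults to 0.38, the empirical median for the spatially separate
paradigm (0.72 for transparent). Amplitudes are drawn U(15, 40) s⁻¹,
baselines U(2, 8) s⁻¹ and Gaussian half-widths at half-maximum
U(30, 60)°, bracketing the published population medians. Negative draws
are clipped at zero (an unclipped mode exists for strict null
simulations). Because the sample standard deviation is biased low at 2–15
trials, the *measured* median cv of a cv = 0.38 dataset sits near 0.36.

Noise-matched surrogates follow the published probe of model
identifiability: fit a wrapped Gaussian or third-order Fourier series to
each trial-averaged curve and add independent Gaussian noise with the
empirical per-direction σ.

What the generator does not emulate: non-Gaussian trial statistics
(spiking is closer to Poisson), correlations between trials or cells,
drift, and ground-truth shapes outside the wrapped-Gaussian family.
Passing tests therefore demonstrate correctness of the machinery and
qualitative behaviour under realistic noise levels, not distributional
fidelity to any particular recording.

## Problem sizes and numerical choices

Test-suite and acceptance-script runs use desk-scale sizes chosen once:
20–40 cells per experiment, 100–150 Monte-Carlo replicas for non-linear
goodness of fit (10000 for the vectorized linear calibration check), 10⁴
simulated comparisons for the null false-positive rate. The low-noise
identifiability experiment uses cv = 0.02 with 15 trials per stimulus:
there the generating wrapped Gaussian wins AIC among the equal-parameter
families for ≥ 95% of cells and the peak position is recovered to ≈ 0.1°.

## Known limitations

* Model identifiability has structural limits on a 12-point grid: at
  half-widths ≳ 75° the von Mises and wrapped Gaussian are numerically
  indistinguishable (approximation SSE < 0.1 at amplitude 25 s⁻¹), and at
  half-widths ≈ 30° the symmetric Beta can track a realized noise pattern
  better than the generating Gaussian. No noise level separates families
  in those regimes — the heart of the case for model-free analysis.
* AIC is evaluated on unweighted SSE while fits minimize weighted χ²; with
  strongly heteroscedastic σ the two objectives can disagree on nearby
  minima.
* The skewness and right-peak conventions are reconstructions, and the
  feature rules are deliberately interpolation-free, so direct-method
  angular features carry 30° quantization error.
* The exact KS test's conservativeness at equal small n (above) is a
  property of the test, not of the implementation.
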