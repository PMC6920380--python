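# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Histology quantification

**Model.** Brightfield H-DAB sections are treated as Beer–Lambert
absorbers: per pixel and channel, `I_c = I0_c · 10^(−OD_c)`, and the OD
vector is a non-negative mix of stain directions,
`OD = c_h·v_h + c_d·v_d + c_r·v_r`. The default basis uses the standard
H-DAB optical-density vectors — hematoxylin (0.650, 0.704, 0.286) and
DAB (0.269, 0.568, 0.778), each unit-normalized, with the residual as
their normalized cross product. Deconvolution inverts this 3×3 matrix
per pixel; negative concentrations (noise outside the stain cone) are
clipped to zero.

**White balance.** The per-channel white point `I0` is estimated as the
99th intensity percentile (default). The percentile is robust to
specular or saturated pixels; it assumes the field of view contains
clear (unstained) background, which holds for slide scans with glass
margins. OD is computed on the original image with the estimated `I0`
rather than on the rescaled image, avoiding a second quantization.
`ε = 1` intensity unit guards the logarithm at zero, so fully dark
pixels map to the finite `log10(I0)`.

**Grayscale and threshold.** The DAB concentration channel is mapped
affinely and order-reversingly to a grayscale,
`gray = 255 − (255/od_max)·c_d` with `od_max = 2.0`, so heavier DAB is
darker and "dark pixels below the threshold" has its conventional
sense. The map is a documented choice: a luminance conversion of the
RGB image would also respond to hematoxylin, which the deconvolution
deliberately separates out. Per region and section, ipsilateral and
contralateral ROI pixels are pooled and the threshold set to
`T = mean − 0.5·SD` with the sample (n−1) SD; each region in each
section therefore gets its own threshold, which absorbs
section-to-section differences in DAB color development. Pixels
strictly below `T` count as TH+ (boundary pixels excluded); the area
fraction is normalized to the ROI pixel count.

**Aggregation.** Per mouse and region, per-section fractions are
averaged per hemisphere with equal section weights, and the DAB area
ratio is the ratio of the two means. Ratio-of-means is preferred over
mean-of-ratios because a single small contralateral section fraction
would otherwise dominate. ROIs arrive as integer label masks (16-bit
TIFF plus a JSON legend); atlas-based manual segmentation is upstream
of this package.

## Histology simulator

TH+ pixels are drawn as a spatially random subset of each ROI at the
requested fraction, rounded to a whole pixel count — that count divided
by the ROI size is the stored exact truth, making area-fraction
recovery testable to the single-pixel quantum. TH+ pixels carry a DAB
OD amplitude (default 1.0) on top of a uniform hematoxylin background
(default 0.3 OD); pixels outside the ROIs are clear glass at the white
point. Gaussian pixel noise (OD units, default 0) is applied to tissue
pixels only, modelling stain heterogeneity; clear-glass noise is
omitted so the simulated white point remains estimable, as on real
slides with clean background. An optional float mode disables 8-bit
quantization for exact round-trip tests.

Deliberately *not* emulated: morphological clustering of TH+ fibers and
somata, counterstain texture, uneven illumination, section artifacts
(folds, debris), and stain-vector variation between batches. Passing
recovery tests therefore shows the estimator chain is unbiased under
the Beer–Lambert model with known stain vectors — not that it is robust
to segmentation error or stain drift on real slides.

## Cavitation dose metrics

Each pulse's one-sided FFT amplitude spectrum is scaled to
RMS-equivalent bin amplitudes: `a_k = sqrt(w_k)·|X_k|/N` with `w_k = 2`
except at DC and Nyquist. With this scaling the root-sum-square over
any bin set equals the RMS of the signal restricted to those
frequencies, a bin-frequency sinusoid of amplitude A contributes
`A/√2`, and the full-band root-sum-square equals the time-domain RMS
exactly (Parseval) — the property the test suite checks to 0.5%.

The band plan places harmonic windows at n·f0 and ultraharmonic
windows at (n+½)·f0 inside the 3–9 MHz analysis band (f0 = 1.5 MHz
default: harmonics {3.0, 4.5, 6.0, 7.5, 9.0} MHz, ultraharmonics
{3.75, 5.25, 6.75, 8.25} MHz). Windows are ±Δf around each center with
Δf = 150 kHz (10% of f0) by default, clipped at the band edges; a
center is included iff its window intersects the band. Δf must stay
below f0/4 so the window families cannot touch. Bins are selected by
center frequency on half-open intervals `[c−Δf, c+Δf)`. SCDh/SCDu are
the root-sum-square of bin amplitudes over the respective window
unions; ICD over the band minus all windows. No spectral taper is
applied by default (a Hann option exists for off-bin tones at the cost
of exact Parseval); per-sonication aggregates are means over pulses, so
the normalized dose (with-microbubbles ÷ baseline) is insensitive to
pulse count.

The pulse simulator sums sinusoids with per-pulse random phases,
broadband Gaussian noise band-limited to 3–9 MHz by spectral masking
and scaled so its expected in-band RMS equals the configured SD, and
full-band white sensor noise. Each component's RMS is analytic, and the
expected value of each dose metric under a given band plan is computed
in closed form (tone power within windows + flat noise densities times
window widths), giving the 5% recovery oracle. Not emulated: transducer
and medium transfer functions, attenuation, pulse envelopes, or
physical bubble dynamics — dose values are in arbitrary spectral-RMS
units, as in practice, which the baseline normalization cancels.

## Rotation counting

Headings are unwrapped by mapping successive differences to
(−180°, +180°] and accumulating. The counter keeps a running reference:
each time the cumulative angle falls a further 360° below the reference
a CW turn is registered and the reference steps down 360°
(symmetrically for CCW). A 1e-9° tolerance on the 360° comparison keeps
exact-boundary crossings robust to unwrap round-off. CW = decreasing
heading by default, exposed as a flag because camera mounting flips
chirality. An optional half-open time window trims acclimation periods
before counting.

The trace simulator follows a piecewise-linear cumulative path through
the requested CW then CCW turns. With jitter (Gaussian, clipped at
4·SD ≤ 85° so every excursion stays below 90°), the true path
overshoots each turn boundary by (clip + 5°); under these bounds the
accumulator provably recovers the requested counts exactly, which the
suite verifies over 50 random configurations. Jitter SDs above 21.25°
are rejected as violating the no-spurious-crossing bound. Counting is
time-reversal symmetric for traces that complete turns exactly; with
endpoint jitter the reversed trace's final crossing can shift by one
count because the reference grid anchors at the first sample. The
commercial tracking software's internal turn criterion is unknown; the
accumulator rule is a documented stand-in, and the simulator does not
emulate partial-arc behavior, grooming pauses, or tracking dropouts.

## Grubbs screen

Single-pass, two-sided: `G = max|x_i − x̄|/s` against
`G_crit = ((n−1)/√n)·sqrt(t²/(n−2+t²))`, t the upper α/(2n) Student-t
quantile with n−2 df. At most one value is flagged per call (no
iterative removal), matching the single-outlier screening use case.

## Group statistics

Paired t (two-tailed, df = n−1) within groups and one-way ANOVA across
groups delegate to scipy; Holm–Sidak is implemented directly: sort m
raw p-values ascending, adjust the i-th to `1 − (1 − p_(i))^(m−i+1)`,
enforce monotone non-decreasing down the sorted list, map back, and
reject while adjusted p < α. Pairwise post-hoc comparisons use
pooled-variance two-sample t-tests over all group pairs by default.
Degenerate inputs (zero-variance differences, identical ratios) yield
flagged, non-significant result objects inside `group_analysis` so
batch runs complete; the individual test functions raise instead. No
correction is applied to the within-group paired tests — only the
across-group pairwise family is corrected.

The fraction-level study simulator draws each mouse's contralateral
baseline fraction from N(0.20, 0.03), multiplies the ipsilateral mean
by the effect (1.2 in the treated group, 1.0 elsewhere), and adds
N(0, 0.01) section noise, with the study's group sizes (7/6/7) and six
sections per mouse as defaults. These defaults put the treated-group
paired test's expected t well above the rejection threshold while
keeping control groups null; the type-I property (rejection rate ≤
α + 2·SE over 200 null replicates) is checked at these same settings.

## Reporting conversions

Percent injected dose per gram is `100 × (µg/g) ÷ µg injected`,
truncated (not rounded) to one decimal by default, matching the
convention of reporting conservative delivery efficiencies; a flag
switches to rounding. Dose arithmetic multiplies droplet count ×
droplet volume × concentration; the packaged study schedule is eight
3 µL droplets (24 µL) of 16.67 mg/mL solution per session
(≈ 0.40008 mg ≈ 0.4 mg) over three sessions (≈ 1.2 mg). Droplet timing
is metadata: delivered mass depends only on total volume and
concentration.

## Problem sizes and tolerances

Synthetic sections default to 128×128 px with two ~40×50 px ROIs per
hemisphere — small enough for sub-second quantification while leaving
the per-ROI fraction quantum near 2×10⁻⁴. PCD pulses default to 10⁴
samples at 50 MS/s (5 kHz bins), putting all default tone centers on
exact bins; the noisy-recovery tolerance of 5% covers the ~2–3%
realization scatter of band-limited noise RMS at that length. The
noisy-histology tolerance of ±0.02 is evaluated at a TH+/background
separation of 4 noise SDs in the deconvolved DAB channel, where the
threshold sits ≈2 SD from each mode and the expected misclassification
bias is ≈0.01. Statistical oracles (explicit-formula paired t, ANOVA
sum-of-squares, Holm–Sidak brute force, Grubbs critical values by
root-finding on the t survival function) agree with the implementation
to 1e−10 on seeded grids.
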