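# Methods

## Measurement model

One measurement is a four-channel intensity vector (R', G', B', C) from
an RGBC photodiode sensor reading a leaf under a fixed internal LED
pair, in counts/uW/cm2. The clear channel C is the unfiltered
broadband intensity; dividing each color channel by it cancels the
overall illumination level, and the factor 255 puts the normalized
indices R, G, B on the familiar 8-bit color scale. Because the ratio is
kept at full floating precision (no integer quantization — that is a
sensor artifact, not part of the method), the normalized indices, hue,
saturation and all channel ratios are exactly invariant to scaling all
four channels by any k > 0; brightness-dependent features (V and the
products) are not.

HSV uses the standard hexcone transform with H in degrees [0, 360) and
S, V in [0, 1]. These scale conventions are forced by the calibrated
coefficient magnitudes: a term like 0.008×H only makes dimensional
sense with H on a degree scale, and 85.096×S / −170.899×V only with S,
V on the unit interval. When max = min (achromatic input) hue is
defined as 0 so the transform is total.

Replicates are averaged on the raw channels first and features
computed once from the mean reading. The alternative (average the
features) differs through the nonlinearity of HSV and the ratios; the
raw-first order matches how replicate summaries are reported at
channel level by the instrument protocol.

Zero denominators in the ratio features raise a named error rather
than emitting NaN: a leaf reading with a zero channel is a defective
measurement, and silent NaNs would poison a calibration design matrix.

## Content models and the abnormality guard

The production models are affine in the five screened features
(normalized blue `b`, raw blue `b_raw`, `h`, `s`, `v`); coefficients
are shipped verbatim in `src/chloroleaf/data/default_models.json` and
round-trip bit-identically through the model-document format. The two
"blue" symbols are the easiest pair to confuse, so the mapping is
enforced by the canonical feature-name set: `b` is the normalized
index, `b_raw` the raw channel.

The total-chlorophyll coefficients equal the a+b sums except for 0.001
print rounding on the two blue terms (1.609 vs 1.610, −0.276 vs
−0.277); the intercepts sum exactly (−30.623 + −13.164 = −43.787).
Hence |TCL − (CL-a + CL-b)| ≤ 0.001·(b + b_raw) for any non-negative
blue features — tested over 10⁴ random feature vectors.

The firmware displays "detection error" for abnormal output but the
threshold is not published. The guard here is: any content < 0, or
TCL > 6.0 mg/g, flags the estimate. The ceiling brackets the largest
content observed on real calibration material (4.859 mg/g) with
headroom, and is configurable (`PlausibilityWindow`). Rounding to
3 decimals happens only at the display layer; internal math is full
precision.

## Calibration workflow

`fit_mlr` is ordinary least squares (statsmodels) with per-coefficient
homoscedastic t-tests; the significance screen keeps features with
p < α (α = 0.05 default), preserving canonical feature order, with no
multiple-testing correction — the screen is a model-simplification
device, not an inference claim. Rank-deficient designs and n ≤ p + 1
raise rather than silently pseudo-inverting. Reported R² is the plain
fitting-set coefficient of determination (not adjusted, not
cross-validated) and is labelled as such; RMSE uses the 1/n
denominator.

`fit_plsr` wraps scikit-learn's NIPALS PLS with `scale=False`. sklearn
predicts on centered X, so the affine intercept is reconstructed as
ȳ − x̄·β; with the full component count on full-rank data PLS
predictions coincide with OLS to machine precision (tested at 1e-8).
When no component count is given it is chosen by leave-one-out
cross-validated RMSE over 1..10 (capped by n−1 and p), ties toward
fewer components — a standard choice where the original calibration's
count is unknown.

Crops are pooled by default (the production models are a single
wheat+maize calibration); `CalibrationDataset.subset(crop)` supports
per-crop evaluation. A `spad` column, when present, feeds the same
single-index regression path for baseline comparisons.

## Reference assay

Contents are grounded in a destructive assay: leaf extracted in 80%
acetone to a fixed flask volume (intermediate dilution steps collapse
into the final volume — only it enters the mass balance), absorbances
read at 645/663 nm, and the classical two-wavelength simultaneous
equations applied: Ca = (12.7·A663 − 2.69·A645)/L, Cb = (22.9·A645 −
4.68·A663)/L, Ct = (20.2·A645 + 8.02·A663)/L (mg/L, L in cm). These
are the canonical coefficients for that solvent/wavelength pair; they
live in a config object (`ArnonCoefficients`) so a national-standard
variant can be swapped in. Coefficient algebra gives Ct − (Ca + Cb) =
−0.01·A645 exactly (the A663 terms cancel: 12.7 − 4.68 = 8.02; the
A645 terms leave 20.2 − 20.21), so total tracks the component sum to
print-rounding accuracy. Concentrations are linear in the absorbance
pair (superposition tested); negative results for out-of-model
absorbance pairs are returned for the caller to flag, not clipped.

## QC statistics

All coefficients of variation use the population SD (divide by n):
this is the convention that regenerates the instrument's published
stability CVs (0.911/1.103/0.941/0.771%) from the underlying
timepoint means — the sample SD does not — and it is the descriptive
convention instrument reports use. CVs are displayed to 3 decimals;
test comparisons against printed tables use |Δ| ≤ 5e-4.
`cv_from_summary` exists only for checking printed mean ± SD cells;
the report builders always compute from raw replicates, because SDs
rounded for print cannot reliably regenerate the CV (a printed
27.0 ± 0.1 row can carry a CV of 0.341%). The repeatability report's
headline number is the arithmetic mean CV over all sample × channel
cells.

## Synthetic data

The generator draws raw channels uniformly within ranges spanning the
counts observed on real leaves (R' 24–32, G' 22–30, B' 17–22, C 70–90),
clamped so no color channel exceeds the clear channel; uniform
sampling is the assumption-minimal choice given only observed ranges.
Reference contents are computed *from the production models* plus
N(0, noise_sd) noise (default 0.05 mg/g, below the scatter of real
calibration residuals), with out-of-window rows resampled. This makes
the shipped models the exact planted truth: noiseless data must return
their coefficients to 1e-6, and recovery error must grow monotonically
with noise — both tested. The price is realism: the generator emulates
no leaf optics, no vein structure, no crop-specific color
distributions, and its content noise is homoscedastic and independent
across targets. Passing recovery tests therefore demonstrates the
correctness of the calibration machinery, not the field accuracy of
the instrument; the published field RMSEs (≈0.27/0.09/0.35 mg/g)
depend on leaf material that is not deposited anywhere and are out of
reach of desk-scale simulation.

A note on one replicate-noise check: a single 10-replicate CV estimate
has ≈ 21% chance of missing the planted noise ratio by more than 30%
(chi-square dispersion of an SD at n = 10), so the recovery check is
stated on the report's overall mean CV (12 cells averaged), which is
both the protocol's actual summary statistic and well-concentrated.

## Device emulator

The firmware loop is a seven-state machine (INIT, WELCOME, READY,
MEASURING, RESULT, ERROR, TRANSMITTED) with deterministic transitions;
measurement consumes a reading, runs the full feature → prediction →
guard pipeline and lands in RESULT or ERROR. Timing (welcome screen,
~2 s measurement) is modeled as zero-cost `tick` events and Bluetooth
transmission as a sink callback, since both are hardware-bound with no
computational content. Illegal events are logged no-ops — the machine
never crashes on input, which is fuzz-tested with random event
streams.

## Problem sizes

Test and acceptance workloads are sized for a laptop-class single
core: recovery fits use 60–200 samples, the RMSE-consistency check
10⁴, Monte-Carlo claims 40–100 fixed seeds, and the brute-force HSV
and additivity sweeps 10⁴ points each; the whole suite runs in a few
seconds.
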