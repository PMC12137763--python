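# Methods

## Signal model and solvers

The per-voxel model is the single-compartment decay S(TE) = S0·exp(−TE/T2*)
with two free parameters, fitted by unweighted least squares. Two solvers
are provided because "least squares on a monoexponential" admits two
standard readings:

- **loglinear** — ordinary least squares of ln S on TE; T2* = −1/slope,
  S0 = exp(intercept). Closed form, exact on noiseless data, but the log
  transform re-weights noise (late, low-SNR echoes dominate).
- **nlls** (default) — least squares on the untransformed signal with
  bounds T2* ∈ [t2_min, t2_max] (default [1, 2000] ms) and S0 ≥ 0,
  initialized from the log-linear solution. This optimizes the objective
  magnitude data actually obey and is the default.

The NLLS implementation is a vectorized two-parameter Levenberg–Marquardt:
all voxels of a volume iterate simultaneously with per-voxel damping, and
a step is accepted for a voxel only if it lowers that voxel's residual sum
of squares. Monotone acceptance from the log-linear start point gives two
useful guarantees: the NLLS residual never exceeds the log-linear residual
on any voxel, and the solver is deterministic. Convergence is declared at
relative parameter change < 1e−8 (≤ 200 iterations); a voxel whose damping
is exhausted is at a local minimum to machine precision. A 64×64×48 volume
(~197k voxels) fits in well under a minute on one core; problem sizes in
the tests (full grid noiseless, 10⁴ replicate voxels per noisy condition)
were chosen to keep each check in the seconds-to-one-minute range.

Voxel validity, not exceptions, carries all per-voxel failure modes:
fewer than `min_valid_echoes` (default 2) samples strictly above the
signal floor (default 0 — all positive samples used), a non-decaying
signal (log-linear slope ≥ 0; a flat signal is invalid rather than
saturating at t2_max, which would silently bias organ means), an estimate
clipped to the T2* bounds, or NLLS termination at a bound. Invalid voxels
carry NaN in the maps. Fit quality is the coefficient of determination of
the prediction against the untransformed signal for both solvers, clipped
to [0, 1] (the log-linear fit can otherwise score negatively in linear
space); it is reported only where valid.

The magnitude noise floor is **not** corrected by default: the fit uses
the raw magnitudes, which is appropriate at the moderate-to-high SNR the
targeted low-field protocol maintains and keeps the default pipeline free
of a tunable noise parameter. The optional correction
S_corr = sqrt(max(S² − 2σ_n², 0)) (the even-moment inversion of the
Rician expectation) is available with a user-supplied σ_n.

## Organ quantification

The organ mean is computed over voxels that are in the mask, validly
fitted, and at or below the organ's upper-limit threshold — 500 ms for
the placenta, 900 ms for the fetal brain — which excludes fluid-dominated
partial-volume voxels (amniotic fluid T2* is far longer than parenchyma).
The comparison is inclusive (t2star ≤ threshold kept) and over-threshold
voxels are *excluded*, not clipped: clipping would bias the mean toward
the threshold. Volume is mask voxel count × voxel volume, independent of
the fit, so invalid-fit voxels count toward volume but not the mean. The
three counts (used, over-threshold, invalid-fit) always partition the
mask. GA is carried as decimal weeks.

## Normative curves and classification

Per (organ, measure) the mean trend is OLS-polynomial in GA — quadratic
for fetal-brain mean T2*, linear for placental mean T2* and both volumes
— and the 5th/95th centiles are quantile regressions (pinball loss,
statsmodels QuantReg IRLS) sharing the trend's polynomial degree; the
degree of the quantile model is a design choice here since only the trend
degrees are conventionally fixed. No non-crossing constraint is imposed;
crossing of the fitted centile curves on a 100-point GA grid inside the
training range raises a model-quality warning (with a small relative
tolerance so coincident curves from degenerate zero-noise data do not
warn). At least 10 records per combination are required; sparser
combinations are omitted with a warning.

Classification is "low" strictly below the 5th centile and "high"
strictly above the 95th; values exactly on a curve are "normal"
(inclusive band boundaries — the documented tie rule). GA outside the
training range is answered but flagged `extrapolated` rather than
refused. Models serialize to a versioned JSON store; classification is
invariant under a consistent affine rescaling of the measure.

## Robustness metrics

Bland–Altman differences are oriented first-listed minus second-listed
(labels record the orientation), with the sample (n−1) standard deviation
— the conventional estimator for agreement studies — and ±1.96 SD limits
of agreement. Dice is 2|A∩B|/(|A|+|B|); two empty masks score 1.0
(agreement about absence) and exactly one empty scores 0.0, conventions
needed for degenerate phantom cases. Repeat consistency reports all
k(k−1)/2 pairwise mean-T2* differences (earlier minus later), each
repeat's centile band, and a stability flag true only when all repeats
share one band.

## Synthetic phantom and cohort

The phantom emulates the whole-uterus protocol's geometry: voxels
3.125×3.125×3 mm³, echo times [57, 152, 248, 344] ms, default grid
64×64×48 (a 200×200×144 mm³ field of view — half the clinical in-plane
FOV, enough to hold both organs with margin). An ellipsoidal fetal brain
(semi-axes 8×7×6 voxels) and an oblate-ellipsoid placenta (14×12×7) sit
disjoint in short-T2* (60 ms), low-S0 background tissue, making the
reference segmenter's job trivially separable by design — segmentation
quality is not this package's subject, and real exams use external
(e.g. nnU-Net) masks through the pluggable interface.

Organ T2* defaults follow the GA trends of the synthetic cohort:
placenta 337 − 4·GA ms (185 ms at 38 wk) and fetal brain
280 + 6.5·GA − 0.19·GA² ms (252.6 ms at 38 wk), both decreasing across
the modelled 20–40 wk span and placed in ranges plausible for low-field
(0.55 T) imaging — comfortably below the 500/900 ms thresholds — as test
constants, not physiological claims. The cohort's volume trends
(placenta 3800·GA − 1100 mm³, brain 1400·GA − 13150 mm³) are calibrated
to pass near the fixed phantom geometry's discrete volumes at 38 wk
(143 291 / 40 049 mm³), so a default phantom exam classifies "normal"
against a default cohort; residual SDs (12 / 15 ms for T2*, 8000 / 2500
mm³ for volume) give realistic centile bandwidths. The default cohort
size is 88 cases.

Noise is additive Gaussian by default — deliberately magnitude-bias-free
so solver correctness is tested separately from noise-model bias — with
Rician noise (magnitude of a complex Gaussian) available to exercise the
optional floor correction. "SNR n" helpers set σ to 1/n of an organ's
first-echo signal. Confounder modes mirror the two real-world failure
cases a real-time pipeline must flag: a *contraction* multiplies T2* by
(1 − depression) on a fixed fraction of placental voxels (the first
⌊f·n⌋ in C order, so f = 0.5 on an even-count region is exactly half),
and *motion* rigidly shifts the brain by per-echo integer-voxel offsets,
with vacated voxels reverting to background. The contraction is part of
the generated truth map (fitting recovers the depressed values); the
truth mask stays at the reference position under motion. Repeat series
derive per-repeat seeds from the base seed by hashing, so any k is
bit-reproducible.

What the phantom does **not** model — realistic anatomy, partial-volume
mixing at organ boundaries, EPI distortion, B0 inhomogeneity, coil
sensitivity, continuous motion — bounds what passing tests show: they
validate the estimation and classification machinery, not segmentation
robustness or fit accuracy under acquisition artifacts.

## Known limitations

- The monoexponential model ignores multi-compartment decay and the noise
  floor (unless the optional correction is enabled), so very low-SNR late
  echoes bias T2* upward.
- Quantile curves can cross outside dense data; crossing is detected,
  not prevented.
- The reference segmenter is intentionally phantom-only; it uses the
  generating spec and cannot segment real data.
- Masks must share the acquisition grid; no resampling is performed.
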