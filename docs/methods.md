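# Methods notes

This note documents the models, conventions and design choices behind
`thalfc`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, what the synthetic generator does and does not
emulate, and where the numerically delicate decisions lie.

## Study design modelled

A subject contributes four task-free BOLD scans in one day — baseline,
prodrome, full-blown, recovery — of 200 volumes each at TR = 3.01 s,
2.5 mm isotropic. Two analysis branches share one preprocessing chain:

* static: seed-based correlation per scan, group inference, rcFC index;
* dynamic: group ICA → salience-network time course → 800-point
  concatenated signals → wavelet coherence against each thalamic seed.

Motion correction and registration are out of scope; inputs are assumed
already in a common (MNI-like) space, which the synthetic generator
produces by construction.

## Preprocessing

**High-pass (cutoff 0.007 Hz ≈ 150 s).** Implemented as a raised-cosine
gain applied to the DCT-II coefficients of each series (basis frequency
k/(2·n·dt)): zero at or below cutoff/2, one at or above 3·cutoff/2,
half-cosine in between, DC always removed. The DCT's implicit even
extension keeps slow drifts compact in a few low-order coefficients, so
they are removed without the wrap-around leakage a periodic FFT filter
would produce. The filter is diagonal in the DCT basis, hence exactly
idempotent on inputs without transition-band content. One caveat is
documented as `HIGHPASS_STOPBAND_BOUND = 0.1`: a sub-cutoff sinusoid
observed for only a fraction of its period genuinely carries a percent-level
share of its amplitude *above* the cutoff (about 8% for a 0.001 Hz drift on
a 602 s window), and any filter with the stated pass band must let that
through.

**Spatial smoothing (FWHM 5 mm default).** Per-volume Gaussian kernel,
sigma = FWHM/(2√(2 ln 2)) converted to voxels through the affine scales;
only orthogonal affines are supported (an oblique affine has no per-axis
voxel size). Optional — the synthetic data do not need it, but it is on by
default to mirror the target acquisition's processing.

**Nuisance regression.** The mean white-matter and CSF series (plus an
intercept) are regressed out of every voxel by least squares;
rank-deficient designs fall back to the pseudo-inverse. Residuals are
orthogonal to every regressor by construction.

**Sphere ROIs.** A voxel belongs to a sphere when its centre lies within
the radius, boundary inclusive — the simplest convention that is exactly
testable against exhaustive enumeration. Eight bundled brainstem /
diencephalic spheres (dorsal pons, periaqueductal grey, hypothalamus,
spinal trigeminal nuclei, dorsal raphe) serve as the small-volume-correction
set.

## Static branch

**Seed correlation.** Pearson r of every voxel against the seed-mean
series; zero-variance voxels get r = 0 and a flag. Fisher z (atanh) is
applied before group statistics (toggleable) as the standard variance
stabilisation.

**Group mean effect.** Covariates (age, gender, disease duration) are
mean-centred and residualised out of the subject maps *without* an
intercept, so the group mean — the tested quantity — survives. The null
flips the sign of whole subject residual maps (exchangeable under a
symmetric null); all 2^n patterns are enumerated when 2^n ≤ n_perm
(n = 5 → 32 patterns, minimum FWE p = 1/32), otherwise n_perm random
patterns with the identity always included. Requesting thousands of random
permutations of a 32-element null would only resample it, hence the
exhaustive path. TFCE uses E = 0.5, H = 2, dh = max|t|/100,
26-connectivity (the common defaults); negative values are enhanced on the
negated map and returned negated. Where the across-subject SD is zero but
the mean is not (degenerate but legal), t is set to a large finite
sentinel (1e10) rather than infinity, with a relative tolerance of 1e-12
so that a few ulps of float noise do not masquerade as signal.

**rcFC.** rcFC_x = (meanFC_x − meanFC_baseline)/meanFC_baseline, with
meanFC the mean r over non-zero voxels of the phase's FWE-significant mask
(FWE p < 0.05; if no voxel survives, the positive-t support is used so the
index stays defined on weak synthetic data — flagged in the result).
Zero at baseline by construction; invariant to common positive rescaling.
Phases are compared with a repeated-measures ANOVA (statsmodels `AnovaRM`;
a zero-between-phase-variance design short-circuits to F = 0, p = 1) and
Bonferroni-multiplied paired t-tests capped at 1.

## Dynamic branch

**Group ICA.** Scans are voxel-demeaned, stacked along time across
subjects and scans, PCA-whitened to k dimensions via randomized SVD and
unmixed with fixed-point ICA (scikit-learn FastICA, log-cosh contrast, 500
iterations, tol 1e-6) treating voxels as samples, so the sources are
spatial maps. Model order is a fixed k (default 8 in the pipeline);
Bayesian model-order estimation is deliberately out of scope. Maps are
unit-norm, sign-aligned (largest-magnitude weight positive) and ordered by
variance explained; k = 1 reduces analytically to the first singular
vector. Network selection maximises |spatial correlation| with a template
(the generator's ground-truth map for synthetic runs, any NIfTI map
otherwise); a best score under 0.3 warns but still returns.

**Dual-regression time course.** Per volume, the voxel intensities are
regressed on [intercept, map]; the map coefficient is the network signal.
Per-subject four-scan concatenations (800 points) are z-scored per subject
— so no subject dominates — and averaged pointwise into the group signal.
For the group average to retain the planted oscillation, the generator
locks the per-scan absolute oscillation phase across subjects (see below).

**Wavelet coherence.** Analytic Morlet (omega0 = 6), scales
s_j = 2·dt·2^(j/12) up to a largest Fourier period of n·dt/2, transform by
frequency-domain multiplication after zero-padding to the next power of
two. Fourier period = 4π s/(omega0+√(2+omega0²)) ≈ 1.033 s. Smoothing:
Gaussian in time with SD = s per scale, boxcar over 0.6 octave in scale;
both kernels renormalised at the boundaries, so the operator is linear and
preserves constants exactly. R² is floored symmetrically in numerator and
denominator at 1e-20 of the spectral maxima so cells where *both* spectra
sink into FFT round-off (possible only for exactly band-limited inputs
such as pure tones) resolve to the self-coherence limit 1 instead of 0/0
noise; broadband signals sit far above the floor. The phase is the
argument of the smoothed cross-spectrum `S(s⁻¹·conj(Wx)·Wy)`: positive
phase ⇔ x lags y; −π/2 ⇔ x leads by a quarter cycle. Classification bins
are centred on the cardinal directions (boundaries ±π/4, ±3π/4).

**Red-noise significance.** AR(1) parameters are fitted to each input
(lag-1 autocorrelation; innovation SD from the stationary-variance
identity); mc_n surrogate pairs (default 1000; 300 in the calibration
tests for speed) are transformed and their in-cone coherence pooled over
time per scale; the (1−alpha) quantile per scale is the threshold. The
false-positive rate on independent AR(1) pairs calibrates to ~0.05 at
alpha = 0.05 (acceptance suite asserts [0.03, 0.08] over 50 replicates).

**Cone of influence and segment attribution.** The global COI uses the
e-folding convention period ≤ √2·ff·(distance to series edge)·dt; it is
applied identically to data and surrogates, so the significance
calibration is internally consistent. Per-phase summaries are stricter: a
coherence cell at scale s draws on the wavelet envelope (SD s) *convolved
with* the time-smoothing kernel (SD s), a combined Gaussian of SD √2·s
whose amplitude e-folding distance is 2s. Cells closer than 2s to any
segment seam therefore mix neighbouring phases and are excluded from that
segment's statistics, along with a 5-sample guard band around each seam
(concatenation discontinuities). Without this local cone, the strongly
coherent baseline/prodrome segments measurably leak into the incoherent
full-blown segment at large scales.

**"None" class.** A segment is reported as having no coherent relationship
when its significant-cell fraction does not exceed 2·alpha: at alpha =
0.05 an incoherent segment still flags ~5% of cells by construction, and
scattered cells at chance level are not evidence of coupling. Above the
floor, the dominant class is the majority vote of the classified
significant cells and the summary phase is their circular mean.

## Synthetic data generator

Each subject's session shares one geometry (default 24×24×16 voxels at
2.5 mm): two spherical "thalamus" seeds mid-grid, a salience-like network
map of three Gaussian clusters (bilateral insula-like plus dorsal
midline), and WM/CSF slabs at the grid's bottom/top slices. Per scan,
every voxel receives independent stationary AR(1) noise (phi = 0.3,
sigma = 1); seed voxels add a 0.05 Hz sinusoid; network voxels add the
same oscillation weighted by the map and shifted by the scan's planted
phase offset (baseline π, prodrome −π/2, full-blown incoherent → an
independent AR(1) stands in, recovery 0); WM/CSF voxels add shared
compartment signals at twice the noise SD. The coupling SNR (oscillation
amplitude / stationary noise SD) defaults to 1. The per-scan absolute
oscillation phase is drawn from the study seed and shared across subjects
— modelling a common attack-locked rhythm — because subject-averaging
would otherwise cancel the oscillation; relative offsets, which are what
the analysis measures, are unaffected. 0.05 Hz sits inside the high-pass
pass band and far below the 0.166 Hz Nyquist.

What the generator does **not** emulate: spatial autocorrelation of noise
(optional smoothing switch exists, off by default so the analytic
significance calibration stays valid), hemodynamic response convolution,
motion and physiological artefacts, scanner drift beyond AR(1), and
between-subject anatomical variability. Passing recovery tests therefore
demonstrate the correctness of the analysis chain on data obeying its
assumptions, not robustness to real-data artefacts.

## Numerical choices and degenerate inputs

* All generators and analyses are pure functions of (config, seed); reruns
  are bit-identical.
* Coherence overshoot beyond 1 from float arithmetic is clipped (warning
  above 1e-6).
* AR(1) fits clip phi into (−0.999, 0.999) and warn above 0.98
  (trend-like input → the red-noise null is a poor surrogate); surrogates
  use |phi| to stay stationary.
* Constant series are rejected wherever a correlation or coherence would
  be undefined; empty ROI masks raise with the ROI's name.
* Fisher z clips |r| = 1 to 1 − 1e-7 with a warning.
* Problem sizes in the test and acceptance suites (grid 24×24×16, five
  subjects, mc_n = 300, 50 calibration replicates, 200 FWE-calibration
  replicates on a 5×5×3 grid) were chosen as the smallest sizes at which
  the statistical assertions have comfortable Monte-Carlo margins.

## Known limitations

* The segment-local cone discards large-period cells near seams; for
  200-sample segments, periods above ~150 s cannot be attributed to a
  single phase at all. This is a property of time–frequency attribution,
  not of the implementation.
* The rcFC fallback mask (positive-t support when nothing survives FWE)
  keeps the index defined but mixes non-significant voxels into meanFC;
  real studies should report it only over surviving clusters.
* Exhaustive sign-flipping with five subjects yields a 32-point null: FWE
  p-values are quantised to multiples of 1/32 and the achievable
  significance floor is 0.03125.
* Group ICA determinism holds for a fixed seed, but component order and
  sign depend on the data; downstream selection is invariant to both.
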