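# Methods

This note documents the models behind `qusresp`, the parameters that
matter, what the synthetic data generator does and does not emulate, the
numerical choices, and the known limitations.

## RF simulation model

Frames are synthesized by a 2-D (axial × lateral) point-scatterer model.
Each scan line receives an impulse train at the round-trip delays
`t = 2z/c` of the scatterers assigned to it (nearest line by lateral
position, nearest sample by delay), convolved with a Gaussian-envelope
pulse. Per scatterer, the impulse amplitude is multiplied in the
frequency domain by

* the square root of the Gaussian form factor
  `FF(f) = exp(−0.827 k² a²)`, `k = 2πf/c`, `a = d/2` — so the *power*
  spectrum carries the standard Gaussian form factor for effective
  diameter `d`; and
* a round-trip attenuation amplitude factor
  `10^(−2 α f_MHz z_cm / 20)` with `α` in dB/cm/MHz, evaluated on 1 mm
  depth bins (bin-centre depth; worst-case within-bin amplitude error
  ≈ 0.3 dB at the top of the band, unbiased for the depth regression).

White Gaussian electronic noise is added at a configurable SNR (default
30 dB relative to the frame RMS). There is no diffraction or beam model,
no transmit focusing and no elevational dimension: the downstream
estimators consume windowed per-line spectra, and per-line convolution
is sufficient to give them the correct first- and second-order spectral
statistics. Consequences: no depth-dependent diffraction correction is
needed (or modelled), speckle is fully developed only in the lateral
direction insofar as scatterer density allows, and absolute echo levels
are arbitrary.

The form-factor convention deserves a note. The classical Rayleigh
backscatter model carries an `f⁴` prefactor in the power spectrum. Here
the simulator and the form-factor fit both omit it by default (the
`rayleigh_prefactor` option restores it symmetrically on both sides), so
that a vanishing-diameter diffuse phantom produces a *flat* normalized
spectrum — the natural null case for spectral-slope estimators, and the
convention in which the reference normalization is interpreted as
dividing out the full system response including the Rayleigh rise. What
matters for every estimate in the package is that the two sides share
one convention; AAC is in dB relative to an arbitrary reference either
way.

Regular scatterer spacing is simulated as axial lattice columns
(lateral pitch = spacing/5 so every scan line crosses the lattice), each
column with an independent uniform phase offset and per-scatterer
Gaussian position jitter, superimposed on the diffuse Poisson
population.

**Jitter and detectability.** The spectral ripple of a lattice with
spacing `d` survives positional disorder only while the round-trip delay
spread stays below a fraction of the carrier period: the ripple
amplitude at frequency `f` is attenuated by
`exp(−½ (2πf·√2·2σ/c)²)` for per-scatterer position jitter σ. At 6 MHz,
σ = 10 µm (1% of a 1 mm spacing) costs ~20%; σ = 50 µm (5%) suppresses
the ripple by ~e⁻⁶ and is physically undetectable by any power-spectrum
method. The validation lattice therefore uses 1% jitter.

## Reference normalization

The spec-normalization reference is the *analytic* pulse power spectrum
(a closed-form Gaussian calibrated to the plain DFT convention), exposed
by `Pulse.analytic_psd`. A measured reference spectrum can be
substituted — the reference is an explicit argument of
`normalized_spectrum`. Window periodograms are per-line, mean-removed,
Hann-tapered, averaged over the window's lines, and carry no
window-power compensation, so a window containing exactly the reference
pulse normalizes to 0 dB on the band. The analysis band is the
reference −6 dB band intersected with [1 MHz, 0.8 × Nyquist]
([4.2, 7.8] MHz at the defaults).

## Estimators

* **MBF/SS/SI** — OLS of band power (dB) on frequency (MHz);
  `MBF = SS·f_c + SI` holds exactly by construction.
* **ASD/AAC** — linearized fit (`ln S` on `k²`) followed by a bounded
  golden-section polish of ASD (1 µm tolerance) on the linear-power
  residual with the concentration refit in closed form per candidate.
  A non-negative slope carries no size information: ASD is pinned to the
  lower search bound (10 µm) and flagged. Search range 10–500 µm.
* **SAS** — autocorrelation of the linearly detrended linear-power
  spectrum. Two refinements matter in practice: (1) pure speckle
  imprints a *known* autocorrelation on the periodogram — the squared
  normalized DFT of the squared taper — which is subtracted before peak
  picking, removing spurious low-lag peaks; (2) a subharmonic-preference
  rule replaces a winning peak by a half-lag peak carrying ≥ 50% of its
  value, suppressing second-harmonic picking. The peak lag is refined by
  parabolic interpolation, and `SAS = c/(2Δf)`, searched over lags
  mapping into 250–2500 µm. The prominence threshold (0.40 in units of
  the detrended spectral variance) was calibrated on synthetic lattice
  vs diffuse ensembles: it gives ≈ 90% absent-flag rate on pure speckle
  at ≈ 75% per-window detection on a lattice-dominant phantom.
* **ACE** — spectral difference across depth: per band frequency,
  regress power (dB) on window depth (cm); the slope of that decay rate
  against frequency equals `−2·ACE`. Requires ≥ 3 windows spanning
  ≥ 1 cm. An optional first-order compensation
  (`compensate_attenuation`) can be applied to deeper windows before the
  other fits; it is off by default since map-level attenuation
  correction is a configuration choice, not part of the estimator
  contract.

**Window geometry.** 2 × 2 mm windows: 104 axial samples and 10 lines at
the 40 MHz / 1540 m/s / 0.2 mm defaults. Map production uses 94% overlap
(step = max(1, round(0.06 × length)) per axis); windows ≥ 90% inside the
ROI mask are kept. Estimator-recovery studies use 50% overlap and
frame-averaged spectra — recovery does not depend on map oversampling,
and averaging the window periodograms before the nonlinear fits
suppresses speckle-induced bias (the `ln`/`√` nonlinearities plus range
clipping would otherwise skew per-window ASD at small diameters).

## Regions of interest

The core is rasterized from the contour polygon (pixel centres, boundary
inclusive); the margin is every outside pixel within 5 mm *Euclidean
physical* distance of the core (axial and lateral pitches differ, so a
pixel-based dilation would be anisotropic), clipped at the frame edges.
Whether the clinical margin was contoured or derived is not knowable
from the study description; derivation by dilation is the assumption
consistent with a fixed 5 mm rim.

## Features

49 QUS features per patient: 7 core means (MBF, SS, SI, SAS, ASD, AAC,
ACE), 6 margin means (no ACE — attenuation is a single core scalar, and
it has no per-window map in the schema), 24 core-map GLCM textures
(6 maps × CON/COR/ENE/HOM), 6 CMR and 6 CMCR; plus ER/PR/HER2 → 52.
GLCM uses 16 equal-width levels over each map's own min–max (making
texture invariant to affine rescaling of the parameter values),
symmetric co-occurrence at distance 1 over the four principal offsets,
pairs involving absent cells skipped, offset features averaged. A
constant map follows the single-bin convention CON = 0, ENE = 1,
HOM = 1, and COR = 0 (bounded, no NaN propagates into the classifier).
CMCR is defined as a contrast-to-noise ratio,
`|mean_core − mean_margin| / (sd_core + sd_margin)` (denominator floored
at machine epsilon, result capped at 10⁶); the definition is isolated in
one function because alternative contrast-ratio conventions exist.
Plane feature vectors are averaged per patient over the planes where
each feature is present.

## Statistics and classification

Univariate ranking applies a Shapiro–Wilk screen (α = 0.05, both
classes) to choose between the equal-variance two-sample t-test and the
two-sided Mann–Whitney test (exact for small tie-free samples); features
are ranked ascending by p with ties broken by |standardized mean
difference| then name. No multiple-testing correction enters the
ranking; Bonferroni-adjusted values are reported alongside.

Class balancing repeatedly draws minority-size majority subsets (without
replacement within a set, with replacement across sets) until every
majority patient is covered; set *sizes* are deterministic
(2 × minority), set *counts* are stochastic realizations of the coverage
process.

SFFS starts from the top-ranked feature and alternates greedy inclusion
with conditional exclusion, capped at 5 features; the criterion is the
validation AUC of the configured classifier averaged over 3 fixed inner
stratified 70/15/15 splits (averaging stabilizes the criterion enough to
recover interaction pairs reliably while remaining deterministic given
the seed). The best subset over all visited sizes is returned, ties
preferring fewer features.

The ANN is a single hidden layer of logistic units with logistic output
and cross-entropy loss, trained to tolerance by L-BFGS; features are
standardized by training-split statistics only; the hidden size (1–10)
is selected by validation AUC — this model-selection step is the
validation-based stopping mechanism. KNN tunes k over {1, 3, 5, 7, 9} on
the same splits, scoring AUC by vote fraction. Per balanced set the
protocol repeats over 10 bootstrap re-splits; test sensitivity,
specificity and accuracy (percent) and trapezoidal AUC are averaged over
the bootstraps and reported across balanced sets as mean ± SD (n−1).
All randomness descends from one master seed through a counter-based
tag-derivation scheme, so identical seeds reproduce reports byte for
byte.

## Synthetic cohorts

`simulate_cohort` draws class-conditional equicorrelated Gaussian
feature vectors with specified standardized mean differences, named per
the 49-feature schema, with Bernoulli ER/PR/HER2 columns at the study's
per-class prevalences (61/71%, 54/65%, 37/24%). Defaults are the study's
class counts (83/17) and null effects; validation scenarios state their
effect sizes explicitly. What the generator does *not* emulate: feature
distributions inherited from shared windows (QUS features of one patient
are correlated through the same maps), non-Gaussian tails, plane-count
variation, or any genuine biological linkage between receptor status
and QUS features. Passing classification checks on these cohorts
validates the machinery (balancing, selection, tuning, anti-leakage,
calibration), not clinical performance.

## Validation problem sizes

Phantom recovery runs 20 frames per condition on 14 × 12 mm phantoms
(40 mm deep for attenuation), 2 × 2 mm windows at 50% overlap: diffuse
diameters {50, 100, 200} µm at 25 /mm², a density doubling at 100 µm, a
1 mm lattice (1% jitter, 1 /mm² diffuse background), and α = 0.7
dB/cm/MHz. These sizes make the Monte-Carlo tight enough for the 10–15%
recovery checks while keeping the whole validation desk-scale.

## Known limitations

* ACE reads ~5–10% low: log-domain averaging of speckle combined with
  the electronic noise floor compresses the apparent spectral decay of
  the deepest windows (0.666 recovered at infinite SNR, 0.63 at 30 dB,
  truth 0.7). Well inside the 15% validation band, but systematic.
* SAS carries a ~4–6% low bias (finite-band autocorrelation with ~4.7
  ripple periods on the band) and per-window estimates on 2 × 2 mm
  windows are intrinsically marginal for spacings near 1 mm (the window
  holds two periods); frame-level averaging is the reliable mode.
  Spacings above ~1.3 mm are unresolvable at this window size even
  though the nominal search range extends to 2.5 mm.
* The simulator's amplitude statistics (Gaussian about a positive mean)
  produce slightly sub-Rayleigh speckle at low densities; estimators are
  validated in expectation, not against absolute backscatter levels.
* `fit_form_factor` at diameters ≲ 30 µm approaches the flat-spectrum
  degeneracy; per-window estimates there cluster at the lower search
  bound and only frame-averaged spectra are informative.
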