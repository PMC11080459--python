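# Methods

This note documents the models behind `metabarcode`: what is simulated, the
physical and statistical assumptions, the numerical choices, and what the
synthetic experiments can and cannot demonstrate.

## The measurement being emulated

A pixelated all-dielectric metasurface ("molecular barcode") images
mid-infrared molecular absorption onto space.  49 metapixel designs with
resonances spaced linearly over 1400–1800 cm⁻¹ are duplicated (pixel
doubling), joined by two extra designs, and arranged in a seeded random
10×10 pattern.  An IR microscope records hyperspectral reflectance cubes
(one per 64 s frame) of the chip under D₂O, while a supported AzoPC
photolipid bilayer on the surface is switched between its trans and cis
conformations by UV (365 nm) and visible (465 nm) LEDs.  Downstream, spectra
are extracted per metapixel, absorbance is computed against the D₂O
reference, and a 1D CNN classifies the membrane state, with
integrated-gradients attribution selecting the most informative metapixel
for a pruned single-metapixel classifier.

## Optical forward model

Each metapixel resonance is a single-mode temporal coupled-mode (Fano)
lineshape rather than a numerically solved electromagnetic response:

    R(ν) = bg(ν) · | r_bg + a · γ_r / ( i(ν − ν₀) + γ_r + γ_nr + ℓ(ν) ) |²

with total half-width γ_r + γ_nr = ν₀ / (2Q), radiative fraction
γ_r/(γ_r+γ_nr) = 0.85, direct background reflection r_bg = 0.1, and
amplitude a = 0.6 by default.  Defaults give peak reflectances ≈ 0.35 over
a ≈ 0.01 background, with Q = 100 (the fabricated resonators exceed Q = 80).
Because r_bg is real, the noise-free lineshape is an exact symmetric
Lorentzian; the package's Q-recovery oracle exploits this by curve-fitting
constant + Lorentzian and recovering ν₀ and Q to machine precision.

Molecular absorption enters as an added loss channel ℓ(ν) ≥ 0 in the
denominator — the weak-coupling regime where vibrational bands attenuate
the resonance rather than split it.  ℓ(ν) is a coverage-scaled sum of
unit-peak Lorentzian bands whose strengths (peak added linewidth, cm⁻¹)
interpolate linearly between the trans band set (cis fraction 0) and the
cis band set (cis fraction 1).

The AzoPC band model: CH₂ scissoring 1470 cm⁻¹ (strength 0.8), azobenzene
ring breathing 1496 cm⁻¹ (0.6), ester C=O stretch 1735 cm⁻¹ (1.5) in both
isomers, plus the N=N stretch 1511 cm⁻¹ (1.0) in cis only; all FWHM
15 cm⁻¹.  Cis strengths are additionally scaled by 1/1.2 ≈ 0.83, encoding
the ≈ 20 % lipid footprint increase (lower areal density) upon
photoisomerization.  Strengths were set so that retrieved absorbances fall
in the 10⁻²–10⁻¹ range typical of surface-enhanced IR absorption; γ ≈
7–9 cm⁻¹ against band losses ≤ 1.5 cm⁻¹ keeps the system safely in the
weak-coupling regime the loss-channel model assumes.

The D₂O medium is a smooth Beer–Lambert attenuation 10^(−A_med(ν)) with
A_med a broad Lorentzian wing (centre 1210 cm⁻¹, FWHM 180 cm⁻¹, amplitude
0.25) plus a constant 0.02 — a qualitative stand-in for the D₂O absorption
rising toward the low-wavenumber edge of the window; its true quantitative
profile is not modelled.  The instrument's gold-mirror background is treated
as already divided out.

## Switching kinetics

The cis fraction obeys piecewise first-order relaxation toward the
photostationary state of the active LED: dc/dt = k(pss − c) with k_UV =
k_VIS = 0.03 s⁻¹, pss_UV = 0.9, pss_VIS = 0.1; in the dark c is constant
(AzoPC thermal relaxation is hours-slow against the experiment).  Rates are
chosen so switching completes well inside the 4 min 30 s LED window
(time constant ≈ 33 s).  Trajectories are evaluated analytically per event,
so there is no integration error and c ∈ [0, 1] holds exactly.  The default
protocol is a 70 min lead-in followed by three UV/VIS cycles (LED on 270 s,
off 900 s), sampled at the 64 s frame period.

## Noise model and synthetic datasets

Imaging pixels carry i.i.d. additive Gaussian noise (σ = 5×10⁻³ reflectance
units per pixel) plus a frame-wide multiplicative drift, an
Ornstein–Uhlenbeck process around 1 (stationary sd 0.02, timescale 600 s)
emulating slow illumination/evaporation drifts.  Spatially, each of the 100
physical pixels is a 16×16 block of imaging pixels on a 160×160 grid — a
desk-scale stand-in for the instrument's 480×480 field of view (block size
configurable).

Labeled datasets reproduce the study conditions: 247 items per class (494
total), each item the full set of 49 averaged metapixel spectra on the
1300–1800 cm⁻¹ model grid (251 points).  Cis items draw their cis fraction
from N(0.9, 0.03) (the UV photostationary state), trans items from
N(0.1, 0.03); coverage from N(0.9, 0.03); labels follow the generating state
(cis fraction ≥ 0.5 → cis).  The default generator synthesizes items
directly at the averaged level with noise σ/√(2·16²) — exactly the standard
error block averaging of a full cube would produce; the full cube → extract
→ average route exists as `mode="cube"` and the equivalence is verified by
tests rather than assumed.  Frames recorded while an LED is on, or within
14 min before the first illumination, are flagged excluded and not used for
training.

Two control configurations: a *null* contrast (both classes generated from
the identical distribution — the synthetic analogue of training on bare
substrate spectra) and a *band-only* contrast in which the classes differ
solely by one band at 1742 cm⁻¹ (strength 1.0, matched to the default band
scale) for validating attribution-driven feature selection.

What the generator does *not* emulate: water-vapour/atmospheric lines,
spatially structured noise or membrane inhomogeneity within a block,
resonance-position drift or fabrication disorder, detector nonlinearity, and
any coupling-induced lineshape distortion beyond the loss channel.  Passing
tests therefore demonstrate the *pipeline's* correctness and the
architecture's capacity under realistic amplitude/noise scales, not
instrument-level performance on real membranes.

## Spectral extraction and absorbance

Extraction averages each slot's block per wavenumber; doubled metapixels are
averaged pairwise (extras excluded), giving exactly 49 spectra ordered by
design.  Absorbance is A = −log₁₀(R_sample/R_D₂O) evaluated at each
design's resonance position snapped to the nearest grid point (base-10 by
spectroscopic convention; the alternative of tracking the fitted resonance
minimum is configurable).  Dense absorbance spectra are reconstructed by
linear interpolation onto the model grid followed by one third-order
Savitzky–Golay pass (window 11 points; edges handled by polynomial fit, so
cubics are preserved exactly).  The 7×7 barcode map places the 49 per-pixel
absorbances in target-design order, not physical order.

## Classifier, training, attribution

Both CNNs are implemented directly on numpy (im2col convolutions over BLAS
matmuls, float32, exact analytic backprop verified against finite
differences).  The *original* network: conv layers (128, k5, s2), (100, k3),
then 80/60/40/20 with k1, ReLU after the first five, dropout 0.2 before a
fully connected softmax head with two outputs.  The *pruned* network: four
conv layers 8/16/32/32 with kernels 7/5/5/5 on a single metapixel spectrum.
All convolutions are unpadded ("valid").  Metapixel spectra enter the
original network as 49 input channels of length 251; a concatenated
single-channel arrangement (49×251 features) is available as
`arrangement="concat"`.  Training: stratified 70/30 split, 160 epochs,
softmax cross-entropy, Adam (lr 10⁻³, batch 32 — standard defaults, exposed
in `TrainConfig`).  Every random element (split, init, batch order, dropout)
is seeded, and runs are bit-reproducible single-threaded.

Integrated gradients uses the all-zeros baseline and a right-endpoint
Riemann sum on the pre-softmax score of the target class (logits avoid
softmax saturation).  The completeness residual |ΣIG − (F(x) − F(0))| is
recorded on every map; at 512 steps it sits at the float32 accumulation
floor (≪ 1 % of the score difference).  Per-metapixel importance is the sum
of |IG| over each metapixel's wavenumber block, averaged over validation
inputs and normalized to max 1; the importance *ranking* converges at far
coarser quadrature than completeness, so aggregation defaults to 64 steps
over 64 inputs.  Ties in top-k selection break toward lower resonance
wavenumber.  "Pruning" is architecture replacement — the small network is
trained from scratch on the selected metapixel — not magnitude pruning of
weights.

## Problem sizes and numerical choices

Experiments run at desk scale chosen for a single CPU: the dataset protocol
(494 spectra, 160 epochs) is kept in full for the headline experiments; the
feature-selection control (band-only contrast) runs at 240 spectra and 60
epochs, which is past that task's convergence point; Monte-Carlo invariants
use ≥ 100 seeds on reduced layouts; the acceptance experiments use 5 seeds
(signal) and 10 seeds (null) and report medians.  Degenerate inputs are
validated errors, not silent behaviour: non-positive reflectance in the
absorbance ratio, Q ≤ 0, overlapping LED events, inputs shorter than the
first kernel, classes with fewer than two items, Savitzky–Golay windows not
exceeding the polynomial order.

## Known limitations

- The coupled-mode lineshape is a phenomenological stand-in; no claim is
  made that it reproduces any fabricated device's spectra quantitatively.
- The loss-channel coupling omits strong-coupling effects (mode splitting)
  and any frequency pulling by the molecular resonance.
- The D₂O profile and the LED photokinetic constants are plausible choices,
  not fitted values.
- The null-contrast control bounds what the classifier can learn from the
  generator's nuisance structure, but chance-level accuracy there does not
  rule out confounds present only in real measurements.
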