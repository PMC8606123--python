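# Methods

## Problem and model

Fourier-domain OCT resolves depth by interfering broadband light with a
reference arm: the spectral interferogram carries one cosine fringe per
reflector, `fringe(k) ∝ S(k) cos(2 k z)`, and the axial point-spread
function (PSF) is the envelope of the coherence function — the Fourier
transform of the source power spectrum `S(k)` over wavenumber with the
round-trip kernel `exp(i·2kz)`. A continuous visible band (425–685 nm)
yields a single-lobed PSF of roughly micrometre width; concentrating the
same spectral support into two narrow bands (510 nm / 10 nm FWHM and
635 nm / 6 nm FWHM) leaves each band's own coherence envelope
(`(2 ln 2/π)·λ²/Δλ` ≈ 11.5 µm and 29.7 µm) modulated by the beat between
the two carriers (period `π/Δk` ≈ 1.3 µm), i.e. a wide envelope cut into
ghost replicas. The package reconstructs the broadband-quality amplitude
image from the two-band acquisition with a conditional GAN whose input is
the complex image expressed as two channels, log-compressed amplitude and
wrapped phase, both normalized to [0, 1].

## Simulator

`phantoms` implements the standard forward model: discrete scatterers
`(x, z, r)`, per-A-scan Gaussian lateral beam weighting (2.0 µm FWHM
transverse resolution), fringe synthesis on a uniform-wavelength
spectrometer grid, additive white Gaussian noise on the fringes, and
reconstruction by mean-spectrum subtraction → cubic resampling to uniform
wavenumber → FFT → positive-depth half-space. Three phantom families mimic
the study samples: thin regularly spaced scattering bands (tape), isolated
beads with a minimum spacing of five broadband PSF widths (so per-bead
fits are uncontaminated), and a three-layer piecewise-constant random
scatterer field (tissue) whose reconstructed amplitude exhibits fully
developed, Rayleigh-like speckle.

Paired data are produced in two modes. `synthetic-gap` (default)
multiplies the broadband fringes per wavelength with the two-Gaussian
window and reconstructs both members from the same realization — pairs are
co-registered by construction, which is also how the study generated its
synthetically gapped training data. `two-source` synthesizes the gapped
member from the windowed spectrum with the same scatterers and noise seed,
emulating a physically separate second source.

Key simulator defaults and the reasoning behind them:

* **Spectral axis 400–710 nm, 256 samples; 64 A-scans over a 128 µm field;
  64 depth pixels kept (pitch 0.458 µm).** The margin around the 425–685 nm
  band keeps the rolled-off band edges and window tails on-grid. Only the
  shallow quarter of the FFT half-space is imaged because the blue end of a
  wavelength-sampled spectrometer aliases fringes from deep reflectors;
  with 256 spectral samples the blue-end Nyquist depth (≈ 33 µm) lies
  safely below the deepest scatterer, mirroring how real 4096-pixel
  systems are operated. The full study geometry (500×4096, 400 µm field)
  is reachable by configuration.
* **Broadband spectral shape: raised cosine over 425–685 nm.** The true
  filtered-supercontinuum shape is not public. A near-flat band is the
  wrong model here for two reasons: any top-hat-like spectrum rings (first
  PSF sidelobe 13–22 %), putting visible ghost lobes on isolated
  reflectors in the *ground truth*, which real broadband acquisitions do
  not show; and its ideal ~0.5 µm resolution is well beyond the 1.2 µm the
  real system measures. The raised-cosine band is ringing-free and its
  Gaussian-fit PSF FWHM (≈ 1.13 µm) reproduces the measured resolution
  class. A smoothed top-hat remains available (`shape="tophat"`).
* **Fringe noise σ = 0.2 of the noiseless fringe RMS.** This places the
  broadband image's noise floor ≈ 31 dB below the peak — visible within
  the 40 dB display window, matching the plainly visible background noise
  of real B-scans (which the network demonstrably suppresses). Much
  smaller values produce unrealistically clean images and remove the
  signal/noise-separation role attributed to the phase channel.
* The blue SLED band (450 nm / 5 nm) is modelled but excluded from the
  default window, as it was not used for imaging.

## Processing conventions

Amplitude is log-compressed over a 40 dB window below the per-image
maximum and mapped to [0, 1]; the display range is a choice (figures in
the field are log-scaled but the exact range is rarely stated). Phase is
the wrapped angle mapped by `(angle+π)/2π`, not unwrapped. Normalization
is per image, making the network exposure-invariant. The inverse of the
log mapping (`channels_to_linear_amplitude`) is used whenever physical
linear amplitude is needed, e.g. for FWHM fits on network output.

## Network and objective

The generator is a U-Net: stride-2 4×4 convolutions with LeakyReLU(0.2)
encoding, stride-2 transposed convolutions with ReLU decoding, skip
concatenations, batch normalization on hidden levels (skipped where the
spatial extent degenerates), tanh output mapped to [0, 1]. The
discriminator is a stack of F = 5 strided convolutions whose activation
maps feed the perceptual loss, with a global-average-pool + linear +
sigmoid head. Channel widths double per level from a configurable base
(64 up to a 512 cap at full scale; 16 up to 128 for the desk-scale
experiments below). Weights are initialized from a truncated normal
(std 0.02), seeded. The discriminator judges the single image it is given
(generated or real) without concatenating the generator's condition; a
conditional variant can be built by widening `DiscriminatorSpec.in_channels`.

The objective uses the weights λ_G = 100, θ_G = 1, θ_D = −1, margin
m = 50, λ_j = (5.0, 1.5, 1.5, 1.5, 1.0), with λ_1 applied to the
shallowest hidden layer. The perceptual term is
`L_P = Σ_j λ_j · mean_batch ‖d_j(y_real) − d_j(y_recon)‖₁` with the L1
norm taken over the full feature map; the discriminator objective is
`L_D = θ_D·½(L_real + L_recon) + max(0, m − L_P)`; the generator objective
is `L_G = θ_G·L_adv + λ_G·mean|y_real − y_recon|` with the image term a
per-pixel mean.

**Sign conventions.** If the per-label terms `L_real`, `L_recon` are read
as log-likelihoods, θ_D = −1 makes the discriminator *minimize* the usual
cross-entropy while the hinge pushes the hidden-feature distance up to the
margin m — the perceptual-adversarial formulation. This package's
`bce_loss` returns the standard positive cross-entropy, so the optimizer
descends `½(BCE(1, D(real)) + BCE(0, D(fake))) + max(0, m − L_P)` — the
same direction the min/max objective implies — while the pure function
`discriminator_loss` evaluates the formula as written for reporting. The
generator's adversarial term uses target label 1 on generated images (the
non-saturating direction).

Because no deep-learning framework is part of the package's dependency
set, the conv layers, batch norm, transposed convolutions, Adam and
backpropagation are implemented in numpy (`octgan.nn`), with im2col/col2im
convolutions (BLAS matmuls inside) and finite-difference-verified
gradients. Batch statistics are used at inference as in training; with
batch size 1 this is instance normalization, so checkpoints store no
running moments.

## Training protocol

Adam with learning rate 2·10⁻⁴ and β = (0.5, 0.999) for both networks;
batch size 1; three discriminator updates per generator step (one fresh
fake and two drawn through the history pool, each paired with the current
real image); an image pool of capacity 50 that fills first and then
replaces a uniformly chosen entry with probability 0.5 (returning the
evicted image for training); a random 95:5 train/validation split;
per-epoch shuffling; and augmentation with probability 0.5 per image per
epoch. Augmentation operations are restricted to geometry that preserves
pair registration — lateral mirror and a small circular lateral roll
(≤ 4 px), applied identically to both members; intensity transforms are
excluded for the same reason. The epoch count is not part of the published
protocol; the checkpoint kept is the lowest-validation-L1 epoch, and NaN
losses abort with a diagnostic. A fixed seed reproduces a run bit-for-bit
on one device.

## Evaluation

SSIM (single scale, Gaussian window σ = 1.5, K₁ = 0.01, K₂ = 0.03, data
range 1) and PSNR (flagged infinite at zero MSE) are computed per image
for input-vs-truth (I) and prediction-vs-truth (P); cohort similarity uses
the Fréchet distance `‖µ₁−µ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^{1/2})` between
Gaussian fits of feature distributions. The default feature extractor is a
fixed-seed three-stage random convolutional embedding (64 features): it
requires no downloaded weights, is deterministic, and keeps relative
comparisons (I vs P) meaningful; any pretrained embedding can be plugged
in and shares the same matrix-square-root formula. Absolute FID values are
therefore not comparable to Inception-based numbers.

Bead axial resolution is measured by least-squares Gaussian + offset fits
on linear-amplitude profiles through each bead, restricted to ±3 expected
FWHMs of the respective source (the model PSF's own Gaussian-fit width).
A fit is rejected — and counted — when r² < 0.3, the FWHM exceeds the fit
window or falls below half a pixel, or the fitted center strays more than
half a window from the bead; rejections are typically dim beads the
network suppressed. The improvement factor is
mean FWHM(input) / mean FWHM(prediction).

## Desk-scale experiment sizes

The quantitative self-checks (`octgan.experiments`, exercised by the test
suite and `scripts/acceptance.py`) run on 64×64-pixel B-scans with a
4-level base-16 U-Net and base-16 discriminator: the image-quality
experiment trains on 200 mixed-phantom pairs (tape:beads:tissue = 3:3:2,
the study corpus proportion) for 8 epochs and evaluates 50 held-out pairs;
the resolution experiment trains on 200 bead pairs for 30 epochs
(validation L1 plateaus near epoch 20) and fits the held-out beads; the
phase ablation repeats an identical mixed run three times per arm with
only the input channels differing. These sizes are the package's choice of
a single-workstation experiment; the library accepts the full study
geometry through the same configuration objects.

Two interpretation notes on the desk-scale quantities. First, with the
nominal Gaussian two-band window the input bead profile's Gaussian fit is
pinned near the green band's coherence envelope (~11–12 µm, stable across
seeds), so the resolution-improvement factor is governed almost entirely
by how sharply the trained generator draws beads; the factor is therefore
a joint property of the method *and* the training scale, and grows toward
the physics ratio (input envelope / broadband PSF ≈ 10) as the generator
approaches the ground truth. Real two-band SLED spectra carry pedestals
outside their nominal Gaussian FWHM that shorten the input coherence
envelope, which the nominal-band simulator deliberately does not model.
Second, the phase-ablation comparison is a seed-averaged difference
between GAN training runs; at desk scale the run-to-run spread of the FID
is of the same order as the with/without-phase gap, so the comparison is
meaningful only as an average over repeated runs, which is how it is
computed.

## Known limitations

* The simulator is an idealized two-dimensional single-scattering model:
  no dispersion mismatch, spectrometer roll-off, relative-intensity noise,
  absorption or polarization contrast, and no cross-source
  misregistration (the drying/shrinkage issue of real tissue pairs is at
  most a sub-pixel-shift augmentation, off by default). Passing tests
  therefore demonstrate that the method behaves as described under the
  modelled physics — artifact structure, speckle statistics, resolution
  ratios — not that it reaches any particular quality on real data.
* Absolute SSIM/PSNR/FID values at desk scale are not comparable to
  full-scale values on measured data; only their direction (prediction
  better than input) is meaningful here.
* Speckle is reproduced statistically, but a GAN cannot reproduce a
  specific speckle realization; per-pixel metrics on speckle-dominated
  tissue images are accordingly low for input and prediction alike.
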