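# Methods

This note documents the models, numerical choices and known limitations of
`spectral-n2i`. It is the package's own account of its science; every
number quoted here is recomputed by the test-suite or the example scripts,
not asserted from elsewhere.

## Problem setting

Spectral (photon-counting) CT bins every detected photon by energy, so a
single scan yields one sinogram — and one reconstructed image — per energy
channel. Fine energy channels mean few photons per channel and therefore
strongly noise-limited channel-wise reconstructions, which is what makes
quantitative material identification (attenuation profiles, K-edge
fingerprints) hard. The package implements a self-supervised denoiser for
such data, following the Noise2Inverse idea: noise in CT measurements is
independent from projection to projection, so reconstructions from disjoint
angular subsets of one scan are independently-noisy views of the same
object, and a network trained to map one to the other converges toward the
clean image without ever seeing clean data.

## Simulation model

**Source spectrum.** A semi-empirical thick-target tungsten-anode model:
Kramers-type bremsstrahlung production distributed over electron
penetration depth via the Thomson–Whiddington relation
(C_TW = 7.85x10^5 keV^2 cm^2/g), with each depth's photons attenuated along
the oblique escape path through the anode at the take-off angle (default
12 deg). The absolute scale comes from the Kramers radiative efficiency
eta = k_e Z V with k_e = 1.1x10^-9 per volt, isotropic emission, and
fluence referenced at 100 cm (the length of the air column in the default
filtration). Tungsten K-lines (K-alpha 58.0/59.3, K-beta 67.2/69.1 keV) are
added above the 69.525 keV K-shell threshold with a (U0-1)^1.63
overvoltage yield law (1.1x10^-3 photons/electron at unit reduced
overvoltage). External filtration (default 4 mm Al + 1 mm Be + 1000 mm
air) applies Beer–Lambert factors. The model reproduces the shape and
order of magnitude of measured 150 kVp spectra — with 0.5 keV bins the
spectral maximum is the K-alpha1 line bin, an order of magnitude above the
continuum — but it is not a Monte-Carlo code and its absolute normalisation
is uncertain at the tens-of-percent level. In the pipeline this does not
matter: the channel spectrum is renormalised to a fixed photon budget
(60,000 photons per detector pixel summed over channels) before noise is
drawn.

The channel grid follows the study protocol: generate at 0.5 keV,
interpolate the spectral density linearly to a 0.1 keV grid on
[19.550, 150.450] keV, average blocks of 10 (giving 131 one-keV channels
centred at 20…150 keV), renormalise. Rebinning averages per-bin fluence,
so a constant spectrum stays constant and mean flux is conserved.

**Attenuation data.** Mass-attenuation coefficients come from small
packaged element tables (H, Be, C, N, O, Al, Ar, I, W) with log-log
interpolation, following the standard XCOM-style compilations to a few
percent; edges are represented by near-duplicate abscissae (iodine K at
33.1694 keV, tungsten K at 69.525 keV). Sub-6 keV L/M fine structure of
the heavy elements is smoothed or omitted — irrelevant above the 20 keV
lower bound of the simulated channels, but a real limitation if the tables
were used for low-energy work. Compounds use the mixture rule with mass
fractions derived from parsed chemical formulas; densities are nominal
room-temperature values.

**Phantoms.** Two four-material presets on a 100x100 grid (water, olive
oil, nitromethane, acetone; methanol, ethylenediamine, aluminium,
nitrobenzene), rasterised as four non-overlapping discs (radii 13–16 px)
at the quadrant centres — the disc layout is a package choice, recorded in
metadata, since only "four distinct objects" is prescribed. Densities are
modulated sinusoidally along x (amplitude 0.05, period 25 px by default)
to emulate relative density variations; the background is exactly zero.
LAC is linear in density by construction, and any edge-free material's LAC
decreases strictly with energy — both are tested properties.

**Geometry and forward model.** Fan-beam: point source 57.50 cm from the
rotation axis, flat 256-pixel detector (0.8 mm pitch) 58.05 cm behind it,
360 projections at 1 deg. The image pixel size defaults to
field-of-view/grid so the phantom spans the fan's field of view
(~1.02 mm/px at full size). Line integrals are sampled at half-pixel steps
with bilinear interpolation (Joseph-style), making the operator exactly
linear with a well-defined sparse-matrix form (used by the iterative
solver). Parallel-beam mode exists as a simpler fallback. Noise follows
the poly-energetic Beer–Lambert model per channel: counts ~
Poisson(I0(E) exp(-y)), attenuation recovered as ln(I0/counts) with counts
clipped to >= 1 (the standard fix for zero counts; flagged in provenance).
Channels, angles and detector pixels are corrupted independently — the
independence that underwrites the self-supervision. Scatter, pile-up,
detector cross-talk and beam hardening are not modelled.

## Reconstruction

Channel-wise filtered backprojection with the discrete Ram-Lak kernel
(h[0] = 1/(4 du^2), h[odd k] = -1/(pi k du)^2), optionally apodised by a
Hann window; the cutoff parameter s is the fraction of Nyquist where the
window reaches zero (Hann) or the response truncates (Ram-Lak). Fan-beam
FBP uses virtual-detector rebinning-free weighting (cosine pre-weight,
1/U^2 backprojection weight) over the full 360 deg. Per-angle weighting is
2*pi/n_angles, so a reconstruction from any equally spaced angular subset
is unbiased and the mean of the K subset reconstructions equals the
all-angle reconstruction to machine precision on noiseless data — the
algebraic backbone of the leave-one-out scheme. On a noiseless uniform
disc the interior LAC is recovered well within 3 %.

Angular splitting uses the stride rule: subset j takes angle indices
j, j+K, j+2K, …, giving K interleaved, equally spaced subsets whose sizes
differ by at most one.

## Denoiser

From K subset reconstructions, K leave-one-out pairs are formed: input =
mean of K-1 reconstructions, target = the held-out one (for K=2 the pair
degenerates to plain Noise2Noise). Training operates on overlapping
energy-spatial blocks (default 4x16x16, i.e. 4 energy channels deep; the
energy depth maps onto the convolution channel axis, which is what couples
neighbouring channels and regularises along energy). Block stride is
round(size x (1-overlap)) per axis with a flush block appended at each
border so every voxel is covered; overlapping predictions are recombined
by plain averaging, and extract->assemble is an exact round-trip.

The network is a three-level 2-D U-Net (double 3x3 conv + batch norm +
ReLU per level, 2x2 max pooling, nearest-neighbour upsampling with a 3x3
conv, skip concatenation, 1x1 output conv), implemented in numpy with
manual backpropagation and Adam. Choices the study leaves open and this
package fixes: base width 32 doubling per level (configurable); blocks are
standardised by the training-input mean/SD; and the net is trained
*residually* — it predicts the correction added to its input — which keeps
an undertrained network close to the identity map and makes short
training budgets behave sensibly. The MSE objective between prediction
and held-out target is unchanged by this reparameterisation. No
train/validation split and no early stopping: a fixed epoch schedule
(default 100 epochs, lr 1e-4, batch 32, Adam), as in the study protocol.
One integer seed drives weight initialisation and batch shuffling, and
training is bit-reproducible on one machine for a fixed seed.

At inference the trained network is applied to the mean of the K
reconstructions (algebraically identical to the mean of the K training
inputs) block-by-block, and the blocks are averaged back together.

## Baselines

**Low2High** reconstructs one full-angle sinogram twice — Hann s=0.2
(low-pass, nearly noise-free) and Ram-Lak s=1 (full band, noisy) — and
trains the same block-based machinery to predict high from low; inference
applies the model to the low-pass reconstruction (the study does not state
which input is used at test time; the low image is the choice consistent
with "predicting the high frequencies from the low-frequency content").
Unlike the Noise2Inverse denoiser, the baseline's network is plain (no
residual shortcut), matching the published scheme — and it is the plain
network that inherits the low-pass filter's amplitude shrinkage. The
residual variant over-corrects instead and loses the bias, which is why
the baseline deliberately does not share that design choice. Expected
behaviour, reproduced in the acceptance suite: smoother ROI statistics
than Ram-Lak FBP but a negative attenuation bias.

**IR-TV** minimises 0.5||Ax-y||^2 + alpha TV(x) channel-by-channel with
FISTA (default 100 iterations); the TV proximal step is Chambolle's
projection algorithm (scikit-image), the gradient step is 1/L with L from
50 power iterations on A^T A. TV is isotropic and strictly per-channel —
deliberately no energy coupling, since that is the baseline's documented
weakness. alpha=0 reduces to accelerated least squares and matches the
dense pseudo-inverse on a tiny system to 1e-4; study presets alpha=1
(phantom 1), 0.5 (phantom 2), 0.035 (real data).

## Evaluation

PSNR uses the *joint* maximum of both images as the peak — faithful to the
protocol's printed formula, with a reference-max switch — and reports an
infinity sentinel when MSE = 0. SSIM is the local-window form (7x7 uniform
window, c1=(0.01L)^2, c2=(0.03L)^2 with L the reference data range),
cross-checked against scikit-image. CNR = |S_T - S_B|/(sigma_T + sigma_B);
the denominator follows the formula line (the prose contains a typo
repeating sigma_T). ROI analysis reports per-channel mean/SD profiles, the
channel-averaged SD as the scalar noise summary, and the mean/SD over
channels of the per-channel squared profile error.

## Scaled-down study conditions

The full-size experiment (131 channels, 100x100, K=4, 100 epochs, 75 %
block overlap) is runnable but slow on one CPU, so the packaged fixture —
used by the tests and the worked example — scales it down once, as a fixed
set of conditions: 32 channels (the 131-channel spectrum trimmed to 128
and rebinned by 4), a 64x64 two-material phantom, a 128-pixel detector,
360 projections, K=4, the same 60,000-photon budget, blocks 4x16x16 with
50 % overlap, base width 8, and 20 epochs at the study's lr of 1e-4 —
only the epoch count is scaled, so the scaled-down networks are
deliberately undertrained relative to the full 100-epoch schedule. On this fixture the denoiser
beats the noisy all-angle FBP in channel-mean PSNR and SSIM, with the
largest gains in the low-flux edge channels; the margins are necessarily
smaller than a 100-epoch full-size run would give.

What passing these tests shows — and what it does not: the synthetic data
exercise the full measurement chain (poly-energetic source, energy-resolved
attenuation, Poisson statistics, fan-beam geometry) but contain circular
objects only, no scatter or detector imperfections, and hard material
boundaries; performance on real scans (cone-beam, volumetric, detector
artefacts) is beyond what this simulation can certify.

## Numerical notes and degenerate inputs

* Zero counts are clipped to 1 before the log; with 60,000 photons over
  131 channels this affects a small tail of strongly attenuated rays.
* FBP of an all-zero sinogram is exactly zero (linearity); FBP and
  projection are exactly homogeneous of degree 1.
* `find_k_edge` returns the midpoint of the largest positive jump between
  consecutive samples if it exceeds 20 % of the local value, else None;
  a non-monotone energy grid is an error, not a silent sort.
* The spectrum's absolute fluence scale is model-limited (see above);
  everything downstream of `normalize_total_counts` is scale-free.
* Infinity sentinels (PSNR of identical images, CNR with constant ROIs)
  are propagated, never capped; summary means skip non-finite values.
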