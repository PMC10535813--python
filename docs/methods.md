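# Methods

## Overview

`dermoptics` decomposes cross-polarized sRGB skin images into per-pixel
melanin, hemoglobin and shading maps, modifies those maps with numeric
control, and quantifies the result. The pipeline has four layers:

1. a **spectral forward model** of skin reflectance (two-layer Kubelka-Munk),
2. a **color pipeline** turning reflectance spectra into white-balanced
   linear sRGB under a daylight illuminant and an idealized camera,
3. a **self-supervised inverse model** (residual encoder-decoder) trained so
   that re-rendering its maps reproduces the input image, and
4. **pigment metrics** (individual typology angle, melanin index, two
   erythema indices) that verify modifications behave as intended.

Because no clinical dataset ships with the package, a synthetic-skin
generator provides labelled data with the statistical structure the
pipeline assumes.

## Forward model

Skin is modelled as a thin melanin-bearing epidermis over a semi-infinite
hemoglobin-bearing dermis.

**Absorption.** mu_a(lambda) = vm * eps_mel(lambda) + vh * eps_hb(lambda),
linear in the chromophore volume fractions vm (melanin, 1.3-43 %) and vh
(hemoglobin, 2-7 %). Concentration is folded into the effective extinction
curves, so volume fraction is the model's only per-pixel pigment parameter.
The melanin curve is the standard epidermal power law
51.9 * (lambda/500 nm)^-3.33 mm^-1; the hemoglobin curves are smooth
idealizations anchored at representative whole-blood magnitudes (Soret
tail, 542/577 nm oxy peaks, 556 nm deoxy peak, low red absorption), mixed
at 75 % oxygenation by default. The spectra ship as two-column text files
and are replaceable.

**Scattering.** mu_s'(lambda) = a * [f_Ray (lambda/lambda0)^-4 +
(1 - f_Ray)(lambda/lambda0)^-b], defaults a = 3.0 mm^-1, b = 1.3,
f_Ray = 0.4, lambda0 = 500 nm.

**Layers.** The epidermis transmits by Beer-Lambert over its thickness
(0.06 mm default) with melanin plus a pigment-independent short-wavelength
baseline absorber, 6 mm^-1 at 450 nm decaying with a 30 nm constant —
a carotenoid-like term that gives minimally pigmented skin its residual
warm tint. Without it the model renders melanin-free skin bluish, which
contradicts the saturation behaviour of real light skin. The dermis uses
the semi-infinite Kubelka-Munk solution R_inf = 1 + K/S - sqrt((K/S)^2 +
2K/S) with the two-flux convention K = 2 mu_a and S = mu_s'. Total diffuse
reflectance is T_epidermis^2 * R_dermis; specular reflection is absent by
construction (cross-polarized acquisition).

All layer constants were fixed by calibrating the rendered tone scale
against the skin-tone anchors the modification experiments assume: typical
subjects near ITA 30 deg, saturation in the 40-50 deg range when either
pigment is fully removed, and a dark-brown (about -37 deg) limit at full
melanin addition. They are ordinary configuration values, not fitted
quantities.

**Image formation.** Per channel, I_m = integral L(lambda) R(lambda)
M_shading C_m(lambda) d lambda on a 5 nm grid over 450-750 nm (trapezoid
rule). L is a shipped daylight (D65-like) SPD; C_m is an idealized
three-Gaussian sensor (blue 465/35 nm, green 535/40 nm, red 630/35 nm).
The red channel is centered at 630 nm so that its hemoglobin sensitivity is
small, matching the red band's role in the melanin index; with a 600 nm
red channel the deoxy-hemoglobin shoulder leaks into the band and the
intensity-ratio erythema index responds to hemoglobin with the wrong sign.
White balance divides by the sensor's response to the bare illuminant, so a
perfect reflector maps to exactly (1,1,1). The camera -> XYZ matrix is a
least-squares fit of the sensor curves to an analytic multi-lobe Gaussian
approximation of the CIE 1931 observer; the combined camera -> linear-sRGB
matrix is row-normalized to preserve the white point exactly. Display
encoding uses the standard sRGB transfer function.

**Reflectance LUT.** The full spectral chain (without shading and gamma) is
baked into a 64 x 64 bilinear lookup table over the physiological (vm, vh)
ranges. Node values agree with brute-force spectral integration to 1e-9;
off-node bilinear error is below 1e-3 per channel. Bilinear interpolation
is monotonicity-preserving and has closed-form partial derivatives, which
is what makes the renderer differentiable.

## Inverse model and training

The decomposition network is a residual encoder-decoder (U-shaped, skip
concatenation) emitting three maps in [0, 1]. Desk-scale defaults: 16 base
channels, channel doubling capped at 2x, depth 4, 64 px patches, about
0.26 M parameters. It is implemented on a compact numpy reverse-mode
autodiff engine written for this package (conv via im2col, nearest-neighbour
upsampling, leaky ReLU); the engine is float32 with a float64 switch used
by the gradient-verification tests.

Training is purely self-supervised: the masked reconstruction error between
the input patch and the LUT rendering of the predicted maps, minimized with
Adam (lr 1e-3, 50-step linear warmup, global gradient-norm clip 1.0, weight
decay 1e-4), batch 8, 2000 steps by default, random 78 -> 64 px crops as
the only augmentation.  The error is computed between log-intensities,
``MSE(log(I + 0.01))``: skin absorbs most green and blue light, so a
linear-RGB MSE weights the bright red channel roughly ten times more than
the channels that carry the hemoglobin signature, and hemoglobin maps then
converge an order of magnitude more slowly than melanin maps.  The log
domain equalizes fractional error across channels and is also the domain in
which pigment amounts act linearly (optical density).  A plain linear-RGB
MSE remains available (``loss_space="linear"``).  Progress and checkpoints
always track the linear-RGB masked PSNR regardless of the optimization
domain; checkpoints are recorded whenever the running PSNR exceeds 35 dB.
Runs are bit-reproducible under the config seed.

Three further numerical choices matter and were found necessary:

- **Bounded linear head.** The maps are produced by a hard clip to [0, 1]
  with leaky (0.05) gradients outside the bounds rather than a sigmoid.
  The reconstruction loss has a constrained local minimum at the corner
  (melanin at its lower bound, hemoglobin at its upper bound) that captures
  a sigmoid head permanently: once saturated its gradient vanishes and the
  coordinated (melanin up, hemoglobin down) escape move is unreachable.
- **Prior-mean head initialization.** Head bias starts the maps at
  (0.15, 0.5, 0.85) with 10x-reduced weight scale. A neutral 0.5 start
  renders far too dark and the resulting transient slams melanin into its
  bound (the same corner trap).
- **Scaled residual branches.** Each residual branch is gated by a learnable
  scalar initialized at 0.3, keeping the norm-free trunk near identity at
  initialization. Group normalization was tried and rejected: it amplifies
  activations exactly when maps become near-constant, which is the expected
  solution for smooth skin fields, and destabilized training mid-run.

The shading head receives no supervision; a total-variation regularizer
is not applied (matching the training objective used for the maps).

## Full-image inference and modification

Images are mask-overlaid, linearized (inverse gamma), split into
overlapping patches (15 px overlap; the last patch in each dimension is
anchored to the image border), decomposed per patch, and the maps blended
with separable tent-profile weights normalized to an exact partition of
unity — in a two-patch overlap band this reduces to the symmetric linear
crossfade, so constant offsets blend as straight ramps with no seam.

Skin-tone modification adds a constant (normalized units; -1/+1 spans the
full physiological range) to the melanin and/or hemoglobin map and clips to
[0, 1]; clipping, not renormalization, is what produces the characteristic
saturation at strong negative shifts. Pigmented-region modification scales
the maps multiplicatively (0.8-1.4 melanin, 0.6-1.4 hemoglobin as the
conventional ranges). Modified maps are re-rendered per patch, blended, and
gamma-encoded. An identity modification reproduces the model's plain
reconstruction bit for bit.

## Pigment metrics

- ITA = arctan2(L* - 50, b*) * 180/pi, from the CIELAB coordinates (D65) of
  the mean masked sRGB color. The conventional dark..very-light category
  bands are exposed as a lookup but unused.
- Indices are computed on white-balanced linear RGB, where intensities are
  reflectances and the optical-density reference is I0 = 1:
  OD = -log10(I / I0), capped at OD 4 for zero intensities.
- Melanin index M.I = OD_R; erythema index E.I1 = OD_G - OD_R (Diffey);
  E.I2 = I_B * I_R / I_G (intensity-ratio form). Region contrast is the
  difference of mask means (pigmented region minus surround).

A structural note on E.I2: with a Beer-Lambert epidermis the exponent
OD_B + OD_R - OD_G is strictly positive for any monotonically decreasing
melanin spectrum, so the intensity-ratio form can never be fully
melanin-insensitive. In practice its region contrast is stable under
melanin-only scaling (within 10 % relative) when regions are macroscopic —
blob radii large against the pigment-field correlation length, with an
adjacent surround annulus — which is the geometry of real lesion-scale
measurements. For small regions comparable to the field correlation length,
random field differences between region and surround dominate the contrast
and no such band holds; that is a property of the fixture, not of the
modification machinery.

## Synthetic skin generator

Each subject is defined by base melanin/hemoglobin levels, Gaussian-filtered
white-noise fields around those levels (sigma chosen so the autocorrelation
falls to 1/e at the declared correlation length, default 8 px; amplitude
0.05), a slower multiplicative shading field confined to [0.6, 1.0], and
optional raised-cosine hyperpigmented blobs (default radius 20-28 px, gain
0.10-0.25 in normalized units) with core (r <= R/2) and annulus
(1.2-1.6 R) masks for region-contrast experiments. Population draws use
base melanin U(0.02, 0.12) and hemoglobin U(0.30, 0.60) in normalized
units (melanin volume fractions of roughly 2-8 %), which renders a
light-to-intermediate cohort with mean ITA near 30 deg — the population
structure the skin-tone experiments assume. Everything is deterministic
under the subject/master seed.

What the generator does *not* emulate: facial geometry, hair, pores and
fine texture, specular residue, camera noise, chromatic aberration,
illumination color casts, or inter-device variation. Tests passing on this
data therefore show that the training framework inverts its own forward
model and that the modification/metric chain behaves as designed; they do
not certify accuracy on clinical images, which would require device data
and a reference instrument.

## Problem sizes

The package's reference experiments run at desk scale on one CPU: 200
training patches (78 px, cropped to 64 px), 2000 optimization steps, 20
held-out subjects for reconstruction PSNR and parameter-recovery
correlation, 20 plain subjects (96 px) for skin-tone sweeps, and 12
single-pigment blob subjects (128 px) per pigment for region-contrast
sweeps. The architecture and training loop scale to larger patches and
budgets without code changes.

## Known limitations

- The two-layer Kubelka-Munk model ignores depth-dependent sampling of the
  dermis; channel OD sensitivities are therefore layer-separable, which is
  only approximately true in real skin.
- Hemoglobin spectra are idealized approximations, adequate for band-level
  structure but not for spectroscopic use.
- The shading/pigment decomposition is identifiable only through the
  spectral signatures of the pigments; strongly colored illumination would
  break it.
- The desk-scale reconstruction quality (roughly 50 dB masked PSNR on
  held-out synthetic patches) reflects a short CPU budget; the training
  framework, not the asymptote, is what the package exercises by default.
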