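# Methods

`fiberimg` is a desk-scale digital twin of an all-fiber high-speed imaging
system: a short laser pulse illuminates a small binary object, the
reflected light excites the guided modes of a long step-index multimode
fiber (MMF), intermodal dispersion stretches the pulse into a train of
per-mode subpulses, and a fast photodetector records the resulting 1D
waveform — one waveform per displayed frame. Learned and linear inverse
models then recover the 2D image from the 1D trace. This note documents
the physical model, its assumptions, the synthetic data, and the numerical
choices.

## Fiber model

**Modes.** The fiber is step-index and weakly guiding, so modes are the
scalar LP(l, m) family. For each azimuthal order l the characteristic
equation

    u·J_{l−1}(u)·K_l(w) = −w·K_{l−1}(w)·J_l(u),   u² + w² = V²,
    V = 2π·a·NA/λ

is solved for every radial root u in (0, V). We use the pole-free product
form with exponentially scaled Bessel K (`scipy.special.kve`), bracket
roots by a sign-change scan on a uniform 4000-point u grid per order, and
refine by bisection to 1e-12. This is robust against the poles of the
ratio form at Bessel zeros. For l > 0 both orientations (cos lφ, sin lφ)
are enumerated; they share u, β and group delay exactly. The reference
fiber (a = 25 µm, NA = 0.22, λ = 1064 nm) has V ≈ 32.48 and 269 guided
spatial modes, matching both a fine-grid sign-change oracle and the
closed-form cutoff count (zeros of J_{l−1} below V).

**Indices.** Only the NA of the hardware fiber is public, so the cladding
index defaults to fused silica near 1064 nm (n_clad = 1.4496) and
n_core = √(n_clad² + NA²). Absolute transit times depend on this choice;
delay *spreads* essentially do not. Material dispersion (Sellmeier) is out
of scope: indices are held constant when differentiating β.

**Group delays.** τ/L = dβ/dω is evaluated by a centred finite difference
of β over wavelength with relative step 1e-4, re-solving each mode's root
at λ(1 ± h); a mode that falls below cutoff at the longer wavelength is
differenced one-sided. Differentiating the same solver avoids validating a
separate closed form. Delays are exactly linear in fiber length by
construction. For the reference fiber the solver gives a 1 km delay spread
of ≈ 50 ns — above the ≈ 45 ns span observed on the hardware (which
plausibly excites a mode subset) and below the ray-optics bound
L·NA²/(2·n_core·c) ≈ 55 ns.

**Fields.** Transverse fields use the analytic J_l/K_l profiles sampled on
a square grid spanning 1.5× the core diameter (default 128×128), then
symmetric (Löwdin) orthonormalisation S^(−1/2)Ψ enforces exact discrete
orthonormality while staying as close as possible to the analytic
profiles. Cross-inner products are at machine precision afterwards.

## Forward encoder

**Coupling.** The object pattern is bilinearly resampled onto the facet
grid through a geometry block (pixel pitch, magnification, lateral
offset). Two coupling models are provided:

* *coherent* (default): c_m = Σ_px √I_px·e^{iφ_px}·ψ_m(px), P_m = |c_m|²,
  with φ = 0 (plane-wave illumination) or a seeded random speckle screen;
* *incoherent*: P_m = Σ_px I_px·ψ_m(px)², exactly linear in the image
  intensity — the model under which the linear pseudoinverse is an exact
  oracle.

Raw powers are returned by default so the incoherent model stays linear;
`normalize=True` divides by the input intensity over the facet window,
giving power fractions bounded by 1 (the discrete Bessel inequality — the
window rather than the core circle is the correct normaliser because the
mode fields carry evanescent tails beyond the core).

The default geometry maps the 28×28 × 7.56 µm object patch onto the 50 µm
core (magnification 0.24) with a (2, 3) µm lateral offset: a perfectly
centred launch is a measure-zero alignment and would give the forward map
an artificial circular symmetry.

**Waveform synthesis.** Subpulse powers add incoherently at the detector
(it measures intensity; inter-modal interference is not modelled at
detection). The trace is Σ_m P_m·g(t − τ_m) with g a unit-energy Gaussian
of the pulse FWHM (45.1 ps default), convolved with a unit-DC-gain
Gaussian detector impulse (15 ps) — evaluated in closed form as a single
Gaussian of combined width — sampled at 100 GS/s. The time window spans
[min τ − 5·FWHM, max τ + 5·FWHM + 5·impulse] and is shared by all frames
of one configuration (oscilloscope-style triggering). Additive white
Gaussian noise is scaled to the trace RMS at the configured SNR (default
30 dB — the hardware noise level is not public); omitting the noise seed
yields the noiseless trace. Pre-noise, the sampled integral equals the
total coupled power to 1e-3.

**Perturbation model.** Temperature and bending effects are abstracted as
(i) a random special-orthogonal mixing among modes whose delays differ by
less than one pulse FWHM (block-wise on the delay-sorted modes),
geodesically interpolated between identity (strength 0) and a full random
rotation (strength 1), which conserves total power to 1e-9; and (ii)
zero-mean Gaussian delay jitter of scale jitter·strength. Physical °C or
bend-radius coefficients are out of scope; only ordinal claims (e.g.
joint training tolerates at least the single-condition range) are
meaningful in the abstract strength units.

## Synthetic patterns

Glyphs (28×28, binarised, up to 36 classes) are stroke skeletons rendered
at 1–2 px width with per-sample affine jitter (±10 % scale, ±10°, ±2 px);
random-line patterns are dilated quadratic Béziers with optional
shift/rotate/scale augmentation; resolution targets are three-bar groups
of descending pitch (bar width = pitch/2; a 2 px pitch at 7.56 µm/px is
15.12 µm); grayscale blobs are sums of 2–5 Gaussians min-max normalised.
All generators are deterministic per seed.

What the generator does *not* emulate: the stroke statistics, thickness
profile and class overlap of real handwritten corpora; clothing textures;
DMD diffraction; illumination non-uniformity. Passing the recovery tests
therefore shows the *pipeline* (encode → waveform → learned inverse)
works at realistic mode counts, noise and sampling — not that the specific
published accuracy on real handwritten data would be reproduced pixel for
pixel.

## Decoders

Waveforms are cropped/zero-padded to 4096 samples (40.96 ns at 100 GS/s)
symmetrically about the support centroid — for the 1 km configuration this
window is slightly shorter than the full ≈ 50 ns spread, so the extreme
tail subpulses are cropped (documented, configurable) — then normalised by
scalar training-set statistics (zero mean, unit max-abs).

* `fc5`: five fully connected layers 4096→2048→1024→2048→4096, ReLU
  hidden, sigmoid output, MSE loss, Adam (lr 1e-3), batch 64, default 50
  epochs; runs ≥ 24 epochs apply a step decay (×0.3 at 60 %, ×0.1 at
  85 %). The hidden widths and training recipe are this package's choices.
* `unet`: a 4-level convolutional encoder–decoder on the 64×64 reshape
  (one 3×3 conv + ReLU per level, max-pool down, nearest-neighbour up,
  skip concatenation, sigmoid head). In this pure-numpy implementation it
  is practical at small training scales; the fully connected decoder is
  the workhorse at the 10⁴-pair scale.
* `linear`: ridge-regularised least squares with intercept. The ridge
  weight is relative to the mean Gram eigenvalue; the default (1e-2) is
  matched to 30 dB-class measurement noise, while oracle tests on
  noiseless data pass an explicitly tiny value.

All decoders are trained on 64×64 bilinear-interpolated targets and clip
outputs to [0, 1]. Training is deterministic for a fixed seed under a
single-threaded BLAS. Classification uses a 4096→512→K softmax head on
the same preprocessed waveforms.

**Metrics.** Fidelity is the pixelwise Pearson correlation (constant
images score 0 by convention). SSIM uses an 11×11 Gaussian window
(σ = 1.5), K1 = 0.01, K2 = 0.03, dynamic range 1, via scikit-image, with a
single-window fallback below 11 px.

## Information structure, and a known limitation

Orientation-degenerate modes share delays exactly, so under incoherent
coupling the waveform only probes circularly averaged image structure
(cos² + sin² is radial); the coherent model, and any lateral offset, break
this degeneracy partially. Any intensity-only encoding is also blind to
reflections about the fiber axis; decoders resolve the ambiguity through
the training distribution. These are properties of the physics, not bugs.

In the glyph-recovery study (10,000 training pairs, 30 dB SNR, fully
connected decoder at reduced epochs) mean pixel-correlation fidelity and
waveform-classification accuracy come out high, but mean SSIM lags well
behind fidelity for this architecture on this generator's thin-stroke
glyphs: SSIM penalises sub-pixel stroke misplacement and residual
background texture much harder than pixel correlation does, and a dense
network without spatial inductive bias renders interpolated poses softly.
Convolutional decoders are the natural remedy; in this implementation
they are only practical at smaller training scales. The acceptance
script reports the values it actually computes.

## Study sizes

Desk-scale defaults: 2,000/500 pairs for ablation-style studies (ordering
and plateau claims need far fewer samples than headline metrics), 10,000/
1,000 for the recovery and classification studies, 600-pair rank probes
for the length-ablation ordering (full-rank random stimuli, incoherent
coupling, so fidelity tracks the number of temporally resolved modes
rather than the glyph prior). The resolution threshold (Michelson
contrast > 0.2 across a bar group) is this package's operationalisation
of "visually distinguishable".
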