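# Methods

## The problem and the model family

MR-only radiotherapy planning needs a CT-like image (a *synthetic CT*,
sCT) to supply the electron-density information that dose calculation
requires, because MR intensities carry no fixed relationship to tissue
attenuation. `sctgan` implements a family of four cycle-consistent
adversarial translation models that map T2-weighted pelvic MR axial
slices to sCT (and back), differing only in the generator objective:

| variant      | objective                                              | λ_cycle | λ_SSIM | λ_flow |
|--------------|--------------------------------------------------------|---------|--------|--------|
| `cyclegan`   | L_GAN + λ_cycle·L_cycle                                | 10      | –      | –      |
| `structcgan` | … + λ_SSIM·L_SSIM                                      | 8       | 2      | –      |
| `flowcgan`   | … + λ_flow·L_flow                                      | 8       | –      | 2      |
| `sfcgan`     | … + λ_SSIM·L_SSIM + λ_flow·L_flow                      | 6       | 2      | 2      |

All adversarial terms are least-squares (LSGAN): the generator drives
discriminator scores on synthetic images toward 1; each discriminator
minimises E[(D(real) − 1)²] + E[D(fake)²], and the net discriminator
loss is the average of the CT- and MR-side losses. Cycle consistency is
mean L1 of each input against its double translation. Expectations are
realised as batch means.

**Windowed SSIM term.** The structural-similarity index is computed on
uniform 11×11 windows at valid positions (no padding) on [0, 1]-scaled
slices, with stabilisers C1 = 1e-4 and C2 = 9e-3; window statistics use
the population convention. The loss is 1 minus the average of the
CT-direction and MR-direction indices. C2 here deliberately follows
the model family's published value, which differs from the conventional
(0.03)² = 9e-4; the conventional value can be passed explicitly.
Whether training SSIM operates on [0, 1] or network-range intensities
was an open choice; the [0, 1] contract was adopted and is what the
loss expects.

**Flow-consistency term.** Dense optical flow between *ground-truth*
adjacent axial slices is precomputed once per volume (never
re-estimated on synthetic images). The field f_{n,k} is defined
operationally: applied to slice n by backward bilinear sampling it
reconstructs neighbour k, so it is estimated by
`farneback_flow(slice_k, slice_n)`. During training, a synthesized
slice is warped through f_{n,n−1} and f_{n,n+1} and compared by mean
L1 to the real neighbours; boundary slices contribute their single
available side unscaled; the CT and MR directions are averaged.

## Automatic differentiation

Because every loss must be differentiable end-to-end through the
generators, the package carries a compact reverse-mode autodiff engine
(`sctgan.autodiff`) over NumPy arrays: broadcast arithmetic,
reductions, strided 2-D convolution (evaluated as a tap-concatenated
column matmul), instance normalisation, leaky ReLU / tanh / sigmoid,
nearest 2× upsampling, a uniform valid-window box filter (SSIM), and
bilinear warping through a fixed displacement field (flow loss; the
gradient flows through the image, the field is data). Every operator's
adjoint is verified against central differences in the test suite.
Networks train in float32; unit tests run the same code in float64.

## Networks

Generators are the canonical 9-residual-block translation network:
7×7 stem, two stride-2 downsamplings, `n_res` residual blocks at 4×
base width, two nearest-upsample+conv stages, 7×7 head, tanh output.
Zero padding is used throughout, instance normalisation carries no
affine parameters, and the input is mapped affinely from the 16-bit
range [0, 65535] to [−1, 1] (inverted on output). These internals are
package decisions — the family's architecture is specified only as
"residual with 9 blocks".

Discriminators have five 4×4 stride-2 convolutional blocks with
channels 64→128→256→512, instance norm + leaky ReLU (slope 0.2) after
every block but the last; the final 1-channel map passes through a
sigmoid and is spatially averaged to one score in [0, 1] per image
(a patch-map output is available but off by default).

Weights are zero-mean Gaussian (σ = 0.02) from a seeded generator;
construction, training steps and checkpoint resume are all
bit-reproducible on CPU.

## Optical flow estimation

Farnebäck's polynomial-expansion method is implemented directly:
each image is approximated pixel-wise by a quadratic surface through
Gaussian-weighted least squares (six separable correlations plus one
constant 6×6 Gram solve), and the displacement follows from matching
the two expansions, iterated with a 15-px uniform averaging window
over a 3-level image pyramid (3 iterations per level, applicability
half-width 5, σ = 1.1). The estimation hyperparameters are exposed in
`FlowParams`; the publication this family follows names the method but
none of its parameters, so these defaults are package choices. Inputs
are rescaled jointly per slice pair to a [0, 255] display range before
estimation, the common dense-flow practice. A cross-check test
compares shift recovery against scikit-image's iterative Lucas-Kanade
estimator; recovery of known integer shifts is accurate to well under
half a pixel.

## Preprocessing

Raw co-registered volumes pass through: background masking (out-of-body
voxels → 0 for MR, −1024 HU for CT); upper truncation (CT at a fixed
1400 HU; MR at the volume's in-body 99th percentile, linear
interpolation between order statistics, background excluded); 16-bit
min-max encoding (round half to even); removal of the first and last
two axial slices; bicubic resampling to 256×256 (nearest-neighbour for
masks; values re-clipped after interpolation overshoot); and the
cross-scanner site split (sites 2 and 3 train, site 1 tests).

CT normalisation uses the *fixed global* range [−1024, 1400] HU rather
than per-volume min-max, so one HU maps to the same 16-bit code in
every volume and HU-space evaluation is consistent across patients;
MR, having no absolute scale, is normalised per volume. Whether the
16-bit CT mapping should be global or per-volume was an open question;
the global choice is this package's decision. A normalise→denormalise
round trip is exact to within one quantisation step (≈0.037 HU for
CT). An Otsu + largest-connected-component body-mask fallback is
provided for unmasked data as a convenience; provided delineations are
always preferred.

## Training procedure

Per step: one joint update of both generators on the variant objective
(discriminators frozen), then one update of each discriminator on the
averaged least-squares loss, with fakes routed through a 50-image
history buffer per modality (store until full; then each fresh image
is swapped with a uniformly chosen stored one with probability 1/2).
The published schedule — 200 epochs, batch 4, Adam (lr 2e-4, β =
0.5/0.999) — is the default; the learning rate holds for the first 100
epochs and then follows lr·(1 − (e − 100)/100), reaching zero at the
final epoch. Training is paired: each batch item couples MR slice n
with CT slice n of the same patient, and neighbours/flows travel with
the sample. Both discriminators update every step. Epoch shuffling is
seeded from the config seed; checkpoints embed a configuration hash
and restore optimiser moments, buffers and RNG states so a resumed run
reproduces subsequent epochs bit-identically.

## Evaluation

ME = mean(CT − sCT) and MAE = mean|CT − sCT| are computed in HU after
denormalising through the stored record, restricted to the body
contour and to each organ delineation; aggregation across test volumes
is mean ± population SD (the SD convention was unstated; population SD
is asserted in tests). PSNR uses MAX_I = 65535 on the 16-bit scale.
Two conventions are provided because the family's printed formula
divides MAX_I by the MSE rather than its square root, which cannot
yield the ~57 dB magnitudes reported alongside ~40 HU MAE; `standard`
(MAX/RMSE) is the default and `paper` reproduces the literal formula.
Neither mode is claimed to reproduce published tables. Per-organ PSNR
uses only in-mask voxels. Identical volumes report +inf as a sentinel.

`interframe_residual` quantifies 3-D consistency of a synthetic
volume: each slice is warped through the ground-truth interslice flow
toward its successor and compared by mean L1 in HU within the body.

## The phantom generator

Phantoms exist so every stage runs and is testable without patient
data. Each patient is an elliptical body in air containing two
bone-like discs (~1000 HU), a bladder-like near-water ellipse, a
rectum-like ellipse with an air core (~−900 HU), a small
prostate-like ellipse, and textured soft tissue (~20–80 HU); all
structures drift slice-to-slice along a smoothly turning direction
with per-slice displacement ≈ `drift_step` (default 1 px), bounded and
reflected so anatomy stays in frame. Structures are rendered with
anti-aliased (~1.5 px) edges so sub-pixel drift appears as smooth
intensity change that dense flow can track — with hard binary edges
the interslice difference is aliasing flicker that no displacement
field explains. The MR channel is a monotone decreasing nonlinear
remap of the HU map (bone dark, fluid bright, T2-like), multiplied by
a smooth bias field, with independent texture and noise (CT σ = 10 HU,
MR σ = 15 a.u. by default). Organ masks are exact, pairwise disjoint
and inside the body, which makes per-organ evaluation exact: a known
HU bias injected into one organ moves exactly that organ's ME.

All randomness derives from one cohort seed through a hierarchical
`SeedSequence`. A 19-patient cohort defaults to the 8/7/4 site layout
of the public multi-centre pelvis cohort this family was studied on,
so the site split yields the familiar 11 train / 8 test volumes.

What the phantom does **not** emulate: scanner physics (TR/TE,
bandwidth, kernels), inter-scan air-pocket differences between MR and
CT, anatomical variability beyond ellipse geometry, through-plane
partial-volume effects, and registration error. Tests passing on
phantoms therefore demonstrate the machinery (losses, flows, schedule,
metrics) and qualitative learning behaviour, not clinical image
quality.

## Problem sizes for desk-scale runs

The full-scale configuration (256×256 slices, ngf = ndf = 64, 9
residual blocks, 200 epochs) is the library default. The test suite
and the acceptance script exercise the identical code paths at reduced
size, chosen once as this package's scaled study conditions: 64×64
phantoms, 12 slices, 4 training patients (sites 2/3) and 2 test
patients (site 1), ngf = ndf = 6 with 3 residual blocks, batch 4, 200
optimizer steps, seeds {0, 1, 2}. At this scale every variant's
generator loss falls well below its initial value and five epochs of
SFCGAN roughly halve the test MAE relative to an untrained generator;
between-variant differences in interframe residual, however, are
smaller than seed-to-seed noise, so the flow-guided-vs-baseline
consistency comparison is a directional probe only.

## Known limitations

- CPU-only NumPy training: suitable for phantom-scale experiments and
  verification, orders of magnitude slower than GPU frameworks at the
  full 256×256 / 64-channel scale.
- The Farnebäck hyperparameters and the 8-bit estimation range are
  defaults, not fitted; volumes with very large interslice motion may
  need more pyramid levels.
- The literal published PSNR formula and its reported magnitudes are
  mutually inconsistent; this package exposes both conventions and
  endorses neither as a reproduction.
- Organ masks are trusted as given; no mask QC is performed beyond
  shape checks.
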