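# Methods

This note documents the models, parameters and design choices behind
`jressr`: what the simulator emulates, how degradation and the
super-resolution network are defined, how resolution enhancement is
quantified, and where the desk-scale defaults deviate from a full-scale
training campaign.

## Spectrum container and coordinate conventions

A spectrum is a float32 grid with rows indexed by F1 (J-coupling, Hz) and
columns by F2 (chemical shift, ppm), plus explicit axes.  Pixel *i* of an
axis covers `[start + i·w, start + (i+1)·w)` with `w = (end − start)/n`;
its centre is `start + (i + 0.5)·w`.  The reference grid is 256 × 16,384
points over F1 −39.1542…39.1542 Hz and F2 −3.560…13.129 ppm at an observe
frequency of 600 MHz, where 30 px along F2 ≈ 0.031 ppm ≈ 18.6 Hz.

For an even row count over a symmetric F1 range the J = 0 line falls on
the boundary between rows n/2−1 and n/2, making "upper half" rows
0…n/2−1 and "lower half" rows n/2…n−1.  This between-row convention is the
only mirror-symmetric choice on even grids; its one practical consequence
is that a J = 0 singlet's apex is a two-row plateau, which peak picking
handles explicitly (below).  Printed ppm/Hz values round half away from
zero.  float32 storage follows the high dynamic range of spectral
intensities; internal numerics are float64.

The native file format is single-file HDF5 (a `grid` dataset with axis
attributes); round trips are bit-exact.  Vendor processed-data formats are
out of scope for this package — spectra enter already processed, through
the native container.

## Synthetic spectra

Each metabolite is a list of first-order multiplets: chemical shift centre
δ (ppm), scalar couplings J (Hz), a proton weight (relative integral), and
linewidths.  A multiplet with couplings J₁…J_k produces 2^k lines at
offsets Σ ±J_i/2 with intensity 2^(−k) each, coincident lines merging —
the usual doublet / triplet / doublet-of-doublets hierarchy.  Offsets are
merged after rounding to 10⁻⁹ Hz.  Lines are rendered as separable 2D
peaks: a unit-area Gaussian along F1 (default FWHM 0.4 Hz) and a unit-area
Lorentzian along F2 (default FWHM 0.002 ppm), so a signature's grid
integral equals its total proton weight.  Because F1 pixel centres mirror
about J = 0 and line offsets negate pairwise, every rendered spectrum is
symmetric under an F1 flip to float rounding — the property the symmetric
loss later exploits.

Mixtures are linear combinations of library signatures with per-metabolite
concentrations drawn from Normal(mean, sd) truncated below at zero by
resampling (sd = 0 returns the mean exactly).  The training recipe draws
1000 spectra for each of five urine-style mixture sizes (6, 8, 15, 34, 40
metabolites — 5000 spectra at full scale); the plasma-style test recipe
uses mixture sizes 1, 3, 6, 9, 12, 15.

The packaged library is parametric and seeded: 40 synthetic compounds with
1–4 multiplets each, shifts in 0.5–9.5 ppm, up to three couplings of
2–18 Hz, proton weights 1–9, concentration means 0.2–5 (arbitrary units)
with sd at 10–50% of the mean.  It reproduces the *statistical character*
of biofluid spectra (shift coverage, multiplet complexity, abundance
spread), not any specific compound list — so tests demonstrate behaviour
on realistic spectral structure, not agreement with a particular
experimental peak map.  Real-data features deliberately not modelled:
second-order (strong-coupling) effects, tilting artifacts, solvent
signals, baseline distortion, and acquisition noise (an optional additive
noise hook exists but defaults off).

**Reduced grids.**  Tests and the demo fixture run on a 64 × 1024 grid
spanning the same physical ranges.  Linewidths are scaled by the
pixel-width ratio (`scaled_linewidths`), keeping peak FWHM at the same
1–2 pixels as on the reference grid; without this, peaks collapse into
single-pixel spikes and the blur/down-sample degradation is
misrepresented.  Grid size is a configuration field throughout, never
hard-coded.

## Degradation (HR → LR)

LR counterparts are made by convolving with a normalized truncated
Gaussian kernel of dimensions (5, 7) in (F1, F2) and down-sampling by
exact 2 × 2 block averaging ("areal interpolation" for an integer factor
on divisible grids): 256 × 16,384 → 128 × 8,192.  Kernel standard
deviations default to (size − 1)/4 px — ±2σ at the kernel edge, a standard
truncation — and boundary handling is reflect padding, so margins are not
darkened; both are configurable and the operation is bit-reproducible.
The kernel is normalized (constants are preserved), block averaging
preserves the grid mean exactly, and the whole degradation commutes with
the F1 flip, so LR spectra of symmetric HR spectra remain symmetric.

## Super-resolution model

**Generator.**  A ×2 residual CNN: a 3×3 convolution lifts the single
input channel to `n_features`, `n_blocks` two-convolution residual blocks
(residual scaling 0.2) refine it, nearest-neighbour ×2 upsampling plus two
convolutions produce the output residual, and a global nearest-neighbour
×2 skip carries the input — an untrained generator is therefore ≈ plain
interpolation and training learns the sharpening correction.  All
convolutions are *bias-free*; with leaky ReLU activations the network is
then positively homogeneous, `G(a·x) = a·G(x)` for a > 0 (a property used
by bias-free denoising CNNs), so one network treats dim and bright
spectral regions identically regardless of external normalization.
Desk-scale default: 3 blocks × 24 features.  A reference-scale
RRDB-style configuration is a preset, not required by the tests.

**Discriminator.**  Three convolutions with two 2× average poolings,
emitting a per-pixel realness logit map.

**Losses.**  The generator minimizes
`w_pixel·L_pix + w_perceptual·L_perc + w_gan·L_G + w_sym·L_sym`:

* *Pixel*: mean absolute difference.  At train time the default compresses
  intensities with a signed square root, `T(x) = sign(x)(√(|x|+c) − √c)`,
  c = 10⁻³, before the L1 — peak heights span orders of magnitude even
  within one patch and plain L1 is dominated by the tallest peaks, the
  same rationale as the log inside the symmetric loss.  The public
  `pixel_loss` operation remains plain MAE; the transform is a training
  option (`pixel_transform="identity"` disables it).
* *Symmetric*: for each column i containing signal, Pearson-correlate the
  log upper-half intensities with the mirrored log lower-half intensities;
  the loss is `1 − mean r` — 0 at perfect symmetry, at most 2.  Log uses
  `log(clip(x, 0) + ε)`, ε = 10⁻⁶ × global max; "nonzero" means strictly
  positive after clipping.  Columns where either half has zero variance
  are excluded (r undefined) except identical-constant halves, which
  contribute r = 1.  The analytic gradient (column selection, clipping
  mask and ε held constant) is finite-difference-validated.
* *GAN*: non-saturating logistic objectives on the logit maps
  (`L_G = E[softplus(−D(fake))]`,
  `L_D = E[softplus(−D(real))] + E[softplus(D(fake))]`).
* *Perceptual*: a pluggable callable hook, default off — no pretrained
  feature backbone is bundled, and at desk scale the pixel + symmetric
  terms carry the supervision.

Default weights: `w_pixel = 1`, `w_symmetric = 0.1`, `w_gan = 0.05`
(`w_gan = 0` in the desk-scale preset, where 200 iterations are too few
for adversarial training to help), `w_perceptual = 0`.

**Patch selection.**  Training crops span the *full F1 extent* and a
random even-aligned window along F2 (HR 256 rows × 256 columns at
reference scale; full-height × 48 columns at desk scale).  Keeping all rows puts the
J = 0 mirror line at the patch midline, so the symmetric loss measures the
same symmetry on a patch as on the whole spectrum — a random 2D crop would
place the mirror axis arbitrarily and the loss would penalize the wrong
symmetry.  A patch is kept iff its maximum exceeds `peak_threshold`
(default 0.01 at desk scale) × the spectrum maximum, skipping the empty
regions that dominate J-Res grids.  Each HR/LR patch pair is normalized by
the LR patch maximum (consistent with any inference-time scaling thanks to
scale equivariance, and giving dim and bright patches equal loss weight).

**Training.**  Adam (β₁ = 0.9, β₂ = 0.999) alternates one generator and —
if `w_gan > 0` — one discriminator step per iteration.  The pixel loss is
evaluated only on columns whose receptive field lies inside the patch
(8-px margin): border columns see zero-padded context that full-grid
inference interiors never see.  The learning rate follows a half-cosine
decay to zero; an exponential moving average of the generator weights
(decay 0.99) is kept and used for inference, standard practice in GAN
super-resolution.  Training is deterministic given the seeds; non-finite
losses abort with the state attached.  Reference-scale settings (86K
iterations at learning rate 10⁻⁴) are configuration presets; the
desk-scale preset is 200 iterations at 4 × 10⁻³, batch 16, which trains in
about a minute on one CPU.

**Inference.**  The LR grid is scaled by its maximum, passed through the
generator (tiled with ≥16 px of context for large grids — tile interiors
reproduce the full-grid computation exactly, so tiling is seam-free) and
rescaled.  By default the prediction is averaged with the F1-flipped
prediction of the F1-flipped input: a geometric self-ensemble over the
mirror symmetry J-Res data obey, which makes outputs for symmetric inputs
exactly symmetric and averages down prediction noise.

## Evaluation

**Peak picking.**  Local maxima over 3×3 neighbourhoods at ≥ a threshold
fraction of the global maximum.  Plateaus (connected components of pixels
equal to their neighbourhood maximum) yield one peak each at the
component's smallest (row, col) — necessary because J = 0 singlet apexes
straddle the two centre rows with equal intensity.

**Pair formation.**  Each peak contributes its 3 nearest neighbours
(Euclidean pixel distance; ties broken by (distance, row, col));
unordered duplicates are removed and pairs farther than 30 px are
dropped.  Verified against an O(n²) brute-force oracle.

**Cross-resolution matching.**  An HR pair position is mapped into another
grid by the per-axis size ratio and refined to the highest local maximum
within a ±3 px window (window scaled with the same ratio — a fixed window
on a half-size grid would span twice the physical area and capture
unrelated neighbouring multiplet lines); if the window holds no local
maximum, its highest pixel is used.  A pair whose members match the same
pixel is flagged merged and scored 0, never dropped.

**Scoring.**  Valley height is the minimum along the straight line
between the matched members, sampled at unit steps with bilinear
interpolation (axis-aligned lines reduce to exact grid slices; this
generalizes F1-, F2- and diagonal-aligned profiles uniformly).  The score
is `1 − 2h_v/(h_i + h_j)` clipped to [0, 1]; a min-height variant
(`1 − h_v/min(h_i, h_j)`) is available behind a switch.  Categories:
[0, 0.2) poorly, [0.2, 0.6) partially, [0.6, 1] well resolved (bins closed
on the left; 1.0 is "well resolved").  Summaries report improvement
fractions (SR ≥ LR and SR > LR), the HR–SR score correlation (reported as
undefined, not NaN, under zero variance), medians, and 10-px distance-bin
statistics.

**Reliability.**  Ground-truth peaks are picked on a higher-resolution
spectrum at a 0.5% threshold; LR and SR peaks picked at thresholds
{1%, 5%, 10%} are mapped to the truth grid and matched greedily
(nearest-first, one-to-one) within 2 px.  The gained-peak fraction is the
share of additional SR detections (beyond the LR count) accounted for by
additional true-positive matches; with no LR peaks it is computed over all
SR detections.

## Desk-scale benchmark and what it shows

`toy_benchmark(seed)` trains the desk-scale preset for 200 iterations on
the 20-spectrum demo fixture (64 × 1024, five mixture sizes × 4) and
scores a held-out plasma-style set (six mixture sizes × 3 spectra,
~1300–1600 pairs pooled; six spectra proved too few — the median
comparison was dominated by test-set sampling noise).  Across seeds this
yields median LR resolvability ≈ 0.62–0.80, median SR ≈ 0.75–0.88, 80–92%
of pairs improved, and HR–SR score correlation ≈ 0.70–0.80.  The pattern —
a "V" from HR down to LR and back up in SR, with recovery weakest for the
closest pairs — matches full-scale behaviour qualitatively; the
quantitative gap (full-scale training recovers HR resolvability almost
completely, with near-perfect HR–SR correlation) is the expected cost of
three orders of magnitude less training compute and a far smaller model.

## Numerical choices and degenerate inputs

* Axes permit n = 1 point so that down-sampling a 2 × 2 grid is defined.
* All-zero spectra: symmetric loss 0, no peaks, empty patch lists;
  enhancement returns finite output (scale falls back to 1).
* Coincident multiplet lines merge after rounding offsets to 10⁻⁹ Hz.
* k-NN ties and equal-height peaks break deterministically by
  (distance, row, col) / (height, row, col).
* Training seeds: generator init, discriminator init (seed + 1), patch and
  batch sampling all derive from the run seed; repeated runs are
  byte-identical on one machine.

## Known limitations

* First-order multiplets only; no strong coupling, no lineshape
  distortions, no noise by default — synthetic results bound what can be
  expected on clean, well-processed real data, not on noisy data.
* The desk-scale network under-resolves pairs closer than ~4–6 HR px;
  reliability of gained peaks at the 1% threshold is correspondingly
  noisy.
* The perceptual-loss hook ships without a backbone.
* Reading vendor processed-data directories is not implemented; convert to
  the native HDF5 container first.
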