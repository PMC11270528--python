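# jressr — super-resolution of 2D J-resolved NMR spectra

2D J-resolved (J-Res) ¹H NMR separates scalar coupling (F1, Hz) from
chemical shift (F2, ppm) and is a workhorse of NMR metabolomics.  High
F1 resolution costs hours of spectrometer time; quick low-resolution (LR)
acquisitions suffer severe peak overlap.  `jressr` is a toolkit for
metabolomics practitioners and NMR methods developers that

* **simulates** paired high/low-resolution J-Res spectra of metabolite
  mixtures (linear combinations of parametric multiplet signatures with
  truncated-normal concentrations, on the standard 256 × 16,384 grid:
  F1 −39.1542…39.1542 Hz, F2 −3.560…13.129 ppm),
* **degrades** HR spectra to LR counterparts by Gaussian blurring
  (kernel 5 × 7) followed by ×2 areal down-sampling,
* **trains** a ×2 GAN super-resolution generator whose loss stack includes
  a *symmetric loss* exploiting the mirror symmetry of J-Res spectra about
  the J = 0 Hz line, and
* **quantifies** resolution enhancement with a peak-pair *resolvability
  score* and a threshold-sweep reliability analysis.

## The score and the loss

For two adjacent picked peaks with heights *hᵢ*, *hⱼ* and the valley-floor
height *h_v* between them, the resolvability score is

    R = 1 − 2 h_v / (hᵢ + hⱼ),  clipped to [0, 1],

so R = 1 for a baseline-resolved pair and R = 0 for a fully merged one.
Pairs are formed on the HR spectrum (3 nearest neighbours per peak,
duplicates removed, pairs farther than 30 px ≈ 0.031 ppm ≈ 18.6 Hz at
600 MHz discarded) and the same physical pairs are then located and scored
in the LR and super-resolved (SR) spectra.

The symmetric loss compares, column by column, the log intensities of the
upper half spectrum *S_iu* with those of the mirrored lower half *S_il*
via the Pearson correlation *r*:

    L_sym = 1 − (1/n) Σ_{i∈P} r(S_iu, S_il),

summed over the *n* columns *P* that contain signal.  It is 0 for a
perfectly symmetric spectrum and bounded by 2; the log keeps the loss from
being dominated by the most intense peaks.

The generator is a bias-free residual CNN with a global nearest-neighbour
upsampling skip (bias-free convolutions + leaky ReLU make it exactly
scale-equivariant, which suits the high dynamic range of NMR data); a
small patch discriminator provides the adversarial term.  Training and
backpropagation are implemented in NumPy — gradients are validated against
finite differences in the test suite.

## Worked example

```python
import numpy as np
from jressr.pipeline import demo_fixture, toy_benchmark

summary = toy_benchmark(seed=0)   # ~2 min on one CPU
print(f"pairs scored        : {summary['n_pairs']}")
print(f"median resolvability: HR {summary['median_HR']:.2f}  "
      f"LR {summary['median_LR']:.2f}  SR {summary['median_SR']:.2f}")
print(f"pairs improved      : {100 * summary['frac_sr_ge_lr']:.1f}%")
print(f"HR-SR correlation   : {summary['corr_hr_sr']:.2f}")
```

prints (seed 0):

```
pairs scored        : 1605
median resolvability: HR 0.98  LR 0.66  SR 0.77
pairs improved      : 84.7%
HR-SR correlation   : 0.74
```

That is the characteristic "V" shape of the method: degradation pulls the
median pair resolvability from 0.98 down to 0.66, and the trained
generator — here only a 200-iteration desk-scale run on the 20-spectrum
demo fixture — lifts it back to 0.77, improving 85% of pairs.  A
full-scale training run (tens of thousands of iterations on thousands of
spectra) recovers HR resolvability nearly completely.

The same pipeline is scriptable from the shell:

```bash
jressr demo --seed 0 --outdir runs/fixture     # paired HR/LR spectra
jressr run  --seed 0 --outdir runs/demo        # simulate→degrade→train→evaluate
jressr degrade runs/fixture/hr_0000.h5 lr.h5 --kernel 5 7 --factor 2
jressr enhance lr.h5 sr.h5 --weights runs/demo/checkpoint.npz
jressr evaluate --hr runs/fixture/hr_0000.h5 --lr lr.h5 --sr sr.h5
```

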