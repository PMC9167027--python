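# vertaseg

Level-set segmentation of vertebral CT slices, with the downstream spinal
morphometry and clinical-efficacy statistics used to evaluate lumbar disc
herniation (LDH) treatment.

The package is aimed at medical-image-analysis work on bone segmentation in
2-D CT-like slices. It implements, end to end:

* **Contrast enhancement** by a neighborhood-fused exponential gray
  adjustment: `f0' = f0 · e^(α − 0.45)` with `α = Σᵢ fᵢ / (255·9)` over the
  3×3 neighborhood — pixels in bright surroundings are brightened, pixels
  in dark surroundings darkened.
* **Active-contour segmentation** with the contour carried as the zero
  level of a field φ:
  * the **Chan-Vese (C-V)** global two-phase energy
    `μ·Length(C) + ν·Area + λ₁∫(I−c₁)²H(φ) + λ₂∫(I−c₂)²(1−H(φ))`, and
  * the **local binary fitting (LBF)** energy
    `Σₓ Σᵧ K_σ(x−y)[λ₁(I(y)−g₁(x))²H(φ) + λ₂(I(y)−g₂(x))²(1−H(φ))]`,
    whose kernel-weighted local means g₁, g₂ stay accurate under smooth
    intensity inhomogeneity (bias fields / "gray unevenness") that defeats
    the global fit.
* **Iterative frame-fusion bone prediction** across sequential slices:
  fuse the previous frame's binary mask with the next enhanced frame
  (`I_mod = α·I_b + β·I_enh`), suppress fusion noise in the suture band
  around the previous contour (dark band pixels damped by μ₁/μ₂), segment,
  and repeat to frame n.
* **Seeded vertebra phantoms** (cortical ring + spinous process, bias
  field, Gaussian noise, salt impulses) with ground-truth masks, so every
  property is testable without patient data.
* **Morphometry & efficacy**: protrusion/canal area ratio, disc height,
  vertebral slippage from endplate lines, four-level efficacy grading,
  total effective rate, and chi-square / t-test group comparisons.

## Worked example

```python
import numpy as np
import vertaseg as vs

# a 128x128 vertebra phantom with a 30% bias field and noise
spec = vs.PhantomSpec(noise_sigma=5.0, bias_amplitude=0.3, seed=1)
img, truth = vs.generate_vertebra_phantom(spec)

init = vs.circle_level_set(img.shape)
cv_field, _ = vs.cv_evolve(img, init)
lbf_field, _ = vs.lbf_evolve(img, init)
print("C-V Dice :", round(vs.dice(vs.binarize(cv_field), truth), 4))
print("LBF Dice :", round(vs.dice(vs.binarize(lbf_field), truth), 4))

a = vs.EfficacyCounts(cured=7, markedly=10, effective=16, ineffective=6)
b = vs.EfficacyCounts(cured=9, markedly=17, effective=10, ineffective=3)
print("rate A   :", vs.total_effective_rate(a))
print("rate B   :", vs.total_effective_rate(b))
```

prints

```
C-V Dice : 0.7875
LBF Dice : 1.0
rate A   : 84.62
rate B   : 92.31
```

Under gray unevenness the global C-V fit started from the default circle
init cannot resolve the dark trabecular interior of the ring (it returns
the filled body, Dice 0.79), while the LBF model's local fitting recovers
the bone region exactly. The two rates are the groups' total effective
rates (responders / total, in %): 84.62% for lateral-crypt-block treatment
and 92.31% for scalpel treatment.

The same functionality is exposed as a CLI:

```bash
vertaseg phantom --out work/ --seed 7 --n 5 --noise 5
vertaseg segment --in work/img_000.png --method lbf --out work/mask.png
vertaseg pipeline --frames work/img_*.png --method cv --out work/pipe/
vertaseg efficacy --counts 7,10,16,6 --counts-b 9,17,10,3 --out report.csv
```

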