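# ocuquant

Quantitative analysis for preclinical intravitreal anti-VEGF pharmacology.
The package implements the measurement machinery used to evaluate
long-acting protein drugs that are retained in the eye by binding
hyaluronan, the major polysaccharide of the vitreous:

- **Fluorescein-leakage quantification** from paired retinal angiograms
  (rabbit VEGF-challenge model): landmark-based co-registration of the
  vessel-reference (intravascular FITC-dextran) and fluorescein channels,
  ROI cropping (optic nerve, medullary-ray band, artifacts), photometric
  normalization on vessel pixels, pixel-wise subtraction, and per-eye
  percent inhibition relative to the control group.
- **CNV lesion grading** (cynomolgus laser model): per-lesion averaging of
  four masked observers' 1–4 severity scores into Grades I–IV and
  per-group grade distributions.
- **Ocular pharmacokinetics**: terminal drug-level unit conversion
  (ng/ml ↔ pmol per eye via molecular weight and vitreal volume), percent
  of injected dose, mono-exponential half-life by log-linear least squares,
  four-parameter logistic (4PL) standard-curve fitting with closed-form
  inverse interpolation, and a blank + m·SD limit of detection.
- **Vitreal target carrying capacity**: molar abundance of candidate
  binding targets per eye and the drug mass they can hold at a stated
  binding footprint and stoichiometry.
- **Synthetic data generators** with full ground truth (branched
  retinal-vessel scenes with controllable extravasation, mis-registration
  and noise; decay series; rater tables), so every stage is testable
  without animal data.

## Core quantities

For one eye, after registration and normalization, the leakage statistic is

```
leak(x)  = max(F(x) − g·R(x), 0)            pixel-wise, x analyzable
leakage  = Σ leak(x) / |analyzable|         intensity per unit area
inhibition = 100 · (1 − leakage / mean(control leakages))   [%]
```

where `F` is the registered fluorescein channel, `R` the vessel-reference
channel, and `g` the gain fitted on vessel pixels. Terminal kinetics use
`A(t) = A0·e^(−kt)` fitted as OLS of `ln A` on `t`, with `t½ = ln 2 / k`;
standard curves use
`Y = Bottom + (Top − Bottom) / (1 + 10^((LogEC50 − X)·HillSlope))` with
`X = log10(concentration)`.

## Worked example

```python
import numpy as np
from ocuquant import (QuantifyConfig, SceneConfig, generate_vessel_scene,
                      quantify_pair, inhibition, fit_monoexponential)
from ocuquant.registration import SimilarityTransform
import pandas as pd

# a synthetic eye: 50% leak intensity, 5 degree / few-pixel mis-registration
t = SimilarityTransform(scale=1.02, rotation=np.deg2rad(5), translation=(4, -6))
pair, truth = generate_vessel_scene(
    SceneConfig(leak_intensity=0.5, transform_true=t, seed=3))
config = QuantifyConfig(optic_nerve_region=((128, 36), 18), medullary_band=(80, 176))
eye = quantify_pair(pair.reference, pair.fluorescein, pair.landmarks, config)
print(f"leakage = {eye.result.leakage:.4f}, registration RMS = {eye.rms_residual:.2f} px")

# terminal vitreal series (pmol/eye) of the hyaluronan-binding Fab
series = pd.DataFrame({"day": [21, 24, 26, 30, 31],
                       "amount_pmol": [9.8, 5.6, 3.9, 3.1, 3.0]})
fit = fit_monoexponential(series)
print(f"t_half = {fit.t_half:.2f} d, r^2 = {fit.r_squared:.3f}")
```

prints

```
leakage = 0.0453, registration RMS = 0.33 px
t_half = 6.09 d, r^2 = 0.919
```

`leakage` is the mean extravasated-dye intensity per analyzable pixel
(compare with the generator's ground-truth leak field); the decay fit says
the drug leaves the vitreous with a half-life of about six days.

A command-line interface mirrors the library:
`ocuquant simulate|register|quantify|grade|pk|capacity|run` (see
`ocuquant --help`).

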