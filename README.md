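# aopmeter

Automatic measurement of the **angle of progression (AoP)** from 2-D
transperineal-ultrasound-like images. The AoP — the angle between the long
axis of the pubic symphysis (PS) and the line from its inferior endpoint
tangent to the fetal head (FH) contour — is the most reproducible
ultrasound index of fetal head descent during labor; measuring it by hand
requires recognizing the standard plane and placing three key points, which
is operator-dependent. `aopmeter` automates the whole chain:

1. a **multitask encoder–decoder network** (shared encoder with
   efficient channel attention; three decoders for standard-plane
   classification, PS/FH segmentation, and PS-endpoint heatmap regression,
   coupled by attention-fusion gates, trained with Dice + convex
   shape-prior + weighted heatmap-MSE losses in two stages), and
2. **exact ellipse/tangent geometry**: direct least-squares conic fit of
   the FH contour, tangent construction through the polar line of the
   right PS endpoint, and the angle at that endpoint

        AoP = ∠( ray → left endpoint,  ray → tangent point )   at the right endpoint.

Because clinical data cannot ship with the package, a seeded **phantom
generator** produces ultrasound-like images (bright elliptical FH, capsule-
shaped PS, multiplicative speckle, nonstandard-plane variants) with
analytically known masks, endpoints and AoP, so every stage — including
end-to-end training — is testable on a laptop CPU. The intended users are
researchers in obstetric image analysis who want a complete, dependency-
light reference implementation of this measurement pipeline.

## Worked example

```python
import numpy as np
from aopmeter import phantom, geometry

spec = phantom.PhantomSpec()                       # 96x96 desk-scale phantoms
s = phantom.generate_standard(spec, "P000", seed=42)
print(f"analytic AoP: {s.aop_true:.2f} deg")

res = geometry.measure(s.mask, (s.left_endpoint, s.right_endpoint))
print(f"measured AoP: {res.aop_deg:.2f} deg  (valid={res.valid})")
print(f"tangent point: ({res.tangent_point[0]:.1f}, {res.tangent_point[1]:.1f})")
```

prints

```
analytic AoP: 173.87 deg
measured AoP: 174.07 deg  (valid=True)
tangent point: (63.4, 36.8)
```

the 0.2° gap is mask-rasterization error: the analytic angle comes from the
generating ellipse, the measured one from an ellipse re-fitted to the
rasterized FH boundary. Over 100 phantoms this geometry-only error averages
≈ 0.13°.

The full pipeline from the shell (phantom dataset → two-stage training →
measurement → evaluation):

```bash
aopmeter phantom --seed 1 --out data/
aopmeter train   --stage 1 --manifest data/manifest.csv --seed 1 --out run/
aopmeter train   --stage 2 --manifest data/manifest.csv \
                 --from-checkpoint run/stage1.npz --seed 1 --out run/
aopmeter measure --checkpoint run/stage2.npz --manifest data/manifest.csv \
                 --out run/predictions.csv
aopmeter evaluate --predictions run/predictions.csv \
                  --manifest data/manifest.csv --out run/report/
```

`measure` emits one row per image (class decision, endpoints, tangent
point, AoP, validity); nonstandard-plane images are flagged and skipped —
the AoP is only defined on the standard plane. `evaluate` writes a
per-image CSV and a JSON summary with classification rates, Dice scores,
endpoint distances (mm), PS-axis angle error (APT), |ΔAoP| and
Pearson/Bland–Altman agreement.

## Tests

```bash
python -m pytest tests/
```

The suite contains closed-form oracles for every geometric and loss
primitive (circle tangency, ellipse-fit round trips, a brute-force loop for
the convex shape-prior loss), finite-difference gradient checks for every
autodiff operator, property tests for the phantom generator and data
pipeline, and a scaled end-to-end training study; the full run takes about
a quarter of an hour on one CPU core.

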