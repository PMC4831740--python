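# ctstain

Staining-kinetics analysis for contrast-enhanced X-ray computed tomography
of ligaments and tendons.

Soft tissues attenuate X-rays weakly, so micro-CT of ligaments and tendons
relies on heavy-element contrast agents — iodine potassium iodide (I2KI),
phosphotungstic acid (PTA), phosphomolybdic acid (PMA) — that diffuse into
the sample over days. Under-staining leaves the core invisible;
over-staining shrinks and deforms the tissue. `ctstain` quantifies the
trade-off from daily CT slice series: it extracts line profiles, locates
sample edges and stain fronts with gradient thresholds, fits the staining
kinetics at every depth, predicts optimal staining times, and tracks
shrinkage. It is aimed at imaging scientists planning staining protocols
and at analysts reprocessing staining time series.

## Models

Intensity at a fixed depth rises with staining time as a saturating
exponential

    I(t) = I0 + (Imax − I0)(1 − e^(−k t)),

with unstained intensity `I0`, asymptote `Imax` and rate `k` (1/days).
Inverting the per-depth fits at a saturation level `f` (90/95/99% of
`Imax`) gives times that grow exponentially with depth `x`,

    t_stain(x) = A e^(c x),

so `c` (1/mm) is the depth penalty on staining time. Agents that advance
as a sharp front (PTA, PMA) are instead summarised by the front depth

    x(t) = C (1 − e^(−K t)),

whose asymptote `C` (mm) is the deepest the stain will ever reach — an
upper limit on the radius of a sample that can be stained through.

Detection follows the three-stage gradient protocol for staining line
profiles: Gaussian filtering (σ = 4 px), locating the extremal intensity
gradient, then walking toward the sample centre to the first point with
|gradient| < 0.01 per mm. Stain fronts trigger on the first inward
gradient below −0.2 per mm and are located the same way.

A synthetic phantom generator (`ctstain.phantom`) produces slice series
with exact closed-form ground truth for both staining behaviours, plus
radial shrinkage and Gaussian noise, so every stage of the pipeline is
testable without scan data.

## Worked example

```python
from ctstain import StainTimeModel, FrontModel, predict_staining_time, max_penetration_depth

m90 = StainTimeModel(A=1.007, c=0.313, saturation_level=0.90)
print(round(predict_staining_time(m90, 1.5), 1))   # 1.6
print(round(predict_staining_time(m90, 3.0), 1))   # 2.6

pta = FrontModel(C=3.094, K=0.367)
print(round(max_penetration_depth(pta), 1))        # 3.1
```

Reaching 90% saturation with I2KI takes 1.6 days at 1.5 mm depth but
2.6 days at 3 mm — the exponential depth penalty. A PTA front stalls at
3.1 mm, so thicker samples can never be stained to the centre. The
scripts in `examples/` walk through each capability end to end, including
recovering the generating kinetics from synthetic image series alone
(`examples/depth_kinetics_recovery.py` prints `c = 0.298/mm` against a
generating value of 0.3/mm).

A thin CLI wraps the same library:

```sh
ctstain simulate specs.yaml cohort/          # phantom cohort + truth manifest
ctstain run-all --manifest cohort/manifest.json --output-dir out/
ctstain predict out/fits.json --depth-mm 1.5 --radius-mm 2.5
```

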