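# echogaze

A synthetic ultrasound test bench for eye-gaze estimation, with the full
analysis pipeline: physics-based acoustic simulation of a model eye,
digitized receiver traces, time-of-flight/amplitude feature extraction,
and gradient-boosted-tree gaze regression.

## The problem

Camera-based eye trackers struggle with ambient light and power, which has
motivated airborne ultrasound as an alternative sensing channel for AR/VR
devices: the air–tissue impedance mismatch makes the eye an almost perfect
acoustic mirror (R = ((Z₂−Z₁)/(Z₂+Z₁))² > 99.8%), and because the cornea
protrudes from the eyeball, the timing and amplitude of eye echoes depend
on where the eye points. `echogaze` is for researchers who want a
reproducible, fully synthetic stand-in for such a benchtop study — no
deposited bench data exist — to develop and stress the estimation pipeline
end to end.

The emulated rig: a sphere-on-sphere model eye (cornea radius 7.8 mm,
sclera radius 11.925 mm, offset 5.6 mm) on a goniometer stepped over gaze
poses within ±5°, a parametric occluder (eyelid aperture + nose pad), a
fixed receiver and a transmitter stepped over a 180° arc in 10° steps.
Each shot is a 7-cycle 1.74 MHz tone burst repeated at 2 kHz, digitized at
80 MHz, 50 repeats per position, 9 sessions with day-to-day gain/timing
drift. Directional transducer physics (native curve
w(α) = cos(min(α·90/15, 90°)), hard 15° cutoff), 470 dB/m absorption in
air, and specular ray acoustics generate the echoes.

From each trace block the pipeline extracts X = {a_r, τ_r}: averages of 10
consecutive traces, an order-4 Butterworth band-pass at [1.6, 1.9] MHz, a
45 µs window centred on the squared filtered peak, and the first raw-trace
maximum inside it. Two independent regressors per gaze axis
F_m(x) = F_{m−1}(x) + h_m(x) (gradient-boosted regression trees, plus an
OLS baseline) map X → (θ, ϕ), evaluated by 5-fold cross-validated RMSE and
adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), an epsilon-ball sensitivity curve,
feature importances, ablations and a per-pose error map.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

The default study (36 poses × 19 transmitter positions × 9 sessions,
group-averaged fast mode) at seed 11:

```python
import numpy as np
from echogaze import (ProtocolSpec, BurstSpec, NoiseSpec, run_protocol,
                      build_feature_matrix, cross_validate, epsilon_ball_curve)
from echogaze.bench import bench_scene_factory
from echogaze.pipeline import split_features

dataset = run_protocol(ProtocolSpec(), bench_scene_factory(),
                       BurstSpec(), NoiseSpec(), seed=11)
features = build_feature_matrix(dataset)          # 1620 rows x 38 features
X, Y = split_features(features)
for kind in ("gbrt", "linear"):
    r = cross_validate(X, Y, kind=kind, seed=11)
    print(f"{kind:<7} 5-fold RMSE {r.rmse_pooled.mean():.3f} +/- {r.rmse_pooled.std():.3f} deg, "
          f"adjusted R^2 {r.adj_r2_mean.mean():.1f} +/- {r.adj_r2_mean.std():.1f} %")
r = cross_validate(X, Y, kind="gbrt", seed=11)
curve = epsilon_ball_curve(r.oof_pred, r.truth, np.arange(0, 5.05, 0.05))
print(f"50% of estimates within {curve.radius_at(0.5):.2f} deg, "
      f"90% within {curve.radius_at(0.9):.2f} deg")
```

prints (about two minutes on one core):

```
gbrt    5-fold RMSE 1.316 +/- 0.050 deg, adjusted R^2 83.1 +/- 1.7 %
linear  5-fold RMSE 1.836 +/- 0.272 deg, adjusted R^2 66.6 +/- 9.9 %
50% of estimates within 1.45 deg, 90% within 2.90 deg
```

Reading it: on this synthetic bench the boosted trees recover gaze to
about 1.3° RMSE over a ±5° range and clearly beat the linear baseline —
the occluder makes the feature-to-gaze map nonlinear — and half of all
estimates land within 1.5° of the true pose. Absolute numbers depend on
the configured noise and occluder; the suite asserts the stable properties
(RMSE within the 2° resolution bound, GBRT ≤ linear, time-of-flight
features dominating importance, occlusion signatures).

The same pipeline is scriptable from the shell:

```bash
echogaze all --seed 11 --out runs/demo --ablate   # simulate -> features -> train -> figures
echogaze simulate --config my_bench.yaml          # individual stages
echogaze extract-features runs/demo/dataset
echogaze train runs/demo/features.csv --ablate
echogaze report runs/demo/report
```

Configuration is a strict YAML file (geometry, burst, noise, protocol,
features, regression; unknown keys are rejected); every output carries a
config hash and seed, and a rerun from the same config reproduces the same
bytes.

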