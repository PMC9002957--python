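# mvkin — multi-view markerless kinematics

`mvkin` estimates 3D joint kinematics from multi-camera 2D pose detections
and quantifies how well the result agrees with a marker-based reference
protocol. It is aimed at biomechanists and sports scientists who want a
transparent, fully scriptable version of the markerless workflow:

1. **Triangulation** — per-camera keypoint detections (OpenPose-dialect
   JSON, `x, y, confidence` triplets) are fused by a confidence-weighted
   Direct Linear Transform. Each camera contributes two homogeneous rows
   scaled by its confidence; the 3D point is the smallest-singular-value
   right singular vector, dehomogenized. A robust loop re-solves while the
   mean reprojection residual exceeds a threshold, dropping the worst view
   each round (never below two).
2. **Filtering and events** — 3D trajectories are low-passed with a
   zero-phase 4th-order 6 Hz Butterworth (cutoff pre-warped so the dual-pass
   cascade is exactly −3 dB at 6 Hz). Heel strikes are the coordinate-based
   events: local maxima of the heel-relative-to-sacrum position along the
   direction of travel.
3. **Constrained inverse kinematics** — a full-body skeletal model with
   typed degrees of freedom (locks, limits, couplings) is scaled by
   measurement ratios from a static trial, then solved per frame:

   minimize over q:  Σᵢ wᵢ ‖xᵢ_exp − xᵢ_model(q)‖²

   subject to joint locks (wrist flexion/deviation 0°, forearm
   pronation/supination 90°), limits (hip flexion ≤ 150°), and couplings
   (knee abduction/rotation are functions of knee flexion; five lumbar
   vertebrae share total lumbar flexion equally). The constraints are what
   make the result robust to the systematic joint-center biases (up to
   5 cm at hip and knee) of deep-learning pose detectors.
4. **Agreement statistics** — cycle-normalized angle waveforms from two
   protocols are compared with the inter-protocol coefficient of multiple
   correlation (CMC), Pearson's r, paired range-of-motion (ROM) error tests
   (Shapiro–Wilk + paired t-test), and Bland–Altman bias with 95% limits of
   agreement (bias ± 1.96 sd) and a heteroscedasticity flag.

Everything is testable without laboratory data: `mvkin.simulate` is a
first-class virtual-camera gait simulator (8-camera rig, 30 Hz,
walking/running/pedaling harmonics, pixel noise, per-keypoint systematic
3D offsets, occlusions) with a parallel anatomical-marker reference channel
and exact ground truth.

## Worked example

```python
import numpy as np
from mvkin.simulate import MotionSpec, CorruptionSpec
from mvkin.pipeline import run_synthetic_experiment
from mvkin.ik import SAGITTAL_ANGLES

res = run_synthetic_experiment(
    MotionSpec(task="walking", n_cycles=8, seed=42),
    CorruptionSpec(pixel_noise_sd=2.0, seed=42),
    with_reference=True, soft_tissue_sd=0.003,
)
print(f"frames: {res.truth.q.shape[0]}, heel strikes: {list(res.events)}")
print(f"marker-fit RMSE: {100*res.ik.rmse.min():.2f}-{100*res.ik.rmse.max():.2f} cm")
for a in SAGITTAL_ANGLES:
    err = res.angles[a] - res.truth.angles[a]
    r = np.corrcoef(res.angles[a], res.truth.angles[a])[0, 1]
    print(f"{a:16s} MAE vs truth {np.abs(err).mean():.2f} deg, r = {r:.3f}")
print(res.agreement_table[["angle", "cmc", "cmc_class", "mean_err", "rmse"]]
      .round(2).to_string(index=False))
```

prints

```
frames: 240, heel strikes: [3, 33, 62, 92, 123, 153, 182, 212]
marker-fit RMSE: 0.21-0.50 cm
hip_flexion_r    MAE vs truth 1.98 deg, r = 0.992
knee_flexion_r   MAE vs truth 0.46 deg, r = 1.000
ankle_flexion_r  MAE vs truth 0.55 deg, r = 0.996
           angle  cmc cmc_class  mean_err  rmse
   hip_flexion_r 0.99 excellent     -1.72  2.91
 hip_adduction_r 0.97 excellent     -0.62  1.30
  hip_rotation_r 0.77      good      0.99  2.67
  knee_flexion_r 1.00 excellent     -1.45  1.71
knee_adduction_r 1.00 excellent     -0.05  0.06
 knee_rotation_r 1.00 excellent     -0.13  0.15
 ankle_flexion_r 0.98 excellent     -2.29  2.53
      subtalar_r 0.59      poor     -0.67  5.91
```

The trial is an 8-cycle back-and-forth walk filmed by 8 virtual cameras at
30 Hz with 2 px detection noise. The marker-fit RMSE is far inside the
2–4 cm best-practice band; sagittal waveforms are recovered to within ~2°
of ground truth; the markerless-vs-marker agreement table shows the usual
pattern — excellent sagittal CMC, weaker non-sagittal agreement where the
ranges of motion are small.

## Command line

```bash
mvkin simulate --task walking --n-cycles 8 --pixel-noise 2 --seed 1 --out trial/
mvkin run --config trial/config.toml          # full pipeline from a config
mvkin triangulate --rig trial/rig.toml --pose-dir trial/pose --out out.trc
mvkin scale --static static.trc --out scaled.toml
mvkin ik --model scaled.toml --trc out.trc --out angles.mot
mvkin agree --test angles.mot --ref marker.mot --events cycles.csv --out report.csv
```

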