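# gazecal

Calibration methods for **mobile gaze tracking**: estimating where a freely
moving person is looking on a large display, from a motion tracker's 6-DOF
head pose **h** = (h_x, h_y, h_z, h_φ, h_θ, h_ψ) and a head-mounted video
eye tracker's pupil centroid **p** = (p_x, p_y).

Standard video eye trackers assume a restrained head; once the user stands
up and walks, the mapping from pupil position to on-screen point of regard
(POR) depends on the full head pose.  `gazecal` implements and compares the
two principled ways out, for researchers who run large-display or
locomotion experiments:

* **Geometric method** — reconstruct the line of sight explicitly.  A rigid
  head-eye transform gives the eye pose (e = h + R_h t, R_e = R_h R_T), a
  linear eye model maps the pupil image to eye-in-head rotations
  (φ = m_φ p_x + b_φ, θ = m_θ p_y + b_θ), and the gaze ray
  g = R_e R_φ R_θ (1,0,0)ᵀ is intersected with a planar screen model
  (centre, normal, metric size, pixel resolution).  All free parameters are
  calibrated by bounded derivative-free minimisation of the mean pixel
  error on data collected while the user fixates known targets.
* **Regression method** — skip the geometry and learn the map directly.
  Two Gaussian processes with an automatic-relevance-determination kernel,
  k(x_i, x_j) = σ_s exp(−½ Σ_d |x_id − x_jd|/l_d), map the 8-D input
  (h, p) to the u and v screen coordinates.  Hyperparameters are fitted by
  marginal-likelihood maximisation; every prediction comes with a
  predictive standard deviation in pixels that can be used to reject
  unreliable PORs.

The package also ships a **session simulator** (pursuit and static-grid
stimulus protocols under head-fixed / head-free / walking mobility, with a
ground-truth forward model) and an **evaluation harness** (calibration/
validation splits, fixation filtering, angular-error metrics in degrees of
visual angle, a head-pupil coverage-overlap statistic, confidence-based
rejection).  The full model and numerical details are in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a walking session (3 min pursuit + 5 min static grid on a
1024×768 px, 220×160 cm display), calibrate both methods on the first two
minutes of pursuit, and validate on the final minute:

```sh
cat > cfg.yaml <<EOF
seed: 5
simulate:
  mobility: walking
calibrate:
  subset_size: 400
evaluate:
  pairing: "dynamic:dynamic"
  subset_size: 400
EOF

gazecal simulate --config cfg.yaml --out session.csv
gazecal calibrate session.csv --config cfg.yaml --method geometric --out geo.json
gazecal evaluate session.csv --config cfg.yaml --method geometric --out report_geo.json
gazecal evaluate session.csv --config cfg.yaml --method gpr --out report_gpr.json
```

which prints

```
wrote 28800 samples to session.csv
geometric calibration cost 3.28 px -> geo.json
session.csv: combined error 0.225 deg (geometric, dynamic:dynamic)
session.csv: combined error 0.994 deg (gpr, dynamic:dynamic)
```

The session is 28 800 aligned 60 Hz samples with realistic sensor noise
(pupil ≈ 0.15°, head 0.05 cm / 0.1°).  The geometric calibration residual
of 3.28 px is the mean pixel distance between predicted and true PORs on
the calibration data.  On held-out validation data the geometric method is
accurate to 0.23° of visual angle and the regression method to 0.99° —
both far below the ≈4° reported for earlier mobile gaze-tracking systems,
and the regression report additionally carries per-sample predictive
standard deviations (here all below the 75 px rejection threshold:
`"rejected_fraction": 0.0`).

The same machinery is available as a library:

```python
from gazecal import (SimulationConfig, simulate_session, split_session,
                     EvalPairing, run_evaluation, default_screen)

cfg = SimulationConfig(seed=5, mobility="walking")
ds = simulate_session(cfg, protocol="both")
cd, vd, cs, vs = split_session(ds, ds)
summary = run_evaluation(EvalPairing(cd, vd), "gpr", default_screen())
print(summary.combined_mean)     # mean combined angular error, degrees
```

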