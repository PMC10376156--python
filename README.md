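# stairhip

Hip joint angles and moments during stair ascent, estimated from wearable
sensors with a shallow neural network — plus everything needed to exercise the
full workflow at desk scale without any data downloads.

## The problem

Quantifying hip kinematics (angles) and kinetics (net joint moments) during
demanding activities of daily living such as stair ascent normally requires
optical motion capture and laboratory inverse dynamics. A portable
alternative instruments the subject with two inertial measurement units
(IMUs, shank and thigh, 128 Hz, 13 channels each: 3D acceleration, angular
velocity, magnetic field and a 4D orientation quaternion) and one
force-instrumented insole (vertical ground reaction force, 100 Hz), and maps
those streams to sagittal/frontal-plane hip angles (deg) and mass-normalized
moments (Nm/kg) with a small feed-forward network:

* inputs: 28 per-timestep features (2 × 13 IMU channels + vertical GRF +
  activity duration), min–max scaled to [−1, 1];
* architecture: two tanh hidden layers of five nodes each and a linear
  4-output layer, `y = S⁻¹(W₃ tanh(W₂ tanh(W₁x + b₁) + b₂) + b₃)`;
* training: Nguyen–Widrow initialization, full-batch Levenberg–Marquardt
  (`(JᵀJ + λI)δ = −Jᵀr`), stopping when the error-gradient norm stalls for
  more than six passes;
* validation: subject-wise leave-one-out cross-validation with repeated
  training rounds (17 subjects × 10 rounds = 170 trained/tested iterates),
  scored with the coefficient of determination R² and the relative RMSE

  `rRMSE = 100 · RMSE / (½ (range(y) + range(ŷ)))  [%]`,

  plus paired t-tests at heel strike (0 %), mid-stance (30 %), toe off
  (~60 %) and mid-swing (80 %) of the gait cycle, and per-subject KDE violin
  summaries.

Because no public recordings exist for this protocol, the package ships a
synthetic cohort generator (`stairhip.synth`) calibrated to the published
cohort statistics and curve features (sagittal ROM 55.6°, frontal ROM 17.4°,
first abduction-moment peak 1.6 Nm/kg, peak flexion moment 1.0 Nm/kg, stance
67 % of the cycle, 20 N contact threshold, 121.3° shank-mount rotation), and
a planar link-segment inverse-dynamics surrogate (`stairhip.dynamics`) that
reproduces the gold-standard convention of applying the vertical GRF at the
talus.

## Worked example

Simulate a small cohort, run the LOO-CV experiment and print the report:

```sh
stairhip run-all demo --subjects 5 --rounds 2 --seed 7
```

```
Leave-one-out cross-validation of the wearable-ANN workflow
================================================================
iterates: 10 (5 subjects x 2 rounds)
----------------------------------------------------------------
output                       R^2         rRMSE %
sagittal_angle        0.97 +/-0.06      4.7 +/-  4.8
sagittal_moment       0.88 +/-0.18      9.2 +/-  8.3
frontal_angle         0.57 +/-0.74     14.0 +/- 14.9
frontal_moment        0.87 +/-0.24      9.1 +/- 10.4
overall mean          0.82              9.2
----------------------------------------------------------------
benchmark vs ANN, discrete gait points (paired t-test, subject means)
output             gait %     bench       ANN        t        p
sagittal_angle          0     57.43     54.75     1.93   0.1258
sagittal_angle         30     25.28     24.06     1.09   0.3369
...
```

Each row of the first block is the mean ± SD across all trained/tested
iterates of one output's accuracy on the held-out subjects: the network
predicts the ground-truth hip curves of subjects it never saw, and, e.g., a
sagittal-angle rRMSE of 4.7 % means the average prediction error is ~5 % of
the signal range. The second block compares the benchmark and predicted
subject-mean curves at the four discrete gait events; with only five
synthetic subjects no difference is statistically significant (p > 0.05).
With the full default experiment (17 subjects, 10 rounds,
`stairhip run-all out --seed 0`, a few minutes on one CPU) the synthetic
cohort reaches an overall mean R² ≈ 0.97 and rRMSE ≈ 4 %, comfortably inside
the published real-data bounds (0.77 / 17.7 %).

The same pieces are available as a library, statsmodels-style:

```python
import stairhip as sh
from stairhip.evaluation import loocv

cohort = sh.generate_cohort(n_subjects=17, seed=0)   # TrialRecords
result = loocv(cohort, n_rounds=10, seed=0)          # LoocvResult
print(result.summary())                              # table above
ax = sh.evaluation.plot_violins(result, metric="r2") # per-subject violins

prepared = [sh.prepare_trial(t) for t in cohort]
model = sh.HipAnn.from_trials(prepared, stride=32)   # model object
fit = model.fit()                                    # HipAnnResults
print(fit.summary()); fit.save("model.json")
```

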