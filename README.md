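# spinemotion

Concurrent-validity analysis for an instrumented-spine simulation
mannequin, validated against optical motion capture.

Mid-fidelity training mannequins for spinal motion restriction (SMR)
scenarios can carry an instrumented spine: each spine segment (cervical:
head relative to trunk; lumbar: trunk relative to pelvis) is a serial
chain of four encoder-equipped revolute joints — two in flexion, one in
lateral flexion, one in axial rotation.  Before such a mannequin can score
SMR manoeuvres, its orientation measurements must be shown to agree with a
gold-standard optoelectronic system.  `spinemotion` implements that whole
validation pipeline as a reusable library and CLI:

- **Forward kinematics** — Denavit–Hartenberg chains convert the four
  encoder angles θ₁..θ₄ into the end-effector orientation via
  T₁ⁿ = T₁² T₂³ … Tₙ₋₁ⁿ with the standard per-link transform
  (rotation Rz(θᵢ)·Rx(αᵢ)).  Orientations are handled both as anatomical
  Euler angles (flexion / lateral flexion / rotation, configurable
  intrinsic sequence) and as quaternions, whose angle component
  2·arccos|w| gives an axis-independent *global* range-of-motion score.
- **Calibration** — software encoder zeroing from a quasi-static neutral
  window, plus estimation of the two constant frame rotations between the
  systems from one combined-motion trial, by minimizing the mean squared
  relative-rotation angle of q_base ∘ q_mannequin(t) ∘ q_sensor versus the
  reference.
- **Pre-processing** — slerp resampling to a common rate, cross-correlation
  time synchronization on the anatomical plane with the greatest range of
  motion (each trial keeps 1 s of neutral rest for this), removal of
  samples faster than 120°/s of global rotation (marker-obstruction
  artifacts) and slerp reconstruction where fewer than half the samples in
  a 0.2 s span are affected.
- **Agreement statistics** — per-plane RMSE = √(Σ(x₁ᵢ−x₂ᵢ)²/n) with the
  clinical bands (≤2° good, ≤5° acceptable, ≤10° tolerable), Bland–Altman
  bias and limits of agreement (bias ± 1.96·SD, Shapiro–Wilk checked) on
  10 randomly sampled points per trial, parallel-forms reliability r →
  SEM = SD·√(1−r) → MDC₉₅ = 1.96·√2·SEM, and a one-sided non-inferiority
  t-test (α = 2.5%) that motion speed does not degrade accuracy beyond an
  MDC-based margin.
- **Synthetic study generator** — the full 80-trial design (2 segments ×
  4 motion conditions × 10 repetitions; 5 fast at 1 s/cycle, 5 slow at
  4 s/cycle; 3 cycles per trial) with known injected corruption: encoder
  quantization (0.0219°), per-trial zero offsets, frame misalignment,
  inter-system time lag, rotational noise and obstruction bursts near the
  amplitude extremes — all recorded in a ground-truth ledger so every
  pipeline stage is testable as parameter recovery.

## Worked example

```python
from spinemotion import SpineValidationStudy, NoiseModel, StudyDesign

model = SpineValidationStudy.from_synthetic(
    StudyDesign(), NoiseModel.paper_like(), seed=1
)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Concurrent validity of instrumented-spine motion measurement
Trials analyzed: 75   discarded: 5
Alignment residual (cervical): 0.41 deg RMS
Alignment residual (lumbar): 0.40 deg RMS

Root-mean-square error (deg)
                                cervical                lumbar
                          RMSE        SD        RMSE        SD
Global                     0.3       0.0         0.3       0.0
Flexion                    0.2       0.0         0.2       0.0
...
Non-inferiority of fast vs slow motion (one-sided t, alpha=2.5%)
  cervical: diff=+0.04 deg, margin=0.49 deg, p=8.1e-41 -> speed has no effect
  lumbar: diff=+0.04 deg, margin=0.50 deg, p=4.2e-47 -> speed has no effect
```

Reading this: the two frame-alignment fits absorbed the injected 7°/4°
misalignments down to a residual equal to the simulated mocap noise
(0.4° RMS); the five trials with prolonged rigid-body loss were discarded
with reasons rather than silently dropped; every per-plane RMSE lands in
the "Good" band; and the fast-vs-slow RMSE difference stays far inside
the detectable-change margin, so speed has no measurable effect on
accuracy.  `results.trial_table`, `results.bland_altman_table` and
`results.reliability_table` hold the full pandas tables, and
`results.plot_bland_altman("cervical", "global")` draws the
difference-vs-mean plot.

The same pipeline runs from the shell:

```sh
spinemotion simulate --preset paper_like --seed 1 --out study/
spinemotion analyze --study study/ --out report.json
spinemotion report --json report.json
```

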