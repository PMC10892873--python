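# Methods

This note documents the models, numerical choices and limitations of
`spinemotion`: what exactly is computed, which knobs matter, and what the
synthetic experiments do and do not demonstrate.

## Kinematic model

Each spine segment is a serial chain of four revolute joints described in
the Denavit–Hartenberg (DH) convention: per link a length *a*, twist *α*,
offset *d* and joint angle *θ*, giving the homogeneous transform with
rotation block Rz(θ)·Rx(α).  The segment orientation is the ordered
product of the link transforms.  The shipped chain configurations
(`spinemotion/chains/*.yaml`) describe the cervical chain (5 rows: 4
actuated + 1 fixed virtual frame that makes head and trunk share an
orientation in the neutral posture) and the lumbar chain (4 actuated
rows).  Two properties of these parameter tables are load-bearing and are
enforced by tests against an independent symbolic (sympy) oracle:

- the all-zero configuration yields exactly the identity relative
  orientation, and
- each joint moved alone produces a fixed single-axis rotation whose
  magnitude equals the encoder angle (cervical axes: z, −y, −y, x;
  lumbar: z, −y, x, −y).

Link lengths r₁..r₃ enter only the translation column and never the
relative orientation — the validated quantity — so they default to 1.0
and are plain config parameters.

A note on the link transform: the only rotation block consistent with
R = Rz(θ)Rx(α) has element (2,3) equal to −cosθ·sinα, and that is what is
implemented.

### Orientation representations

Quaternions are scalar-first and canonicalized to w ≥ 0 (removes the
double-cover ambiguity from comparisons).  Angles are radians internally
and degrees at every API boundary.  Anatomical angles are intrinsic Euler
decompositions; the sequence is configurable with default **YXZ** =
flexion (y) → lateral flexion (x) → axial rotation (z).  The hardware
measures joint angles, not Euler angles, so the sequence is a reporting
convention; what matters for agreement statistics is only that both
systems are decomposed with the same convention.  Within 0.5° of a ±90°
middle angle the decomposition is flagged degenerate (gimbal lock) rather
than silently split; the global quaternion angle 2·arccos|w| is immune to
this and carries the "Global" rows of every table.

## Calibration

**Encoder zeroing.**  Per-channel means over a quasi-static window
(≥ 0.5 s; motion gate 2 °/s, measured over ~0.1 s spans so the 0.0219°
quantization steps do not masquerade as motion).

**Frame alignment.**  The systems differ by two constant rotations — one
on the reference side of the chain (how the lab frame was set down) and
one on the body side (how the rigid body sits on the segment).  The model
q_ref(t) ≈ q_base ∘ q_mann(t) ∘ q_sensor is fitted on one combined-motion
trial per segment by minimizing the mean squared relative-rotation angle,
parameterized by two rotation vectors (optionally + 4 encoder-zero
deltas), with L-BFGS-B from a zero start plus 8 seeded random restarts
(deterministic given the seed).  The trial must excite every anatomical
plane by ≥ 5°: under single-plane (rank-1) motion the pair (q_base,
q_sensor) is only identifiable up to a one-parameter family of rotations
about the motion axis, and the fit refuses such trials.  Sample weighting
is uniform by default; a neutral-weighted mode (Gaussian weight in the
global angle, 10° scale) is available for use cases that care most about
accuracy near the neutral posture.  The cost is evaluated on at most 600
evenly spaced samples for speed; the reported residual RMS uses the full
series.

## Pre-processing

Both streams are slerp-resampled onto a uniform common grid (default
100 Hz); a resampled point is valid only if both bracketing source
samples are valid.  Synchronization picks the anatomical-angle channel
with the largest range of motion and maximizes the per-lag
overlap-normalized Pearson correlation over integer lags up to ±2 s.
Normalizing per overlap (rather than using one global norm) matters:
raised-cosine motion has a large mean offset, and a single-norm
correlation is biased by several samples by the truncated window edges.
An optional parabolic sub-sample refinement exists but is off by default
(integer alignment suffices at 100 Hz).  Both streams must open with
≥ 1 s of quasi-neutral rest (tolerance 5° on the sync channel).

Outlier screening applies to the reference stream (the failure mode being
marker obstruction): any step faster than 120 °/s of global rotation
flags both bounding samples.  Repair examines sliding 0.2 s windows with
50 % overlap; a flagged sample is reconstructed by slerp between its
nearest clean neighbours if *any* window containing it is less than half
flagged, otherwise it stays invalid and is excluded downstream.  Trials
keeping fewer than 70 % valid paired samples after repair are discarded
with an explicit reason (mirroring how prolonged rigid-body loss is
handled in practice); analyzed + discarded always equals the input count.

## Agreement statistics

- **RMSE** per plane over all valid paired samples of a trial, read
  against the bands ≤2° good / ≤5° acceptable / ≤10° tolerable / >10°
  unbearable (left-inclusive boundaries).
- **Bland–Altman**: bias = mean(x₁−x₂), limits = bias ± 1.96·SD (sample
  SD, n−1), on a pool of 10 points per trial sampled uniformly without
  replacement (seeded per trial) — the fixed per-trial count is what
  equalizes fast and slow trials.  Shapiro–Wilk W is reported with
  W > 0.96 as a soft normality gate: a warning-level flag, not an abort,
  since limits of agreement are tolerant of mild non-normality.
- **Reliability → SEM → MDC**: r is the Pearson correlation between the
  two systems' pooled scores; SD is the sample SD of the per-point mean
  motion value (the spread of what was measured, 8–12° for the default
  synthetic design); SEM = SD·√(1−r); MDC₉₅ = 1.96·√2·SEM exactly.
- **Non-inferiority**: one-sided two-sample Welch t-test of
  H₀: mean(RMSE_fast) − mean(RMSE_slow) ≥ margin against the smaller
  alternative, α = 0.025, on per-trial global RMSE values.  The margin
  defaults to the study's own global MDC per segment; the published
  margins for the physical mannequin (2.05° cervical, 2.45° lumbar) ship
  as `PUBLISHED_MDC_THRESHOLDS`.  A paired variant is available
  (`paired=True`); pairing is not asserted by default because fast and
  slow repetitions are distinct trials.
- Report tables round to one decimal with ties away from zero.

## Synthetic study generator

The generator emulates the validation protocol, not the optics: per
segment one combined-motion calibration trial plus 4 conditions × 10
repetitions (5 fast at 1 s/cycle, 5 slow at 4 s/cycle), 3 raised-cosine
cycles per trial (C¹, neutral at both ends), 1 s neutral prefix, encoder
stream at 100 Hz and mocap at 120 Hz.  Defaults that the protocol leaves
open were fixed once at values a motion-capture practitioner would call
realistic:

| parameter | default | why |
|---|---|---|
| amplitude, slow / fast | 40° / 15° per plane | keeps true peak global velocity (A·π/period) at 31/47 °/s, under the 120 °/s outlier gate — large fast-trial amplitudes would inherently collide with that rule |
| combined-trial scale | 0.5 × amplitude | bounds the summed multi-plane velocity |
| combined cycle counts | 3/4/5 per plane | a shared envelope would make the motion rank-1 and the alignment unidentifiable (see Calibration) |
| encoder quantization | 0.0219° | the hardware's claimed precision |
| mocap noise | 0.5° RMS total rotation angle (rotvec components iid N(0, σ/√3)) | optical rigid-body orientation jitter at sub-degree level |
| frame misalignment | 7° (base, about z) and 4° (sensor, about x) | distinct axes, recoverable |
| time lag | 0.25 s | an integer number of analysis samples |
| obstruction bursts | p = 0.3 per peak passage, 0.08 s of 3°/axis jitter where the global angle is within 10 % of the trial maximum | obstructions happen at amplitude extremes, where markers rotate away from the cameras |

The `paper_like` preset additionally injects five lumbar trials (one
flexion, three rotation, one combined) with a prolonged corrupted stretch
covering ~60 % of the trial, emulating extended rigid-body loss; the
pipeline must discard exactly these.  Every injected quantity — per-trial
zero offsets, burst sample indices, lag, misalignment rotations — is
written to a ledger, and one global seed fans out to per-trial
substreams (`numpy` SeedSequence spawning), so studies are bit-identical
for a given seed.

**What the generator does not emulate:** marker-level optics (individual
marker dropout, rigid-body re-solving), soft-tissue-like compliance
between encoder and surface, encoder drift, or human variation in how an
operator moves the segment.  Green tests therefore demonstrate that the
*pipeline* is correct and its statistics behave as designed under the
stated noise model — not that any physical mannequin meets a particular
accuracy.  With the default noise preset the synthetic study lands at
~0.3° global RMSE, below the 0.7–2.3° range a physical device shows,
because the simulated corruption is by construction cleaner than a
laboratory; the acceptance checks on the full study are therefore band
assertions (everything "Good/Acceptable"), not value reproductions.
An optional backlash model (play-operator hysteresis) exists for
emulating mechanical looseness, default off.

## Numerical details and edge cases

- Rotation conversions, slerp and Euler decompositions are delegated to
  `scipy.spatial.transform` behind thin convention-fixing wrappers;
  quaternions already unit within 1e-9 are not renormalized, which keeps
  CSV round trips byte-stable.
- Degenerate statistics are flagged, not fabricated: zero-variance
  differences give a degenerate Bland–Altman (W set to 1), zero-variance
  RMSE groups decide non-inferiority by direct comparison with a flag,
  and zero-variance scores make reliability an error.
- Problem sizes were chosen so the default test suite and the acceptance
  script each complete in a few minutes on one CPU: the full 80-trial
  study fits in ~5 s; Monte-Carlo loops use 20 seeds (recovery bands) and
  1000 replicates (non-inferiority power).

## Known limitations

- The anatomical Euler sequence is a convention knob; reported per-plane
  values (not the global angle) change under a different sequence.
- The alignment fit assumes the misalignment is constant over a trial;
  slow drift between systems is not modeled or corrected.
- Sub-sample lag is not corrected by default; at 100 Hz and ≤ 50 °/s this
  contributes at most ~0.25° of apparent error, folded into the reported
  agreement rather than removed.
- The 120 °/s outlier rule and genuinely fast large-amplitude motion can
  collide; the generator's defaults avoid the collision by design, and
  the tension is inherent to the rule, not resolved here.
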