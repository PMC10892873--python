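# Lumbar spine DH chain: trunk (end-effector) relative to pelvis (base).
# Four encoder-driven revolute joints; the neutral posture yields identity
# relative orientation by construction of the theta offsets.
segment: lumbar
link_lengths: {r1: 1.0, r2: 1.0, r3: 1.0}
joint_limits_deg: 90.0
rows:
  - {a: r1, alpha: 1.5707963267948966, d: 0.0, theta_offset: 0.0,
     joint_index: 1, plane: rotation, plane_sign: 1}
  - {a: 0.0, alpha: 1.5707963267948966, d: 0.0, theta_offset: 1.5707963267948966,
     joint_index: 2, plane: flexion, plane_sign: -1}
  - {a: 0.0, alpha: -1.5707963267948966, d: r2+r3, theta_offset: 0.0,
     joint_index: 3, plane: lateral_flexion, plane_sign: 1}
  - {a: 0.0, alpha: -1.5707963267948966, d: 0.0, theta_offset: -1.5707963267948966,
     joint_index: 4, plane: flexion, plane_sign: -1}
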