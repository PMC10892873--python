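# Cervical spine DH chain: head (end-effector) relative to trunk (base).
# Four encoder-driven revolute joints plus one fixed virtual frame so that
# the head and trunk share the same orientation in the neutral posture.
# Angles in radians; link lengths are symbolic (r1..r3) and only affect
# translation, never the relative orientation.
segment: cervical
link_lengths: {r1: 1.0, r2: 1.0, r3: 1.0}
joint_limits_deg: 90.0
rows:
  - {a: r1, alpha: 1.5707963267948966, d: 0.0, theta_offset: 0.0,
     joint_index: 1, plane: rotation, plane_sign: 1}
  - {a: r2, alpha: 0.0, d: 0.0, theta_offset: 0.0,
     joint_index: 2, plane: flexion, plane_sign: -1}
  - {a: 0.0, alpha: 1.5707963267948966, d: 0.0, theta_offset: 1.5707963267948966,
     joint_index: 3, plane: flexion, plane_sign: -1}
  - {a: 0.0, alpha: -1.5707963267948966, d: r3, theta_offset: 0.0,
     joint_index: 4, plane: lateral_flexion, plane_sign: 1}
  - {a: 0.0, alpha: -1.5707963267948966, d: 0.0, theta_offset: -1.5707963267948966,
     joint_index: fixed}
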