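"""Simulate one countermovement jump and compute its per-trial outcomes.

Builds a noise-free CMJ with a 25 cm target flight height, segments it into
phases from the force plate and pelvis markers, and prints jump height (two
methods), eccentric-phase relative torque and power peaks, and the rate of
force development.
"""

from kinegen import events, kinematics, outcomes
from kinegen.synthetic import JumpSimConfig, simulate_jump_trial

cfg = JumpSimConfig(jump_type="CMJ", target_flight_height=0.25, body_mass=55.0)
markers, forceplate, truth = simulate_jump_trial(cfg)

seg = events.segment_jump_phases(markers, forceplate, "CMJ")
lin = kinematics.linear_kinematics(markers)

h_flight = events.jump_height(seg, lin, "flight_time")
h_marker = events.jump_height(seg, lin, "marker")
print(f"jump height, flight-time method: {h_flight:.3f} m")
print(f"jump height, marker-apex method: {h_marker:.3f} m")
print(f"(simulated ground truth:         {truth.flight_height:.3f} m)")

anthro = outcomes.AnthropometryConfig()
ecc = seg.phases["E"]
for joint in ("hip", "knee"):
    ang = kinematics.joint_angle_series(markers, joint, side="R")
    seg_mass = anthro.chain_mass(joint, cfg.body_mass)
    rt, rt_peak = outcomes.relative_torque(seg_mass, ang, cfg.body_mass, phase=ecc)
    _, p_peak = outcomes.joint_power(rt, ang.angular_velocity, phase=ecc)
    print(f"{joint}: eccentric relative-torque peak {rt_peak:8.1f} "
          f"(kg·deg·s⁻²/kg), power peak {p_peak:10.0f}")

ratio = forceplate.frequency / markers.frequency
prop = (int(seg.phases["E"][0] * ratio), int(seg.phases["C"][1] * ratio))
rfd = outcomes.rate_of_force_development(forceplate, prop)
print(f"rate of force development over the propulsion phase: {rfd:.0f} N/s")
print("Higher torque/power peaks and RFD indicate a more explosive jump.")
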