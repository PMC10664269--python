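"""Reactive-strength profile from a drop jump and a squat jump.

Simulates a 20 cm-box drop jump and a squat jump for the same athlete,
derives the reactive strength index (DJ height / ground contact time), the
index of reactive force ((DJ − SJ) / SJ), and classifies the stretch-
shortening cycle as fast (<250 ms contact) or slow.
"""

from kinegen import events, kinematics
from kinegen.outcomes import reactive_indices
from kinegen.synthetic import JumpSimConfig, simulate_jump_trial

dj_cfg = JumpSimConfig(jump_type="DJ", target_flight_height=0.27,
                       contact_time=0.20, box_height=0.20)
sj_cfg = JumpSimConfig(jump_type="SJ", target_flight_height=0.24)

heights = {}
for cfg in (dj_cfg, sj_cfg):
    markers, fp, _ = simulate_jump_trial(cfg)
    seg = events.segment_jump_phases(markers, fp, cfg.jump_type)
    lin = kinematics.linear_kinematics(markers)
    heights[cfg.jump_type] = events.jump_height(seg, lin, "flight_time")
    if cfg.jump_type == "DJ":
        contact = seg.contact_time

print(f"DJ height {heights['DJ']:.3f} m, SJ height {heights['SJ']:.3f} m, "
      f"ground contact {contact * 1000:.0f} ms")
rsi, ireaf = reactive_indices(heights["DJ"], heights["SJ"], contact)
print(f"reactive strength index (RSI): {rsi:.2f}")
print(f"index of reactive force (IReaF): {ireaf:.2f}")
print(f"stretch-shortening cycle: {events.classify_ssc_speed(contact)} "
      f"(<250 ms contact is 'fast')")
print("A positive IReaF means the rebound (eccentric pre-load) added height "
      "beyond the purely concentric squat jump.")
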