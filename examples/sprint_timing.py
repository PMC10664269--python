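"""Time a 5-m sprint between two virtual gates from the sacrum trajectory.

Simulates an athlete accelerating at 2.4 m/s² from half a metre behind the
first gate, with 1 mm marker noise, and compares the detected gate-to-gate
time with the simulator's exact crossing times.
"""

from kinegen.events import sprint_time
from kinegen.synthetic import SprintSimConfig, simulate_sprint_trial

cfg = SprintSimConfig(v0=0.0, acceleration=2.4, start_x=-0.5,
                      noise_sd=0.001, seed=3)
markers, truth = simulate_sprint_trial(cfg)

detected = sprint_time(markers, truth.gate_positions)
exact = truth.gate_times[1] - truth.gate_times[0]
print(f"gates at x = {truth.gate_positions[0]} m and {truth.gate_positions[1]} m")
print(f"detected 5-m sprint time: {detected:.4f} s")
print(f"exact (ground truth):     {exact:.4f} s")
print("The gate times come from linear interpolation of the sacrum marker "
      "crossing each plane, so the error is well under one frame period.")
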