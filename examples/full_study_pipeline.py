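"""Run the whole study pipeline on a synthetic cohort written to disk.

Simulates a 12-participant cohort (marker/force TSV files, trial manifest,
genotype CSV) with an additive ACE effect on explosiveness, runs the full
analysis (per-trial outcomes -> per-participant aggregation -> Hardy-
Weinberg -> association), and prints where the result tables landed.
"""

import tempfile
from pathlib import Path

import pandas as pd

from kinegen.pipeline import run_pipeline, simulate_study

workdir = Path(tempfile.mkdtemp(prefix="kinegen_study_"))
config = simulate_study(workdir, n_participants=12, trials_per_test=2,
                        seed=5, effect_size=1.0, model="additive",
                        target_locus="ace", noise_sd=0.001)

paths = run_pipeline(config)
for name, path in paths.items():
    print(f"{name:22s} {path}")

part = pd.read_csv(paths["participant_outcomes"])
print(f"\n{len(part)} participants analysed; cohort mean CMJ height "
      f"{part['cmj_height_m'].mean():.3f} m, mean RSI {part['rsi'].mean():.2f}")
assoc = pd.read_csv(paths["association"])
row = assoc[(assoc.outcome == "cmj_hip_rt_peak") & (assoc.locus == "ace")].iloc[0]
print(f"CMJ hip torque vs ACE: ANOVA p = {row['p_anova']:.2g}, "
      f"carrier mean {row['carrier_mean']:.1f} vs {row['noncarrier_mean']:.1f}")
print("With only 12 participants the p-values are illustrative; the carrier "
      "group mean should still trend higher, matching the simulated effect.")
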