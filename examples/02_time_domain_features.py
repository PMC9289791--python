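"""Extract the four time-domain feature sets from running windows.

Cuts 175 ms windows (20% overlap) from the steady state of each stimulus
and runs MAV, MAV&WL, TDD and TSD.  Each framework fuses every window's
features with an earlier window of the same stimulus, so the rows carry
temporal context; column counts depend only on the channel count.
"""

from engfeat import (ProtocolConfig, SignalModelConfig, generate_dataset,
                     WindowSpec, design_bandpass, apply_filter,
                     windows_from_recording, run_mav_framework,
                     run_mav_wl_framework, run_tdd_framework, run_tsd_framework)

pc = ProtocolConfig(n_channels=4, fs=10000.0, n_blocks=1,
                    stimuli_per_class_per_block=3, on_s=1.0, off_s=0.5, seed=0)
rec = generate_dataset(pc, SignalModelConfig(gain_depth=0.8, seed=1))
rec = apply_filter(rec, design_bandpass(rec.fs, order=200))
ws = windows_from_recording(rec, WindowSpec(0.175, 0.20), trim_s=0.25)
print(f"{len(ws)} windows of {ws.windows[0].shape[1]} samples "
      f"from {len(rec.events)} stimuli")

for name, runner in [("MAV", run_mav_framework), ("MAV&WL", run_mav_wl_framework),
                     ("TDD", run_tdd_framework), ("TSD", run_tsd_framework)]:
    fm = runner(ws)
    print(f"{name:7s} {fm.n_instances} x {fm.n_features:4d}  "
          f"first row head: {fm.values[0, :3].round(4)}")
# MAV: one feature per channel; MAV&WL doubles that; TDD has 6 descriptors
# per channel; TSD has 8 per stream (channels + pairwise differences).
# Fused rows are unit-norm, which is why values sit in [-1, 1].
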