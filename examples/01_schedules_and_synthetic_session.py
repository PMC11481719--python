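"""Build the session schedules and a synthetic cohort with known ground truth.

The conditioning (FC) session is 5 min habituation, five 30 s tones each
co-terminated by a 1 s footshock, 180 s inter-trial intervals and a 180 s
tail; extinction (FE) swaps in fifteen unshocked tones with 30 s intervals.
The trace simulator couples a chosen fraction of neurons to the tones so
that downstream stages have an exact answer to recover.
"""

import numpy as np

import fearscope as fs

fc = fs.make_fc_schedule()
fe = fs.make_fe_schedule()
print(f"FC session: {fc.duration_s:.0f} s, {len(fc.tone_intervals)} tones, "
      f"{len(fc.shock_intervals)} shocks")
print(f"FE session: {fe.duration_s:.0f} s, {len(fe.tone_intervals)} tones, "
      f"{len(fe.shock_intervals)} shocks")
first_tone = fc.tone_intervals[0]
first_shock = fc.shock_intervals[0]
print(f"first tone frames {first_tone}, shock occupies {first_shock} "
      "(the final second of the tone)")

coupling = fs.CouplingSpec.from_fractions(
    50, {"excited": 0.2, "inhibited": 0.1, "null": 0.7})
traces, truth = fs.simulate_traces(fc, 50, coupling=coupling, seed=1)
print(f"\nsimulated {traces.n_neurons} neurons x {traces.n_frames} frames "
      f"at {traces.fps:.0f} fps")
counts = np.array([s.size for s in truth.spike_times])
print(f"mean ground-truth event rate: {counts.mean() / fc.duration_s:.3f} "
      "events/s (base rate 0.2/s, trimmed slightly by the refractory gap)")

freezing, _ = fs.simulate_freezing(fc, p_freeze_tone=0.8, p_freeze_iti=0.2, seed=1)
print(f"freezing trace: {freezing.n_seconds} one-second samples, "
      f"{100 * freezing.binary.mean():.1f}% of seconds frozen")
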