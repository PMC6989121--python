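"""Optogenetic stimulus-response classification.

Two stimulation paradigms on simulated sessions with known per-cell
classes: (1) short pulses (50 ms) with the mean+2*sigma responder call
and sigmoid-fit onset latency relative to stimulus offset; (2) long
(10 s) stimulation with the paired-t three-way modulation classification
and per-cluster event rates.
"""

import numpy as np

from ninsync import (
    EventTrain,
    SynthConfig,
    build_trials,
    classify_modulation,
    classify_responders,
    simulate_session,
)

# --- short-pulse paradigm: responders and onset latencies ------------------
pulse = SynthConfig(
    duration_s=220.0, seed=5, n_stimuli=10, stim_isi_s=20.0,
    stim_duration_s=0.05, sp_rate_hz=0.0, rearing_rate_per_min=0.0,
)
traces, _, stim, truth = simulate_session(pulse)
tensor = build_trials(traces, stim, pre_s=2.0, post_s=4.0)
calls, frac = classify_responders(tensor)
onsets = [c.onset_s for c in calls if c.onset_s is not None]
print(f"pulse paradigm: {frac:.0%} responders of {len(calls)} cells "
      f"(planted increased fraction {pulse.p_increased:.0%})")
print(f"median sigmoid-fit onset: {np.median(onsets)*1000:.0f} ms "
      f"post-offset (planted ~{pulse.stim_response_latency_s*1000:.0f} ms)")

# --- long-stimulation paradigm: three-way modulation -----------------------
long = SynthConfig(
    duration_s=320.0, seed=5, n_stimuli=10, stim_isi_s=30.0,
    stim_duration_s=10.0, sp_rate_hz=0.0, rearing_rate_per_min=0.0,
)
traces, _, stim, truth = simulate_session(long)
tensor = build_trials(traces, stim, pre_s=5.0, post_s=12.0)
trains = [
    EventTrain(cid, reg, truth.onsets[cid], np.ones(truth.onsets[cid].size))
    for cid, reg in zip(traces.cell_ids, traces.region)
]
mods, fractions, rates = classify_modulation(tensor, trains=trains, stim=stim)
print("modulation clusters:", {k: round(v, 2) for k, v in fractions.items()})
print("event rate during stimulation by cluster (Hz):",
      {k: round(v, 2) for k, v in rates.items() if not np.isnan(v)})
agree = np.mean([m.cls == truth.response_class[m.cell_id] for m in mods])
print(f"agreement with planted classes: {agree:.0%}")
# "decreased" cells had 80% of their baseline events suppressed during
# stimulation; "increased" cells fire ~1.4 Hz of extra events during the
# window plus a strong offset-locked transient.
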