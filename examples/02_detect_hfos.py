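"""Pseudo-prospective HFO detection on synthesized raw iEEG.

Embeds known oscillatory bursts (140 Hz, 50 ms) in 1/f noise, runs the
causal RMS detector (background = previous 10 min only, emission in 30-s
steps), and scores recall/precision against the ground truth.
"""

import numpy as np

from hforate import (
    HFOEvent,
    SimConfig,
    make_channel_map,
    pseudo_prospective_detect,
    synthesize_ieeg,
)

channels = make_channel_map(n_soz=1, n_out=2)
config = SimConfig(n_soz=1, n_out=2, sampling_rate=2048.0, burst_snr=10.0,
                   rng_seed=7)
duration = 900.0

rng = np.random.default_rng(7)
truth = [HFOEvent(ch, float(s), float(s) + 0.05)
         for ch in channels.ids()
         for s in np.sort(rng.uniform(605.0, duration - 5.0, 20))]

segment = synthesize_ieeg(truth, channels, config, duration)
detected = pseudo_prospective_detect(segment, channels)

hits = sum(any(d.channel_id == t.channel_id and d.start_s < t.end_s
               and t.start_s < d.end_s for d in detected) for t in truth)
print(f"embedded bursts: {len(truth)}   detected events: {len(detected)}")
print(f"recall {hits / len(truth):.2f}   precision {hits / len(detected):.2f}")
print(f"first event at {min(d.start_s for d in detected):.1f} s "
      "(never before the 600-s warm-up)")
# Recall/precision near 1.0 at snr 10: the RMS threshold (background mean +
# 5 SD) plus the >=6-peak rule separate bursts cleanly from 1/f noise.
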