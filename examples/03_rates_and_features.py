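"""From events to continuous HFO rates to 16-dimensional feature vectors.

Computes the cHFO rate (1-min window, 1-s step, per channel group) for a
synthetic patient and extracts the 8 statistics x 2 groups over 30-min
feature windows.
"""

import numpy as np

from hforate import (
    FeatureWindowConfig,
    PreictalEffect,
    SimConfig,
    build_feature_matrix,
    compute_chfo_rate,
    generate_seizure_schedule,
    make_channel_map,
    simulate_event_stream,
)

schedule = generate_seizure_schedule(4, 12 * 3600.0, rng_seed=3)
channels = make_channel_map(4, 8)
config = SimConfig(n_soz=4, n_out=8,
                   preictal_effect=PreictalEffect("linear_ramp", 30.0, 3.0),
                   rng_seed=3)
events = simulate_event_stream(schedule, channels, config)

series = compute_chfo_rate(events, channels, schedule.recording_duration)
print(f"rate grid: {series.times.size} samples at 1 s; "
      f"mean SOZ rate {series.rate_soz.mean():.2f}, "
      f"OUT {series.rate_out.mean():.2f} events/min/channel")

features = build_feature_matrix(series, FeatureWindowConfig(30))
print(f"{len(features)} overlapping 30-min feature windows (1-min grid)")

# compare the window right before the first seizure with a distant one
onset = schedule.onsets[0]
pre = min(features, key=lambda f: abs(f.window_end_s - (onset - 60.0)))
far = min(features, key=lambda f: abs(f.window_end_s - (onset - 7200.0)))
for name in ("MEAN-SOZ", "SLOPE-SOZ", "VAR-SOZ"):
    print(f"{name:10s} preictal {pre.as_dict()[name]:+.3f}   "
          f"interictal {far.as_dict()[name]:+.3f}")
# SLOPE-SOZ (events/min/channel per minute) is clearly positive in the
# window leading into the seizure and near zero far from it.
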