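"""Full single-patient analysis: simulate -> label -> LASSO -> significance.

One synthetic patient with 12 seizures and a 3x SOZ preictal ramp; the
split/fit/test cycle runs 10 times per feature window (30/15/10 min), AUCs
are tested by label permutation, and per-window p-values are combined with
the harmonic mean.
"""

from hforate import PreictalEffect, SimConfig, run_patient, summarize_patient
from hforate.pipeline import RunConfig, simulate_patient_observations

config = RunConfig(
    n_seizures=12,
    recording_duration_s=26 * 3600.0,
    sim=SimConfig(n_soz=4, n_out=8,
                  preictal_effect=PreictalEffect("linear_ramp", 30.0, 3.0)),
    master_seed=11,
)
obs_by_window, extras = simulate_patient_observations(config)
for L, obs in sorted(obs_by_window.items(), reverse=True):
    n_pre = sum(o.label == "preictal" for o in obs)
    print(f"{L:2d}-min window: {n_pre} preictal / "
          f"{len(obs) - n_pre} interictal observations")

results = run_patient(obs_by_window, n_repeats=10,
                      base_seed=config.master_seed)
summary = summarize_patient(results, n_perm=1000, seed=config.master_seed)
print(summary.to_frame().to_string(index=False))
print("patient is a responder:", summary.responder)
# A responder window has mean held-out AUC >= 0.6 with harmonic-mean
# permutation p < 0.05; with this effect size all three windows respond.
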