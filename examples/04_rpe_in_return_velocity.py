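"""Detect the post-feedback RPE modulation in normalized velocity traces.

Synthesizes out-and-back reaches whose return phase is scaled by
1 + rpe_gain * RPE starting 212 ms after feedback, extracts feedback-aligned
normalized-velocity windows (-150..+300 ms), runs the per-subject first-level
regression on trial RPE and the across-subject second-level test with
max-|t| sign-flip control, and reports the detected onset — which should
land near the generating 212 ms latency.
"""

import numpy as np

from reachvigor import cohort, kinematics as km, vigorstats as vs

rng = np.random.default_rng(0)
kin = cohort.KinematicGenParams()  # default rpe_gain 0.04
rpe_levels = [-2 / 3, -1 / 3, 0.0, 1 / 3, 2 / 3]

curves, regressors, subjects = [], [], []
for s in range(8):
    for _ in range(30):
        rpe = rng.choice(rpe_levels)
        out_pk = 0.6 * np.exp(rng.normal(0, 0.05))
        tr = cohort.simulate_trace(out_pk, 0.9 * out_pk, rpe, kin, 45.0,
                                   rt_ms=float(rng.uniform(250, 350)))
        f = km.filter_trace(tr)
        km.attach_radial_velocity(f)
        m = km.extract_metrics(f)
        curves.append(km.extract_aligned_window(f, "feedback",
                                                out_peak_vel=m.out_peak_vel))
        regressors.append(rpe)
        subjects.append(s)

betas, _ = vs.spm_first_level(np.array(curves), np.array(regressors),
                              np.array(subjects))
res = vs.spm_second_level(betas, time_ms=np.arange(-150, 300),
                          n_perm=1000, seed=1)
print(f"family-wise |t| threshold: {res.threshold:.2f}")
print(f"significant samples: {int(res.mask.sum())} of {len(res.mask)}")
print(f"detected modulation onset: {res.onset_ms} ms after feedback")
# The generator applies the gain from +212 ms, but the zero-phase 10 Hz
# filter spreads sharp changes symmetrically by up to ~80 ms, so detected
# onsets scatter around (and can precede) the true latency.
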