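"""Sliding-window CSP: spatial-pattern dynamics and an accuracy time-course.

Fits CSP in every (band, window) cell of one subject, prints which channels
carry the class contrast during the motor-imagery interval (the planted C3/C4
should dominate theta_J), and the cross-validated accuracy before the cue
versus during imagery (chance ~0.5 before, well above after).
"""

import numpy as np

from migroup import build_filterbank, default_cohort_spec, generate_subject, make_window_grid
from migroup.csp import accuracy_timecourse, fit_dynamics
from migroup.preprocess import FilterBank

spec = default_cohort_spec(seed=3, n_subjects=1, n_trials_per_class=60,
                           subject_jitter=0.0)
subject = generate_subject(spec, 0)

mu_bank = FilterBank(bands=((8.0, 12.0),), f_min=8, f_max=12, width=4, step=2)
grid = make_window_grid(tau=1.0, overlap=0.5, trial_span=7.0, sample_rate=250.0)

theta, feats = fit_dynamics(subject, mu_bank, grid, k=3)
sel = theta.position_slice((2.6, 4.6))
pattern = theta.values[None][0, sel].mean(axis=0)
top = np.argsort(pattern)[::-1][:4]
print("theta_J during motor imagery, top channels (planted: C3, C4):")
for i in top:
    print(f"  {theta.channels[i]:4s}  {pattern[i]:.3f}")

mean, sd = accuracy_timecourse(subject, mu_bank, grid, k=3, seed=0)
pre = grid.positions <= 1.0
mi = (grid.positions >= 2.6) & (grid.positions <= 3.6)
print(f"accuracy pre-cue: {mean[pre].mean():.3f}  (chance = 0.5)")
print(f"accuracy during MI: {mean[mi].mean():.3f} +/- {sd[mi].mean():.3f}")
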