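"""Fit the one-phase decay model to chemiluminescence traces.

Builds noiseless traces from four reference half-lifetimes spanning the
serum-protein range (fast-decaying albumin to slow-decaying IgG), plus one
noisy trace, and refits them.  The fitted half-life T1/2 = ln(2)/k is the
time for the signal to fall halfway toward its plateau — the feature every
downstream stage consumes.
"""

import numpy as np

from decaysense import DecayTrace, fit_one_phase_decay

times = np.arange(5.0, 181.0, 5.0)  # minutes, the default imaging window

print("noiseless traces (amplitude 1000, plateau 0):")
for name, t12 in [("albumin", 9.08), ("IgG", 72.70), ("albumin+IgG", 8.57), ("serum", 13.15)]:
    trace = DecayTrace(times, 1000.0 * np.exp(-np.log(2.0) * times / t12))
    fit = fit_one_phase_decay(trace)
    print(f"  {name:12s} true T1/2 = {t12:6.2f} min   fitted = {fit.half_life:8.4f} min")

rng = np.random.default_rng(0)
clean = 1000.0 * np.exp(-np.log(2.0) * times / 30.0) + 50.0
noisy = clean * (1 + rng.normal(0, 0.02, len(times)))  # 2% detector noise
fit = fit_one_phase_decay(DecayTrace(times, noisy))
print(f"\nnoisy trace, true T1/2 = 30 min: fitted = {fit.half_life:.2f} min "
      f"(plateau {fit.plateau:.1f}, rss {fit.rss:.0f}, converged={fit.converged})")
print("A fitted half-life within a few percent of truth at 2% noise is typical.")
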