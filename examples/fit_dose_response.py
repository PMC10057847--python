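"""Fit Hill parameters to replicate dose-response curves.

Simulates 6 replicate measurements of a wild-type-like sensor on the
standard 12-point inducer grid (zero + 2-fold serial dilution), drops
replicates whose saturating output disagrees with the consensus by
more than 1.25-fold, and estimates the four Hill parameters by MCMC.
The printed posterior means/SDs are on the landscape-table scales
(base-10 logs for G0, Ginf, EC50; linear Hill coefficient) and should
bracket the generating values: G0 ~ 158 MEF, Ginf ~ 24.4 kMEF,
EC50 ~ 96 umol/L, n ~ 1.41.
"""

import numpy as np

import sensortune as st

truth = st.biophys_to_hill(st.WT_BIOPHYS)
print(f"generating curve: G0={truth.g0:.0f} MEF  Ginf={truth.ginf:.0f} MEF  "
      f"EC50={truth.ec50:.1f} umol/L  n={truth.n:.2f}")

curves = st.simulate_curves(truth, rel_noise=0.05, n_replicates=6, seed=42)
# corrupt one replicate so the outlier rule has something to catch
bad = curves[2]
curves[2] = st.DoseResponseCurve(
    bad.ligand, bad.geo_mean * np.where(bad.ligand > 100, 1.8, 1.0),
    bad.geo_mean_err, bad.replicate_id,
)

top_signal = {c.replicate_id: float(c.geo_mean[np.argmax(c.ligand)]) for c in curves}
kept, dropped = st.filter_outlier_replicates(top_signal)
print(f"replicates kept: {kept}; dropped as outliers: {dropped}")

post = st.fit_hill([c for c in curves if c.replicate_id in kept], seed=0)
print(f"converged: {post.converged} (split R-hat {post.rhat:.3f})")
for name, (mean, sd) in post.summary().items():
    print(f"  {name:9s} = {mean:7.3f} +/- {sd:.3f}")
med = post.median_params()
print(f"posterior median on linear scales: G0={med.g0:.0f} MEF  "
      f"Ginf={med.ginf:.0f} MEF  EC50={med.ec50:.1f} umol/L  n={med.n:.2f}")
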