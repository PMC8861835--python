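"""Covariate building blocks: terrain indices, VIF pruning, ROC cutoff,
and the direct (distance x time-since) risk/reward metric.
"""

import numpy as np
import pandas as pd

from mesopred import covariates, direct

# Terrain indices on a toy hill
elev = np.zeros((5, 5))
elev[2, 2] = 10.0
print("TRI at the peak:", covariates.compute_tri(elev)[2, 2].round(3))
print("TPI at the peak:", covariates.compute_tpi(elev)[2, 2].round(3))

# VIF pruning drops one of a correlated pair
rng = np.random.default_rng(0)
x = rng.normal(size=5000)
table = pd.DataFrame(
    {"x": x, "x_proxy": 0.9 * x + 0.436 * rng.normal(size=5000),
     "z": rng.normal(size=5000)}
)
kept, log = covariates.vif_prune(table, threshold=3.0)
print("\nVIF pruning kept:", kept)
print(log.round(2).to_string(index=False))

# ROC cutoff: maximize sensitivity at a capped 5% false-positive rate
scores = np.r_[rng.uniform(0.5, 1.0, 100), rng.uniform(0.0, 0.55, 100)]
labels = np.r_[np.ones(100), np.zeros(100)]
thr = covariates.roc_cutoff(scores, labels, max_fpr=0.05)
print(f"\nROC threshold at 5% FPR: {thr:.3f}")

# Direct metric: the minimum over past sources of distance (km) x
# time-since (days); the minimizer is the most spatiotemporally relevant
# source, not the nearest or the most recent
t0 = pd.Timestamp("2019-06-15 12:00", tz="UTC")
sources = np.array([[10_000.0, 0.0], [1_000.0, 0.0], [2_000.0, 0.0]])
times = pd.DatetimeIndex(
    [t0 - pd.Timedelta(days=d) for d in (0.1, 5.0, 0.4)]
)
m = direct.direct_metric(0.0, 0.0, t0, sources, times)
print(f"\ndirect metric: {m.value:.2f} km*days "
      f"(ln = {m.ln_value:.3f}) from source {m.chosen_source} at "
      f"{m.chosen_distance_km:.1f} km, {m.chosen_dt_days:.1f} days ago")
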