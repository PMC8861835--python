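"""Model coyote use of kill sites with concentric-ring records.

Constructs ring-use records whose truth is a scavenging pulse — use
concentrated in the innermost 100-m ring and peaking on days 3-6 after
the kill — and shows the binomial penalized model recovering that
surface, with the lion-active indicator offered to backwards AIC.
"""

import numpy as np
import pandas as pd

from mesopred import killsites

rng = np.random.default_rng(11)
t0 = pd.Timestamp("2019-06-01", tz="UTC")
no_fixes = pd.DataFrame(
    {"animal_id": [], "species": [], "t": pd.DatetimeIndex([], tz="UTC"),
     "x": [], "y": []}
)

frames = []
for i in range(14):
    kill = pd.Series(
        {"kill_id": f"k{i}", "x": 0.0, "y": 0.0, "t_first": t0,
         "t_last": t0 + pd.Timedelta(days=4.5), "prey_large": True}
    )
    rec = killsites.classify_use(kill, no_fixes, "post")
    p = (0.9 * np.exp(-0.5 * ((rec["day"] - 4.5) / 1.2) ** 2)
         * np.exp(-(rec["ring"] - 1) / 1.2))
    rec["used"] = (rng.uniform(size=len(rec)) < p).astype(int)
    rec["local_count"] = float(rng.integers(5, 30))
    rec["fix_rate"] = 0.9
    frames.append(rec)
records = pd.concat(frames, ignore_index=True)
records["ln_ring_area"] = np.log(records["ring_area_m2"])
records["ln_inv_fix_rate"] = np.log(1.0 / records["fix_rate"])

fit, elimination = killsites.fit_killsite_model(records, "post")
print("term summary:")
print(fit.term_summary().round(3).to_string(index=False))
if len(elimination):
    print("backwards AIC removed:", elimination.to_dict("records"))

day_curve, ring_curve = killsites.predict_use_curves(fit, records, "post")
peak_day = day_curve.loc[day_curve["fit"].idxmax(), "day"]
peak_ring = ring_curve.loc[ring_curve["fit"].idxmax(), "ring_distance_m"]
print(f"\nprobability of use peaks on day {peak_day:.0f} at the "
      f"{peak_ring:.0f}-m ring")
# Day 3-6 and ring 100 m recover the generative scavenging pulse: a
# discovery phase, peak use just after lions leave, then decline.
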