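"""Detect coyote-lion encounters and model pre/post-encounter behaviour.

Encounters are coyote and lion fixes within 1 km and 2 h, merged into
bouts and filtered for 5-h independence.  Movement rate around
encounters is modelled with a gamma GAMM (smooth of time-to-encounter,
cyclic smooth of hour of day, random intercepts for coyote and
encounter).
"""

from mesopred import encounters, pipeline, simulate

scenario = simulate.make_scenario(seed=3, n_coyotes=2, steps_per_coyote=800)

pairs = encounters.detect_encounters(scenario.coyote_fixes, scenario.lion_fixes)
bouts = encounters.merge_bouts(pairs)
independent = encounters.filter_independent(bouts)
print(f"qualifying fix pairs: {len(pairs)}")
print(f"encounter bouts: {len(bouts)}, independent: {len(independent)}")
multi = sum(e.multi_hour for e in independent)
print(f"multi-hour encounters: {100 * multi / len(independent):.1f}%")

result = pipeline.run_encounter_analysis(scenario, seed=3)
fit = result["rate_fit"]
print("\nmovement-rate model EDFs:")
for term, edf in fit.edf_by_term.items():
    print(f"  {term}: {edf:.2f}")
curve = result["rate_curve"]
at_peak = curve.loc[curve["fit"].idxmax()]
print(f"fitted rate peaks {at_peak['fit']:.0f} m/h at "
      f"{at_peak['time_to_encounter']:+.2f} h from the encounter")
# The simulated coyotes do not react to lions, so the curve should be
# nearly flat; on real data a peak just before the encounter indicates
# prey movement driving encounters with an ambush predator.
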