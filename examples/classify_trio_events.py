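"""De novo indel classification and length-stratified rate estimation.

Samples labeled mutation events from known instability-rate curves,
classifies each against its reference flanks (expansion / contraction /
non-motif insertion), and re-estimates the per-length rates with
Poisson confidence intervals.
"""

import numpy as np

from strdyn import (
    ParamSpec,
    build_rate_table,
    classify_indel_event,
    default_empirical_curve,
    default_substitution_rates,
    estimate_length_stratified_rates,
    generate_trio_events,
)

subst = default_substitution_rates()
curve = build_rate_table(
    ParamSpec("multiplier_coupled_power", (4.0, 1.6, 2.0)),
    default_empirical_curve(), 40, subst,
)
denom = np.zeros(41)
denom[1:] = np.floor(3.1e9 * 0.37 * 0.372 ** np.arange(1, 41))

events, truths = generate_trio_events(curve, denom, n_genomes=2000, seed=4)
print(f"sampled {len(events)} de novo indel events")

classified = [classify_indel_event(e) for e in events]
agree = sum(c.category == t.category for c, t in zip(classified, truths))
print(f"classification agrees with generating labels: {agree}/{len(events)}")

rates = estimate_length_stratified_rates(
    [(c.category, c.parent_tract_length) for c in classified],
    {int(L): float(d) for L, d in enumerate(denom) if d > 0},
    n_offspring_genomes=2000, seed=5,
)
print("L   est. expansion rate    true        95% CI")
res = rates["expansion"]
for L, r, lo, hi, n in zip(res["length"], res["rate"], res["ci_lo"],
                           res["ci_hi"], res["count"]):
    if n >= 30:
        print(f"{L:<3} {r:#.3g}   {curve.eps[int(L)]:#.3g}   "
              f"[{lo:#.3g}, {hi:#.3g}]")
# Rates rise steeply with tract length (repeat length instability); the
# estimator recovers the generating curve within its Poisson intervals.
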