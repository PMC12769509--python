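"""Grid-ABC inference of repeat-instability parameters (small demo).

Generates a 'truth' DRL at known parameters, perturbs it into a
36-member primate-like ensemble to calibrate the rejection scale sigma,
then scores a small multiplier-coupled grid by KL divergence and prints
the posterior summary.  The full-size recovery experiment lives in the
acceptance suite.
"""

import numpy as np

from strdyn import (
    DRL,
    InferenceConfig,
    ParamGrid,
    ParamSpec,
    SimConfig,
    build_rate_table,
    canonical_label,
    default_empirical_curve,
    default_substitution_rates,
    evolve,
    generate_primate_ensemble,
    initialize_state,
    kl_divergence,
    posterior,
    primate_sigma,
    uniform_prior,
)

subst = default_substitution_rates()
emp = default_empirical_curve()
init = initialize_state(3.1e9, subst)
cfg = SimConfig(stage_iterations=10_000)


def forward(theta):
    curve = build_rate_table(
        ParamSpec("multiplier_coupled_power", theta), emp, 200, subst
    )
    return evolve(init, subst, curve, cfg).final.a


truth = (4.0, 1.6, 2.0)
truth_counts = forward(truth)
ensemble = generate_primate_ensemble(
    DRL.from_array(canonical_label("A"), truth_counts), n=36, dispersion=0.05,
    seed=7,
)
icfg = InferenceConfig()  # KL over L in [4, 200], pseudocount 1
sigma = primate_sigma(ensemble, truth_counts, icfg)

grid = ParamGrid(
    "multiplier_coupled_power",
    {
        "m": np.array([2.5, 4.0, 6.4]),
        "tau_eps": np.array([1.4, 1.6, 1.8]),
        "tau_kap": np.array([1.8, 2.0, 2.2]),
    },
)
kls = np.array([kl_divergence(forward(p.theta), truth_counts, icfg)
                for p in grid.points()])
pg = posterior(kls, uniform_prior(grid), sigma, grid)

print(f"sigma (ensemble KL scale): {sigma:.2e}")
print(f"truth:          {truth}")
print(f"max posterior:  {tuple(float(v) for v in pg.max_posterior().theta)}")
print(f"mean posterior: {tuple(round(float(v), 3) for v in pg.mean_posterior())}")
# With a tight ensemble the posterior concentrates on the generating
# cell; looser ensembles flatten it along the constant-delta_tau ridge.
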