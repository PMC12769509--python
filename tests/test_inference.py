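"""KL summary statistic, rejection-kernel posterior, Bayes factors, HDRs."""

import numpy as np
import pytest

from strdyn.inference import (
    InferenceConfig,
    bayes_factor,
    bayes_factor_ratio,
    hdr,
    kl_divergence,
    posterior,
    posterior_expectation,
    primate_sigma,
)
from strdyn.rates import ParamGrid


@pytest.fixture
def cfg():
    # two-bin toy setting: compare over [1, 2] without pseudocount noise
    return InferenceConfig(L_min=1, L_max_kl=2, pseudocount=1e-12)


def grid2(nm=3, nt=3):
    return ParamGrid(
        "symmetric_power",
        {"c": np.geomspace(1e-8, 1e-7, nm), "tau": np.linspace(1, 2, nt)},
    )


class TestKL:
    def test_identical_distributions_give_zero(self, cfg):
        assert kl_divergence([0, 3, 1], [0, 3, 1], cfg) == pytest.approx(0, abs=1e-9)

    def test_hand_computed_two_bin_value(self, cfg):
        # D(emp=(.5,.5) || model=(.25,.75)) = .5 ln 2 + .5 ln(2/3)
        d = kl_divergence([0, 25, 75], [0, 50, 50], cfg)
        assert d == pytest.approx(0.5 * np.log(2) + 0.5 * np.log(2 / 3), rel=1e-6)
        assert d == pytest.approx(0.14384, abs=1e-4)

    def test_asymmetry(self, cfg):
        a, b = [0, 25, 75], [0, 50, 50]
        assert kl_divergence(a, b, cfg) != pytest.approx(kl_divergence(b, a, cfg))

    def test_pseudocount_makes_missing_bins_finite(self):
        cfg = InferenceConfig(L_min=4, L_max_kl=50, pseudocount=1.0)
        emp = np.zeros(51)
        emp[4:30] = 100
        model = np.zeros(51)
        model[4:20] = 100  # no support above 20
        assert np.isfinite(kl_divergence(model, emp, cfg))

    def test_conditioning_ignores_low_bins(self):
        cfg = InferenceConfig(L_min=4, L_max_kl=50, pseudocount=1e-9)
        emp = np.zeros(51)
        emp[1] = 10**9  # heavy mass below L_min is irrelevant
        emp[4:10] = 50
        model = np.zeros(51)
        model[4:10] = 500
        assert kl_divergence(model, emp, cfg) == pytest.approx(0, abs=1e-6)


class TestSigma:
    def test_literal_rule_on_ranked_divergences(self, cfg, monkeypatch):
        """36 divergences valued 1..36: drop the top 2, sigma = 34/2."""
        import strdyn.inference as inf

        vals = iter(range(1, 37))
        monkeypatch.setattr(inf, "kl_divergence", lambda m, r, c: next(vals))
        assert inf.primate_sigma(range(36), None, cfg) == pytest.approx(17.0)

    def test_identical_ensemble_gives_zero(self, cfg):
        ref = [0, 30, 70]
        assert primate_sigma([ref] * 10, ref, cfg) == pytest.approx(0.0, abs=1e-9)

    def test_order_invariance(self, cfg):
        rng = np.random.default_rng(1)
        members = [[0, 30 + rng.integers(0, 9), 70] for _ in range(12)]
        s1 = primate_sigma(members, [0, 30, 70], cfg)
        s2 = primate_sigma(members[::-1], [0, 30, 70], cfg)
        assert s1 == pytest.approx(s2)


class TestPosterior:
    def test_point_mass_when_one_theta_fits(self):
        g = grid2()
        kl = np.full(g.n, 10.0)
        kl[4] = 0.0
        pg = posterior(kl, np.full(g.n, 1 / g.n), sigma=1.0, grid=g)
        assert pg.posterior[4] > 0.999
        assert pg.max_posterior().theta == g.points()[4].theta

    def test_normalization(self):
        g = grid2()
        rng = np.random.default_rng(0)
        pg = posterior(rng.random(g.n), np.full(g.n, 1 / g.n), 0.5, g)
        assert pg.posterior.sum() == pytest.approx(1.0)

    def test_doubling_sigma_flattens(self):
        """Posterior entropy never decreases when sigma doubles."""
        g = grid2(4, 4)
        rng = np.random.default_rng(3)
        kl = rng.random(g.n) * 3
        prior = np.full(g.n, 1 / g.n)

        def entropy(p):
            p = p[p > 0]
            return -(p * np.log(p)).sum()

        e1 = entropy(posterior(kl, prior, 0.3, g).posterior)
        e2 = entropy(posterior(kl, prior, 0.6, g).posterior)
        assert e2 >= e1

    def test_underflow_handled_in_log_space(self):
        g = grid2()
        kl = np.full(g.n, 1e4)  # e^{-5e7}: every weight underflows linearly
        pg = posterior(kl, np.full(g.n, 1 / g.n), 1.0, g)
        assert np.isfinite(pg.posterior).all()
        assert pg.posterior.sum() == pytest.approx(1.0)


class TestBayesFactors:
    def test_self_ratio_is_one(self):
        g = grid2()
        kl = np.linspace(0, 2, g.n)
        prior = np.full(g.n, 1 / g.n)
        assert bayes_factor_ratio((kl, prior, 0.5), (kl, prior, 0.5)) == 1.0

    def test_nested_restriction_consistency(self):
        """Restricting a decoupled grid to its symmetric diagonal with the
        same weights reproduces the symmetric model's Bayes factor."""
        taus = np.linspace(1, 2, 3)
        cs = np.geomspace(1e-8, 1e-7, 3)
        gd = ParamGrid(
            "decoupled_power",
            {"c_eps": cs, "c_kap": cs, "tau_eps": taus, "tau_kap": taus},
        )
        rng = np.random.default_rng(5)
        kl_fn = {}
        for p in gd.points():
            kl_fn[p.theta] = rng.random()
        kl_d = np.array([kl_fn[p.theta] for p in gd.points()])
        diag = np.array(
            [p.theta[0] == p.theta[1] and p.theta[2] == p.theta[3]
             for p in gd.points()]
        )
        prior_diag = diag / diag.sum()
        bf_restricted = bayes_factor(kl_d, prior_diag, 0.7)
        gs = grid2(3, 3)
        kl_s = np.array(
            [kl_fn[(p.theta[0], p.theta[0], p.theta[1], p.theta[1])]
             for p in gs.points()]
        )
        bf_sym = bayes_factor(kl_s, np.full(gs.n, 1 / gs.n), 0.7)
        assert bf_restricted == pytest.approx(bf_sym)

    def test_distant_models_vanish(self):
        g = grid2()
        kl = np.full(g.n, 50.0)
        assert bayes_factor(kl, np.full(g.n, 1 / g.n), 1.0) < 1e-300

    def test_sigma_mismatch_rejected(self):
        g = grid2()
        kl = np.zeros(g.n)
        prior = np.full(g.n, 1 / g.n)
        with pytest.raises(ValueError):
            bayes_factor_ratio((kl, prior, 0.5), (kl, prior, 0.6))


class TestHDR:
    def test_point_mass_single_cell(self):
        p = np.zeros(20)
        p[7] = 1.0
        masks = hdr(p)
        for m in masks.values():
            assert m.sum() == 1 and m[7]

    def test_uniform_posterior_cell_count(self):
        n = 40
        p = np.full(n, 1 / n)
        masks = hdr(p, levels=(0.95,))
        assert masks[0.95].sum() == n  # ties at the cut are all included

    def test_nesting(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        p /= p.sum()
        masks = hdr(p)
        assert set(np.flatnonzero(masks[0.68])) <= set(np.flatnonzero(masks[0.95]))
        assert set(np.flatnonzero(masks[0.95])) <= set(np.flatnonzero(masks[0.997]))


class TestExpectation:
    def test_point_mass_returns_f_at_theta(self):
        g = grid2()
        kl = np.full(g.n, 30.0)
        kl[2] = 0.0
        pg = posterior(kl, np.full(g.n, 1 / g.n), 0.5, g)
        val = posterior_expectation(pg, lambda p: np.array(p.theta))
        assert np.allclose(val, g.points()[2].theta, rtol=1e-6)

    def test_unit_function(self):
        g = grid2()
        rng = np.random.default_rng(8)
        pg = posterior(rng.random(g.n), np.full(g.n, 1 / g.n), 0.5, g)
        assert posterior_expectation(pg, lambda p: 1.0) == pytest.approx(1.0)

    def test_two_point_posterior_is_convex_combination(self):
        g = grid2()
        kl = np.full(g.n, 100.0)
        kl[1] = kl[5] = 0.0
        prior = np.full(g.n, 1 / g.n)
        pg = posterior(kl, prior, 1.0, g)
        f = {i: np.array([1.0, 0.0]) if i == 1 else np.array([0.0, 1.0])
             for i in range(g.n)}
        pts = g.points()
        val = posterior_expectation(
            pg, lambda p: f[[q.theta for q in pts].index(p.theta)]
        )
        assert val == pytest.approx([0.5, 0.5], abs=1e-9)
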