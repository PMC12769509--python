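"""Deterministic kernel: transition rules, conservation laws, time
rescaling, boundaries, initialization, and flux decomposition."""

import numpy as np
import pytest

from strdyn.kernel import (
    SaturationError,
    SimConfig,
    SimState,
    _run_stage,
    compute_Lmax,
    evolve,
    flux_decomposition,
    initialize_state,
    kernel_step,
    poisson_step,
)
from strdyn.rates import RateCurve, SubstitutionContextRates


def make_state(LA=60, seed=0, support=25):
    rng = np.random.default_rng(seed)
    a = np.zeros(LA + 1)
    b = np.zeros(LA + 1)
    a[1 : support + 1] = rng.random(support) * 100 + 1
    b[1 : support + 1] = rng.random(support) * 100 + 1
    return SimState(a, b)


def only(**kw):
    base = dict(
        lengthening=0.0, shortening=0.0, fusion=0.0, fission=0.0,
        create_a1=0.0, destroy_a1=0.0, b_insert=0.0, b_delete=0.0,
        b1_delete=0.0,
    )
    base.update(kw)
    return SubstitutionContextRates(**base)


@pytest.fixture
def zcurve():
    z = np.zeros(61)
    return RateCurve(z.copy(), z.copy(), z.copy())


class TestTransitionRules:
    def test_fission_substitution_rule(self, zcurve):
        """A pure fission rate f on a[6]=N removes 4fN from bin 6 and adds
        2fN to each of bins 1..4 (target L-2, pieces uniform)."""
        st = SimState(np.zeros(61), np.zeros(61))
        st.a[6] = 1000.0
        f = 1e-3
        out = kernel_step(st, only(fission=f), zcurve)
        assert out.a[6] == pytest.approx(1000 - 4 * f * 1000)
        assert np.allclose(out.a[1:5], 2 * f * 1000)
        assert out.b[1] == pytest.approx(4 * f * 1000)

    def test_expansion_moves_one_bin_up(self):
        z = np.zeros(61)
        eps = z.copy()
        eps[5] = 1e-3
        curve = RateCurve(eps, z.copy(), z.copy())
        st = SimState(np.zeros(61), np.zeros(61))
        st.a[5] = 100.0
        out = kernel_step(st, only(), curve)
        moved = 1e-3 * 5 * 100
        assert out.a[5] == pytest.approx(100 - moved)
        assert out.a[6] == pytest.approx(moved)

    def test_substitutions_conserve_total_nt(self, zcurve):
        st = make_state()
        subst = SubstitutionContextRates(
            1e-4, 2e-4, 3e-4, 1.5e-4, 1e-4, 2e-4, 0, 0, 0
        )
        out = kernel_step(st, subst, zcurve, check=False)
        assert out.total_nt() == pytest.approx(st.total_nt(), abs=1e-9)

    def test_local_indels_conserve_tract_count(self):
        z = np.zeros(61)
        curve = RateCurve(z + 1e-5, z + 2e-5, z.copy())
        st = make_state()
        out = kernel_step(st, only(), curve, check=False)
        assert out.total_tracts() == pytest.approx(st.total_tracts())

    def test_fission_raises_fusion_lowers_tract_count(self, zcurve):
        st = make_state()
        out = kernel_step(st, only(fission=1e-4), zcurve, check=False)
        n_events = 1e-4 * sum(
            (L - 2) * st.a[L] for L in range(3, 61)
        )
        assert out.total_tracts() - st.total_tracts() == pytest.approx(n_events)
        out = kernel_step(st, only(fusion=1e-4), zcurve, check=False)
        assert st.total_tracts() - out.total_tracts() == pytest.approx(
            1e-4 * st.b[1]
        )

    def test_reflective_boundary_keeps_mass(self):
        z = np.zeros(11)
        eps = z + 1e-3
        curve = RateCurve(eps, z.copy(), z.copy())
        st = SimState(np.zeros(11), np.zeros(11))
        st.a[10] = 50.0  # at the boundary: expansion reflects, stays put
        out = kernel_step(st, only(), curve, check=False)
        assert out.a[10] == pytest.approx(50.0)

    def test_saturation_precondition_enforced(self):
        z = np.zeros(61)
        curve = RateCurve(z + 0.05, z.copy(), z.copy())
        st = make_state()
        with pytest.raises(SaturationError):
            kernel_step(st, only(), curve)  # 0.05 * L > 0.1 for L >= 3


class TestNumbaFastPath:
    def test_single_step_matches_reference(self, subst, inflated_curve):
        st = make_state(40, support=20)
        ref = kernel_step(st, subst, inflated_curve, check=False)
        fast, _tr = _run_stage(st, subst, inflated_curve, 0, 1, False)
        assert np.allclose(ref.a, fast.a, rtol=1e-12, atol=1e-9)
        assert np.allclose(ref.b, fast.b, rtol=1e-12, atol=1e-9)

    def test_many_steps_match_reference(self, inflated_subst, inflated_curve):
        st = make_state(40, support=20)
        cur = st
        for _ in range(30):
            cur = kernel_step(cur, inflated_subst, inflated_curve, check=False)
        fast, _tr = _run_stage(st, inflated_subst, inflated_curve, 0, 30, False)
        assert np.allclose(cur.a[1:], fast.a[1:], rtol=1e-9)
        assert np.allclose(cur.b[1:], fast.b[1:], rtol=1e-9)


class TestPoisson:
    def test_zero_rates_identity(self, zcurve):
        st = make_state()
        rng = np.random.default_rng(0)
        out = poisson_step(st, only(), zcurve, rng)
        assert np.array_equal(out.a, st.a)
        assert np.array_equal(out.b, st.b)

    def test_mean_matches_deterministic(self, zcurve):
        """Replicate-mean of Poisson steps matches the deterministic
        expectation within 4 sigma of the sampled fluxes."""
        st = make_state(30, support=15)
        subst = only(fission=2e-3, shortening=1e-3)
        det = kernel_step(st, subst, zcurve, check=False)
        rng = np.random.default_rng(42)
        n = 3000
        acc = np.zeros_like(st.a)
        for _ in range(n):
            acc += poisson_step(st, subst, zcurve, rng, check=False).a
        mean = acc / n
        # per-bin flux scale bounds the Poisson variance contribution
        flux = np.abs(det.a - st.a) + 1e-3
        sd = np.sqrt(flux / n) * 4
        assert np.all(np.abs(mean - det.a) < 4 * np.sqrt((st.a + 1) / n) + sd)

    def test_seeded_reproducibility(self, inflated_subst, inflated_curve):
        st = make_state(40, support=20)
        a = poisson_step(st, inflated_subst, inflated_curve,
                         np.random.default_rng(7), check=False)
        b = poisson_step(st, inflated_subst, inflated_curve,
                         np.random.default_rng(7), check=False)
        assert np.array_equal(a.a, b.a)


class TestLmaxAndSchedule:
    def test_lmax_first_exceedance(self):
        # constant per-tract probability 0.002 * L: crosses 0.1 at L = 51
        z = np.zeros(201)
        curve = RateCurve(z + 1e-3, z + 1e-3, z.copy())
        Lmax = compute_Lmax(curve, only(), 0)
        assert Lmax == 51

    def test_lmax_unbounded_marker(self):
        z = np.zeros(201)
        curve = RateCurve(z + 1e-7, z.copy(), z.copy())
        assert compute_Lmax(curve, only(), 0) is None

    def test_lmax_monotone_in_r(self, subst, empirical):
        from strdyn.rates import ParamSpec, build_rate_table

        curve = build_rate_table(
            ParamSpec("multiplier_coupled_power", (4.0, 1.6, 2.0)), empirical, 200
        )
        vals = [compute_Lmax(curve, subst, r) or 10**9 for r in (0, 1, 2, 3, 4)]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_fast_path_total_generations(self, two_way_subst):
        z = np.zeros(201)
        curve = RateCurve(z.copy(), z.copy(), z.copy())
        st = initialize_state(1e6, two_way_subst, pre_run=False)
        traj = evolve(st, two_way_subst, curve,
                      SimConfig(total_generations=1e9))
        r, iters, _, _ = traj.stages[0]
        assert iters * 10.0**r == pytest.approx(1e9)
        assert traj.final.generation == pytest.approx(1e9)

    def test_staged_schedule_decreasing_r(self, subst, empirical):
        from strdyn.rates import ParamSpec, build_rate_table

        curve = build_rate_table(
            ParamSpec("multiplier_coupled_power", (4.0, 1.0, 2.5)), empirical, 200
        )
        st = initialize_state(3.1e9, subst, pre_run=False)
        traj = evolve(st, subst, curve, SimConfig(stage_iterations=2000))
        rs = [s[0] for s in traj.stages]
        assert rs == sorted(rs, reverse=True)
        bounds = [s[2] for s in traj.stages]
        assert bounds == sorted(bounds)  # L_bound grows as r drops


class TestInitialization:
    def test_two_way_pre_run_is_geometric(self, two_way_subst):
        """After the substitution-only pre-run the DRL matches the
        analytic geometric expectation to 0.1% for L <= 10."""
        st = initialize_state(1e7, two_way_subst, 80, 80)
        pa = two_way_subst.p_a
        L = np.arange(81.0)
        expect = 1e7 * (1 - pa) ** 2 * pa**L
        rel = st.a[1:11] / expect[1:11] - 1
        assert np.abs(rel).max() < 1e-3

    def test_linearity_in_genome_size(self, two_way_subst):
        s1 = initialize_state(1e6, two_way_subst, 60, 60)
        s2 = initialize_state(2e6, two_way_subst, 60, 60)
        assert np.allclose(s2.a[1:40], 2 * s1.a[1:40], rtol=1e-9)

    def test_initializers_converge_to_same_late_state(self, subst, empirical):
        """Two diverged initial conditions give late-time DRLs differing
        by < 1% in every well-populated bin."""
        from strdyn.rates import ParamSpec, build_rate_table

        curve = build_rate_table(
            ParamSpec("multiplier_coupled_power", (4.0, 1.6, 2.0)), empirical, 200
        )
        cfg = SimConfig(stage_iterations=30000)
        t1 = evolve(initialize_state(3.1e9, subst), subst, curve, cfg)
        t2 = evolve(
            initialize_state(3.1e9, subst, mode="uniform"), subst, curve, cfg
        )
        a1, a2 = t1.final.a, t2.final.a
        p1, p2 = a1 / a1[1:].sum(), a2 / a2[1:].sum()
        mask = (a1 >= 1) & (a2 >= 1)
        assert np.abs(p1[mask] / p2[mask] - 1).max() < 0.01


class TestFluxDecomposition:
    def test_expansion_flux_localized(self):
        z = np.zeros(61)
        eps = z.copy()
        eps[5] = 1e-3
        curve = RateCurve(eps, z.copy(), z.copy())
        st = SimState(np.zeros(61), np.zeros(61))
        st.a[5] = 100.0
        ft = flux_decomposition(st, only(), curve)
        fin, fout = ft.raw("local_indel")
        assert fout[5] > 0 and fin[6] == pytest.approx(fout[5])
        assert fin[5] == 0 and fout[6] == 0

    def test_normalized_fluxes_sum_to_one(self, inflated_subst, inflated_curve):
        st = make_state(40, support=20)
        ft = flux_decomposition(st, inflated_subst, inflated_curve)
        norm = ft.normalized()
        tot_in = sum(v[0] for v in norm.values())
        tot_out = sum(v[1] for v in norm.values())
        raw_in = sum(v[0] for v in ft.processes.values())
        raw_out = sum(v[1] for v in ft.processes.values())
        assert np.allclose(tot_in[raw_in > 0], 1.0)
        assert np.allclose(tot_out[raw_out > 0], 1.0)

    def test_net_flux_equals_step_delta(self, inflated_subst, inflated_curve):
        st = make_state(40, support=20)
        st.r = 0
        ft = flux_decomposition(st, inflated_subst, inflated_curve)
        stepped = kernel_step(st, inflated_subst, inflated_curve, check=False)
        assert np.allclose(ft.net()[1:], (stepped.a - st.a)[1:], atol=1e-12)
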