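"""Particle engine: motion, boundaries, reaction sweeps, conservation laws."""

import numpy as np
import pytest

from clusterbind.engine import (
    FPTRecord,
    KineticParams,
    SimConfig,
    SimState,
    ZoneIndex,
    apply_boundaries,
    attempt_binding,
    attempt_unbinding,
    brownian_step,
    record_first_passage,
    run_simulation,
)
from clusterbind.layouts import Geometry, LayoutSpec, build_layout


def _unit_layout(L=8.0, H=8.0, r0=4, n=1, kind="homogeneous", **kw):
    geom = Geometry(L, H, 1.0)
    return build_layout(LayoutSpec(r0=r0, n=n, kind=kind, **kw), geom)


def _state(xy, r0, bound_to=None):
    xy = np.asarray(xy, dtype=float)
    l_total = len(xy)
    s = SimState(
        x=xy[:, 0].copy(),
        y=xy[:, 1].copy(),
        bound_to=np.full(l_total, -1, dtype=np.int64) if bound_to is None else np.asarray(bound_to),
        receptor_occupied=np.zeros(r0, dtype=bool),
    )
    for lig, r in enumerate(s.bound_to):
        if r >= 0:
            s.receptor_occupied[r] = True
    return s


class TestBoundaries:
    def test_periodic_wrap(self):
        geom = Geometry(10.0, 5.0, 1.0)
        x, y = apply_boundaries(np.array([10.3]), np.array([2.0]), geom)
        assert x[0] == pytest.approx(0.3)

    def test_mirror_at_membrane_and_ceiling(self):
        geom = Geometry(10.0, 5.0, 1.0)
        x, y = apply_boundaries(np.array([1.0, 1.0]), np.array([-0.2, 5.1]), geom)
        assert y[0] == pytest.approx(0.2)
        assert y[1] == pytest.approx(4.9)

    def test_composed_reflections_stay_inside(self):
        geom = Geometry(10.0, 5.0, 1.0)
        rng = np.random.default_rng(0)
        x = rng.uniform(-10, 20, 1000)
        y = rng.uniform(-5.0, 10.0, 1000)
        xo, yo = apply_boundaries(x, y, geom)
        assert np.all((xo >= 0) & (xo < 10.0))
        assert np.all((yo >= 0) & (yo <= 5.0))

    def test_oversized_vertical_step_rejected(self):
        geom = Geometry(10.0, 5.0, 1.0)
        with pytest.raises(ValueError, match="dt"):
            apply_boundaries(np.array([1.0]), np.array([11.0]), geom)


class TestBrownianStep:
    def test_zero_diffusion_is_identity(self):
        lay = _unit_layout()
        st = _state([[1.0, 2.0], [3.0, 4.0]], r0=4)
        cfg = SimConfig(l_total=2, n_steps=1, D=0.0)
        before = (st.x.copy(), st.y.copy())
        brownian_step(st, cfg, lay.geometry, np.random.default_rng(0))
        np.testing.assert_array_equal(st.x, before[0])
        np.testing.assert_array_equal(st.y, before[1])

    def test_displacement_variance_matches_2Ddt(self):
        geom = Geometry(1e6, 1e6, 1.0)  # huge box: boundaries never touched
        lay = build_layout(LayoutSpec(r0=1, n=1, kind="homogeneous"), geom)
        n = 100_000
        st = _state(np.full((n, 2), 5e5), r0=1)
        cfg = SimConfig(l_total=n, n_steps=1, D=1.0, dt=1e-2)
        brownian_step(st, cfg, geom, np.random.default_rng(1))
        var = np.var(st.x - 5e5)
        expected = 2 * cfg.D * cfg.dt
        se = expected * np.sqrt(2.0 / n)
        assert abs(var - expected) < 3 * se

    def test_bound_ligand_does_not_move(self):
        lay = _unit_layout()
        st = _state([[1.0, 2.0]], r0=4, bound_to=[2])
        brownian_step(st, SimConfig(l_total=1, n_steps=1, D=5.0), lay.geometry, np.random.default_rng(2))
        assert (st.x[0], st.y[0]) == (1.0, 2.0)


class TestUnbinding:
    def test_certain_unbinding_releases_at_zone_top_center(self):
        geom = Geometry(10.0, 8.0, 1.0)
        lay = build_layout(LayoutSpec(r0=2, n=1, kind="homogeneous"), geom)
        # receptor 0 zone is [2, 3] x [0, 1]
        assert (lay.zone_lo[0], lay.zone_hi[0]) == (2.0, 3.0)
        st = _state([[2.2, 0.0]], r0=2, bound_to=[0])
        kin = KineticParams(p_bind=1.0, p_unbind=1.0)
        cfg = SimConfig(l_total=1, n_steps=1, reinjection_mode="edge")
        attempt_unbinding(st, kin, lay, cfg, np.random.default_rng(0))
        assert (st.x[0], st.y[0]) == (2.5, 1.0)
        assert st.bound_to[0] == -1 and not st.receptor_occupied.any()

    def test_zero_unbinding_is_absorbing(self):
        lay = _unit_layout()
        st = _state([[2.5, 0.5]], r0=4, bound_to=[1])
        kin = KineticParams(p_bind=1.0, p_unbind=0.0)
        cfg = SimConfig(l_total=1, n_steps=1)
        attempt_unbinding(st, kin, lay, cfg, np.random.default_rng(0))
        assert st.bound_to[0] == 1

    def test_unbinding_fraction_binomial(self):
        n = 10_000
        geom = Geometry(float(n), 8.0, 1.0)
        lay = build_layout(LayoutSpec(r0=n, n=1, kind="homogeneous"), geom)
        st = _state(np.zeros((n, 2)), r0=n, bound_to=np.arange(n))
        kin = KineticParams(p_bind=1.0, p_unbind=0.1)
        attempt_unbinding(st, kin, lay, SimConfig(l_total=n, n_steps=1), np.random.default_rng(3))
        frac = np.mean(st.bound_to == -1)
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.1) < 3 * se

    def test_random_bulk_relocates_anywhere(self):
        geom = Geometry(100.0, 50.0, 1.0)
        lay = build_layout(LayoutSpec(r0=10, n=1, kind="homogeneous"), geom)
        n = 2000
        st = _state(np.zeros((n, 2)), r0=10, bound_to=np.zeros(n, dtype=np.int64))
        st.bound_to[:] = np.arange(n) % 10
        kin = KineticParams(p_bind=1.0, p_unbind=1.0)
        cfg = SimConfig(l_total=n, n_steps=1, reinjection_mode="random_bulk")
        attempt_unbinding(st, kin, lay, cfg, np.random.default_rng(4))
        assert st.y.mean() == pytest.approx(25.0, rel=0.1)  # uniform in height


class TestBinding:
    def test_certain_binding_inside_free_zone(self):
        lay = _unit_layout()
        st = _state([[1.0, 0.5]], r0=4)  # inside receptor 0 zone [0.5, 1.5]
        kin = KineticParams(p_bind=1.0, p_unbind=0.1)
        attempt_binding(st, kin, lay, np.random.default_rng(0))
        assert st.bound_to[0] == 0 and st.c == 1

    def test_ligand_outside_zones_never_binds(self):
        lay = _unit_layout(L=16.0, r0=4)  # zones at 1.5..2.5, 5.5..6.5, ...
        st = _state([[4.0, 0.5], [1.0, 3.0]], r0=4)
        kin = KineticParams(p_bind=1.0, p_unbind=0.1)
        attempt_binding(st, kin, lay, np.random.default_rng(0))
        assert st.c == 0

    def test_competition_for_one_receptor_is_exclusive_and_fair(self):
        geom = Geometry(4.0, 4.0, 1.0)
        lay = build_layout(LayoutSpec(r0=1, n=1, kind="homogeneous"), geom)
        kin = KineticParams(p_bind=1.0, p_unbind=0.1)
        wins = np.zeros(2)
        rng = np.random.default_rng(5)
        trials = 4000
        for _ in range(trials):
            st = _state([[2.0, 0.5], [2.1, 0.4]], r0=1)
            attempt_binding(st, kin, lay, rng)
            assert st.c == 1  # exclusion: a receptor takes at most one ligand
            wins[int(st.bound_to[1] == 0)] += 1
        se = np.sqrt(0.25 / trials)
        assert abs(wins[0] / trials - 0.5) < 3 * se

    def test_occupied_receptor_unavailable(self):
        lay = _unit_layout()
        st = _state([[1.0, 0.5]], r0=4)
        st.receptor_occupied[0] = True
        kin = KineticParams(p_bind=1.0, p_unbind=0.1)
        attempt_binding(st, kin, lay, np.random.default_rng(0))
        assert st.bound_to[0] == -1


class TestRunSimulation:
    def test_no_ligand_flatline(self):
        lay = _unit_layout()
        res = run_simulation(lay, KineticParams(0.5, 0.5), SimConfig(l_total=0, n_steps=50))
        assert np.all(res.c == 0)

    def test_conservation_and_bijection(self):
        lay = _unit_layout(L=20.0, H=5.0, r0=4, n=2, kind="contiguous")
        res = run_simulation(
            lay, KineticParams(0.5, 0.2), SimConfig(l_total=30, n_steps=200, seed=6)
        )
        st = res.state
        assert np.count_nonzero(st.bound_to >= 0) == st.receptor_occupied.sum() == res.c[-1]
        bound = st.bound_to[st.bound_to >= 0]
        assert len(np.unique(bound)) == len(bound)  # one ligand per receptor
        assert len(st.x) == 30

    def test_trajectory_deterministic_in_seed(self):
        lay = _unit_layout(L=20.0, H=5.0, r0=4)
        kin = KineticParams(0.5, 0.2)
        a = run_simulation(lay, kin, SimConfig(l_total=25, n_steps=150, seed=9))
        b = run_simulation(lay, kin, SimConfig(l_total=25, n_steps=150, seed=9))
        np.testing.assert_array_equal(a.c, b.c)
        c = run_simulation(lay, kin, SimConfig(l_total=25, n_steps=150, seed=10))
        assert not np.array_equal(a.c, c.c)

    def test_flux_balance_at_equilibrium(self):
        lay = _unit_layout(L=50.0, H=2.0, r0=10)
        kin = KineticParams(0.1, 0.1)
        res = run_simulation(
            lay, kin, SimConfig(l_total=100, n_steps=4000, seed=12), record_events=True
        )
        c_bar = res.c[-2000:].mean()
        bind_rate = res.bind_events[-2000:].mean()
        unbind_rate = res.unbind_events[-2000:].mean()
        expected = kin.p_unbind * c_bar
        assert bind_rate == pytest.approx(expected, rel=0.1)
        assert unbind_rate == pytest.approx(expected, rel=0.1)


class TestNumpyFallback:
    def test_fallback_loop_conserves_and_is_deterministic(self, monkeypatch):
        """The vectorized numpy step loop upholds the same contracts as the kernel."""
        import clusterbind.engine as eng

        monkeypatch.setattr(eng, "_HAVE_NUMBA", False)
        lay = _unit_layout(L=20.0, H=5.0, r0=4, n=2, kind="contiguous")
        kin = KineticParams(0.5, 0.2)
        a = run_simulation(lay, kin, SimConfig(l_total=30, n_steps=200, seed=5))
        b = run_simulation(lay, kin, SimConfig(l_total=30, n_steps=200, seed=5))
        np.testing.assert_array_equal(a.c, b.c)
        st = a.state
        assert np.count_nonzero(st.bound_to >= 0) == st.receptor_occupied.sum() == a.c[-1]


class TestMarkovOracle:
    """Closed unit box = one always-in-zone ligand: exact two-state chain."""

    @staticmethod
    def _stationary_bound_fraction(p1, pm1):
        # brute force: power-iterate the 2x2 per-step transition matrix
        P = np.array([[1 - p1, p1], [pm1, 1 - pm1]])
        pi = np.array([1.0, 0.0])
        for _ in range(10_000):
            pi = pi @ P
        return pi[1]

    def test_bound_fraction_matches_chain(self):
        geom = Geometry(1.0, 1.0, 1.0)
        lay = build_layout(LayoutSpec(r0=1, n=1, kind="homogeneous"), geom)
        p1, pm1 = 0.05, 0.1
        kin = KineticParams(p1, pm1)
        n_steps = 60_000
        res = run_simulation(lay, kin, SimConfig(l_total=1, n_steps=n_steps, seed=21))
        burn = 2000
        frac = (res.c[burn:] > 0).mean()
        target = self._stationary_bound_fraction(p1, pm1)
        assert target == pytest.approx(p1 / (p1 + pm1), abs=1e-9)
        # 3 SE with an autocorrelation-aware effective sample size
        tau = 1.0 / p1 + 1.0 / pm1
        se = np.sqrt(target * (1 - target) / ((n_steps - burn) / tau))
        assert abs(frac - target) < 3 * se


class TestFirstPassage:
    def test_start_inside_zone_counts_zero(self):
        geom = Geometry(2.0, 2.0, 1.0)
        lay = build_layout(LayoutSpec(r0=2, n=1, kind="homogeneous"), geom)
        # zones cover the whole membrane: anything with y <= b is inside
        rec = record_first_passage(lay, SimConfig(l_total=0, n_steps=0, seed=3), 500, max_steps=200)
        assert np.any(rec.passage_times == 0)
        assert rec.n_total == 500

    def test_mfpt_grows_with_box_height(self):
        means = []
        for H in (5.0, 10.0, 20.0):
            geom = Geometry(4.0, H, 1.0)
            lay = build_layout(LayoutSpec(r0=4, n=1, kind="homogeneous"), geom)
            rec = record_first_passage(
                lay, SimConfig(l_total=0, n_steps=0, seed=7), 600, max_steps=60_000
            )
            assert rec.n_censored < 60
            means.append(rec.mfpt_estimate)
        assert means[0] < means[1] < means[2]

    def test_all_censored_when_zones_unreachable(self):
        geom = Geometry(100.0, 50.0, 1.0)
        lay = build_layout(LayoutSpec(r0=1, n=1, kind="homogeneous"), geom)
        cfg = SimConfig(l_total=0, n_steps=0, seed=8, D=0.0)
        rec = record_first_passage(lay, cfg, 50, max_steps=100)
        # frozen particles that did not start inside never arrive
        assert rec.n_censored + np.count_nonzero(rec.passage_times == 0) == 50


class TestZoneIndex:
    def test_disjoint_detection(self):
        assert ZoneIndex(_unit_layout()).disjoint
        assert ZoneIndex(_unit_layout(r0=4, n=2, kind="contiguous")).disjoint
        assert not ZoneIndex(_unit_layout(r0=4, n=2, kind="overstacked")).disjoint

    def test_overstacked_segment_lists_whole_cluster(self):
        lay = _unit_layout(L=16.0, r0=4, n=2, kind="overstacked")
        zidx = ZoneIndex(lay)
        seg = zidx.segment_of(np.array([lay.positions[0]]))
        members = zidx.receptors[zidx.ptr[seg[0]] : zidx.ptr[seg[0] + 1]]
        assert set(members) == {0, 1}

    def test_in_any_zone_respects_height(self):
        lay = _unit_layout()
        zidx = ZoneIndex(lay)
        assert zidx.in_any_zone(np.array([0.7]), np.array([0.5]))[0]
        assert not zidx.in_any_zone(np.array([0.7]), np.array([1.5]))[0]
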