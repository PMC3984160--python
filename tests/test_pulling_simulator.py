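"""Monte Carlo pulling: Bell kinetics, force balance, and ensemble behavior."""

import numpy as np
import pytest
from scipy.stats import kstest

from polypull import (
    PullingProtocol,
    TandemConstruct,
    TwoStateKinetics,
    bell_rate,
    equilibrium_force,
    fit_landscape_mc,
    mean_force_vs_speed,
    simulate_ensemble,
    simulate_pull,
    wlc_force,
    WLCParams,
)
from polypull.pulling_simulator import SimulationError


class TestBellRate:
    def test_zero_force_gives_spontaneous_rate(self):
        kin = TwoStateKinetics(1e-3, 0.5)
        assert bell_rate(0.0, kin) == pytest.approx(1e-3)

    @pytest.mark.parametrize(
        "force, dx, k0, expected",
        [
            (91.0, 0.55, 1.05e-3, 2.0e2),  # apo at its mean rupture force
            (125.0, 0.38, 2.35e-3, 2.4e2),  # holo at its mean rupture force
        ],
    )
    def test_reference_rates(self, force, dx, k0, expected, thermal):
        rate = bell_rate(force, TwoStateKinetics(k0, dx), thermal)
        manual = k0 * np.exp(force * dx / thermal.kT)
        assert rate == pytest.approx(manual, rel=1e-12)
        assert rate == pytest.approx(expected, rel=0.05)

    def test_overflow_capped(self):
        kin = TwoStateKinetics(1.0, 10.0)
        assert np.isfinite(bell_rate(1e6, kin))

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            bell_rate(-1.0, TwoStateKinetics(1e-3, 0.5))


class TestEquilibriumForce:
    def test_zero_base(self, octamer, protocol_1000):
        assert equilibrium_force(0.0, 29.1, octamer, protocol_1000) == (0.0, 0.0)

    def test_rigid_cantilever_limit(self, octamer, thermal):
        from dataclasses import replace

        stiff = PullingProtocol(speed=1000.0, cantilever_k=1e9)
        f, x = equilibrium_force(20.0, 29.1, octamer, stiff, thermal)
        expected = wlc_force(20.0, WLCParams(0.4, 29.1), thermal)
        assert f == pytest.approx(expected, rel=1e-4)
        assert x == pytest.approx(20.0, abs=1e-4)

        rigid = replace(stiff, compliant_cantilever=False)
        f2, x2 = equilibrium_force(20.0, 29.1, octamer, rigid, thermal)
        assert f2 == pytest.approx(expected, rel=1e-12)

    def test_against_bisection_oracle(self, octamer, protocol_1000, thermal):
        """Independent interval-halving solve of base = x + F(x)/k_c."""
        params = WLCParams(0.4, 29.1)
        lo, hi = 0.0, 29.1 * (1 - 1e-12)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mid + wlc_force(mid, params, thermal) / 40.0 < 20.0:
                lo = mid
            else:
                hi = mid
        f_oracle = wlc_force(lo, params, thermal)
        f, x = equilibrium_force(20.0, 29.1, octamer, protocol_1000, thermal)
        assert f == pytest.approx(f_oracle, rel=1e-9)
        assert x == pytest.approx(lo, rel=1e-9)


class TestSimulatePull:
    def test_frozen_kinetics_aborts_at_force_cap(self, octamer):
        protocol = PullingProtocol(speed=1000.0, max_force=500.0)
        trace = simulate_pull(octamer, TwoStateKinetics(1e-30, 0.55), protocol, rng_seed=0)
        assert trace.aborted
        assert len(trace.rupture_events) == 0
        # the ramp is a single WLC stretch: force never decreases
        assert np.all(np.diff(trace.force) >= -1e-9)

    def test_barrierless_limit_unfolds_at_low_force(self, octamer):
        protocol = PullingProtocol(speed=1000.0)
        trace = simulate_pull(octamer, TwoStateKinetics(1e6, 0.55), protocol, rng_seed=1)
        assert len(trace.rupture_events) == octamer.n_domains
        assert all(ev.force < 10.0 for ev in trace.rupture_events)

    def test_event_ladder_conservation(self, octamer, apo, protocol_1000):
        trace = simulate_pull(octamer, apo, protocol_1000, rng_seed=7)
        events = trace.rupture_events
        assert len(events) == octamer.n_domains
        assert [ev.peak_index for ev in events] == list(range(1, 9))
        assert not trace.aborted
        # folded count never increases; drops by exactly one per event
        assert np.all(np.diff(trace.n_folded) <= 0)
        assert trace.n_folded[0] == octamer.n_domains
        assert trace.n_folded[-1] == 0

    def test_force_drops_at_each_rupture(self, octamer, apo, protocol_1000):
        trace = simulate_pull(octamer, apo, protocol_1000, rng_seed=7)
        drops = np.flatnonzero(np.diff(trace.n_folded) < 0)
        for i in drops:
            assert trace.force[i + 1] < trace.force[i]

    def test_seed_determinism(self, octamer, apo, protocol_1000):
        t1 = simulate_pull(octamer, apo, protocol_1000, rng_seed=42)
        t2 = simulate_pull(octamer, apo, protocol_1000, rng_seed=42)
        assert [(e.force, e.time) for e in t1.rupture_events] == [
            (e.force, e.time) for e in t2.rupture_events
        ]
        assert np.array_equal(t1.force, t2.force)


class TestEnsemble:
    def test_event_count_conservation(self, octamer, apo, protocol_1000):
        res = simulate_ensemble(octamer, apo, protocol_1000, n_traces=1, rng_seed=3)
        assert res.datum.n_events == 8
        assert np.sum(res.histogram[0]) == 8

    def test_histogram_determinism(self, octamer, apo, protocol_1000):
        r1 = simulate_ensemble(octamer, apo, protocol_1000, n_traces=20, rng_seed=9)
        r2 = simulate_ensemble(octamer, apo, protocol_1000, n_traces=20, rng_seed=9)
        assert np.array_equal(r1.forces, r2.forces)

    def test_rupture_distribution_matches_constant_loading_oracle(self, thermal):
        """Single domain on a rigid tether loaded through the cantilever at
        nu = k_c * v: survival is S(F) = exp(-(k0*kT)/(nu*dx) * (e^{F dx/kT}-1)).
        """
        kin = TwoStateKinetics(1.05e-3, 0.55)
        construct = TandemConstruct(
            n_domains=1, delta_Lc=29.1, initial_Lc=0.0, persistence_length=0.4
        )
        protocol = PullingProtocol(speed=40.0, cantilever_k=1000.0, max_pu=0.02)
        nu = protocol.loading_rate
        assert nu == pytest.approx(40000.0)
        res = simulate_ensemble(construct, kin, protocol, n_traces=2000, rng_seed=11)

        scale = kin.k_u0 * thermal.kT / (nu * kin.dx_u)

        def cdf(F):
            return 1.0 - np.exp(-scale * (np.exp(np.asarray(F) * kin.dx_u / thermal.kT) - 1.0))

        stat, _ = kstest(res.forces, cdf)
        assert stat < 0.05

    def test_loading_rate_slope_in_stiff_single_domain_limit(self, thermal):
        """Mean force grows ~ (kT/dx) per e-fold of loading rate."""
        kin = TwoStateKinetics(1.05e-3, 0.55)
        construct = TandemConstruct(1, 29.1, 0.0, 0.4)
        means = []
        for speed in (10.0, 100.0, 1000.0):
            protocol = PullingProtocol(speed=speed, cantilever_k=1000.0)
            res = simulate_ensemble(construct, kin, protocol, n_traces=400, rng_seed=21)
            means.append(res.datum.mean_force)
        slope = (means[2] - means[0]) / np.log(100.0)
        assert slope == pytest.approx(thermal.kT / kin.dx_u, rel=0.3)


class TestSpeedDependence:
    def test_mean_force_increases_with_speed(self, apo_speed_series):
        means = [d.mean_force for d in apo_speed_series]
        assert means == sorted(means)

    def test_holo_exceeds_apo_at_every_speed(self, apo_speed_series, holo_speed_series):
        for a, h in zip(apo_speed_series, holo_speed_series):
            assert h.mean_force > a.mean_force

    def test_sem_scales_with_sqrt_n(self, octamer, apo, protocol_1000):
        r1 = simulate_ensemble(octamer, apo, protocol_1000, n_traces=100, rng_seed=31)
        r2 = simulate_ensemble(octamer, apo, protocol_1000, n_traces=200, rng_seed=31)
        sem1 = r1.datum.sd_force / np.sqrt(r1.datum.n_events)
        sem2 = r2.datum.sd_force / np.sqrt(r2.datum.n_events)
        assert sem2 / sem1 == pytest.approx(1 / np.sqrt(2), rel=0.2)


class TestLandscapeGridFit:
    def test_recovers_truth(self, octamer, protocol_1000):
        truth = TwoStateKinetics(1.05e-3, 0.55)
        observed = mean_force_vs_speed(
            octamer, truth, protocol_1000, [200.0, 1000.0, 4000.0],
            n_traces=60, rng_seed=41,
        )
        best, obj, boundary = fit_landscape_mc(
            observed, octamer, protocol_1000,
            k_u0_grid=np.logspace(-5, -1, 5),
            dx_u_grid=np.array([0.45, 0.50, 0.55, 0.60, 0.65]),
            n_traces=25, rng_seed=43,
        )
        assert best.dx_u == pytest.approx(0.55, abs=0.05)
        assert 1.05e-4 < best.k_u0 < 1.05e-2  # within one decade
        assert not boundary

    def test_grid_missing_truth_flags_boundary(self, octamer, protocol_1000):
        truth = TwoStateKinetics(1.05e-3, 0.55)
        observed = mean_force_vs_speed(
            octamer, truth, protocol_1000, [200.0, 1000.0, 4000.0],
            n_traces=30, rng_seed=47,
        )
        _, _, boundary = fit_landscape_mc(
            observed, octamer, protocol_1000,
            k_u0_grid=np.array([1e-3]),
            dx_u_grid=np.array([0.2, 0.25]),
            n_traces=15, rng_seed=48,
        )
        assert boundary

    def test_too_few_speeds_rejected(self, octamer, protocol_1000, apo_speed_series):
        with pytest.raises(ValueError):
            fit_landscape_mc(apo_speed_series[:2], octamer, protocol_1000)


class TestValidation:
    def test_invalid_types_rejected(self):
        with pytest.raises(ValueError):
            TwoStateKinetics(0.0, 0.5)
        with pytest.raises(ValueError):
            TandemConstruct(n_domains=0)
        with pytest.raises(ValueError):
            PullingProtocol(speed=-1.0)

    def test_ensemble_aborts_propagate(self, octamer):
        protocol = PullingProtocol(speed=1000.0, max_force=300.0)
        with pytest.raises(SimulationError):
            simulate_ensemble(octamer, TwoStateKinetics(1e-30, 0.55), protocol, n_traces=2)
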