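"""Shape-index analysis, peeling, localization and conductance fitting."""

import numpy as np
import pytest

from humanl23.cable import Trace, simulate
from humanl23.epsp import (
    EPSPAnalysisError,
    ShapeIndex,
    build_shape_index_curve,
    fit_connection,
    peel_time_constant,
    putative_locations,
    shape_index,
)
from humanl23.synapses import AMPA_DEFAULT, SynapticEvent
from humanl23.synthetic import generate_pair_epsp


def double_exp_trace(tau_d=20.0, tau_r=1.0, dt=0.002, duration=120.0,
                     scale=1.0):
    t = np.arange(0.0, duration, dt)
    return Trace(t=t, v=scale * (np.exp(-t / tau_d) - np.exp(-t / tau_r)))


class TestShapeIndex:
    def test_matches_dense_grid_measurement(self):
        """Rise time and half-width of exp(−t/20) − exp(−t/1) agree with a
        brute-force dense-grid measurement to 1e-3 ms."""
        si = shape_index(double_exp_trace(dt=0.002))
        # dense-grid oracle on a 0.0001 ms grid
        t = np.arange(0.0, 120.0, 1e-4)
        v = np.exp(-t / 20.0) - np.exp(-t / 1.0)
        peak = v.max()
        rising = v[: np.argmax(v) + 1]
        tr = t[: np.argmax(v) + 1]
        t10 = tr[np.searchsorted(rising, 0.1 * peak)]
        t90 = tr[np.searchsorted(rising, 0.9 * peak)]
        above = t[v >= 0.5 * peak]
        assert si.rise_time == pytest.approx(t90 - t10, abs=1e-3)
        assert si.half_width == pytest.approx(above[-1] - above[0], abs=1e-3)

    def test_amplitude_invariance(self):
        a = shape_index(double_exp_trace(scale=1.0))
        b = shape_index(double_exp_trace(scale=7.3))
        assert a.rise_time == pytest.approx(b.rise_time, rel=1e-9)
        assert a.half_width == pytest.approx(b.half_width, rel=1e-9)

    def test_time_dilation_doubles_both_indices(self):
        a = shape_index(double_exp_trace(tau_d=20.0, tau_r=1.0))
        b = shape_index(double_exp_trace(tau_d=40.0, tau_r=2.0))
        assert b.rise_time == pytest.approx(2 * a.rise_time, rel=1e-3)
        assert b.half_width == pytest.approx(2 * a.half_width, rel=1e-3)

    def test_flat_trace_rejected(self):
        with pytest.raises(EPSPAnalysisError):
            shape_index(Trace(t=np.arange(0, 10, 0.1), v=np.zeros(100)))


class TestPeeling:
    def test_pure_exponential_recovered_exactly(self):
        t = np.arange(0.0, 100.0, 0.025)
        tr = Trace(t=t, v=5.0 * np.exp(-t / 16.0))
        assert peel_time_constant(tr, (5.0, 80.0), baseline=0.0) == \
            pytest.approx(16.0, rel=1e-9)

    def test_two_exponential_tail(self):
        """Fast component (τ = 2 ms) dies before the window: the slow 16 ms
        constant is recovered within 2%."""
        t = np.arange(0.0, 120.0, 0.025)
        v = 5.0 * np.exp(-t / 16.0) + 3.0 * np.exp(-t / 2.0)
        tau = peel_time_constant(Trace(t=t, v=v), (10.0, 90.0), baseline=0.0)
        assert tau == pytest.approx(16.0, rel=0.02)

    def test_simulated_rc_compartment(self, soma_model):
        """Peeled τ of an isopotential RC model equals R_m·C_m within 1%."""
        from humanl23.synapses import CurrentStep

        p = soma_model.params
        tau_m = p.r_m * p.c_m * 1e-3  # ms
        tr = simulate(soma_model,
                      [CurrentStep(comp=0, amplitude=0.05, start=0.0, end=2.0)],
                      dt=0.025, duration=60.0)[0]
        tau = peel_time_constant(tr, (6.0, 40.0), baseline=p.e_rest)
        assert tau == pytest.approx(tau_m, rel=0.01)

    def test_negative_tail_rejected(self):
        t = np.arange(0.0, 50.0, 0.025)
        tr = Trace(t=t, v=np.exp(-t / 5.0) - 0.5)
        with pytest.raises(EPSPAnalysisError):
            peel_time_constant(tr, (10.0, 40.0), baseline=0.0)


@pytest.fixture(scope="module")
def curve(ball_sticks_model):
    return build_shape_index_curve(ball_sticks_model, dt=0.05)


class TestShapeIndexCurve:
    def test_one_entry_per_dendritic_compartment(self, ball_sticks_model,
                                                 curve):
        assert len(curve) == int(ball_sticks_model.dendritic_mask().sum())

    def test_indices_increase_with_distance_on_cylinder(self, curve,
                                                        ball_sticks_model):
        """Along one unbranched dendrite both indices grow with distance."""
        m = ball_sticks_model
        sec = m.sec_of[curve.comp[0]]
        on_sec = m.sec_of[curve.comp] == sec
        order = np.argsort(curve.path_dist[on_sec])
        rt = curve.rise_time[on_sec][order]
        hw = curve.half_width[on_sec][order]
        assert np.all(np.diff(rt) > 0)
        assert np.all(np.diff(hw) > -1e-9)

    def test_proximal_site_has_smallest_rise_time(self, curve):
        k = int(np.argmin(curve.path_dist))
        assert curve.rise_time[k] == pytest.approx(curve.rise_time.min())


class TestPutativeLocations:
    def test_infinite_radius_returns_all(self, curve):
        si = ShapeIndex(rise_time=1.0, half_width=5.0)
        assert putative_locations(curve, si, radius=1e9).size == len(curve)

    def test_tiny_radius_returns_exact_site(self, curve):
        k = len(curve) // 2
        si = ShapeIndex(rise_time=float(curve.rise_time[k]),
                        half_width=float(curve.half_width[k]))
        sites = putative_locations(curve, si, radius=1e-9)
        assert curve.comp[k] in sites

    def test_round_trip_localization(self, ball_sticks_model, curve):
        """An EPSP synthesized at a known compartment localizes back to it
        at the default 1 ms radius."""
        m = ball_sticks_model
        soma = m.soma_index
        for site in (int(curve.comp[3]), int(curve.comp[-2])):
            tr = simulate(m, [SynapticEvent(comp=site, kinetics=AMPA_DEFAULT,
                                            onset=1.0)],
                          dt=0.05, duration=120.0, record=[soma])[soma]
            si = shape_index(tr, baseline_t=1.0)
            assert site in putative_locations(curve, si, radius=1.0)


class TestFitConnection:
    def test_recovers_planted_conductance_noiseless(self, human_model):
        tr, gt = generate_pair_epsp(human_model, g_per_contact=0.6, seed=5)
        fit = fit_connection(human_model, tr, np.array(gt.params["sites"]),
                             repeats=3, seed=1, onset=gt.params["onset"])
        assert fit.g_mean == pytest.approx(0.6, rel=0.01)

    def test_bias_under_noise_below_ten_percent(self, human_model):
        """5% additive noise, several seeds: mean recovered conductance
        within 10% of the planted 0.6 nS."""
        clean, _ = generate_pair_epsp(human_model, g_per_contact=0.6, seed=5)
        peak = clean.v.max() - clean.v[0]
        gs = []
        for s in range(8):
            tr, gt = generate_pair_epsp(human_model, g_per_contact=0.6,
                                        seed=200 + s, noise_sd=0.05 * peak)
            f = fit_connection(human_model, tr, np.array(gt.params["sites"]),
                               repeats=2, seed=s, onset=gt.params["onset"])
            gs.append(f.g_mean)
        assert abs(np.mean(gs) - 0.6) / 0.6 < 0.10

    def test_scaled_target_scales_fit(self, human_model):
        tr, gt = generate_pair_epsp(human_model, g_per_contact=0.4, seed=9)
        pool = np.array(gt.params["sites"])
        base = tr.v[0]
        doubled = Trace(t=tr.t, v=base + 2 * (tr.v - base), site=tr.site)
        f1 = fit_connection(human_model, tr, pool, repeats=2, seed=0,
                            onset=5.0)
        f2 = fit_connection(human_model, doubled, pool, repeats=2, seed=0,
                            onset=5.0)
        assert f2.g_mean > f1.g_mean
        assert f2.g_mean == pytest.approx(2 * f1.g_mean, rel=0.1)

    def test_zero_target_gives_zero_conductance(self, human_model):
        t = np.arange(0.0, 60.0, 0.05)
        flat = Trace(t=t, v=np.full(t.size, human_model.params.e_rest))
        dend = np.flatnonzero(human_model.dendritic_mask())[:10]
        f = fit_connection(human_model, flat, dend, repeats=2, seed=0)
        assert f.g_mean == pytest.approx(0.0, abs=2e-3)

    def test_small_pool_rejected(self, human_model):
        t = np.arange(0.0, 60.0, 0.05)
        flat = Trace(t=t, v=np.full(t.size, human_model.params.e_rest))
        with pytest.raises(ValueError):
            fit_connection(human_model, flat, np.array([1, 2]), repeats=1)
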