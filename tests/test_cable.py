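"""Passive cable mechanics: closed-form limits, reciprocity, spine-area
correction and integration accuracy."""

import numpy as np
import pytest

from humanl23.cable import (
    PassiveParams,
    Trace,
    apply_spine_correction,
    build_compartmental_model,
    compute_f_spines,
    resistance_map,
    simulate,
)
from humanl23.morphology import Morphology, Section
from humanl23.synapses import AMPA_DEFAULT, CurrentStep, SynapticEvent

from conftest import make_soma_only


class TestFSpines:
    @pytest.mark.parametrize("dend, spine, expected", [
        (100.0, 90.0, 1.9),       # the human L2/L3 value
        (123.4, 0.0, 1.0),
        (50.0, 50.0, 2.0),
    ])
    def test_direct_arithmetic(self, dend, spine, expected):
        assert compute_f_spines(dend, spine) == pytest.approx(expected)

    def test_zero_dendritic_area_rejected(self):
        with pytest.raises(ValueError):
            compute_f_spines(0.0, 10.0)


class TestSpineCorrection:
    def _model(self, params):
        # one long straight dendrite crossing the 60 μm cutoff
        m = Morphology(sections={
            1: Section(id=1, parent_id=None, type=1,
                       points=np.array([[0, 0, 0, 16.0]])),
            2: Section(id=2, parent_id=1, type=3,
                       points=np.array([[0, 0, 0, 1.0], [0, 0, 200.0, 1.0]])),
        })
        return build_compartmental_model(m, params, d_lambda=0.02)

    def test_distal_compartments_scaled_proximal_untouched(self):
        params = PassiveParams(c_m=0.5, f_spines=1.9, spine_min_dist=60.0)
        base = self._model(params)
        corr = apply_spine_correction(base, params)
        distal = base.dendritic_mask() & (base.path_dist >= 60.0)
        proximal = base.dendritic_mask() & (base.path_dist < 60.0)
        assert distal.any() and proximal.any()
        np.testing.assert_allclose(corr.cm[distal], base.cm[distal] * 1.9)
        np.testing.assert_allclose(corr.g_pas[distal], base.g_pas[distal] * 1.9)
        np.testing.assert_allclose(corr.cm[proximal], base.cm[proximal])
        assert corr.cm[0] == base.cm[0]  # soma untouched
        # effective C_m of 0.5 μF/cm² becomes 0.95 distally
        area_cm2 = base.area[distal] * 1e-8
        c_eff = corr.cm[distal] * 1e-3 / area_cm2  # nF → μF, per cm²
        np.testing.assert_allclose(c_eff, 0.95, rtol=1e-9)

    def test_identity_when_factor_is_one(self):
        params = PassiveParams(f_spines=1.0)
        base = self._model(params)
        corr = apply_spine_correction(base, params)
        np.testing.assert_array_equal(corr.cm, base.cm)
        np.testing.assert_array_equal(corr.g_pas, base.g_pas)

    def test_cutoff_is_sharp_at_60_um(self):
        params = PassiveParams(f_spines=1.9, spine_min_dist=60.0)
        base = self._model(params)
        corr = apply_spine_correction(base, params)
        below = np.flatnonzero(base.path_dist < 60.0)[1:]  # skip soma
        above = np.flatnonzero(base.path_dist >= 60.0)
        assert np.all(corr.cm[below] == base.cm[below])
        assert np.all(corr.cm[above] > base.cm[above])

    def test_membrane_time_constant_conserved(self):
        """R_m·C_m per compartment is invariant under the correction."""
        params = PassiveParams(f_spines=1.9)
        base = self._model(params)
        corr = apply_spine_correction(base, params)
        np.testing.assert_allclose(corr.cm / corr.g_pas, base.cm / base.g_pas,
                                   rtol=1e-12)


class TestAnalyticLimits:
    def test_rc_relaxation_time_constant(self, passive_params):
        """Isopotential compartment relaxes with τ = R_m·C_m (here 10 ms)."""
        params = PassiveParams(c_m=0.5, r_m=20000.0)
        model = build_compartmental_model(make_soma_only(), params)
        tr = simulate(model, [CurrentStep(comp=0, amplitude=0.05, start=0.0)],
                      dt=0.025, duration=80.0)[0]
        v = tr.v - params.e_rest
        vinf = v[-1]
        mask = (tr.t > 1.0) & (tr.t < 40.0)
        slope = np.polyfit(tr.t[mask], np.log(1.0 - v[mask] / vinf), 1)[0]
        assert -1.0 / slope == pytest.approx(10.0, rel=0.01)

    def test_sealed_cylinder_attenuation_matches_cosh(self):
        """Steady-state end-to-end attenuation of a sealed cylinder of
        electrotonic length L equals cosh(L)."""
        params = PassiveParams(c_m=0.5, r_m=20000.0, r_a=200.0)
        d = 2.0
        lam = 100.0 * np.sqrt(params.r_m * d / (4.0 * params.r_a))  # μm
        m = Morphology(sections={
            1: Section(id=1, parent_id=None, type=1,
                       points=np.array([[0, 0, 0, 0.5]])),  # negligible soma
            2: Section(id=2, parent_id=1, type=3,
                       points=np.array([[0, 0, 0, d], [0, 0, lam, d]])),
        })
        model = build_compartmental_model(m, params, d_lambda=0.02,
                                          max_nseg=400)
        start, end = model.sections[2]
        R = resistance_map(model, [start, end - 1])
        # injected at the far (sealed) end, recorded at both ends
        ratio = R[1, 1] / R[1, 0]
        assert ratio == pytest.approx(np.cosh(1.0), rel=0.01)

    def test_input_resistance_of_single_compartment(self):
        params = PassiveParams(r_m=20000.0)
        model = build_compartmental_model(make_soma_only(diam=20.0), params)
        area_cm2 = model.area[0] * 1e-8
        expected = params.r_m / area_cm2 * 1e-6  # MΩ
        R = resistance_map(model)
        assert R[0, 0] == pytest.approx(expected, rel=1e-6)


class TestResistanceMap:
    def test_reciprocity_on_random_tree(self, human_model):
        sites = np.linspace(0, human_model.n - 1, 25).astype(int)
        R = resistance_map(human_model, sites)
        np.testing.assert_allclose(R, R.T, rtol=1e-6)

    def test_transfer_below_input_resistance(self, y_model):
        tips = y_model.terminal_compartments()
        R = resistance_map(y_model, tips[:2])
        assert R[0, 1] < R[0, 0]
        assert R[0, 1] < R[1, 1]

    def test_active_model_rejected(self, moo_cell):
        from humanl23.active import DEFAULT_ACTIVE, attach_active

        act = attach_active(moo_cell, DEFAULT_ACTIVE)
        with pytest.raises(ValueError):
            resistance_map(act)

    def test_matches_dense_solver_on_small_tree(self, y_model):
        """Steady state from the tree solve (long simulation) equals the
        generic sparse/dense solve used by resistance_map."""
        assert y_model.n <= 40
        site = int(y_model.terminal_compartments()[0])
        R = resistance_map(y_model, [site])
        tr = simulate(y_model, [CurrentStep(comp=site, amplitude=0.1,
                                            start=0.0)],
                      dt=0.05, duration=400.0, record=[site])[site]
        r_sim = (tr.v[-1] - y_model.params.e_rest) / 0.1
        assert r_sim == pytest.approx(R[0, 0], rel=1e-4)


class TestSimulate:
    def test_no_stimulus_stays_at_rest(self, y_model):
        traces = simulate(y_model, [], dt=0.05, duration=20.0)
        for tr in traces.values():
            assert np.all(np.abs(tr.v - y_model.params.e_rest) < 1e-9)

    def test_dt_refinement_epsp_peak_stable(self, ball_sticks_model):
        """Halving dt moves a somatic EPSP peak by < 0.5%."""
        m = ball_sticks_model
        site = int(m.terminal_compartments()[0])
        ev = [SynapticEvent(comp=site, kinetics=AMPA_DEFAULT, onset=2.0)]
        peaks = []
        for dt in (0.05, 0.025, 0.0125):
            tr = simulate(m, ev, dt=dt, duration=60.0, record=[0])[0]
            peaks.append(tr.v.max() - m.params.e_rest)
        assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.005
        assert abs(peaks[2] - peaks[1]) / peaks[2] < 0.005

    def test_invalid_site_rejected(self, y_model):
        with pytest.raises(ValueError):
            simulate(y_model, [CurrentStep(comp=10**6, amplitude=0.1)],
                     duration=5.0)


class TestTrace:
    def test_round_trip_csv(self, tmp_path):
        tr = Trace(t=np.arange(0, 5, 0.1), v=np.sin(np.arange(0, 5, 0.1)),
                   site=3)
        p = tmp_path / "trace.csv"
        tr.to_csv(p)
        back = Trace.from_csv(p)
        assert back.site == 3
        np.testing.assert_allclose(back.v, tr.v, atol=1e-12)

    def test_nonuniform_time_base_rejected(self):
        with pytest.raises(ValueError):
            Trace(t=np.array([0.0, 0.1, 0.3]), v=np.zeros(3))
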