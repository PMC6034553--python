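"""Kinetic synapse waveforms, Mg block, and spine biophysics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from humanl23.synapses import (
    AMPA_DEFAULT,
    NMDA_DEFAULT,
    PROTOTYPICAL_SPINE,
    SpineGeometry,
    SynapseKinetics,
    activate_spinous_synapse,
    attach_spines,
    conductance_waveform,
    mg_block,
    neck_resistance,
    normalization_factor,
    synaptic_current,
    t_peak,
)


class TestKineticScheme:
    def test_ampa_peak_time_and_normalization(self):
        """With the human AMPA constants (0.3/1.8 ms) the peak sits at
        0.36·ln 6 ≈ 0.645 ms, N ≈ 1.717, and g(t_peak) = g_max."""
        kin = AMPA_DEFAULT
        tp = t_peak(kin)
        assert tp == pytest.approx(0.36 * np.log(6.0), abs=1e-12)
        assert normalization_factor(kin) == pytest.approx(1.717, abs=2e-3)
        assert conductance_waveform(kin, tp) == pytest.approx(kin.g_max,
                                                              rel=1e-12)

    def test_conductance_zero_at_onset(self):
        for kin in (AMPA_DEFAULT, NMDA_DEFAULT):
            assert conductance_waveform(kin, 0.0, v=0.0) == pytest.approx(0.0)

    @given(tau_rise=st.floats(0.1, 10.0), ratio=st.floats(1.2, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_peak_matches_brute_force_grid(self, tau_rise, ratio):
        """Closed-form t_peak agrees with dense-grid maximization to 1e-6 ms
        and the peak value equals g_max (Eq-4 normalization)."""
        kin = SynapseKinetics(g_max=1.0, tau_rise=tau_rise,
                              tau_decay=tau_rise * ratio)
        tp = t_peak(kin)
        grid = np.linspace(max(tp - 0.01, 0.0), tp + 0.01, 20001)
        g = conductance_waveform(kin, grid)
        assert grid[np.argmax(g)] == pytest.approx(tp, abs=1e-6)
        assert g.max() == pytest.approx(1.0, rel=1e-3)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            SynapseKinetics(g_max=1.0, tau_rise=2.0, tau_decay=1.0)


class TestMgBlock:
    def test_value_at_zero_mv(self):
        """B(0 mV) = 1/(1 + n·[Mg]) = 1/1.28 = 0.78125 for n = 0.28 mM⁻¹,
        [Mg] = 1 mM."""
        assert mg_block(NMDA_DEFAULT, 0.0) == pytest.approx(0.78125, abs=1e-12)

    def test_value_at_rest(self):
        """Direct evaluation at −70 mV with γ = 0.0771 mV⁻¹."""
        b = mg_block(NMDA_DEFAULT, -70.0)
        expected = 1.0 / (1.0 + 0.28 * np.exp(0.0771 * 70.0))
        assert b == pytest.approx(expected, rel=1e-12)
        assert b == pytest.approx(0.0159, abs=5e-4)

    def test_no_magnesium_means_no_block(self):
        kin = SynapseKinetics(g_max=1.0, tau_rise=8.0, tau_decay=35.0,
                              voltage_dependent=True, mg=0.0)
        v = np.linspace(-120, 60, 50)
        np.testing.assert_allclose(mg_block(kin, v), 1.0)

    @given(v=st.floats(-120.0, 60.0), dv=st.floats(0.1, 40.0),
           mg=st.floats(0.1, 4.0))
    @settings(max_examples=60, deadline=None)
    def test_block_monotone_in_voltage_and_magnesium(self, v, dv, mg):
        kin = SynapseKinetics(g_max=1.0, tau_rise=8.0, tau_decay=35.0,
                              voltage_dependent=True, mg=mg)
        b0, b1 = mg_block(kin, v), mg_block(kin, v + dv)
        assert 0.0 < b0 < b1 <= 1.0
        heavier = SynapseKinetics(g_max=1.0, tau_rise=8.0, tau_decay=35.0,
                                  voltage_dependent=True, mg=mg * 2)
        assert mg_block(heavier, v) < b0


class TestSynapticCurrent:
    def test_zero_at_reversal(self):
        assert synaptic_current(AMPA_DEFAULT, 0.0, 1.0) == pytest.approx(0.0)

    def test_ampa_current_at_rest(self):
        """0.88 nS at the peak driving −86 mV gives ≈ −0.0757 nA."""
        i = synaptic_current(AMPA_DEFAULT, -86.0, t_peak(AMPA_DEFAULT))
        assert i == pytest.approx(0.88e-3 * (-86.0), rel=1e-9)
        assert i == pytest.approx(-0.0757, abs=2e-4)

    def test_nmda_current_nonmonotone_in_voltage(self):
        """|I_NMDA| rises then falls as V sweeps −90 → 0 mV (unblocking vs
        vanishing driving force)."""
        v = np.linspace(-90.0, 0.0, 181)
        i = np.abs(synaptic_current(NMDA_DEFAULT, v, t_peak(NMDA_DEFAULT)))
        k = int(np.argmax(i))
        assert 0 < k < v.size - 1
        assert i[k] > i[0] and i[k] > i[-1]


class TestSpine:
    def test_neck_resistance_prototype(self):
        """1.35 μm × 0.25 μm neck: ≈ 55 MΩ at 200 Ω·cm, ≈ 82.5 at 300."""
        assert neck_resistance(PROTOTYPICAL_SPINE, 200.0) == pytest.approx(
            55.0, abs=0.1)
        assert neck_resistance(PROTOTYPICAL_SPINE, 300.0) == pytest.approx(
            82.5, abs=0.2)

    def test_quartering_under_diameter_doubling(self):
        g1 = neck_resistance(PROTOTYPICAL_SPINE, 200.0)
        fat = SpineGeometry(neck_diameter=0.5)
        assert neck_resistance(fat, 200.0) == pytest.approx(g1 / 4, rel=1e-12)

    def test_variation_grid_spans_published_band(self):
        """d ∈ 0.25±0.05 μm, R_a ∈ 200±100 Ω·cm spans ≈ 19–128 MΩ."""
        vals = [neck_resistance(SpineGeometry(neck_diameter=d), ra)
                for d in (0.20, 0.25, 0.30) for ra in (100.0, 200.0, 300.0)]
        assert min(vals) == pytest.approx(19.1, rel=0.01)
        assert max(vals) == pytest.approx(128.9, rel=0.01)

    def test_attenuation_chain_head_base_soma(self, ball_sticks_model):
        m = ball_sticks_model
        site = int(m.terminal_compartments()[0])
        out = activate_spinous_synapse(m, site)
        assert out["epsp_head"] >= out["epsp_base"] >= out["epsp_soma"] > 0
        assert out["head_to_base"] >= 1.0
        assert out["head_to_soma"] >= out["head_to_base"]

    def test_zero_conductance_zero_epsp(self, ball_sticks_model):
        kin = SynapseKinetics(g_max=0.0, tau_rise=0.3, tau_decay=1.8)
        site = int(ball_sticks_model.terminal_compartments()[0])
        out = activate_spinous_synapse(ball_sticks_model, site, kin=kin)
        assert out["epsp_head"] == pytest.approx(0.0, abs=1e-9)
        assert out["epsp_soma"] == pytest.approx(0.0, abs=1e-9)

    def test_distal_spine_epsp_exceeds_proximal(self, ball_sticks_model):
        """Higher local input resistance at thin distal sites gives larger
        spine-head EPSPs, consistent with the transfer-resistance map."""
        from humanl23.cable import resistance_map

        m = ball_sticks_model
        dend = np.flatnonzero(m.dendritic_mask())
        prox = int(dend[np.argmin(m.path_dist[dend])])
        dist = int(dend[np.argmax(m.path_dist[dend])])
        R = resistance_map(m, [prox, dist])
        assert R[1, 1] > R[0, 0]
        e_prox = activate_spinous_synapse(m, prox)["epsp_head"]
        e_dist = activate_spinous_synapse(m, dist)["epsp_head"]
        assert e_dist > e_prox

    def test_spinous_synapse_attenuated_versus_shaft(self, ball_sticks_model):
        """The spine neck's series resistance makes the shaft EPSP of a
        spinous synapse no larger than the same synapse placed on the
        shaft."""
        from humanl23.cable import simulate
        from humanl23.synapses import SynapticEvent

        m = ball_sticks_model
        site = int(m.terminal_compartments()[0])
        shaft = simulate(m, [SynapticEvent(comp=site, kinetics=AMPA_DEFAULT,
                                           onset=1.0)],
                         dt=0.025, duration=60.0, record=[site])[site]
        shaft_peak = shaft.v.max() - m.params.e_rest
        base_peak = activate_spinous_synapse(m, site)["epsp_base"]
        assert base_peak <= shaft_peak * (1 + 1e-9)

    def test_spine_on_axon_rejected(self, moo_cell):
        axon = int(np.flatnonzero(moo_cell.comp_type == 2)[0])
        with pytest.raises(ValueError):
            attach_spines(moo_cell, [axon])
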