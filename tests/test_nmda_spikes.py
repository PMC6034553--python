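"""NMDA-spike detection, minimal synapse counts and independence counting."""

import numpy as np
import pytest

from humanl23.cable import Trace
from humanl23.nmda_spikes import (
    ClusterSpec,
    NMDASpikeCriterion,
    count_independent_nmda_spikes,
    detect_nmda_spike,
    min_synapses_for_nmda_spike,
)
from humanl23.synapses import NMDA_DEFAULT, SynapseKinetics

from conftest import make_star, make_y_tree
from humanl23.cable import PassiveParams, build_compartmental_model


def rect_pulse_trace(level, width, dt=0.05, base=-86.0, duration=100.0,
                     onset=10.0):
    t = np.arange(0.0, duration, dt)
    v = np.full_like(t, base)
    v[(t >= onset) & (t < onset + width)] = level
    return Trace(t=t, v=v)


class TestDetection:
    def test_flat_resting_trace(self):
        tr = rect_pulse_trace(-86.0, 0.0)
        assert detect_nmda_spike(tr)[0] is False

    @pytest.mark.parametrize("width, expected", [(25.0, True), (15.0, False)])
    def test_rectangular_pulse_threshold_logic(self, width, expected):
        tr = rect_pulse_trace(-20.0, width)
        det, onset, dur = detect_nmda_spike(tr)
        assert det is expected
        if det:
            assert dur == pytest.approx(width, abs=0.2)
            assert onset == pytest.approx(10.0, abs=0.2)

    def test_depth_below_threshold_ignored(self):
        tr = rect_pulse_trace(-45.0, 50.0)
        assert detect_nmda_spike(tr)[0] is False

    def test_detection_invariant_to_dt_refinement(self, human_model):
        """A clear plateau detection does not flip when dt is halved."""
        from humanl23.nmda_spikes import cluster_positions
        from humanl23.synapses import attach_spines, SynapticEvent, AMPA_DEFAULT
        from humanl23.cable import simulate

        m = human_model
        elec = m.electrotonic_distance()
        terms = m.terminal_compartments()
        site = int(terms[np.argmax(elec[terms])])
        pos = cluster_positions(m, site, 20.0, 25, np.random.default_rng(0))
        spiny, heads = attach_spines(m, pos)
        ev = []
        for h in heads:
            ev.append(SynapticEvent(comp=h, kinetics=AMPA_DEFAULT, onset=2.0))
            ev.append(SynapticEvent(comp=h, kinetics=NMDA_DEFAULT, onset=2.0))
        results = []
        for dt in (0.05, 0.025):
            tr = simulate(spiny, ev, dt=dt, duration=120.0,
                          record=[site])[site]
            results.append(detect_nmda_spike(tr))
        assert results[0][0] == results[1][0] is True
        assert results[0][2] == pytest.approx(results[1][2], rel=0.05)

    def test_plateau_peak_approaches_nmda_reversal(self, human_model):
        """Growing the cluster drives the local plateau toward 0 mV."""
        from humanl23.nmda_spikes import cluster_positions
        from humanl23.synapses import attach_spines, SynapticEvent, AMPA_DEFAULT
        from humanl23.cable import simulate

        m = human_model
        elec = m.electrotonic_distance()
        terms = m.terminal_compartments()
        site = int(terms[np.argmax(elec[terms])])
        rng = np.random.default_rng(1)
        pos = cluster_positions(m, site, 20.0, 50, rng)
        peaks = []
        for n in (10, 25, 50):
            spiny, heads = attach_spines(m, pos[:n])
            ev = []
            for h in heads:
                ev.append(SynapticEvent(comp=h, kinetics=AMPA_DEFAULT,
                                        onset=2.0))
                ev.append(SynapticEvent(comp=h, kinetics=NMDA_DEFAULT,
                                        onset=2.0))
            tr = simulate(spiny, ev, dt=0.05, duration=120.0,
                          record=[site])[site]
            peaks.append(tr.v.max())
        assert peaks[0] < peaks[1] < peaks[2] < 0.0
        assert peaks[2] > -15.0  # close to the 0 mV reversal


class TestMinSynapses:
    def test_zero_synapses_never_spike(self, human_model):
        site = int(human_model.terminal_compartments()[0])
        n = min_synapses_for_nmda_spike(human_model, site, seed=0,
                                        max_synapses=0)
        assert n is None

    def test_distal_terminal_needs_fewer_than_proximal_branch(self,
                                                              human_model):
        """High-input-resistance distal terminals reach the plateau with
        fewer clustered synapses."""
        m = human_model
        elec = m.electrotonic_distance()
        terms = m.terminal_compartments()
        distal = int(terms[np.argmax(elec[terms])])
        proximal = int(terms[np.argmin(elec[terms])])
        n_d = min_synapses_for_nmda_spike(m, distal, seed=0)
        n_p = min_synapses_for_nmda_spike(m, proximal, seed=0)
        assert n_d is not None
        assert n_p is None or n_d < n_p

    def test_stronger_nmda_lowers_or_preserves_count(self, human_model):
        m = human_model
        elec = m.electrotonic_distance()
        terms = m.terminal_compartments()
        site = int(terms[np.argmax(elec[terms])])
        strong = SynapseKinetics(g_max=2 * NMDA_DEFAULT.g_max,
                                 tau_rise=NMDA_DEFAULT.tau_rise,
                                 tau_decay=NMDA_DEFAULT.tau_decay,
                                 voltage_dependent=True)
        n1 = min_synapses_for_nmda_spike(m, site, seed=0)
        n2 = min_synapses_for_nmda_spike(m, site, seed=0, nmda=strong)
        assert n2 is not None and n1 is not None
        assert n2 <= n1

    def test_cluster_spec_validation(self):
        with pytest.raises(ValueError):
            ClusterSpec(site=0, n_synapses=-1)
        with pytest.raises(ValueError):
            ClusterSpec(site=0, n_synapses=5, span=0.0)


@pytest.fixture(scope="module")
def star_model():
    return build_compartmental_model(make_star(n_arms=6),
                                     PassiveParams(), d_lambda=0.05)


class TestIndependenceCounting:
    def test_decoupled_star_counts_every_arm(self, star_model):
        """Six long thin terminals radiating from a common soma are
        electrotonically decoupled: all six sustain independent spikes."""
        rep = count_independent_nmda_spikes(star_model, seed=0,
                                            strategy="greedy")
        assert rep.count == 6
        assert all(p < -40.0 for p in rep.branch_point_peaks.values())

    def test_coupled_siblings_do_not_both_count(self):
        """Two sibling terminals on a short mother branch interact: at most
        one contributes an independent spike."""
        m = build_compartmental_model(
            make_y_tree(stem=15.0, branch=60.0, d_stem=1.2, d_branch=0.8),
            PassiveParams(), d_lambda=0.05)
        rep = count_independent_nmda_spikes(m, seed=0, strategy="greedy")
        assert rep.count <= 1

    def test_count_bounded_by_terminals(self, star_model):
        rep = count_independent_nmda_spikes(star_model, seed=3,
                                            strategy="greedy")
        assert rep.count <= star_model.terminal_compartments().size

    def test_backtracking_never_worse_than_greedy(self, human_model):
        greedy = count_independent_nmda_spikes(human_model, seed=0,
                                               strategy="greedy",
                                               max_synapses=40)
        back = count_independent_nmda_spikes(human_model, seed=0,
                                             strategy="greedy-backtrack",
                                             backtrack_budget=10,
                                             max_synapses=40)
        assert back.count >= greedy.count

    def test_exhaustive_matches_greedy_on_decoupled_star(self, star_model):
        ex = count_independent_nmda_spikes(star_model, seed=0,
                                           strategy="exhaustive")
        assert ex.count == 6
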