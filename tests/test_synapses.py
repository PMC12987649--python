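"""Synaptic kinetics, short-term depression, weights, and placement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrhythm import synapses as syn
from dendrhythm.synapses import (AMPA, GABA_A, NMDA, STP_SETS, ProtocolError,
                                 STPParams, STPState)


def stp_oracle(params, times):
    """Independent step-by-step recursion for the two-factor depression."""
    d1, d2 = 1.0, 1.0
    t_last = None
    eff = []
    for t in times:
        if t_last is not None:
            dt = t - t_last
            d1 = 1.0 - (1.0 - d1) * math.exp(-dt / params.tau1)
            d2 = 1.0 - (1.0 - d2) * math.exp(-dt / params.tau2)
        eff.append(d1 * d2)
        d1 *= params.d1
        d2 *= params.d2
        t_last = t
    return np.array(eff)


class TestSTP:
    def test_no_depression_when_d_is_one(self):
        p = STPParams(35.0, 1.0, 250.0, 1.0)
        s = STPState()
        for t in [0.0, 10.0, 20.0]:
            s, eff = syn.stp_step(s, p, t)
            assert eff == pytest.approx(1.0)

    def test_full_recovery_at_long_intervals(self):
        p = STP_SETS["excitatory"]
        s = STPState()
        s, _ = syn.stp_step(s, p, 0.0)
        s, eff = syn.stp_step(s, p, 1e7)
        assert eff == pytest.approx(1.0, abs=1e-9)

    def test_eight_pulse_50hz_matches_recursion_oracle(self):
        # reference protocol: 8 pulses at 50 Hz
        p = STP_SETS["excitatory"]
        times = 20.0 * np.arange(8)
        s = STPState()
        got = []
        for t in times:
            s, eff = syn.stp_step(s, p, t)
            got.append(eff)
        np.testing.assert_allclose(got, stp_oracle(p, times), rtol=1e-12)

    def test_time_reversal_rejected(self):
        p = STP_SETS["excitatory"]
        s, _ = syn.stp_step(STPState(), p, 100.0)
        with pytest.raises(ValueError):
            syn.stp_step(s, p, 50.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.5, 100.0), min_size=1, max_size=20))
    def test_depression_factors_stay_in_unit_interval(self, intervals):
        p = STP_SETS["perisomatic_inh"]
        s = STPState()
        t = 0.0
        for dt in intervals:
            t += dt
            s, eff = syn.stp_step(s, p, t)
            assert 0.0 < eff <= 1.0
            assert 0.0 < s.D1 <= 1.0 and 0.0 < s.D2 <= 1.0


class TestMgBlock:
    def test_reference_value_at_zero(self):
        assert syn.mg_block(0.0) == pytest.approx(1.0 / 1.33, rel=1e-12)

    def test_limit_at_depolarization(self):
        assert syn.mg_block(500.0) == pytest.approx(1.0, abs=1e-9)

    def test_strictly_increasing(self):
        v = np.linspace(-100.0, 50.0, 301)
        s = syn.mg_block(v)
        assert np.all(np.diff(s) > 0)

    def test_hyperpolarized_suppression_ratio(self):
        # NMDA current at -70 mV strongly suppressed relative to -20 mV
        assert syn.mg_block(-70.0) / syn.mg_block(-20.0) < 0.3


class TestKinetics:
    @pytest.mark.parametrize("rec", [AMPA, NMDA, GABA_A])
    def test_conductance_peak_time_matches_dual_exponential(self, rec):
        # integrate the two-state gate; peak must match
        # t_peak = tau_r*tau_d/(tau_d - tau_r) * ln(tau_d/tau_r)
        dt = 0.01
        n = int(20 * rec.tau_decay / dt)
        r = 0.0
        rinf = rec.alpha / (rec.alpha + rec.beta)
        on_fac = math.exp(-dt * (rec.alpha + rec.beta))
        off_fac = math.exp(-dt * rec.beta)
        on_steps = int(round(rec.t_peak / dt))
        trace = np.empty(n)
        for k in range(n):
            if k < on_steps:
                r = rinf + (r - rinf) * on_fac
            else:
                r *= off_fac
            trace[k] = r
        t_peak_sim = dt * (1 + int(np.argmax(trace)))
        assert t_peak_sim == pytest.approx(rec.t_peak, abs=2 * dt)

    def test_zero_gating_zero_current(self):
        assert syn.syn_current(0.0, -60.0, 5e-4, AMPA) == 0.0

    def test_zero_driving_force(self):
        assert syn.syn_current(0.5, GABA_A.e_rev, 1e-3, GABA_A) == 0.0

    def test_invalid_gating_rejected(self):
        with pytest.raises(ValueError):
            syn.syn_current(1.5, -60.0, 5e-4, AMPA)


class TestReleaseGate:
    def test_certain_release(self):
        assert syn.release_gate(1.0, 100, seed=0).all()

    def test_binomial_statistics(self):
        acc = syn.release_gate(0.5, 10000, seed=1).sum()
        assert abs(acc - 5000) < 3 * 50

    @pytest.mark.parametrize("p", [0.16, 0.53, 0.72, 0.88, 0.9])
    def test_study_probabilities_representable(self, p):
        out = syn.release_gate(p, 1000, seed=2)
        assert 0 < out.sum() < 1000

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            syn.release_gate(0.0, 10)


class TestWeights:
    def test_inhibitory_fixed_at_1ns(self, small_morph):
        specs = syn.place_inhibitory_synapses(small_morph, seed=0,
                                              n_somatic=20)
        out = syn.draw_weights(specs, seed=1)
        assert all(s.g_gaba == pytest.approx(1e-3) for s in out)

    def test_lognormal_moments(self, small_morph):
        specs = syn.place_excitatory_synapses(small_morph, density=2.16,
                                              seed=0)
        # enough draws to pin the distribution mean within 3 sigma
        reps = [syn.draw_weights(specs, seed=s) for s in range(3)]
        g = np.concatenate([[s.g_ampa for s in specs_w] for specs_w in reps])
        se = 3.45e-4 / np.sqrt(g.size)
        assert abs(g.mean() - 2.0e-4) < 3 * se
        assert np.all(g > 0)
        assert g.std() == pytest.approx(3.45e-4, rel=0.1)


class TestPlacement:
    def test_reference_excitatory_totals(self, full_morph):
        # 2.16/um on 7440 um apical and 4649 um basal cable
        specs = syn.place_excitatory_synapses(full_morph, density=2.16,
                                              seed=0)
        n_api = sum(1 for s in specs if s.subtree == "apical")
        n_bas = sum(1 for s in specs if s.subtree == "basal")
        assert n_api == 16070
        assert n_bas == 10042

    def test_divergence_and_release_ranges(self, small_morph):
        specs = syn.place_excitatory_synapses(small_morph, seed=1)
        by_node = {}
        for s in specs:
            by_node.setdefault(s.node_id, []).append(s)
        counts = [len(v) for v in by_node.values()]
        # divergence uniform on {2..8} (edge nodes may be truncated)
        assert min(counts) >= 1 and max(counts) <= 8
        assert np.mean(counts) == pytest.approx(5.0, abs=0.5)
        for v in by_node.values():
            ps = {s.p_release for s in v}
            assert len(ps) == 1          # per-node release probability
            assert 0.16 <= ps.pop() <= 0.9

    def test_node_contacts_share_a_branch_within_10um(self, small_morph):
        specs = syn.place_excitatory_synapses(small_morph, seed=2)
        by_node = {}
        for s in specs:
            by_node.setdefault(s.node_id, []).append(s)
        for v in by_node.values():
            branches = {small_morph.branch_id[s.comp] for s in v}
            assert len(branches) == 1
            span = (max(small_morph.path_dist[s.comp] for s in v)
                    - min(small_morph.path_dist[s.comp] for s in v))
            assert span <= 10.0 + 2 * small_morph.length[v[0].comp]

    def test_reference_inhibitory_totals(self, full_morph):
        specs = syn.place_inhibitory_synapses(full_morph, density=0.22,
                                              n_somatic=150, seed=0)
        n_api = sum(1 for s in specs if s.subtree == "apical")
        n_bas = sum(1 for s in specs if s.subtree == "basal")
        n_soma = sum(1 for s in specs if s.subtree == "soma")
        assert n_api == int(round(0.22 * 7440))  # 1637
        assert n_bas == int(round(0.22 * 4649))  # 1023
        assert n_soma == 150

    def test_zone_tags_consistent_with_path_distance(self, full_morph):
        specs = syn.place_inhibitory_synapses(full_morph, seed=3)
        for s in specs:
            peri = (full_morph.region[s.comp] == "soma"
                    or full_morph.path_dist[s.comp] <= 100.0)
            assert s.zone == ("perisomatic" if peri else "distal")

    def test_bad_density_rejected(self, small_morph):
        with pytest.raises(ValueError):
            syn.place_excitatory_synapses(small_morph, density=0.0)


class TestTrainInduction:
    def test_depression_only_matches_recursion(self):
        times = 20.0 * np.arange(8)
        for name in STP_SETS:
            amps = stp_oracle(STP_SETS[name], times)
            expect = (amps[5:8].mean() - amps[0]) / amps.max()
            got = syn.stp_train_induction(name, mode="depression_only")
            assert got == pytest.approx(expect, abs=1e-12)

    def test_class_ordering_of_induction_magnitude(self):
        # perisomatic inhibitory depression > excitatory > dendritic
        vals = {name: syn.stp_train_induction(name, mode="depression_only")
                for name in STP_SETS}
        assert all(v < 0 for v in vals.values())
        assert abs(vals["perisomatic_inh"]) > abs(vals["excitatory"]) \
            > abs(vals["dendritic_inh"])

    def test_psc_protocol_depresses(self):
        v = syn.stp_train_induction("excitatory", mode="psc",
                                    receptors=(AMPA,))
        assert -1.0 < v < 0.0

    def test_no_depression_gives_zero_induction(self):
        # depression disabled and pulses far apart (no kinetic summation)
        p = STPParams(35.0, 1.0, 250.0, 1.0)
        v = syn.stp_train_induction(p, mode="psc", receptors=(AMPA,), f=5.0)
        assert v == pytest.approx(0.0, abs=1e-6)

    def test_too_few_pulses_rejected(self):
        with pytest.raises(ProtocolError):
            syn.stp_train_induction("excitatory", n_pulses=4)
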