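"""Morphology construction, passive cable behaviour, and active competence."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from dendrhythm.cell import (NumericalFailure, _passive_system, assemble_cell,
                             attenuation_map, electrotonic_deciles,
                             inject_step, integrate, measure_attenuation)
from dendrhythm.channels import (ChannelDensityMap, PassiveParams,
                                 default_densities)
from dendrhythm.core import SpikeTrain
from dendrhythm.events import detect_aps, detect_na_spikes, detect_plateau
from dendrhythm.morphology import (Morphology, MorphologyParams,
                                   build_synthetic_morphology, read_swc)
from dendrhythm.synapses import SynapseSpec

ZERO = ChannelDensityMap({r: {} for r in
                          ("soma", "axon", "basal", "apical_trunk",
                           "nexus", "tuft")})


class TestMorphology:
    def test_default_cable_totals(self, full_morph):
        assert full_morph.total_length("apical") == pytest.approx(7440.0,
                                                                  rel=0.01)
        assert full_morph.total_length("basal") == pytest.approx(4649.0,
                                                                 rel=0.01)

    def test_single_root_and_region_partition(self, full_morph):
        assert np.sum(full_morph.parent < 0) == 1
        assert set(full_morph.region) <= {"soma", "axon", "basal",
                                          "apical_trunk", "nexus", "tuft"}
        assert np.all(full_morph.length > 0)
        assert np.all(full_morph.diam > 0)

    def test_segments_do_not_exceed_20um(self, full_morph):
        assert full_morph.length.max() <= 25.0 + 1e-9  # soma is one lump

    def test_jitter_preserves_subtree_totals(self):
        m = build_synthetic_morphology(MorphologyParams(jitter=0.2), seed=4)
        assert m.total_length("apical") == pytest.approx(7440.0, rel=1e-6)
        assert m.total_length("basal") == pytest.approx(4649.0, rel=1e-6)

    def test_swc_round_trip(self, tmp_path, small_morph):
        path = tmp_path / "cell.swc"
        small_morph.to_swc(path)
        m2 = read_swc(path)
        np.testing.assert_array_equal(small_morph.parent, m2.parent)
        np.testing.assert_allclose(small_morph.length, m2.length, atol=1e-4)
        np.testing.assert_allclose(small_morph.diam, m2.diam, atol=1e-4)
        assert (small_morph.region == m2.region).all()

    def test_invalid_tree_rejected(self):
        with pytest.raises(ValueError):
            Morphology([-1, 2, 1], [10, 10, 10], [1, 1, 1],
                       ["soma", "basal", "basal"], [0, 1, 1])


class TestAssembly:
    def test_soma_must_not_carry_im(self, small_morph):
        d = default_densities()
        d.densities["soma"]["Im"] = 1.0
        with pytest.raises(ValueError):
            assemble_cell(small_morph, densities=d)

    def test_dendritic_roster_enforced(self, small_morph):
        d = default_densities()
        d.densities["tuft"]["KPst"] = 1.0
        with pytest.raises(ValueError):
            assemble_cell(small_morph, densities=d)

    def test_dendrite_channel_set_is_the_seven(self):
        d = default_densities()
        for region in ("basal", "apical_trunk", "nexus", "tuft"):
            active = {c for c, g in d.densities[region].items() if g > 0}
            assert active == {"CaLVA", "CaHVA", "SK", "SKv31", "NaT",
                              "Im", "Ih"}


class TestPassive:
    def test_settles_to_leak_reversal(self, small_morph):
        cell = assemble_cell(small_morph, densities=ZERO)
        ts = integrate(cell, duration=800.0, record="soma")
        assert ts.v_soma[-1] == pytest.approx(cell.passive.e_leak, abs=0.01)

    def test_step_response_matches_analytic_cable_oracle(self, small_morph):
        # independent oracle: sparse frequency-domain solve at f = 0
        cell = assemble_cell(small_morph, densities=ZERO)
        lu = spla.splu(_passive_system(cell, 0.0))
        r_in = lu.solve(np.eye(cell.n_comp)[:, 0].astype(complex))[0].real
        ts = inject_step(cell, 1.0, 1500.0, record="soma", pre=500.0,
                         post=50.0)
        base = ts.v_soma[int(490 / ts.dt)]
        plateau = ts.v_soma[int(1990 / ts.dt)]
        assert (plateau - base) == pytest.approx(r_in, rel=0.01)

    def test_isolated_compartment_time_constant(self):
        # charge decays with tau = Cm/g_leak on a single compartment
        m = Morphology([-1], [20.0], [20.0], ["soma"], [0])
        pp = PassiveParams()
        cell = assemble_cell(m, densities=ZERO, passive=pp)
        tau_expect = pp.cm_soma * 1e-3 / (pp.g_leak["soma"] * 1e-3)  # ms
        ts = integrate(cell, duration=200.0, dt=0.02, record="soma",
                       v_init=-60.0)
        v = ts.v_soma.astype(float) - pp.e_leak
        i0 = int(5 / ts.dt)
        i1 = int(15 / ts.dt)
        tau_fit = (i1 - i0) * ts.dt / np.log(v[i0] / v[i1])
        assert tau_fit == pytest.approx(tau_expect, rel=0.01)

    def test_convergence_under_step_halving(self, small_cell):
        # active 1 s simulation: halving dt changes V by < 0.5 mV RMS
        spec = [SynapseSpec(0, int(np.nonzero(
            small_cell.morph.subtree == "basal")[0][0]), 0.5, "exc",
            "perisomatic", "basal", 0, 1.0, "excitatory",
            g_ampa=3e-4, g_nmda=3e-4)]
        trains = {0: SpikeTrain(0, np.arange(100.0, 900.0, 40.0))}
        va = integrate(small_cell, spec, trains, duration=1000.0, dt=0.1,
                       record="soma", seed=0).v_soma.astype(float)
        vb = integrate(small_cell, spec, trains, duration=1000.0, dt=0.05,
                       record="soma", seed=0).v_soma.astype(float)
        rms = np.sqrt(np.mean((va - vb[1::2]) ** 2))
        assert rms < 0.5


class TestAttenuation:
    def test_soma_ratio_is_one(self, small_cell):
        assert measure_attenuation(small_cell, 0, 20.0) == pytest.approx(1.0)

    def test_monotone_along_unbranched_path(self, small_cell):
        # walk tuft tip -> soma; the ratio must not decrease toward soma
        m = small_cell.morph
        ratios = attenuation_map(small_cell, 20.0)
        c = int(np.nonzero(m.region == "tuft")[0][-1])
        path = []
        while c >= 0:
            path.append(c)
            c = m.parent[c]
        r = ratios[path]
        assert np.all(np.diff(r) >= -1e-9)

    def test_choice_of_frequency_insensitive(self, small_cell):
        r10 = attenuation_map(small_cell, 10.0)
        r20 = attenuation_map(small_cell, 20.0)
        # same ordering of compartments (qualitative robustness)
        assert np.corrcoef(np.argsort(np.argsort(r10)),
                           np.argsort(np.argsort(r20)))[0, 1] > 0.99

    def test_deciles_partition_equally(self, small_cell):
        ratios = attenuation_map(small_cell, 20.0)
        dec = electrotonic_deciles(small_cell.morph, ratios)
        for cls in ("apical", "basal"):
            table = dec[cls]
            counts = np.bincount(table[:, 1], minlength=10)
            assert counts.max() - counts.min() <= 1
            # decile 0 holds the largest (closest) ratios
            r0 = ratios[table[table[:, 1] == 0, 0]].mean()
            r9 = ratios[table[table[:, 1] == 9, 0]].mean()
            assert r0 > r9

    def test_deciles_tiebreak_matches_brute_force(self):
        m = Morphology([-1, 0, 1, 2], [10.0] * 4, [2.0] * 4,
                       ["soma", "basal", "basal", "basal"], [0, 1, 1, 1])
        ratios = np.array([1.0, 0.5, 0.5, 0.2])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = electrotonic_deciles(m, ratios, n_bins=3)["basal"]
        order = dict(dec)
        # equal ratios break ties by compartment id
        assert order[1] <= order[2]


class TestActiveCompetence:
    """The default desk-scale cell supports every regenerative event class."""

    def test_somatic_aps_overshoot(self, small_cell):
        ts = inject_step(small_cell, 1.5, 500.0, record="soma", pre=200.0)
        aps = detect_aps(ts.v_soma, ts.dt)
        assert aps.n >= 3
        assert ts.v_soma.max() > -10.0

    def test_nexus_ca_plateau_converts_spike_to_burst(self, small_cell):
        nx = small_cell.morph.nexus_index()
        ts = inject_step(small_cell, 0.9, 30.0, compartment=nx,
                         record="dendrites", pre=200.0, post=250.0)
        j = ts.column(nx)
        a = int(200 / ts.dt_rec)
        ca = detect_plateau(ts.v[a:, j], ts.i_ca[a:, j], ts.dt_rec,
                            kind="Ca")
        assert ca.n >= 1
        aps = detect_aps(ts.v_soma, ts.dt)
        sel = aps.onsets[(aps.onsets >= 200.0) & (aps.onsets < 280.0)]
        assert sel.size >= 2            # burst
        assert sel[1] - sel[0] <= 25.0

    def test_tuft_nmda_plateau(self, small_cell):
        m = small_cell.morph
        tgt = int(np.nonzero(m.region == "tuft")[0][-3])
        specs = [SynapseSpec(i, tgt, 0.5, "exc", "distal", "apical", 0,
                             1.0, "excitatory", g_ampa=4e-4, g_nmda=4e-4)
                 for i in range(20)]
        trains = {0: SpikeTrain(0, np.array([100.0, 115.0, 130.0]))}
        ts = integrate(small_cell, specs, trains, duration=400.0,
                       record="dendrites", seed=1)
        j = ts.column(tgt)
        ev = detect_plateau(ts.v[:, j], ts.i_nmda[:, j], ts.dt_rec,
                            kind="NMDA")
        assert ev.n >= 1
        assert (ev.offsets[0] - ev.onsets[0]) >= 20.0
        # and a dendritic Na+ transient accompanies the volley
        na = detect_na_spikes(ts.gna[:, j], ts.dt_rec, np.array([]))
        assert ts.gna.max() > 0.3

    def test_backpropagation_attenuates_into_tuft(self, small_cell):
        ts = inject_step(small_cell, 2.0, 3.0, record="dendrites",
                         pre=200.0, post=100.0)
        seg = slice(int(198 / ts.dt_rec), int(230 / ts.dt_rec))
        trunk = (ts.region == "apical_trunk") & (ts.path_dist < 50.0)
        tip = int(np.nonzero(ts.region == "tuft")[0][-1])
        assert ts.v[seg][:, trunk].max() > ts.v[seg, tip].max()

    def test_numerical_failure_reported(self, small_cell):
        # a non-finite input current must surface as a diagnosed failure,
        # not silently corrupt the traces
        n = int(100.0 / 0.1)
        series = np.zeros(n)
        series[500] = np.nan
        with pytest.raises(NumericalFailure):
            integrate(small_cell, duration=100.0, record="soma",
                      inj=(0, series))
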