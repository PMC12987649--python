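"""Cell assembly and simulation.

`Cell` binds a morphology to channel densities, passive parameters and Ca2+
dynamics, and precomputes the per-compartment arrays the integrator needs.
`integrate` expands synapse specs and presynaptic spike trains into release
events and runs the implicit branched-cable solver; `measure_attenuation`
implements the impedance method (frequency-domain solve on the passive
cell) used for electrotonic distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .channels import (CaDynamics, ChannelDensityMap, PassiveParams,
                       CHANNELS, CHANNEL_INDEX, VGATES, build_gate_tables,
                       default_densities, sk_zinf)
from .core import SpikeTrain
from .kernel import run_sim
from .morphology import Morphology, build_synthetic_morphology
from .synapses import AMPA, GABA_A, NMDA, STP_SETS, SynapseSpec

__all__ = ["Cell", "TraceSet", "assemble_cell", "integrate", "inject_step",
           "measure_attenuation", "attenuation_map", "electrotonic_deciles",
           "NumericalFailure"]

FARADAY = 96485.0


class NumericalFailure(RuntimeError):
    """The membrane state became non-finite during integration."""


@dataclass
class TraceSet:
    """Recorded time series of one simulation.

    ``v``, ``gna``, ``i_nmda``, ``i_ca`` are (n_frames, n_recorded) float32
    arrays at resolution ``dt_rec``; ``v_soma`` is the somatic voltage at
    the full integration step ``dt``.  ``gna`` is the NaT conductance
    density in mS/cm^2; currents are in nA, signed (inward negative).
    """
    dt: float
    dt_rec: float
    comp_ids: np.ndarray
    region: np.ndarray
    subtree: np.ndarray
    path_dist: np.ndarray
    v: np.ndarray
    gna: np.ndarray
    i_nmda: np.ndarray
    i_ca: np.ndarray
    v_soma: np.ndarray
    duration: float

    @property
    def t(self) -> np.ndarray:
        """Frame times (ms) of the per-compartment records."""
        return self.dt_rec * (1 + np.arange(self.v.shape[0]))

    @property
    def t_soma(self) -> np.ndarray:
        return self.dt * (1 + np.arange(self.v_soma.size))

    def column(self, comp: int) -> int:
        j = np.nonzero(self.comp_ids == comp)[0]
        if j.size == 0:
            raise KeyError(f"compartment {comp} was not recorded")
        return int(j[0])


class Cell:
    """A morphology with membrane mechanisms, ready to integrate."""

    def __init__(self, morph: Morphology, densities: ChannelDensityMap,
                 passive: PassiveParams, ca: CaDynamics,
                 ena: float = 50.0, ek: float = -85.0, eh: float = -45.0):
        densities.validate_roster()
        self.morph = morph
        self.densities = densities
        self.passive = passive
        self.ca = ca
        self.ena, self.ek, self.eh = ena, ek, eh
        n = morph.n_comp
        area = morph.area  # cm^2
        self.area = area
        # nF: uF/cm^2 * cm^2 * 1e3, so that cm*dV/dt is in nA
        self.cm = np.array([passive.cm_of(r) for r in morph.region]) \
            * area * 1e3
        self.g_leak = np.array([passive.g_leak[r] for r in morph.region]) \
            * area * 1e3  # mS/cm^2 * cm^2 -> mS -> *1e3 uS
        # axial conductance to parent (uS)
        g_ax = np.zeros(n)
        for c in range(1, n):
            p = morph.parent[c]
            r_half = 0.0
            for k in (c, p):
                radius_cm = 0.5 * morph.diam[k] * 1e-4
                l_cm = 0.5 * morph.length[k] * 1e-4
                r_half += passive.ra * l_cm / (np.pi * radius_cm ** 2)  # ohm
            g_ax[c] = 1e6 / r_half
        self.g_ax = g_ax
        # channel conductances (uS): density mS/cm^2 * cm^2 * 1e3
        gbar = np.zeros((len(CHANNELS), n))
        for ci, (name, _, _) in enumerate(CHANNELS):
            for c in range(n):
                gbar[ci, c] = densities.get(morph.region[c], name) \
                    * area[c] * 1e3
        self.gbar = gbar
        # NaT conductance-density factor: uS -> mS/cm^2
        self.na_fac = gbar[CHANNEL_INDEX["NaT"]] / (area * 1e3)
        # Ca influx factor: cai' (mM/ms) = -kca * I_Ca(nA), from the
        # shell model 1e4*ica[mA/cm^2]*gamma/(2*F*depth[um])
        self.kca = 1e4 * ca.gamma * (1e-6 / area) / (2 * FARADAY * ca.depth)

    @property
    def n_comp(self) -> int:
        return self.morph.n_comp

    def initial_state(self, v_init: float):
        n = self.n_comp
        gates = np.empty((len(VGATES), n))
        for g, (_, fn) in enumerate(VGATES):
            inf, _ = fn(np.full(n, float(v_init)))
            gates[g] = inf
        cai = np.full(n, self.ca.min_cai)
        z = np.full(n, float(sk_zinf(self.ca.min_cai)))
        return gates, z, cai


def assemble_cell(morph: Morphology | None = None,
                  densities: ChannelDensityMap | None = None,
                  passive: PassiveParams | None = None,
                  ca: CaDynamics | None = None) -> Cell:
    """Assemble the default cell (synthetic morphology, default densities)."""
    return Cell(morph if morph is not None else build_synthetic_morphology(),
                densities if densities is not None else default_densities(),
                passive if passive is not None else PassiveParams(),
                ca if ca is not None else CaDynamics())


def _expand_events(pop: list[SynapseSpec], trains: dict[int, SpikeTrain],
                   dt: float, n_steps: int, seed: int):
    """Per-contact release events (step, synapse index, released flag),
    sorted by delivery step, for one synapse population."""
    rng = np.random.default_rng(seed)
    steps, syns, rels = [], [], []
    for j, s in enumerate(pop):
        tr = trains.get(s.node_id)
        if tr is None or len(tr) == 0:
            continue
        st = np.round(tr.times / dt).astype(np.int64)
        st = st[(st >= 0) & (st < n_steps)]
        rel = (rng.random(st.size) < s.p_release).astype(np.int8)
        steps.append(st)
        syns.append(np.full(st.size, j, dtype=np.int64))
        rels.append(rel)
    if steps:
        steps = np.concatenate(steps)
        syns = np.concatenate(syns)
        rels = np.concatenate(rels)
        order = np.argsort(steps, kind="stable")
        return steps[order], syns[order], rels[order]
    z = np.zeros(0, dtype=np.int64)
    return z, z.copy(), np.zeros(0, dtype=np.int8)


def integrate(cell: Cell, specs: list[SynapseSpec] | None = None,
              trains: dict[int, SpikeTrain] | None = None,
              duration: float = 1000.0, dt: float = 0.1,
              record: str | np.ndarray = "dendrites", rec_every: int = 2,
              seed: int = 0, v_init: float = -80.0,
              inj: tuple[int, np.ndarray] | None = None,
              exc_trains: dict | None = None,
              inh_trains: dict | None = None) -> TraceSet:
    """Run the implicit cable solve and record traces.

    ``trains`` maps presynaptic node id -> SpikeTrain shared by exc and inh
    populations; use ``exc_trains``/``inh_trains`` to key them separately
    (inhibitory node ids live in their own namespace).  ``inj`` is a
    (compartment, per-step current nA) pair.  Records V, NaT conductance
    density, NMDA current and total Ca2+ current for the selected
    compartments every ``rec_every`` steps, and somatic V at full
    resolution.
    """
    morph = cell.morph
    n_steps = int(round(duration / dt))
    if isinstance(record, str):
        if record == "dendrites":
            rec_idx = np.nonzero(morph.dendritic_mask())[0]
        elif record == "all":
            rec_idx = np.arange(morph.n_comp)
        elif record == "soma":
            rec_idx = np.array([morph.soma_index()])
        else:
            raise ValueError(f"unknown record selection {record!r}")
    else:
        rec_idx = np.asarray(record, dtype=int)
    specs = specs or []
    trains = trains or {}
    e_specs = [s for s in specs if s.kind == "exc"]
    i_specs = [s for s in specs if s.kind == "inh"]
    e_tr = exc_trains if exc_trains is not None else trains
    i_tr = inh_trains if inh_trains is not None else trains
    rng_seed = int(seed) % (2 ** 31)
    es, ey, er = _expand_events(e_specs, e_tr, dt, n_steps, rng_seed)
    js, jy, jr = _expand_events(i_specs, i_tr, dt, n_steps, rng_seed + 1)

    e_comp = np.array([s.comp for s in e_specs], dtype=np.int64)
    e_gampa = np.array([s.g_ampa * s.weight for s in e_specs])
    e_gnmda = np.array([s.g_nmda * s.weight for s in e_specs])
    i_comp = np.array([s.comp for s in i_specs], dtype=np.int64)
    i_ggaba = np.array([s.g_gaba * s.weight for s in i_specs])
    i_cls = np.array([0 if s.stp == "perisomatic_inh" else 1
                      for s in i_specs], dtype=np.int64)

    stp_e = STP_SETS["excitatory"]
    stp_p = STP_SETS["perisomatic_inh"]
    stp_d = STP_SETS["dendritic_inh"]

    tables, vmin, dvinv = build_gate_tables(dt)
    gates, z, cai = cell.initial_state(v_init)
    v = np.full(cell.n_comp, float(v_init))

    n_frames = n_steps // rec_every
    k = rec_idx.size
    out_v = np.empty((n_frames, k), dtype=np.float32)
    out_gna = np.empty((n_frames, k), dtype=np.float32)
    out_inmda = np.empty((n_frames, k), dtype=np.float32)
    out_ica = np.empty((n_frames, k), dtype=np.float32)
    out_vsoma = np.empty(n_steps, dtype=np.float32)

    if inj is None:
        inj_comp, inj_series = -1, np.zeros(1)
    else:
        inj_comp, inj_series = inj
        inj_series = np.asarray(inj_series, dtype=float)
        if inj_series.size != n_steps:
            raise ValueError("injection series length must equal n_steps")

    def onsteps(rec):
        return max(int(round(rec.t_peak / dt)), 1)

    bad = run_sim(
        morph.parent.astype(np.int64), cell.g_ax, cell.cm / dt, cell.g_leak,
        cell.passive.e_leak,
        cell.gbar, cell.na_fac,
        tables, vmin, dvinv,
        gates, z, cai,
        cell.kca, 1.0 - np.exp(-dt / np.full(cell.n_comp, cell.ca.decay)),
        cell.ca.min_cai, cell.ca.cao,
        cell.ena, cell.ek, cell.eh,
        v, dt, n_steps, 1.0 - np.exp(-dt / 1.0),
        e_comp, e_gampa, e_gnmda,
        AMPA.alpha / (AMPA.alpha + AMPA.beta),
        np.exp(-dt * (AMPA.alpha + AMPA.beta)), np.exp(-dt * AMPA.beta),
        onsteps(AMPA),
        NMDA.alpha / (NMDA.alpha + NMDA.beta),
        np.exp(-dt * (NMDA.alpha + NMDA.beta)), np.exp(-dt * NMDA.beta),
        onsteps(NMDA),
        1.0 - np.exp(-dt / stp_e.tau1), 1.0 - np.exp(-dt / stp_e.tau2),
        stp_e.d1, stp_e.d2,
        es, ey, er,
        i_comp, i_ggaba, i_cls, GABA_A.e_rev,
        GABA_A.alpha / (GABA_A.alpha + GABA_A.beta),
        np.exp(-dt * (GABA_A.alpha + GABA_A.beta)), np.exp(-dt * GABA_A.beta),
        onsteps(GABA_A),
        np.array([1.0 - np.exp(-dt / stp_p.tau1),
                  1.0 - np.exp(-dt / stp_d.tau1)]),
        np.array([1.0 - np.exp(-dt / stp_p.tau2),
                  1.0 - np.exp(-dt / stp_d.tau2)]),
        np.array([stp_p.d1, stp_d.d1]), np.array([stp_p.d2, stp_d.d2]),
        js, jy, jr,
        inj_comp, inj_series,
        rec_every, rec_idx.astype(np.int64), morph.soma_index(),
        out_v, out_gna, out_inmda, out_ica, out_vsoma)
    if bad >= 0:
        raise NumericalFailure(
            f"non-finite membrane state at t = {bad * dt:.1f} ms")
    return TraceSet(dt, dt * rec_every, rec_idx,
                    morph.region[rec_idx], morph.subtree[rec_idx],
                    morph.path_dist[rec_idx],
                    out_v, out_gna, out_inmda, out_ica, out_vsoma, duration)


def inject_step(cell: Cell, amplitude: float, duration: float,
                compartment: int | None = None, pre: float = 200.0,
                post: float = 200.0, dt: float = 0.1,
                **kwargs) -> TraceSet:
    """Square current step of ``amplitude`` nA into a compartment.

    The trace covers pre + duration + post ms; the step occupies
    [pre, pre + duration).
    """
    comp = cell.morph.soma_index() if compartment is None else compartment
    total = pre + duration + post
    n_steps = int(round(total / dt))
    series = np.zeros(n_steps)
    i0 = int(round(pre / dt))
    i1 = int(round((pre + duration) / dt))
    series[i0:i1] = amplitude
    return integrate(cell, duration=total, dt=dt, inj=(comp, series), **kwargs)


# ------------------------------------------------------- impedance method
def _passive_system(cell: Cell, omega: float):
    """Sparse (G + j*omega*C) matrix of the passive cell (uS, uF, 1/ms)."""
    morph = cell.morph
    n = morph.n_comp
    diag = cell.g_leak.astype(complex) + 1j * omega * cell.cm
    rows, cols, vals = [], [], []
    for c in range(1, n):
        p = morph.parent[c]
        g = cell.g_ax[c]
        diag[c] += g
        diag[p] += g
        rows += [c, p]
        cols += [p, c]
        vals += [-g, -g]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    return sp.csc_matrix((vals, (rows, cols)), shape=(n, n))


def attenuation_map(cell: Cell, f: float = 20.0) -> np.ndarray:
    """Soma/local voltage-transfer ratio at ``f`` Hz for every compartment.

    The impedance method on the passive-linearized cell: a subthreshold
    sinusoidal current at compartment c produces local amplitude |Z_cc| and
    somatic amplitude |Z_sc|; the attenuation ratio is |Z_sc|/|Z_cc|, 1 at
    the soma and decreasing with electrotonic distance.
    """
    if f < 0:
        raise ValueError("frequency must be non-negative")
    omega = 2.0 * np.pi * f / 1000.0  # rad/ms
    A = _passive_system(cell, omega)
    lu = spla.splu(A)
    n = cell.n_comp
    Z = lu.solve(np.eye(n, dtype=complex))  # columns: response to unit I
    soma = cell.morph.soma_index()
    return np.abs(Z[soma, :]) / np.abs(np.diagonal(Z))


def measure_attenuation(cell: Cell, compartment: int, f: float = 20.0) -> float:
    """Attenuation ratio (0, 1] between one compartment and the soma."""
    return float(attenuation_map(cell, f)[compartment])


def electrotonic_deciles(morph: Morphology, ratios: np.ndarray,
                         n_bins: int = 10) -> dict[str, np.ndarray]:
    """Group dendritic compartments into electrotonic-distance deciles.

    Within each dendrite class (apical, basal), compartments are ranked by
    attenuation ratio (descending: decile 0 is electrotonically closest to
    the soma) and split into ``n_bins`` equal-count groups; ties are broken
    by compartment id.  Returns {class: array of (compartment, decile)}.
    Classes with fewer than ``n_bins`` compartments fall back to fewer bins
    with a warning.
    """
    out = {}
    for cls in ("apical", "basal"):
        comps = np.nonzero(morph.subtree == cls)[0]
        r = np.asarray(ratios)[comps]
        bins = n_bins
        if comps.size < n_bins:
            warnings.warn(f"only {comps.size} {cls} compartments; "
                          f"using {comps.size} bins")
            bins = max(comps.size, 1)
        order = np.lexsort((comps, -r))  # descending ratio, id tiebreak
        dec = np.empty(comps.size, dtype=int)
        # equal-count split
        edges = (np.arange(comps.size) * bins) // comps.size
        dec[order] = edges
        out[cls] = np.column_stack([comps, dec])
    return out
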