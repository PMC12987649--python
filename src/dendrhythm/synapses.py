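"""Conductance-based synapses and their placement on the morphology.

Excitatory transmission is AMPA+NMDA (with voltage-dependent Mg2+ block),
inhibitory transmission GABA_A.  Each receptor follows a two-state gating
scheme r' = alpha*Tmax*ON*(1-r) - beta*r, where the transmitter pulse ON is
held for the analytic time-to-peak of the equivalent dual-exponential, so a
single activation peaks at t_peak = tau_r*tau_d/(tau_d - tau_r) *
ln(tau_d/tau_r).  Presynaptic release is Bernoulli per contact, and a
two-factor short-term depression D = D1*D2 scales each released event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
import pandas as pd

from .morphology import Morphology

__all__ = [
    "ReceptorKinetics", "KineticParams", "STPParams", "STPState",
    "SynapseSpec", "ProtocolError", "AMPA", "NMDA", "GABA_A", "STP_SETS",
    "mg_block", "stp_step", "release_gate", "draw_weights",
    "place_excitatory_synapses", "place_inhibitory_synapses",
    "stp_train_induction", "synapse_table", "syn_current",
]


class ProtocolError(RuntimeError):
    """A measurement protocol could not be completed as specified."""


@dataclass(frozen=True)
class ReceptorKinetics:
    """Rise/decay time constants (ms) and reversal potential (mV)."""
    name: str
    tau_rise: float
    tau_decay: float
    e_rev: float

    def __post_init__(self):
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need decay > rise > 0")

    @property
    def beta(self) -> float:
        """Closing rate (1/ms); sets the decay time constant."""
        return 1.0 / self.tau_decay

    @property
    def alpha(self) -> float:
        """Opening rate alpha*Tmax (1/ms) during the transmitter pulse."""
        return 1.0 / self.tau_rise - 1.0 / self.tau_decay

    @property
    def t_peak(self) -> float:
        """Time of the conductance peak after a single activation (ms)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def r_peak(self) -> float:
        """Gating value reached at t_peak from r = 0."""
        rinf = self.alpha / (self.alpha + self.beta)
        return rinf * (1.0 - math.exp(-self.t_peak / self.tau_rise))


AMPA = ReceptorKinetics("AMPA", 0.6, 6.9, 0.0)
NMDA = ReceptorKinetics("NMDA", 3.7, 125.0, 0.0)
GABA_A = ReceptorKinetics("GABA_A", 0.5, 6.8, -75.0)

#: Mg2+ block constants of s(V) = 1/(1 + eta*exp(-gamma*V)).
MG_ETA = 0.33
MG_GAMMA = 0.06


@dataclass(frozen=True)
class KineticParams:
    """Receptor bundle used by one synapse class."""
    receptors: tuple = (AMPA, NMDA)
    mg_eta: float = MG_ETA
    mg_gamma: float = MG_GAMMA


def mg_block(v):
    """Voltage-dependent Mg2+ unblock s(V) = [1 + 0.33 exp(-0.06 V)]^-1."""
    return 1.0 / (1.0 + MG_ETA * np.exp(-MG_GAMMA * np.asarray(v, dtype=float)))


# --------------------------------------------------------------------- STP
@dataclass(frozen=True)
class STPParams:
    """Two-factor short-term depression: fast (tau1, d1) and slow (tau2, d2).

    Each factor recovers toward 1 with its time constant and is multiplied
    by its per-stimulus constant d <= 1 after every presynaptic event; the
    effective depression is the product D1*D2.  Setting d = 1 disables a
    factor (the dendritic inhibitory class uses only the fast factor).
    """
    tau1: float
    d1: float
    tau2: float
    d2: float

    def __post_init__(self):
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("recovery time constants must be positive")
        if not (0 < self.d1 <= 1 and 0 < self.d2 <= 1):
            raise ValueError("depression constants must lie in (0, 1]")


#: Calibrated parameter sets (tau1 ms, d1, tau2 ms, d2).
STP_SETS = {
    "excitatory": STPParams(35.0, 0.95, 250.0, 0.8),
    "perisomatic_inh": STPParams(40.0, 0.7, 500.0, 0.7),
    "dendritic_inh": STPParams(200.0, 0.8, 1.0, 1.0),
}


@dataclass
class STPState:
    """Depression factors and the time of the last update."""
    D1: float = 1.0
    D2: float = 1.0
    t_last: float = -np.inf


def stp_step(state: STPState, params: STPParams, t_event: float):
    """Advance depression to a presynaptic event at ``t_event``.

    Each factor first recovers as D <- 1 - (1 - D)*exp(-dt/tau); the
    product D1*D2 at that point is the effective depression applied to this
    event's PSC; afterwards each factor is multiplied by its d.  Returns
    ``(new_state, effective_D)``.
    """
    if t_event < state.t_last:
        raise ValueError("events must be processed in time order")
    dt = t_event - state.t_last
    rec1 = 1.0 - (1.0 - state.D1) * math.exp(-dt / params.tau1)
    rec2 = 1.0 - (1.0 - state.D2) * math.exp(-dt / params.tau2)
    eff = min(rec1 * rec2, 1.0)
    new = STPState(rec1 * params.d1, rec2 * params.d2, t_event)
    return new, eff


def release_gate(p: float, n_events: int, seed: int | None = None) -> np.ndarray:
    """Bernoulli(p) success per presynaptic event."""
    if not (0.0 < p <= 1.0):
        raise ValueError("release probability must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    return rng.random(n_events) < p


def syn_current(r: float, v: float, g_max: float, receptor: ReceptorKinetics,
                D: float = 1.0, w: float = 1.0) -> float:
    """Instantaneous synaptic current (nA) of one receptor.

    I = w * G * (V - E) with G = g_max*D*r (times the Mg2+ unblock s(V) for
    NMDA); g_max in uS, V in mV.
    """
    if not (0.0 <= r <= 1.0):
        raise ValueError("gating variable r must lie in [0, 1]")
    g = g_max * D * r
    if receptor.name == "NMDA":
        g *= float(mg_block(v))
    return w * g * (v - receptor.e_rev)


# ----------------------------------------------------------------- specs
@dataclass
class SynapseSpec:
    """One synaptic contact on the morphology.

    ``zone`` is 'perisomatic' for contacts on the soma or within 100 um path
    distance, else 'distal'.  Conductances are in uS (g_ampa/g_nmda for
    excitatory contacts, g_gaba for inhibitory ones); ``stp`` names the
    short-term-depression parameter set in :data:`STP_SETS`.
    """
    syn_id: int
    comp: int
    pos: float
    kind: str                  # 'exc' | 'inh'
    zone: str                  # 'perisomatic' | 'distal'
    subtree: str               # 'soma' | 'basal' | 'apical'
    node_id: int
    p_release: float
    stp: str
    g_ampa: float = 0.0
    g_nmda: float = 0.0
    g_gaba: float = 0.0
    weight: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.p_release <= 1.0):
            raise ValueError("release probability must lie in (0, 1]")
        if self.kind not in ("exc", "inh"):
            raise ValueError("kind must be 'exc' or 'inh'")


def synapse_table(specs: list[SynapseSpec]) -> pd.DataFrame:
    """Tidy table of synapse specs (one row per contact)."""
    return pd.DataFrame([{
        "synapse_id": s.syn_id, "compartment_id": s.comp, "pos": s.pos,
        "class": s.kind, "zone": s.zone, "subtree": s.subtree,
        "node_id": s.node_id, "p_release": s.p_release, "stp": s.stp,
        "g_ampa_uS": s.g_ampa, "g_nmda_uS": s.g_nmda, "g_gaba_uS": s.g_gaba,
    } for s in specs])


# ------------------------------------------------------------- placement
class _BranchIndex:
    """Arc-length lookup within each unbranched section of a morphology."""

    def __init__(self, morph: Morphology):
        self.morph = morph
        self.comps: dict[int, np.ndarray] = {}
        self.cum: dict[int, np.ndarray] = {}
        for b in np.unique(morph.branch_id):
            idx = np.nonzero(morph.branch_id == b)[0]
            self.comps[int(b)] = idx
            self.cum[int(b)] = np.cumsum(morph.length[idx])

    def length(self, b: int) -> float:
        return float(self.cum[b][-1])

    def locate(self, b: int, arc: float) -> tuple[int, float]:
        """(compartment, position 0-1) at arc length ``arc`` on branch b."""
        cum = self.cum[b]
        arc = min(max(arc, 0.0), cum[-1] - 1e-9)
        k = int(np.searchsorted(cum, arc, side="right"))
        prev = cum[k - 1] if k > 0 else 0.0
        seg_len = cum[k] - prev
        return int(self.comps[b][k]), float((arc - prev) / seg_len)


def _path_dist_from(morph: Morphology, src: int) -> np.ndarray:
    """Path distance (um) from compartment ``src`` to all compartments."""
    n = morph.n_comp
    ch = morph.children()
    dist = np.full(n, np.inf)
    dist[src] = 0.0
    # walk up to root accumulating, then relax downward in Hines order
    c = src
    while morph.parent[c] >= 0:
        p = morph.parent[c]
        dist[p] = dist[c] + 0.5 * morph.length[c] + 0.5 * morph.length[p]
        c = p
    for i in range(n):
        for j in ch[i]:
            step = 0.5 * morph.length[i] + 0.5 * morph.length[j]
            if dist[i] + step < dist[j]:
                dist[j] = dist[i] + step
    return dist


def _zone_of(morph: Morphology, comp: int, radius: float = 100.0) -> str:
    if morph.region[comp] == "soma" or morph.path_dist[comp] <= radius:
        return "perisomatic"
    return "distal"


def place_excitatory_synapses(morph: Morphology, density: float = 2.16,
                              seed: int | None = None,
                              divergence: tuple = (2, 8),
                              p_range: tuple = (0.16, 0.9),
                              cluster_span: tuple = (5.0, 10.0),
                              group_size: int = 100,
                              group_span: float = 100.0) -> list[SynapseSpec]:
    """Place excitatory contacts at ``density`` per um of apical/basal cable.

    Each presynaptic node makes 2-8 contacts (uniform) on a single branch
    within a 5-10 um cluster, with a per-node release probability uniform on
    [0.16, 0.9].  Nodes are organised into functional groups of
    ``group_size``; a group's clusters land within ``group_span`` um path
    distance of a common anchor.  Per-subtree totals are exactly
    round(density * cable length).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    branches = _BranchIndex(morph)
    specs: list[SynapseSpec] = []
    node_id = 0
    syn_id = 0
    for subtree in ("apical", "basal"):
        total = int(round(density * morph.total_length(subtree)))
        sub_mask = morph.subtree == subtree
        sub_comps = np.nonzero(sub_mask)[0]
        if total == 0 or sub_comps.size == 0:
            continue
        placed = 0
        in_group = 0
        candidate_branches = None
        branch_w = None
        while placed < total:
            if in_group == 0 or candidate_branches is None:
                # new functional group: anchor + 100-um neighborhood
                anchor = int(rng.choice(sub_comps,
                                        p=morph.length[sub_comps]
                                        / morph.length[sub_comps].sum()))
                near = _path_dist_from(morph, anchor) <= group_span
                cand = np.unique(morph.branch_id[near & sub_mask])
                if cand.size == 0:
                    cand = np.unique(morph.branch_id[sub_mask])
                candidate_branches = cand
                branch_w = np.array([branches.length(int(b)) for b in cand])
                branch_w = branch_w / branch_w.sum()
            k = int(rng.integers(divergence[0], divergence[1] + 1))
            k = min(k, total - placed)
            b = int(rng.choice(candidate_branches, p=branch_w))
            span = float(rng.uniform(*cluster_span))
            center = float(rng.uniform(0.0, branches.length(b)))
            p_rel = float(rng.uniform(*p_range))
            for _ in range(k):
                arc = center + float(rng.uniform(-span / 2, span / 2))
                comp, pos = branches.locate(b, arc)
                specs.append(SynapseSpec(
                    syn_id, comp, pos, "exc", _zone_of(morph, comp),
                    subtree, node_id, p_rel, "excitatory"))
                syn_id += 1
            placed += k
            node_id += 1
            in_group = (in_group + 1) % group_size
    return specs


#: Divergence (mean, sd) and release probability (mean, sd) per inhibitory
#: population, from paired-recording literature.
INH_POPULATIONS = {
    "perisomatic": {"divergence": (2.8, 1.9), "p_release": (0.88, 0.05)},
    "basal": {"divergence": (2.7, 1.6), "p_release": (0.72, 0.10)},
    "apical": {"divergence": (12.0, 3.0), "p_release": (0.30, 0.08)},
}


def place_inhibitory_synapses(morph: Morphology, density: float = 0.22,
                              n_somatic: int = 150,
                              seed: int | None = None,
                              radius: float = 100.0) -> list[SynapseSpec]:
    """Place inhibitory contacts: ``n_somatic`` on the soma plus
    round(density * cable) per dendritic subtree, uniform along the cable.

    Contacts are tagged perisomatic (path distance <= ``radius`` um, PV-like)
    or distal (SOM-like); divergence per presynaptic node and release
    probability follow the per-population statistics in
    :data:`INH_POPULATIONS` (divergence rounded, clipped >= 1).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    # contact sites first
    sites: list[tuple[int, float, str]] = []  # comp, pos, subtree
    soma = morph.soma_index()
    for _ in range(n_somatic):
        sites.append((soma, float(rng.random()), "soma"))
    for subtree in ("apical", "basal"):
        total = int(round(density * morph.total_length(subtree)))
        comps = np.nonzero(morph.subtree == subtree)[0]
        if total == 0 or comps.size == 0:
            continue
        w = morph.length[comps] / morph.length[comps].sum()
        chosen = rng.choice(comps, size=total, p=w)
        for c in chosen:
            sites.append((int(c), float(rng.random()), subtree))
    # then group sites into presynaptic nodes per population
    pops: dict[str, list[int]] = {"perisomatic": [], "basal": [], "apical": []}
    for i, (comp, pos, subtree) in enumerate(sites):
        if _zone_of(morph, comp, radius) == "perisomatic":
            pops["perisomatic"].append(i)
        else:
            pops[subtree].append(i)
    specs: list[SynapseSpec] = []
    node_id = 0
    for pop, idx in pops.items():
        stats = INH_POPULATIONS[pop]
        stp = "perisomatic_inh" if pop == "perisomatic" else "dendritic_inh"
        zone = "perisomatic" if pop == "perisomatic" else "distal"
        order = rng.permutation(len(idx))
        k = 0
        while k < len(idx):
            div = max(int(round(rng.normal(*stats["divergence"]))), 1)
            members = [idx[j] for j in order[k:k + div]]
            p_rel = float(np.clip(rng.normal(*stats["p_release"]), 0.01, 1.0))
            for i in members:
                comp, pos, subtree = sites[i]
                specs.append(SynapseSpec(
                    i, comp, pos, "inh", zone, subtree, node_id, p_rel, stp))
            node_id += 1
            k += div
    specs.sort(key=lambda s: s.syn_id)
    return specs


# --------------------------------------------------------------- weights
EXC_G_MEAN = 2.0e-4   # uS (0.2 nS), mean of the log-normal itself
EXC_G_SD = 3.45e-4    # uS (0.345 nS)
INH_G = 1.0e-3        # uS (1 nS), fixed


def draw_weights(specs: list[SynapseSpec], seed: int | None = None,
                 mean: float = EXC_G_MEAN, sd: float = EXC_G_SD,
                 nmda_ratio: float = 1.0,
                 inh_g: float = INH_G) -> list[SynapseSpec]:
    """Assign maximal conductances.

    Excitatory AMPA conductances are log-normal with the given distribution
    mean and SD (moment matching on the log-normal itself); NMDA conductance
    is ``nmda_ratio`` times the AMPA value of the same contact.  Inhibitory
    conductances are fixed at 1 nS.  Returns new spec objects.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    out = []
    for s in specs:
        if s.kind == "exc":
            g = float(rng.lognormal(mu, math.sqrt(sigma2)))
            out.append(replace(s, g_ampa=g, g_nmda=nmda_ratio * g))
        else:
            out.append(replace(s, g_gaba=inh_g))
    return out


# --------------------------------------------------- STP train induction
def _simulate_clamp_psc(receptors, stp: STPParams, times, hold: float,
                        g_max: float, dt: float):
    """PSC trace (nA) under voltage clamp for a train of full releases."""
    n = int((times[-1] + 8 * max(r.tau_decay for r in receptors)) / dt)
    t = dt * np.arange(n)
    current = np.zeros(n)
    state = STPState()
    for rec in receptors:
        r = 0.0
        amp = 1.0
        on_left = 0
        evt = 0
        st = STPState()
        scale = float(mg_block(hold)) if rec.name == "NMDA" else 1.0
        rinf = rec.alpha / (rec.alpha + rec.beta)
        on_fac = math.exp(-dt * (rec.alpha + rec.beta))
        off_fac = math.exp(-dt * rec.beta)
        on_steps = max(int(round(rec.t_peak / dt)), 1)
        for k in range(n):
            while evt < len(times) and times[evt] <= t[k] + 1e-9:
                st, amp = stp_step(st, stp, times[evt])
                on_left = on_steps
                evt += 1
            if on_left > 0:
                r = rinf + (r - rinf) * on_fac
                on_left -= 1
            else:
                r *= off_fac
            current[k] += g_max * amp * r * scale * (hold - rec.e_rev)
    return t, current


def stp_train_induction(stp: STPParams | str, n_pulses: int = 8,
                        f: float = 50.0, hold: float = -70.0,
                        receptors: tuple | None = None,
                        g_max: float = 5e-4, dt: float = 0.025,
                        mode: str = "psc") -> float:
    """Short-term-plasticity train-induction value.

    Applies ``n_pulses`` at ``f`` Hz under voltage clamp at ``hold`` mV,
    measures per-pulse PSC peak magnitudes P_k, and returns
    (mean(P6, P7, P8) - P1) / max(P).  ``mode='depression_only'`` replaces
    the PSC peaks by the bare depression sequence D_k (no kinetic
    summation), the calibration reference for the printed induction values.
    """
    if isinstance(stp, str):
        stp = STP_SETS[stp]
    if n_pulses < 8:
        raise ProtocolError("the induction protocol needs at least 8 pulses")
    period = 1000.0 / f
    times = period * np.arange(n_pulses)
    if mode == "depression_only":
        state = STPState()
        amps = []
        for tt in times:
            state, eff = stp_step(state, stp, float(tt))
            amps.append(eff)
        amps = np.asarray(amps)
    elif mode == "psc":
        receptors = receptors or (AMPA, NMDA)
        t, cur = _simulate_clamp_psc(receptors, stp, times, hold, g_max, dt)
        mag = np.abs(cur)
        amps = []
        for k, tt in enumerate(times):
            t1 = times[k + 1] if k + 1 < len(times) else tt + period
            sel = (t >= tt) & (t < t1)
            pk = mag[sel].max()
            if pk <= 0:
                raise ProtocolError(f"no detectable PSC for pulse {k + 1}")
            amps.append(pk)
        amps = np.asarray(amps)
    else:
        raise ValueError("mode must be 'psc' or 'depression_only'")
    return float((amps[5:8].mean() - amps[0]) / amps.max())
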