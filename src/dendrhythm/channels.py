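"""Hodgkin-Huxley channel gating and per-region density configuration.

The active roster is the classic L5 pyramidal set: fast-inactivating Na+
(NaT), persistent Na+ (NaP), h-current (Ih), muscarinic K+ (Im), slow- and
fast-inactivating K+ (KPst, KTst), fast non-inactivating K+ (SKv3.1), high-
and low-voltage-activated Ca2+ (CaHVA, CaLVA), and Ca2+-activated K+ (SK).
Gating functions follow the widely used L5 pyramidal model family; peak
densities are per-region configuration with tunable defaults.

Units: voltages mV, times ms, densities mS/cm^2 in the public map
(converted internally), Ca2+ concentration mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CHANNELS", "VGATES", "gate_inf_tau", "build_gate_tables",
           "ChannelDensityMap", "PassiveParams", "CaDynamics",
           "default_densities", "DENDRITE_CHANNELS"]

_Q10_23_13 = 2.3 ** 1.3  # 2.3^((34-21)/10), acute-slice to body temperature


def _vtrap(x, y):
    """x/(1-exp(-x/y)) with the removable singularity at x=0 patched."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(x / y) < 1e-6, y * (1 + x / (2 * y)),
                       x / (1 - np.exp(-np.clip(x / y, -500, 500))))
    return out


def _nat_m(v):
    a = 0.182 * _vtrap(v + 32.0, 6.0)
    b = 0.124 * _vtrap(-v - 32.0, 6.0)
    return a / (a + b), (1.0 / (a + b)) / _Q10_23_13


def _nat_h(v):
    a = 0.015 * _vtrap(-v - 60.0, 6.0)
    b = 0.015 * _vtrap(v + 60.0, 6.0)
    return a / (a + b), (1.0 / (a + b)) / _Q10_23_13


def _nap_m(v):
    inf = 1.0 / (1.0 + np.exp(-(v + 52.6) / 4.6))
    a = 0.182 * _vtrap(v + 38.0, 6.0)
    b = 0.124 * _vtrap(-v - 38.0, 6.0)
    return inf, 6.0 / (a + b) / _Q10_23_13


def _nap_h(v):
    inf = 1.0 / (1.0 + np.exp((v + 48.8) / 10.0))
    a = 2.88e-6 * _vtrap(-v - 17.0, 4.63)
    b = 6.94e-6 * _vtrap(v + 64.4, 2.63)
    return inf, 1.0 / (a + b) / _Q10_23_13


def _ih_m(v):
    # alpha = 0.00643*(v+154.9)/(exp((v+154.9)/11.9)-1)
    a = 0.001 * 6.43 * _vtrap(-(v + 154.9), 11.9)
    b = 0.001 * 193.0 * np.exp(v / 33.1)
    return a / (a + b), 1.0 / (a + b)


def _im_m(v):
    a = 3.3e-3 * np.exp(0.1 * (v + 35.0))
    b = 3.3e-3 * np.exp(-0.1 * (v + 35.0))
    return a / (a + b), (1.0 / (a + b)) / _Q10_23_13


def _kpst_m(v):
    vs = v + 10.0
    inf = 1.0 / (1.0 + np.exp(-(vs + 1.0) / 12.0))
    tau = np.where(vs < -50.0,
                   1.25 + 175.03 * np.exp(0.026 * vs),
                   1.25 + 13.0 * np.exp(-0.026 * vs)) / _Q10_23_13
    return inf, tau


def _kpst_h(v):
    vs = v + 10.0
    inf = 1.0 / (1.0 + np.exp(-(vs + 54.0) / -11.0))
    tau = (360.0 + (1010.0 + 24.0 * (vs + 55.0))
           * np.exp(-((vs + 75.0) / 48.0) ** 2)) / _Q10_23_13
    return inf, tau


def _ktst_m(v):
    vs = v + 10.0
    inf = 1.0 / (1.0 + np.exp(-(vs - 0.0) / 19.0))
    tau = (0.34 + 0.92 * np.exp(-((vs + 71.0) / 59.0) ** 2)) / _Q10_23_13
    return inf, tau


def _ktst_h(v):
    vs = v + 10.0
    inf = 1.0 / (1.0 + np.exp(-(vs + 66.0) / -10.0))
    tau = (8.0 + 49.0 * np.exp(-((vs + 73.0) / 23.0) ** 2)) / _Q10_23_13
    return inf, tau


def _skv31_m(v):
    inf = 1.0 / (1.0 + np.exp((v - 18.7) / -9.7))
    tau = 4.0 / (1.0 + np.exp((v + 46.56) / -44.14))
    return inf, tau


def _cahva_m(v):
    # alpha = 0.055*(-27-v)/(exp((-27-v)/3.8)-1)
    a = 0.055 * _vtrap(v + 27.0, 3.8)
    b = 0.94 * np.exp((-75.0 - v) / 17.0)
    return a / (a + b), 1.0 / (a + b)


def _cahva_h(v):
    a = 0.000457 * np.exp((-13.0 - v) / 50.0)
    b = 0.0065 / (np.exp((-v - 15.0) / 28.0) + 1.0)
    return a / (a + b), 1.0 / (a + b)


def _calva_m(v):
    inf = 1.0 / (1.0 + np.exp(-(v + 40.0) / 6.0))
    tau = (5.0 + 20.0 / (1.0 + np.exp((v + 35.0) / 5.0))) / _Q10_23_13
    return inf, tau


def _calva_h(v):
    inf = 1.0 / (1.0 + np.exp((v + 90.0) / 6.4))
    tau = (20.0 + 50.0 / (1.0 + np.exp((v + 50.0) / 7.0))) / _Q10_23_13
    return inf, tau


#: Voltage-dependent gates in kernel order: (name, inf/tau function).
VGATES = [
    ("NaT.m", _nat_m), ("NaT.h", _nat_h),
    ("NaP.m", _nap_m), ("NaP.h", _nap_h),
    ("Ih.m", _ih_m),
    ("Im.m", _im_m),
    ("KPst.m", _kpst_m), ("KPst.h", _kpst_h),
    ("KTst.m", _ktst_m), ("KTst.h", _ktst_h),
    ("SKv31.m", _skv31_m),
    ("CaHVA.m", _cahva_m), ("CaHVA.h", _cahva_h),
    ("CaLVA.m", _calva_m), ("CaLVA.h", _calva_h),
]
GATE_INDEX = {name: i for i, (name, _) in enumerate(VGATES)}

#: Channel roster in kernel order, with (gate, power) factors and ion.
CHANNELS = [
    ("NaT", [("NaT.m", 3), ("NaT.h", 1)], "na"),
    ("NaP", [("NaP.m", 3), ("NaP.h", 1)], "na"),
    ("Ih", [("Ih.m", 1)], "h"),
    ("Im", [("Im.m", 1)], "k"),
    ("KPst", [("KPst.m", 2), ("KPst.h", 1)], "k"),
    ("KTst", [("KTst.m", 4), ("KTst.h", 1)], "k"),
    ("SKv31", [("SKv31.m", 1)], "k"),
    ("CaHVA", [("CaHVA.m", 2), ("CaHVA.h", 1)], "ca"),
    ("CaLVA", [("CaLVA.m", 2), ("CaLVA.h", 1)], "ca"),
    ("SK", [], "k"),  # gated by intracellular Ca2+, handled in the kernel
]
CHANNEL_INDEX = {name: i for i, (name, _, _) in enumerate(CHANNELS)}

#: The dendritic compartments carry exactly this subset.
DENDRITE_CHANNELS = frozenset(
    {"CaLVA", "CaHVA", "SK", "SKv31", "NaT", "Im", "Ih"})


def gate_inf_tau(name: str, v):
    """Steady state and time constant (ms) of one voltage gate at v (mV)."""
    return VGATES[GATE_INDEX[name]][1](v)


def build_gate_tables(dt: float, vmin: float = -120.0, vmax: float = 60.0,
                      dv: float = 0.05):
    """Precompute (inf, 1-exp(-dt/tau)) lookup tables on a voltage grid.

    Returns (tables, vmin, 1/dv) with tables of shape (n_gates, 2, n_points);
    the integrator advances each gate with the exponential-Euler update
    x += (x_inf - x) * (1 - exp(-dt/tau)) via linear interpolation.
    """
    grid = np.arange(vmin, vmax + dv / 2, dv)
    tables = np.empty((len(VGATES), 2, grid.size))
    for i, (_, fn) in enumerate(VGATES):
        inf, tau = fn(grid)
        tables[i, 0] = inf
        tables[i, 1] = 1.0 - np.exp(-dt / np.maximum(tau, 1e-6))
    return tables, vmin, 1.0 / dv


def sk_zinf(cai):
    """SK activation as a function of intracellular Ca2+ (mM); tau = 1 ms."""
    return 1.0 / (1.0 + (0.00043 / np.maximum(cai, 1e-9)) ** 4.8)


@dataclass
class PassiveParams:
    """Passive membrane and cable parameters.

    Capacitance is doubled in the dendrites to correct for spine area, as is
    the leak density.  ``ra`` is the axial resistivity in ohm*cm.
    """
    cm_soma: float = 1.0            # uF/cm^2 (soma and axon)
    cm_dend: float = 2.0            # uF/cm^2 (basal and apical)
    ra: float = 100.0               # ohm*cm
    e_leak: float = -90.0           # mV
    g_leak: dict = field(default_factory=lambda: {
        "soma": 0.1, "axon": 0.1, "basal": 0.1,
        "apical_trunk": 0.1, "nexus": 0.1, "tuft": 0.1,
    })                              # mS/cm^2

    def __post_init__(self):
        if self.cm_soma <= 0 or self.cm_dend <= 0 or self.ra <= 0:
            raise ValueError("cm and ra must be positive")
        if any(g <= 0 for g in self.g_leak.values()):
            raise ValueError("leak densities must be positive")

    def cm_of(self, region: str) -> float:
        return self.cm_soma if region in ("soma", "axon") else self.cm_dend


@dataclass
class CaDynamics:
    """Single-pool intracellular Ca2+ model feeding the SK conductance.

    d[Ca]/dt = -k * I_Ca - ([Ca] - min_cai)/decay, with the influx constant
    k set by the submembrane shell ``depth`` and the unitless fraction
    ``gamma`` of the Ca2+ current that enters the pool.
    """
    gamma: float = 0.0005
    decay: float = 120.0   # ms
    depth: float = 0.1     # um
    min_cai: float = 1e-4  # mM
    cao: float = 2.0       # mM, for the Nernst Ca2+ reversal


def default_densities() -> "ChannelDensityMap":
    """Per-region peak conductance densities (mS/cm^2), tunable defaults.

    The soma carries the full roster minus Im; dendrites carry exactly
    {CaLVA, CaHVA, SK, SKv31, NaT, Im, Ih}; the nexus region additionally
    hosts the Ca2+ hot zone (boosted CaLVA/CaHVA) that generates apical
    Ca2+ plateaus.
    """
    soma = {"NaT": 2040.0, "NaP": 1.72, "Ih": 0.2, "KPst": 2.23,
            "KTst": 81.2, "SKv31": 693.0, "CaHVA": 0.992, "CaLVA": 3.43,
            "SK": 44.1}
    axon = {"NaT": 3000.0, "NaP": 1.72, "KPst": 223.0, "KTst": 100.0,
            "SKv31": 900.0, "SK": 0.0, "CaHVA": 0.0, "CaLVA": 0.0,
            "Ih": 0.0}
    soma["KTst"] = 250.0
    soma["SK"] = 100.0
    dend_common = {"NaT": 30.0, "SKv31": 4.0, "Im": 1.0, "Ih": 0.2,
                   "CaHVA": 0.0555, "CaLVA": 0.187, "SK": 1.2}
    basal = dict(dend_common)
    apical = dict(dend_common)
    tuft = dict(dend_common)
    nexus = dict(dend_common, CaHVA=10.0, CaLVA=60.0, SK=4.0, Im=0.05)
    return ChannelDensityMap({
        "soma": soma, "axon": axon, "basal": basal,
        "apical_trunk": apical, "nexus": nexus, "tuft": tuft,
    })


@dataclass
class ChannelDensityMap:
    """Region -> channel -> peak conductance density (mS/cm^2)."""

    densities: dict

    def __post_init__(self):
        for region, chans in self.densities.items():
            for name, g in chans.items():
                if name not in CHANNEL_INDEX:
                    raise ValueError(f"unknown channel {name!r} in {region}")
                if g < 0:
                    raise ValueError(f"negative density for {name} in {region}")

    def validate_roster(self) -> None:
        """Enforce the regional channel roster.

        Raises ValueError if the soma carries Im or a dendritic region
        carries a channel outside the seven-channel dendritic set.
        """
        soma = self.densities.get("soma", {})
        if soma.get("Im", 0.0) > 0:
            raise ValueError("soma must not carry Im")
        for region in ("basal", "apical_trunk", "nexus", "tuft"):
            active = {c for c, g in self.densities.get(region, {}).items()
                      if g > 0}
            extra = active - DENDRITE_CHANNELS
            if extra:
                raise ValueError(
                    f"channels {sorted(extra)} not allowed in region {region}")

    def get(self, region: str, channel: str) -> float:
        return float(self.densities.get(region, {}).get(channel, 0.0))

    def scaled(self, factors: dict) -> "ChannelDensityMap":
        """New map with per-channel multiplicative factors applied globally."""
        out = {r: {c: g * factors.get(c, 1.0) for c, g in chans.items()}
               for r, chans in self.densities.items()}
        return ChannelDensityMap(out)
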