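"""Detection of somatic action potentials and dendritic spikes.

The detectors operate on recorded traces with explicit, paper-style
criteria: APs are upward crossings of -10 mV at the soma; dendritic Na+
spikes are NaT conductance-density crossings of 0.3 mS/cm^2 outside a
backpropagation-exclusion window after each somatic AP; NMDA and Ca2+
spikes are joint voltage (-40 mV for >= 26 ms) and inward-current
(130%/115% ratio) plateau events, applied to the NMDA current or the summed
HVA+LVA Ca2+ current respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventSeries", "detect_aps", "detect_na_spikes", "detect_plateau",
           "events_to_binary", "detect_all"]

AP_THRESHOLD = -10.0        # mV
NA_G_THRESHOLD = 0.3        # mS/cm^2
PLATEAU_V = -40.0           # mV
PLATEAU_MIN_DUR = 26.0      # ms
PLATEAU_ON_FRAC = 1.30
PLATEAU_OFF_FRAC = 1.15
BAP_WINDOW = 2.0            # ms after a somatic AP
BINARY_BIN = 2.0            # ms


@dataclass
class EventSeries:
    """Detected events of one kind in one compartment.

    ``onsets`` are strictly increasing times (ms); ``offsets`` are present
    for plateau events (NMDA/Ca) and equal to onsets for point events
    (AP/Na).  ``peaks`` holds AP peak times for threshold analysis.
    """
    comp: int
    kind: str                      # 'AP' | 'Na' | 'NMDA' | 'Ca'
    onsets: np.ndarray
    offsets: np.ndarray | None = None
    peaks: np.ndarray | None = None

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.offsets is not None:
            self.offsets = np.asarray(self.offsets, dtype=float)
            if self.offsets.size != self.onsets.size:
                raise ValueError("onsets and offsets must align")
            if np.any(self.offsets < self.onsets):
                raise ValueError("offsets must not precede onsets")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n(self) -> int:
        return self.onsets.size


def detect_aps(v_soma: np.ndarray, dt: float,
               threshold: float = AP_THRESHOLD, comp: int = 0) -> EventSeries:
    """Somatic APs: upward threshold crossings with positive slope.

    The event time is the first sample at or above threshold; the peak time
    (for AP-threshold analysis) is the voltage maximum between the crossing
    and the next downward crossing.
    """
    v = np.asarray(v_soma, dtype=float)
    up = np.nonzero((v[1:] >= threshold) & (v[:-1] < threshold))[0] + 1
    onsets = dt * up
    peaks = []
    for i in up:
        j = i
        while j < v.size - 1 and v[j + 1] >= threshold:
            j += 1
        seg = v[i:j + 1]
        peaks.append(dt * (i + int(np.argmax(seg))))
    return EventSeries(comp, "AP", onsets, peaks=np.asarray(peaks, dtype=float))


def detect_na_spikes(gna: np.ndarray, dt: float,
                     ap_times: np.ndarray | None = None,
                     threshold: float = NA_G_THRESHOLD,
                     bap_window: float = BAP_WINDOW,
                     comp: int = 0) -> EventSeries:
    """Dendritic Na+ spikes from the NaT conductance density (mS/cm^2).

    Each upward crossing of ``threshold`` is one event unless it falls
    within ``bap_window`` ms after a somatic AP (backpropagating spikes are
    excluded).
    """
    g = np.asarray(gna, dtype=float)
    up = np.nonzero((g[1:] >= threshold) & (g[:-1] < threshold))[0] + 1
    t = dt * up
    if ap_times is not None and len(ap_times) > 0 and t.size:
        ap = np.asarray(ap_times, dtype=float)
        idx = np.searchsorted(ap, t, side="right") - 1
        prev = np.where(idx >= 0, ap[np.clip(idx, 0, None)], -np.inf)
        t = t[(t - prev) > bap_window]
    return EventSeries(comp, "Na", t)


def detect_plateau(v: np.ndarray, i_drive: np.ndarray, dt: float,
                   v_thresh: float = PLATEAU_V,
                   min_dur: float = PLATEAU_MIN_DUR,
                   on_frac: float = PLATEAU_ON_FRAC,
                   off_frac: float = PLATEAU_OFF_FRAC,
                   kind: str = "NMDA", comp: int = 0,
                   bridge: float = 0.0) -> EventSeries:
    """Plateau (NMDA or Ca2+ spike) detection by joint voltage and current
    criteria.

    The voltage criterion holds over contiguous excursions above
    ``v_thresh`` lasting at least ``min_dur`` ms (sub-``bridge``-ms dips are
    bridged).  Within such an excursion, the current criterion compares the
    inward-current magnitude with its value at the -40 mV upward crossing
    (t_v): the event starts when it exceeds ``on_frac`` times that
    reference, and ends when it falls back to ``off_frac`` times it (or the
    excursion ends).  ``i_drive`` is the magnitude of the relevant inward
    current (NMDA, or summed HVA+LVA Ca2+).
    """
    v = np.asarray(v, dtype=float)
    i_mag = np.abs(np.asarray(i_drive, dtype=float))
    if v.shape != i_mag.shape:
        raise ValueError("v and i_drive must share the time base")
    above = v >= v_thresh
    if bridge > 0:
        gap = max(int(round(bridge / dt)), 0)
        if gap:
            above = _bridge_gaps(above, gap)
    onsets, offsets = [], []
    n = v.size
    i0 = 0
    while i0 < n:
        if not above[i0]:
            i0 += 1
            continue
        i1 = i0
        while i1 < n and above[i1]:
            i1 += 1
        # excursion [i0, i1)
        if (i1 - i0) * dt >= min_dur:
            ref = i_mag[i0]
            seg = i_mag[i0:i1]
            started = np.nonzero(seg >= on_frac * ref)[0]
            if ref > 0 and started.size:
                s = started[0]
                endc = np.nonzero(seg[s:] <= off_frac * ref)[0]
                e = s + endc[0] if endc.size else (i1 - i0 - 1)
                onsets.append(dt * (i0 + s))
                offsets.append(dt * (i0 + e))
        i0 = i1
    return EventSeries(comp, kind, np.asarray(onsets), np.asarray(offsets))


def _bridge_gaps(mask: np.ndarray, gap: int) -> np.ndarray:
    out = mask.copy()
    n = mask.size
    i = 0
    while i < n:
        if not out[i]:
            j = i
            while j < n and not out[j]:
                j += 1
            if 0 < i and j < n and (j - i) <= gap:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def events_to_binary(events: EventSeries, duration: float,
                     bin_ms: float = BINARY_BIN) -> np.ndarray:
    """Binary presence series: bin true iff an event overlaps the bin.

    Plateau events occupy [onset, offset]; point events are instantaneous.
    Bins are [k*bin, (k+1)*bin), covering [0, duration).
    """
    n_bins = int(np.ceil(duration / bin_ms))
    out = np.zeros(n_bins, dtype=bool)
    offs = events.offsets if events.offsets is not None else events.onsets
    for t0, t1 in zip(events.onsets, offs):
        b0 = int(t0 // bin_ms)
        b1 = int(t1 // bin_ms)
        if b0 >= n_bins or t0 < 0:
            continue
        out[b0:min(b1 + 1, n_bins)] = True
    return out


def detect_all(traces, ap_series: EventSeries | None = None,
               bap_window: float = BAP_WINDOW) -> dict:
    """Run all detectors on a TraceSet.

    Returns {'AP': EventSeries, 'Na': [...], 'NMDA': [...], 'Ca': [...]},
    with one list entry per recorded dendritic compartment.  Na+ spikes are
    screened against the somatic AP times; Ca2+ events are only meaningful
    in the apical/nexus region but are computed wherever Ca2+ current was
    recorded.
    """
    if ap_series is None:
        ap_series = detect_aps(traces.v_soma, traces.dt)
    out = {"AP": ap_series, "Na": [], "NMDA": [], "Ca": []}
    dt = traces.dt_rec
    for j, comp in enumerate(traces.comp_ids):
        out["Na"].append(detect_na_spikes(
            traces.gna[:, j], dt, ap_series.onsets, bap_window=bap_window,
            comp=int(comp)))
        out["NMDA"].append(detect_plateau(
            traces.v[:, j], traces.i_nmda[:, j], dt, kind="NMDA",
            comp=int(comp)))
        out["Ca"].append(detect_plateau(
            traces.v[:, j], traces.i_ca[:, j], dt, kind="Ca",
            comp=int(comp)))
    return out
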