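"""Statistics over events, phases, and traces.

Implements the spike-triggered average of dendritic-spike presence around
somatic APs, rhythm-phase histograms and the pairwise phase consistency
(PPC), peak/trough phase stratification, the rhythm-corrected
cross-correlogram between presynaptic spikes and APs, f-I curves, AP
voltage thresholds, and phase-binned membrane-potential fluctuation bias.

Phase convention throughout: the rhythm phase of an inhibitory modulation
r(t) = A sin(2 pi f t + phi) + off is 0 where inhibition is maximal and
+/-pi where it is minimal; all phase assignment goes through
:func:`phase_of`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RhythmSpec

__all__ = [
    "STAResult", "PhaseHistogram", "CCResult", "FICurve",
    "sta_percent_change", "phase_of", "phase_histogram", "ppc",
    "peak_trough_masks", "phase_stratified_cc", "fi_curve",
    "fi_from_counts", "ap_threshold", "fluctuation_bias", "group_median",
]


# ---------------------------------------------------------------- results
@dataclass
class STAResult:
    """Percent change of event presence around somatic APs.

    ``pct`` has one row per contributing compartment (see ``comp_ids``) and
    one column per lag; values are 100*(STA/global_mean - 1).
    """
    lags: np.ndarray
    pct: np.ndarray
    comp_ids: np.ndarray


@dataclass
class PhaseHistogram:
    """Percent change from mean of event presence in 8 rhythm-phase bins."""
    edges: np.ndarray          # n_bins+1 edges over (-pi, pi]
    pct: np.ndarray            # (n_comp, n_bins) or (n_bins,)
    raw: np.ndarray            # raw mean presence per bin
    occupancy: np.ndarray      # number of samples per bin

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class CCResult:
    """Rhythm-corrected cross-correlogram for one phase stratum."""
    lags: np.ndarray           # ms
    cc: np.ndarray
    stratum: str               # 'peak' | 'trough' | 'all'
    peak_area: float


@dataclass
class FICurve:
    """Firing rate vs injected current with threshold and gain."""
    amplitudes: np.ndarray     # nA
    rates: np.ndarray          # Hz
    threshold: float           # nA (first amplitude with rate > 0; nan if none)
    slope: float               # Hz/nA over suprathreshold points; nan if < 2


# -------------------------------------------------------------------- STA
def sta_percent_change(binaries: np.ndarray, ap_times: np.ndarray,
                       bin_ms: float = 2.0, max_lag: float = 50.0,
                       comp_ids: np.ndarray | None = None) -> STAResult:
    """Spike-triggered average of binary event presence around APs.

    ``binaries`` is (n_comp, n_bins) at ``bin_ms`` resolution.  For each
    lag in [-max_lag, +max_lag] the mean presence across AP-aligned windows
    is expressed as percent change from that compartment's global mean.
    Compartments with zero global mean are excluded with a warning.
    """
    binaries = np.atleast_2d(np.asarray(binaries, dtype=float))
    ap_times = np.asarray(ap_times, dtype=float)
    if ap_times.size < 1:
        raise ValueError("need at least one AP")
    n_comp, n_bins = binaries.shape
    if comp_ids is None:
        comp_ids = np.arange(n_comp)
    L = int(round(max_lag / bin_ms))
    lags = bin_ms * np.arange(-L, L + 1)
    centers = np.round(ap_times / bin_ms).astype(int)
    means = binaries.mean(axis=1)
    keep = means > 0
    if not np.all(keep):
        warnings.warn(f"excluding {np.sum(~keep)} compartments with no events")
    sta = np.zeros((int(keep.sum()), lags.size))
    rows = binaries[keep]
    for li, off in enumerate(range(-L, L + 1)):
        idx = centers + off
        ok = (idx >= 0) & (idx < n_bins)
        if not np.any(ok):
            sta[:, li] = np.nan
            continue
        sta[:, li] = rows[:, idx[ok]].mean(axis=1)
    pct = 100.0 * (sta / means[keep, None] - 1.0)
    return STAResult(lags, pct, np.asarray(comp_ids)[keep])


def group_median(values: np.ndarray, comp_ids: np.ndarray,
                 deciles: dict[str, np.ndarray]) -> pd.DataFrame:
    """Median across compartments per (dendrite class, electrotonic decile).

    ``deciles`` is the output of :func:`dendrhythm.cell.electrotonic_deciles`;
    ``values`` is (n_comp, n_cols) aligned with ``comp_ids``.  Returns a tidy
    frame with columns (cls, decile, col, value).
    """
    values = np.atleast_2d(values)
    lookup = {int(c): i for i, c in enumerate(comp_ids)}
    rows = []
    for cls, table in deciles.items():
        for dec in np.unique(table[:, 1]):
            members = [lookup[c] for c in table[table[:, 1] == dec, 0]
                       if c in lookup]
            if not members:
                continue
            med = np.nanmedian(values[members], axis=0)
            for col, val in enumerate(np.atleast_1d(med)):
                rows.append((cls, int(dec), col, float(val)))
    return pd.DataFrame(rows, columns=["cls", "decile", "col", "value"])


# ------------------------------------------------------------------ phase
def phase_of(times: np.ndarray, rhythm: RhythmSpec) -> np.ndarray:
    """Rhythm phase in (-pi, pi] at the given times (ms).

    Phase 0 corresponds to the maximum of the modulated (inhibitory) rate
    and +/-pi to its minimum.
    """
    t = np.asarray(times, dtype=float)
    raw = 2.0 * np.pi * rhythm.f * t / 1000.0 + rhythm.phase - np.pi / 2.0
    return _wrap(raw)


def _wrap(phi):
    """Wrap to (-pi, pi]."""
    out = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def phase_histogram(data, rhythm: RhythmSpec, duration: float | None = None,
                    bin_ms: float = 2.0, n_bins: int = 8) -> PhaseHistogram:
    """Event presence per rhythm-phase bin, as percent change from mean.

    ``data`` is either a binary presence series (bool array at ``bin_ms``
    resolution, possibly (n_comp, n_bins)) or a 1-D array of event times
    (ms), in which case ``duration`` must be given and the events are first
    binned at ``bin_ms``.
    """
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    data = np.asarray(data)
    if data.dtype != bool and data.ndim == 1 and duration is not None:
        series = np.zeros(int(np.ceil(duration / bin_ms)), dtype=bool)
        idx = (data // bin_ms).astype(int)
        series[idx[(idx >= 0) & (idx < series.size)]] = True
        data = series
    binaries = np.atleast_2d(data).astype(float)
    n_bins_t = binaries.shape[1]
    t_centers = bin_ms * (np.arange(n_bins_t) + 0.5)
    ph = phase_of(t_centers, rhythm)
    which = np.clip(np.searchsorted(edges, ph, side="left") - 1, 0, n_bins - 1)
    raw = np.zeros((binaries.shape[0], n_bins))
    occ = np.zeros(n_bins)
    for b in range(n_bins):
        sel = which == b
        occ[b] = sel.sum()
        raw[:, b] = binaries[:, sel].mean(axis=1) if occ[b] else np.nan
    gmean = binaries.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (raw / gmean - 1.0)
    return PhaseHistogram(edges, np.squeeze(pct), np.squeeze(raw), occ)


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency: mean cosine of all pairwise differences.

    Unbiased under the null (expectation 0 for uniform phases); equals the
    squared-resultant form (n*R^2 - 1)/(n - 1).
    """
    ph = np.asarray(phases, dtype=float)
    n = ph.size
    if n < 2:
        raise ValueError("PPC needs at least two phases")
    z = np.exp(1j * ph)
    s = np.abs(z.sum()) ** 2
    return float((s - n) / (n * (n - 1)))


def peak_trough_masks(rhythm: RhythmSpec, times: np.ndarray) -> np.ndarray:
    """True where the modulated inhibitory rate exceeds its offset (peak).

    Peak phase: inhibition above its mean (phase in (-pi/2, pi/2)); trough:
    below.  The boundary (rate exactly at offset) counts as trough.
    """
    ph = phase_of(times, rhythm)
    return np.cos(ph) > 0


# ------------------------------------------------ corrected correlogram
def phase_stratified_cc(presyn_times: np.ndarray, ap_times: np.ndarray,
                        duration: float, mod_freq: float | None,
                        rhythm: RhythmSpec | None = None,
                        stratum: str = "all", max_lag: float = 50.0,
                        bin_ms: float = 1.0, zero_width: int = 1,
                        eps_frac: float = 1e-6) -> CCResult:
    """Rhythm-corrected cross-correlogram between presynaptic spikes and APs.

    Presynaptic spikes are optionally restricted to the rhythm ``stratum``
    ('peak' or 'trough', via ``rhythm``).  Both trains are binned at 1 ms;
    the cross- and auto-spectra are computed by FFT, the coefficients at the
    modulation frequency (nearest bin +/- ``zero_width`` neighbours, and
    conjugates) are zeroed, and the cross-spectrum is divided element-wise
    by the square root of the product of the autospectra before inverse
    transform.  ``peak_area`` integrates the positive lobe nearest zero lag
    between its surrounding sign changes.
    """
    pre = np.asarray(presyn_times, dtype=float)
    ap = np.asarray(ap_times, dtype=float)
    if pre.size == 0 or ap.size == 0:
        warnings.warn("empty spike train; returning empty CC")
        return CCResult(np.zeros(0), np.zeros(0), stratum, 0.0)
    if stratum in ("peak", "trough"):
        if rhythm is None:
            raise ValueError("stratum selection requires a rhythm")
        mask = peak_trough_masks(rhythm, pre)
        pre = pre[mask] if stratum == "peak" else pre[~mask]
        if pre.size == 0:
            warnings.warn(f"empty {stratum} stratum; returning empty CC")
            return CCResult(np.zeros(0), np.zeros(0), stratum, 0.0)
    n = int(np.ceil(duration / bin_ms))
    x = np.bincount(np.clip((pre // bin_ms).astype(int), 0, n - 1),
                    minlength=n).astype(float)
    y = np.bincount(np.clip((ap // bin_ms).astype(int), 0, n - 1),
                    minlength=n).astype(float)
    L = int(round(max_lag / bin_ms))
    lags = bin_ms * np.arange(-L, L + 1)
    # windowed correlograms (per presynaptic spike), means removed so the
    # DC pedestal does not dominate the spectra
    cc = _xcorr(x - x.mean(), y - y.mean(), L) / max(pre.size, 1)
    acx = _xcorr(x - x.mean(), x - x.mean(), L) / max(pre.size, 1)
    acy = _xcorr(y - y.mean(), y - y.mean(), L) / max(ap.size, 1)
    CC = np.fft.rfft(cc)
    AX = np.fft.rfft(acx)
    AY = np.fft.rfft(acy)
    if mod_freq is not None and mod_freq > 0:
        freqs = np.fft.rfftfreq(cc.size, d=bin_ms / 1000.0)
        k = int(np.argmin(np.abs(freqs - mod_freq)))
        lo, hi = max(k - zero_width, 0), min(k + zero_width + 1, CC.size)
        CC[lo:hi] = 0.0
        AX[lo:hi] = 0.0
        AY[lo:hi] = 0.0
    denom = np.sqrt(np.abs(AX) * np.abs(AY))
    floor = eps_frac * denom.max() if denom.max() > 0 else 1.0
    norm = np.where(denom > floor, CC / np.maximum(denom, floor), 0.0)
    corrected = np.fft.irfft(norm, n=cc.size)
    return CCResult(lags, corrected, stratum,
                    _peak_area(lags, corrected, bin_ms))


def _xcorr(x: np.ndarray, y: np.ndarray, L: int) -> np.ndarray:
    """Cross-correlation sum_t x[t]*y[t+lag] for lags -L..L (FFT-based)."""
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(n + L + 1)))
    X = np.fft.rfft(x, nfft)
    Y = np.fft.rfft(y, nfft)
    full = np.fft.irfft(np.conj(X) * Y, nfft)
    return np.concatenate([full[-L:], full[:L + 1]])


def _peak_area(lags: np.ndarray, cc: np.ndarray, bin_ms: float) -> float:
    """Area of the positive CC lobe nearest zero lag."""
    pos = cc > 0
    if not np.any(pos):
        return 0.0
    # contiguous positive segments
    best = None
    i = 0
    n = cc.size
    while i < n:
        if not pos[i]:
            i += 1
            continue
        j = i
        while j < n and pos[j]:
            j += 1
        seg = slice(i, j)
        pk = i + int(np.argmax(cc[seg]))
        d = abs(lags[pk])
        if best is None or d < best[0]:
            best = (d, seg)
        i = j
    seg = best[1]
    return float(cc[seg].sum() * bin_ms)


# ------------------------------------------------------------------- f-I
def fi_from_counts(amplitudes: np.ndarray, counts: np.ndarray,
                   step_dur: float) -> FICurve:
    """Build an f-I curve from AP counts per amplitude.

    Threshold is the lowest amplitude with a nonzero rate (ties resolved
    toward the lower amplitude by the sorted scan); the slope is the
    least-squares gain over suprathreshold (rate > 0) points, nan when
    fewer than two such points exist.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(np.diff(amplitudes) < 0):
        raise ValueError("amplitudes must be sorted ascending")
    rates = np.asarray(counts, dtype=float) / (step_dur / 1000.0)
    supra = rates > 0
    threshold = float(amplitudes[supra][0]) if np.any(supra) else np.nan
    if supra.sum() >= 2:
        A = np.vstack([amplitudes[supra], np.ones(supra.sum())]).T
        slope = float(np.linalg.lstsq(A, rates[supra], rcond=None)[0][0])
    else:
        slope = np.nan
    return FICurve(amplitudes, rates, threshold, slope)


def fi_curve(cell, amplitudes: np.ndarray, step_dur: float = 2000.0,
             specs=None, exc_trains=None, inh_trains=None, seed: int = 0,
             pre: float = 300.0, dt: float = 0.1) -> FICurve:
    """f-I curve by somatic current steps, optionally on synaptic background.

    Runs one simulation per amplitude (step of ``step_dur`` ms after a
    ``pre`` ms settling period) and counts APs during the step.
    """
    from .cell import inject_step
    from .events import detect_aps
    counts = []
    for k, amp in enumerate(np.asarray(amplitudes, dtype=float)):
        ts = inject_step(cell, float(amp), step_dur, pre=pre, post=50.0,
                         dt=dt, record="soma", specs=specs,
                         exc_trains=exc_trains, inh_trains=inh_trains,
                         seed=seed + 17 * k)
        aps = detect_aps(ts.v_soma, ts.dt)
        sel = (aps.onsets >= pre) & (aps.onsets < pre + step_dur)
        counts.append(int(sel.sum()))
    return fi_from_counts(np.asarray(amplitudes, dtype=float),
                          np.asarray(counts), step_dur)


# ------------------------------------------------------------ thresholds
def ap_threshold(v_soma: np.ndarray, dt: float, peak_times: np.ndarray,
                 lead: float = 1.0) -> np.ndarray:
    """AP voltage threshold: V at ``lead`` ms before each AP peak.

    Peaks earlier than ``lead`` ms into the trace are skipped with a
    warning.  A constant offset added to the trace shifts every threshold
    by exactly that offset.
    """
    v = np.asarray(v_soma, dtype=float)
    out = []
    skipped = 0
    for tp in np.asarray(peak_times, dtype=float):
        i = int(round((tp - lead) / dt))
        if i < 0:
            skipped += 1
            continue
        out.append(v[min(i, v.size - 1)])
    if skipped:
        warnings.warn(f"skipped {skipped} APs peaking within {lead} ms "
                      "of trace start")
    return np.asarray(out)


def fluctuation_bias(v_soma: np.ndarray, dt: float, rhythm: RhythmSpec,
                     delay: float = 1.0, n_bins: int = 8) -> np.ndarray:
    """Mean membrane-potential fluctuation dV = V(t+delay) - V(t) per
    rhythm-phase bin (phase taken at t)."""
    v = np.asarray(v_soma, dtype=float)
    k = int(round(delay / dt))
    if k < 1 or abs(k * dt - delay) > 1e-9:
        raise ValueError("dt must evenly divide the delay")
    dv = v[k:] - v[:-k]
    t = dt * (1 + np.arange(dv.size))
    ph = phase_of(t, rhythm)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, ph, side="left") - 1, 0, n_bins - 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if np.any(sel):
            out[b] = dv[sel].mean()
    return out
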