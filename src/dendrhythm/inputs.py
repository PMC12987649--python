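"""Synthetic presynaptic drive.

Generates every input regime the study uses: tonic 1/f-modulated Poisson
excitation organised into functional groups, lagged feedforward inhibition,
sinusoidal (beta/gamma) and bursty rhythmic inhibitory modulation, and
jittered clustered excitatory inputs.
"""

from __future__ import annotations

import numpy as np

from .core import FunctionalGroup, RateTrace, RhythmSpec, SpikeTrain

__all__ = [
    "gen_pink_modulator",
    "build_functional_groups",
    "draw_node_rates",
    "modulate_node_rates",
    "derive_inhibitory_modulator",
    "sharpen_modulator",
    "sine_rate",
    "sine_modulator",
    "burst_envelope",
    "sample_poisson",
    "gen_cluster_trains",
]

#: Mean +/- SD (Hz) of the empirical excitatory per-node firing-rate
#: distribution the drive is matched to (moment-matched gamma, floor 0.1 Hz).
EXC_RATE_MEAN = 4.43
EXC_RATE_SD = 2.9
RATE_FLOOR = 0.1


def gen_pink_modulator(duration: float, dt: float = 1.0, seed: int | None = None,
                       lo: float = 0.5, hi: float = 1.5) -> RateTrace:
    """Unitless 1/f-spectrum rate modulator, min-max normalized to [lo, hi].

    White Gaussian noise is filtered in the frequency domain with a 1/sqrt(f)
    amplitude mask (power ~ 1/f), then min-max normalized so the extrema hit
    the requested bounds exactly.

    Parameters
    ----------
    duration : float
        Trace length in ms (>= 1000 so the slow end of the spectrum exists).
    dt : float
        Sample interval in ms (default 1 ms, the spike-generation grid).
    seed : int
        Seed for the white-noise draw.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if duration < 1000.0:
        raise ValueError("duration must be at least 1000 ms")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt / 1000.0)  # Hz
    mask = np.zeros_like(freqs)
    mask[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * mask, n=n)
    lo_v, hi_v = pink.min(), pink.max()
    values = lo + (hi - lo) * (pink - lo_v) / (hi_v - lo_v)
    return RateTrace(0.0, dt, values)


def build_functional_groups(n_synapses: int, mean_divergence: int = 5,
                            group_size: int = 100) -> list[FunctionalGroup]:
    """Partition presynaptic nodes into fixed-size functional groups.

    The node count is ``floor(n_synapses / mean_divergence)`` rounded down to
    a multiple of ``group_size``; e.g. 26112 synapses at divergence 5 give
    5222 nodes, retained as 5200 nodes in 52 groups of 100.
    """
    if n_synapses <= 0 or mean_divergence <= 0 or group_size <= 0:
        raise ValueError("n_synapses, mean_divergence, group_size must be positive")
    n_nodes = n_synapses // mean_divergence
    if group_size > n_nodes:
        raise ValueError(
            f"group_size {group_size} exceeds available node count {n_nodes}")
    n_groups = n_nodes // group_size
    kept = n_groups * group_size
    ids = np.arange(kept)
    return [FunctionalGroup(g, ids[g * group_size:(g + 1) * group_size])
            for g in range(n_groups)]


def draw_node_rates(n: int, seed: int | None = None, mean: float = EXC_RATE_MEAN,
                    sd: float = EXC_RATE_SD, floor: float = RATE_FLOOR) -> np.ndarray:
    """Per-node mean firing rates (Hz) from a moment-matched gamma distribution.

    The empirical distribution is only available as mean +/- SD; a gamma with
    those moments (positive, right-skewed) stands in, floored at 0.1 Hz.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    rng = np.random.default_rng(seed)
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return np.maximum(rng.gamma(shape, scale, size=n), floor)


def modulate_node_rates(base_rates: np.ndarray | float,
                        modulator: RateTrace) -> list[RateTrace] | RateTrace:
    """Multiply per-node base rates (Hz) with a shared unitless modulator.

    Returns one RateTrace per node (or a single trace for a scalar input).
    The time-averaged rate of each output is ``base * mean(modulator)``.
    """
    scalar = np.isscalar(base_rates)
    base = np.atleast_1d(np.asarray(base_rates, dtype=float))
    if np.any(base < 0):
        raise ValueError("base rates must be non-negative")
    out = [modulator.copy_with(b * modulator.values) for b in base]
    return out[0] if scalar else out


def derive_inhibitory_modulator(exc_modulator: RateTrace, lag: float = 4.0,
                                target_mean: float = 1.0) -> RateTrace:
    """Feedforward-inhibition modulator: delayed, rescaled excitatory modulator.

    The excitatory modulation trace is shifted forward in time by ``lag`` ms
    (circularly, so length and statistics are preserved) and multiplicatively
    rescaled to the requested mean, so inhibitory node rates modulated with it
    attain ``base_rate * target_mean`` on average.  The cross-correlation of
    input and output peaks at +lag.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if lag >= exc_modulator.duration:
        raise ValueError("lag exceeds trace duration")
    if target_mean <= 0:
        raise ValueError("target mean must be positive")
    shift = int(round(lag / exc_modulator.dt))
    shifted = np.roll(exc_modulator.values, shift)
    shifted = shifted * (target_mean / shifted.mean())
    return exc_modulator.copy_with(shifted)


def sharpen_modulator(modulator: RateTrace, power: float = 4.0) -> RateTrace:
    """Raise a modulator to a power, renormalized to preserve its mean.

    Exaggerates excursions away from the mean (variance never decreases)
    while the mean rate stays the same; used to stress E/I balance in the
    lag experiments.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    raised = modulator.values ** power
    m = raised.mean()
    if m == 0:
        return modulator.copy_with(raised)
    return modulator.copy_with(raised * (modulator.values.mean() / m))


def sine_rate(spec: RhythmSpec, duration: float, dt: float = 1.0,
              t0: float = 0.0) -> RateTrace:
    """Sinusoidally modulated rate r(t) = A*sin(2*pi*f*t + phase) + off.

    ``A = off/(1/d - 1)``; for depth <= 0.5 the trace is non-negative by
    construction, larger depths are clipped at zero.  An attached burst
    envelope (unitless, 0-1) scales the sine term only, so the offset rate
    is untouched outside the burst.
    """
    n = int(round(duration / dt))
    if n < 1:
        raise ValueError("duration must cover at least one sample")
    t = t0 + dt * np.arange(n)
    a = spec.amplitude
    sine = np.sin(2.0 * np.pi * spec.f * t / 1000.0 + spec.phase)
    if spec.envelope is not None:
        env = np.interp(t, spec.envelope.times, spec.envelope.values,
                        left=0.0, right=0.0)
        sine = sine * env
    values = np.maximum(a * sine + spec.offset, 0.0)
    return RateTrace(t0, dt, values)


def sine_modulator(spec: RhythmSpec, duration: float, dt: float = 1.0,
                   t0: float = 0.0) -> RateTrace:
    """Unitless version of :func:`sine_rate`: 1 + (d/(1-d))*sin(...), mean 1.

    Multiplying a node's base rate with this trace reproduces sine_rate with
    off = base rate.
    """
    unit = RhythmSpec(spec.f, spec.depth, spec.phase, offset=1.0,
                      envelope=spec.envelope)
    return sine_rate(unit, duration, dt, t0)


def burst_envelope(f: float, center: float, duration: float,
                   dt: float = 1.0) -> RateTrace:
    """Gaussian burst envelope with sigma = two oscillatory cycles.

    Unitless, peak value exactly 1 at ``center`` (ms), symmetric; emulates the
    few-hundred-ms packets in which beta/gamma rhythms occur in vivo.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    n = int(round(duration / dt))
    t = dt * np.arange(n)
    sigma = 2.0 * (1000.0 / f)
    return RateTrace(0.0, dt, np.exp(-0.5 * ((t - center) / sigma) ** 2))


def sample_poisson(rate: RateTrace, seed: int | None = None,
                   node_id: int = 0) -> SpikeTrain:
    """Inhomogeneous Poisson spikes by per-bin Bernoulli thinning.

    A spike is emitted in bin t iff ``x[t] <= r[t]*dt`` with x ~ U(0,1);
    requires ``r*dt < 1`` in every bin (the default 1 ms grid keeps cortical
    rates far from that limit).  Each spike is placed at its bin's left edge.
    """
    p = rate.values * (rate.dt / 1000.0)
    if np.any(p >= 1.0):
        raise ValueError("rate*dt must stay below 1 per bin; use a finer dt")
    rng = np.random.default_rng(seed)
    x = rng.random(p.size)
    idx = np.nonzero(x <= p)[0]
    return SpikeTrain(node_id, rate.t0 + rate.dt * idx)


def gen_cluster_trains(base: SpikeTrain, n_trains: int, jitter: float = 2.0,
                       seed: int | None = None) -> list[SpikeTrain]:
    """Co-activated trains: independent +/-jitter copies of one base train.

    Each output train is the base train with i.i.d. uniform jitter in
    [-jitter, +jitter] ms per spike, re-sorted; spike counts are preserved.
    Any post-jitter coincidences are minutely separated to keep trains
    strictly increasing.
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    if n_trains <= 0:
        raise ValueError("n_trains must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_trains):
        if jitter == 0:
            t = base.times.copy()
        else:
            t = np.sort(base.times + rng.uniform(-jitter, jitter, base.times.size))
            # enforce strict monotonicity after jitter collisions
            for k in range(1, t.size):
                if t[k] <= t[k - 1]:
                    t[k] = t[k - 1] + 1e-6
        out.append(SpikeTrain(i, t))
    return out
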