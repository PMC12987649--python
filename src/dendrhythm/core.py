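"""Core containers shared across the pipeline.

Time is everywhere in milliseconds, rates in Hz (events/s), conductances in
microsiemens, voltages in millivolts, currents in nanoamperes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RateTrace", "RhythmSpec", "SpikeTrain", "FunctionalGroup"]


@dataclass
class RateTrace:
    """A discretized instantaneous firing-rate (or unitless modulator) trace.

    Parameters
    ----------
    t0 : float
        Time origin in ms.
    dt : float
        Sample interval in ms.
    values : ndarray
        Rate per sample, in Hz, or a unitless multiplier.  Must be >= 0.
    """

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("rate values must be non-negative")

    @property
    def duration(self) -> float:
        """Total covered time span in ms."""
        return self.dt * self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times (bin left edges) in ms."""
        return self.t0 + self.dt * np.arange(self.values.size)

    def copy_with(self, values: np.ndarray) -> "RateTrace":
        return RateTrace(self.t0, self.dt, np.asarray(values, dtype=float))

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class RhythmSpec:
    """A sinusoidal rate modulation r(t) = A*sin(2*pi*f*t + phase) + off.

    ``depth`` (0 < d < 1) is the modulation depth relative to the offset rate;
    the sine amplitude follows as ``A = off / (1/d - 1) = off*d/(1-d)``.

    The rhythm phase convention used throughout the package maps phase 0 to the
    maximum of the (inhibitory) rate and +/-pi to its minimum.
    """

    f: float
    depth: float
    phase: float = 0.0
    offset: float = 1.0
    envelope: "RateTrace | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.depth < 1.0):
            raise ValueError("depth must lie in (0, 1)")
        if self.f <= 0:
            raise ValueError("frequency must be positive")
        if self.offset <= 0:
            raise ValueError("offset rate must be positive")

    @property
    def amplitude(self) -> float:
        """Sine amplitude A = off/(1/d - 1), in the units of ``offset``."""
        return self.offset / (1.0 / self.depth - 1.0)

    @property
    def period(self) -> float:
        """Cycle length in ms."""
        return 1000.0 / self.f


@dataclass
class SpikeTrain:
    """Sorted event times (ms) of one presynaptic node."""

    node_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class FunctionalGroup:
    """A set of presynaptic nodes sharing one slow rate modulator.

    Emulates a correlated afferent cell assembly: all member nodes are driven
    by the same normalized 1/f rate-modulation trace.
    """

    group_id: int
    node_ids: np.ndarray
    modulator: "RateTrace | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        if self.node_ids.ndim != 1 or self.node_ids.size == 0:
            raise ValueError("node_ids must be a non-empty 1-D array")
        if np.unique(self.node_ids).size != self.node_ids.size:
            raise ValueError("node_ids must be unique")

    def __len__(self) -> int:
        return self.node_ids.size
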