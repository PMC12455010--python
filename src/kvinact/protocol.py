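"""Voltage-step stimulus protocols.

The default protocol is the standard 18-step depolarization family used for
fast-inactivating Kv channels: from a −90 mV holding potential, 500 ms steps
from −90 mV to +80 mV in 10 mV increments, sampled at 10 kHz.  A 100 ms
pre-step holding segment precedes the pulse so that the conventional
70–599 ms analysis window (sweep-relative) covers the last 30 ms of holding
plus the full step.

Units are fixed package-wide: time in ms, potential in mV, rate in kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

DEFAULT_STEP_POTENTIALS: tuple[float, ...] = tuple(float(v) for v in range(-90, 81, 10))


@dataclass(frozen=True)
class VoltageProtocol:
    """A square voltage-step protocol: holding → step → holding.

    Attributes
    ----------
    holding_potential : float
        Potential (mV) during the pre- and post-step segments.
    pre_step_duration : float
        Duration (ms) of the holding segment before the pulse.
    step_potentials : tuple of float
        Strictly increasing step potentials (mV); one sweep per entry.
    step_duration : float
        Duration (ms) of the depolarizing pulse.
    post_step_duration : float
        Duration (ms) of the holding segment after the pulse (may be 0).
    sampling_rate : float
        Sampling rate in kHz (samples per ms).
    """

    holding_potential: float = -90.0
    pre_step_duration: float = 100.0
    step_potentials: tuple[float, ...] = field(default=DEFAULT_STEP_POTENTIALS)
    step_duration: float = 500.0
    post_step_duration: float = 0.0
    sampling_rate: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_potentials", tuple(float(v) for v in self.step_potentials))
        if not self.step_potentials:
            raise ValidationError("step_potentials: at least one step potential required")
        diffs = np.diff(self.step_potentials)
        if len(diffs) and not np.all(diffs > 0):
            raise ValidationError("step_potentials: must be strictly increasing")
        for name in ("pre_step_duration", "post_step_duration"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: must be non-negative, got {getattr(self, name)}")
        if self.step_duration <= 0:
            raise ValidationError(f"step_duration: must be positive, got {self.step_duration}")
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate: must be positive, got {self.sampling_rate}")
        n = self.total_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-6:
            raise ValidationError(
                "sampling_rate: total sweep duration "
                f"{self.total_duration} ms does not give an integer sample count at "
                f"{self.sampling_rate} kHz"
            )

    @property
    def total_duration(self) -> float:
        """Total sweep duration in ms."""
        return self.pre_step_duration + self.step_duration + self.post_step_duration

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1.0 / self.sampling_rate

    @property
    def step_onset(self) -> float:
        """Sweep-relative time (ms) at which the pulse starts."""
        return self.pre_step_duration

    @property
    def step_end(self) -> float:
        return self.pre_step_duration + self.step_duration

    def times(self) -> np.ndarray:
        """Sample times in ms, first sample at t = 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def segments(self, step_potential: float) -> list[tuple[float, float]]:
        """(potential, duration) segments of one sweep, zero-length ones dropped."""
        segs = [
            (self.holding_potential, self.pre_step_duration),
            (float(step_potential), self.step_duration),
            (self.holding_potential, self.post_step_duration),
        ]
        return [(v, d) for v, d in segs if d > 0]


def make_protocol(**config) -> VoltageProtocol:
    """Build a :class:`VoltageProtocol`; omitted fields take the defaults above.

    Raises :class:`ValidationError` naming the offending field on bad input.
    """
    allowed = {f for f in VoltageProtocol.__dataclass_fields__}
    unknown = set(config) - allowed
    if unknown:
        raise ValidationError(f"unknown protocol field(s): {sorted(unknown)}")
    return VoltageProtocol(**config)
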