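"""In-memory representation of whole-cell voltage-clamp recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingSweepError, ValidationError


@dataclass
class CellRecording:
    """One cell's sweeps plus recording-quality metadata.

    ``sweeps`` maps step potential (mV) to the current trace (pA) sampled on
    the shared ``time`` base (ms from sweep start, first sample at t = 0).
    QC metadata (``v_offset`` mV, ``r_seal`` MΩ, ``r_series`` MΩ, ``c_slow``
    pF) may be NaN to mark an explicitly missing measurement.
    ``ground_truth``, present on simulated cells, lists per-component gating
    parameters (keys: component, weight, k, lam, tau_m, g_max, f_ss).
    """

    cell_id: str
    condition: str
    time: np.ndarray
    sweeps: dict[float, np.ndarray]
    v_offset: float = float("nan")
    r_seal: float = float("nan")
    r_series: float = float("nan")
    c_slow: float = float("nan")
    temperature: float = 25.0
    ground_truth: list[dict] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sweeps = {float(v): np.asarray(i, dtype=float) for v, i in self.sweeps.items()}
        n = self.time.size
        for v, trace in self.sweeps.items():
            if trace.size != n:
                raise ValidationError(
                    f"cell {self.cell_id}: sweep at {v} mV has {trace.size} samples, "
                    f"time base has {n}"
                )

    @property
    def step_potentials(self) -> list[float]:
        return sorted(self.sweeps)

    def sweep(self, potential: float, tol: float = 1e-6) -> np.ndarray:
        """Current trace at the given step potential (exact within ``tol``)."""
        for v, trace in self.sweeps.items():
            if abs(v - potential) <= tol:
                return trace
        raise MissingSweepError(
            f"cell {self.cell_id}: no sweep at {potential} mV; "
            f"available steps: {self.step_potentials}"
        )
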