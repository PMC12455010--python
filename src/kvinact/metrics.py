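"""Inactivation-delay feature extraction.

The core statistic is the inactivation width (Inac-width): the temporal
width of the normalized +80 mV current trace at 70% of its peak, measured
inside a sweep-relative analysis window (default 70–599 ms).  The upward
crossing is the first time the trace rises through the level, the downward
crossing the last time it falls through it (both linearly interpolated
between bracketing samples), which makes the width robust to brief noise
dips.  A trace that never falls back below the level before the window end
is censored: its width is recorded as window_end − t_up and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import CellRecording
from .errors import NoPeakAboveLevelError, UnanalysableSweepError, ValidationError

DEFAULT_WINDOW: tuple[float, float] = (70.0, 599.0)
DEFAULT_LEVEL: float = 0.7
DEFAULT_TARGET_MV: float = 80.0


@dataclass(frozen=True)
class InactivationMeasurement:
    """Per-cell inactivation measurement on the target sweep.

    ``i_max_na`` is the peak current (nA) inside the window; ``t_up`` /
    ``t_down`` are the interpolated level crossings (ms, sweep-relative);
    ``inac_width = t_down − t_up``.  ``censored`` marks a width truncated
    by the window end.
    """

    cell_id: str
    i_max_na: float
    window: tuple[float, float]
    level: float
    t_up: float
    t_down: float
    inac_width: float
    censored: bool
    n_level_crossings: int


def extract_target_sweep(
    cell: CellRecording, target_potential: float = DEFAULT_TARGET_MV
) -> tuple[np.ndarray, np.ndarray]:
    """Return (time, current) of the sweep at the target step potential."""
    return cell.time, cell.sweep(target_potential)


def normalize_trace(
    time: np.ndarray,
    current: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
    lowpass_khz: float | None = None,
    subtract_baseline: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalize a sweep to its in-window peak.

    Returns ``(t_window, normalized, i_max_pa)`` where ``i_max_pa`` is the
    maximum current inside the window and the normalized trace is the
    windowed current divided by it (so its maximum is exactly 1 at the
    peak sample).  Peak search and normalization are both confined to the
    window, matching the overlay convention.

    ``lowpass_khz`` applies an optional zero-phase 4-pole Butterworth
    low-pass before anything else (e.g. 2.9 to mimic a bench Bessel
    filter); ``subtract_baseline`` removes the mean of the pre-window
    samples first.  Both are off by default.

    Raises :class:`UnanalysableSweepError` for an all-zero or
    negative-peak sweep.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValidationError(f"window must satisfy start < end, got {window}")
    if lo < time[0] - 1e-9 or hi > time[-1] + 1e-9:
        raise ValidationError(
            f"window {window} not contained in sweep time range [{time[0]}, {time[-1]}] ms"
        )
    if subtract_baseline:
        pre = current[time < lo]
        if pre.size:
            current = current - pre.mean()
    if lowpass_khz is not None:
        fs = 1.0 / np.median(np.diff(time))  # kHz
        sos = signal.butter(4, lowpass_khz, btype="low", fs=fs, output="sos")
        current = signal.sosfiltfilt(sos, current)
    mask = (time >= lo - 1e-9) & (time <= hi + 1e-9)
    t_win = time[mask]
    i_win = current[mask]
    i_max = float(i_win.max())
    if i_max <= 0.0:
        raise UnanalysableSweepError(
            f"unanalysable sweep: in-window peak current {i_max:.3g} pA is not positive"
        )
    return t_win, i_win / i_max, i_max


def inac_width(
    t: np.ndarray,
    normalized: np.ndarray,
    level: float = DEFAULT_LEVEL,
    cell_id: str = "",
    i_max_na: float = float("nan"),
) -> InactivationMeasurement:
    """Width at ``level`` of a normalized (max = 1) windowed trace.

    ``t_up``: first upward crossing of the level, linearly interpolated; a
    trace starting at or above the level takes the window start.
    ``t_down``: last downward crossing; if the trace never falls back below
    the level, the measurement is censored at the window end.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    t = np.asarray(t, dtype=float)
    y = np.asarray(normalized, dtype=float)
    above = y >= level
    if not above.any():
        raise NoPeakAboveLevelError(
            f"cell {cell_id or '<unnamed>'}: trace never reaches level {level} "
            f"(max {y.max():.3g})"
        )
    n_crossings = int(np.count_nonzero(np.diff(above.astype(int)) != 0))

    if above[0]:
        t_up = float(t[0])
    else:
        i = int(np.argmax(above))  # first sample at/above level
        frac = (level - y[i - 1]) / (y[i] - y[i - 1])
        t_up = float(t[i - 1] + frac * (t[i] - t[i - 1]))

    if above[-1]:
        t_down = float(t[-1])
        censored = True
    else:
        j = len(y) - 1 - int(np.argmax(above[::-1]))  # last sample at/above level
        frac = (y[j] - level) / (y[j] - y[j + 1])
        t_down = float(t[j] + frac * (t[j + 1] - t[j]))
        censored = False

    return InactivationMeasurement(
        cell_id=cell_id,
        i_max_na=float(i_max_na),
        window=(float(t[0]), float(t[-1])),
        level=float(level),
        t_up=t_up,
        t_down=t_down,
        inac_width=t_down - t_up,
        censored=censored,
        n_level_crossings=n_crossings,
    )


def measure_cell(
    cell: CellRecording,
    target_potential: float = DEFAULT_TARGET_MV,
    window: tuple[float, float] = DEFAULT_WINDOW,
    level: float = DEFAULT_LEVEL,
    **normalize_kwargs,
) -> InactivationMeasurement:
    """End-to-end measurement of one cell's target sweep."""
    time, current = extract_target_sweep(cell, target_potential)
    t_win, y, i_max_pa = normalize_trace(time, current, window=window, **normalize_kwargs)
    return inac_width(t_win, y, level=level, cell_id=cell.cell_id, i_max_na=i_max_pa / 1000.0)


def peak_current_na(
    cell: CellRecording,
    target_potential: float = DEFAULT_TARGET_MV,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """In-window peak current of the target sweep, in nA."""
    time, current = extract_target_sweep(cell, target_potential)
    _, _, i_max_pa = normalize_trace(time, current, window=window)
    return i_max_pa / 1000.0


def measure_cohort(
    cells: list[CellRecording],
    target_potential: float = DEFAULT_TARGET_MV,
    window: tuple[float, float] = DEFAULT_WINDOW,
    level: float = DEFAULT_LEVEL,
    **normalize_kwargs,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Measure every cell; returns (table, failures).

    The table has one row per analysable cell (cell_id, condition,
    i_max_nA, t_up_ms, t_down_ms, inac_width_ms, censored,
    n_level_crossings); ``failures`` maps the cell ids that could not be
    measured to the reason, mirroring manual exclusion of unusable traces.
    """
    rows = []
    failures: dict[str, str] = {}
    for cell in cells:
        try:
            m = measure_cell(cell, target_potential, window, level, **normalize_kwargs)
        except (UnanalysableSweepError, KeyError) as exc:
            failures[cell.cell_id] = str(exc)
            continue
        rows.append(
            {
                "cell_id": m.cell_id,
                "condition": cell.condition,
                "i_max_nA": m.i_max_na,
                "t_up_ms": m.t_up,
                "t_down_ms": m.t_down,
                "inac_width_ms": m.inac_width,
                "censored": m.censored,
                "n_level_crossings": m.n_level_crossings,
            }
        )
    columns = [
        "cell_id", "condition", "i_max_nA", "t_up_ms", "t_down_ms",
        "inac_width_ms", "censored", "n_level_crossings",
    ]
    return pd.DataFrame(rows, columns=columns), failures


def overlay_matrix(
    cells: list[CellRecording],
    target_potential: float = DEFAULT_TARGET_MV,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Normalized overlay matrix (rows: time_ms, columns: cell_id).

    Cells whose target sweep is unanalysable are silently omitted, as in
    the measurement table.
    """
    series = {}
    index = None
    for cell in cells:
        try:
            time, current = extract_target_sweep(cell, target_potential)
            t_win, y, _ = normalize_trace(time, current, window=window)
        except (UnanalysableSweepError, KeyError):
            continue
        if index is None:
            index = t_win
        series[cell.cell_id] = y
    out = pd.DataFrame(series, index=index if index is not None else [])
    out.index.name = "time_ms"
    return out
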