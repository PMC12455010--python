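"""Two-stage cell-selection (quality-control) filtering.

Stage 1 screens amplifier/seal metadata with strict inequalities:
|V-offset| < 45 mV, seal resistance > 200 MΩ, series resistance < 15 MΩ,
slow capacitance < 35 pF.  Stage 2, evaluated only for stage-1 passers,
keeps cells whose peak current lies in the inclusive 0.5–45 nA window.
Missing metadata fails the corresponding criterion (flagged as missing)
rather than raising.  Manual review of unstable recordings is modelled as
an explicit exclusion list.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .cohort import CellRecording
from .errors import ValidationError
from . import metrics


@dataclass(frozen=True)
class QCThresholds:
    """Acceptance thresholds; stage-1 comparisons are strict, stage-2 inclusive."""

    v_offset_max_mv: float = 45.0
    r_seal_min_mohm: float = 200.0
    r_series_max_mohm: float = 15.0
    c_slow_max_pf: float = 35.0
    i_max_min_na: float = 0.5
    i_max_max_na: float = 45.0


@dataclass
class QCResult:
    """Per-cell QC outcome.

    ``failed_criteria`` holds (criterion name, observed value, threshold)
    for each violated criterion of the most recent evaluated stage;
    ``stage2_pass`` is None while stage 2 has not been evaluated.
    """

    cell_id: str
    stage1_pass: bool
    stage2_pass: bool | None = None
    failed_criteria: list[tuple[str, float, float]] = field(default_factory=list)
    manually_excluded: bool = False

    @property
    def final_pass(self) -> bool:
        return (
            self.stage1_pass
            and self.stage2_pass is True
            and not self.manually_excluded
        )


def _is_missing(value: float | None) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def stage1_qc(cell: CellRecording, thresholds: QCThresholds | None = None) -> QCResult:
    """Stage-1 metadata screen; missing fields fail their criterion."""
    th = thresholds or QCThresholds()
    checks = [
        ("V-offset", abs(cell.v_offset) if not _is_missing(cell.v_offset) else float("nan"),
         lambda v: v < th.v_offset_max_mv, th.v_offset_max_mv),
        ("seal resistance", cell.r_seal, lambda v: v > th.r_seal_min_mohm, th.r_seal_min_mohm),
        ("series resistance", cell.r_series, lambda v: v < th.r_series_max_mohm, th.r_series_max_mohm),
        ("C-slow", cell.c_slow, lambda v: v < th.c_slow_max_pf, th.c_slow_max_pf),
    ]
    failed = []
    for name, observed, ok, threshold in checks:
        if _is_missing(observed) or not ok(observed):
            failed.append((name, float("nan") if _is_missing(observed) else float(observed), threshold))
    return QCResult(cell_id=cell.cell_id, stage1_pass=not failed, failed_criteria=failed)


def stage2_qc(result: QCResult, i_max_na: float, thresholds: QCThresholds | None = None) -> QCResult:
    """Stage-2 amplitude criterion (inclusive bounds) on a stage-1 passer."""
    th = thresholds or QCThresholds()
    if not result.stage1_pass:
        raise ValidationError(f"cell {result.cell_id}: stage 2 requires a stage-1 pass")
    failed: list[tuple[str, float, float]] = []
    if _is_missing(i_max_na):
        failed.append(("I_max", float("nan"), th.i_max_min_na))
    elif i_max_na < th.i_max_min_na:
        failed.append((f"I_max below {th.i_max_min_na} nA", float(i_max_na), th.i_max_min_na))
    elif i_max_na > th.i_max_max_na:
        failed.append((f"I_max above {th.i_max_max_na} nA", float(i_max_na), th.i_max_max_na))
    return replace(result, stage2_pass=not failed, failed_criteria=failed)


def _format_failures(failed: list[tuple[str, float, float]]) -> str:
    return "; ".join(f"{name} (observed {obs:g}, threshold {thr:g})" for name, obs, thr in failed)


def apply_qc(
    cells: list[CellRecording],
    thresholds: QCThresholds | None = None,
    exclusion_list: Iterable[str] = (),
    i_max_na: Mapping[str, float] | None = None,
    target_potential: float = metrics.DEFAULT_TARGET_MV,
    window: tuple[float, float] = metrics.DEFAULT_WINDOW,
) -> tuple[list[CellRecording], pd.DataFrame]:
    """Run both stages over a cohort; returns (passing cells, report table).

    Peak currents for stage 2 are computed from the target sweep unless
    supplied via ``i_max_na``; cells whose target sweep is unanalysable
    fail stage 2 with that reason.  The report has exactly one row per
    input cell (conservation), so pass + fail + excluded = input.  Unknown
    ids in ``exclusion_list`` produce a warning, not an error.
    """
    th = thresholds or QCThresholds()
    excluded = set(exclusion_list)
    known = {c.cell_id for c in cells}
    unknown = excluded - known
    if unknown:
        warnings.warn(f"exclusion list names unknown cell_id(s): {sorted(unknown)}", stacklevel=2)

    rows = []
    passing: list[CellRecording] = []
    for cell in cells:
        res = stage1_qc(cell, th)
        imax = float("nan")
        if res.stage1_pass:
            if i_max_na is not None and cell.cell_id in i_max_na:
                imax = float(i_max_na[cell.cell_id])
                res = stage2_qc(res, imax, th)
            else:
                try:
                    imax = metrics.peak_current_na(cell, target_potential, window)
                    res = stage2_qc(res, imax, th)
                except Exception as exc:
                    res = replace(
                        res,
                        stage2_pass=False,
                        failed_criteria=[
                            (f"unanalysable target sweep: {exc}", float("nan"), float("nan"))
                        ],
                    )
        res.manually_excluded = cell.cell_id in excluded
        if res.final_pass:
            passing.append(cell)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "condition": cell.condition,
                "stage1_pass": res.stage1_pass,
                "stage2_pass": res.stage2_pass,
                "i_max_nA": imax,
                "failed_criteria": _format_failures(res.failed_criteria),
                "manually_excluded": res.manually_excluded,
                "final_pass": res.final_pass,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "condition", "stage1_pass", "stage2_pass", "i_max_nA",
            "failed_criteria", "manually_excluded", "final_pass",
        ],
    )
    return passing, report
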