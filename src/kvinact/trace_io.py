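"""Portable on-disk cohort layout.

A cohort directory contains:

* ``manifest.tsv`` — one row per cell: cell_id, condition, temperature_C,
  v_offset_mV, r_seal_MOhm, r_series_MOhm, c_slow_pF, trace_file (path
  relative to the manifest).
* ``traces/<cell_id>.tsv`` — long format, columns
  ``step_potential_mV  time_ms  current_pA``, time in ms from sweep start
  (first sample at t = 0), current in pA.
* ``ground_truth.tsv`` (optional sidecar, simulated cohorts only) —
  cell_id, component, weight, k, lambda_per_ms, tau_m_ms, g_max_nS, f_ss.

Floats are written with shortest round-trip decimal representation so that
write→read is bit-exact on the data model and read→write is byte-identical
on canonical files.  Missing QC metadata is written as ``nan``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CellRecording
from .errors import CohortFormatError

MANIFEST_COLUMNS = [
    "cell_id",
    "condition",
    "temperature_C",
    "v_offset_mV",
    "r_seal_MOhm",
    "r_series_MOhm",
    "c_slow_pF",
    "trace_file",
]
TRACE_COLUMNS = ["step_potential_mV", "time_ms", "current_pA"]
_CURRENT_SCALE = {"pA": 1.0, "nA": 1000.0}


def _fmt(x: float) -> str:
    return repr(float(x))


def write_cohort(
    cells: list[CellRecording], out_dir: str | Path, current_unit: str = "pA"
) -> Path:
    """Write a cohort in the portable layout; returns the manifest path.

    ``current_unit`` declares the unit of the in-memory traces; anything
    other than pA is converted on write (the files are always pA).  File
    ordering is deterministic (sorted cell_id).
    """
    if current_unit not in _CURRENT_SCALE:
        raise CohortFormatError(
            f"unsupported current unit {current_unit!r}; expected one of {sorted(_CURRENT_SCALE)}"
        )
    scale = _CURRENT_SCALE[current_unit]
    out_dir = Path(out_dir)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)
    ordered = sorted(cells, key=lambda c: c.cell_id)
    seen: set[str] = set()
    for cell in ordered:
        if cell.cell_id in seen:
            raise CohortFormatError(f"duplicate cell_id {cell.cell_id!r} in cohort")
        seen.add(cell.cell_id)

    manifest_lines = ["\t".join(MANIFEST_COLUMNS)]
    gt_rows: list[str] = []
    for cell in ordered:
        trace_rel = f"traces/{cell.cell_id}.tsv"
        lines = ["\t".join(TRACE_COLUMNS)]
        for v in sorted(cell.sweeps):
            v_str = _fmt(v)
            trace = cell.sweeps[v] * scale
            lines.extend(
                f"{v_str}\t{_fmt(t)}\t{_fmt(i)}" for t, i in zip(cell.time, trace)
            )
        (out_dir / trace_rel).write_text("\n".join(lines) + "\n")
        manifest_lines.append(
            "\t".join(
                [
                    cell.cell_id,
                    cell.condition,
                    _fmt(cell.temperature),
                    _fmt(cell.v_offset),
                    _fmt(cell.r_seal),
                    _fmt(cell.r_series),
                    _fmt(cell.c_slow),
                    trace_rel,
                ]
            )
        )
        if cell.ground_truth:
            for row in cell.ground_truth:
                gt_rows.append(
                    "\t".join(
                        [
                            cell.cell_id,
                            str(int(row["component"])),
                            _fmt(row["weight"]),
                            str(int(row["k"])),
                            _fmt(row["lam"]),
                            _fmt(row["tau_m"]),
                            _fmt(row["g_max"]),
                            _fmt(row.get("f_ss", 0.0)),
                        ]
                    )
                )
    manifest_path = out_dir / "manifest.tsv"
    manifest_path.write_text("\n".join(manifest_lines) + "\n")
    if gt_rows:
        header = "cell_id\tcomponent\tweight\tk\tlambda_per_ms\ttau_m_ms\tg_max_nS\tf_ss"
        (out_dir / "ground_truth.tsv").write_text("\n".join([header] + gt_rows) + "\n")
    return manifest_path


def _read_trace_file(path: Path, cell_id: str) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    try:
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise CohortFormatError(f"{path}: cannot parse trace file for cell {cell_id!r}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise CohortFormatError(f"{path}, line 1: missing column(s) {missing}")
    time_base: np.ndarray | None = None
    sweeps: dict[float, np.ndarray] = {}
    for v, group in table.groupby("step_potential_mV", sort=True):
        t = group["time_ms"].to_numpy(dtype=float)
        if t.size > 1:
            dts = np.diff(t)
            if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9):
                first_bad = int(np.argmax(~np.isclose(dts, dts[0], rtol=1e-9, atol=1e-9)))
                line = int(group.index[first_bad + 1]) + 2  # +header +0-based
                raise CohortFormatError(
                    f"{path}, line {line}: non-uniform time grid in sweep at {v} mV"
                )
        if time_base is None:
            time_base = t
        elif t.size != time_base.size or not np.array_equal(t, time_base):
            raise CohortFormatError(
                f"{path}: sweep at {v} mV does not share the time base of the first sweep"
            )
        sweeps[float(v)] = group["current_pA"].to_numpy(dtype=float)
    if time_base is None:
        raise CohortFormatError(f"{path}: trace file for cell {cell_id!r} contains no samples")
    return time_base, sweeps


def read_cohort(manifest_path: str | Path) -> list[CellRecording]:
    """Read a cohort written by :func:`write_cohort` (or hand-converted data).

    Validates unique cell ids, existing trace files, required columns and a
    uniform shared time grid per cell; attaches the ground-truth sidecar
    when present.  Errors name the offending file (and line where known).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CohortFormatError(f"{manifest_path}: manifest not found")
    try:
        manifest = pd.read_csv(manifest_path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise CohortFormatError(f"{manifest_path}: cannot parse manifest: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise CohortFormatError(f"{manifest_path}, line 1: missing column(s) {missing}")
    dupes = manifest["cell_id"][manifest["cell_id"].duplicated()].tolist()
    if dupes:
        raise CohortFormatError(f"{manifest_path}: duplicate cell_id(s): {sorted(set(dupes))}")

    gt_path = manifest_path.parent / "ground_truth.tsv"
    gt_by_cell: dict[str, list[dict]] = {}
    if gt_path.exists():
        gt = pd.read_csv(gt_path, sep="\t", float_precision="round_trip")
        for cell_id, group in gt.groupby("cell_id"):
            gt_by_cell[str(cell_id)] = [
                {
                    "component": int(r["component"]),
                    "weight": float(r["weight"]),
                    "k": int(r["k"]),
                    "lam": float(r["lambda_per_ms"]),
                    "tau_m": float(r["tau_m_ms"]),
                    "g_max": float(r["g_max_nS"]),
                    "f_ss": float(r.get("f_ss", 0.0)),
                }
                for _, r in group.iterrows()
            ]

    cells: list[CellRecording] = []
    for line_no, row in enumerate(manifest.itertuples(index=False), start=2):
        trace_path = manifest_path.parent / str(row.trace_file)
        if not trace_path.exists():
            raise CohortFormatError(
                f"{manifest_path}, line {line_no}: trace file {row.trace_file!r} for "
                f"cell {row.cell_id!r} does not exist"
            )
        time_base, sweeps = _read_trace_file(trace_path, str(row.cell_id))
        cells.append(
            CellRecording(
                cell_id=str(row.cell_id),
                condition=str(row.condition),
                time=time_base,
                sweeps=sweeps,
                v_offset=float(row.v_offset_mV),
                r_seal=float(row.r_seal_MOhm),
                r_series=float(row.r_series_MOhm),
                c_slow=float(row.c_slow_pF),
                temperature=float(row.temperature_C),
                ground_truth=gt_by_cell.get(str(row.cell_id)),
            )
        )
    return cells
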