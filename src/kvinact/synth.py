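"""Synthetic voltage-clamp cohort generator with full ground truth.

Forward model for one sweep at step potential V:

    I(t) = Σ_c w_c · g_max,c · m_c(t)^p · h_c(t) · (V_seg − E_K,c)
           + g_leak · (V_seg − E_leak) + ε(t),   ε ~ N(0, baseline_sd²)

with the activation gate solved exactly per voltage segment and the Erlang
docking chain engaged only while the segment potential is at or above an
engagement threshold (default −40 mV), reflecting open-state N-type block —
the chain holds its occupancy during hyperpolarized segments.

Heterogeneity across a "control" cohort comes from per-cell glycoform
mixtures: each cell mixes a fast component (short docking chain) with a
slow one (longer chain, long mean latency) in random proportion, so
measured inactivation delays span tens to hundreds of ms.  A
"deglycosylated" cohort (tunicamycin-like) collapses every cell to the
single fast component, giving a narrow fast range.  Per-cell maximal
conductance is drawn log-uniformly so peak currents fall in the 0.5–45 nA
acceptance window.

Determinism: cohort parameter draws are seeded by ``seed + global cell
index``; measurement noise is seeded independently from
``NoiseModel.rng_seed`` and the cell index, so the same parameter seed with
a different noise seed reproduces the same ground truth under fresh noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cohort import CellRecording
from .errors import ValidationError
from .gating import E_K_DEFAULT, ErlangChainState, GatingModel
from .protocol import VoltageProtocol

__all__ = [
    "GlycoformMixture",
    "NoiseModel",
    "QCSpec",
    "ConditionSpec",
    "simulate_cell",
    "simulate_cohort",
    "control_sampler",
    "deglyco_sampler",
    "delay_spread_sampler",
    "PRESETS",
]

#: Chain engagement threshold (mV): docking proceeds only at or above this.
INACTIVATION_ENGAGE_MV = -40.0


@dataclass(frozen=True)
class GlycoformMixture:
    """Weighted mixture of channel sub-populations within one cell.

    Weights must be non-negative and sum to 1 (within 1e−9).
    """

    components: tuple[tuple[GatingModel, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((m, float(w)) for m, w in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValidationError("mixture needs at least one component")
        weights = np.array([w for _, w in comps])
        if np.any(weights < 0):
            raise ValidationError(f"mixture weights must be >= 0, got {weights.tolist()}")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError(f"mixture weights must sum to 1, got {weights.sum()!r}")

    @classmethod
    def single(cls, model: GatingModel) -> "GlycoformMixture":
        return cls(((model, 1.0),))

    def ground_truth(self) -> list[dict]:
        return [
            {
                "component": i,
                "weight": w,
                "k": m.k,
                "lam": m.lam,
                "tau_m": m.tau_m,
                "g_max": m.g_max,
                "f_ss": m.f_ss,
            }
            for i, (m, w) in enumerate(self.components)
        ]


@dataclass(frozen=True)
class NoiseModel:
    """Additive recording imperfections: Gaussian baseline noise and ohmic leak."""

    baseline_sd: float = 5.0  # pA
    leak_conductance: float = 0.5  # nS
    leak_reversal: float = 0.0  # mV
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValidationError(f"baseline_sd must be >= 0, got {self.baseline_sd}")
        if self.leak_conductance < 0:
            raise ValidationError(f"leak_conductance must be >= 0, got {self.leak_conductance}")


@dataclass(frozen=True)
class QCSpec:
    """Distributions for simulated recording-quality metadata.

    Passing cells draw each metric uniformly from its ``*_pass`` range, all
    safely inside the acceptance thresholds (|V-offset| < 45 mV, R-seal >
    200 MΩ, R-series < 15 MΩ, C-slow < 35 pF).  A ``fail_fraction`` of
    cells per condition is planted as stage-1 failures: one metric, chosen
    at random, is drawn from its ``*_fail`` range instead.
    """

    fail_fraction: float = 0.0
    v_offset_pass: tuple[float, float] = (1.0, 30.0)
    r_seal_pass: tuple[float, float] = (300.0, 2000.0)
    r_series_pass: tuple[float, float] = (4.0, 12.0)
    c_slow_pass: tuple[float, float] = (8.0, 30.0)
    v_offset_fail: tuple[float, float] = (50.0, 80.0)
    r_seal_fail: tuple[float, float] = (50.0, 180.0)
    r_series_fail: tuple[float, float] = (18.0, 40.0)
    c_slow_fail: tuple[float, float] = (38.0, 60.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fail_fraction <= 1.0:
            raise ValidationError(f"fail_fraction must be in [0, 1], got {self.fail_fraction}")

    def draw(self, rng: np.random.Generator, plant_failure: bool) -> dict[str, float]:
        meta = {
            "v_offset": rng.uniform(*self.v_offset_pass) * rng.choice([-1.0, 1.0]),
            "r_seal": rng.uniform(*self.r_seal_pass),
            "r_series": rng.uniform(*self.r_series_pass),
            "c_slow": rng.uniform(*self.c_slow_pass),
        }
        if plant_failure:
            which = rng.choice(["v_offset", "r_seal", "r_series", "c_slow"])
            fail_range = getattr(self, f"{which}_fail")
            meta[which] = float(rng.uniform(*fail_range))
        return meta


def simulate_cell(
    mixture: GlycoformMixture,
    protocol: VoltageProtocol,
    noise: NoiseModel,
    qc_metadata: dict[str, float] | None = None,
    cell_id: str = "cell-000",
    condition: str = "control",
    temperature: float = 25.0,
    noise_rng: np.random.Generator | None = None,
    engage_potential: float = INACTIVATION_ENGAGE_MV,
) -> CellRecording:
    """Simulate one cell: every sweep of the protocol plus QC metadata.

    Deterministic given ``noise_rng``; with ``baseline_sd = 0``,
    ``leak_conductance = 0`` and a zero-conductance mixture the sweeps are
    identically zero, and a sweep at V = E_K carries no channel current.
    """
    if noise_rng is None:
        noise_rng = np.random.default_rng(noise.rng_seed)
    qc_metadata = qc_metadata or {}
    times = protocol.times()
    n = times.size
    sweeps: dict[float, np.ndarray] = {}
    for v_step in protocol.step_potentials:
        current = np.zeros(n)
        segs = protocol.segments(v_step)
        for model, weight in mixture.components:
            if weight == 0.0 or model.g_max == 0.0:
                continue
            chain = ErlangChainState(model.k, model.lam, model.f_ss)
            m_cur = float(model.m_inf(protocol.holding_potential))
            start = 0
            t0 = 0.0
            for v_seg, dur in segs:
                n_seg = int(round(dur * protocol.sampling_rate))
                sl = slice(start, min(start + n_seg, n))
                t_rel = times[sl] - t0
                minf = float(model.m_inf(v_seg))
                m_vals = minf + (m_cur - minf) * np.exp(-t_rel / model.tau_m)
                if v_seg >= engage_potential:
                    h_vals = chain.survival_profile(t_rel)
                    chain.advance(dur)
                else:
                    h_vals = chain.survival_now
                current[sl] += weight * model.g_max * m_vals**model.p * h_vals * (v_seg - model.e_k)
                m_cur = minf + (m_cur - minf) * np.exp(-dur / model.tau_m)
                start += n_seg
                t0 += dur
        # leak follows the command potential segment-wise
        start = 0
        for v_seg, dur in segs:
            n_seg = int(round(dur * protocol.sampling_rate))
            current[start : start + n_seg] += noise.leak_conductance * (v_seg - noise.leak_reversal)
            start += n_seg
        if noise.baseline_sd > 0:
            current += noise_rng.normal(0.0, noise.baseline_sd, size=n)
        sweeps[float(v_step)] = current
    return CellRecording(
        cell_id=cell_id,
        condition=condition,
        time=times,
        sweeps=sweeps,
        v_offset=qc_metadata.get("v_offset", float("nan")),
        r_seal=qc_metadata.get("r_seal", float("nan")),
        r_series=qc_metadata.get("r_series", float("nan")),
        c_slow=qc_metadata.get("c_slow", float("nan")),
        temperature=temperature,
        ground_truth=mixture.ground_truth(),
    )


# ---------------------------------------------------------------------------
# Cohort presets

def _draw_conductance(rng: np.random.Generator) -> float:
    """Per-cell maximal conductance, log-uniform 15–220 nS.

    At +80 mV with E_K ≈ −85 mV this puts peak currents roughly in the
    1–25 nA range, inside the 0.5–45 nA amplitude-acceptance window.
    """
    return float(10 ** rng.uniform(np.log10(15.0), np.log10(220.0)))


def control_sampler(rng: np.random.Generator) -> GlycoformMixture:
    """Fully glycosylated ("control") cell: fast + slow glycoform mixture.

    Fast component: single-step docking (k = 1), mean latency 8–15 ms.
    Slow component: k ∈ {4, …, 12} chain with mean latency 60–400 ms.
    Mixing fraction of the fast component is uniform on [0.15, 0.6], so
    measured inactivation widths span tens to hundreds of ms across cells.
    """
    g = _draw_conductance(rng)
    w_fast = float(rng.uniform(0.15, 0.6))
    fast = GatingModel(g_max=g, k=1, lam=1.0 / rng.uniform(8.0, 15.0), f_ss=0.02)
    k_slow = int(rng.integers(4, 13))
    mean_slow = float(rng.uniform(60.0, 400.0))
    slow = GatingModel(g_max=g, k=k_slow, lam=k_slow / mean_slow, f_ss=0.02)
    return GlycoformMixture(((fast, w_fast), (slow, 1.0 - w_fast)))


def deglyco_sampler(rng: np.random.Generator) -> GlycoformMixture:
    """Deglycosylated (tunicamycin-like) cell: single fast component only."""
    g = _draw_conductance(rng)
    fast = GatingModel(g_max=g, k=1, lam=1.0 / rng.uniform(8.0, 15.0), f_ss=0.02)
    return GlycoformMixture.single(fast)


def delay_spread_sampler(
    mean_ms: float = 120.0, sd_ms: float = 60.0, k: int = 4
) -> Callable[[np.random.Generator], GlycoformMixture]:
    """Single-component sampler with controllable ground-truth delay spread.

    Each cell draws its mean docking latency from N(mean_ms, sd_ms²)
    truncated below at 5 ms; ``sd_ms = 0`` gives identical kinetics in
    every cell.  Used for heterogeneity-recovery studies where the
    between-cell delay SD is the known quantity.
    """
    if mean_ms <= 5.0:
        raise ValidationError(f"mean_ms must exceed the 5 ms floor, got {mean_ms}")
    if sd_ms < 0:
        raise ValidationError(f"sd_ms must be >= 0, got {sd_ms}")

    def sampler(rng: np.random.Generator) -> GlycoformMixture:
        mu = max(5.0, float(rng.normal(mean_ms, sd_ms))) if sd_ms > 0 else mean_ms
        model = GatingModel(g_max=_draw_conductance(rng), k=k, lam=k / mu, f_ss=0.02)
        return GlycoformMixture.single(model)

    return sampler


PRESETS: dict[str, Callable[[np.random.Generator], GlycoformMixture]] = {
    "control": control_sampler,
    "deglyco": deglyco_sampler,
    "tunicamycin": deglyco_sampler,
}


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition in a simulated cohort."""

    label: str
    sampler: Callable[[np.random.Generator], GlycoformMixture]
    n_cells: int
    qc_spec: QCSpec = field(default_factory=QCSpec)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(f"n_cells must be >= 1, got {self.n_cells}")

    @classmethod
    def preset(cls, label: str, n_cells: int, qc_spec: QCSpec | None = None,
               preset: str | None = None) -> "ConditionSpec":
        name = preset or label
        if name not in PRESETS:
            raise ValidationError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        return cls(label, PRESETS[name], n_cells, qc_spec or QCSpec())


def simulate_cohort(
    condition_specs: Sequence[ConditionSpec],
    protocol: VoltageProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> list[CellRecording]:
    """Simulate a multi-condition cohort, deterministic given ``seed``.

    Cell ``i`` (global index across conditions, in spec order) draws its
    gating parameters and QC metadata from ``default_rng(seed + i)`` and
    its noise from ``default_rng([noise.rng_seed, i])``.  Within each
    condition, ``round(fail_fraction · n_cells)`` cells are planted as
    stage-1 QC failures (chosen by a per-condition RNG).
    """
    protocol = protocol or VoltageProtocol()
    noise = noise or NoiseModel()
    cells: list[CellRecording] = []
    global_idx = 0
    for cond_idx, spec in enumerate(condition_specs):
        cond_rng = np.random.default_rng([seed, cond_idx])
        n_fail = int(round(spec.qc_spec.fail_fraction * spec.n_cells))
        fail_cells = set(cond_rng.choice(spec.n_cells, size=n_fail, replace=False).tolist())
        for i in range(spec.n_cells):
            param_rng = np.random.default_rng(seed + global_idx)
            noise_rng = np.random.default_rng([noise.rng_seed, global_idx])
            mixture = spec.sampler(param_rng)
            qc_meta = spec.qc_spec.draw(param_rng, plant_failure=i in fail_cells)
            cells.append(
                simulate_cell(
                    mixture,
                    protocol,
                    noise,
                    qc_metadata=qc_meta,
                    cell_id=f"{spec.label}-{i:03d}",
                    condition=spec.label,
                    noise_rng=noise_rng,
                )
            )
            global_idx += 1
    return cells
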