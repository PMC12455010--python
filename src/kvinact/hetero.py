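"""Heterogeneity quantification via Tukey boxplot whisker spans.

The heterogeneity of an Inac-width distribution is the distance between
the boxplot whiskers, where each whisker extends from the box edge to the
furthest observation within 1.5·IQR of that edge and anything beyond is an
outlier.  A wide whisker span means cells range from fast to slow
inactivation; a collapsed span means kinetic homogeneity.  Quartiles use
linear interpolation of the empirical quantile function by default
("type 7"), with Tukey hinges available as a sensitivity alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, UnknownConditionError, ValidationError

QUARTILE_CONVENTIONS = ("linear", "hinges")


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number boxplot summary plus the Tukey outlier partition."""

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    whisker_span: float
    outliers: tuple[float, ...]
    low_n: bool = False

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n", "median", "q1", "q3", "iqr", "whisker_low", "whisker_high",
            "whisker_span", "low_n")}
        d["outliers"] = list(self.outliers)
        return d


def _tukey_hinges(sorted_values: np.ndarray) -> tuple[float, float]:
    # hinges: medians of the lower/upper halves, each half including the
    # overall median position for odd n
    n = sorted_values.size
    h = (n + 1) // 2
    return float(np.median(sorted_values[:h])), float(np.median(sorted_values[-h:]))


def boxplot_stats(values, convention: str = "linear") -> BoxplotStats:
    """Boxplot statistics of a sample of inactivation widths (ms).

    ``convention`` selects the quartile rule: "linear" (interpolated
    empirical quantiles) or "hinges" (Tukey hinges).  Raises on empty
    input; samples with n < 4 are computed but flagged ``low_n``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("boxplot_stats requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("boxplot_stats requires finite values")
    arr = np.sort(arr)
    median = float(np.median(arr))
    if convention == "linear":
        q1, q3 = (float(q) for q in np.quantile(arr, [0.25, 0.75]))
    elif convention == "hinges":
        q1, q3 = _tukey_hinges(arr)
    else:
        raise ValidationError(
            f"unknown quartile convention {convention!r}; expected one of {QUARTILE_CONVENTIONS}"
        )
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    return BoxplotStats(
        n=int(arr.size),
        median=median,
        q1=q1,
        q3=q3,
        iqr=iqr,
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        whisker_span=whisker_high - whisker_low,
        outliers=tuple(float(x) for x in outliers),
        low_n=arr.size < 4,
    )


def whisker_span(stats: BoxplotStats) -> float:
    """Whisker-to-whisker distance: the heterogeneity metric."""
    return stats.whisker_high - stats.whisker_low


def pearson_corr(x, y) -> float:
    """Pearson product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 pairs, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined: zero variance in input")
    return float(sps.pearsonr(x, y).statistic)


@dataclass
class HeterogeneityReport:
    """Per-condition boxplot statistics and span comparison vs a reference.

    ``span_ratio[label]`` is that condition's whisker span divided by the
    reference condition's span (NaN when the reference span is zero);
    ``correlations[label]`` is the Pearson r between peak current and
    width, None when not computable (n < 3 or zero variance).
    """

    reference: str
    convention: str
    include_censored: bool
    conditions: dict[str, BoxplotStats] = field(default_factory=dict)
    span_ratio: dict[str, float] = field(default_factory=dict)
    correlations: dict[str, float | None] = field(default_factory=dict)
    n_censored: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "convention": self.convention,
            "include_censored": self.include_censored,
            "conditions": {k: v.to_dict() for k, v in self.conditions.items()},
            "span_ratio": self.span_ratio,
            "correlations": self.correlations,
            "n_censored": self.n_censored,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, st in self.conditions.items():
            row = {"condition": label, **st.to_dict()}
            row["outliers"] = ";".join(repr(v) for v in st.outliers)
            row["span_ratio_vs_reference"] = self.span_ratio[label]
            row["pearson_imax_width"] = self.correlations[label]
            row["n_censored"] = self.n_censored[label]
            rows.append(row)
        return pd.DataFrame(rows)


def compare_conditions(
    measurements: pd.DataFrame,
    reference: str = "control",
    convention: str = "linear",
    include_censored: bool = True,
) -> HeterogeneityReport:
    """Condition-level heterogeneity comparison of an Inac-width table.

    ``measurements`` is the per-cell table from the measurement step
    (columns: condition, inac_width_ms, i_max_nA, censored).  Censored
    (window-limited) widths are included with their truncated value by
    default; ``include_censored=False`` is the sensitivity mode that drops
    them.  Raises :class:`UnknownConditionError` if the reference label is
    absent.
    """
    labels = list(dict.fromkeys(measurements["condition"]))
    if reference not in labels:
        raise UnknownConditionError(
            f"reference condition {reference!r} not present; available: {labels}"
        )
    report = HeterogeneityReport(
        reference=reference, convention=convention, include_censored=include_censored
    )
    data = measurements if include_censored else measurements[~measurements["censored"]]
    for label in labels:
        sub = data[data["condition"] == label]
        if sub.empty:
            raise ValidationError(
                f"condition {label!r} has no measurable cells"
                + ("" if include_censored else " after dropping censored widths")
            )
        report.conditions[label] = boxplot_stats(sub["inac_width_ms"], convention=convention)
        full = measurements[measurements["condition"] == label]
        report.n_censored[label] = int(full["censored"].sum())
        try:
            report.correlations[label] = pearson_corr(sub["i_max_nA"], sub["inac_width_ms"])
        except (ValidationError, DomainError):
            report.correlations[label] = None
    ref_span = report.conditions[reference].whisker_span
    for label in labels:
        span = report.conditions[label].whisker_span
        report.span_ratio[label] = span / ref_span if ref_span > 0 else float("nan")
    return report
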