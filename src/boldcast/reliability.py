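"""Test-retest reliability of functional connectivity (FC).

The FC matrix of a subject is the Pearson correlation between every pair of
region time series. To ask whether forecasts preserve a subject's connectome,
the predicted and ground-truth series are treated as two "sessions": for each
FC edge, the intraclass correlation coefficient ICC(2,1) — two-way random
effects, absolute agreement, single measures — is computed across subjects,

    ICC(2,1) = (MS_R - MS_E) /
               (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n),

with n subjects, k = 2 sessions, and MS_R / MS_C / MS_E the rows (subjects),
columns (sessions) and error mean squares of the two-way ANOVA. Edges are
graded by the conventional test-retest thresholds: poor (< 0.40),
fair (0.40-0.60), good (0.60-0.75), excellent (> 0.75); values exactly at
0.40 or 0.60 take the higher grade and exactly 0.75 is good.

Individual-level agreement is the per-region Pearson correlation between the
predicted and true series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RoiTimeSeries

__all__ = [
    "FcMatrix",
    "ReliabilityReport",
    "fc_matrix",
    "icc21",
    "icc_edges",
    "grade_icc",
    "subject_pearson",
    "reliability_report",
]


@dataclass
class FcMatrix:
    """Symmetric Pearson-correlation matrix with unit diagonal."""

    values: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        self.values = v

    def upper_edges(self) -> np.ndarray:
        """Upper-triangle edge values in row-major order, length m(m-1)/2."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class ReliabilityReport:
    icc_per_edge: np.ndarray           # NaN where the edge is degenerate
    grades: list[str | None]           # None where degenerate
    per_subject_pearson: np.ndarray    # (n_subjects, m)
    n_degenerate_edges: int
    edge_labels: list[tuple[str, str]]

    def grade_histogram(self) -> dict[str, int]:
        counts = {"poor": 0, "fair": 0, "good": 0, "excellent": 0}
        for g in self.grades:
            if g is not None:
                counts[g] += 1
        return counts


def fc_matrix(series: RoiTimeSeries) -> FcMatrix:
    """Pairwise Pearson correlation of all region time series."""
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for an FC matrix")
    sd = series.data.std(axis=1)
    if np.any(sd == 0):
        bad = series.region_labels[int(np.argmax(sd == 0))]
        raise ValueError(f"region {bad!r} is constant; correlation undefined")
    return FcMatrix(np.corrcoef(series.data), list(series.region_labels))


def icc21(data: np.ndarray) -> float:
    """ICC(2,1) of an (n_subjects, k_sessions) table; NaN if degenerate."""
    y = np.asarray(data, dtype=np.float64)
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 sessions")
    grand = y.mean()
    row_m = y.mean(axis=1)
    col_m = y.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_edges(fc_predicted: list[FcMatrix], fc_true: list[FcMatrix]
              ) -> np.ndarray:
    """Per-edge ICC(2,1) across subjects, sessions = {predicted, true}.

    Degenerate edges (zero variance everywhere) come back NaN; values are
    clipped to [-1, 1] for reporting.
    """
    if len(fc_predicted) != len(fc_true):
        raise ValueError("session lists must cover the same subjects")
    if len(fc_predicted) < 3:
        raise ValueError("need at least 3 subjects")
    labels = fc_predicted[0].region_labels
    for f in (*fc_predicted, *fc_true):
        if f.region_labels != labels:
            raise ValueError("all FC matrices must share the region set")
    pred = np.stack([f.upper_edges() for f in fc_predicted])  # (n, E)
    true = np.stack([f.upper_edges() for f in fc_true])
    n_edges = pred.shape[1]
    out = np.empty(n_edges)
    for e in range(n_edges):
        table = np.column_stack([pred[:, e], true[:, e]])
        if np.allclose(table, table.flat[0]):
            out[e] = np.nan
        else:
            out[e] = icc21(table)
    finite = np.isfinite(out)
    out[finite] = np.clip(out[finite], -1.0, 1.0)
    return out


def grade_icc(icc: float) -> str:
    """Map an ICC value to poor/fair/good/excellent."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc <= 0.75:
        return "good"
    return "excellent"


def subject_pearson(predicted: RoiTimeSeries, truth: RoiTimeSeries
                    ) -> np.ndarray:
    """Pearson r between predicted and true series, one value per region."""
    if predicted.data.shape != truth.data.shape:
        raise ValueError("predicted and truth must have matching shapes")
    out = np.empty(predicted.n_regions)
    for i in range(predicted.n_regions):
        a, b = predicted.data[i], truth.data[i]
        if a.std() == 0 or b.std() == 0:
            raise ValueError(
                f"region {predicted.region_labels[i]!r} segment is constant; "
                "correlation undefined")
        out[i] = np.corrcoef(a, b)[0, 1]
    return out


def reliability_report(predicted: list[RoiTimeSeries],
                       truth: list[RoiTimeSeries]) -> ReliabilityReport:
    """Full report: per-edge ICC + grades + per-subject Pearson."""
    fc_p = [fc_matrix(s) for s in predicted]
    fc_t = [fc_matrix(s) for s in truth]
    icc = icc_edges(fc_p, fc_t)
    grades = [grade_icc(v) if np.isfinite(v) else None for v in icc]
    pearson = np.stack([subject_pearson(p, t)
                        for p, t in zip(predicted, truth)])
    labels = fc_p[0].region_labels
    iu = np.triu_indices(len(labels), k=1)
    edge_labels = [(labels[i], labels[j]) for i, j in zip(*iu)]
    return ReliabilityReport(icc, grades, pearson,
                             int(np.sum(~np.isfinite(icc))), edge_labels)
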