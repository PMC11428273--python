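"""ROI time-series containers and their on-disk formats.

A subject is a ``regions x timepoints`` real matrix with region labels and the
sampling interval (TR, seconds). Tables are CSV/TSV with the region label in
the first column and one column per timepoint; cohorts can also live in a
single HDF5 file with one dataset per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "Cohort",
    "read_roi_table",
    "write_roi_table",
    "read_cohort_h5",
    "write_cohort_h5",
]


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


@dataclass
class RoiTimeSeries:
    """One subject's ROI-averaged BOLD signals.

    Parameters
    ----------
    subject_id : str
        Identifier; used as the HDF5 group name in cohort containers.
    region_labels : list of str
        Unique region names, one per row of ``data``.
    data : ndarray, shape (m, T)
        Finite real matrix; row ``i`` is the time series of region ``i``.
    tr_seconds : float
        Repetition time (sampling interval) in seconds; converts
        cycles/sample to Hz.
    """

    subject_id: str
    region_labels: list[str]
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.region_labels = list(self.region_labels)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D regions x timepoints matrix")
        m, T = self.data.shape
        if m == 0:
            raise ValidationError("at least one region is required")
        if T < 2:
            raise ValidationError(f"need at least 2 timepoints, got {T}")
        if len(self.region_labels) != m:
            raise ValidationError(
                f"{len(self.region_labels)} labels for {m} data rows")
        if len(set(self.region_labels)) != m:
            raise ValidationError("region labels must be unique")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValidationError(
                f"non-finite value at region {self.region_labels[bad[0]]!r}, "
                f"timepoint {bad[1]}")
        if not (self.tr_seconds > 0):
            raise ValidationError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class Cohort:
    """An ordered list of subjects sharing region labels and TR."""

    subjects: list[RoiTimeSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValidationError("cohort must contain at least one subject")
        ref = self.subjects[0]
        for s in self.subjects[1:]:
            if s.region_labels != ref.region_labels:
                raise ValidationError(
                    f"subject {s.subject_id!r} region labels differ from "
                    f"{ref.subject_id!r}")
            if s.tr_seconds != ref.tr_seconds:
                raise ValidationError(
                    f"subject {s.subject_id!r} TR differs from {ref.subject_id!r}")

    @property
    def region_labels(self) -> list[str]:
        return self.subjects[0].region_labels

    @property
    def tr_seconds(self) -> float:
        return self.subjects[0].tr_seconds

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_roi_table(path: str | Path, tr_seconds: float,
                   subject_id: str | None = None) -> RoiTimeSeries:
    """Read a regions x timepoints table (CSV/TSV, labels in first column)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str,
                     skipinitialspace=True)
    # optional header row: first cell non-numeric AND remaining cells of row 0
    # non-numeric beyond the label column is ambiguous; we detect a header by
    # the second cell of the first row failing float conversion
    first_vals = df.iloc[0, 1:]
    try:
        first_vals.astype(float)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    labels = df.iloc[:, 0].tolist()
    raw = df.iloc[:, 1:]
    try:
        data = raw.astype(float).to_numpy()
    except (TypeError, ValueError):
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                try:
                    float(raw.iat[i, j])
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"malformed numeric cell at row {i} "
                        f"(region {labels[i]!r}), column {j + 1}") from None
        raise
    return RoiTimeSeries(subject_id or path.stem, labels, data, tr_seconds)


def write_roi_table(series: RoiTimeSeries, path: str | Path) -> None:
    """Write a RoiTimeSeries as a label + timepoints table (CSV or TSV)."""
    path = Path(path)
    df = pd.DataFrame(series.data, index=series.region_labels)
    df.to_csv(path, sep=_sep_for(path), header=False, float_format="%.17g")


def write_cohort_h5(cohort: Cohort, path: str | Path) -> None:
    """Store a cohort in one HDF5 file: /<subject_id>/data + shared attrs."""
    with h5py.File(path, "w") as f:
        f.attrs["region_labels"] = [str(x) for x in cohort.region_labels]
        f.attrs["tr_seconds"] = float(cohort.tr_seconds)
        f.attrs["subject_order"] = [s.subject_id for s in cohort.subjects]
        for s in cohort.subjects:
            f.create_dataset(f"{s.subject_id}/data", data=s.data)


def read_cohort_h5(path: str | Path) -> Cohort:
    with h5py.File(path, "r") as f:
        labels = [x.decode() if isinstance(x, bytes) else str(x)
                  for x in f.attrs["region_labels"]]
        tr = float(f.attrs["tr_seconds"])
        order = [x.decode() if isinstance(x, bytes) else str(x)
                 for x in f.attrs["subject_order"]]
        subjects = [RoiTimeSeries(sid, labels, f[f"{sid}/data"][()], tr)
                    for sid in order]
    return Cohort(subjects)
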