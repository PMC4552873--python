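"""Readers and writers for the connectome / ROI-fMRI ASCII dialects.

The structural connectivity matrix is a whitespace-delimited square ASCII
table of non-negative fiber densities (region self-coupling is forced to
zero on load because the node model already accounts for local recurrence).
ROI time series come as one long ASCII table: one row per frame, one column
per ROI, a subject-number column, and — for task recordings — a trailing
0/1 column flagging stimulus-onset frames.  Runs are fixed-length
consecutive blocks of frames within each subject.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, FormatError, ValidationError

__all__ = [
    "Connectome",
    "FMRIDataset",
    "read_connectome",
    "link_density",
    "read_fmri",
    "write_report",
    "read_report",
]

FRAMES_PER_RUN = 194


@dataclass
class Connectome:
    """An N-region anatomical coupling matrix with region labels.

    ``weights[i, j]`` is the (dimensionless) fiber density from region *j*
    into region *i*; the diagonal is identically zero and the matrix need
    not be symmetric.
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"connectome matrix must be square, got {w.shape}")
        if w.shape[0] < 2:
            raise ValidationError("connectome needs at least 2 regions")
        if np.any(w < 0):
            raise ValidationError("connectome weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValidationError("connectome diagonal must be zero")
        self.weights = w
        if not self.labels:
            self.labels = [f"R{i + 1:03d}" for i in range(w.shape[0])]
        if len(self.labels) != w.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {w.shape[0]} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def node_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label {label!r}") from None


@dataclass
class FMRIDataset:
    """ROI BOLD time series split by subject and run.

    ``series[subject]`` is a list of (frames, rois) arrays, one per run.
    ``onsets[subject][run]`` lists the within-run frame indices of stimulus
    onsets; only present for the task condition.
    """

    series: dict[int, list[np.ndarray]]
    roi_labels: list[str]
    condition: str
    tr_seconds: float = 2.16
    onsets: dict[int, list[list[int]]] | None = None

    def __post_init__(self):
        if self.condition not in ("rest", "task"):
            raise ValidationError(f"condition must be rest|task, got {self.condition}")
        shapes = {run.shape for runs in self.series.values() for run in runs}
        if len({s[0] for s in shapes}) > 1 or len({s[1] for s in shapes}) > 1:
            raise ValidationError(f"inconsistent run shapes: {shapes}")
        if self.condition == "rest" and self.onsets is not None:
            raise ValidationError("rest dataset cannot carry stimulus onsets")
        if self.onsets is not None:
            for subj, runs in self.onsets.items():
                for r, ons in enumerate(runs):
                    if any(b <= a for a, b in zip(ons, ons[1:])):
                        raise ValidationError(
                            f"onsets not strictly increasing (subject {subj} run {r})"
                        )

    @property
    def subjects(self) -> list[int]:
        return sorted(self.series)

    @property
    def n_rois(self) -> int:
        first = next(iter(self.series.values()))
        return first[0].shape[1]

    @property
    def frames_per_run(self) -> int:
        first = next(iter(self.series.values()))
        return first[0].shape[0]

    def concatenated(self, subject: int) -> np.ndarray:
        """All runs of one subject stacked in time, (frames*runs, rois)."""
        return np.vstack(self.series[subject])


def read_connectome(path: str, labels_path: str | None = None) -> Connectome:
    """Load a square whitespace-delimited coupling matrix.

    The diagonal is forced to zero.  Labels come from ``labels_path`` (one
    label per line), from a sibling ``*labels*.txt`` file with a matching
    line count, or are synthesized as R001..RNNN.
    """
    try:
        w = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: not a numeric ASCII matrix ({exc})") from exc
    if w.size == 0:
        raise FormatError(f"{path}: empty matrix file")
    if w.shape[0] != w.shape[1]:
        raise FormatError(f"{path}: matrix is {w.shape[0]}x{w.shape[1]}, not square")
    if np.any(w < 0):
        raise ValidationError(f"{path}: negative coupling entries")
    np.fill_diagonal(w, 0.0)

    labels: list[str] = []
    if labels_path is None:
        folder = os.path.dirname(os.path.abspath(path))
        for name in sorted(os.listdir(folder)):
            if "labels" in name.lower() and name.endswith(".txt"):
                candidate = os.path.join(folder, name)
                lines = _read_labels(candidate)
                if len(lines) == w.shape[0]:
                    labels = lines
                    break
    else:
        labels = _read_labels(labels_path)
    return Connectome(weights=w, labels=labels)


def _read_labels(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def link_density(conn: Connectome) -> float:
    """Fraction of strictly positive off-diagonal entries, in [0, 1]."""
    n = conn.n_regions
    off = ~np.eye(n, dtype=bool)
    return float(np.count_nonzero(conn.weights[off] > 0) / (n * (n - 1)))


def read_fmri(
    path: str,
    condition: str,
    n_subjects: int | None = None,
    frames_per_run: int = FRAMES_PER_RUN,
    roi_labels: list[str] | None = None,
    tr_seconds: float = 2.16,
) -> FMRIDataset:
    """Parse the long-table ROI fMRI dialect into per-subject runs.

    Rest tables have N ROI columns plus a subject column; task tables add a
    trailing stimulus-onset flag column.  Runs are consecutive blocks of
    ``frames_per_run`` rows within each subject, in file order.
    """
    if condition not in ("rest", "task"):
        raise ValidationError(f"condition must be rest|task, got {condition}")
    try:
        table = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: not a numeric ASCII table ({exc})") from exc
    if table.size == 0:
        raise FormatError(f"{path}: empty file")

    extra = 1 if condition == "rest" else 2
    n_rois = table.shape[1] - extra
    if n_rois < 1:
        raise FormatError(
            f"{path}: {table.shape[1]} columns cannot hold ROI data plus "
            f"{extra} metadata column(s) for condition {condition}"
        )
    subj_col = table[:, n_rois].astype(int)
    if np.any(np.abs(table[:, n_rois] - subj_col) > 0):
        raise FormatError(f"{path}: subject column is not integral")

    series: dict[int, list[np.ndarray]] = {}
    onsets: dict[int, list[list[int]]] = {}
    for subj in np.unique(subj_col):
        rows = table[subj_col == subj]
        if rows.shape[0] % frames_per_run != 0:
            raise FormatError(
                f"{path}: subject {subj} has {rows.shape[0]} rows, not a "
                f"multiple of {frames_per_run} frames per run"
            )
        n_runs = rows.shape[0] // frames_per_run
        runs = [
            rows[r * frames_per_run : (r + 1) * frames_per_run, :n_rois]
            for r in range(n_runs)
        ]
        series[int(subj)] = runs
        if condition == "task":
            flag = rows[:, n_rois + 1]
            onsets[int(subj)] = [
                np.flatnonzero(
                    flag[r * frames_per_run : (r + 1) * frames_per_run] == 1
                ).tolist()
                for r in range(n_runs)
            ]
    if n_subjects is not None and len(series) != n_subjects:
        raise FormatError(
            f"{path}: found {len(series)} subjects, expected {n_subjects}"
        )
    if roi_labels is None:
        roi_labels = [f"ROI{i + 1:02d}" for i in range(n_rois)]
    return FMRIDataset(
        series=series,
        roi_labels=roi_labels,
        condition=condition,
        tr_seconds=tr_seconds,
        onsets=onsets if condition == "task" else None,
    )


def write_report(table: dict[str, list] | pd.DataFrame, path: str) -> None:
    """Write a named-column table as TSV (header line first, 12 sig digits)."""
    df = pd.DataFrame(table)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_report(path: str) -> pd.DataFrame:
    """Read back a TSV report written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t")
    if df.columns.size == 0:
        raise DegenerateDataError(f"{path}: no columns")
    return df
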