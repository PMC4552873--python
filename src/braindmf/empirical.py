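"""Rest-vs-task entropy analysis of ROI fMRI time series.

Per subject, runs of one condition are concatenated and the differential
entropy of the (frames x ROIs) matrix is estimated either parametrically
(rank-truncated Gaussian form) or nonparametrically (nearest neighbours);
the rest-task difference is tested with an exact Wilcoxon signed-rank test.
A peristimulus, sliding-window analysis tracks how entropy drops after
stimulus onset and recovers toward the resting reference H0.  All stages
run identically on surrogate datasets — no code path requires empirical
files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import FMRIDataset
from .errors import DegenerateDataError, ValidationError
from .entropy import knn_entropy, svd_entropy

__all__ = [
    "subject_entropy",
    "entropy_difference_test",
    "EntropyTimecourse",
    "time_resolved_entropy",
    "fc_comparison",
]


def subject_entropy(
    data: FMRIDataset, method: str = "gaussian_svd"
) -> dict[int, float]:
    """Differential entropy (bits) per subject on concatenated runs."""
    if method not in ("gaussian_svd", "knn"):
        raise ValidationError(f"method must be gaussian_svd|knn, got {method!r}")
    out: dict[int, float] = {}
    for subj in data.subjects:
        runs = data.series[subj]
        if len(runs) < 2:
            raise ValidationError(f"subject {subj} has fewer than 2 runs")
        x = data.concatenated(subj)
        if method == "gaussian_svd":
            out[subj], _ = svd_entropy(x)
        else:
            out[subj] = knn_entropy(x, k_neighbors=1)
    return out


def subject_rank(data: FMRIDataset) -> dict[int, int]:
    """Number of non-zero singular values of each subject's covariance."""
    return {s: svd_entropy(data.concatenated(s))[1] for s in data.subjects}


def entropy_difference_test(
    h_rest: np.ndarray, h_task: np.ndarray
) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test on paired entropies.

    Returns (statistic, p).  Suitable for small cohorts (n ~ 17) where the
    exact permutation distribution is required.
    """
    h_rest = np.asarray(h_rest, dtype=float)
    h_task = np.asarray(h_task, dtype=float)
    if h_rest.shape != h_task.shape or h_rest.ndim != 1:
        raise ValidationError("paired 1-D arrays required")
    if h_rest.size < 6:
        raise ValidationError("need at least 6 pairs for a meaningful test")
    diff = h_rest - h_task
    if np.all(diff == 0):
        raise DegenerateDataError("all paired differences are zero")
    res = stats.wilcoxon(h_rest, h_task, alternative="two-sided", method="exact")
    return float(res.statistic), float(res.pvalue)


@dataclass
class EntropyTimecourse:
    t: np.ndarray          # window-center times relative to onset (s)
    H_rest: np.ndarray     # across-subject mean rest entropy per window (bits)
    H_task: np.ndarray     # across-subject mean task entropy per window (bits)
    H0: float              # resting reference entropy (bits)
    p_values: np.ndarray   # per-window paired t-test p
    n_subjects: int
    per_subject_rest: np.ndarray | None = None  # (subjects, windows)
    per_subject_task: np.ndarray | None = None


def _window_entropy(run: np.ndarray, start: int, width: int) -> float:
    h, _ = svd_entropy(run[start : start + width])
    return h


def time_resolved_entropy(
    data_rest: FMRIDataset,
    data_task: FMRIDataset,
    window_frames: int = 5,
    step_frames: int = 1,
    span_seconds: float = 17.3,
) -> EntropyTimecourse:
    """Peristimulus sliding-window entropy, rest-referenced.

    For every stimulus onset, entropy is computed in ``window_frames``-frame
    windows whose centers range from -span to +span seconds around the
    onset, per subject, then averaged over presentations; presentations
    whose full span crosses a run boundary are skipped.  Rest runs are
    probed at the same within-run positions ("equivalent periods") by
    mapping each task run's onsets onto the same-order rest run.  H0 is the
    rest entropy averaged over subjects and all sliding windows.
    """
    if data_task.onsets is None:
        raise ValidationError("task dataset carries no stimulus onsets")
    tr = data_task.tr_seconds
    frames = data_task.frames_per_run
    half = window_frames // 2
    span = int(round(span_seconds / tr))
    offsets = np.arange(-span, span + 1, step_frames)
    t = offsets * tr

    subjects = sorted(set(data_rest.subjects) & set(data_task.subjects))
    if not subjects:
        raise ValidationError("no common subjects between conditions")
    per_task = np.full((len(subjects), offsets.size), np.nan)
    per_rest = np.full((len(subjects), offsets.size), np.nan)
    h0_vals = []

    for si, subj in enumerate(subjects):
        task_runs = data_task.series[subj]
        rest_runs = data_rest.series[subj]
        ons_by_run = data_task.onsets.get(subj, [])
        acc_t = np.zeros(offsets.size)
        acc_r = np.zeros(offsets.size)
        count = 0
        for run_idx, task_run in enumerate(task_runs):
            rest_run = rest_runs[run_idx % len(rest_runs)]
            for onset in ons_by_run[run_idx] if run_idx < len(ons_by_run) else []:
                starts = onset + offsets - half
                if starts.min() < 0 or starts.max() + window_frames > frames:
                    continue  # span crosses the run edge: presentation skipped
                for k, st in enumerate(starts):
                    acc_t[k] += _window_entropy(task_run, st, window_frames)
                    acc_r[k] += _window_entropy(rest_run, st, window_frames)
                count += 1
        if count:
            per_task[si] = acc_t / count
            per_rest[si] = acc_r / count
        # H0: all sliding windows of all rest runs for this subject
        subj_h0 = [
            _window_entropy(r, st, window_frames)
            for r in rest_runs
            for st in range(0, frames - window_frames + 1, step_frames)
        ]
        h0_vals.append(np.mean(subj_h0))

    valid = ~np.isnan(per_task).any(axis=1)
    per_task, per_rest = per_task[valid], per_rest[valid]
    if per_task.shape[0] < 2:
        raise ValidationError("fewer than 2 subjects with usable presentations")
    h0 = float(np.mean(h0_vals))
    p = np.array(
        [
            stats.ttest_rel(per_task[:, k], per_rest[:, k]).pvalue
            if np.ptp(per_task[:, k] - per_rest[:, k]) > 0
            else 1.0
            for k in range(offsets.size)
        ]
    )
    return EntropyTimecourse(
        t=t,
        H_rest=per_rest.mean(axis=0),
        H_task=per_task.mean(axis=0),
        H0=h0,
        p_values=p,
        n_subjects=per_task.shape[0],
        per_subject_rest=per_rest,
        per_subject_task=per_task,
    )


def fc_comparison(data_rest: FMRIDataset, data_task: FMRIDataset) -> np.ndarray:
    """Upper-triangle differences of subject-averaged FC matrices (rest - task)."""
    if data_rest.n_rois != data_task.n_rois:
        raise ValidationError("conditions use different ROI sets")

    def avg_fc(data: FMRIDataset) -> np.ndarray:
        mats = []
        for subj in data.subjects:
            x = data.concatenated(subj)
            if np.any(x.std(axis=0) == 0):
                raise DegenerateDataError(
                    f"subject {subj}: constant ROI series, correlation undefined"
                )
            mats.append(np.corrcoef(x, rowvar=False))
        return np.mean(mats, axis=0)

    fc_r = avg_fc(data_rest)
    fc_t = avg_fc(data_task)
    iu = np.triu_indices(data_rest.n_rois, k=1)
    return (fc_r - fc_t)[iu]
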