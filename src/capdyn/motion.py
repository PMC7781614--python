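"""Framewise-displacement motion QC and per-CAP motion summaries.

FD follows the Power backward-difference convention: the sum of absolute
frame-to-frame changes of the three translations (mm) plus the three
rotations converted to arc length on a 50 mm sphere. Subjects are
excluded — not frame-censored — when mean FD exceeds 0.5 mm or more
than 35 frames exceed 0.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class MotionError(ValueError):
    pass


@dataclass(frozen=True)
class FDTrace:
    """Per-frame framewise displacement in mm; frame 0 is defined as 0."""

    subject_id: str
    values: np.ndarray
    radius_mm: float = 50.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or np.any(v < 0) or not np.all(np.isfinite(v)):
            raise MotionError(f"{self.subject_id}: FD must be 1-D, finite, nonnegative")

    @property
    def mean_fd(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class QCDecision:
    subject_id: str
    mean_fd_mm: float
    n_frames_above: int
    included: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def compute_fd(
    realignment: np.ndarray, subject_id: str = "", radius_mm: float = 50.0
) -> FDTrace:
    """Power FD from a (T, 6) realignment matrix (mm x3, rad x3)."""
    rp = np.asarray(realignment, dtype=float)
    if rp.ndim != 2 or rp.shape[1] != 6:
        raise MotionError(
            f"{subject_id}: realignment must have 6 columns, got shape {rp.shape}"
        )
    if rp.shape[0] < 2:
        raise MotionError(f"{subject_id}: need at least 2 frames")
    if not np.all(np.isfinite(rp)):
        raise MotionError(f"{subject_id}: realignment contains non-finite values")
    d = np.abs(np.diff(rp, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return FDTrace(subject_id=subject_id, values=np.concatenate([[0.0], fd]),
                   radius_mm=radius_mm)


def evaluate_exclusion(
    fd: FDTrace,
    mean_thresh: float = 0.5,
    frame_thresh: float = 0.5,
    max_frames: int = 35,
) -> QCDecision:
    """Exclude iff mean FD > ``mean_thresh`` or more than ``max_frames``
    frames have FD > ``frame_thresh`` (both inequalities strict)."""
    mean_fd = fd.mean_fd
    n_above = int(np.sum(fd.values > frame_thresh))
    reasons = []
    if mean_fd > mean_thresh:
        reasons.append(f"mean FD {mean_fd:.3f} mm > {mean_thresh} mm")
    if n_above > max_frames:
        reasons.append(
            f"{n_above} frames with FD > {frame_thresh} mm (limit {max_frames})"
        )
    return QCDecision(
        subject_id=fd.subject_id,
        mean_fd_mm=mean_fd,
        n_frames_above=n_above,
        included=not reasons,
        reasons=tuple(reasons),
    )


def align_fd_to_trim(
    fd: FDTrace, n_drop_leading: int, target_frames: int
) -> FDTrace:
    """Re-index an FD trace to match a trimmed time series."""
    if fd.values.size < n_drop_leading + target_frames:
        raise MotionError(
            f"{fd.subject_id}: FD trace shorter than trimmed series"
        )
    return FDTrace(
        subject_id=fd.subject_id,
        values=fd.values[n_drop_leading : n_drop_leading + target_frames],
        radius_mm=fd.radius_mm,
    )


def cap_motion_summary(
    fd_by_subject: Mapping[str, FDTrace] | Mapping[str, np.ndarray],
    subject_index: Sequence[str],
    frame_index: Sequence[int],
    cap_labels: Sequence[int],
) -> pd.DataFrame:
    """Mean FD over all pooled frames assigned to each CAP.

    ``subject_index``/``frame_index`` give the provenance of each pooled
    frame (already aligned to the trimmed series); ``cap_labels`` its
    state assignment. Returns one row per state with frame count, mean,
    sd and quartiles of FD.
    """
    subject_index = list(subject_index)
    frame_index = list(frame_index)
    cap_labels = np.asarray(cap_labels)
    if not (len(subject_index) == len(frame_index) == cap_labels.size):
        raise MotionError("provenance and label lengths disagree")
    fd_vals = np.empty(cap_labels.size)
    for i, (sid, f) in enumerate(zip(subject_index, frame_index)):
        trace = fd_by_subject[sid]
        values = trace.values if isinstance(trace, FDTrace) else np.asarray(trace)
        if f >= values.size:
            raise MotionError(
                f"frame {f} of {sid} has no FD value (trace length {values.size})"
            )
        fd_vals[i] = values[f]
    df = pd.DataFrame({"state": cap_labels, "fd": fd_vals})
    out = df.groupby("state")["fd"].agg(
        n_frames="size", mean_fd="mean", sd_fd="std",
        q25=lambda x: x.quantile(0.25), median="median",
        q75=lambda x: x.quantile(0.75),
    )
    return out.reset_index()


def qc_report(decisions: Sequence[QCDecision]) -> pd.DataFrame:
    """One row per subject: FD summary, verdict and triggered rules."""
    return pd.DataFrame(
        {
            "participant_id": [d.subject_id for d in decisions],
            "mean_fd_mm": [d.mean_fd_mm for d in decisions],
            "n_frames_above": [d.n_frames_above for d in decisions],
            "included": [d.included for d in decisions],
            "reasons": ["; ".join(d.reasons) for d in decisions],
        }
    )
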