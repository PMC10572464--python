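"""ROI-to-ROI functional connectivity: Pearson correlation and Fisher z.

For a subject with centered ROI series R_i(t), the connectivity between ROIs
i and j is the Pearson coefficient

    r(i, j) = sum_t R_i(t) R_j(t) / sqrt(sum_t R_i(t)^2 * sum_t R_j(t)^2)

and the variance-stabilized edge value used by all group statistics is the
Fisher transform Z(i, j) = atanh(r(i, j)).  An optional scrubbing step
censors motion/global-signal outlier timepoints before correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import NuisanceTraces, ROITimeSeries

__all__ = [
    "ConnectivityMatrix",
    "ScrubbingRule",
    "DegenerateInputError",
    "scrub",
    "pearson_matrix",
    "fisher_z",
    "connectivity_matrix",
]

_CLIP = 1.0 - 1e-7


class DegenerateInputError(ValueError):
    """Input leaves too little data or variance to estimate connectivity."""


@dataclass
class ScrubbingRule:
    """Outlier-scan rule: censor timepoints whose global signal deviates from
    its mean by more than ``global_signal_sd_threshold`` SDs, or whose
    framewise displacement exceeds ``fd_mm_threshold`` mm."""

    global_signal_sd_threshold: float = 5.0
    fd_mm_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.global_signal_sd_threshold <= 0 or self.fd_mm_threshold <= 0:
            raise ValueError("scrubbing thresholds must be positive")


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson (r) and Fisher-z (z) matrices for one subject.

    The diagonal of ``r`` is 1 by convention; the diagonal of ``z`` is stored
    as 0 and excluded from every statistic.
    """

    subject_id: str
    r: np.ndarray
    roi_labels: tuple[str, ...]
    n_timepoints_used: int
    z: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.roi_labels)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape does not match ROI labels")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


def scrub(
    timeseries: ROITimeSeries,
    fd_trace: np.ndarray,
    global_signal_trace: np.ndarray,
    rule: ScrubbingRule | None = None,
) -> ROITimeSeries:
    """Censor outlier timepoints (union of the FD and global-signal rules)."""
    rule = rule or ScrubbingRule()
    fd = np.asarray(fd_trace, dtype=float)
    gs = np.asarray(global_signal_trace, dtype=float)
    n_t = timeseries.n_timepoints
    if fd.shape != (n_t,) or gs.shape != (n_t,):
        raise ValueError(
            f"nuisance traces must have length {n_t} "
            f"(got FD {fd.shape}, global signal {gs.shape})"
        )
    gs_dev = np.abs(gs - gs.mean())
    sd = gs.std(ddof=0)
    gs_out = gs_dev > rule.global_signal_sd_threshold * sd if sd > 0 else np.zeros(n_t, bool)
    bad = gs_out | (fd > rule.fd_mm_threshold)
    keep = ~bad
    if keep.sum() < 10:
        raise DegenerateInputError(
            f"scrubbing leaves only {int(keep.sum())} timepoints for "
            f"{timeseries.subject_id} (minimum 10)"
        )
    return ROITimeSeries(
        subject_id=timeseries.subject_id,
        data=timeseries.data[keep],
        roi_labels=timeseries.roi_labels,
        tr_seconds=timeseries.tr_seconds,
    )


def scrub_with_traces(
    timeseries: ROITimeSeries, traces: NuisanceTraces, rule: ScrubbingRule | None = None
) -> ROITimeSeries:
    return scrub(timeseries, traces.fd, traces.global_signal, rule)


def pearson_matrix(timeseries: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation matrix of the (mean-centered) ROI columns."""
    data = timeseries.data
    sd = data.std(axis=0, ddof=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(timeseries.roi_labels[i] for i in dead[:5])
        raise DegenerateInputError(
            f"zero-variance ROI column(s) for {timeseries.subject_id}: {names}"
        )
    centered = data - data.mean(axis=0)
    norm = centered / np.sqrt((centered**2).sum(axis=0))
    r = norm.T @ norm
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        subject_id=timeseries.subject_id,
        r=r,
        roi_labels=timeseries.roi_labels,
        n_timepoints_used=timeseries.n_timepoints,
    )


def fisher_z(conn: ConnectivityMatrix) -> ConnectivityMatrix:
    """Populate the Fisher-z matrix z = atanh(r), diagonal stored as 0.

    Off-diagonal |r| = 1 (degenerate duplicated signals) is clipped to
    1 - 1e-7 with a warning naming the offending pair.
    """
    r = conn.r.copy()
    off = ~np.eye(conn.n_rois, dtype=bool)
    saturated = off & (np.abs(r) >= 1.0)
    if saturated.any():
        i, j = np.argwhere(saturated)[0]
        warnings.warn(
            f"|r| = 1 for ROI pair ({conn.roi_labels[i]!r}, {conn.roi_labels[j]!r}) "
            f"of subject {conn.subject_id}; clipping to {_CLIP} before atanh",
            RuntimeWarning,
            stacklevel=2,
        )
        r[saturated] = np.sign(r[saturated]) * _CLIP
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    conn.z = z
    return conn


def connectivity_matrix(
    timeseries: ROITimeSeries,
    traces: NuisanceTraces | None = None,
    rule: ScrubbingRule | None = None,
) -> ConnectivityMatrix:
    """Convenience pipeline: optional scrubbing, then Pearson + Fisher z."""
    if traces is not None:
        timeseries = scrub_with_traces(timeseries, traces, rule)
    return fisher_z(pearson_matrix(timeseries))
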