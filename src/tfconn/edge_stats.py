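"""Edgewise group-contrast statistics on Fisher-z connectivity matrices.

Two-sample pooled-variance t maps for pairwise group contrasts and one-way
fixed-effects F maps across three groups, computed independently at every
edge of the upper triangle and mirrored into symmetric matrices.  Edges with
zero pooled variance (possible in degenerate synthetic designs) get a 0
statistic and a warning rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix
from .design import StudyDesign

__all__ = ["EdgeStatMap", "stack_z", "two_sample_t_map", "anova_f_map"]


@dataclass
class EdgeStatMap:
    """Symmetric N x N map of a group-contrast statistic with its df."""

    stat: np.ndarray
    stat_kind: str  # "t" or "F"
    df: tuple
    contrast: str
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=float)
        if not np.all(np.isfinite(self.stat)):
            raise ValueError("edge statistics must be finite everywhere")
        if not np.allclose(self.stat, self.stat.T):
            raise ValueError("edge statistic map must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.stat.shape[0]


def stack_z(z_matrices: list[ConnectivityMatrix]) -> np.ndarray:
    """Stack per-subject Fisher-z matrices into an (n_subjects, N, N) array,
    checking that every subject shares the same ROI ordering."""
    if not z_matrices:
        raise ValueError("no connectivity matrices supplied")
    labels = z_matrices[0].roi_labels
    for m in z_matrices:
        if m.roi_labels != labels:
            raise ValueError(f"ROI ordering differs for subject {m.subject_id}")
        if m.z is None:
            raise ValueError(f"subject {m.subject_id} has no Fisher-z matrix")
    return np.stack([m.z for m in z_matrices])


def _group_arrays(
    z_matrices: list[ConnectivityMatrix], design: StudyDesign, groups: list[str]
) -> list[np.ndarray]:
    by_id = {m.subject_id: m for m in z_matrices}
    missing = [s for s in design.subject_ids if s not in by_id]
    if missing:
        raise ValueError(f"no connectivity matrix for subjects {missing[:5]}")
    out = []
    for g in groups:
        subs = design.subjects_in(g)
        if len(subs) < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects, has {len(subs)}")
        out.append(stack_z([by_id[s] for s in subs]))
    return out


def pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise pooled-variance two-sample t of a minus b along axis 0."""
    na, nb = a.shape[0], b.shape[0]
    diff = a.mean(axis=0) - b.mean(axis=0)
    ss = a.var(axis=0, ddof=1) * (na - 1) + b.var(axis=0, ddof=1) * (nb - 1)
    pooled = ss / (na + nb - 2) * (1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(pooled)
    return np.where(pooled > 0, t, 0.0)


def welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    diff = a.mean(axis=0) - b.mean(axis=0)
    se2 = a.var(axis=0, ddof=1) / na + b.var(axis=0, ddof=1) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    return np.where(se2 > 0, t, 0.0)


def two_sample_t_map(
    z_matrices: list[ConnectivityMatrix],
    design: StudyDesign,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> EdgeStatMap:
    """Edgewise two-sample t map; positive t means group_a > group_b."""
    za, zb = _group_arrays(z_matrices, design, [group_a, group_b])
    t = welch_t(za, zb) if welch else pooled_t(za, zb)
    if np.any((t == 0) & _degenerate_mask(za, zb)):
        warnings.warn(
            "zero pooled variance at some edges; t set to 0 there",
            RuntimeWarning,
            stacklevel=2,
        )
    np.fill_diagonal(t, 0.0)
    return EdgeStatMap(
        stat=t,
        stat_kind="t",
        df=(za.shape[0] + zb.shape[0] - 2,),
        contrast=f"{group_a}>{group_b}",
        roi_labels=z_matrices[0].roi_labels,
    )


def _degenerate_mask(*arrays: np.ndarray) -> np.ndarray:
    pooled = sum(a.var(axis=0, ddof=1) * (a.shape[0] - 1) for a in arrays)
    means = np.stack([a.mean(axis=0) for a in arrays])
    return (pooled == 0) & (np.ptp(means, axis=0) > 0)


def anova_f_map(
    z_matrices: list[ConnectivityMatrix],
    design: StudyDesign,
    groups: tuple[str, ...] = ("HC", "MCI", "AD"),
) -> EdgeStatMap:
    """Edgewise one-way fixed-effects F map across ``groups``."""
    arrays = _group_arrays(z_matrices, design, list(groups))
    ns = np.array([a.shape[0] for a in arrays])
    n_total = int(ns.sum())
    k = len(arrays)
    grand = sum(a.sum(axis=0) for a in arrays) / n_total
    ssb = sum(
        n * (a.mean(axis=0) - grand) ** 2 for n, a in zip(ns, arrays)
    )
    ssw = sum(a.var(axis=0, ddof=0) * a.shape[0] for a in arrays)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n_total - k))
    f = np.where(ssw > 0, f, 0.0)
    np.fill_diagonal(f, 0.0)
    return EdgeStatMap(
        stat=f,
        stat_kind="F",
        df=(k - 1, n_total - k),
        contrast="-".join(groups),
        roi_labels=z_matrices[0].roi_labels,
    )
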