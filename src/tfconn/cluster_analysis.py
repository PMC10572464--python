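"""Downstream analysis of clusters of interest (COIs).

Once TFCE (or NBS) has identified edge clusters, each subject is summarized
by the mean Fisher-z over the cluster's edges.  Group structure is then
tested with a one-way ANOVA across HC/MCI/AD plus pairwise two-sample
t-tests, and clinical severity is related to cluster connectivity by the
within-group Pearson correlation between mean z and the global Clinical
Dementia Rating (CDR).

A correlation is flagged for reporting when p < 0.05 and |R| > 0.35
(equivalently R^2 > 0.1225); non-passing results are returned with the flag
down rather than suppressed, so the screening rule is auditable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import ConnectivityMatrix
from .design import StudyDesign
from .network_stats import Cluster

__all__ = [
    "COISummary",
    "CorrelationResult",
    "coi_mean_z",
    "coi_anova",
    "cdr_correlation",
    "passes_reporting_rule",
]

R_REPORTING_THRESHOLD = 0.35
P_REPORTING_THRESHOLD = 0.05


@dataclass
class COISummary:
    """Per-subject cluster means with the three-group ANOVA and pairwise tests."""

    cluster_id: str
    per_subject_mean_z: dict[str, float]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    anova_f: float
    anova_p: float
    df: tuple[int, int]
    pairwise: dict[tuple[str, str], tuple[float, float]]
    pairwise_bonferroni: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    """Within-group Pearson correlation of cluster mean z with CDR."""

    cluster_id: str
    group: str
    R: float
    R2: float
    p: float
    n: int
    passes_reporting_rule: bool


def passes_reporting_rule(R: float, p: float) -> bool:
    """The reporting screen: p < 0.05 and |R| > 0.35.  Pure in (R, p)."""
    return bool(p < P_REPORTING_THRESHOLD and abs(R) > R_REPORTING_THRESHOLD)


def _edge_indices(cluster: Cluster, labels: tuple[str, ...]) -> list[tuple[int, int]]:
    if not cluster.edges:
        raise ValueError(f"cluster {cluster.cluster_id} has no edges")
    idx = {lab: i for i, lab in enumerate(labels)}
    try:
        return [(idx[a], idx[b]) for a, b in cluster.edges]
    except KeyError as err:
        raise ValueError(f"cluster edge ROI {err.args[0]!r} not in matrices") from None


def coi_mean_z(
    cluster: Cluster, z_matrices: list[ConnectivityMatrix]
) -> dict[str, float]:
    """Per-subject arithmetic mean of Fisher z over the cluster's edges."""
    out: dict[str, float] = {}
    for m in z_matrices:
        pairs = _edge_indices(cluster, m.roi_labels)
        out[m.subject_id] = float(np.mean([m.z[i, j] for i, j in pairs]))
    return out


def coi_anova(
    cluster: Cluster,
    z_matrices: list[ConnectivityMatrix],
    design: StudyDesign,
    groups: tuple[str, ...] = ("HC", "MCI", "AD"),
) -> COISummary:
    """One-way ANOVA of the cluster's per-subject mean z across groups, with
    unadjusted pairwise pooled-variance t-tests (Bonferroni column included)."""
    means = coi_mean_z(cluster, z_matrices)
    samples = {}
    for g in groups:
        subs = design.subjects_in(g)
        if len(subs) < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")
        samples[g] = np.array([means[s] for s in subs])
    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:
        raise ValueError("all per-subject cluster means identical; ANOVA undefined")
    f, p = stats.f_oneway(*samples.values())
    if not np.isfinite(f):  # identical group distributions with zero variance
        f, p = 0.0, 1.0
    n_total = pooled.size
    pairwise = {}
    n_tests = len(groups) * (len(groups) - 1) // 2
    bonf = {}
    for a, b in itertools.combinations(groups, 2):
        t, pp = stats.ttest_ind(samples[a], samples[b], equal_var=True)
        pairwise[(a, b)] = (float(t), float(pp))
        bonf[(a, b)] = float(min(1.0, pp * n_tests))
    return COISummary(
        cluster_id=cluster.cluster_id,
        per_subject_mean_z=means,
        group_means={g: float(v.mean()) for g, v in samples.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in samples.items()},
        anova_f=float(f),
        anova_p=float(p),
        df=(len(groups) - 1, n_total - len(groups)),
        pairwise=pairwise,
        pairwise_bonferroni=bonf,
    )


def cdr_correlation(
    cluster: Cluster,
    z_matrices: list[ConnectivityMatrix],
    design: StudyDesign,
    group: str,
) -> CorrelationResult:
    """Pearson R between cluster mean z and CDR within one diagnostic group,
    with the two-sided p from the t-transform of R on n - 2 df."""
    subs = [s for s in design.subjects_in(group) if s in design.cdr]
    if len(subs) < 4:
        raise ValueError(f"group {group!r} has {len(subs)} subjects with CDR; need >= 4")
    means = coi_mean_z(cluster, [m for m in z_matrices if m.subject_id in set(subs)])
    x = np.array([means[s] for s in subs])
    y = np.array([design.cdr[s] for s in subs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            f"zero variance in {'mean z' if np.ptp(x) == 0 else 'CDR'} "
            f"for group {group!r}; correlation undefined"
        )
    res = stats.pearsonr(x, y)
    R, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(
        cluster_id=cluster.cluster_id,
        group=group,
        R=R,
        R2=R * R,
        p=p,
        n=len(subs),
        passes_reporting_rule=passes_reporting_rule(R, p),
    )
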