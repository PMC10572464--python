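"""Synthetic multi-group ROI BOLD cohorts with planted connectivity effects.

The generator emulates the statistical structure an ROI-to-ROI group study
assumes: per-subject BOLD time series whose population correlation matrix is
block-structured by network (within-network correlation ``loading**2``), with
temporal AR(1) autocorrelation, and with a configurable set of "planted"
edges whose Fisher-z connectivity is reduced by ``delta_z`` in one diagnostic
group.  Clinical scores (CDR, an MMSE-like score) are coupled to each
subject's empirical mean connectivity over the planted edges.

Sampling works by building the exact target population correlation matrix
for each group and driving its Cholesky factor with independent unit-variance
AR(1) innovations; for the baseline block structure this is distributionally
identical to a shared-latent-signal model with per-network factors, and it
realizes every planted edge's population correlation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .atlas import NetworkAtlas
from .design import StudyDesign

__all__ = [
    "ConfigurationError",
    "ROITimeSeries",
    "NuisanceTraces",
    "SimulationScenario",
    "default_scenario",
    "population_correlation",
    "generate_cohort",
    "generate_nuisance",
]


class ConfigurationError(ValueError):
    """A simulation scenario is internally inconsistent."""


@dataclass
class ROITimeSeries:
    """One subject's BOLD matrix, timepoints x ROIs, with ROI labels."""

    subject_id: str
    data: np.ndarray
    roi_labels: tuple[str, ...]
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (timepoints x ROIs)")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_labels)} ROI labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in series for {self.subject_id}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class NuisanceTraces:
    """Per-timepoint framewise displacement (mm) and global-signal traces."""

    subject_id: str
    fd: np.ndarray
    global_signal: np.ndarray
    spiked: np.ndarray  # boolean mask of construction-time spikes


# Default per-group CDR intercepts / MMSE levels mirror the cohort this
# generator emulates (group CDR means ~0.04 / 0.5 / 0.95).  The intercepts
# offset the slope term at each group's expected mean planted-edge z under
# the default scenario (~0.34 baseline, ~-0.03 in AD).
_DEFAULT_CDR_INTERCEPT = {"HC": 0.39, "MCI": 0.84, "AD": 0.92}
_DEFAULT_MMSE = {"HC": (28.9, 1.65), "MCI": (27.5, 2.02), "AD": (20.87, 3.6)}


@dataclass
class SimulationScenario:
    """Parameters of one synthetic cohort; a pure function of ``seed``."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 31, "MCI": 31, "AD": 33}
    )
    n_timepoints: int = 200
    tr_seconds: float = 3.0
    within_network_loading: float = 0.6
    ar1_coefficient: float = 0.3
    planted_edges: list[tuple[str, str, float]] = field(default_factory=list)
    affected_group: str = "AD"
    cdr_model: tuple = (None, -1.0, 0.15)  # (intercept | per-group map, slope, noise sd)
    realistic_cdr: bool = False
    nuisance_spike_fraction: float = 0.02
    fd_spike_mm: float = 1.5
    gs_spike_sd: float = 30.0
    seed: int = 0

    def validate(self, atlas: NetworkAtlas) -> None:
        if self.n_timepoints < 10:
            raise ConfigurationError("n_timepoints must be at least 10")
        if not 0.0 <= self.within_network_loading <= 1.0:
            raise ConfigurationError("within_network_loading must lie in [0, 1]")
        if not -1.0 < self.ar1_coefficient < 1.0:
            raise ConfigurationError("ar1_coefficient must lie in (-1, 1)")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        if self.affected_group not in self.n_per_group:
            raise ConfigurationError(
                f"affected_group {self.affected_group!r} not among groups"
            )
        known = set(atlas.roi_labels)
        for a, b, dz in self.planted_edges:
            for roi in (a, b):
                if roi not in known:
                    raise ConfigurationError(f"planted edge names unknown ROI {roi!r}")
            if a == b:
                raise ConfigurationError(f"planted edge is a self-loop at {a!r}")
            if not np.isfinite(dz):
                raise ConfigurationError(f"non-finite delta_z on edge ({a!r}, {b!r})")


def default_scenario(**overrides) -> SimulationScenario:
    """The packaged study scenario: 95 subjects (HC 31 / MCI 31 / AD 33) and a
    connected 10-edge cluster — within-network default-mode and sensorimotor
    hypoconnectivity plus one bridging edge — whose Fisher-z connectivity is
    0.4 lower in the AD group, with CDR coupled to the cluster's mean z.

    Concentrating the group difference in contiguous within-network blocks
    mirrors how resting-state disruption presents in a sorted connectivity
    matrix, and keeps the affected-group correlation target positive
    definite at this effect size."""
    edges = [
        # default-mode hypoconnectivity: the full within-DMN edge set
        ("DefaultMode.MPFC", "DefaultMode.LP (L)"),
        ("DefaultMode.MPFC", "DefaultMode.LP (R)"),
        ("DefaultMode.MPFC", "DefaultMode.PCC"),
        ("DefaultMode.LP (L)", "DefaultMode.LP (R)"),
        ("DefaultMode.LP (L)", "DefaultMode.PCC"),
        ("DefaultMode.LP (R)", "DefaultMode.PCC"),
        # sensorimotor hypoconnectivity
        ("SensoriMotor.Lateral (L)", "SensoriMotor.Lateral (R)"),
        ("SensoriMotor.Lateral (L)", "SensoriMotor.Superior"),
        ("SensoriMotor.Lateral (R)", "SensoriMotor.Superior"),
        # one between-network bridge
        ("DefaultMode.PCC", "SensoriMotor.Superior"),
    ]
    scenario = SimulationScenario(planted_edges=[(a, b, 0.4) for a, b in edges])
    return replace(scenario, **overrides) if overrides else scenario


def population_correlation(
    scenario: SimulationScenario, atlas: NetworkAtlas, group: str
) -> np.ndarray:
    """Exact population ROI correlation matrix for one diagnostic group.

    Baseline: ``loading**2`` between same-network ROIs, 0 across networks.
    In the affected group each planted edge (a, b, dz) is moved from its
    baseline r0 to tanh(atanh(r0) - dz).
    """
    n = atlas.n_rois
    lam2 = scenario.within_network_loading**2
    nets = np.array([atlas.network_of[r] for r in atlas.roi_labels])
    C = np.where(nets[:, None] == nets[None, :], lam2, 0.0)
    np.fill_diagonal(C, 1.0)
    if group == scenario.affected_group:
        idx = {r: i for i, r in enumerate(atlas.roi_labels)}
        for a, b, dz in scenario.planted_edges:
            i, j = idx[a], idx[b]
            r_target = np.tanh(np.arctanh(C[i, j]) - dz)
            if not np.abs(r_target) < 1.0:
                raise ConfigurationError(
                    f"delta_z={dz} on edge ({a!r}, {b!r}) pushes |r| to 1 or beyond"
                )
            C[i, j] = C[j, i] = r_target
    return C


def _cholesky_pd(C: np.ndarray, what: str) -> np.ndarray:
    eigmin = np.linalg.eigvalsh(C).min()
    if eigmin <= 1e-10:
        raise ConfigurationError(
            f"{what} population correlation is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); weaken the planted effects"
        )
    return np.linalg.cholesky(C)

def _ar1(rng: np.random.Generator, n_t: int, n_series: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) columns."""
    x = np.empty((n_t, n_series))
    x[0] = rng.standard_normal(n_series)
    innov_sd = np.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal((n_t - 1, n_series))
    for t in range(1, n_t):
        x[t] = phi * x[t - 1] + innov_sd * eps[t - 1]
    return x


def _subject_ids(scenario: SimulationScenario) -> list[tuple[str, str]]:
    ids = []
    for group in scenario.n_per_group:
        for k in range(scenario.n_per_group[group]):
            ids.append((f"{group}{k + 1:03d}", group))
    return ids


def _mean_planted_z(data: np.ndarray, pairs: list[tuple[int, int]]) -> float:
    if not pairs:
        return 0.0
    r = np.corrcoef(data, rowvar=False)
    vals = np.clip([r[i, j] for i, j in pairs], -1 + 1e-7, 1 - 1e-7)
    return float(np.mean(np.arctanh(vals)))


def generate_cohort(
    scenario: SimulationScenario, atlas: NetworkAtlas
) -> tuple[list[ROITimeSeries], StudyDesign]:
    """Draw a full cohort of ROI time series plus its study design.

    Deterministic given ``scenario.seed``; subject streams are split from a
    single SeedSequence so that, e.g., changing the CDR noise never perturbs
    the BOLD draws.
    """
    scenario.validate(atlas)
    idx = {r: i for i, r in enumerate(atlas.roi_labels)}
    planted_pairs = [(idx[a], idx[b]) for a, b, _ in scenario.planted_edges]

    chol = {
        g: _cholesky_pd(
            population_correlation(scenario, atlas, g),
            "affected-group" if g == scenario.affected_group else "baseline",
        )
        for g in scenario.n_per_group
    }

    ss = np.random.SeedSequence(scenario.seed)
    bold_seed, score_seed = ss.spawn(2)
    subjects = _subject_ids(scenario)
    subj_streams = bold_seed.spawn(len(subjects))
    score_rng = np.random.default_rng(score_seed)

    intercept, slope, noise_sd = scenario.cdr_model
    if intercept is None:
        intercept = dict(_DEFAULT_CDR_INTERCEPT)

    series: list[ROITimeSeries] = []
    cdr: dict[str, float] = {}
    mmse: dict[str, float] = {}
    for (sid, group), stream in zip(subjects, subj_streams):
        rng = np.random.default_rng(stream)
        innov = _ar1(rng, scenario.n_timepoints, atlas.n_rois, scenario.ar1_coefficient)
        data = innov @ chol[group].T
        # standardize per column: zero mean, unit sample SD
        data = data - data.mean(axis=0)
        data = data / data.std(axis=0, ddof=1)
        series.append(
            ROITimeSeries(sid, data, atlas.roi_labels, tr_seconds=scenario.tr_seconds)
        )
        mean_z = _mean_planted_z(data, planted_pairs)
        a0 = intercept[group] if isinstance(intercept, dict) else float(intercept)
        value = a0 + slope * mean_z + noise_sd * score_rng.standard_normal()
        if scenario.realistic_cdr:
            value = float(np.clip(round(value * 2.0) / 2.0, 0.0, 3.0))
        cdr[sid] = float(value)
        mu, sd = _DEFAULT_MMSE.get(group, (28.0, 2.0))
        mmse[sid] = float(mu + sd * score_rng.standard_normal())

    design = StudyDesign(
        subject_ids=tuple(sid for sid, _ in subjects),
        group_of={sid: g for sid, g in subjects},
        cdr=cdr,
        mmse=mmse,
        seed=scenario.seed,
    )
    return series, design


def generate_nuisance(scenario: SimulationScenario) -> dict[str, NuisanceTraces]:
    """Framewise-displacement and global-signal traces per subject.

    Exactly ``round(spike_fraction * n_timepoints)`` timepoints per subject
    are spiked above both scrubbing thresholds (FD above 0.9 mm; global
    signal far outside its baseline scatter).  Large spike fractions inflate
    the trace SD enough that spikes may no longer clear a mean/SD-based rule;
    the default fraction (0.02) and magnitudes keep them clearly above it.
    """
    n_t = scenario.n_timepoints
    n_spikes = int(round(scenario.nuisance_spike_fraction * n_t))
    if n_spikes > n_t:
        raise ConfigurationError("nuisance_spike_fraction exceeds 1")
    ss = np.random.SeedSequence(scenario.seed)
    # third child stream: independent of the BOLD and score streams
    _, _, nuis_seed = ss.spawn(3)
    out: dict[str, NuisanceTraces] = {}
    subjects = _subject_ids(scenario)
    for (sid, _group), stream in zip(subjects, nuis_seed.spawn(len(subjects))):
        rng = np.random.default_rng(stream)
        fd = np.abs(rng.normal(0.2, 0.05, size=n_t))
        fd = np.minimum(fd, 0.85)  # baseline never crosses the 0.9 mm rule
        gs = rng.standard_normal(n_t)
        spiked = np.zeros(n_t, dtype=bool)
        if n_spikes:
            where = rng.choice(n_t, size=n_spikes, replace=False)
            spiked[where] = True
            fd[where] = scenario.fd_spike_mm + np.abs(rng.normal(0.0, 0.2, n_spikes))
            sign = np.where(rng.random(n_spikes) < 0.5, -1.0, 1.0)
            gs[where] = sign * scenario.gs_spike_sd
        out[sid] = NuisanceTraces(sid, fd=fd, global_signal=gs, spiked=spiked)
    return out
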