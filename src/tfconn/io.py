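"""Delimited-text and JSON readers/writers for every pipeline artifact.

Everything is plain text: one TSV per subject for time series and
connectivity matrices (header row = ROI labels), TSV subject tables and
nuisance traces, a flat TSV edge-list report, and JSON for scenario files,
stat-map sidecars and full results.  Every writer has a matching reader and
write-read-write is idempotent.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityMatrix
from .edge_stats import EdgeStatMap
from .network_stats import Cluster, TFCEParams, TFCEResult
from .simulate import NuisanceTraces, ROITimeSeries, SimulationScenario

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_matrix",
    "read_matrix",
    "write_connectivity",
    "read_connectivity",
    "write_nuisance",
    "read_nuisance",
    "write_report",
    "read_report",
    "write_results_json",
    "read_results_json",
    "read_scenario",
    "write_scenario",
]

_FLOAT_FMT = "%.10g"


# --- ROI time series -------------------------------------------------------


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=list(ts.roi_labels))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(
    path: str | Path, subject_id: str | None = None, tr_seconds: float = 3.0
) -> ROITimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        roi_labels=tuple(df.columns),
        tr_seconds=tr_seconds,
    )


# --- square matrices -------------------------------------------------------


def write_matrix(matrix: np.ndarray, roi_labels, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(roi_labels), columns=list(roi_labels))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(df.index):
        raise ValueError(f"matrix file {path} is not square with matching labels")
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_connectivity(conn: ConnectivityMatrix, directory: str | Path) -> None:
    """One file for r and one for z: <subject>_r.tsv, <subject>_z.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(conn.r, conn.roi_labels, directory / f"{conn.subject_id}_r.tsv")
    if conn.z is not None:
        write_matrix(conn.z, conn.roi_labels, directory / f"{conn.subject_id}_z.tsv")


def read_connectivity(directory: str | Path, subject_id: str) -> ConnectivityMatrix:
    directory = Path(directory)
    r, labels = read_matrix(directory / f"{subject_id}_r.tsv")
    conn = ConnectivityMatrix(
        subject_id=subject_id, r=r, roi_labels=labels, n_timepoints_used=-1
    )
    z_path = directory / f"{subject_id}_z.tsv"
    if z_path.exists():
        conn.z, _ = read_matrix(z_path)
    return conn


# --- nuisance traces -------------------------------------------------------


def write_nuisance(traces: NuisanceTraces, path: str | Path) -> None:
    pd.DataFrame(
        {"fd_mm": traces.fd, "global_signal": traces.global_signal}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_nuisance(path: str | Path, subject_id: str | None = None) -> NuisanceTraces:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    fd = df["fd_mm"].to_numpy(float)
    return NuisanceTraces(
        subject_id=subject_id or path.stem,
        fd=fd,
        global_signal=df["global_signal"].to_numpy(float),
        spiked=np.zeros(len(fd), dtype=bool),
    )


# --- edge-list report ------------------------------------------------------


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- full results JSON -----------------------------------------------------


def _cluster_to_dict(cl: Cluster) -> dict:
    return {
        "cluster_id": cl.cluster_id,
        "sign": cl.sign,
        "mass": cl.mass,
        "p_uncorrected": cl.p_uncorrected,
        "peak_tfce": cl.peak_tfce,
        "peak_p_fwe": cl.peak_p_fwe,
        "edges": [list(e) for e in cl.edges],
        "edge_stats": cl.edge_stats,
        "networks_involved": sorted(cl.networks_involved),
    }


def _cluster_from_dict(d: dict) -> Cluster:
    return Cluster(
        cluster_id=d["cluster_id"],
        edges=[tuple(e) for e in d["edges"]],
        mass=d["mass"],
        p_uncorrected=d["p_uncorrected"],
        peak_tfce=d["peak_tfce"],
        peak_p_fwe=d["peak_p_fwe"],
        sign=d["sign"],
        networks_involved=set(d.get("networks_involved", [])),
        edge_stats=d.get("edge_stats", []),
    )


def write_results_json(result: TFCEResult, path: str | Path, provenance: dict | None = None) -> None:
    payload = {
        "contrast": result.contrast,
        "roi_labels": list(result.roi_labels),
        "roi_order": result.roi_order.tolist(),
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "tfce_threshold": result.tfce_threshold,
        "params": dataclasses.asdict(result.params) if result.params else None,
        "clusters": [_cluster_to_dict(c) for c in result.clusters],
        "null_peaks": result.null_peaks.tolist(),
        "null_masses": result.null_masses.tolist(),
        "tfce_map": result.tfce_map.tolist(),
        "provenance": provenance or {},
    }
    with Path(path).open("w") as f:
        json.dump(payload, f, indent=1)


def read_results_json(path: str | Path) -> TFCEResult:
    with Path(path).open() as f:
        d = json.load(f)
    return TFCEResult(
        tfce_map=np.array(d["tfce_map"]),
        roi_order=np.array(d["roi_order"]),
        clusters=[_cluster_from_dict(c) for c in d["clusters"]],
        null_peaks=np.array(d["null_peaks"]),
        null_masses=np.array(d["null_masses"]),
        n_permutations=d["n_permutations"],
        seed=d["seed"],
        roi_labels=tuple(d["roi_labels"]),
        params=TFCEParams(**d["params"]) if d.get("params") else None,
        tfce_threshold=d["tfce_threshold"],
        contrast=d.get("contrast", ""),
    )


def write_stat_sidecar(stat_map: EdgeStatMap, path: str | Path) -> None:
    with Path(path).open("w") as f:
        json.dump(
            {
                "contrast": stat_map.contrast,
                "stat_kind": stat_map.stat_kind,
                "df": list(stat_map.df),
            },
            f,
            indent=1,
        )


# --- scenario files --------------------------------------------------------


def write_scenario(scenario: SimulationScenario, path: str | Path) -> None:
    d = dataclasses.asdict(scenario)
    d["planted_edges"] = [list(e) for e in scenario.planted_edges]
    d["cdr_model"] = list(scenario.cdr_model)
    with Path(path).open("w") as f:
        json.dump(d, f, indent=1)


def read_scenario(path: str | Path) -> SimulationScenario:
    """Scenario config as JSON or YAML key/value mapping."""
    text = Path(path).read_text()
    try:
        d = json.loads(text)
    except json.JSONDecodeError:
        d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError(f"scenario file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(SimulationScenario)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if "planted_edges" in d:
        d["planted_edges"] = [(a, b, float(dz)) for a, b, dz in d["planted_edges"]]
    if "cdr_model" in d:
        d["cdr_model"] = tuple(d["cdr_model"])
    return SimulationScenario(**d)
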