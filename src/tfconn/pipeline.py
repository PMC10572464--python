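"""End-to-end pipeline: simulate -> connectivity -> group stats -> TFCE/NBS -> COIs.

Every stage writes inspectable delimited-text/JSON artifacts under one
output directory, with provenance (config hash, seed, package version)
recorded once and per-stage timings appended to a log file.  All stochastic
stages draw their seeds from the single configured seed through a
SeedSequence spawn, so one integer reproduces the whole run byte-for-byte
(timestamps in the log aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import default_atlas, read_atlas
from .cluster_analysis import cdr_correlation, coi_anova
from .connectivity import connectivity_matrix
from .design import StudyDesign, write_subject_table
from .edge_stats import anova_f_map
from .io import (
    read_scenario,
    write_connectivity,
    write_nuisance,
    write_report,
    write_results_json,
    write_scenario,
    write_stat_sidecar,
    write_matrix,
    write_timeseries,
)
from .network_stats import (
    Cluster,
    TFCEParams,
    TFCEResult,
    extract_report,
    nbs,
    permutation_inference,
)
from .simulate import default_scenario, generate_cohort, generate_nuisance

__all__ = ["PipelineConfig", "PipelineStageError", "PipelineResult", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str | Path = "tfconn_out"
    atlas_path: str | Path | None = None
    scenario_path: str | Path | None = None
    contrasts: tuple[str, ...] = ("HC-AD", "HC-MCI")
    tfce: TFCEParams = field(default_factory=TFCEParams)
    n_permutations: int = 1000
    nbs_threshold: float = 3.0
    coi_alpha: float = 0.05
    scrub: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["out_dir"] = None  # location does not change the computation
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    design: StudyDesign
    tfce_results: dict[str, TFCEResult]
    nbs_clusters: dict[str, list[Cluster]]
    coi_table: pd.DataFrame
    correlation_table: pd.DataFrame


def _stage_seeds(seed: int, contrasts: tuple[str, ...]) -> dict[str, int]:
    """Derive one sub-seed per stochastic stage from the config seed.

    Children of SeedSequence(seed) are assigned in a fixed order: scenario,
    then one per TFCE contrast, then one per NBS contrast.  Values are
    reduced below 2**31 so they remain portable integers.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + 2 * len(contrasts))
    names = ["scenario"]
    names += [f"tfce:{c}" for c in contrasts]
    names += [f"nbs:{c}" for c in contrasts]
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; raises PipelineStageError on failure."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    log_lines: list[str] = []
    seeds = _stage_seeds(config.seed, config.contrasts)

    def _log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def _run(stage: str, fn):
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                result = fn()
            except PipelineStageError:
                raise
            except Exception as err:
                _log(f"stage {stage} FAILED: {err}")
                log_path.write_text("\n".join(log_lines) + "\n")
                raise PipelineStageError(stage, err) from err
        for w in caught:
            _log(f"stage {stage} warning: {w.message}")
        _log(f"stage {stage} done in {time.time() - t0:.2f}s")
        return result

    # --- configure -------------------------------------------------------
    def _load_inputs():
        atlas = read_atlas(config.atlas_path) if config.atlas_path else default_atlas()
        if config.scenario_path:
            scenario = read_scenario(config.scenario_path)
        else:
            scenario = default_scenario()
        scenario = dataclasses.replace(scenario, seed=seeds["scenario"])
        return atlas, scenario

    atlas, scenario = _run("configure", _load_inputs)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "tfconn_version": __version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1) + "\n")

    # --- simulate --------------------------------------------------------
    def _simulate():
        series, design = generate_cohort(scenario, atlas)
        traces = generate_nuisance(scenario)
        write_scenario(scenario, out / "scenario.json")
        write_subject_table(design, out / "subject_table.tsv")
        ts_dir = out / "timeseries"
        nz_dir = out / "nuisance"
        ts_dir.mkdir(exist_ok=True)
        nz_dir.mkdir(exist_ok=True)
        for ts in series:
            write_timeseries(ts, ts_dir / f"{ts.subject_id}.tsv")
            write_nuisance(traces[ts.subject_id], nz_dir / f"{ts.subject_id}.tsv")
        return series, design, traces

    series, design, traces = _run("simulate", _simulate)

    # --- connectivity ----------------------------------------------------
    def _connect():
        conn_dir = out / "connectivity"
        mats = []
        for ts in series:
            tr = traces[ts.subject_id] if config.scrub else None
            conn = connectivity_matrix(ts, tr)
            write_connectivity(conn, conn_dir)
            mats.append(conn)
        return mats

    mats = _run("connectivity", _connect)

    # --- group statistics + TFCE + NBS ----------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)

    def _anova_map():
        fmap = anova_f_map(mats, design)
        write_matrix(fmap.stat, fmap.roi_labels, stats_dir / "anova_F.tsv")
        write_stat_sidecar(fmap, stats_dir / "anova_F.json")
        return fmap

    _run("edge-stats", _anova_map)

    tfce_results: dict[str, TFCEResult] = {}
    nbs_clusters: dict[str, list[Cluster]] = {}
    for contrast in config.contrasts:
        def _compare(contrast=contrast):
            res = permutation_inference(
                mats,
                design,
                contrast,
                params=config.tfce,
                n_permutations=config.n_permutations,
                seed=seeds[f"tfce:{contrast}"],
                atlas=atlas,
            )
            write_matrix(
                res.stat_map.stat, res.roi_labels, stats_dir / f"{contrast}_t.tsv"
            )
            write_stat_sidecar(res.stat_map, stats_dir / f"{contrast}_t.json")
            write_results_json(res, out / f"tfce_{contrast}.json", provenance)
            write_report(extract_report(res, atlas), out / f"report_{contrast}.tsv")
            return res

        tfce_results[contrast] = _run(f"tfce:{contrast}", _compare)

        def _nbs(contrast=contrast):
            clusters = nbs(
                tfce_results[contrast].stat_map,
                mats,
                design,
                contrast,
                edge_threshold=config.nbs_threshold,
                n_permutations=config.n_permutations,
                seed=seeds[f"nbs:{contrast}"],
                atlas=atlas,
            )
            write_report(extract_report(clusters, atlas), out / f"nbs_{contrast}.tsv")
            return clusters

        nbs_clusters[contrast] = _run(f"nbs:{contrast}", _nbs)

    # --- clusters of interest -------------------------------------------
    def _coi():
        rows, corr_rows = [], []
        k = 0
        for contrast, res in tfce_results.items():
            for cl in res.clusters:
                if cl.p_uncorrected >= config.coi_alpha:
                    continue
                k += 1
                coi_id = f"COI{k}"
                summary = coi_anova(cl, mats, design)
                row = {
                    "coi": coi_id,
                    "contrast": contrast,
                    "sign": cl.sign,
                    "n_edges": cl.size,
                    "mass": cl.mass,
                    "p_uncorrected": cl.p_uncorrected,
                    "peak_p_fwe": cl.peak_p_fwe,
                    "anova_F": summary.anova_f,
                    "anova_p": summary.anova_p,
                }
                for g, m in summary.group_means.items():
                    row[f"mean_z_{g}"] = m
                    row[f"sd_z_{g}"] = summary.group_sds[g]
                for (a, b), (t, p) in summary.pairwise.items():
                    row[f"t_{a}_{b}"] = t
                    row[f"p_{a}_{b}"] = p
                    row[f"p_bonf_{a}_{b}"] = summary.pairwise_bonferroni[(a, b)]
                rows.append(row)
                scatter = design.to_frame()
                scatter["mean_z"] = [
                    summary.per_subject_mean_z[s] for s in design.subject_ids
                ]
                scatter.to_csv(
                    out / f"scatter_{coi_id}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.10g",
                )
                for group in ("AD", "MCI"):
                    c = cdr_correlation(cl, mats, design, group)
                    corr_rows.append(
                        {
                            "coi": coi_id,
                            "contrast": contrast,
                            "group": group,
                            "R": c.R,
                            "R2": c.R2,
                            "p": c.p,
                            "n": c.n,
                            "passes_reporting_rule": c.passes_reporting_rule,
                        }
                    )
        coi_table = pd.DataFrame(rows)
        corr_table = pd.DataFrame(corr_rows)
        coi_table.to_csv(out / "coi_anova.tsv", sep="\t", index=False, float_format="%.10g")
        corr_table.to_csv(
            out / "coi_cdr_correlations.tsv", sep="\t", index=False, float_format="%.10g"
        )
        return coi_table, corr_table

    coi_table, corr_table = _run("coi", _coi)

    log_path.write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        out_dir=out,
        design=design,
        tfce_results=tfce_results,
        nbs_clusters=nbs_clusters,
        coi_table=coi_table,
        correlation_table=corr_table,
    )
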