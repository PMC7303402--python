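"""End-to-end orchestration: QC -> denoise -> adjacency -> sweep -> stats.

``run_pipeline`` executes the stages in analysis order on a directory of
per-participant inputs, persists every intermediate as text, and writes a
run manifest (config hash, package version, per-stage row counts,
exclusions with reasons, wall-clock per stage).  Re-running the same
config on the same inputs reproduces all numeric outputs bit-identically:
every random draw comes from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import load_atlas
from .connectivity import build_adjacency
from .denoise import (SPIKE_FD_MM, build_confounds, clean_timeseries,
                      spike_regressors)
from .design import CONDITIONS
from .design_weights import block_regressor, condition_weights
from .graph_metrics import (MAIN_COST_GRID, auc_table, metric_curves)
from .group_stats import (MEASURES, decomposition_anova, mixed_ancova,
                          omnibus_mancova, posthoc_contrasts)
from .io import (FormatError, design_from_events, read_events,
                 read_participants, read_realignment, read_timeseries,
                 write_adjacency, write_long_csv)
from .motion_qc import max_motion_prefilter, qc_cohort, summarize_motion
from .network_summary import (condition_delta, decomposition_table,
                              network_means)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    atlas: str
    data_dir: str
    output_dir: str
    tr: float = 2.45
    n_volumes: int = 260
    seed: int = 0
    z_threshold: float = 3.0
    alpha: float = 0.05
    null_iters: int = 100
    use_spike_regressors: bool = False
    spike_fd_mm: float = SPIKE_FD_MM
    convolved_task_fd: bool = False
    normalize_random: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for name in ("atlas",):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config {name}: no such file {p}")
        d = Path(self.data_dir)
        if not (d / "participants.tsv").exists():
            raise FileNotFoundError(f"missing participants table in {d}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)

    def record(self, stage: str, t0: float, **counts) -> None:
        self.stages[stage] = {"seconds": round(time.perf_counter() - t0, 3),
                              **counts}


def _stats_family(summary: pd.DataFrame, family: str, alpha: float) -> dict:
    """Omnibus MANCOVA, per-measure ANCOVAs, gated post hoc contrasts."""
    table = summary.melt(
        id_vars=["participant", "group", "age", "network"],
        value_vars=list(MEASURES), var_name="measure", value_name="value")
    out: dict = {"family": family}
    omni = omnibus_mancova(table)
    out["omnibus"] = {k: vars(v) for k, v in omni.effects.items()}
    omni_gate = (omni.effects["group"].p < alpha
                 or omni.effects["group:network"].p < alpha)
    out["omnibus_significant"] = bool(omni_gate)
    out["ancova"] = {}
    for m in MEASURES:
        uni = mixed_ancova(table, m)
        rec = {k: vars(uni.reported(k)) for k in uni.effects}
        rec["sphericity"] = vars(uni.sphericity)
        rec["gg_applied"] = uni.gg_applied
        gate = (uni.reported("group").p < alpha
                or uni.reported("group:network").p < alpha)
        rec["posthoc_gate"] = bool(gate)
        if omni_gate and gate:
            rec["contrasts"] = [
                vars(c) for c in posthoc_contrasts(
                    table, m, upstream_significant=True)]
        out["ancova"][m] = rec
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.digest(), version=__version__)
    atlas = load_atlas(config.atlas)
    data_dir = Path(config.data_dir)
    participants = read_participants(data_dir / "participants.tsv")

    # ---- stage 1: motion QC -------------------------------------------------
    t0 = time.perf_counter()
    sessions, summaries = {}, []
    for row in participants.itertuples():
        pid = row.participant_id
        try:
            ts = read_timeseries(data_dir / f"{pid}_timeseries.tsv",
                                 n_nodes=atlas.n_nodes)
            nuis = read_timeseries(data_dir / f"{pid}_nuisance.tsv")
            rp = read_realignment(data_dir / f"{pid}_rp.txt")
            events = read_events(data_dir / f"{pid}_events.tsv")
        except (FormatError, FileNotFoundError) as exc:
            raise RuntimeError(f"stage qc, participant {pid}: {exc}") from exc
        design = design_from_events(events, config.tr, config.n_volumes)
        if max_motion_prefilter(rp):
            manifest.exclusions.append(
                {"participant": pid, "rule": "max motion > 3 mm / 3 deg"})
            continue
        sessions[pid] = (ts, nuis, rp, design)
        summaries.append(summarize_motion(pid, rp, design, config.tr,
                                          convolved_task=config.convolved_task_fd))
    groups = dict(zip(participants.participant_id, participants.group))
    qc = qc_cohort(summaries, groups, config.z_threshold)
    write_long_csv(qc, out / "qc.csv")
    for row in qc[qc.excluded].itertuples():
        manifest.exclusions.append(
            {"participant": row.participant_id,
             "rule": f"within-group z > {config.z_threshold}: {row.reason}"})
        sessions.pop(row.participant_id, None)
    manifest.record("qc", t0, participants=len(participants),
                    retained=len(sessions))

    # ---- stage 2+3: denoise and adjacency ----------------------------------
    t0 = time.perf_counter()
    fd_by_pid = {s.participant_id: s.fd_series for s in summaries}
    adjacencies: dict[str, dict[str, np.ndarray]] = {}
    for pid, (ts, nuis, rp, design) in sessions.items():
        task = np.column_stack([
            block_regressor(design, c, config.tr, config.n_volumes)
            for c in CONDITIONS])
        spikes = None
        if config.use_spike_regressors:
            spikes = spike_regressors(fd_by_pid[pid], config.spike_fd_mm)
        confounds = build_confounds(nuis, rp, task, spikes)
        clean = clean_timeseries(ts, confounds, config.tr)
        adjacencies[pid] = {}
        for cond in CONDITIONS:
            w = condition_weights(design, cond, config.tr, config.n_volumes)
            adj = build_adjacency(clean, w.weights, condition=cond,
                                  participant_id=pid)
            adjacencies[pid][cond] = adj
            write_adjacency(adj.matrix, out / f"{pid}_{cond}_adj.tsv")
    manifest.record("adjacency", t0, matrices=2 * len(sessions))

    # ---- stage 4: graph sweep and AUC ---------------------------------------
    t0 = time.perf_counter()
    auc_rows, summary_rows = [], []
    meta = participants.set_index("participant_id")
    summaries_by_pid: dict[str, dict[str, pd.DataFrame]] = {}
    for pid, by_cond in adjacencies.items():
        summaries_by_pid[pid] = {}
        for cond, adj in by_cond.items():
            curves = metric_curves(adj.matrix, MAIN_COST_GRID)
            aucs = auc_table(curves, MAIN_COST_GRID)
            for node in range(atlas.n_nodes):
                auc_rows.append({"participant": pid, "condition": cond,
                                 "node": node,
                                 **{k: aucs[k][node] for k in aucs}})
            nm = network_means(aucs, atlas)
            summaries_by_pid[pid][cond] = nm
            for net, r in nm.iterrows():
                summary_rows.append({
                    "participant": pid, "group": meta.loc[pid, "group"],
                    "age": meta.loc[pid, "age"], "condition": cond,
                    "network": net, "dc": r["dc"], "cc": r["cc"],
                    "ecc": r["ecc"]})
    write_long_csv(pd.DataFrame(auc_rows), out / "auc.csv")
    summary = pd.DataFrame(summary_rows)
    write_long_csv(summary, out / "summary.csv")
    manifest.record("graph_sweep", t0, rows=len(auc_rows))

    # ---- stage 5: deltas and decomposition ----------------------------------
    t0 = time.perf_counter()
    delta_rows, decomp_rows = [], []
    for pid, by_cond in summaries_by_pid.items():
        delta = condition_delta(by_cond["motion"], by_cond["static"], pid, pid)
        for net, r in delta.iterrows():
            delta_rows.append({
                "participant": pid, "group": meta.loc[pid, "group"],
                "age": meta.loc[pid, "age"], "network": net,
                "dc": r["dc"], "cc": r["cc"], "ecc": r["ecc"]})
        dt = decomposition_table(adjacencies[pid], atlas)
        dt.insert(0, "participant", pid)
        dt.insert(1, "group", meta.loc[pid, "group"])
        decomp_rows.append(dt)
    delta = pd.DataFrame(delta_rows)
    decomp = pd.concat(decomp_rows, ignore_index=True)
    write_long_csv(delta, out / "delta.csv")
    write_long_csv(decomp, out / "decomposition.csv")
    manifest.record("summaries", t0, delta_rows=len(delta),
                    decomposition_rows=len(decomp))

    # ---- stage 6: group statistics ------------------------------------------
    t0 = time.perf_counter()
    stats: dict = {}
    try:
        for cond in CONDITIONS:
            stats[cond] = _stats_family(
                summary[summary.condition == cond], cond, config.alpha)
        stats["delta"] = _stats_family(delta.assign(condition="delta"),
                                       "delta", config.alpha)
        stats["decomposition"] = {}
        # delta of the decomposition values (motion - static), plus static
        for family in ("static", "delta"):
            stats["decomposition"][family] = {}
            if family == "static":
                dtab = decomp[decomp.condition == "static"].copy()
                dtab = dtab.rename(columns={"mean_auc_dc": "value"})
            else:
                wide = decomp.pivot_table(
                    index=["participant", "group", "focal", "partition"],
                    columns="condition", values="mean_auc_dc").reset_index()
                wide["value"] = wide["motion"] - wide["static"]
                dtab = wide
            for focal in ("sensorimotor", "cerebellum"):
                uni, contrasts = decomposition_anova(dtab, focal)
                stats["decomposition"][family][focal] = {
                    "effects": {k: vars(uni.reported(k)) for k in uni.effects},
                    "contrasts": [vars(c) for c in contrasts]}
    except Exception as exc:
        raise RuntimeError(f"stage stats: {exc}") from exc
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, default=float)
    manifest.record("stats", t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(vars(manifest), fh, indent=2, default=str)
    return out
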