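"""End-to-end orchestration: simulate/load -> preprocess -> per-subject
connectomes -> group comparison -> report.

A run is fully described by a :class:`PipelineConfig` plus a master seed;
identical config + seed reproduce the stats tables and per-subject CFC
files byte for byte.  Every run directory gets a fixed layout::

    <out_dir>/
      cfc/<subject>.csv          adjacency matrices (signed weights)
      baselines/                 GC / SPC outputs when enabled
      stats/                     edge-wise Welch tables, both directions
      figures/                   adjacency heatmaps
      report.md                  top-k edge listings
      run.json                   config echo, seed, versions, timings
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import cv_select_lambda, gc_statistics, threshold_gc
from .errors import CausalFCError
from .graphs import write_graph
from .groups import SubjectCFCSet, edge_density, edgewise_comparison, top_k_edges
from .plotting import plot_adjacency
from .synthetic import make_ground_truth, simulate_cohort, write_cohort
from .timeseries import ROITimeSeries, detrend_bandpass, drop_initial_volumes, read_roi_timeseries
from .tpc import TPCParams, run_tpc

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class SimulateSpec:
    """Synthetic-cohort stage settings (used when no manifest is given)."""

    n_regions: int = 10
    edge_density: float = 0.05
    contemp_fraction: float = 0.3
    weight_range: tuple[float, float] = (0.2, 0.8)
    inhibitory_fraction: float = 0.2
    noise_sd: float = 1.0
    n_per_group: Mapping[str, int] = field(default_factory=lambda: {"A": 5, "B": 5})
    group_deltas: Mapping[str, Any] = field(default_factory=dict)
    n_timepoints: int = 140


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a run (serialisable to YAML)."""

    out_dir: str = "causalfc_run"
    seed: int = 0
    manifest: str | None = None  # CSV: subject_id, group, path
    simulate: SimulateSpec | None = field(default_factory=SimulateSpec)
    drop_initial: int = 0
    band: tuple[float, float] | None = None
    tpc: TPCParams = field(default_factory=TPCParams)
    run_gc: bool = False
    gc_order: int = 1
    gc_percentile: float = 95.0
    run_spc: bool = False
    spc_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.4)
    spc_folds: int = 5
    compare_groups: tuple[str, str] | None = None
    top_k: int = 10
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML/JSON config file into a :class:`PipelineConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "tpc" in raw and isinstance(raw["tpc"], dict):
        raw["tpc"] = TPCParams(**raw["tpc"])
    if "simulate" in raw and isinstance(raw["simulate"], dict):
        sim = dict(raw["simulate"])
        if "weight_range" in sim:
            sim["weight_range"] = tuple(sim["weight_range"])
        raw["simulate"] = SimulateSpec(**sim)
    for key in ("band", "compare_groups", "spc_grid"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _stage(stage: str, subject: str | None = None):
    tag = f"stage {stage!r}" + (f", subject {subject!r}" if subject else "")

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, CausalFCError):
                raise CausalFCError(f"{tag} failed: {exc}") from exc
            if isinstance(exc, CausalFCError):
                raise CausalFCError(f"{tag} failed: {exc}") from exc
            return False

    return _ctx()


def _load_subjects(config: PipelineConfig) -> list[tuple[str, str, ROITimeSeries]]:
    if config.manifest is not None:
        mpath = Path(config.manifest)
        df = pd.read_csv(mpath, dtype=str)
        required = {"subject_id", "group", "path"}
        if not required <= set(df.columns):
            raise CausalFCError(f"manifest must have columns {sorted(required)}")
        return [
            (r.subject_id, r.group, read_roi_timeseries(mpath.parent / r.path))
            for r in df.itertuples(index=False)
        ]
    if config.simulate is None:
        raise CausalFCError("config needs either a manifest or a simulate spec")
    sim = config.simulate
    model = make_ground_truth(
        n_regions=sim.n_regions,
        edge_density=sim.edge_density,
        contemp_fraction=sim.contemp_fraction,
        weight_range=sim.weight_range,
        inhibitory_fraction=sim.inhibitory_fraction,
        seed=config.seed,
        noise_sd=sim.noise_sd,
        group_deltas={
            g: tuple(tuple(d) for d in ds) for g, ds in sim.group_deltas.items()
        },
    )
    cohort = simulate_cohort(
        model, dict(sim.n_per_group), sim.n_timepoints, seed=config.seed
    )
    return list(cohort.subjects)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the run log as a dict.

    Stage failures abort with the stage name and subject id attached.
    """
    out = Path(config.out_dir)
    for sub in ("cfc", "stats", "figures"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    if config.run_gc or config.run_spc:
        (out / "baselines").mkdir(exist_ok=True)

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    with _stage("load"):
        subjects = _load_subjects(config)
    timings["load"] = time.perf_counter() - t0

    groups = sorted({g for _, g, _ in subjects})
    cmp_groups = config.compare_groups or tuple(groups[:2])
    for g in cmp_groups:
        if g not in groups:
            raise CausalFCError(
                f"stage 'compare' failed: group {g!r} not in cohort {groups}"
            )

    t0 = time.perf_counter()
    processed = []
    for sid, group, ts in subjects:
        with _stage("preprocess", sid):
            if config.drop_initial:
                ts = drop_initial_volumes(ts, config.drop_initial)
            if config.band is not None:
                ts = detrend_bandpass(ts, *config.band)
        processed.append((sid, group, ts))
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    entries = []
    densities = {}
    for sid, group, ts in processed:
        with _stage("tpc", sid):
            cfc = run_tpc(ts, config.tpc)
            write_graph(cfc, out / "cfc" / f"{sid}.csv", "adjacency-csv")
            densities[sid] = edge_density(cfc)
        entries.append((sid, group, cfc))
    pd.DataFrame(
        [
            {"subject_id": sid, "group": g, "path": f"cfc/{sid}.csv"}
            for sid, g, _ in entries
        ]
    ).to_csv(out / "manifest.csv", index=False)
    timings["tpc"] = time.perf_counter() - t0

    if config.run_gc:
        t0 = time.perf_counter()
        for sid, group, ts in processed:
            with _stage("gc", sid):
                stat = gc_statistics(ts, config.gc_order)
                res = threshold_gc(stat, config.gc_percentile, ts.region_labels)
                write_graph(res.graph, out / "baselines" / f"gc_{sid}.csv")
                pd.DataFrame(
                    stat, index=ts.region_labels, columns=ts.region_labels
                ).to_csv(out / "baselines" / f"gc_stat_{sid}.csv", float_format="%.12g")
        timings["gc"] = time.perf_counter() - t0

    if config.run_spc:
        t0 = time.perf_counter()
        for sid, group, ts in processed:
            with _stage("spc", sid):
                _, res = cv_select_lambda(ts, config.spc_grid, config.spc_folds)
                write_graph(res.graph, out / "baselines" / f"spc_{sid}.csv")
        timings["spc"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    with _stage("compare"):
        cfcs = SubjectCFCSet(tuple(entries))
        g1, g2 = cmp_groups
        tables = {}
        for direction, name in (("g1>g2", f"{g1}_gt_{g2}"), ("g2>g1", f"{g2}_gt_{g1}")):
            table = edgewise_comparison(cfcs, g1, g2, direction=direction)
            table.to_csv(
                out / "stats" / f"edge_stats_{name}.csv",
                index=False,
                float_format="%.12g",
            )
            tables[name] = table
    timings["compare"] = time.perf_counter() - t0

    if config.make_figures:
        t0 = time.perf_counter()
        with _stage("figures"):
            sid0, _, cfc0 = entries[0]
            plot_adjacency(
                cfc0,
                out / "figures" / f"{sid0}_cfc.png",
                mask_diagonal=True,
                title=f"CFC, subject {sid0}",
            )
        timings["figures"] = time.perf_counter() - t0

    with _stage("report"):
        lines = ["# Edge-wise group comparison\n"]
        lines.append(
            f"Cohort: {len(entries)} subjects, groups {groups}; "
            f"mean CFC edge density "
            f"{np.mean(list(densities.values())):.4f}\n"
        )
        for name, table in tables.items():
            lines.append(f"\n## Top {config.top_k} edges, {name.replace('_', ' ')}\n")
            top = top_k_edges(table, config.top_k)
            lines.append("```\n" + top.to_string(index=False) + "\n```")
            lines.append("")
        (out / "report.md").write_text("\n".join(lines))

    run_log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "numpy_version": np.__version__,
        "n_subjects": len(entries),
        "groups": groups,
        "edge_density_mean": float(np.mean(list(densities.values()))),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    (out / "run.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return run_log
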