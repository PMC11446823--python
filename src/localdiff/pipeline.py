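"""Staged pipeline tying the analysis together.

Stages (prerequisites in parentheses):

* ``simulate`` — synthetic scene + 1 Hz drive traces
* ``grid`` (simulate) — per-cell median-of-pass-means MM estimates
* ``features`` (simulate) — 21-column KLS feature matrix
* ``harmonize`` (simulate, grid) — LUR resampling, population allocation,
  localized difference; the tidy per-cell record table
* ``fit-kls`` (harmonize, features) — BART of LD on the KLS matrix, VIP
  ranking and top-variable PDPs, per pollutant
* ``fit-demo`` (harmonize, features) — Models A/B, demographic PDPs,
  attenuation report, population-weighted LD summaries
* ``report`` (all above) — OLS comparison table, LD summaries, key-number
  JSON

Every stage writes a manifest (sha256 of inputs and outputs, config echo,
seed, package version); rerunning with unchanged inputs is a no-op unless
forced, and a stage refuses to run when a prerequisite's recorded output
hash no longer matches the file on disk.

The single tidy per-cell table (``cells.csv``) is the hand-off contract:
stages append columns keyed by ``cell_id`` and never mutate existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, equity, io
from .bart import BART, BartConfig
from .features import build_feature_matrix, sparsity_report
from .gridding import grid_concentration_field
from .harmonize import allocate_population, areal_resample, compute_ld, ols_compare
from .scene import POLLUTANTS, SHARE_NAMES, Scene, SceneConfig, generate_scene, simulate_drive_traces

STAGES = ("simulate", "grid", "features", "harmonize", "fit-kls", "fit-demo", "report")

_PREREQS = {
    "simulate": (),
    "grid": ("simulate",),
    "features": ("simulate",),
    "harmonize": ("simulate", "grid"),
    "fit-kls": ("harmonize", "features"),
    "fit-demo": ("harmonize", "features"),
    "report": ("simulate", "grid", "features", "harmonize", "fit-kls", "fit-demo"),
}


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "ld_out"
    scene: SceneConfig = field(default_factory=SceneConfig)
    gap_threshold_s: float = 60.0
    buffers_m: tuple = (50.0, 150.0, 300.0)
    denominator: str = "buffer"
    bart_kls: BartConfig = field(default_factory=BartConfig)
    bart_demo: BartConfig = field(default_factory=BartConfig)
    pollutants: tuple = POLLUTANTS
    n_top_variables: int = 8

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        seed = int(data.get("seed", 0))
        scene_data = dict(data.pop("scene", {}))
        scene_data.setdefault("seed", seed)
        if "base_shares" in scene_data:
            scene_data["base_shares"] = tuple(scene_data["base_shares"])
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name in ("scene", "bart_kls", "bart_demo"):
                continue
            if f.name in data:
                kw[f.name] = data[f.name]
        kw["scene"] = SceneConfig(**scene_data)
        kw["bart_kls"] = BartConfig(**data.get("bart_kls", {}))
        kw["bart_demo"] = BartConfig(**data.get("bart_demo", {}))
        if "buffers_m" in kw:
            kw["buffers_m"] = tuple(kw["buffers_m"])
        if "pollutants" in kw:
            kw["pollutants"] = tuple(kw["pollutants"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {})

    def echo(self) -> dict:
        return io._jsonable(dataclasses.asdict(self))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _manifest_path(out: Path, stage: str) -> Path:
    return out / f"manifest_{stage.replace('-', '_')}.json"


def _hash_files(paths) -> dict:
    return {str(Path(p).name): _sha256(p) for p in paths if Path(p).exists()}


def _stage_io(stage: str, out: Path, config: PipelineConfig):
    """(input paths, output paths) of a stage within the output directory."""
    scene_dir = out / "scene"
    scene_files = sorted(scene_dir.glob("*.geojson")) + [
        scene_dir / "grid.json", scene_dir / "truth.csv", scene_dir / "scene_config.yaml",
    ] if scene_dir.exists() else []
    pols = config.pollutants
    table = {
        "simulate": ([], scene_files + [out / "traces.csv"]),
        "grid": ([out / "traces.csv", scene_dir / "grid.json"], [out / "mm.csv"]),
        "features": (scene_files, [out / "kls.csv", out / "kls_sparsity.csv"]),
        "harmonize": (
            [out / "mm.csv", scene_dir / "block_groups.geojson", scene_dir / "grid.json"],
            [out / "cells.csv"],
        ),
        "fit-kls": (
            [out / "cells.csv", out / "kls.csv"],
            [out / f"vip_{p}.csv" for p in pols]
            + [out / f"pdp_kls_{p}.csv" for p in pols]
            + [out / "kls_fit.json"],
        ),
        "fit-demo": (
            [out / "cells.csv", out / "kls.csv"],
            [out / f"pdp_demo_{p}.csv" for p in pols]
            + [out / f"attenuation_{p}.csv" for p in pols]
            + [out / "weighted_ld.csv", out / "demo_fit.json"],
        ),
        "report": (
            [out / "cells.csv"] + [out / f"vip_{p}.csv" for p in pols],
            [out / "ols_comparison.csv", out / "ld_summary.csv", out / "report.json"],
        ),
    }
    return table[stage]


def run_stage(stage: str, config: PipelineConfig, force: bool = False) -> str:
    """Run one pipeline stage; returns "ran" or "up-to-date".

    Prerequisite stages must have been run and their recorded outputs must
    still hash-match the files on disk; a mismatch (corrupted or manually
    edited intermediate) raises :class:`StageError` naming the stage to
    rerun.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for pre in _PREREQS[stage]:
        mpath = _manifest_path(out, pre)
        if not mpath.exists():
            raise StageError(f"stage {stage!r} requires {pre!r}; run `{pre}` first")
        recorded = json.loads(mpath.read_text())["outputs"]
        current = _hash_files([out / n for n in recorded] + [out / "scene" / n for n in recorded])
        for name, h in recorded.items():
            cur = current.get(name)
            if cur is None or cur != h:
                raise StageError(
                    f"output {name!r} of prerequisite stage {pre!r} is missing or "
                    f"modified; rerun `{pre}`"
                )

    inputs, outputs = _stage_io(stage, out, config)
    mpath = _manifest_path(out, stage)
    echo = config.echo()
    if not force and mpath.exists():
        man = json.loads(mpath.read_text())
        if (
            man.get("config") == echo
            and man.get("inputs") == _hash_files(inputs)
            and all(Path(p).exists() for p in _stage_io(stage, out, config)[1])
            and man.get("outputs") == _hash_files(_stage_io(stage, out, config)[1])
        ):
            return "up-to-date"

    _RUNNERS[stage](out, config)
    inputs, outputs = _stage_io(stage, out, config)  # simulate creates its outputs list
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "version": __version__,
        "config": echo,
        "inputs": _hash_files(inputs),
        "outputs": _hash_files(outputs),
    }
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return "ran"


def run_all(config: PipelineConfig, force: bool = False) -> dict:
    return {stage: run_stage(stage, config, force=force) for stage in STAGES}


# ---------------------------------------------------------------------------
# stage implementations


def _load_scene(out: Path) -> Scene:
    return io.read_scene(out / "scene")


def _run_simulate(out: Path, config: PipelineConfig):
    scene = generate_scene(config.scene)
    traces = simulate_drive_traces(scene, config.scene)
    io.write_scene(out / "scene", scene)
    io.write_traces(out / "traces.csv", traces)


def _run_grid(out: Path, config: PipelineConfig):
    scene = _load_scene(out)
    traces = io.read_traces(out / "traces.csv")
    mm = grid_concentration_field(traces, scene.grid, config.gap_threshold_s, config.pollutants)
    mm.to_csv(out / "mm.csv")


def _run_features(out: Path, config: PipelineConfig):
    scene = _load_scene(out)
    kls = build_feature_matrix(
        scene.layers(), scene.grid, buffers_m=config.buffers_m,
        denominator=config.denominator,
    )
    kls.to_csv(out / "kls.csv")
    sparsity_report(kls).rename("zero_fraction").to_csv(out / "kls_sparsity.csv")


def _run_harmonize(out: Path, config: PipelineConfig):
    scene = _load_scene(out)
    mm = pd.read_csv(out / "mm.csv", index_col="cell_id")
    lur_fields = [f"lur_{p}" for p in config.pollutants]
    lur = areal_resample(scene.block_groups, lur_fields, scene.grid)
    cells = compute_ld(mm, lur, config.pollutants)
    cells.insert(0, "n_passes", mm["n_passes"].reindex(cells.index))
    alloc = allocate_population(scene.block_groups, scene.grid)
    cells = cells.join(alloc, how="left")
    cells.to_csv(out / "cells.csv")


def _load_cells(out: Path, config: PipelineConfig):
    cells = pd.read_csv(out / "cells.csv", index_col="cell_id")
    kls = pd.read_csv(out / "kls.csv", index_col="cell_id")
    kls = kls.reindex(cells.index)
    return cells, kls


def _run_fit_kls(out: Path, config: PipelineConfig):
    cells, kls = _load_cells(out, config)
    metrics = {}
    for i, p in enumerate(config.pollutants):
        res = BART(cells[f"ld_{p}"], kls, config=config.bart_kls).fit(
            seed=config.seed + 101 + i
        )
        vip = res.variable_inclusion_proportions()
        vip.rename("vip").to_csv(out / f"vip_{p}.csv")
        frames = [
            res.partial_dependence(f).to_frame()
            for f in res.top_variables(config.n_top_variables).index
        ]
        pd.concat(frames, ignore_index=True).to_csv(out / f"pdp_kls_{p}.csv", index=False)
        metrics[p] = {"pseudo_r2": res.pseudo_r2, "nrmse": res.nrmse, "n": len(cells)}
    (out / "kls_fit.json").write_text(json.dumps(metrics, indent=1))


def _run_fit_demo(out: Path, config: PipelineConfig):
    cells, kls = _load_cells(out, config)
    metrics = {}
    weighted_frames = []
    for i, p in enumerate(config.pollutants):
        ld = cells[f"ld_{p}"]
        fit_a, fit_b = equity.fit_models_ab(
            cells["pop"], cells[list(SHARE_NAMES)], kls, ld,
            config=config.bart_demo, seed=config.seed + 201 + i,
        )
        frames = []
        for model, f in (("A", fit_a), ("B", fit_b)):
            for name, pdp in f.pdps.items():
                df = pdp.to_frame()
                df.insert(0, "model", model)
                frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(out / f"pdp_demo_{p}.csv", index=False)
        equity.attenuation_table(fit_a, fit_b).to_csv(out / f"attenuation_{p}.csv")
        counts = cells[[c for c in cells.columns if c.startswith("count_")]]
        wq = equity.population_weighted_quantiles(ld, counts)
        wq.insert(0, "pollutant", p)
        weighted_frames.append(wq.reset_index())
        metrics[p] = {
            "model_a_pseudo_r2": fit_a.pseudo_r2,
            "model_b_pseudo_r2": fit_b.pseudo_r2,
            "n": len(cells),
        }
    pd.concat(weighted_frames, ignore_index=True).to_csv(out / "weighted_ld.csv", index=False)
    (out / "demo_fit.json").write_text(json.dumps(metrics, indent=1))


def _run_report(out: Path, config: PipelineConfig):
    cells = pd.read_csv(out / "cells.csv", index_col="cell_id")
    ols_rows, ld_rows = [], []
    for p in config.pollutants:
        res = ols_compare(cells[f"mm_{p}"], cells[f"lur_{p}"])
        res["pollutant"] = p
        ols_rows.append(res)
        ld = cells[f"ld_{p}"]
        ld_rows.append(
            {
                "pollutant": p,
                "mean_ld": float(ld.mean()),
                "median_ld": float(ld.median()),
                "q25_ld": float(ld.quantile(0.25)),
                "q75_ld": float(ld.quantile(0.75)),
                "n_cells": int(len(ld)),
            }
        )
    pd.DataFrame(ols_rows).set_index("pollutant").to_csv(out / "ols_comparison.csv")
    pd.DataFrame(ld_rows).set_index("pollutant").to_csv(out / "ld_summary.csv")
    report = {
        "seed": config.seed,
        "ols": {r["pollutant"]: {k: r[k] for k in ("slope", "intercept", "r2", "p_value")} for r in ols_rows},
        "ld": {r["pollutant"]: r for r in ld_rows},
        "kls_fit": json.loads((out / "kls_fit.json").read_text()),
        "demo_fit": json.loads((out / "demo_fit.json").read_text()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))


_RUNNERS = {
    "simulate": _run_simulate,
    "grid": _run_grid,
    "features": _run_features,
    "harmonize": _run_harmonize,
    "fit-kls": _run_fit_kls,
    "fit-demo": _run_fit_demo,
    "report": _run_report,
}
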