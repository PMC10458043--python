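"""Configuration-driven orchestration of the full analysis.

A :class:`PipelineConfig` (usually loaded from YAML) drives ``run``, which
executes the stages in order, logs every artifact it writes with a SHA-256
checksum, and returns the manifest.  A single global seed fans out to
deterministic per-stage seeds, so identical config + seed reproduces
identical outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import lulc as lulc_mod
from . import synthetic as synth_mod
from .grid import RasterStack, read_geotiff, write_geotiff
from .maxent import (
    MaxentSettings,
    env_at_points,
    fit,
    importance,
    project,
    response_curve,
    sample_background,
)
from .occurrences import OccurrenceSet, convex_hull, load_occurrences, thin_to_grid
from .suitability import (
    binarize,
    classify_equal_interval,
    percentile_threshold,
    presence_change,
)
from .varselect import correlation_matrix, remove_collinear

logger = logging.getLogger("ecoshift")

ALL_STAGES = [
    "simulate",
    "thin",
    "select",
    "fit",
    "diagnostics",
    "project",
    "threshold",
    "classify",
    "change",
    "lulc-areas",
    "lulc-transitions",
]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global one."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown YAML keys are rejected."""

    output_dir: str = "ecoshift_out"
    seed: int = 0
    # synthetic scenario (None -> file inputs required)
    synthetic: dict | None = None
    # file inputs
    rasters: dict[str, str] = field(default_factory=dict)
    categorical_rasters: list[str] = field(default_factory=list)
    occurrence_files: list[str] = field(default_factory=list)
    occurrence_xy_cols: list[str] = field(default_factory=lambda: ["x", "y"])
    # analysis parameters
    collinearity_cutoff: float = 0.8
    maxent: dict = field(default_factory=dict)
    threshold_percentile: float = 10.0
    future_shift: dict[str, float] = field(default_factory=dict)
    # LULC inputs: either epoch rasters or a published wide CSV of shares
    lulc_maps: list[str] = field(default_factory=list)
    lulc_legend: str | None = None
    lulc_level: int | str = 1
    lulc_published_table: str | None = None
    lulc_mask: str = "none"  # none | hull

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def maxent_settings(self) -> MaxentSettings:
        return MaxentSettings(**self.maxent)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.doc: dict = {"stages": {}}

    def stage(self, name: str) -> dict:
        return self.doc["stages"].setdefault(
            name, {"artifacts": {}, "params": {}, "metrics": {}}
        )

    def record(self, stage: str, key: str, path: Path) -> None:
        self.stage(stage)["artifacts"][key] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.doc, fh, indent=1, sort_keys=True)
        return path


def run(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in canonical order; returns the manifest."""
    stages = list(ALL_STAGES) if stages is None else stages
    bad = [s for s in stages if s not in ALL_STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    state: dict = {}

    order = [s for s in ALL_STAGES if s in stages]
    for name in order:
        logger.info("stage %s", name)
        try:
            _STAGE_FUNCS[name](config, state, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest.write()
    return manifest.doc


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _require(state: dict, key: str, stage: str, producer: str):
    if key not in state:
        raise ValueError(
            f"stage {stage!r} needs {key!r}; run stage {producer!r} first "
            "or provide file inputs"
        )
    return state[key]


def _load_stack(config: PipelineConfig) -> RasterStack:
    layers = []
    for name, path in config.rasters.items():
        layer = read_geotiff(path, name=name)
        if name in config.categorical_rasters:
            layer.kind = "categorical"
        layers.append(layer)
    return RasterStack(layers)


def _stage_simulate(config, state, manifest):
    st = manifest.stage("simulate")
    if config.synthetic is None:
        # file-input mode: "simulate" just loads the declared inputs
        state["stack"] = _load_stack(config)
        occ = OccurrenceSet([])
        xcol, ycol = config.occurrence_xy_cols
        for p in config.occurrence_files:
            occ = occ.union(load_occurrences(p, x_col=xcol, y_col=ycol))
        state["occurrences"] = occ
        st["params"]["mode"] = "files"
        return
    seed = stage_seed(config.seed, "simulate")
    scenario = synth_mod.SyntheticScenario(**{**config.synthetic, "seed": seed})
    state["scenario"] = scenario
    stack = synth_mod.gen_env_stack(scenario)
    state["stack"] = stack
    weights = scenario.true_weights or {scenario.variables[0]: 2.0}
    state["occurrences"] = synth_mod.gen_occurrences(
        stack, weights, scenario.m_presence, stage_seed(config.seed, "occurrences")
    )
    state["lulc_layers"] = synth_mod.gen_lulc_series(
        scenario, stage_seed(config.seed, "lulc")
    )
    st["params"]["mode"] = "synthetic"
    st["params"]["variables"] = scenario.variables
    occ_path = manifest.out_dir / "occurrences.csv"
    state["occurrences"].to_csv(occ_path)
    manifest.record("simulate", "occurrences", occ_path)
    for layer in stack:
        p = manifest.out_dir / f"env_{layer.name}.tif"
        write_geotiff(layer, p)
        manifest.record("simulate", f"env_{layer.name}", p)


def _stage_thin(config, state, manifest):
    occ = _require(state, "occurrences", "thin", "simulate")
    stack = _require(state, "stack", "thin", "simulate")
    thinned = thin_to_grid(occ, stack.spec)
    state["thinned"] = thinned
    path = manifest.out_dir / "occurrences_thinned.csv"
    thinned.to_csv(path)
    manifest.record("thin", "occurrences_thinned", path)
    st = manifest.stage("thin")
    st["metrics"]["n_input"] = len(occ)
    st["metrics"]["n_thinned"] = len(thinned)


def _stage_select(config, state, manifest):
    stack = _require(state, "stack", "select", "simulate")
    report = correlation_matrix(stack)
    retained = remove_collinear(report, cutoff=config.collinearity_cutoff)
    state["retained"] = retained
    path = manifest.out_dir / "correlation_matrix.csv"
    report.to_csv(path)
    manifest.record("select", "correlation_matrix", path)
    rpath = manifest.out_dir / "retained_variables.txt"
    rpath.write_text("\n".join(retained) + "\n")
    manifest.record("select", "retained_variables", rpath)
    st = manifest.stage("select")
    st["params"]["cutoff"] = config.collinearity_cutoff
    st["metrics"]["n_retained"] = len(retained)


def _stage_fit(config, state, manifest):
    stack = _require(state, "stack", "fit", "simulate")
    thinned = state.get("thinned") or _require(state, "occurrences", "fit", "simulate")
    retained = state.get("retained") or stack.names
    retained = [v for v in retained if v not in ("dem",)]
    model_stack = stack.subset(retained)
    settings = config.maxent_settings()
    settings.seed = stage_seed(config.seed, "fit")
    background = sample_background(model_stack, settings.n_background, settings.seed)
    presence_env = env_at_points(model_stack, thinned.xy)
    categorical = [l.name for l in model_stack if l.kind == "categorical"]
    model = fit(presence_env, background, settings, categorical=categorical)
    state.update(
        model=model, background=background, presence_env=presence_env,
        model_stack=model_stack,
    )
    path = manifest.out_dir / "model.json"
    model.to_json(path)
    manifest.record("fit", "model", path)
    st = manifest.stage("fit")
    st["metrics"]["gain"] = model.gain
    st["metrics"]["iterations"] = model.iterations
    st["metrics"]["n_presence"] = model.n_presence


def _stage_diagnostics(config, state, manifest):
    model = _require(state, "model", "diagnostics", "fit")
    report = importance(
        model, state["presence_env"], state["background"],
        seed=stage_seed(config.seed, "diagnostics"),
    )
    path = manifest.out_dir / "importance.csv"
    report.to_csv(path)
    manifest.record("diagnostics", "importance", path)
    curves = []
    for v in model.variables:
        xs, ys = response_curve(model, v)
        curves.append(pd.DataFrame({"variable": v, "value": xs, "cloglog": ys}))
    cpath = manifest.out_dir / "response_curves.csv"
    pd.concat(curves, ignore_index=True).to_csv(cpath, index=False)
    manifest.record("diagnostics", "response_curves", cpath)
    st = manifest.stage("diagnostics")
    st["metrics"]["training_auc"] = report.training_auc
    st["metrics"]["full_gain"] = report.full_gain


def _stage_project(config, state, manifest):
    model = _require(state, "model", "project", "fit")
    stack = state["model_stack"]
    current = project(model, stack, "cloglog", name="suitability_current")
    state["suit_current"] = current
    p = manifest.out_dir / "suitability_current.tif"
    write_geotiff(current, p)
    manifest.record("project", "suitability_current", p)
    # future scenario: shifted copies of the environmental layers
    shift = config.future_shift
    if not shift and config.synthetic is not None:
        shift = {model.variables[0]: 0.5}
    if shift:
        future_layers = []
        for layer in stack:
            delta = shift.get(layer.name, 0.0)
            if delta and layer.kind == "continuous":
                future_layers.append(layer.with_values(layer.values + delta))
            else:
                future_layers.append(layer)
        future_stack = RasterStack(future_layers)
        future = project(model, future_stack, "cloglog", name="suitability_future")
        state["suit_future"] = future
        p = manifest.out_dir / "suitability_future.tif"
        write_geotiff(future, p)
        manifest.record("project", "suitability_future", p)


def _stage_threshold(config, state, manifest):
    model = _require(state, "model", "threshold", "fit")
    thr = percentile_threshold(
        model, state["presence_env"], q=config.threshold_percentile
    )
    state["threshold"] = thr
    st = manifest.stage("threshold")
    st["metrics"]["threshold"] = thr
    st["params"]["percentile"] = config.threshold_percentile
    for key in ("suit_current", "suit_future"):
        if key in state:
            bmap = binarize(state[key], thr)
            state[key.replace("suit", "bin")] = bmap
            p = manifest.out_dir / f"{state[key].name}_binary.tif"
            write_geotiff(bmap.layer, p)
            manifest.record("threshold", f"{key}_binary", p)


def _stage_classify(config, state, manifest):
    tables = []
    for key, tag in (("suit_current", "current"), ("suit_future", "future")):
        if key not in state:
            continue
        classed, table = classify_equal_interval(state[key], scenario=tag)
        p = manifest.out_dir / f"{state[key].name}_classes.tif"
        write_geotiff(classed, p)
        manifest.record("classify", f"{key}_classes", p)
        tables.append(table.to_frame())
    if tables:
        p = manifest.out_dir / "suitability_classes.csv"
        pd.concat(tables, ignore_index=True).to_csv(p, index=False)
        manifest.record("classify", "class_table", p)


def _stage_change(config, state, manifest):
    if "bin_current" not in state or "bin_future" not in state:
        raise ValueError("presence change needs current and future binary maps")
    report = presence_change(state["bin_current"], state["bin_future"])
    p = manifest.out_dir / "presence_change.csv"
    report.to_frame().to_csv(p, index=False)
    manifest.record("change", "presence_change", p)
    st = manifest.stage("change")
    st["metrics"]["relative_change_pct"] = report.relative_change_pct


def _lulc_tables(config, state):
    if config.lulc_published_table:
        return lulc_mod.LULCTable.series_from_csv(config.lulc_published_table), None
    layers = state.get("lulc_layers")
    if layers is None and config.lulc_maps:
        layers = [read_geotiff(p) for p in config.lulc_maps]
        for l in layers:
            l.kind = "categorical"
        state["lulc_layers"] = layers
    if layers is None:
        raise ValueError("no LULC inputs: set lulc_maps, lulc_published_table, "
                         "or use synthetic mode")
    mask = None
    if config.lulc_mask == "hull":
        occ = state.get("thinned") or state.get("occurrences")
        if occ is None:
            raise ValueError("lulc_mask=hull requires occurrences")
        mask = convex_hull(occ)
    legend = (
        lulc_mod.LULCLegend.from_csv(config.lulc_legend)
        if config.lulc_legend
        else None
    )
    if legend is not None:
        layers = [
            lulc_mod.reclass_to_level(l, legend, config.lulc_level) for l in layers
        ]
    tables = [
        lulc_mod.class_area_table(l, mask=mask, epoch=l.name) for l in layers
    ]
    return tables, (layers, mask)


def _stage_lulc_areas(config, state, manifest):
    tables, _ = _lulc_tables(config, state)
    frames = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    p = manifest.out_dir / "lulc_class_areas.csv"
    frames.to_csv(p, index=False)
    manifest.record("lulc-areas", "class_areas", p)
    deltas = {}
    for a, b in zip(tables, tables[1:]):
        deltas[f"{a.epoch} -> {b.epoch}"] = lulc_mod.table_change(a, b)
    overall = lulc_mod.table_change(tables[0], tables[-1])
    deltas[overall.name] = overall
    dp = manifest.out_dir / "lulc_deltas.csv"
    pd.DataFrame(deltas).to_csv(dp)
    manifest.record("lulc-areas", "deltas", dp)


def _stage_lulc_transitions(config, state, manifest):
    tables, raster_info = _lulc_tables(config, state)
    if raster_info is None:
        raise ValueError("transition matrices need LULC rasters, not published tables")
    layers, mask = raster_info
    st = manifest.stage("lulc-transitions")
    for a, b in zip(layers, layers[1:]):
        tm = lulc_mod.transition_matrix(a, b, mask=mask)
        p = manifest.out_dir / f"transitions_{a.name}_{b.name}.csv"
        tm.to_csv(p)
        manifest.record("lulc-transitions", f"{a.name}->{b.name}", p)
        st["metrics"][f"persistence_{a.name}->{b.name}"] = tm.persistence_pct
    overall = lulc_mod.transition_matrix(layers[0], layers[-1], mask=mask)
    p = manifest.out_dir / f"transitions_{layers[0].name}_{layers[-1].name}_overall.csv"
    overall.to_csv(p)
    manifest.record("lulc-transitions", "overall", p)
    st["metrics"]["persistence_overall"] = overall.persistence_pct


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "thin": _stage_thin,
    "select": _stage_select,
    "fit": _stage_fit,
    "diagnostics": _stage_diagnostics,
    "project": _stage_project,
    "threshold": _stage_threshold,
    "classify": _stage_classify,
    "change": _stage_change,
    "lulc-areas": _stage_lulc_areas,
    "lulc-transitions": _stage_lulc_transitions,
}
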