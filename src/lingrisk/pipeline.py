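"""Pipeline orchestration: stages, manifest, exclusion accounting.

Stages run in dependency order over a workspace directory:

    simulate -> components -> breakpoints -> grid -> sar -> average
             -> assess -> report

Each stage reads the standard-format artifacts of its upstream stages
and writes CSV/GeoJSON outputs plus bookkeeping into the run manifest
(row counts, exclusion tallies, content hashes).  Identical config and
seed reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from shapely import union_all

from . import __version__, io
from .components import component_table, eligible_series, fit_growth_rate, project_geometry
from .grid import GridSpec, analysis_table, assign_languages, latitudinal_bands, summarize_cells
from .mmi import all_subsets_sar
from .segmented import pairwise_threshold_analyses
from .spatial import select_neighborhood
from .synthetic import SyntheticConfig, generate_world
from .threat import IucnThresholds, assess_all, threat_maps

log = logging.getLogger("lingrisk")

STAGE_ORDER = ("simulate", "components", "breakpoints", "grid", "sar", "average", "assess", "report")

STAGE_DEPS = {
    "simulate": (),
    "components": ("ranges.geojson", "series.csv"),
    "breakpoints": ("components.csv",),
    "grid": ("ranges.geojson", "components.csv", "covariates.csv"),
    "sar": ("cell_summary.csv",),
    "average": ("cell_summary.csv", "sar_selection.csv"),
    "assess": ("components.csv",),
    "report": ("assessments.csv", "membership.csv", "cell_summary.csv"),
}

RESPONSES = (
    "median_log10_range",
    "median_log10_population",
    "median_growth_rate",
    "median_transmission_score",
)

#: Candidate neighbourhood distances (km) per response: 250-500 by 50,
#: plus 1000/2000 for range & population and 1000/1500 for growth &
#: transmission.
def default_distances():
    base = list(range(250, 501, 50))
    return {
        "median_log10_range": base + [1000, 2000],
        "median_log10_population": base + [1000, 2000],
        "median_growth_rate": base + [1000, 1500],
        "median_transmission_score": base + [1000, 1500],
    }


@dataclass
class PipelineConfig:
    workspace: str = "lingrisk_out"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    responses: tuple = RESPONSES
    covariates: list | None = None  # None = all covariate columns present
    distances: dict = field(default_factory=default_distances)
    include_richness_for: tuple = ("median_growth_rate", "median_transmission_score")
    iucn: dict = field(default_factory=dict)
    mmi_level: float = 0.95
    mmi_renormalize: bool = True
    breakpoint_ci: str = "delta"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["responses"] = list(self.responses)
        d["include_richness_for"] = list(self.include_richness_for)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(ws: Path, stage: str):
    missing = [f for f in STAGE_DEPS[stage] if not (ws / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage '{stage}' needs upstream artifacts {missing}; run earlier stages first"
        )


def _load_grid(ws: Path) -> GridSpec:
    meta = json.loads((ws / "world_meta.json").read_text())["grid"]
    return GridSpec(
        cell_size=meta["cell_size"],
        x0=meta["x0"],
        y0=meta["y0"],
        n_cols=meta["n_cols"],
        n_rows=meta["n_rows"],
    )


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages; returns the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    ws = Path(config.workspace)
    ws.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages else list(STAGE_ORDER)
    bad = set(stages) - set(STAGE_ORDER)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    stages = [s for s in STAGE_ORDER if s in stages]

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    for stage in stages:
        _require(ws, stage)
        log.info("stage %s", stage)
        counts = _STAGE_FUNCS[stage](config, ws)
        manifest["stages"][stage] = counts

    manifest["hashes"] = {
        p.name: _sha256(p) for p in sorted(ws.iterdir()) if p.is_file() and p.suffix != ".json"
    }
    (ws / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    (ws / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return manifest


# -- stages ----------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, ws: Path) -> dict:
    syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
    world = generate_world(syn)
    io.write_world(world, ws)
    return {
        "n_languages": len(world.records),
        "n_series": len(world.series),
        "n_extinct_points": len(world.extinct_points),
        "n_cells": world.grid.n_cells,
    }


def _stage_components(config: PipelineConfig, ws: Path) -> dict:
    records = io.read_ranges(ws / "ranges.geojson")
    series = io.read_series(ws / "series.csv")
    eligible = [s for s in series if eligible_series(s)]
    estimates = []
    for s in eligible:
        estimates.append(fit_growth_rate(s))
    converged = [e for e in estimates if e.converged]
    table = component_table(records, growth_estimates=estimates)
    table.to_csv(ws / "components.csv")
    return {
        "n_languages": len(records),
        "n_series": len(series),
        "n_eligible_series": len(eligible),
        "n_ineligible_series": len(series) - len(eligible),
        "n_growth_converged": len(converged),
        "n_growth_nonconverged": len(estimates) - len(converged),
    }


def _stage_breakpoints(config: PipelineConfig, ws: Path) -> dict:
    table = pd.read_csv(ws / "components.csv", index_col="language_id")
    results = pairwise_threshold_analyses(
        table, segmented_kwargs={"ci_method": config.breakpoint_ci, "random_state": config.seed}
    )
    rows = []
    for name, res in results.items():
        for cand in res["candidates"]:
            rows.append(
                {
                    "analysis": name,
                    "family": cand.family,
                    "aic": cand.aic,
                    "log_likelihood": cand.log_likelihood,
                    "k": cand.k,
                    "best": cand.family == res["best_family"],
                    "n": res["n"],
                    "psi": res["breakpoint"].psi
                    if cand.family == "segmented" and res["breakpoint"]
                    else np.nan,
                    "psi_ci_low": res["breakpoint"].psi_ci[0]
                    if cand.family == "segmented" and res["breakpoint"]
                    else np.nan,
                    "psi_ci_high": res["breakpoint"].psi_ci[1]
                    if cand.family == "segmented" and res["breakpoint"]
                    else np.nan,
                    "psi_natural": res.get("psi_natural", np.nan)
                    if cand.family == "segmented"
                    else np.nan,
                    "slope_left": res["breakpoint"].slope_left
                    if cand.family == "segmented" and res["breakpoint"]
                    else np.nan,
                    "slope_right": res["breakpoint"].slope_right
                    if cand.family == "segmented" and res["breakpoint"]
                    else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(ws / "breakpoints.csv", index=False)
    return {"n_analyses": len(results)}


def _stage_grid(config: PipelineConfig, ws: Path) -> dict:
    grid = _load_grid(ws)
    records = io.read_ranges(ws / "ranges.geojson")
    table = pd.read_csv(ws / "components.csv", index_col="language_id")
    covariates = io.read_covariates(ws / "covariates.csv")
    geoms = {
        r.language_id: project_geometry(
            r.polygons[0] if len(r.polygons) == 1 else union_all(r.polygons)
        )
        for r in records
    }
    membership = assign_languages(grid, geoms)
    summaries = summarize_cells(grid, membership, table, covariates)
    membership.to_csv(ws / "membership.csv", index=False)
    summaries.to_csv(ws / "cell_summary.csv")
    bands = latitudinal_bands(grid, summaries)
    bands.to_csv(ws / "lat_bands.csv")
    n_low_land = int((summaries["land_fraction"] < 0.5).sum())
    return {
        "n_cells": grid.n_cells,
        "n_cells_low_land": n_low_land,
        "n_membership_pairs": len(membership),
    }


def _covariate_names(config: PipelineConfig, summaries: pd.DataFrame, response: str):
    if config.covariates is not None:
        names = list(config.covariates)
    else:
        drop = set(RESPONSES) | {
            "language_richness",
            "land_fraction",
            "centroid_lon",
            "centroid_lat",
        }
        names = [c for c in summaries.columns if c not in drop]
    if response in config.include_richness_for and "language_richness" in summaries:
        names = names + ["language_richness"]
    return names


def _stage_sar(config: PipelineConfig, ws: Path) -> dict:
    summaries = pd.read_csv(ws / "cell_summary.csv", index_col="cell_id")
    grid = _load_grid(ws)
    rows = []
    for response in config.responses:
        if response not in summaries:
            continue
        names = _covariate_names(config, summaries, response)
        tab = analysis_table(summaries, response, names)
        if len(tab) < len(names) + 5:
            log.warning("response %s: too few cells (%d); skipped", response, len(tab))
            continue
        xy = grid.centroids_projected()[tab.index.to_numpy()] / 1000.0
        X = np.column_stack([np.ones(len(tab))] + [tab[c].to_numpy(float) for c in names])
        y = tab[response].to_numpy(float)
        dist, fit, sw, dtable = select_neighborhood(
            y, X, xy, config.distances.get(response, default_distances()[response]),
            names=["intercept"] + names,
        )
        for _, r in dtable.iterrows():
            rows.append(
                {
                    "response": response,
                    "threshold_km": r["threshold_km"],
                    "aic": r["aic"],
                    "selected": r["threshold_km"] == dist,
                    "n_cells": len(tab),
                    "lambda": fit.lam if r["threshold_km"] == dist else np.nan,
                    "pseudo_r2": fit.pseudo_r2 if r["threshold_km"] == dist else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(ws / "sar_selection.csv", index=False)
    return {"n_fits": len(rows)}


def _stage_average(config: PipelineConfig, ws: Path) -> dict:
    summaries = pd.read_csv(ws / "cell_summary.csv", index_col="cell_id")
    selection = pd.read_csv(ws / "sar_selection.csv")
    grid = _load_grid(ws)
    from .spatial import distance_band_neighbors

    n_models = 0
    for response in config.responses:
        sel = selection[(selection["response"] == response) & selection["selected"]]
        if sel.empty:
            continue
        dist = float(sel.iloc[0]["threshold_km"])
        names = _covariate_names(config, summaries, response)
        tab = analysis_table(summaries, response, names)
        xy = grid.centroids_projected()[tab.index.to_numpy()] / 1000.0
        sw = distance_band_neighbors(xy, dist)
        y = tab[response].to_numpy(float)
        _, models, table = all_subsets_sar(
            y, tab[names], sw, level=config.mmi_level, renormalize=config.mmi_renormalize
        )
        table.to_csv(ws / f"model_average_{response}.csv", index=False)
        n_models += len(models)
    return {"n_models_fit": n_models}


def _stage_assess(config: PipelineConfig, ws: Path) -> dict:
    table = pd.read_csv(ws / "components.csv", index_col="language_id")
    thresholds = IucnThresholds(**config.iucn)
    assessments, summary = assess_all(table, thresholds)
    assessments.to_csv(ws / "assessments.csv")
    return summary


def _stage_report(config: PipelineConfig, ws: Path) -> dict:
    grid = _load_grid(ws)
    membership = pd.read_csv(ws / "membership.csv")
    assessments = pd.read_csv(ws / "assessments.csv", index_col="language_id")
    extinct_cells = []
    points_path = ws / "extinct_points.geojson"
    if points_path.exists():
        from .projection import behrmann_project

        for _, lon, lat in io.read_points(points_path):
            x, y = behrmann_project(lon, lat)
            col = int((x - grid.x0) // grid.cell_size)
            row = int((y - grid.y0) // grid.cell_size)
            if 0 <= col < grid.n_cols and 0 <= row < grid.n_rows:
                extinct_cells.append(grid.cell_id(row, col))
    cells = threat_maps(grid, membership, assessments, extinct_cells)
    cells.to_csv(ws / "threat_cells.csv")
    return {
        "n_threatened": int(assessments["threatened"].sum()),
        "n_extinct_points": len(extinct_cells),
        "n_cells_high_threat_low_extinction": int(
            (cells["filter_class"] == "high-threat-low-extinction").sum()
        ),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "components": _stage_components,
    "breakpoints": _stage_breakpoints,
    "grid": _stage_grid,
    "sar": _stage_sar,
    "average": _stage_average,
    "assess": _stage_assess,
    "report": _stage_report,
}
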