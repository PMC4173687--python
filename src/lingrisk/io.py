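"""File formats: GeoJSON ranges/points, CSV series/covariates/tables.

Writers and readers round-trip: writing a world and reading it back
yields equal content.  Validation errors name the offending feature or
row so malformed inputs fail loudly at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .components import LanguageRecord, SpeakerSeries


def write_ranges(records, path):
    """Language ranges as a GeoJSON FeatureCollection of (multi)polygons."""
    features = []
    for rec in records:
        geom = (
            mapping(rec.polygons[0])
            if len(rec.polygons) == 1
            else {
                "type": "MultiPolygon",
                "coordinates": [mapping(p)["coordinates"] for p in rec.polygons],
            }
        )
        features.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {
                    "language_id": rec.language_id,
                    "name": rec.name,
                    "population": rec.population,
                    "transmission_status": rec.transmission_status,
                },
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_ranges(path):
    """Parse a range FeatureCollection into LanguageRecords.

    Non-polygon geometries are rejected with the feature index and id
    named.
    """
    payload = json.loads(Path(path).read_text())
    records = []
    for i, feat in enumerate(payload.get("features", [])):
        props = feat.get("properties", {})
        lang_id = props.get("language_id", f"<feature {i}>")
        geom = shape(feat["geometry"])
        if geom.geom_type == "Polygon":
            polys = [geom]
        elif geom.geom_type == "MultiPolygon":
            polys = list(geom.geoms)
        else:
            raise ValueError(
                f"feature {i} ({lang_id}): expected Polygon/MultiPolygon, got {geom.geom_type}"
            )
        records.append(
            LanguageRecord(
                language_id=lang_id,
                polygons=polys,
                population=props.get("population"),
                transmission_status=props.get("transmission_status"),
                name=props.get("name"),
            )
        )
    return records


def write_series(series_list, path):
    rows = [
        {"language_id": s.language_id, "year": int(y), "population": c}
        for s in series_list
        for y, c in zip(s.years, s.counts)
    ]
    pd.DataFrame(rows, columns=["language_id", "year", "population"]).to_csv(path, index=False)


def read_series(path):
    """Speaker series CSV -> list of SpeakerSeries.

    Duplicate (language_id, year) rows are an error naming the row
    number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    required = {"language_id", "year", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"series CSV must have columns {sorted(required)}")
    dup = df.duplicated(subset=["language_id", "year"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 1
        key = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate (language_id, year) = ({key['language_id']}, {key['year']}) at row {row}"
        )
    out = []
    for lang_id, grp in df.groupby("language_id", sort=True):
        grp = grp.sort_values("year")
        out.append(
            SpeakerSeries(
                str(lang_id), grp["year"].to_numpy(float), grp["population"].to_numpy(float)
            )
        )
    return out


def write_covariates(covariates: pd.DataFrame, path):
    covariates.to_csv(path, index=True, index_label="cell_id")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise ValueError("covariate CSV must have a cell_id column")
    return df.set_index("cell_id")


def write_points(points, path):
    """Extinct-language locations as GeoJSON points."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [lon, lat]},
            "properties": {"language_id": lang_id},
        }
        for lang_id, lon, lat in points
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True))


def read_points(path):
    payload = json.loads(Path(path).read_text())
    points = []
    for i, feat in enumerate(payload.get("features", [])):
        geom = feat["geometry"]
        if geom["type"] != "Point":
            raise ValueError(f"feature {i}: expected Point, got {geom['type']}")
        lon, lat = geom["coordinates"][:2]
        points.append((feat.get("properties", {}).get("language_id", f"<feature {i}>"), lon, lat))
    return points


def write_world(world, outdir):
    """Write every world artifact (plus the truth ledger) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ranges(world.records, outdir / "ranges.geojson")
    write_series(world.series, outdir / "series.csv")
    write_covariates(world.covariates, outdir / "covariates.csv")
    write_points(world.extinct_points, outdir / "extinct_points.geojson")
    world.truth.to_csv(outdir / "truth.csv")
    meta = dict(world.meta)
    meta["grid"] = {
        "cell_size": world.grid.cell_size,
        "x0": world.grid.x0,
        "y0": world.grid.y0,
        "n_cols": world.grid.n_cols,
        "n_rows": world.grid.n_rows,
    }
    (outdir / "world_meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return outdir
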