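"""Equal-area gridding: cell tiling, any-overlap membership, per-cell medians.

The analysis grid tiles a Behrmann-projected extent with square cells
(default grain 192.9725 km, about 2° at the standard parallels).  A cell
"contains" a language when the language's range polygon overlaps any
positive-area portion of the cell; per-cell summaries are medians of the
member languages' risk components, and covariates are averaged per cell.
Cells with less than 50% land are excluded from analysis tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .projection import (
    AUTHALIC_RADIUS_M,
    behrmann_inverse,
    global_extent,
)

#: Paper-scale grain: 192.9725 km cells.
DEFAULT_CELL_SIZE_M = 192_972.5

#: Minimum land fraction for a cell to enter analysis tables.
MIN_LAND_FRACTION = 0.5

RESPONSE_COLUMNS = (
    "median_log10_range",
    "median_log10_population",
    "median_growth_rate",
    "median_transmission_score",
)


@dataclass(frozen=True)
class GridSpec:
    """Regular equal-area grid over a projected extent.

    Cells are indexed row-major from the lower-left corner:
    ``cell_id = row * n_cols + col``.
    """

    cell_size: float = DEFAULT_CELL_SIZE_M
    x0: float = 0.0
    y0: float = 0.0
    n_cols: int = 0
    n_rows: int = 0
    radius: float = AUTHALIC_RADIUS_M

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def row_col(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_bounds(self, cell_id: int):
        row, col = divmod(int(cell_id), self.n_cols)
        x = self.x0 + col * self.cell_size
        y = self.y0 + row * self.cell_size
        return (x, y, x + self.cell_size, y + self.cell_size)

    def cell_polygon(self, cell_id: int):
        return box(*self.cell_bounds(cell_id))

    def centroids_projected(self):
        """(n_cells, 2) array of projected cell-centre coordinates."""
        ids = np.arange(self.n_cells)
        row, col = self.row_col(ids)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 + (row + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def centroids_geographic(self):
        xy = self.centroids_projected()
        lon, lat = behrmann_inverse(xy[:, 0], xy[:, 1], self.radius)
        return np.column_stack([lon, lat])


def build_grid(
    extent=None,
    cell_size: float = DEFAULT_CELL_SIZE_M,
    radius: float = AUTHALIC_RADIUS_M,
) -> GridSpec:
    """Anchor a grid at the lower-left of a projected extent.

    ``extent`` is (xmin, ymin, xmax, ymax) in projected metres; by default
    the full global Behrmann extent.  Column/row counts are ceilings so the
    grid covers the extent entirely.
    """
    if extent is None:
        extent = global_extent(radius)
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate extent")
    n_cols = int(np.ceil((xmax - xmin) / cell_size - 1e-9))
    n_rows = int(np.ceil((ymax - ymin) / cell_size - 1e-9))
    return GridSpec(
        cell_size=cell_size, x0=xmin, y0=ymin, n_cols=n_cols, n_rows=n_rows, radius=radius
    )


def _looks_geographic(geom: BaseGeometry) -> bool:
    xmin, ymin, xmax, ymax = geom.bounds
    return abs(xmin) <= 180 and abs(xmax) <= 180 and abs(ymin) <= 90 and abs(ymax) <= 90


def assign_languages(grid: GridSpec, geoms: dict) -> pd.DataFrame:
    """Any-overlap membership of projected range polygons in grid cells.

    Parameters
    ----------
    grid : GridSpec
    geoms : dict
        ``language_id -> shapely geometry`` in *projected* coordinates.

    Returns
    -------
    DataFrame with columns (cell_id, language_id); a pair is present iff
    the polygon's intersection with the closed cell square has positive
    area (boundary touching does not confer membership).
    """
    # the unprojected-input check only makes sense for planetary-scale
    # grids (cells of kilometres); on toy metre-scale grids degree-sized
    # coordinates are legitimate
    grid_metric = grid.cell_size >= 10_000.0
    rows = []
    for lang_id, geom in geoms.items():
        if geom.is_empty:
            continue
        if grid_metric and _looks_geographic(geom):
            raise ValueError(
                f"range polygon for {lang_id!r} looks unprojected "
                "(coordinates within geographic bounds); project it first"
            )
        xmin, ymin, xmax, ymax = geom.bounds
        c0 = max(0, int(np.floor((xmin - grid.x0) / grid.cell_size)))
        c1 = min(grid.n_cols - 1, int(np.floor((xmax - grid.x0) / grid.cell_size)))
        r0 = max(0, int(np.floor((ymin - grid.y0) / grid.cell_size)))
        r1 = min(grid.n_rows - 1, int(np.floor((ymax - grid.y0) / grid.cell_size)))
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                cid = grid.cell_id(r, c)
                cell = grid.cell_polygon(cid)
                if geom.intersects(cell):
                    inter = geom.intersection(cell)
                    if inter.area > 0.0:
                        rows.append((cid, lang_id))
    return pd.DataFrame(rows, columns=["cell_id", "language_id"])


def language_richness(membership: pd.DataFrame) -> pd.Series:
    """Distinct-language count per cell."""
    return membership.groupby("cell_id")["language_id"].nunique()


def summarize_cells(
    grid: GridSpec,
    membership: pd.DataFrame,
    language_table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell medians of the risk components plus covariate means.

    Parameters
    ----------
    membership : DataFrame (cell_id, language_id) from :func:`assign_languages`.
    language_table : DataFrame indexed by language_id; recognised columns
        ``area_km2``, ``population``, ``rate``, ``transmission_score``
        (any subset; missing values are simply absent from the medians).
    covariates : optional DataFrame indexed by cell_id (covariate values,
        already at cell resolution, plus ``land_fraction``).  If a cell
        appears several times the values are averaged.

    Returns
    -------
    DataFrame indexed by cell_id covering every grid cell, with columns
    ``language_richness``, the four medians, ``land_fraction`` and the
    covariate columns.  Medians use the midpoint convention for even
    counts (pandas default).
    """
    idx = pd.RangeIndex(grid.n_cells, name="cell_id")
    out = pd.DataFrame(index=idx)
    out["language_richness"] = language_richness(membership).reindex(idx).fillna(0).astype(int)

    joined = membership.join(language_table, on="language_id")
    grouped = joined.groupby("cell_id")
    if "area_km2" in joined:
        vals = joined.loc[joined["area_km2"] > 0]
        out["median_log10_range"] = (
            np.log10(vals["area_km2"]).groupby(vals["cell_id"]).median().reindex(idx)
        )
    if "population" in joined:
        vals = joined.loc[joined["population"] > 0]
        out["median_log10_population"] = (
            np.log10(vals["population"]).groupby(vals["cell_id"]).median().reindex(idx)
        )
    if "rate" in joined:
        out["median_growth_rate"] = grouped["rate"].median().reindex(idx)
    if "transmission_score" in joined:
        out["median_transmission_score"] = grouped["transmission_score"].median().reindex(idx)

    if covariates is not None:
        cov = covariates.groupby(level=0).mean() if covariates.index.has_duplicates else covariates
        out = out.join(cov.reindex(idx))
    if "land_fraction" not in out:
        out["land_fraction"] = 1.0

    cen = grid.centroids_geographic()
    out["centroid_lon"] = cen[:, 0]
    out["centroid_lat"] = cen[:, 1]
    return out


def analysis_table(
    summaries: pd.DataFrame,
    response: str,
    covariate_names=(),
    min_land_fraction: float = MIN_LAND_FRACTION,
) -> pd.DataFrame:
    """Cells eligible for the regression of one response.

    Drops cells with land fraction below ``min_land_fraction`` (strictly
    less than), cells lacking the response, and cells lacking any requested
    covariate.
    """
    cols = [response, *covariate_names]
    mask = summaries["land_fraction"] >= min_land_fraction
    tab = summaries.loc[mask, cols + ["centroid_lon", "centroid_lat"]].dropna()
    return tab


def latitudinal_bands(
    grid: GridSpec,
    summaries: pd.DataFrame,
    responses=RESPONSE_COLUMNS,
    min_land_fraction: float = MIN_LAND_FRACTION,
) -> pd.DataFrame:
    """Band summaries: median of cell medians per grid row.

    Bands are grid rows (constant projected y, hence equal true area),
    labelled by their central geographic latitude.  Band land area is the
    sum of cell land fractions times the cell area.  Bands with no
    eligible cells keep a row with missing medians.
    """
    row_of = summaries.index.values // grid.n_cols
    df = summaries.copy()
    df["band_row"] = row_of

    land = df.groupby("band_row")["land_fraction"].sum() * grid.cell_area_km2
    eligible = df[df["land_fraction"] >= min_land_fraction]

    out = pd.DataFrame(index=pd.RangeIndex(grid.n_rows, name="band_row"))
    y_centres = grid.y0 + (np.arange(grid.n_rows) + 0.5) * grid.cell_size
    _, lat = behrmann_inverse(np.zeros(grid.n_rows), y_centres, grid.radius)
    out["central_lat"] = lat
    out["land_area_km2"] = land.reindex(out.index).fillna(0.0)
    for resp in responses:
        if resp in df:
            out[resp] = eligible.groupby("band_row")[resp].median().reindex(out.index)
    return out
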