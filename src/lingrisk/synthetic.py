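"""Synthetic world generator with a ground-truth ledger.

Emulates the structure of a global language-range + speaker-survey data
set at desk scale: lognormal range-size and population-size
distributions, a speaker growth-rate distribution centred near the
global human growth ratio (1.016 per year) with a long left tail driven
by a decline regime below a minimum-viable-population threshold
(default 334 speakers), spatially autocorrelated covariate fields on an
equal-area grid, and an optional SAR-error response with known
coefficients for parameter-recovery studies.  Every generated quantity
any downstream analysis might recover (true growth rates, the decline
threshold, the SAR lambda/beta) is recorded in the truth ledger.

Identical (config, seed) produce identical worlds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely import union_all
from shapely.geometry import box
from shapely.ops import transform as shapely_transform

from .components import LanguageRecord, SpeakerSeries
from .grid import GridSpec
from .projection import behrmann_inverse
from .spatial import SpatialWeights
from scipy import sparse

COVARIATE_NAMES = (
    "annual_precipitation",
    "vegetation_productivity",
    "temperature_seasonality",
    "precipitation_seasonality",
    "elevation_range",
    "habitat_diversity",
    "population_density",
    "population_change",
    "gdp_per_capita",
)

_STREAMS = {"covariates": 1, "languages": 2, "series": 3, "land": 4, "sar": 5, "transmission": 6}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic world.

    Lognormal parameters are on the log10 scale (log10 km² for ranges,
    log10 speakers for populations).  ``decline_log_rate`` replaces the
    baseline per-year log growth for languages whose initial population
    falls below ``threshold_speakers`` — the generating
    minimum-viable-population regime.  ``gdp_effect_on_growth`` couples a
    language's growth rate to the (standardised) GDP covariate of its
    home cell.
    """

    seed: int = 0
    grid_cols: int = 40
    grid_rows: int = 20
    cell_km: float = 192.9725
    n_languages: int = 600
    range_lognormal: tuple = (3.3, 1.2)  # log10 km²
    pop_lognormal: tuple = (3.4, 1.3)  # log10 speakers
    pop_range_coupling: tuple | None = None  # (psi_log10_pop, slope_below, slope_above, sd)
    baseline_log_growth: float = float(np.log(1.016))
    growth_sd: float = 0.01
    threshold_speakers: float = 334.0
    decline_log_rate: float = -0.03
    decline_sd: float = 0.01
    decline_mode: str = "segmented"  # "segmented": r linear in log10 N0
    # below the threshold (continuous at it), reaching decline_log_rate at
    # decline_reference_pop and steeper beyond; "step": decline_log_rate
    # for every language below the threshold
    decline_reference_pop: float = 100.0
    gdp_effect_on_growth: float = -0.005
    covariate_fields: dict = field(
        default_factory=lambda: {name: (5.0, 1.0) for name in COVARIATE_NAMES}
    )
    sar_lambda: float = 0.5
    sar_beta: dict = field(default_factory=lambda: {"gdp_per_capita": -0.01})
    sar_sigma2: float = 0.01
    survey_min_n: int = 3
    survey_max_n: int = 8
    survey_span: tuple = (1949, 2005)
    extinct_fraction: float = 0.12
    ocean_fraction: float = 0.10
    range_subdivision: int = 8
    count_noise: str = "poisson"  # or "none" for exact expected counts

    def __post_init__(self):
        if self.range_lognormal[1] < 0 or self.pop_lognormal[1] < 0:
            raise ValueError("lognormal sigma must be >= 0")
        if self.growth_sd < 0 or self.decline_sd < 0 or self.sar_sigma2 < 0:
            raise ValueError("variance parameters must be >= 0")
        if not 0 <= self.extinct_fraction < 1:
            raise ValueError("extinct_fraction must be in [0, 1)")
        if self.threshold_speakers <= 0:
            raise ValueError("threshold_speakers must be positive")
        for name, (rng_cells, sill) in self.covariate_fields.items():
            if sill < 0:
                raise ValueError(f"negative sill for {name}")
        if self.count_noise not in ("poisson", "none"):
            raise ValueError("count_noise must be 'poisson' or 'none'")
        if self.decline_mode not in ("segmented", "step"):
            raise ValueError("decline_mode must be 'segmented' or 'step'")
        if not 0 < self.decline_reference_pop < self.threshold_speakers:
            raise ValueError("decline_reference_pop must lie below the threshold")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), _STREAMS[stream]])

    def build_grid(self) -> GridSpec:
        """Equator-centred equal-area grid for this world."""
        cell = self.cell_km * 1000.0
        return GridSpec(
            cell_size=cell,
            x0=-0.5 * self.grid_cols * cell,
            y0=-0.5 * self.grid_rows * cell,
            n_cols=self.grid_cols,
            n_rows=self.grid_rows,
        )


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    grid: GridSpec
    records: list
    series: list
    covariates: pd.DataFrame  # indexed by cell_id; 9 fields + land_fraction
    extinct_points: list  # (language_id, lon, lat)
    truth: pd.DataFrame  # per-language ledger
    meta: dict  # world-level generating parameters


def _rook_weights(n_cols: int, n_rows: int) -> sparse.csr_matrix:
    """Row-standardised rook adjacency on a regular grid."""
    n = n_cols * n_rows
    rows, cols = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    rows.append(i)
                    cols.append(rr * n_cols + cc)
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return sparse.diags(1.0 / deg) @ adj


def rook_spatial_weights(n_cols: int, n_rows: int) -> SpatialWeights:
    """Rook adjacency packaged as :class:`SpatialWeights` (for tests and
    covariate simulation to share machinery with inference)."""
    n = n_cols * n_rows
    rows, cols = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr, dc in ((1, 0), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    j = rr * n_cols + cc
                    rows.extend([i, j])
                    cols.extend([j, i])
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    w = sparse.diags(1.0 / np.maximum(deg, 1)) @ adj
    return SpatialWeights(threshold_km=np.nan, adjacency=adj, w=w.tocsr(), isolates=deg == 0)


def sar_error_sample(
    W: sparse.spmatrix, lam: float, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw u = (I - lam W)^-1 eps with eps ~ N(0, sigma2 I)."""
    n = W.shape[0]
    eps = rng.normal(0.0, np.sqrt(sigma2), n)
    A = np.eye(n) - lam * np.asarray(W.todense())
    return np.linalg.solve(A, eps)


def generate_covariate_field(config: SyntheticConfig, variable_name: str, rng=None) -> np.ndarray:
    """One spatially autocorrelated covariate field on the grid.

    The field is a SAR draw u = (I - rho W)^-1 eps on the rook grid with
    rho = 1 - 1/range (range in cells), standardised to mean 0 / unit
    variance, then scaled by sqrt(sill); sill 0 gives a constant field.
    Deterministic under (config, seed): each variable has a fixed
    substream.
    """
    if variable_name not in config.covariate_fields:
        raise ValueError(f"unknown covariate {variable_name!r}")
    names = list(config.covariate_fields)
    idx = names.index(variable_name)
    if rng is None:
        rng = np.random.default_rng(
            [int(config.seed) % (2**31), _STREAMS["covariates"], idx]
        )
    corr_range, sill = config.covariate_fields[variable_name]
    n = config.grid_cols * config.grid_rows
    if sill == 0:
        return np.zeros(n)
    rho = max(0.0, 1.0 - 1.0 / max(corr_range, 1.0))
    W = _rook_weights(config.grid_cols, config.grid_rows)
    u = sar_error_sample(W, rho, 1.0, rng)
    u = (u - u.mean()) / u.std()
    return u * np.sqrt(sill)


def generate_covariates(config: SyntheticConfig) -> pd.DataFrame:
    """All covariate fields plus the land fraction, indexed by cell_id."""
    n = config.grid_cols * config.grid_rows
    out = pd.DataFrame(index=pd.RangeIndex(n, name="cell_id"))
    for name in config.covariate_fields:
        out[name] = generate_covariate_field(config, name)
    rng = config.rng("land")
    land = np.ones(n)
    n_ocean = int(round(config.ocean_fraction * n))
    if n_ocean:
        ocean = rng.choice(n, size=n_ocean, replace=False)
        land[ocean] = rng.uniform(0.0, 0.45, n_ocean)
    out["land_fraction"] = land
    return out


def _grow_blob(rng, n_sub_cols, n_sub_rows, seed_idx, n_cells):
    """Randomised contiguous blob of subcells grown from a seed subcell."""
    chosen = [seed_idx]
    chosen_set = {seed_idx}
    frontier = []

    def neighbors(idx):
        r, c = divmod(idx, n_sub_cols)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_sub_rows and 0 <= cc < n_sub_cols:
                yield rr * n_sub_cols + cc

    frontier.extend(n for n in neighbors(seed_idx) if n not in chosen_set)
    while len(chosen) < n_cells:
        if not frontier:
            warnings.warn("blob growth exhausted the grid; range capped", stacklevel=2)
            break
        k = rng.integers(0, len(frontier))
        nxt = frontier.pop(k)
        if nxt in chosen_set:
            continue
        chosen.append(nxt)
        chosen_set.add(nxt)
        frontier.extend(n for n in neighbors(nxt) if n not in chosen_set)
    return chosen


def generate_languages(config: SyntheticConfig, grid: GridSpec | None = None):
    """Language ranges (contiguous subcell blobs) and populations.

    Range areas follow the configured lognormal exactly: blobs are grown
    on a ``range_subdivision``-times finer subgrid and the last subcell
    is trimmed to a partial rectangle matching the drawn area.  With
    ``pop_range_coupling`` set, the range area is instead a two-segment
    function of log10 population (+ noise), making the range-population
    breakpoint recoverable downstream.

    Returns (records, per-language truth DataFrame).  Record polygons are
    geographic (lon/lat); the home cell of the blob seed is recorded for
    covariate coupling.
    """
    grid = grid or config.build_grid()
    rng = config.rng("languages")
    s = config.range_subdivision
    n_sub_cols, n_sub_rows = config.grid_cols * s, config.grid_rows * s
    sub_km = config.cell_km / s
    sub_area = sub_km**2
    max_area = 0.5 * grid.n_cells * grid.cell_area_km2

    mu_r, sd_r = config.range_lognormal
    mu_p, sd_p = config.pop_lognormal

    records, truth_rows = [], []
    for i in range(config.n_languages):
        lang_id = f"L{i:04d}"
        log10_pop = rng.normal(mu_p, sd_p)
        population = max(1, int(round(10.0**log10_pop)))

        if config.pop_range_coupling is not None:
            psi, slope_lo, slope_hi, sd = config.pop_range_coupling
            d = log10_pop - psi
            log10_area = mu_r + slope_lo * min(d, 0.0) + slope_hi * max(d, 0.0)
            log10_area += rng.normal(0.0, sd) if sd > 0 else 0.0
        else:
            log10_area = rng.normal(mu_r, sd_r)
        area = min(10.0**log10_area, max_area)

        n_full = int(area // sub_area)
        remainder = area - n_full * sub_area
        seed_idx = int(rng.integers(0, n_sub_cols * n_sub_rows))
        blob = _grow_blob(rng, n_sub_cols, n_sub_rows, seed_idx, n_full + (1 if remainder else 0))

        boxes = []
        for j, idx in enumerate(blob):
            r, c = divmod(idx, n_sub_cols)
            x = grid.x0 + c * sub_km * 1000.0
            y = grid.y0 + r * sub_km * 1000.0
            full = x + sub_km * 1000.0, y + sub_km * 1000.0
            if j == len(blob) - 1 and remainder and len(blob) == n_full + 1:
                if n_full == 0:
                    side = np.sqrt(area) * 1000.0
                    boxes.append(box(x, y, x + side, y + side))
                else:
                    h = remainder / sub_km * 1000.0  # strip of width sub_km
                    boxes.append(box(x, y, x + sub_km * 1000.0, y + h))
            else:
                boxes.append(box(x, y, *full))
        geom_proj = union_all(boxes)

        # store geographic coordinates (the analysis reprojects them)
        def _inv(x, y, z=None):
            lon, lat = behrmann_inverse(x, y)
            return (lon, lat)

        geom_geo = shapely_transform(_inv, geom_proj)
        polys = list(geom_geo.geoms) if geom_geo.geom_type == "MultiPolygon" else [geom_geo]

        seed_r, seed_c = divmod(seed_idx, n_sub_cols)
        home_cell = grid.cell_id(seed_r // s, seed_c // s)

        records.append(
            LanguageRecord(
                language_id=lang_id,
                polygons=polys,
                population=population,
                name=f"synthetic-{i:04d}",
            )
        )
        truth_rows.append(
            {
                "language_id": lang_id,
                "true_area_km2": area,
                "true_log10_area": float(np.log10(area)),
                "true_population": population,
                "true_log10_population": log10_pop,
                "home_cell": home_cell,
            }
        )
    columns = [
        "language_id",
        "true_area_km2",
        "true_log10_area",
        "true_population",
        "true_log10_population",
        "home_cell",
    ]
    truth = pd.DataFrame(truth_rows, columns=columns).set_index("language_id")
    return records, truth


def generate_speaker_series(
    config: SyntheticConfig, records, truth: pd.DataFrame, covariates: pd.DataFrame | None = None
):
    """Survey time series per language under the decline-threshold regime.

    Each language gets k ~ U{min_n..max_n} survey years in the span;
    counts are Poisson around N0 exp(r (t - t0)) where N0 is the
    language's population.  Above the threshold,

        r = baseline + gdp_effect * GDP(home cell) + noise;

    below it the decline regime applies: in the default "segmented" mode
    r falls linearly in log10 N0 — from the baseline at the threshold
    through ``decline_log_rate`` at the reference population and steeper
    beyond — so the growth-population relationship is a continuous
    two-segment (breakpoint) function with its break at the threshold;
    in "step" mode every below-threshold language gets
    ``decline_log_rate`` outright.

    Extinction is absorbing: once a count is zero all later counts stay
    zero.  A configured fraction of declining languages is flagged for
    the curated extinct-point layer and forced to zero at the last
    survey; small declining languages can also die out naturally through
    the Poisson draws (the ledger marks both, but only flagged languages
    produce extinct point features).  The oldest record is non-zero by
    construction (it is the reference population estimate).

    Returns (series list, updated truth with
    true_rate/declining/extinct/extinct_point).
    """
    rng = config.rng("series")
    y0, y1 = config.survey_span
    years_all = np.arange(y0, y1 + 1)
    gdp = None
    if covariates is not None and "gdp_per_capita" in covariates:
        g = covariates["gdp_per_capita"].to_numpy(float)
        sdev = g.std()
        gdp = (g - g.mean()) / sdev if sdev > 0 else np.zeros_like(g)

    truth = truth.copy()
    truth["true_rate"] = np.nan
    truth["declining"] = False
    truth["extinct"] = False  # series ends at zero (flagged or emergent)
    truth["extinct_point"] = False  # member of the curated extinct layer

    series = []
    for rec in records:
        row = truth.loc[rec.language_id]
        n0 = float(row["true_population"])
        k = int(rng.integers(config.survey_min_n, config.survey_max_n + 1))
        years = np.sort(rng.choice(years_all, size=k, replace=False))

        if n0 < config.threshold_speakers:
            if config.decline_mode == "step":
                r = config.decline_log_rate
            else:
                # one-segment decline: linear in log10 N0, continuous at
                # the threshold, hitting decline_log_rate exactly at the
                # reference population and steeper below it
                gap = np.log10(config.threshold_speakers) - np.log10(max(n0, 1.0))
                gap_ref = np.log10(config.threshold_speakers) - np.log10(
                    config.decline_reference_pop
                )
                r = config.baseline_log_growth + (gap / gap_ref) * (
                    config.decline_log_rate - config.baseline_log_growth
                )
            r += rng.normal(0.0, config.decline_sd) if config.decline_sd > 0 else 0.0
        else:
            r = config.baseline_log_growth + (
                rng.normal(0.0, config.growth_sd) if config.growth_sd > 0 else 0.0
            )
            if gdp is not None and config.gdp_effect_on_growth != 0.0:
                r += config.gdp_effect_on_growth * gdp[int(row["home_cell"])]

        declining = r < 0
        extinct = bool(declining and rng.random() < config.extinct_fraction)

        mu = n0 * np.exp(r * (years - years[0]))
        if config.count_noise == "poisson":
            counts = rng.poisson(np.minimum(mu, 1e12)).astype(float)
        else:
            counts = mu.copy()
        counts[0] = max(counts[0], 1.0)
        if extinct:
            # flagged for the curated extinct-point layer: the last survey
            # finds no speakers
            counts[-1] = 0.0
        # extinction is absorbing: once zero, always zero (small declining
        # languages can also die out naturally through the Poisson draws)
        zero = np.flatnonzero(counts == 0)
        if zero.size:
            counts[zero[0] :] = 0.0

        truth.loc[
            rec.language_id, ["true_rate", "declining", "extinct", "extinct_point"]
        ] = (r, declining, bool(counts[-1] == 0), extinct)
        series.append(SpeakerSeries(rec.language_id, years, counts))
    return series, truth


_TRANSMISSION_BY_SEVERITY = [
    "safe/other",
    "vulnerable",
    "definitely_endangered",
    "severely_endangered",
    "critically_endangered",
]


def _assign_transmission(config, records, truth):
    """Transmission status loosely tracking the decline regime."""
    rng = config.rng("transmission")
    for rec in records:
        row = truth.loc[rec.language_id]
        if row["extinct"]:
            weights = [0.0, 0.05, 0.15, 0.3, 0.5]
        elif row["declining"]:
            weights = [0.1, 0.25, 0.3, 0.25, 0.1]
        else:
            weights = [0.75, 0.15, 0.07, 0.03, 0.0]
        rec.transmission_status = str(rng.choice(_TRANSMISSION_BY_SEVERITY, p=weights))


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Assemble the full synthetic world deterministically."""
    grid = config.build_grid()
    covariates = generate_covariates(config)
    records, truth = generate_languages(config, grid)
    series, truth = generate_speaker_series(config, records, truth, covariates)
    _assign_transmission(config, records, truth)

    extinct_points = []
    for rec in records:
        if truth.loc[rec.language_id, "extinct_point"]:
            geom = union_all(rec.polygons)
            c = geom.centroid
            extinct_points.append((rec.language_id, float(c.x), float(c.y)))

    meta = {
        "seed": config.seed,
        "threshold_speakers": config.threshold_speakers,
        "decline_log_rate": config.decline_log_rate,
        "baseline_log_growth": config.baseline_log_growth,
        "gdp_effect_on_growth": config.gdp_effect_on_growth,
        "sar_lambda": config.sar_lambda,
        "sar_beta": dict(config.sar_beta),
        "sar_sigma2": config.sar_sigma2,
    }
    return SyntheticWorld(
        config=config,
        grid=grid,
        records=records,
        series=series,
        covariates=covariates,
        extinct_points=extinct_points,
        truth=truth,
        meta=meta,
    )


def generate_sar_response(config: SyntheticConfig, covariates: pd.DataFrame | None = None):
    """SAR-error response with the configured ground truth.

    y = b0 + X beta + u with u = (I - lambda W)^-1 eps on the rook grid;
    beta is ``config.sar_beta`` over covariate columns (zero elsewhere).
    Returns (y, X DataFrame, weights) for regression-recovery studies.
    """
    if covariates is None:
        covariates = generate_covariates(config)
    rng = config.rng("sar")
    sw = rook_spatial_weights(config.grid_cols, config.grid_rows)
    X = covariates[list(config.covariate_fields)]
    beta = np.array([config.sar_beta.get(c, 0.0) for c in X.columns])
    u = sar_error_sample(sw.w, config.sar_lambda, config.sar_sigma2, rng)
    y = X.to_numpy(float) @ beta + u
    return pd.Series(y, index=covariates.index, name="sar_response"), X, sw
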