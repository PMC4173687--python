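"""Per-language extinction-risk components.

Three components summarise a language's extinction risk, mirroring the
symptoms used for species: geographic range size (total polygon area in
km² on an equal-area projection), speaker population size (latest
estimate), and the speaker growth rate — the per-year coefficient of
survey year in a Poisson log-link GLM of speaker counts.  A fourth score
grades intergenerational transmission from 0 (safe) to 4 (critically
endangered).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shapely_transform
from shapely.ops import unary_union
from shapely.validation import make_valid

from .projection import behrmann_project

#: Intergenerational-transmission scoring: vulnerable = 1 up to
#: critically endangered = 4, everything else 0.  Missing status is not 0 —
#: the language is excluded from transmission analyses.
TRANSMISSION_SCORES = {
    "safe/other": 0,
    "safe": 0,
    "vulnerable": 1,
    "definitely_endangered": 2,
    "severely_endangered": 3,
    "critically_endangered": 4,
}

#: Fitting contract for the growth-rate GLM.
GLM_TOL = 1e-10
GLM_MAX_ITER = 100


@dataclass
class LanguageRecord:
    """A language's range geometry and attribute data.

    ``polygons`` hold geographic (lon/lat) coordinates; areas are always
    measured after equal-area projection.
    """

    language_id: str
    polygons: list = field(default_factory=list)
    population: int | None = None
    transmission_status: str | None = None
    name: str | None = None
    area_km2: float | None = None


@dataclass
class SpeakerSeries:
    """Speaker-count survey records (year, count) for one language."""

    language_id: str
    years: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.years.size == 0:
            raise ValueError(f"{self.language_id}: empty series")
        if self.years.size != self.counts.size:
            raise ValueError(f"{self.language_id}: years/counts length mismatch")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError(f"{self.language_id}: years must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.language_id}: negative speaker count")


@dataclass
class GrowthEstimate:
    """Poisson-GLM trend for one language's speaker counts."""

    language_id: str
    rate: float
    se: float
    n_records: int
    oldest_year: int
    initial_population: float
    converged: bool = True
    intercept: float = np.nan


@dataclass
class BiasCheck:
    """Kendall correlation between growth rate and oldest survey year."""

    tau: float
    p_value: float
    n: int


def project_geometry(geom: BaseGeometry, radius=None) -> BaseGeometry:
    """Project a geographic geometry to Behrmann metres."""
    kwargs = {} if radius is None else {"radius": radius}

    def _fwd(x, y, z=None):
        px, py = behrmann_project(x, y, **kwargs)
        return (px, py)

    return shapely_transform(_fwd, geom)


def language_range_area(record: LanguageRecord, radius=None) -> float:
    """Total range size in km²: union of projected polygons.

    Overlapping polygons of the same language are unioned before summing
    so shared area is not double-counted.  Invalid geometries are repaired
    with ``make_valid``; an irreparable geometry raises ``ValueError`` so
    the caller can exclude the language and record the error.
    """
    if not record.polygons:
        return 0.0
    projected = []
    for poly in record.polygons:
        geom = project_geometry(poly, radius=radius)
        if not geom.is_valid:
            geom = make_valid(geom)
        if not geom.is_valid:
            raise ValueError(f"{record.language_id}: irreparable geometry")
        projected.append(geom)
    merged = unary_union(projected)
    return merged.area / 1e6


def eligible_series(series: SpeakerSeries) -> bool:
    """At least three survey records, at least one of them non-zero."""
    return series.years.size >= 3 and bool(np.any(series.counts > 0))


def _poisson_loglink_irls(years, counts, tol=GLM_TOL, max_iter=GLM_MAX_ITER):
    """Newton/IRLS for the two-parameter Poisson log-link GLM.

    Model: counts ~ Poisson(exp(a + b * (year - mean_year))).  Centering
    the years is a pure reparameterisation of the intercept; the slope is
    unaffected.  Returns (a, b, se_b, converged).
    """
    t = years - years.mean()
    y = counts
    a = np.log(max(y.mean(), 1e-12))
    b = 0.0
    converged = False
    for _ in range(max_iter):
        eta = a + b * t
        if np.max(np.abs(eta)) > 500:  # diverging mean; flag
            return a, b, np.nan, False
        mu = np.exp(eta)
        # Fisher scoring: X' W X with W = diag(mu)
        s0 = mu.sum()
        s1 = (mu * t).sum()
        s2 = (mu * t * t).sum()
        g0 = (y - mu).sum()
        g1 = ((y - mu) * t).sum()
        det = s0 * s2 - s1 * s1
        if det <= 0 or not np.isfinite(det):
            return a, b, np.nan, False
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        a += da
        b += db
        scale = max(abs(a), abs(b), 1.0)
        if max(abs(da), abs(db)) < tol * scale:
            converged = True
            break
    eta = a + b * t
    mu = np.exp(eta)
    s0, s1, s2 = mu.sum(), (mu * t).sum(), (mu * t * t).sum()
    det = s0 * s2 - s1 * s1
    se_b = np.sqrt(s0 / det) if det > 0 else np.nan
    return a, b, se_b, converged


def fit_growth_rate(series: SpeakerSeries) -> GrowthEstimate:
    """Speaker growth rate: year coefficient of the Poisson log-link GLM.

    The rate is on the log scale (per-year log growth); ``exp(rate)`` is
    the annual multiplicative change, comparable with the 1.016 global
    human growth ratio.  Non-convergent series (e.g. a lone non-zero
    count at the series end) are returned flagged for downstream
    exclusion.
    """
    if not eligible_series(series):
        raise ValueError(
            f"{series.language_id}: series ineligible (need >= 3 records, one non-zero)"
        )
    a, b, se_b, converged = _poisson_loglink_irls(series.years, series.counts)
    oldest = int(series.years[0])
    return GrowthEstimate(
        language_id=series.language_id,
        rate=b,
        se=se_b,
        n_records=int(series.years.size),
        oldest_year=oldest,
        initial_population=float(series.counts[0]),
        converged=converged,
        intercept=a - b * series.years.mean(),
    )


def growth_rate_survey_bias(estimates) -> BiasCheck:
    """Kendall's tau-b between growth rate and oldest survey year.

    A significant correlation would signal circularity in using the
    initial population size (count at the oldest year) as a predictor of
    the growth rate.
    """
    rates = np.array([e.rate for e in estimates], dtype=float)
    years = np.array([e.oldest_year for e in estimates], dtype=float)
    if rates.size < 2:
        raise ValueError("need at least two growth estimates")
    if np.all(years == years[0]):
        raise ValueError("all oldest survey years identical; tau undefined")
    res = stats.kendalltau(rates, years)
    return BiasCheck(tau=float(res.statistic), p_value=float(res.pvalue), n=rates.size)


def transmission_score(status: str | None) -> int | None:
    """Map a transmission status label to its 0-4 score.

    Missing status returns ``None`` (the language is excluded from
    transmission analyses, not scored 0); an unknown label is an error.
    """
    if status is None or (isinstance(status, float) and np.isnan(status)):
        return None
    key = str(status).strip().lower().replace(" ", "_")
    if key in ("", "nan", "none"):
        return None
    if key not in TRANSMISSION_SCORES:
        raise ValueError(f"unknown transmission status {status!r}")
    return TRANSMISSION_SCORES[key]


def component_table(records, growth_estimates=None, radius=None) -> pd.DataFrame:
    """Per-language table of the risk components.

    Columns: area_km2, population, transmission_score, and (when growth
    estimates are supplied) rate, se, n_records, oldest_year,
    initial_population, converged.  Languages whose geometry cannot be
    repaired get ``geometry_error=True`` and no area.
    """
    rows = {}
    for rec in records:
        try:
            area = (
                rec.area_km2
                if rec.area_km2 is not None and not rec.polygons
                else language_range_area(rec, radius=radius)
            )
            geom_err = False
        except ValueError:
            area, geom_err = np.nan, True
        rows[rec.language_id] = {
            "area_km2": area,
            "population": np.nan if rec.population is None else rec.population,
            "transmission_score": transmission_score(rec.transmission_status),
            "geometry_error": geom_err,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "language_id"

    if growth_estimates is not None:
        g = pd.DataFrame(
            {
                e.language_id: {
                    "rate": e.rate,
                    "rate_se": e.se,
                    "n_records": e.n_records,
                    "oldest_year": e.oldest_year,
                    "initial_population": e.initial_population,
                    "converged": e.converged,
                }
                for e in growth_estimates
            }
        ).T
        g = g.astype(
            {
                "rate": float,
                "rate_se": float,
                "n_records": "Int64",
                "oldest_year": "Int64",
                "initial_population": float,
                "converged": bool,
            }
        )
        table = table.join(g)
        if "converged" in table:
            bad = table["converged"] == False  # noqa: E712  (NaN-safe mask)
            table.loc[bad, "rate"] = np.nan
    return table
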