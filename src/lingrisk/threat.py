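"""IUCN-style threat categorisation of languages and threat mapping.

Languages are assessed against five Red List criteria adapted from the
species rules, combining the three risk components:

- A3: projected decline exceeding 30/50/80% over three generations
  (decline fraction 1 - exp(3 G r) for per-year log growth r < 0),
- B1: small range (< 20 000 / 5 000 / 100 km²) with continuing decline,
- C1: small population (< 10 000 / 2 500 / 250) with a decline of at
  least the category's stated rate over its window,
- D1: very small population (< 1 000 / 250 / 50),
- D2: very small range (< 20 km², Vulnerable).

Population/range thresholds are strict ("smaller than"); the A3 decline
is strict ("exceeded"); the C1 decline requirement is inclusive ("at
least", IUCN v3.1 wording).  Generation length defaults to 25 years and
every threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORY_ORDER = {"CR": 3, "EN": 2, "VU": 1, "not_threatened": 0, "data_deficient": -1}
LEVELS = ("CR", "EN", "VU")  # most to least severe

#: Tie tolerance for decline-fraction comparisons: a rate constructed to
#: sit exactly at a boundary (e.g. ln(0.7)/75 for 30% over three
#: generations) must behave as "exactly at", not drift across it by one
#: floating-point ulp.
_TIE_EPS = 1e-12


def _default_c1_decline(G: float) -> dict:
    # (required decline fraction, window in years): v3.1 defaults
    return {
        "VU": (0.10, max(10.0, 3 * G)),
        "EN": (0.20, max(5.0, 2 * G)),
        "CR": (0.25, max(3.0, 1 * G)),
    }


@dataclass
class IucnThresholds:
    """Thresholds for criteria A3, B1, C1, D1, D2 (all configurable)."""

    generation_years: float = 25.0
    a3_decline: dict = field(default_factory=lambda: {"VU": 0.30, "EN": 0.50, "CR": 0.80})
    b1_area_km2: dict = field(default_factory=lambda: {"VU": 20_000.0, "EN": 5_000.0, "CR": 100.0})
    c1_population: dict = field(default_factory=lambda: {"VU": 10_000.0, "EN": 2_500.0, "CR": 250.0})
    c1_decline: dict | None = None
    d1_population: dict = field(default_factory=lambda: {"VU": 1_000.0, "EN": 250.0, "CR": 50.0})
    d2_area_km2: float = 20.0

    def __post_init__(self):
        if self.c1_decline is None:
            self.c1_decline = _default_c1_decline(self.generation_years)
        for crit in (self.a3_decline,):
            if not (crit["CR"] >= crit["EN"] >= crit["VU"]):
                raise ValueError("A3 decline thresholds must nest CR >= EN >= VU")
        for crit in (self.b1_area_km2, self.c1_population, self.d1_population):
            if not (crit["CR"] <= crit["EN"] <= crit["VU"]):
                raise ValueError("size thresholds must nest CR <= EN <= VU")


@dataclass
class ThreatAssessment:
    language_id: str
    category: str
    criteria_met: list
    decline_3gen: float | None
    levels_by_criterion: dict


def decline_over_3gen(rate: float | None, generation_years: float) -> float | None:
    """Fractional decline over three generations: 1 - exp(3 G r), r < 0.

    Growing or stable languages (r >= 0) have decline 0; a missing rate
    stays missing.
    """
    if generation_years <= 0:
        raise ValueError("generation length must be positive")
    if rate is None or (isinstance(rate, float) and np.isnan(rate)):
        return None
    if rate >= 0:
        return 0.0
    return float(1.0 - np.exp(3.0 * generation_years * rate))


def _decline_over(rate: float, years: float) -> float:
    if rate >= 0:
        return 0.0
    return float(1.0 - np.exp(rate * years))


def classify_language(
    area_km2,
    population,
    rate=None,
    thresholds: IucnThresholds | None = None,
    language_id: str = "",
) -> ThreatAssessment:
    """Evaluate one language against the five criteria.

    D1/D2 need only the attributes; A3/B1/C1 are evaluated only when a
    growth rate is available ("continuing decline" for B1 means r < 0).
    The category is the most severe level triggered by any criterion;
    with neither area nor population the language is data deficient.
    """
    thr = thresholds or IucnThresholds()

    def missing(v):
        return v is None or (isinstance(v, float) and np.isnan(v))

    if not missing(area_km2) and area_km2 < 0:
        raise ValueError(f"{language_id}: negative area")
    if not missing(population) and population < 0:
        raise ValueError(f"{language_id}: negative population")

    if missing(area_km2) and missing(population):
        return ThreatAssessment(language_id, "data_deficient", [], None, {})

    has_rate = not missing(rate)
    d3 = decline_over_3gen(rate, thr.generation_years) if has_rate else None

    levels: dict[str, str] = {}

    if has_rate and d3 is not None:
        for lvl in LEVELS:  # strict "exceeded"
            if d3 > thr.a3_decline[lvl] + _TIE_EPS:
                levels["A3"] = lvl
                break

    if not missing(area_km2) and has_rate and rate < 0:
        for lvl in LEVELS:  # strict "smaller than" + continuing decline
            if area_km2 < thr.b1_area_km2[lvl]:
                levels["B1"] = lvl
                break

    if not missing(population) and has_rate:
        for lvl in LEVELS:
            need_frac, window = thr.c1_decline[lvl]
            if (
                population < thr.c1_population[lvl]
                and _decline_over(rate, window) >= need_frac - _TIE_EPS
            ):
                levels["C1"] = lvl
                break

    if not missing(population):
        for lvl in LEVELS:
            if population < thr.d1_population[lvl]:
                levels["D1"] = lvl
                break

    if not missing(area_km2) and area_km2 < thr.d2_area_km2:
        levels["D2"] = "VU"

    if levels:
        category = max(levels.values(), key=lambda c: CATEGORY_ORDER[c])
    else:
        category = "not_threatened"
    criteria = sorted(levels)
    return ThreatAssessment(language_id, category, criteria, d3, levels)


def assess_all(language_table: pd.DataFrame, thresholds: IucnThresholds | None = None):
    """Assess every language in the component table.

    ``language_table`` is indexed by language_id with columns area_km2,
    population and (optionally) rate.  Returns (assessments DataFrame,
    summary dict) where the summary counts languages per category and
    per triggering criterion (a language may trigger several criteria
    but counts once per category via its worst level).
    """
    if language_table.empty:
        raise ValueError("no languages to assess")
    thr = thresholds or IucnThresholds()
    rows = []
    per_criterion = {c: 0 for c in ("A3", "B1", "C1", "D1", "D2")}
    per_category = {c: 0 for c in CATEGORY_ORDER}
    for lang_id, row in language_table.iterrows():
        a = classify_language(
            row.get("area_km2"),
            row.get("population"),
            row.get("rate"),
            thresholds=thr,
            language_id=str(lang_id),
        )
        for c in a.criteria_met:
            per_criterion[c] += 1
        per_category[a.category] += 1
        rows.append(
            {
                "language_id": lang_id,
                "category": a.category,
                "criteria_met": ";".join(a.criteria_met),
                "decline_3gen": np.nan if a.decline_3gen is None else a.decline_3gen,
                "threatened": a.category in LEVELS,
            }
        )
    df = pd.DataFrame(rows).set_index("language_id")
    summary = {
        "n": int(len(df)),
        "n_threatened": int(df["threatened"].sum()),
        "prop_threatened": float(df["threatened"].mean()),
        "per_criterion": per_criterion,
        "per_category": per_category,
    }
    return df, summary


FILTER_CLASSES = (
    "low-both",
    "high-threat-low-extinction",
    "low-threat-high-extinction",
    "high-both",
)


def threat_maps(
    grid,
    membership: pd.DataFrame,
    assessments: pd.DataFrame,
    extinct_cells=None,
    cutoffs=(0.25, 0.25),
) -> pd.DataFrame:
    """Per-cell threatened/extinct richness and extinction-filter classes.

    A threatened language counts in every cell its range overlaps.
    ``extinct_cells`` maps past extinctions to cells (iterable of
    cell_ids, one per extinct language's last-population point).  The two
    proportions are threatened/extant and extinct/extant richness; the
    filter class cuts both at the given thresholds (>= cutoff = "high").
    Cells with no extant languages but recorded extinctions are flagged
    ``undefined_extant``.
    """
    idx = pd.RangeIndex(grid.n_cells, name="cell_id")
    extant = membership.groupby("cell_id")["language_id"].nunique().reindex(idx).fillna(0)

    joined = membership.join(assessments[["threatened"]], on="language_id")
    threatened = (
        joined[joined["threatened"] == True]  # noqa: E712
        .groupby("cell_id")["language_id"]
        .nunique()
        .reindex(idx)
        .fillna(0)
    )
    crit_cols = {}
    if "criteria_met" in assessments:
        for crit in ("A3", "B1", "C1", "D1", "D2"):
            hit = assessments["criteria_met"].str.contains(crit, na=False)
            sub = membership[membership["language_id"].isin(assessments.index[hit])]
            crit_cols[f"threatened_{crit}"] = (
                sub.groupby("cell_id")["language_id"].nunique().reindex(idx).fillna(0)
            )

    extinct = pd.Series(0, index=idx, dtype=float)
    if extinct_cells is not None:
        vc = pd.Series(list(extinct_cells)).value_counts()
        extinct = vc.reindex(idx).fillna(0)

    out = pd.DataFrame(
        {
            "extant_richness": extant.astype(int),
            "threatened_richness": threatened.astype(int),
            "extinct_richness": extinct.astype(int),
        },
        index=idx,
    )
    for k, v in crit_cols.items():
        out[k] = v.astype(int)

    with np.errstate(divide="ignore", invalid="ignore"):
        out["prop_threatened"] = np.where(extant > 0, threatened / extant, np.nan)
        out["prop_extinct"] = np.where(extant > 0, extinct / extant, np.nan)
    out["undefined_extant"] = (extant == 0) & (extinct > 0)

    ct, ce = cutoffs
    hi_t = out["prop_threatened"] >= ct
    hi_e = out["prop_extinct"] >= ce
    cls = np.select(
        [hi_t & hi_e, hi_t & ~hi_e, ~hi_t & hi_e],
        ["high-both", "high-threat-low-extinction", "low-threat-high-extinction"],
        default="low-both",
    )
    out["filter_class"] = np.where(out["prop_threatened"].isna(), "no-data", cls)
    return out
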