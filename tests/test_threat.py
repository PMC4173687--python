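"""IUCN criteria: boundary strictness, nesting, monotonicity, maps."""

import numpy as np
import pandas as pd
import pytest

from lingrisk.grid import GridSpec
from lingrisk.threat import (
    IucnThresholds,
    assess_all,
    classify_language,
    decline_over_3gen,
    threat_maps,
)

THR = IucnThresholds()
BIG_AREA, BIG_POP = 1e6, 1e6


def rate_for_decline(frac, years):
    """Per-year log rate producing exactly `frac` decline over `years`."""
    return np.log(1 - frac) / years


class TestDecline:
    def test_zero_rate(self):
        assert decline_over_3gen(0.0, 25) == 0.0

    def test_exact_thirty_percent(self):
        r = np.log(0.7) / 75  # 30% over three 25-year generations
        assert decline_over_3gen(r, 25) == pytest.approx(0.30, abs=1e-12)

    def test_direct_evaluation(self):
        assert decline_over_3gen(-0.01, 25) == pytest.approx(1 - np.exp(-0.75), abs=1e-12)

    def test_growth_gives_zero(self):
        assert decline_over_3gen(0.05, 25) == 0.0

    def test_missing_rate_stays_missing(self):
        assert decline_over_3gen(None, 25) is None

    def test_bad_generation_length(self):
        with pytest.raises(ValueError):
            decline_over_3gen(-0.01, 0)


class TestClassification:
    def test_small_range_d2(self):
        a = classify_language(19.0, 10_000, None, THR)
        assert a.category == "VU"
        assert a.criteria_met == ["D2"]

    def test_small_population_d1(self):
        assert classify_language(BIG_AREA, 900, None, THR).category == "VU"
        assert classify_language(BIG_AREA, 200, None, THR).category == "EN"
        assert classify_language(BIG_AREA, 40, None, THR).category == "CR"

    def test_a3_strict_exceedance(self):
        vu = classify_language(BIG_AREA, BIG_POP, rate_for_decline(0.35, 75), THR)
        assert vu.category == "VU" and "A3" in vu.criteria_met
        # exactly 30% does not exceed the threshold
        at = classify_language(BIG_AREA, BIG_POP, rate_for_decline(0.30, 75), THR)
        assert "A3" not in at.criteria_met

    def test_b1_requires_continuing_decline(self):
        stable = classify_language(15_000, BIG_POP, 0.001, THR)
        assert "B1" not in stable.criteria_met
        declining = classify_language(15_000, BIG_POP, -0.001, THR)
        assert "B1" in declining.criteria_met and declining.category == "VU"

    def test_c1_needs_population_and_decline_rate(self):
        # VU C1: pop < 10 000 with >= 10% decline over 3 generations
        r10 = rate_for_decline(0.10, 75)
        hit = classify_language(BIG_AREA, 9_000, r10, THR)
        assert "C1" in hit.criteria_met
        slow = classify_language(BIG_AREA, 9_000, r10 * 0.5, THR)
        assert "C1" not in slow.criteria_met

    def test_data_deficient(self):
        assert classify_language(None, None, None, THR).category == "data_deficient"

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_language(-1.0, 100, None, THR)
        with pytest.raises(ValueError):
            classify_language(10.0, -5, None, THR)

    def test_category_is_most_severe_criterion(self):
        # CR via D1 even though D2 only gives VU
        a = classify_language(10.0, 30, None, THR)
        assert a.category == "CR"
        assert set(a.criteria_met) == {"D1", "D2"}


def boundary_cases():
    """(criterion, level, kwargs_fn, should_trigger) triples around each
    threshold: just-below, exactly-at, just-above the stated limit."""
    cases = []
    eps = 1e-9
    for lvl, lim in THR.d1_population.items():
        cases.append(("D1", lvl, dict(area_km2=BIG_AREA, population=lim - 1), True))
        cases.append(("D1", lvl, dict(area_km2=BIG_AREA, population=lim), False))
        cases.append(("D1", lvl, dict(area_km2=BIG_AREA, population=lim + 1), False))
    for lvl, lim in THR.b1_area_km2.items():
        base = dict(population=BIG_POP, rate=-0.001)
        cases.append(("B1", lvl, dict(area_km2=lim - eps, **base), True))
        cases.append(("B1", lvl, dict(area_km2=lim, **base), False))
        cases.append(("B1", lvl, dict(area_km2=lim + eps, **base), False))
    for lvl, lim in THR.a3_decline.items():
        for delta, trig in ((0.01, True), (0.0, False), (-0.01, False)):
            r = rate_for_decline(min(lim + delta, 0.999), 75)
            cases.append(("A3", lvl, dict(area_km2=BIG_AREA, population=BIG_POP, rate=r), trig))
    for lvl, lim in THR.c1_population.items():
        need, window = THR.c1_decline[lvl]
        r = rate_for_decline(need, window)  # exactly "at least" -> triggers
        cases.append(("C1", lvl, dict(area_km2=BIG_AREA, population=lim - 1, rate=r), True))
        cases.append(("C1", lvl, dict(area_km2=BIG_AREA, population=lim, rate=r), False))
    cases.append(("D2", "VU", dict(area_km2=THR.d2_area_km2 - eps, population=BIG_POP), True))
    cases.append(("D2", "VU", dict(area_km2=THR.d2_area_km2, population=BIG_POP), False))
    return cases


class TestTruthTable:
    @pytest.mark.parametrize("criterion,level,kwargs,should", boundary_cases())
    def test_boundary(self, criterion, level, kwargs, should):
        a = classify_language(
            kwargs.get("area_km2"), kwargs.get("population"), kwargs.get("rate"), THR
        )
        if should:
            assert a.levels_by_criterion.get(criterion) == level, (criterion, level, kwargs)
        else:
            assert a.levels_by_criterion.get(criterion) != level, (criterion, level, kwargs)

    def test_cr_nesting(self):
        # a CR language satisfies the EN and VU conditions of its criterion
        a = classify_language(BIG_AREA, 40, None, THR)
        assert a.levels_by_criterion["D1"] == "CR"
        assert 40 < THR.d1_population["EN"] < THR.d1_population["VU"]


class TestMonotonicity:
    def _table(self, rng, n=200):
        return pd.DataFrame(
            {
                "area_km2": 10 ** rng.uniform(0, 6, n),
                "population": 10 ** rng.uniform(0, 6, n),
                "rate": rng.normal(-0.005, 0.02, n),
            },
            index=[f"l{i}" for i in range(n)],
        )

    def test_lowering_thresholds_never_increases_count(self, rng):
        table = self._table(rng)
        _, s_default = assess_all(table, IucnThresholds())
        tight = IucnThresholds(
            d1_population={"VU": 500.0, "EN": 125.0, "CR": 25.0},
            b1_area_km2={"VU": 10_000.0, "EN": 2_500.0, "CR": 50.0},
            d2_area_km2=10.0,
        )
        _, s_tight = assess_all(table, tight)
        assert s_tight["n_threatened"] <= s_default["n_threatened"]

    def test_worse_rate_never_improves_category(self, rng):
        order = {"not_threatened": 0, "VU": 1, "EN": 2, "CR": 3}
        for _ in range(50):
            area = float(10 ** rng.uniform(0, 6))
            pop = float(10 ** rng.uniform(0, 6))
            r = float(rng.normal(-0.01, 0.02))
            a = classify_language(area, pop, r, THR)
            b = classify_language(area, pop, r - 0.01, THR)
            assert order[b.category] >= order[a.category]


class TestAssessAll:
    def test_all_safe(self):
        table = pd.DataFrame(
            {"area_km2": [1e6] * 5, "population": [1e6] * 5, "rate": [0.01] * 5},
            index=[f"l{i}" for i in range(5)],
        )
        _, summary = assess_all(table)
        assert summary["n_threatened"] == 0

    def test_constructed_small_populations_counted(self):
        table = pd.DataFrame(
            {"area_km2": [1e6] * 4, "population": [500, 900, 1e6, 2e6]},
            index=list("abcd"),
        )
        df, summary = assess_all(table)
        assert summary["n_threatened"] == 2
        assert summary["per_criterion"]["D1"] == 2

    def test_truth_table_fixture(self):
        # six languages spanning the five criteria
        table = pd.DataFrame(
            {
                "area_km2": [10.0, 1e6, 1e6, 4000.0, 1e6, 1e6],
                "population": [1e6, 700.0, 1e6, 1e6, 2000.0, 1e6],
                "rate": [np.nan, np.nan, -0.02, -0.001, np.log(0.8) / 50, 0.01],
            },
            index=["d2", "d1", "a3", "b1", "c1", "safe"],
        )
        df, _ = assess_all(table)
        assert df.loc["d2", "category"] == "VU" and df.loc["d2", "criteria_met"] == "D2"
        assert df.loc["d1", "category"] == "VU" and "D1" in df.loc["d1", "criteria_met"]
        assert "A3" in df.loc["a3", "criteria_met"]  # 78% decline over 3 gens -> EN
        assert df.loc["a3", "category"] == "EN"
        assert "B1" in df.loc["b1", "criteria_met"] and df.loc["b1", "category"] == "EN"
        assert "C1" in df.loc["c1", "criteria_met"]
        assert df.loc["safe", "category"] == "not_threatened"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            assess_all(pd.DataFrame())


class TestThreatMaps:
    grid = GridSpec(cell_size=100.0, x0=0.0, y0=0.0, n_cols=2, n_rows=1)

    def _inputs(self):
        membership = pd.DataFrame(
            {
                "cell_id": [0, 0, 0, 0, 1],
                "language_id": ["a", "b", "c", "d", "a"],
            }
        )
        assessments = pd.DataFrame(
            {
                "threatened": [True, True, False, False],
                "criteria_met": ["D1", "D2", "", ""],
            },
            index=pd.Index(list("abcd"), name="language_id"),
        )
        return membership, assessments

    def test_proportions_and_filter_class(self):
        membership, assessments = self._inputs()
        cells = threat_maps(self.grid, membership, assessments, extinct_cells=[])
        assert cells.loc[0, "extant_richness"] == 4
        assert cells.loc[0, "threatened_richness"] == 2
        assert cells.loc[0, "prop_threatened"] == pytest.approx(0.5)
        assert cells.loc[0, "prop_extinct"] == 0.0
        assert cells.loc[0, "filter_class"] == "high-threat-low-extinction"

    def test_low_both_class(self):
        membership = pd.DataFrame({"cell_id": [0], "language_id": ["c"]})
        assessments = pd.DataFrame(
            {"threatened": [False], "criteria_met": [""]},
            index=pd.Index(["c"], name="language_id"),
        )
        cells = threat_maps(self.grid, membership, assessments)
        assert cells.loc[0, "filter_class"] == "low-both"

    def test_extinct_without_extant_flagged(self):
        membership, assessments = self._inputs()
        cells = threat_maps(self.grid, membership, assessments, extinct_cells=[1, 1])
        # cell 1 has one extant language; move extinctions to an empty cell
        membership2 = membership[membership["cell_id"] == 0]
        cells = threat_maps(self.grid, membership2, assessments, extinct_cells=[1])
        assert bool(cells.loc[1, "undefined_extant"])

    def test_counts_match_brute_force_recount(self, tiny_world, tiny_components):
        from shapely import union_all

        from lingrisk.components import project_geometry
        from lingrisk.grid import assign_languages

        assessments, _ = assess_all(tiny_components)
        geoms = {
            r.language_id: project_geometry(union_all(r.polygons)) for r in tiny_world.records
        }
        membership = assign_languages(tiny_world.grid, geoms)
        cells = threat_maps(tiny_world.grid, membership, assessments)
        threatened_ids = set(assessments.index[assessments["threatened"]])
        for cid in membership["cell_id"].unique():
            langs = set(membership.loc[membership["cell_id"] == cid, "language_id"])
            assert cells.loc[cid, "extant_richness"] == len(langs)
            assert cells.loc[cid, "threatened_richness"] == len(langs & threatened_ids)
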