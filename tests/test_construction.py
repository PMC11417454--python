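"""Matching/imputation protocol: elementary operations and the full build."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from antioxdb.construction import (
    MolecularWeightEntry,
    Recipe,
    SourceDatabase,
    SourceRecord,
    ZeroRule,
    assign_logical_zeros,
    average_varieties,
    build_database,
    deduplicate_foods,
    default_zero_rules,
    glycoside_to_aglycone,
    match_direct,
    moisture_convert,
    order_recipes,
    recipe_compose,
    substitute_similar,
)
from antioxdb.taxonomy import (
    MG,
    UG,
    CompositionTable,
    FoodItem,
    Provenance,
    load_taxonomy,
)

# ---------------------------------------------------------------------------
# a 6-food x 3-component fixture small enough to enumerate by hand

MINI_TAXONOMY = {
    "components": [
        {"component_id": "vitamin_c", "unit": MG, "antioxidant_class": "vitamin_C"},
        {"component_id": "beta_carotene", "unit": UG, "antioxidant_class": "carotenoids"},
        {
            "component_id": "quercetin",
            "unit": MG,
            "antioxidant_class": "flavonoids",
            "flavonoid_subclass": "flavonols",
        },
    ]
}


def _food(fid, name, group, form="raw", water=None, **attrs):
    return FoodItem(
        food_id=fid, names=(name,), food_group=group, form=form,
        water_content=water, attributes=attrs,
    )


@pytest.fixture(scope="module")
def mini_registry():
    return load_taxonomy(MINI_TAXONOMY)


@pytest.fixture(scope="module")
def mini_world(mini_registry):
    foods = [
        _food("apple", "Apple", "Fruits", water=85.0,
              genus="malus", family="rosaceae", plant_part="fruit", color="red"),
        _food("apple_dried", "Apple", "Fruits", form="dried", water=10.0,
              genus="malus", family="rosaceae", plant_part="fruit", color="red"),
        _food("beef", "Beef", "Meats and their products", water=60.0),
        _food("pear", "Pear", "Fruits", water=84.0,
              genus="pyrus", family="rosaceae", plant_part="fruit", color="green"),
        _food("stew", "Stew", "Prepared dishes", form="prepared"),
        _food("kale", "Kale", "Vegetables", water=90.0),
    ]
    sources = {
        "KMFDS": SourceDatabase("KMFDS", [
            SourceRecord("Apple", "raw", "vitamin_c", 10.0, water_content=85.0),
            # two varieties -> averaged to 50
            SourceRecord("Apple", "raw", "beta_carotene", 45.0, water_content=85.0),
            SourceRecord("Apple", "raw", "beta_carotene", 55.0, water_content=85.0),
            SourceRecord("Beef", "raw", "vitamin_c", 2.0, water_content=60.0),
        ]),
        # lower-priority source disagreeing on apple vitamin C: must lose
        "JMEXT": SourceDatabase("JMEXT", [
            SourceRecord("Apple", "raw", "vitamin_c", 99.0, water_content=85.0),
        ]),
        "USDA_flavonoid": SourceDatabase("USDA_flavonoid", [
            SourceRecord("Apple", "raw", "quercetin", 4.0, water_content=85.0),
        ]),
        # lower-priority flavonoid source disagreeing on apple quercetin
        "PhenolExplorer": SourceDatabase("PhenolExplorer", [
            SourceRecord("Apple", "raw", "quercetin", 5.0, water_content=85.0),
        ]),
    }
    recipes = [Recipe("stew", (("apple", 100.0), ("beef", 100.0)))]
    table, ledger = build_database(
        foods, sources, recipes=recipes,
        zero_rules=default_zero_rules(mini_registry), registry=mini_registry,
    )
    return foods, table, ledger


#: hand-enumerated expectation: (food, component) -> (method, value, source)
MINI_EXPECTED = {
    ("apple", "vitamin_c"): ("source_direct", 10.0, "KMFDS"),
    ("apple", "beta_carotene"): ("variety_average", 50.0, "KMFDS"),
    ("apple", "quercetin"): ("source_direct", 4.0, "USDA_flavonoid"),
    # dried apple: dry-matter factor (100-10)/(100-85) = 6
    ("apple_dried", "vitamin_c"): ("moisture_conversion", 60.0, "KMFDS"),
    ("apple_dried", "beta_carotene"): ("moisture_conversion", 300.0, "KMFDS"),
    ("apple_dried", "quercetin"): ("moisture_conversion", 24.0, "USDA_flavonoid"),
    ("beef", "vitamin_c"): ("source_direct", 2.0, "KMFDS"),
    ("beef", "beta_carotene"): ("logical_zero", 0.0, None),
    ("beef", "quercetin"): ("logical_zero", 0.0, None),
    # pear shares family/plant part with both apple forms; tie broken by id
    ("pear", "vitamin_c"): ("similar_food", 10.0, None),
    ("pear", "beta_carotene"): ("similar_food", 50.0, None),
    ("pear", "quercetin"): ("similar_food", 4.0, None),
    # stew: vitamin C from the recipe; beef's carotene/quercetin cells are
    # still missing when recipes run (zeros come last), so those propagate
    ("stew", "vitamin_c"): ("recipe", (100 * 10.0 + 100 * 2.0) / 200, None),
    ("stew", "beta_carotene"): ("missing", None, None),
    ("stew", "quercetin"): ("missing", None, None),
    ("kale", "vitamin_c"): ("missing", None, None),
    ("kale", "beta_carotene"): ("missing", None, None),
    ("kale", "quercetin"): ("missing", None, None),
}


class TestBuildDatabase:
    def test_ledger_matches_hand_enumeration(self, mini_world):
        _, table, ledger = mini_world
        assert len(ledger) == len(MINI_EXPECTED)
        for row in ledger.itertuples(index=False):
            method, value, source = MINI_EXPECTED[(row.food_id, row.component_id)]
            assert row.method == method, (row.food_id, row.component_id)
            cell = table.get_cell(row.food_id, row.component_id)
            if value is None:
                assert cell.value is None
            else:
                assert cell.value == pytest.approx(value)
            assert cell.source_db == source

    def test_build_is_deterministic(self, mini_world, mini_registry):
        foods, _, ledger = mini_world
        sources = {
            "KMFDS": SourceDatabase("KMFDS", [
                SourceRecord("Apple", "raw", "vitamin_c", 10.0, water_content=85.0),
                SourceRecord("Apple", "raw", "beta_carotene", 45.0, water_content=85.0),
                SourceRecord("Apple", "raw", "beta_carotene", 55.0, water_content=85.0),
                SourceRecord("Beef", "raw", "vitamin_c", 2.0, water_content=60.0),
            ]),
            "JMEXT": SourceDatabase("JMEXT", [
                SourceRecord("Apple", "raw", "vitamin_c", 99.0, water_content=85.0),
            ]),
            "USDA_flavonoid": SourceDatabase("USDA_flavonoid", [
                SourceRecord("Apple", "raw", "quercetin", 4.0, water_content=85.0),
            ]),
            "PhenolExplorer": SourceDatabase("PhenolExplorer", [
                SourceRecord("Apple", "raw", "quercetin", 5.0, water_content=85.0),
            ]),
        }
        recipes = [Recipe("stew", (("apple", 100.0), ("beef", 100.0)))]
        _, again = build_database(
            foods, sources, recipes=recipes,
            zero_rules=default_zero_rules(mini_registry), registry=mini_registry,
        )
        pd.testing.assert_frame_equal(ledger, again)

    def test_provenance_counts_conserve_food_total(self, tiny_world):
        ledger = tiny_world["ledger"]
        n_foods = len(tiny_world["table"].food_ids)
        per_component = ledger.groupby("component_id")["method"].count()
        assert (per_component == n_foods).all()

    def test_adding_a_source_never_decreases_coverage(self, mini_world, mini_registry):
        foods, full_table, _ = mini_world
        sources_small = {
            "KMFDS": SourceDatabase("KMFDS", [
                SourceRecord("Apple", "raw", "vitamin_c", 10.0, water_content=85.0),
            ]),
        }
        small, _ = build_database(
            foods, sources_small, recipes=[Recipe("stew", (("apple", 100.0), ("beef", 100.0)))],
            zero_rules=default_zero_rules(mini_registry), registry=mini_registry,
        )
        for cid in mini_registry.component_ids:
            assert full_table.values[cid].notna().sum() >= small.values[cid].notna().sum()

    def test_adding_a_zero_rule_never_decreases_coverage(self, mini_world, mini_registry):
        foods, with_rules, _ = mini_world
        sources = {
            "KMFDS": SourceDatabase("KMFDS", [
                SourceRecord("Apple", "raw", "vitamin_c", 10.0, water_content=85.0),
                SourceRecord("Apple", "raw", "beta_carotene", 45.0, water_content=85.0),
                SourceRecord("Apple", "raw", "beta_carotene", 55.0, water_content=85.0),
                SourceRecord("Beef", "raw", "vitamin_c", 2.0, water_content=60.0),
            ]),
            "USDA_flavonoid": SourceDatabase("USDA_flavonoid", [
                SourceRecord("Apple", "raw", "quercetin", 4.0, water_content=85.0),
            ]),
        }
        without, _ = build_database(
            foods, sources, recipes=[Recipe("stew", (("apple", 100.0), ("beef", 100.0)))],
            zero_rules=[], registry=mini_registry,
        )
        for cid in mini_registry.component_ids:
            assert with_rules.values[cid].notna().sum() >= without.values[cid].notna().sum()

    def test_cyclic_recipes_rejected(self):
        recipes = [
            Recipe("dish_a", (("dish_b", 50.0),)),
            Recipe("dish_b", (("dish_a", 50.0),)),
        ]
        with pytest.raises(ValueError, match="cyclic"):
            order_recipes(recipes)


class TestDeduplicateFoods:
    def test_475_candidates_with_63_duplicates_yield_412(self):
        unique = [
            _food(f"f{i:03d}", f"food {i:03d}", "Vegetables") for i in range(412)
        ]
        rng = np.random.default_rng(0)
        dup_idx = rng.choice(412, size=63, replace=False)
        candidates = list(unique)
        for i in dup_idx:
            candidates.append(
                _food(f"dup{i}", f"FOOD  {i:03d}", "Vegetables")  # case/space variant
            )
        assert len(candidates) == 475
        out = deduplicate_foods(candidates)
        assert len(out) == 412
        assert [f.food_id for f in out] == [f.food_id for f in unique]

    def test_no_duplicates_is_identity(self):
        foods = [_food("a", "A", "Fruits"), _food("b", "B", "Fruits")]
        assert deduplicate_foods(foods) == foods

    def test_same_name_different_form_both_kept(self):
        foods = [
            _food("a_raw", "Apple", "Fruits", form="raw"),
            _food("a_dry", "Apple", "Fruits", form="dried"),
        ]
        assert len(deduplicate_foods(foods)) == 2


class TestMatchDirect:
    def test_highest_priority_source_wins(self, mini_registry):
        food = _food("apple", "Apple", "Fruits", water=85.0)
        rank1 = SourceDatabase("S1", [SourceRecord("Apple", "raw", "vitamin_c", 11.0)])
        rank3 = SourceDatabase("S3", [SourceRecord("Apple", "raw", "vitamin_c", 77.0)])
        cell = match_direct(food, "vitamin_c", [rank1, rank3])
        assert cell.value == 11.0
        assert cell.source_db == "S1"
        assert cell.provenance == Provenance.SOURCE_DIRECT.value

    def test_absent_food_gives_no_match(self):
        food = _food("kale", "Kale", "Vegetables")
        src = SourceDatabase("S1", [SourceRecord("Apple", "raw", "vitamin_c", 11.0)])
        assert match_direct(food, "vitamin_c", [src]) is None

    def test_different_form_only_gives_no_match(self):
        food = _food("a", "Apple", "Fruits", form="dried", water=10.0)
        src = SourceDatabase("S1", [SourceRecord("Apple", "raw", "vitamin_c", 11.0)])
        assert match_direct(food, "vitamin_c", [src]) is None


class TestAverageVarieties:
    @pytest.mark.parametrize(
        "values, expected", [([10, 20, 30], 20.0), ([7], 7.0), ([0, 0], 0.0)]
    )
    def test_examples(self, values, expected):
        assert average_varieties(values) == pytest.approx(expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_varieties([])


class TestMoistureConvert:
    def test_drying_concentrates(self):
        assert moisture_convert(5.0, 91.0, 10.0) == pytest.approx(50.0)

    def test_equal_water_is_identity(self):
        assert moisture_convert(7.0, 50.0, 50.0) == pytest.approx(7.0)

    @pytest.mark.parametrize("bad", [100.0, 150.0, -1.0])
    def test_water_bounds_enforced(self, bad):
        with pytest.raises(ValueError, match="water content"):
            moisture_convert(1.0, bad, 10.0)

    @given(
        st.floats(min_value=0, max_value=1e4),
        st.floats(min_value=0, max_value=99.0),
        st.floats(min_value=0, max_value=99.0),
    )
    def test_round_trip_recovers_value(self, value, w1, w2):
        there = moisture_convert(value, w1, w2)
        assert moisture_convert(there, w2, w1) == pytest.approx(value, rel=1e-9, abs=1e-12)


class TestGlycosideToAglycone:
    def test_equal_weights_is_identity(self):
        entry = MolecularWeightEntry("x", "quercetin", 300.0, 300.0)
        assert glycoside_to_aglycone(10.0, entry) == pytest.approx(10.0)

    def test_quercetin_glucoside_example(self):
        entry = MolecularWeightEntry(
            "quercetin-3-O-glucoside", "quercetin", 464.38, 302.24
        )
        assert glycoside_to_aglycone(10.0, entry) == pytest.approx(6.5085, abs=1e-4)

    def test_zero_stays_zero(self):
        entry = MolecularWeightEntry("x", "quercetin", 464.38, 302.24)
        assert glycoside_to_aglycone(0.0, entry) == 0.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MolecularWeightEntry("x", "q", -1.0, 300.0)
        with pytest.raises(ValueError, match="heavier"):
            MolecularWeightEntry("x", "q", 300.0, 464.0)


class TestRecipeCompose:
    @pytest.fixture()
    def two_food_table(self, mini_registry):
        foods = [_food("a", "A", "Fruits"), _food("b", "B", "Fruits")]
        table = CompositionTable(foods, mini_registry)
        table.set_cell("a", "vitamin_c", 10.0, Provenance.SOURCE_DIRECT)
        table.set_cell("b", "vitamin_c", 30.0, Provenance.SOURCE_DIRECT)
        return table

    def test_equal_weights_give_midpoint(self, two_food_table):
        recipe = Recipe("dish", (("a", 50.0), ("b", 50.0)))
        assert recipe_compose(recipe, two_food_table, "vitamin_c") == pytest.approx(20.0)

    def test_single_ingredient_is_identity(self, two_food_table):
        recipe = Recipe("dish", (("a", 120.0),))
        assert recipe_compose(recipe, two_food_table, "vitamin_c") == pytest.approx(10.0)

    def test_missing_ingredient_propagates_missing(self, two_food_table):
        recipe = Recipe("dish", (("a", 50.0), ("b", 50.0)))
        assert recipe_compose(recipe, two_food_table, "quercetin") is None

    def test_recipe_validation(self):
        with pytest.raises(ValueError, match="at least one ingredient"):
            Recipe("dish", ())
        with pytest.raises(ValueError, match="non-positive"):
            Recipe("dish", (("a", 0.0),))


class TestSubstituteSimilar:
    @pytest.fixture()
    def donor_table(self, mini_registry):
        foods = [
            _food("target", "T", "Fruits", genus="g1", family="f1",
                  plant_part="fruit", color="red"),
            _food("genus_donor", "G", "Fruits", genus="g1", family="f9"),
            _food("color_donor", "C", "Fruits", genus="g9", color="red"),
            _food("twin_a", "TA", "Fruits", genus="g1", family="f1"),
            _food("twin_b", "TB", "Fruits", genus="g1", family="f1"),
        ]
        table = CompositionTable(foods, mini_registry)
        for fid, v in [("genus_donor", 1.0), ("color_donor", 2.0),
                       ("twin_a", 3.0), ("twin_b", 4.0)]:
            table.set_cell(fid, "vitamin_c", v, Provenance.SOURCE_DIRECT)
        return foods, table

    def test_genus_beats_color(self, donor_table):
        foods, table = donor_table
        target = foods[0]
        donors = [foods[1], foods[2]]
        cell = substitute_similar(target, donors, table, "vitamin_c")
        assert cell.value == 1.0
        assert cell.provenance == Provenance.SIMILAR_FOOD.value

    def test_no_shared_attribute_gives_no_match(self, donor_table, mini_registry):
        foods, table = donor_table
        loner = _food("loner", "L", "Fruits", genus="zz")
        assert substitute_similar(loner, foods[1:3], table, "vitamin_c") is None

    def test_tie_broken_by_lexicographic_food_id(self, donor_table):
        foods, table = donor_table
        target = foods[0]
        cell = substitute_similar(target, [foods[4], foods[3]], table, "vitamin_c")
        assert cell.value == 3.0  # twin_a < twin_b


class TestAssignLogicalZeros:
    def test_animal_group_missing_cell_becomes_zero(self, mini_registry):
        foods = [_food("beef", "Beef", "Meats and their products")]
        table = CompositionTable(foods, mini_registry)
        assign_logical_zeros(table, default_zero_rules(mini_registry))
        cell = table.get_cell("beef", "quercetin")
        assert cell.value == 0.0
        assert cell.provenance == Provenance.LOGICAL_ZERO.value

    def test_unruled_group_stays_missing(self, mini_registry):
        foods = [_food("spinach", "Spinach", "Vegetables")]
        table = CompositionTable(foods, mini_registry)
        assign_logical_zeros(table, default_zero_rules(mini_registry))
        assert table.get_cell("spinach", "quercetin").value is None

    def test_existing_data_never_overwritten(self, mini_registry):
        foods = [_food("beef", "Beef", "Meats and their products")]
        table = CompositionTable(foods, mini_registry)
        table.set_cell("beef", "quercetin", 0.0, Provenance.SOURCE_DIRECT, "KMFDS")
        assign_logical_zeros(table, default_zero_rules(mini_registry))
        cell = table.get_cell("beef", "quercetin")
        assert cell.provenance == Provenance.SOURCE_DIRECT.value
        assert cell.source_db == "KMFDS"

    def test_unknown_component_in_rule_rejected(self, mini_registry):
        foods = [_food("beef", "Beef", "Meats and their products")]
        table = CompositionTable(foods, mini_registry)
        rule = ZeroRule(frozenset({"nonexistent"}), food_groups=frozenset({"Meats and their products"}))
        with pytest.raises(ValueError, match="unknown component"):
            assign_logical_zeros(table, [rule])

    def test_rule_requires_groups_and_components(self):
        with pytest.raises(ValueError):
            ZeroRule(frozenset(), food_groups=frozenset({"Eggs"}))
        with pytest.raises(ValueError):
            ZeroRule(frozenset({"quercetin"}))
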