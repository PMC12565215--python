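import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycograze import survey
from mycograze.survey import (
    SurveyDesign,
    ValidationError,
    aggregate_counts,
    normalize_category,
    read_environment,
    read_observations,
    read_traits,
    venn_partition,
    wide_to_long,
    write_environment,
    write_observations,
    write_traits,
)


class TestDesign:
    def test_default_layout_consistency(self):
        d = SurveyDesign()
        assert d.subquadrats_per_quadrat * d.subquadrat_area_m2 == d.quadrat_area_m2
        assert d.units_per_plot() == 12
        assert d.units_per_plot(level="quadrat") == 3

    def test_unit_keys_unique_and_resolvable(self):
        d = SurveyDesign()
        keys = d.unit_keys()
        assert len(keys) == len(set(keys)) == 3 * 2 * 12
        f, t, q, s = survey.parse_unit_key(keys[0])
        assert f in d.forest_types and t in d.treatments and s is not None

    def test_inconsistent_areas_rejected(self):
        with pytest.raises(ValidationError):
            SurveyDesign(subquadrats_per_quadrat=3)


class TestIO:
    def test_round_trip_observations(self, toy_obs, tmp_path):
        p = tmp_path / "obs.csv"
        write_observations(toy_obs, p)
        back = read_observations(p)
        pd.testing.assert_frame_equal(back, toy_obs)

    def test_duplicate_pair_named_in_error(self, toy_obs, tmp_path):
        bad = pd.concat([toy_obs, toy_obs.iloc[[0]]], ignore_index=True)
        p = tmp_path / "obs.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="f1/ungrazed/q1/s1.*'A'"):
            read_observations(p)

    def test_nonpositive_individual_number_rejected(self, toy_obs, tmp_path):
        bad = toy_obs.copy()
        bad.loc[0, "individual_number"] = 0
        p = tmp_path / "obs.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="individual_number"):
            read_observations(p)

    def test_trait_normalization_and_round_trip(self, toy_traits, tmp_path):
        p = tmp_path / "traits.csv"
        write_traits(toy_traits, p)
        back = read_traits(p)
        assert back.loc[0, "trophic"] == "wood saprotroph"
        assert back.loc[1, "sporocarp"] == "polyporoid"
        assert back.loc[0, "geographic"] == "cosmopolitan"
        # normalization is idempotent
        pd.testing.assert_frame_equal(survey.validate_traits(back), back)

    def test_unknown_category_named_in_error(self, toy_traits):
        bad = toy_traits.copy()
        bad.loc[0, "trophic"] = "rock saprotroph"
        with pytest.raises(ValidationError, match="rock saprotroph"):
            survey.validate_traits(bad)

    def test_environment_round_trip_and_range(self, tmp_path):
        env = pd.DataFrame(
            {
                "unit": ["f1/grazed/q1/s1"],
                "lay1_cm": [2.0],
                "lay2_cm": [1.0],
                "lay3_cm": [0.5],
                "remains_level": [3],
            }
        )
        p = tmp_path / "env.csv"
        write_environment(env, p)
        back = read_environment(p)
        assert back.loc[0, "lays_cm"] == pytest.approx(3.5)
        env.loc[0, "remains_level"] = 5
        env.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="remains_level"):
            read_environment(p)

    def test_wide_converter_drops_zeros(self):
        wide = pd.DataFrame(
            {"unit": ["f1/grazed/q1/s1", "f1/grazed/q1/s2"], "A": [2, 0], "B": [1, 3]}
        )
        long = wide_to_long(wide)
        assert len(long) == 3
        assert set(long["species"]) == {"A", "B"}


class TestNormalization:
    @pytest.mark.parametrize(
        "axis, raw, expected",
        [
            ("trophic", "Wood saprotrophs", "wood saprotroph"),
            ("trophic", "ALGA SYMBIONTS", "alga symbiont"),
            ("sporocarp", "Slime molds", "slime mold"),
            ("sporocarp", "Ascomycetes", "ascomycete"),
            ("geographic", "east asian", "East Asian"),
            ("attachment", "Wood-Inhabiting", "wood-inhabiting"),
        ],
    )
    def test_case_and_plural_insensitive(self, axis, raw, expected):
        assert normalize_category(axis, raw) == expected


class TestAggregation:
    def test_single_unit(self):
        d = SurveyDesign(forest_types=("f1",))
        obs = pd.DataFrame(
            {"unit": ["f1/grazed/q1/s1"], "species": ["A"], "individual_number": [3]}
        )
        c = aggregate_counts(obs, d, forest="f1", treatment="grazed")
        assert c.N == 3 and c.S == 1 and c.occupancy["A"] == 1 and c.Q == 12

    def test_two_units_hand_enumeration(self):
        d = SurveyDesign(forest_types=("f1",))
        obs = pd.DataFrame(
            {
                "unit": ["f1/grazed/q1/s1", "f1/grazed/q1/s2", "f1/grazed/q1/s2"],
                "species": ["A", "A", "B"],
                "individual_number": [2, 1, 1],
            }
        )
        c = aggregate_counts(obs, d, forest="f1", treatment="grazed")
        assert c.N == 4 and c.S == 2
        assert c.occupancy == {"A": 2, "B": 1}
        assert c.pooled == {"A": 3, "B": 1}

    def test_disjoint_units_add_richness(self):
        d = SurveyDesign(forest_types=("f1",))
        obs = pd.DataFrame(
            {
                "unit": ["f1/grazed/q1/s1", "f1/grazed/q1/s2"],
                "species": ["A", "B"],
                "individual_number": [1, 1],
            }
        )
        c = aggregate_counts(obs, d, forest="f1", treatment="grazed")
        assert c.S == sum(len(v) for v in c.per_unit.values())

    def test_quadrat_level_pools_subquadrats(self):
        d = SurveyDesign(forest_types=("f1",))
        obs = pd.DataFrame(
            {
                "unit": ["f1/grazed/q1/s1", "f1/grazed/q1/s2"],
                "species": ["A", "A"],
                "individual_number": [2, 3],
            }
        )
        c = aggregate_counts(obs, d, forest="f1", treatment="grazed", level="quadrat")
        assert c.pooled == {"A": 5}
        assert c.occupancy == {"A": 1}
        assert c.Q == 3

    def test_count_conservation_across_strata(self, sim_default):
        config, obs, _, _, _ = sim_default
        design = config.design
        total = aggregate_counts(obs, design).N
        by_stratum = sum(
            aggregate_counts(obs, design, forest=f, treatment=t).N
            for f in design.forest_types
            for t in design.treatments
        )
        assert total == by_stratum

    def test_occupancy_bounds(self, sim_default):
        config, obs, _, _, _ = sim_default
        c = aggregate_counts(obs, config.design, treatment="grazed")
        for sp, q in c.occupancy.items():
            assert 1 <= q <= c.Q
            assert c.pooled[sp] >= q  # at least one individual per occupied unit

    def test_foreign_unit_rejected(self):
        d = SurveyDesign(forest_types=("f1",))
        obs = pd.DataFrame(
            {"unit": ["f9/grazed/q1/s1"], "species": ["A"], "individual_number": [1]}
        )
        with pytest.raises(ValidationError, match="f9"):
            aggregate_counts(obs, d, treatment="grazed")


class TestVenn:
    def test_identical_and_disjoint_sets(self):
        same = venn_partition({"a", "b"}, {"a", "b"})
        assert same["unique_grazed"] == same["unique_ungrazed"] == 0
        assert same["total"] == same["shared"] == 2
        disj = venn_partition({"a"}, {"b"})
        assert disj["shared"] == 0 and disj["total"] == 2

    @given(
        st.sets(st.integers(0, 50)),
        st.sets(st.integers(0, 50)),
    )
    @settings(max_examples=200, deadline=None)
    def test_inclusion_exclusion(self, a, b):
        v = venn_partition(a, b)
        assert v["total"] == v["shared"] + v["unique_grazed"] + v["unique_ungrazed"]
        assert v["total"] == len(a | b)
        assert v["n_grazed"] == v["shared"] + v["unique_grazed"] == len(a)
        assert v["n_ungrazed"] == len(b)
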