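"""Life-table engine: floor rule, survivorship, scaling, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import deer_cba as d
from deer_cba.demography import N_AGES, SEXES, cohort_frame, schedule_frame

from conftest import random_schedule


def flat(rate, patches=None):
    """Build per-sex hunting rates: flat, with optional {age: rate} patches."""
    r = np.full(N_AGES, rate, dtype=float)
    for age, v in (patches or {}).items():
        r[age] = v
    return r


class TestEffectiveMortality:
    @pytest.mark.parametrize(
        "hunting, baseline, expected",
        [(0.35, 0.02, 0.35), (0.00, 0.02, 0.02), (0.02, 0.02, 0.02)],
    )
    def test_floor_rule(self, hunting, baseline, expected):
        sch = d.effective_mortality(
            {"female": flat(hunting), "male": flat(hunting)}, baseline=baseline
        )
        assert sch.female[3] == expected
        assert sch.male[3] == expected

    def test_floor_provenance_recorded(self):
        sch = d.effective_mortality(
            {"female": flat(0.0), "male": flat(0.5)}, baseline=0.02
        )
        assert set(sch.provenance["female"]) == {"floor"}
        assert set(sch.provenance["male"]) == {"stated"}

    def test_out_of_range_rate_names_sex_and_age(self):
        with pytest.raises(ValueError, match="male.*ages \\[4\\]"):
            d.effective_mortality(
                {"female": flat(0.1), "male": flat(0.1, {4: 1.2})}
            )

    def test_bad_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            d.effective_mortality(
                {"female": flat(0.1), "male": flat(0.1)}, baseline=1.0
            )


class TestSurvivorship:
    def test_starts_at_one_and_never_increases(self, schedules):
        for sch in schedules.values():
            lx = d.survivorship(sch)
            for sex in SEXES:
                curve = lx.curve(sex)
                assert curve[0] == 1.0
                assert (np.diff(curve) <= 1e-15).all()

    def test_trophy_males_reach_maturity_at_56_percent(self, schedules):
        # 0.65 * 0.98^7: heavy calf harvest, then only the collision floor
        l8 = d.survivorship(schedules["2"]).male[8]
        assert l8 == pytest.approx(0.65 * 0.98**7, rel=1e-12)
        assert round(l8, 2) == 0.56

    def test_uniform_male_rate_gives_6_1_percent(self, schedules):
        l8 = d.survivorship(schedules["4A"]).male[8]
        assert round(100 * l8, 1) == 6.1


class TestStationaryTable:
    def test_spring_census_equals_target(self, tables):
        for t in tables.values():
            assert t.n_spring == pytest.approx(1000.0, abs=1e-9)

    def test_trophy_anchor_cells(self, tables):
        pop = tables["2"].population
        assert round(pop["male"][8:].sum()) == 130  # mature stags
        assert round(pop["female"][2:].sum()) == 299  # adult females

    def test_doubling_the_target_doubles_every_cell(self, schedules):
        sch = schedules["4B"]
        t1 = d.stationary_table(sch, 1000.0)
        t2 = d.stationary_table(sch, 2000.0)
        for sex in SEXES:
            np.testing.assert_allclose(
                t2.population[sex], 2 * t1.population[sex], rtol=1e-12
            )
            np.testing.assert_allclose(
                t2.harvest[sex], 2 * t1.harvest[sex], rtol=1e-12
            )

    def test_all_lethal_schedule_is_degenerate(self):
        with pytest.raises(d.DegenerateScheduleError):
            d.stationary_table(
                d.effective_mortality({"female": flat(1.0), "male": flat(1.0)})
            )

    def test_nonpositive_target_rejected(self, schedules):
        with pytest.raises(ValueError, match="spring_target"):
            d.stationary_table(schedules["1"], 0.0)


class TestMortalityPartition:
    def test_harvest_plus_collisions_equals_deaths(self, tables):
        for t in tables.values():
            for sex in SEXES:
                np.testing.assert_allclose(
                    t.harvest[sex] + t.collisions[sex], t.deaths[sex],
                    rtol=0, atol=1e-9,
                )

    def test_floor_only_class_has_zero_harvest(self, tables):
        # trophy males aged 1-7 die only to collisions
        assert tables["2"].harvest["male"][1:8] == pytest.approx(0.0)
        assert (tables["2"].collisions["male"][1:8] > 0).all()

    def test_trophy_mature_stag_harvest(self, tables):
        h = tables["2"].harvest["male"][8:].sum()
        assert h == pytest.approx(62.6, abs=0.5)

    def test_free_harvest_calf_cull(self, tables):
        t = tables["1"]
        assert round(t.population["female"][0]) == 206
        assert round(t.harvest["female"][0]) in (68, 69)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_recruits_equal_deaths(self, seed):
        sch = random_schedule(np.random.default_rng(seed))
        try:
            table = d.stationary_table(sch, 1000.0)
        except d.DegenerateScheduleError:
            return
        for sex in SEXES:
            assert table.deaths[sex].sum() == pytest.approx(
                table.population[sex][0], abs=1e-9 * table.population[sex][0]
            )


class TestSeptemberPopulation:
    def test_no_females_means_no_calves(self, schedules):
        t = d.stationary_table(schedules["1"], 1000.0)
        for arr in (t.population, t.deaths, t.harvest, t.collisions):
            arr["female"] = np.zeros_like(arr["female"])
        assert d.september_population(t) == t.n_spring

    def test_trophy_preseason_census(self, tables):
        assert d.september_population(tables["2"]) == pytest.approx(1288, abs=1)

    def test_matches_direct_fecundity_evaluation(self, tables):
        fec = d.FecundityParameters()
        for t in tables.values():
            born = 0.57 * t.population["female"][1] + 0.82 * t.population[
                "female"
            ][2:].sum()
            assert d.september_population(t, fec) == pytest.approx(
                t.n_spring + born, rel=1e-12
            )


class TestProjectForward:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_converges_to_closed_form(self, seed):
        sch = random_schedule(np.random.default_rng(seed))
        lx = d.survivorship(sch)
        recruits = {"female": 100.0, "male": 100.0}
        state = d.project_forward(sch, recruits, years=60)
        for sex in SEXES:
            np.testing.assert_allclose(
                state[sex], recruits[sex] * lx.curve(sex), rtol=1e-6, atol=1e-9
            )

    def test_stationary_structure_is_a_fixed_point(self, schedules, tables):
        t = tables["4A"]
        state = d.project_forward(
            schedules["4A"],
            recruits_per_year=t.recruits,
            years=1,
            initial_structure=t.population,
        )
        for sex in SEXES:
            np.testing.assert_allclose(
                state[sex], t.population[sex], rtol=1e-12
            )

    def test_zero_recruitment_empties_the_population(self, schedules):
        start = {sex: np.full(N_AGES, 10.0) for sex in SEXES}
        state = d.project_forward(
            schedules["1"], {"female": 0.0, "male": 0.0}, years=25,
            initial_structure=start,
        )
        for sex in SEXES:
            assert state[sex].sum() == 0.0


def test_tabular_views_are_complete(schedules, tables):
    sf = schedule_frame(schedules["1"])
    cf = cohort_frame(tables["1"])
    assert len(sf) == len(cf) == 2 * N_AGES
    assert set(sf["provenance"]) <= {"stated", "derived", "floor"}
    assert cf["population"].sum() == pytest.approx(
        1000.0 + sum(tables["1"].recruits.values())
    )
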