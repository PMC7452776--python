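"""Study-data model: I/O round trips, weather assignment, encounter
histories, failure summaries and covariate centering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import turkeydem as td
from turkeydem.data import SchemaError, ValidationError


def _station(sid, x, y, base_temp=10.0):
    dates = np.arange(100, 200)
    return td.WeatherStation(
        station_id=sid, x_m=x, y_m=y, dates=dates,
        precip_mm=np.full(dates.size, float(sid[-1]) if sid[-1].isdigit() else 1.0),
        temp_c=np.full(dates.size, base_temp),
    )


def _nest(nest_id="n1", fate="depredated", n_days=4, **kw):
    y = np.ones(n_days, dtype=np.int8)
    if fate not in ("hatched",) and fate not in td.data.CENSOR_FATES:
        y[-1] = 0
    defaults = dict(
        nest_id=nest_id, hen_id="h1", year=2017, attempt=1, start_date=120,
        survival=y, fate=fate, cover_type="grassland", vor_mean=4.0,
        total_cover_mean=0.8, dist_road_m=100.0, x_m=0.0, y_m=0.0,
    )
    defaults.update(kw)
    return td.NestHistory(**defaults)


class TestRoundTrip:
    def test_write_then_read_reproduces_records(self, small_study, tmp_path):
        study, _, _ = small_study
        td.write_study_tables(study, tmp_path)
        back = td.load_study_tables(tmp_path)
        assert len(back.hens) == len(study.hens)
        assert len(back.nests) == len(study.nests)
        assert len(back.broods) == len(study.broods)
        for a, b in zip(study.nests, back.nests):
            assert a.nest_id == b.nest_id and a.fate == b.fate
            assert np.array_equal(a.survival, b.survival)
            assert a.start_date == b.start_date
            if a.vor_mean is None:
                assert b.vor_mean is None
            else:
                assert a.vor_mean == pytest.approx(b.vor_mean)
        for a, b in zip(study.broods, back.broods):
            assert a.counts == b.counts and a.hen_death_day == b.hen_death_day
        for a, b in zip(study.hens, back.hens):
            assert (a.hen_id, a.year, a.age_class, a.nested) == (
                b.hen_id, b.year, b.age_class, b.nested
            )

    def test_missing_required_column_names_it(self, small_study, tmp_path):
        study, _, _ = small_study
        td.write_study_tables(study, tmp_path)
        df = pd.read_csv(tmp_path / "nests.csv").drop(columns=["cover_type"])
        df.to_csv(tmp_path / "nests.csv", index=False)
        with pytest.raises(SchemaError, match="cover_type"):
            td.load_study_tables(tmp_path)


class TestValidation:
    def test_unknown_cover_type_rejected(self):
        with pytest.raises(ValidationError, match="wetland"):
            _nest(cover_type="wetland").validate()

    def test_unknown_fate_rejected(self):
        with pytest.raises(ValidationError, match="fate"):
            _nest(fate="exploded").validate()

    def test_nonmonotone_brood_counts_rejected(self):
        b = td.BroodSeries("b", "h", 2017, "adult", 150, 8, {8: 5, 15: 7, 29: 4})
        with pytest.raises(ValidationError, match="non-increasing"):
            b.validate()

    def test_census_after_hen_death_must_be_zero(self):
        b = td.BroodSeries("b", "h", 2017, "adult", 150, 8, {8: 5, 15: 3, 29: 0},
                           hen_death_day=10)
        with pytest.raises(ValidationError, match="hen death"):
            b.validate()

    def test_terminal_event_before_onset_rejected(self, tmp_path):
        rows = pd.DataFrame(
            [{"nest_id": "n", "hen_id": "h", "year": 2017, "attempt": 1,
              "start_date": 150, "end_date": 150, "fate": "depredated",
              "cover_type": "grassland", "vor_mean": 4, "total_cover_mean": 0.8,
              "dist_road_m": 10, "x_m": 0, "y_m": 0, "clutch_size": 10,
              "eggs_hatched": None}]
        )
        rows.to_csv(tmp_path / "nests.csv", index=False)
        pd.DataFrame(columns=td.data._HEN_COLS).to_csv(tmp_path / "hens.csv", index=False)
        pd.DataFrame(columns=td.data._BROOD_COLS).to_csv(tmp_path / "broods.csv", index=False)
        pd.DataFrame(columns=td.data._WEATHER_COLS).to_csv(tmp_path / "weather.csv", index=False)
        with pytest.raises(ValidationError, match="onset"):
            td.load_study_tables(tmp_path)

    def test_hatched_nest_cannot_miss_vegetation_covariates(self):
        with pytest.raises(ValidationError, match="failed"):
            _nest(fate="hatched", vor_mean=None).validate()

    def test_age_class_never_reverts(self):
        hens = [
            td.HenYear("h1", 2017, "adult", 5.0, True, True),
            td.HenYear("h1", 2018, "yearling", 5.0, True, True),
        ]
        study = td.StudyData(hens=hens, nests=[], broods=[], stations=[])
        with pytest.raises(ValidationError, match="revert"):
            study.validate()


class TestAssignWeather:
    def test_nearest_station_supplies_series(self):
        stations = [_station("S0", 0, 0), _station("S1", 10, 0)]
        precip, temp = td.assign_weather(2.0, 0.0, stations, np.arange(110, 115))
        assert np.all(precip == 0.0)  # S0's constant series

    def test_tie_broken_by_smaller_station_id(self):
        stations = [_station("S1", 10, 0), _station("S0", 0, 0)]
        precip, _ = td.assign_weather(5.0, 0.0, stations, np.arange(110, 112))
        assert np.all(precip == 0.0)

    def test_single_station_used_regardless_of_location(self):
        stations = [_station("S3", 0, 0)]
        precip, _ = td.assign_weather(1e6, 1e6, stations, np.arange(110, 112))
        assert np.all(precip == 3.0)

    def test_invariant_to_station_ordering(self):
        stations = [_station(f"S{k}", 7 * k, 3 * k) for k in range(5)]
        dates = np.arange(120, 140)
        a = td.assign_weather(11.0, 5.0, stations, dates)
        b = td.assign_weather(11.0, 5.0, stations[::-1], dates)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_uncovered_dates_raise(self):
        with pytest.raises(ValidationError, match="cover"):
            td.assign_weather(0, 0, [_station("S0", 0, 0)], np.arange(250, 260))


class TestEncounterHistories:
    def test_censored_attempts_excluded(self):
        attempts = [_nest(f"n{i}") for i in range(137)]
        attempts += [_nest(f"c{i}", fate="censored_interference") for i in range(5)]
        attempts += [_nest(f"a{i}", fate="censored_access") for i in range(5)]
        retained = td.build_nest_histories(attempts)
        assert len(attempts) == 147
        assert len(retained) == 137

    def test_retained_plus_censored_equals_input(self, medium_study):
        study, _, _ = medium_study
        retained = td.build_nest_histories(study.nests)
        censored = sum(1 for n in study.nests if n.censored)
        assert len(retained) + censored == len(study.nests)

    def test_hatched_attempt_is_all_ones(self):
        (n,) = td.build_nest_histories([_nest(fate="hatched", n_days=28)])
        assert np.all(n.survival == 1)

    def test_hen_death_encoded_as_terminal_failure(self):
        (n,) = td.build_nest_histories([_nest(fate="hen_died", n_days=4)])
        assert list(n.survival) == [1, 1, 1, 0]
        assert n.fate == "hen_died"


class TestFailureSummary:
    def test_observed_count_partition(self):
        attempts = []
        for cause, k in [("abandoned", 7), ("hen_died", 10), ("hayed", 13),
                         ("depredated", 47), ("trampled", 4)]:
            attempts += [_nest(f"{cause}{i}", fate=cause) for i in range(k)]
        table = td.summarize_failure_causes(attempts)
        assert table.total_failed == 81
        assert table.percentages == {
            "abandoned": 9, "hen_died": 12, "hayed": 16, "depredated": 58,
            "trampled": 5,
        }
        assert sum(table.proportions.values()) == pytest.approx(1.0)

    def test_single_failure_is_total(self):
        table = td.summarize_failure_causes([_nest(fate="depredated")])
        assert table.percentages["depredated"] == 100

    def test_symmetric_causes(self):
        attempts = [_nest(f"n{i}", fate=c) for i, c in
                    enumerate(["abandoned", "hayed", "depredated", "trampled"])]
        table = td.summarize_failure_causes(attempts)
        assert all(
            table.percentages[c] == 25
            for c in ["abandoned", "hayed", "depredated", "trampled"]
        )

    def test_zero_failures_gives_empty_table(self):
        table = td.summarize_failure_causes([_nest(fate="hatched", n_days=28)])
        assert table.total_failed == 0
        assert all(v == 0 for v in table.percentages.values())

    @given(st.lists(st.sampled_from(td.data.FAILURE_FATES), min_size=1, max_size=60))
    @settings(max_examples=25, deadline=None)
    def test_percentages_sum_near_100(self, fates):
        attempts = [_nest(f"n{i}", fate=f) for i, f in enumerate(fates)]
        table = td.summarize_failure_causes(attempts)
        n_causes = sum(1 for v in table.counts.values() if v)
        assert abs(sum(table.percentages.values()) - 100) <= n_causes
        assert sum(table.proportions.values()) == pytest.approx(1.0)


class TestCentering:
    def test_mean_subtracted(self):
        df = pd.DataFrame({"w": [4.0, 5.0, 6.0]})
        out, means = td.center_covariates(df, ["w"])
        assert list(out["w"]) == [-1.0, 0.0, 1.0]
        assert means["w"] == 5.0

    def test_constant_becomes_zero(self):
        out, _ = td.center_covariates(pd.DataFrame({"w": [3.0, 3.0, 3.0]}), ["w"])
        assert list(out["w"]) == [0.0, 0.0, 0.0]

    def test_missing_excluded_from_mean(self):
        out, means = td.center_covariates(
            pd.DataFrame({"w": [2.0, np.nan, 4.0]}), ["w"]
        )
        assert means["w"] == 3.0
        assert list(out["w"].dropna()) == [-1.0, 1.0]
        assert out["w"].isna().sum() == 1

    def test_all_missing_errors(self):
        with pytest.raises(ValidationError):
            td.center_covariates(pd.DataFrame({"w": [np.nan, np.nan]}), ["w"])
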