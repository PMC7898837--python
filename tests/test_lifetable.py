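"""Lifetable loading, lookup conventions, and expected-survival integration."""

import io

import numpy as np
import pandas as pd
import pytest

from relmediate import (
    ConfigurationError,
    Lifetable,
    LifetableSchema,
    SchemaError,
    ValidationError,
    expected_hazard_at,
    expected_survival,
    load_lifetable,
    write_lifetable,
)

from conftest import flat_lifetable


def _csv(text, tmp_path, name="lt.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoading:
    def test_two_row_table(self, tmp_path):
        p = _csv("age,sex,year,rate\n70,male,2012,0.02\n71,male,2012,0.03\n", tmp_path)
        lt = load_lifetable(p)
        assert lt.n_entries == 2
        assert (lt.age_min, lt.age_max) == (70, 71)
        assert not lt.stratified

    def test_negative_rate_rejected(self, tmp_path):
        p = _csv("age,sex,year,rate\n70,male,2012,-0.1\n", tmp_path)
        with pytest.raises(ValidationError, match="negative"):
            load_lifetable(p)

    def test_unmapped_sex_code_named_in_error(self, tmp_path):
        p = _csv(
            "age,sex,year,rate\n70,1,2012,0.02\n70,2,2012,0.02\n70,9,2012,0.02\n",
            tmp_path,
        )
        schema = LifetableSchema(sex_map={"1": "male", "2": "female"})
        with pytest.raises(SchemaError, match="9"):
            load_lifetable(p, schema)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _csv("age,sex,rate\n70,male,0.02\n", tmp_path)
        with pytest.raises(SchemaError, match="year"):
            load_lifetable(p)

    def test_duplicate_key_rejected(self, tmp_path):
        p = _csv("age,sex,year,rate\n70,male,2012,0.02\n70,male,2012,0.03\n", tmp_path)
        with pytest.raises(ValidationError, match="duplicated"):
            load_lifetable(p)

    def test_age_gap_rejected(self, tmp_path):
        p = _csv("age,sex,year,rate\n70,male,2012,0.02\n72,male,2012,0.03\n", tmp_path)
        with pytest.raises(ValidationError, match="contiguous"):
            load_lifetable(p)

    def test_round_trip_bit_stable(self, tmp_path):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "age": np.repeat([70, 71], 2),
                "sex": ["male", "male", "male", "male"],
                "year": [2012, 2013] * 2,
                "rate": rng.uniform(0.001, 0.2, 4),
            }
        )
        lt = Lifetable.from_frame(df)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_lifetable(lt, p1)
        write_lifetable(load_lifetable(p1), p2)
        assert p1.read_text() == p2.read_text()


@pytest.fixture(scope="module")
def lt():
    df = pd.DataFrame(
        {
            "age": [69, 70, 71],
            "sex": "male",
            "year": 2012,
            "rate": [0.018, 0.02, 0.03],
        }
    )
    return Lifetable.from_frame(df)


class TestLookup:
    def test_band_lookup(self, lt):
        assert expected_hazard_at(lt, 70.4, "male", 2012) == 0.02

    def test_age_above_cap_clamps(self, lt):
        assert expected_hazard_at(lt, 120, "male", 2012) == 0.03

    def test_band_boundary(self, lt):
        assert expected_hazard_at(lt, 69.999, "male", 2012) == 0.018
        assert expected_hazard_at(lt, 70.0, "male", 2012) == 0.02

    def test_year_clamps_to_nearest(self, lt):
        assert expected_hazard_at(lt, 70.5, "male", 1990) == 0.02
        assert expected_hazard_at(lt, 70.5, "male", 2030) == 0.02

    def test_stratum_on_unstratified_table_is_config_error(self, lt):
        with pytest.raises(ConfigurationError):
            expected_hazard_at(lt, 70.5, "male", 2012, stratum="1")

    def test_missing_stratum_on_stratified_table_is_config_error(self):
        lt = flat_lifetable(0.01, strata=("0", "1"))
        with pytest.raises(ConfigurationError):
            expected_hazard_at(lt, 70.5, "male", 2012)


class TestExpectedSurvival:
    def test_constant_rate_closed_form(self):
        lt = flat_lifetable(0.1)
        traj = expected_survival(lt, 70.0, "male", 2012, np.array([0.0, 1.0]))
        assert traj.survival[0] == 1.0
        assert np.isclose(traj.survival[1], np.exp(-0.1), atol=1e-14)

    def test_hand_integral_across_age_boundary(self):
        df = pd.DataFrame(
            {"age": [70, 71], "sex": "male", "year": 2012, "rate": [0.02, 0.03]}
        )
        lt = Lifetable.from_frame(df)
        traj = expected_survival(lt, 70.5, "male", 2012.0, np.array([1.0]))
        # 0.5 years at 0.02 (age 70), then 0.5 years at 0.03 (age 71)
        assert np.isclose(traj.survival[0], np.exp(-0.025), atol=1e-15)

    def test_negative_time_rejected(self):
        lt = flat_lifetable(0.1)
        with pytest.raises(Exception):
            expected_survival(lt, 70, "male", 2012, np.array([-0.5]))

    def test_riemann_sum_agreement(self):
        """Exact integration matches a brute-force Riemann sum at step 1e-4
        over 5 years (integer age/year so breakpoints align with the step)."""
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            [
                {"age": a, "sex": "male", "year": y, "rate": rng.uniform(0.01, 0.3)}
                for a in range(60, 70)
                for y in range(2010, 2020)
            ]
        )
        lt = Lifetable.from_frame(df)
        t_grid = np.array([0.5, 1.0, 2.5, 5.0])
        traj = expected_survival(lt, 62.0, "male", 2011.0, t_grid)
        h = 1e-4
        steps = np.arange(0, 5.0, h)
        rates = np.array(
            [expected_hazard_at(lt, 62.0 + s, "male", 2011.0 + s) for s in steps]
        )
        cum = np.cumsum(rates * h)
        brute = np.interp(t_grid, steps + h, cum)
        assert np.max(np.abs(traj.cumhaz - brute)) < 1e-9

    def test_monotone_and_rate_increase_decreases_survival(self):
        lt_lo = flat_lifetable(0.05)
        lt_hi = flat_lifetable(0.06)
        grid = np.linspace(0, 5, 21)
        s_lo = expected_survival(lt_lo, 71.3, "female", 2012.0, grid).survival
        s_hi = expected_survival(lt_hi, 71.3, "female", 2012.0, grid).survival
        assert np.all(np.diff(s_lo) <= 0)
        assert np.all(s_hi[1:] < s_lo[1:])
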