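"""Model 3: cohort initialisation, stochastic evolution, period prevalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import expowin as e
from expowin.errors import ConfigurationError, InputError
from expowin.microsim import (
    LifeTable,
    SimulationConfig,
    assign_window_category,
    largest_remainder,
    occupational_turnover,
    step_mortality,
    step_transition,
)
from expowin.transitions import TransitionMatrix

from conftest import prevalence_frame


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"window_start": 2011, "window_end": 2002},
        {"window_start": 2002, "window_end": 2011, "estimation_year": 2005},
        {"window_start": 2002, "window_end": 2011, "n": 0},
        {"window_start": 2002, "window_end": 2011, "rule": "median"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_estimation_year_defaults_to_window_end(self):
        cfg = SimulationConfig(window_start=2002, window_end=2011)
        assert cfg.estimation_year == 2011


class TestLargestRemainder:
    def test_textbook_allocation(self):
        np.testing.assert_array_equal(
            largest_remainder(np.array([0.5, 0.3, 0.2]), 10), [5, 3, 2])

    @given(st.lists(st.floats(min_value=0.01, max_value=10.0),
                    min_size=1, max_size=12),
           st.integers(min_value=1, max_value=5000))
    def test_allocation_sums_to_n(self, shares, n):
        alloc = largest_remainder(np.array(shares), n)
        assert alloc.sum() == n
        assert (alloc >= 0).all()


class TestInitialize:
    def test_degenerate_prevalence(self, single_stratum_pop):
        cfg = SimulationConfig(window_start=2002, window_end=2011, n=500,
                               seed=1)
        cohort = e.initialize_cohort(single_stratum_pop,
                                     prevalence_frame([1, 0, 0, 0, 0, 0]),
                                     cfg)
        assert (cohort.categories[:, 0] == 0).all()

    def test_stratum_sizes_and_ages(self):
        pop = pd.DataFrame([
            {"sex": "female", "age_group": "40-44", "count": 5},
            {"sex": "male", "age_group": "60-64", "count": 3},
            {"sex": "male", "age_group": "95+", "count": 2}])
        prev = pd.concat([prevalence_frame([0.5, 0.5, 0, 0, 0, 0], s, g)
                          for s, g in [("female", "40-44"),
                                       ("male", "60-64"), ("male", "95+")]])
        cfg = SimulationConfig(window_start=2002, window_end=2003, n=10,
                               seed=2)
        cohort = e.initialize_cohort(pop, prev, cfg)
        assert (pd.Series(cohort.age_group).value_counts()
                .to_dict() == {"40-44": 5, "60-64": 3, "95+": 2})
        in_band = ((cohort.age_group == "40-44")
                   & (cohort.age0 >= 40) & (cohort.age0 < 45))
        assert in_band.sum() == 5
        open_band = cohort.age_group == "95+"
        assert np.all(cohort.age0[open_band] >= 95)
        assert np.all(cohort.age0[open_band] < 100)

    def test_all_zero_population_rejected(self):
        pop = pd.DataFrame([{"sex": "female", "age_group": "40-44",
                             "count": 0}])
        cfg = SimulationConfig(window_start=2002, window_end=2003)
        with pytest.raises(InputError):
            e.initialize_cohort(pop, prevalence_frame([1, 0, 0, 0, 0, 0]),
                                cfg)


class TestElementarySteps:
    @pytest.mark.parametrize("u,expected", [(0.6, 2), (0.0, 0), (0.19, 0),
                                            (0.2, 1), (0.499, 1), (0.5, 2)])
    def test_inverse_cdf_split(self, u, expected):
        assert step_transition(1, np.array([0.2, 0.3, 0.5]), u) == expected

    def test_identity_row_stays(self):
        row = np.zeros(6)
        row[3] = 1.0
        for u in (0.0, 0.5, 0.999999):
            assert step_transition(3, row, u) == 3

    def test_invalid_row_rejected(self):
        with pytest.raises(InputError):
            step_transition(0, np.array([0.5, 0.2]), 0.1)

    @given(st.floats(min_value=0.0, max_value=0.999999),
           st.integers(min_value=0, max_value=9))
    def test_inverse_cdf_property(self, u, seed):
        row = np.random.default_rng(seed).dirichlet(np.ones(5))
        k = step_transition(0, row / row.sum(), u)
        cum = np.cumsum(row / row.sum())
        assert u < cum[k] + 1e-12
        if k > 0:
            assert u >= cum[k - 1] - 1e-12

    def test_certain_and_impossible_death(self):
        lt1 = LifeTable.constant(1.0)
        lt0 = LifeTable.constant(0.0)
        for u in (0.0, 0.5, 0.99):
            assert step_mortality("male", 40, 0, lt1, u) is False
        for u in (0.0, 0.5, 0.99):
            assert step_mortality("male", 40, 0, lt0, u) is True

    def test_death_fraction_matches_q(self, single_stratum_pop):
        cfg = SimulationConfig(window_start=0, window_end=1, n=1_000_000,
                               seed=3)
        cohort = e.initialize_cohort(single_stratum_pop,
                                     prevalence_frame([1, 0, 0, 0, 0, 0]),
                                     cfg)
        lt = LifeTable.constant(0.5)
        e.simulate_window(cohort, TransitionMatrix(probs=np.eye(6)), lt,
                          cfg)
        frac = 1.0 - cohort.alive.mean()
        assert abs(frac - 0.5) <= 0.0015        # 3 sigma at n = 1e6


class TestSimulateWindow:
    def _cohort(self, n=2000, seed=4, window=(2002, 2011)):
        cfg = SimulationConfig(window_start=window[0], window_end=window[1],
                               n=n, seed=seed)
        pop = pd.DataFrame([{"sex": "female", "age_group": "40-44",
                             "count": 1}])
        cohort = e.initialize_cohort(
            pop, prevalence_frame([0.3, 0.2, 0.2, 0.15, 0.1, 0.05]), cfg)
        return cohort, cfg

    def test_identity_no_mortality_freezes_sequences(self):
        cohort, cfg = self._cohort()
        e.simulate_window(cohort, TransitionMatrix(probs=np.eye(6)), None,
                          cfg)
        assert (cohort.categories
                == cohort.categories[:, :1]).all()
        assert cohort.alive.all()

    def test_certain_death_leaves_no_survivors(self):
        cohort, cfg = self._cohort()
        e.simulate_window(cohort, TransitionMatrix(probs=np.eye(6)),
                          LifeTable.constant(1.0), cfg)
        assert not cohort.alive.any()
        assert (cohort.death_year == cfg.window_start + 1).all()

    def test_conservation_of_individuals(self, both_matrix):
        cohort, cfg = self._cohort()
        e.simulate_window(cohort, TransitionMatrix(probs=both_matrix),
                          LifeTable.constant(0.05), cfg)
        dead = (~cohort.alive).sum()
        assert dead + cohort.alive.sum() == cohort.n
        assert ((cohort.death_year >= 0) == ~cohort.alive).all()

    def test_dead_individuals_keep_last_category(self, both_matrix):
        cohort, cfg = self._cohort(seed=9)
        e.simulate_window(cohort, TransitionMatrix(probs=both_matrix),
                          LifeTable.constant(0.2), cfg)
        years = cohort.window_years()
        for i in np.flatnonzero(~cohort.alive)[:50]:
            t_dead = int(cohort.death_year[i] - cohort.start_year)
            frozen = cohort.categories[i, t_dead - 1:]
            assert (frozen == frozen[0]).all()

    def test_reproducible_under_fixed_seed(self, both_matrix):
        a, cfg = self._cohort(seed=5)
        b, _ = self._cohort(seed=5)
        lt = LifeTable.constant(0.02)
        e.simulate_window(a, TransitionMatrix(probs=both_matrix), lt, cfg)
        e.simulate_window(b, TransitionMatrix(probs=both_matrix), lt, cfg)
        np.testing.assert_array_equal(a.categories, b.categories)
        np.testing.assert_array_equal(a.alive, b.alive)


class TestCensoring:
    def test_estimation_at_window_end_changes_nothing(self, both_matrix):
        cfg = SimulationConfig(window_start=2002, window_end=2011, n=1000,
                               seed=6)
        pop = pd.DataFrame([{"sex": "male", "age_group": "50-54",
                             "count": 1}])
        cohort = e.initialize_cohort(
            pop, prevalence_frame([1, 0, 0, 0, 0, 0], "male", "50-54"),
            cfg)
        lt = LifeTable.constant(0.1)
        e.simulate_window(cohort, TransitionMatrix(probs=both_matrix), lt,
                          cfg)
        before = cohort.alive.copy()
        e.censor_to_estimation_year(cohort, lt, 2011, cfg)
        np.testing.assert_array_equal(cohort.alive_at_estimation, before)

    def test_survival_matches_closed_form_product(self):
        """Gompertz censoring 5 years past the window, single stratum."""
        cfg = SimulationConfig(window_start=2002, window_end=2011,
                               estimation_year=2016, n=100_000, seed=7)
        pop = pd.DataFrame([{"sex": "male", "age_group": "60-64",
                             "count": 1}])
        cohort = e.initialize_cohort(
            pop, prevalence_frame([1, 0, 0, 0, 0, 0], "male", "60-64"),
            cfg)
        a, b = 4.7e-5, 0.085
        lt = LifeTable.from_function(
            lambda sex, age, year: min(1.0, a * np.exp(b * age)),
            years=(0,))
        e.simulate_window(cohort, TransitionMatrix(probs=np.eye(6)), lt,
                          cfg)
        e.censor_to_estimation_year(cohort, lt, 2016, cfg)
        # expected survival: product over the simulated integer ages
        expected = np.mean([
            np.prod([1 - min(1.0, a * np.exp(b * int(age0 + dt)))
                     for dt in range(1, 15)])
            for age0 in cohort.age0[:2000]])
        observed = cohort.alive_at_estimation.mean()
        se = np.sqrt(expected * (1 - expected) / cohort.n)
        assert abs(observed - expected) <= 3 * se + 2e-3


class TestAssignmentRules:
    def test_max_rule_takes_highest(self):
        seq = np.array([[1, 3, 2]], dtype=np.int8)
        assert assign_window_category(seq, "max", 6)[0] == 3

    def test_constant_sequence_agrees_under_all_rules(self):
        seq = np.full((4, 7), 2, dtype=np.int8)
        for rule in ("max", "max-2-consecutive", "most-time"):
            assert (assign_window_category(seq, rule, 6) == 2).all()

    def test_most_time_breaks_ties_upward(self):
        seq = np.array([[1, 1, 4, 4]], dtype=np.int8)
        assert assign_window_category(seq, "most-time", 6)[0] == 4

    def test_max_two_consecutive_against_enumeration(self):
        """All 16 length-4 binary sequences versus a literal reference."""

        def reference(s):
            held = {s[i] for i in range(3) if s[i] == s[i + 1]}
            return max(held) if held else max(s)

        seqs = np.array([[(n >> i) & 1 for i in range(4)]
                         for n in range(16)], dtype=np.int8)
        got = assign_window_category(seqs, "max-2-consecutive", 2)
        want = [reference(list(s)) for s in seqs]
        np.testing.assert_array_equal(got, want)

    def test_alternating_high_low_falls_back_to_max(self):
        seq = np.array([[5, 1, 5, 1]], dtype=np.int8)
        assert assign_window_category(seq, "max-2-consecutive", 6)[0] == 5


class TestPeriodPrevalenceAndOT:
    def test_point_times_ot_recovers_period(self):
        ot = occupational_turnover(np.array([0.4]), np.array([0.1]))
        assert ot[0] == pytest.approx(4.0)

    def test_zero_point_prevalence_is_undefined(self):
        ot = occupational_turnover(np.array([0.4, 0.2]),
                                   np.array([0.1, 0.0]))
        assert np.isnan(ot[1])

    def test_identity_no_mortality_gives_unit_ot(self, single_stratum_pop):
        cfg = SimulationConfig(window_start=2002, window_end=2011, n=20000,
                               seed=8)
        cohort = e.initialize_cohort(
            single_stratum_pop,
            prevalence_frame([0.3, 0.2, 0.2, 0.15, 0.1, 0.05]), cfg)
        e.simulate_window(cohort, TransitionMatrix(probs=np.eye(6)), None,
                          cfg)
        e.censor_to_estimation_year(cohort, None, 2011, cfg)
        period = e.period_prevalence(cohort)
        point = e.point_prevalence(cohort, 2002)
        merged = occupational_turnover(period, point)
        assert np.allclose(merged["ot"].dropna(), 1.0)

    def test_zero_survivors_reported_missing(self, single_stratum_pop):
        cfg = SimulationConfig(window_start=2002, window_end=2003, n=100,
                               seed=9)
        cohort = e.initialize_cohort(single_stratum_pop,
                                     prevalence_frame([1, 0, 0, 0, 0, 0]),
                                     cfg)
        e.simulate_window(cohort, TransitionMatrix(probs=np.eye(6)),
                          LifeTable.constant(1.0), cfg)
        e.censor_to_estimation_year(cohort, None, 2003, cfg)
        out = e.period_prevalence(cohort)
        assert (out["alive_n"] == 0).all()
        assert out["proportion"].isna().all()


class TestLifeTable:
    def test_missing_year_error_names_cell(self):
        lt = LifeTable.from_function(lambda s, a, y: 0.01,
                                     years=(2000, 2001))
        with pytest.raises(InputError, match="2050"):
            lt.q(0, 40, 2050)

    def test_interior_gap_filled_with_warning(self, caplog):
        rows = [{"sex": "female", "age": a, "year": 2000, "qx": 0.01 * i}
                for i, a in enumerate((40, 41, 43))]
        with caplog.at_level("WARNING"):
            lt = LifeTable.from_frame(pd.DataFrame(rows),
                                      sexes=("female",))
        assert "missing interior" in caplog.text
        assert 0.01 <= lt.q(0, 42, 2000) <= 0.02

    def test_out_of_band_qx_rejected(self, tmp_path):
        from expowin import io as eio

        df = pd.DataFrame({"sex": ["male"], "age": [40], "year": [2000],
                           "qx": [1.5]})
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(InputError, match="row"):
            eio.read_life_table(tmp_path / "bad.csv")
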