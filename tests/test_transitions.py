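"""Model 2: matching, reweighting, FP selection, transition matrices."""

import numpy as np
import pandas as pd
import pytest

import expowin as e
from expowin.errors import InputError
from expowin.transitions import (
    MultinomialTransitionModel,
    load_fixed_matrix,
    match_pseudo_panel,
    panel_margins,
    reweight_panel,
    select_fp,
)


def _wave(rows, year):
    df = pd.DataFrame(rows, columns=["hh_id", "seq", "sex", "birth_year",
                                     "category"])
    df["year"] = year
    df["weight"] = 1.0
    return df


class TestMatching:
    def test_disjoint_households_match_nothing(self):
        a = _wave([(1, 1, "female", 1970, 2)], 2009)
        b = _wave([(2, 1, "female", 1970, 3)], 2010)
        assert len(match_pseudo_panel(a, b)) == 0

    def test_unique_individual_matches_once(self):
        a = _wave([(1, 1, "male", 1970, 2)], 2009)
        b = _wave([(1, 1, "male", 1970, 4)], 2010)
        pairs = match_pseudo_panel(a, b)
        assert len(pairs) == 1
        assert pairs.loc[0, "category_from"] == 2
        assert pairs.loc[0, "category_to"] == 4
        assert pairs.loc[0, "age"] == 39.0

    def test_ambiguous_keys_discarded(self):
        a = _wave([(1, 1, "male", 1970, 2), (1, 1, "male", 1970, 3),
                   (2, 1, "male", 1960, 1)], 2009)
        b = _wave([(1, 1, "male", 1970, 4), (2, 1, "male", 1960, 0)], 2010)
        pairs = match_pseudo_panel(a, b)
        assert len(pairs) == 1
        assert pairs.loc[0, "category_from"] == 1

    def test_missing_key_column_named(self):
        a = _wave([(1, 1, "male", 1970, 2)], 2009).drop(columns="birth_year")
        b = _wave([(1, 1, "male", 1970, 4)], 2010)
        with pytest.raises(InputError, match="birth_year"):
            match_pseudo_panel(a, b)


class TestReweighting:
    @pytest.fixture
    def pairs(self, truth):
        panel = e.sample_rotating_panel(truth, 2000, (2009, 2010), seed=9,
                                        attrition=0.2)
        return match_pseudo_panel(panel[panel.year == 2009],
                                  panel[panel.year == 2010])

    def test_identity_targets_leave_weights_unchanged(self, pairs):
        out = reweight_panel(pairs, panel_margins(pairs))
        np.testing.assert_allclose(out["weight"], pairs["weight"],
                                   rtol=1e-12)

    def test_doubled_target_doubles_cell_weights(self, pairs):
        targets = panel_margins(pairs)
        cell = targets.iloc[0]
        targets.loc[0, "target"] *= 2
        out = reweight_panel(pairs, targets)
        from expowin.categories import decade_group_of

        in_cell = ((pairs["category_from"] == cell["status"])
                   & (pairs["sex"] == cell["sex"])
                   & (decade_group_of(pairs["age"].to_numpy())
                      == cell["age10"]))
        ratio = out.loc[in_cell, "weight"] / pairs.loc[in_cell, "weight"]
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-12)

    def test_margins_match_targets_exactly(self, pairs):
        targets = panel_margins(pairs)
        targets["target"] *= np.linspace(0.5, 2.0, len(targets))
        out = reweight_panel(pairs, targets)
        achieved = panel_margins(out).set_index(["status", "sex", "age10"])
        wanted = targets.set_index(["status", "sex", "age10"])
        rel = ((achieved["target"] - wanted["target"]).abs()
               / wanted["target"])
        assert rel.max() <= 1e-9

    def test_zero_mass_target_skipped_with_warning(self, pairs, caplog):
        targets = panel_margins(pairs)
        extra = pd.DataFrame([{"status": 5, "sex": "female",
                               "age10": "75+", "target": 999.0}])
        ghost = pd.concat([targets, extra], ignore_index=True)
        ghost = ghost.drop_duplicates(["status", "sex", "age10"],
                                      keep="last")
        with caplog.at_level("WARNING"):
            reweight_panel(pairs[pairs["age"] < 70], ghost)
        assert "no panel mass" in caplog.text

    def test_reweighting_corrects_status_biased_attrition(self, truth):
        """Attrition concentrated in origin 0 biases the raw estimate;
        post-stratifying back to full margins must shrink the error."""
        panel = e.sample_rotating_panel(truth, 8000, (2009, 2010), seed=13,
                                        attrition=0.0)
        w1, w2 = panel[panel.year == 2009], panel[panel.year == 2010]
        full = match_pseudo_panel(w1, w2)
        targets = panel_margins(full)

        rng = np.random.default_rng(1)
        keys = ["hh_id", "seq", "sex", "birth_year"]
        merged = w2.merge(w1[keys + ["category"]], on=keys,
                          suffixes=("", "_w1"))
        drop = (merged["category_w1"] == 0) & (rng.random(len(merged)) < 0.7)
        attrited = match_pseudo_panel(w1, merged[~drop][w2.columns])
        reweighted = reweight_panel(attrited, targets)

        def overall_stay_share(p):
            # weighted share of pairs starting inactive (margin-sensitive)
            w = p["weight"]
            return float(w[p["category_from"] == 0].sum() / w.sum())

        truth_share = overall_stay_share(full)
        err_raw = abs(overall_stay_share(attrited) - truth_share)
        err_rw = abs(overall_stay_share(reweighted) - truth_share)
        assert err_rw < err_raw
        assert err_rw < 1e-9        # post-stratification is exact on margins


@pytest.fixture(scope="module")
def origin_pairs():
    """Pairs from a single origin with linear-in-age log-odds."""
    rng = np.random.default_rng(5)
    n = 4000
    age = rng.uniform(20, 70, n)
    male = rng.integers(0, 2, n)
    eta = np.column_stack([np.zeros(n),
                           -2.0 + 0.03 * age + 0.3 * male,
                           1.0 - 0.02 * age])
    p = np.exp(eta) / np.exp(eta).sum(1, keepdims=True)
    dest = np.array([rng.choice(3, p=pi) for pi in p])
    return pd.DataFrame({
        "sex": np.where(male == 1, "male", "female"), "age": age,
        "category_from": 1, "category_to": dest, "weight": 1.0})


class TestFPSelection:
    def test_selected_spec_is_global_argmin(self, origin_pairs):
        model = MultinomialTransitionModel(n_categories=3).fit(origin_pairs)
        log = model.deviance_log_[1]
        assert len(log) == 44
        best = model.fp_specs_[1]
        assert best.deviance <= min(s.deviance for s in log) + 1e-9

    def test_selected_model_recovers_probabilities(self, origin_pairs):
        model = MultinomialTransitionModel(n_categories=3).fit(origin_pairs)
        ages = np.arange(25, 61, 5, dtype=float)
        for sex, male in (("female", 0), ("male", 1)):
            for a in ages:
                eta = np.array([0.0, -2.0 + 0.03 * a + 0.3 * male,
                                1.0 - 0.02 * a])
                p_true = np.exp(eta) / np.exp(eta).sum()
                row = model.predict_matrix(sex, a).probs[1]
                np.testing.assert_allclose(row, p_true, atol=0.05)

    def test_select_fp_requires_two_destinations(self):
        pairs = pd.DataFrame({"sex": ["f"] * 5, "age": 40.0,
                              "category_from": 0, "category_to": 0,
                              "weight": 1.0})
        from expowin.errors import FittingError

        with pytest.raises(FittingError):
            select_fp(pairs, n_categories=2)


class TestPrediction:
    def test_zero_coefficients_give_uniform_rows(self):
        model = MultinomialTransitionModel.from_coefficients(
            {o: np.zeros((3, 6)) for o in range(6)})
        mat = model.predict_matrix("male", 40.0)
        np.testing.assert_allclose(mat.probs, 1 / 6)

    def test_rows_are_distributions_at_every_age(self, truth):
        panel = e.sample_rotating_panel(truth, 3000, (2009, 2010), seed=3,
                                        attrition=0.0)
        pairs = match_pseudo_panel(panel[panel.year == 2009],
                                   panel[panel.year == 2010])
        model = MultinomialTransitionModel(fp_spec=(1.0,)).fit(pairs)
        for age in (15.0, 33.3, 64.9, 110.0):
            for sex in ("female", "male"):
                probs = model.predict_matrix(sex, age).probs
                np.testing.assert_allclose(probs.sum(1), 1.0, atol=1e-9)
                assert probs.min() >= 0

    def test_age_outside_range_clamped_with_warning(self, caplog):
        model = MultinomialTransitionModel.from_coefficients(
            {o: np.zeros((3, 6)) for o in range(6)})
        with caplog.at_level("WARNING"):
            mat = model.predict_matrix("male", 150.0)
        assert "clamped" in caplog.text
        assert mat.age == 110.0

    def test_unobserved_origin_row_is_identity(self):
        pairs = pd.DataFrame({
            "sex": ["female"] * 60,
            "age": np.linspace(20, 60, 60),
            "category_from": 0,
            "category_to": np.tile([0, 1, 2], 20),
            "weight": 1.0})
        model = MultinomialTransitionModel(n_categories=3,
                                           fp_spec=(1.0,)).fit(pairs)
        row = model.predict_matrix("female", 40.0).probs[2]
        np.testing.assert_allclose(row, [0, 0, 1])

    def test_delta_method_table_is_ordered(self, truth):
        panel = e.sample_rotating_panel(truth, 3000, (2009, 2010), seed=3,
                                        attrition=0.0)
        pairs = match_pseudo_panel(panel[panel.year == 2009],
                                   panel[panel.year == 2010])
        model = MultinomialTransitionModel(fp_spec=(1.0,)).fit(pairs)
        table = model.table_with_ur("female", 40.0)
        assert (table["lower_pct"] <= table["probability_pct"] + 1e-9).all()
        assert (table["probability_pct"] <= table["upper_pct"] + 1e-9).all()
        assert (table["method"] == "delta").all()


class TestFixedMatrix:
    def test_printed_rows_renormalise_to_one(self, printed_table):
        probs = printed_table["both"]["matrix"].probs
        np.testing.assert_allclose(probs.sum(1), 1.0, atol=1e-12)

    def test_identity_percent_unchanged(self):
        mat = load_fixed_matrix(np.eye(6) * 100)
        np.testing.assert_allclose(mat.probs, np.eye(6))

    def test_row_sum_divides_printed_total(self, printed_table):
        pct = printed_table["both"]["point_pct"]
        assert pct[0].sum() == pytest.approx(101.7, abs=1e-9)
        renorm = printed_table["both"]["matrix"].probs
        assert renorm[0, 0] == pytest.approx(65.8 / 101.7, abs=1e-12)

    def test_negative_entry_rejected(self):
        bad = np.eye(6) * 100
        bad[0, 1] = -1
        with pytest.raises(InputError):
            load_fixed_matrix(bad)

    def test_wild_row_sum_rejected(self):
        bad = np.full((6, 6), 25.0)       # rows sum to 150%
        with pytest.raises(InputError, match="20%"):
            load_fixed_matrix(bad)
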