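import numpy as np
import pandas as pd
import pytest

from ageplace import sae


def _survey_2x2(counts=((1, 1), (1, 1)), outcomes=None):
    """Tiny survey: one row per (age-ish, gender-ish) cell copy."""
    rows = []
    for i, age in enumerate(("young", "old")):
        for j, sex in enumerate(("M", "F")):
            for _ in range(counts[i][j]):
                rows.append({"ageband": age, "sex": sex})
    df = pd.DataFrame(rows)
    for c in sae.OUTCOME_COLUMNS:
        df[c] = 0 if outcomes is None else outcomes
    return df


class TestIPF:
    def test_proportional_survey_gets_uniform_weights(self):
        survey = _survey_2x2(counts=((2, 2), (2, 2)))
        cons = {
            "ageband": {"young": 20.0, "old": 20.0},
            "sex": {"M": 20.0, "F": 20.0},
        }
        res = sae.ipf_reweight_area(survey, cons)
        assert res.converged
        assert np.allclose(res.weights, 40.0 / 8)

    def test_2x2_closed_form_from_independence_seed(self):
        # uniform seed, row margins (30, 10), column margins (20, 20):
        # IPF converges to the independence table margins product / total
        survey = _survey_2x2()
        cons = {
            "ageband": {"young": 30.0, "old": 10.0},
            "sex": {"M": 20.0, "F": 20.0},
        }
        res = sae.ipf_reweight_area(survey, cons)
        assert res.converged
        w = res.weights  # rows ordered young-M, young-F, old-M, old-F
        assert np.allclose(w, [15.0, 15.0, 5.0, 5.0], atol=1e-6)

    def test_preserves_cross_product_ratio_of_seed(self):
        # two copies of young-M: seed odds ratio (2*1)/(1*1) = 2
        survey = _survey_2x2(counts=((2, 1), (1, 1)))
        cons = {
            "ageband": {"young": 35.0, "old": 25.0},
            "sex": {"M": 18.0, "F": 42.0},
        }
        res = sae.ipf_reweight_area(survey, cons, tol=1e-12)
        w = res.weights
        cell = {
            ("young", "M"): w[0] + w[1],
            ("young", "F"): w[2],
            ("old", "M"): w[3],
            ("old", "F"): w[4],
        }
        ratio = (cell[("young", "M")] * cell[("old", "F")]) / (
            cell[("young", "F")] * cell[("old", "M")]
        )
        assert ratio == pytest.approx(2.0, abs=1e-6)

    def test_marginals_match_on_five_variable_synthetic_area(
        self, survey_constraints
    ):
        survey, cons = survey_constraints
        area_id = cons["area_id"].iloc[0]
        area_cons = sae.constraints_for_area(cons, area_id)
        res = sae.ipf_reweight_area(survey, area_cons)
        assert res.converged
        total = sum(area_cons["age"].values())
        for var, targets in area_cons.items():
            for cat, target in targets.items():
                got = res.weights[(survey[var] == cat).to_numpy()].sum()
                assert got == pytest.approx(target, abs=1e-8 * total + 1e-9)
        assert (res.weights >= 0).all()
        assert res.weights.sum() == pytest.approx(total, rel=1e-8)

    def test_infeasible_cell_raises_or_redistributes(self):
        survey = _survey_2x2(counts=((1, 1), (0, 0)))  # no 'old' rows
        cons = {
            "ageband": {"young": 30.0, "old": 10.0},
            "sex": {"M": 20.0, "F": 20.0},
        }
        with pytest.raises(sae.InfeasibleConstraintError, match="old"):
            sae.ipf_reweight_area(survey, cons, on_empty="error")
        res = sae.ipf_reweight_area(survey, cons)  # default redistributes
        assert ("ageband", "old") in res.redistributed
        assert res.weights.sum() == pytest.approx(40.0, rel=1e-6)

    def test_inconsistent_area_totals_rejected(self):
        survey = _survey_2x2()
        cons = {
            "ageband": {"young": 30.0, "old": 10.0},
            "sex": {"M": 20.0, "F": 30.0},
        }
        with pytest.raises(ValueError, match="area total"):
            sae.ipf_reweight_area(survey, cons)


class TestAreaPercentages:
    def test_saturated_and_empty_outcomes(self):
        survey = _survey_2x2(outcomes=1)
        pct = sae.estimate_area_percentages({"A": np.ones(4)}, survey)
        assert (pct.drop(columns="area_id") == 100.0).all().all()
        survey0 = _survey_2x2(outcomes=0)
        pct0 = sae.estimate_area_percentages({"A": np.ones(4)}, survey0)
        assert (pct0.drop(columns="area_id") == 0.0).all().all()

    def test_matches_hand_computed_weighted_mean(self):
        survey = _survey_2x2()
        survey["broadband"] = [1, 0, 1, 0]
        w = np.array([4.0, 1.0, 2.0, 3.0])
        pct = sae.estimate_area_percentages({"A": w}, survey, outcomes=("broadband",))
        assert pct["pct_broadband"].iloc[0] == pytest.approx(100 * 6.0 / 10.0)

    def test_outcome_dominance_monotonicity(self):
        survey = _survey_2x2()
        survey["broadband"] = [0, 0, 1, 0]
        w = {"A": np.array([1.0, 2.0, 3.0, 4.0])}
        before = sae.estimate_area_percentages(w, survey, ("broadband",))
        survey2 = survey.copy()
        survey2.loc[0, "broadband"] = 1  # flip one 0 -> 1
        after = sae.estimate_area_percentages(w, survey2, ("broadband",))
        assert after["pct_broadband"].iloc[0] >= before["pct_broadband"].iloc[0]


class TestTrainingSelection:
    def _survey(self, counts):
        rows = []
        for area, n in counts.items():
            rows += [{"area_id": area}] * n
        rows += [{"area_id": None}] * 3
        return pd.DataFrame(rows)

    def test_min_obs_boundary(self):
        training, counts = sae.select_training_areas(
            self._survey({"A": 11, "B": 10, "C": 25})
        )
        assert set(training) == {"A", "C"}  # 11 in, 10 out
        assert counts["B"] == 10

    def test_counts_match_brute_force(self, survey_constraints):
        survey, _ = survey_constraints
        training, counts = sae.select_training_areas(survey)
        located = survey.dropna(subset=["area_id"])
        brute = located["area_id"].value_counts()
        assert set(training) == set(brute.index[brute >= 11])
        assert len(training) == int((brute >= 11).sum())

    def test_training_share_arithmetic(self):
        assert sae.training_share(1, 4) == pytest.approx(25.0)
        with pytest.raises(ValueError):
            sae.training_share(1, 0)


class TestFitPredict:
    def _features(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.random((n, 5)),
            index=[f"A{i}" for i in range(n)],
            columns=list("abcde"),
        )

    def _targets(self, ids, value=50.0):
        return pd.DataFrame(
            {c: value for c in sae.PCT_COLUMNS}, index=pd.Index(ids, name="area_id")
        ).reset_index()

    def test_constant_targets_give_constant_predictions(self):
        feats = self._features()
        train = feats.index[:15]
        preds = sae.fit_predict_sae(
            feats, self._targets(train), pd.Series(12, index=train), seed=0
        )
        for c in sae.PCT_COLUMNS:
            assert np.allclose(preds[c], 50.0, atol=1e-6)

    def test_too_few_training_areas_errors(self):
        feats = self._features()
        train = feats.index[:5]
        with pytest.raises(ValueError, match="training areas"):
            sae.fit_predict_sae(
                feats, self._targets(train), pd.Series(12, index=train)
            )

    def test_upweighting_pulls_fit_towards_area(self):
        rng = np.random.default_rng(3)
        feats = self._features(n=30, seed=3)
        train = feats.index[:20]
        targets = self._targets(train)
        targets[list(sae.PCT_COLUMNS)] = rng.uniform(20, 80, (20, 4))
        special = train[0]
        base_w = pd.Series(1.0, index=train)
        up_w = base_w.copy()
        up_w[special] = 100.0
        base = sae.fit_predict_sae(feats, targets, base_w, seed=3)
        up = sae.fit_predict_sae(feats, targets, up_w, seed=3)
        tgt = targets.set_index("area_id").loc[special, "pct_broadband"]
        base_err = abs(base.set_index("area_id").loc[special, "pct_broadband"] - tgt)
        up_err = abs(up.set_index("area_id").loc[special, "pct_broadband"] - tgt)
        assert up_err <= base_err

    def test_predictions_clipped_to_percentage_range(self):
        feats = self._features()
        train = feats.index[:15]
        targets = self._targets(train, value=99.9)
        preds = sae.fit_predict_sae(
            feats, targets, pd.Series(12, index=train), seed=1
        )
        assert ((preds[list(sae.PCT_COLUMNS)] >= 0).all() & (
            preds[list(sae.PCT_COLUMNS)] <= 100).all()).all()


def test_constraint_features_are_category_shares(survey_constraints):
    _, cons = survey_constraints
    feats = sae.constraint_features(cons)
    first = cons["area_id"].iloc[0]
    sub = cons[(cons["area_id"] == first) & (cons["variable"] == "gender")]
    total = sub["count"].sum()
    male = sub.loc[sub["category"] == "Male", "count"].iloc[0]
    assert feats.loc[first, "gender:Male"] == pytest.approx(male / total)
    # shares of one variable sum to 1 per area
    age_cols = [c for c in feats.columns if c.startswith("age:")]
    assert np.allclose(feats[age_cols].sum(axis=1), 1.0)
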