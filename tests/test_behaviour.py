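import numpy as np
import pandas as pd
import pytest

from caoss.behaviour import (accuracy_filter, apply_transform, compare_models,
                             empirical_logit, icc, prepare_design,
                             speed_accuracy_check, suggest_transform)
from caoss.composition import score_proximities
from caoss.lmm import AnalysisResult, FixedEffect, fit_lmm
from conftest import simulate_crossed


class TestTransformSuggestion:
    def test_inverse_generated_times_map_to_inverse(self):
        rng = np.random.default_rng(0)
        z = rng.normal(3.0, 0.3, 4000)
        z = z[z > 0.5][:2000]
        s = suggest_transform(1.0 / z)
        assert -1.3 <= s.lambda_hat <= -0.7
        assert s.transform == "inverse"

    def test_gaussian_data_maps_to_none(self):
        # small coefficient of variation flattens the Box-Cox profile, so a
        # large sample is needed for lambda to be identified near 1
        rng = np.random.default_rng(1)
        y = rng.normal(100.0, 5.0, 50_000)
        assert suggest_transform(y[y > 0]).transform == "none"

    def test_lognormal_data_maps_to_log(self):
        rng = np.random.default_rng(2)
        assert suggest_transform(np.exp(rng.normal(0, 1, 2000))).transform == "log"

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            suggest_transform(np.array([1.0, -1.0] + [1.0] * 10))

    def test_inverse_transform_of_typical_latency(self):
        assert apply_transform(np.array([0.723]), "inverse")[0] == pytest.approx(1.383, abs=1e-3)


@pytest.fixture(scope="module")
def world(small_dataset):
    ds = small_dataset
    prox = score_proximities(ds.lexicon, ds.table, weights=ds.truth_weights)
    return ds, prox


class TestPrepareDesign:
    def test_predictor_columns_are_mean_centered(self, world):
        ds, prox = world
        design = prepare_design(ds.behaviour["rating"], ds.lexicon, prox, model="caoss")
        for col in design.attrs["predictors"]:
            assert abs(design[col].mean()) < 1e-10

    def test_novel_vs_existing_predictor_counts(self, world):
        ds, prox = world
        novel = prepare_design(ds.behaviour["rating"], ds.lexicon, prox, model="caoss")
        existing = prepare_design(ds.behaviour["rt"], ds.lexicon, prox, model="caoss",
                                  include_word_freq=True, transform="inverse")
        assert len(novel.attrs["predictors"]) == 4
        assert len(existing.attrs["predictors"]) == 5
        assert existing.attrs["predictors"][-1] == "log_word_freq"

    def test_additive_proximities_collapse_to_shared_predictor(self, world):
        # equal-norm constituent vectors make the additive model's two
        # proximities identical, so the design keeps only one of them
        ds, prox = world
        design = prepare_design(ds.behaviour["rating"], ds.lexicon, prox, model="additive")
        assert design.attrs.get("collinear_proximities")
        assert "prox_c2" not in design.attrs["predictors"]

    def test_unjoinable_items_are_dropped(self, world):
        ds, prox = world
        items = ds.behaviour["rating"].copy()
        items.loc[0, "item"] = "nonexistent"
        design = prepare_design(items, ds.lexicon, prox, model="caoss")
        assert len(design) == len(items) - 1


class TestCompareModels:
    def _result(self, label, loglik, n=100, k=8):
        fe = [FixedEffect("intercept", 1.0, 0.1, 10.0, 50.0, 0.0, None)]
        return AnalysisResult(fixed_effects=fe, var_components={}, var_resid=1.0,
                              loglik=loglik, n_items=n, n_params=k, model_label=label)

    def test_ranking_and_delta_aic(self):
        cmp = compare_models([self._result("a", -100.0), self._result("b", -90.0)])
        assert list(cmp["model"]) == ["b", "a"]
        assert cmp["delta_aic"].iloc[1] == pytest.approx(20.0)
        assert bool(cmp["winner"].iloc[0])

    def test_tie_keeps_input_order(self):
        cmp = compare_models([self._result("first", -50.0), self._result("second", -50.0)])
        assert list(cmp["model"]) == ["first", "second"]

    def test_different_row_counts_rejected(self):
        with pytest.raises(ValueError, match="row counts"):
            compare_models([self._result("a", -1.0, n=100), self._result("b", -1.0, n=99)])

    def test_true_model_omitting_null_predictor_usually_wins(self):
        wins = 0
        n_rep = 20
        for rep, ss in enumerate(np.random.SeedSequence(99).spawn(n_rep)):
            rng = np.random.default_rng(ss)
            df = simulate_crossed(rng, 250, 10, 10, (1.0, 0.8, 0.0), 0.2, 0.2, 0.5, p=2)
            with_null = fit_lmm(df, "y", ["x1", "x2"], model_label="full")
            without = fit_lmm(df, "y", ["x1"], model_label="reduced")
            if compare_models([with_null, without])["model"].iloc[0] == "reduced":
                wins += 1
        assert wins > n_rep / 2


class TestICC:
    def test_identical_raters_give_one(self):
        R = np.tile(np.array([1.0, 2.0, 3.0, 4.0])[:, None], (1, 5))
        for model, type_, unit in [("oneway", "consistency", "single"),
                                   ("twoway", "consistency", "average"),
                                   ("twoway", "agreement", "single")]:
            assert icc(R, model=model, type=type_, unit=unit) == pytest.approx(1.0)

    def test_matches_pingouin_oracle_on_random_matrices(self):
        import pingouin
        rng = np.random.default_rng(10)
        variants = [("oneway", "consistency", "single", "ICC(1,1)"),
                    ("twoway", "agreement", "single", "ICC(A,1)"),
                    ("twoway", "consistency", "single", "ICC(C,1)"),
                    ("oneway", "consistency", "average", "ICC(1,k)"),
                    ("twoway", "agreement", "average", "ICC(A,k)"),
                    ("twoway", "consistency", "average", "ICC(C,k)")]
        for _ in range(24):
            n, k = rng.integers(4, 9), rng.integers(3, 6)
            R = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
            long = pd.DataFrame({
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": R.ravel(),
            })
            ref = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                           ratings="scores").set_index("Type")["ICC"]
            for model, type_, unit, code in variants:
                assert icc(R, model=model, type=type_, unit=unit) == pytest.approx(
                    ref[code], abs=1e-10), (model, type_, unit)

    def test_pure_noise_ratings_give_near_zero(self):
        rng = np.random.default_rng(11)
        R = rng.normal(3.0, 1.0, (500, 30))
        assert abs(icc(R)) < 0.05

    def test_too_few_raters_rejected(self):
        with pytest.raises(ValueError):
            icc(np.array([[1.0], [2.0]]))

    def test_incomplete_rows_are_dropped(self):
        R = np.array([[1.0, 1.1, 0.9], [2.0, 2.2, np.nan],
                      [3.0, 2.9, 3.1], [4.0, 4.1, 3.9]])
        complete = R[[0, 2, 3]]
        assert icc(R) == pytest.approx(icc(complete))


class TestAccuracyFilter:
    def test_boundary_is_strictly_less_than(self):
        items = pd.DataFrame({"item": list("abc"), "accuracy": [0.69, 0.70, 0.71]})
        surviving, report = accuracy_filter(items)
        assert len(surviving) == 2
        assert report["n_after"] == 2

    def test_no_drops_reports_zero_percent(self):
        items = pd.DataFrame({"item": list("ab"), "accuracy": [0.9, 0.95]})
        _, report = accuracy_filter(items)
        assert report["drop_rate_percent"] == 0.0

    def test_hand_counted_drop_rate(self):
        acc = [0.5, 0.6, 0.65] + [0.8] * 7
        items = pd.DataFrame({"item": [str(i) for i in range(10)], "accuracy": acc})
        surviving, report = accuracy_filter(items)
        assert len(surviving) == 7
        assert report["drop_rate_percent"] == 30.0


def _result_with(effects):
    fes = [FixedEffect("intercept", 1.0, 0.1, 10.0, 50.0, 0.0, None)]
    for name, est, t in effects:
        fes.append(FixedEffect(name, est, 0.1, t, 50.0, 0.01, 0.1))
    return AnalysisResult(fixed_effects=fes, var_components={}, var_resid=1.0,
                          loglik=-10.0, n_items=100, n_params=5)


class TestSpeedAccuracyCheck:
    def test_slower_and_less_accurate_is_concordant(self):
        # inverse-RT coefficient < 0 means slower; accuracy < 0 means less accurate
        rt = _result_with([("prox_c1", -0.2, -5.0)])
        acc = _result_with([("prox_c1", -0.4, -4.0)])
        out = speed_accuracy_check(rt, acc)
        assert out["overall"] == "no trade-off"

    def test_faster_but_less_accurate_is_flagged(self):
        rt = _result_with([("prox_c1", 0.2, 5.0)])
        acc = _result_with([("prox_c1", -0.4, -4.0)])
        assert speed_accuracy_check(rt, acc)["overall"] == "trade-off"

    def test_weak_effects_are_inconclusive(self):
        rt = _result_with([("prox_c1", 0.01, 0.5)])
        acc = _result_with([("prox_c1", -0.01, -0.4)])
        assert speed_accuracy_check(rt, acc)["overall"] == "inconclusive"


def test_empirical_logit_is_monotone_and_finite_at_extremes():
    n = np.full(4, 33.0)
    acc = np.array([0.0, 0.5, 0.9, 1.0])
    el = empirical_logit(acc, n)
    assert np.all(np.diff(el) > 0)
    assert np.all(np.isfinite(el))
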