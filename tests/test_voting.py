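"""Signal-to-noise weighted voting: statistic, estimator, wrappers."""
import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import ipfkinome as ik
from ipfkinome.panel import ValidationError
from ipfkinome.voting import WeightedVotingClassifier, signal_to_noise


class TestSignalToNoise:
    def test_closed_form_and_zero(self):
        # mu 2 vs 0, both SDs 0.5 -> S = 2
        pos = [1.5, 2.5]  # mean 2, pop SD 0.5
        neg = [-0.5, 0.5]
        assert signal_to_noise(pos, neg) == pytest.approx(2.0)
        assert signal_to_noise([1, 2, 3], [1, 2, 3]) == 0.0

    def test_matches_direct_formula(self, rng):
        for _ in range(25):
            a = rng.normal(3, 2, 3)
            b = rng.normal(0, 1, 3)
            expected = (a.mean() - b.mean()) / (a.std() + b.std())
            assert signal_to_noise(a, b) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            signal_to_noise([1.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="degenerate"):
            signal_to_noise([2.0, 2.0], [1.0, 1.0])


def _toy_training():
    """Two informative genes: one induced (mu 4 vs 0), one suppressed."""
    X = pd.DataFrame({
        "up": [3.0, 5.0, -1.0, 1.0],
        "down": [-2.0, 0.0, 3.0, 5.0],
        "flat": [1.0, 1.2, 0.9, 1.1],
    }, index=["p1", "p2", "n1", "n2"])
    y = np.array(["severe", "severe", "non_severe", "non_severe"])
    return X, y


class TestWeightedVotingClassifier:
    def test_weights_and_boundaries_closed_form(self):
        X, y = _toy_training()
        est = WeightedVotingClassifier(positive_class="severe").fit(X, y)
        by_gene = dict(zip(est.feature_names_in_[est.selected_features_],
                           zip(est.weights_, est.boundaries_,
                               est.gene_classes_)))
        # "up": mu 4 vs 0, both pop SDs 1 -> S = 2, b = 2
        w, b, cls = by_gene["up"]
        assert (w, b, cls) == (pytest.approx(2.0), pytest.approx(2.0),
                               "induced")
        # "down": mu -1 vs 4, both pop SDs 1 -> S = -2.5, b = 1.5
        w, b, cls = by_gene["down"]
        assert (w, b, cls) == (pytest.approx(-2.5), pytest.approx(1.5),
                               "suppressed")
        assert "flat" not in by_gene

    def test_fit_is_deterministic(self):
        X, y = _toy_training()
        a = WeightedVotingClassifier(positive_class="severe").fit(X, y)
        b = WeightedVotingClassifier(positive_class="severe").fit(X, y)
        np.testing.assert_array_equal(a.weights_, b.weights_)
        np.testing.assert_array_equal(a.boundaries_, b.boundaries_)

    def test_scores_match_loop_oracle(self, rng):
        X, y = _toy_training()
        est = WeightedVotingClassifier(positive_class="severe").fit(X, y)
        T = rng.normal(0, 3, (6, 3))
        totals = est.decision_function(T)
        names = list(X.columns)
        sel = [names[i] for i in est.selected_features_]
        for r in range(6):  # naive per-gene vote summation
            total = 0.0
            for k, g in enumerate(sel):
                total += est.weights_[k] * (T[r, names.index(g)]
                                            - est.boundaries_[k])
            assert totals[r] == pytest.approx(total, abs=1e-9)

    def test_label_swap_antisymmetry(self, rng):
        X, y = _toy_training()
        a = WeightedVotingClassifier(positive_class="severe").fit(X, y)
        b = WeightedVotingClassifier(positive_class="non_severe").fit(X, y)
        T = rng.normal(0, 3, (5, 3))
        np.testing.assert_allclose(a.weights_, -b.weights_, rtol=1e-12)
        np.testing.assert_allclose(a.decision_function(T),
                                   -b.decision_function(T), rtol=1e-9)

    def test_affine_shift_of_one_gene_moves_boundary_only(self):
        X, y = _toy_training()
        a = WeightedVotingClassifier(positive_class="severe").fit(X, y)
        X2 = X.copy()
        X2["up"] += 10.0
        b = WeightedVotingClassifier(positive_class="severe").fit(X2, y)
        names = list(X.columns)
        k = [names[i] for i in a.selected_features_].index("up")
        assert b.boundaries_[k] == pytest.approx(a.boundaries_[k] + 10.0)
        np.testing.assert_allclose(a.weights_, b.weights_, rtol=1e-12)
        T = np.random.default_rng(0).normal(0, 3, (5, 3))
        T2 = T.copy()
        T2[:, names.index("up")] += 10.0
        np.testing.assert_allclose(a.decision_function(T),
                                   b.decision_function(T2), atol=1e-9)

    def test_sklearn_params_and_clone(self):
        est = WeightedVotingClassifier(threshold=2.0, positive_class="severe")
        assert est.get_params()["threshold"] == 2.0
        c = clone(est)
        assert c.get_params() == est.get_params()

    def test_tie_predicts_non_severe_with_warning(self):
        X, y = _toy_training()
        est = WeightedVotingClassifier(positive_class="severe").fit(X, y)
        tied = np.array([[2.0, 1.5, 0.0]])  # every gene exactly at boundary
        with pytest.warns(UserWarning, match="tie"):
            assert est.predict(tied)[0] == "non_severe"

    def test_requires_two_classes_and_two_per_class(self):
        X, y = _toy_training()
        with pytest.raises(ValueError, match="two-class"):
            WeightedVotingClassifier().fit(X, ["a"] * 4)
        with pytest.raises(ValueError, match="at least 2"):
            WeightedVotingClassifier().fit(X, ["a", "b", "b", "b"])


class TestModelWrappers:
    def test_select_genes_by_mean_difference(self, tiny_sheet):
        genes = ["gi", "gs", "gn"]
        values = pd.DataFrame(0.0, index=genes, columns=tiny_sheet.samples)
        pos = ["S0", "S1"]  # P1 severe (Ashcroft 7, 6)
        neg = ["S2", "S3"]  # P1 moderate (3, 4)
        values.loc["gi", pos] = [2.0, 2.4]   # diff +1.2 -> induced
        values.loc["gi", neg] = [1.0, 1.0]
        values.loc["gs", pos] = [1.0, 1.0]   # diff -1.2 -> suppressed
        values.loc["gs", neg] = [2.0, 2.4]
        values.loc["gn", pos] = [1.5, 1.5]   # diff +0.5 -> unselected
        values.loc["gn", neg] = [1.0, 1.0]
        expr = ik.ExpressionMatrix(values, log_transformed=True)
        induced, suppressed = ik.select_genes(expr, tiny_sheet, "P1",
                                              scale="log2")
        assert induced == ["gi"]
        assert suppressed == ["gs"]
        ind_inf, sup_inf = ik.select_genes(expr, tiny_sheet, "P1",
                                           threshold=np.inf, scale="log2")
        assert ind_inf == [] and sup_inf == []

    def test_fit_model_matches_two_pass_recomputation(self, rng, tiny_sheet):
        values = pd.DataFrame(
            rng.normal(5, 2, (8, 11)),
            index=[f"g{i}" for i in range(8)], columns=tiny_sheet.samples)
        expr = ik.ExpressionMatrix(values, log_transformed=True)
        model = ik.fit_model(expr, tiny_sheet, "P1", scale="log2")
        pos, neg = ["S0", "S1"], ["S2", "S3"]
        for g in model.genes:  # independent recomputation of S and b
            a = values.loc[g, pos].to_numpy()
            b = values.loc[g, neg].to_numpy()
            S = (a.mean() - b.mean()) / (a.std() + b.std())
            assert model.table.loc[g, "weight"] == pytest.approx(S, abs=1e-12)
            assert model.table.loc[g, "boundary"] == pytest.approx(
                (a.mean() + b.mean()) / 2, abs=1e-12)

    def test_one_gene_model_scores_closed_form(self, tiny_sheet):
        table = pd.DataFrame({"class_label": ["induced"], "weight": [2.0],
                              "boundary": [1.0]}, index=["g"])
        model = ik.WeightedVotingModel(
            table=table, training_patient="P1", positive_samples=("S0",),
            negative_samples=("S2",), threshold=1.0, scale="log2",
            log_pseudocount=0.1)
        expr = ik.ExpressionMatrix(pd.DataFrame([[3.0]], index=["g"],
                                                columns=["S5"]),
                                   log_transformed=True)
        scores = ik.score_samples(model, expr)
        assert scores.loc["S5", "total_score"] == pytest.approx(4.0)
        assert scores.loc["S5", "predicted_class"] == "severe"

    def test_missing_model_gene_named(self, tiny_sheet, tiny_expr):
        model = ik.fit_model(ik.ExpressionMatrix(tiny_expr.values,
                                                 log_transformed=True),
                             tiny_sheet, "P1", threshold=0.0, scale="log2")
        reduced = ik.ExpressionMatrix(
            tiny_expr.values.drop(index=model.genes[0]), log_transformed=True)
        with pytest.raises(ValidationError, match=model.genes[0]):
            ik.score_samples(model, reduced)

    def test_scores_invariant_to_gene_order(self, rng, tiny_sheet):
        values = pd.DataFrame(
            rng.normal(5, 2, (8, 11)),
            index=[f"g{i}" for i in range(8)], columns=tiny_sheet.samples)
        expr = ik.ExpressionMatrix(values, log_transformed=True)
        model = ik.fit_model(expr, tiny_sheet, "P1", scale="log2",
                             threshold=0.5)
        shuffled = ik.ExpressionMatrix(
            values.loc[list(rng.permutation(values.index))],
            log_transformed=True)
        a = ik.score_samples(model, expr)["total_score"]
        b = ik.score_samples(model, shuffled)["total_score"]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_save_load_round_trip(self, tmp_path, rng, tiny_sheet):
        values = pd.DataFrame(
            rng.normal(5, 2, (8, 11)),
            index=[f"g{i}" for i in range(8)], columns=tiny_sheet.samples)
        expr = ik.ExpressionMatrix(values, log_transformed=True)
        model = ik.fit_model(expr, tiny_sheet, "P1", scale="log2",
                             threshold=0.5)
        p = tmp_path / "model.tsv"
        model.save(p)
        back = ik.WeightedVotingModel.load(p)
        assert back.training_patient == "P1"
        assert back.positive_samples == model.positive_samples
        np.testing.assert_allclose(back.table["weight"],
                                   model.table["weight"], rtol=1e-9)

    def test_training_patient_needs_both_strata(self, tiny_expr, tiny_sheet):
        with pytest.raises(ValidationError, match="each"):
            ik.fit_model(tiny_expr, tiny_sheet, "P2")  # only 1 per stratum


class TestEvaluateModel:
    def _scores(self, sheet, predicted):
        return pd.DataFrame({
            "total_score": [1.0 if p == "severe" else -1.0 for p in predicted],
            "predicted_class": predicted, "tie": False,
        }, index=sheet.samples)

    def test_perfect_and_inverted_accuracy(self, tiny_sheet):
        truth = [tiny_sheet.stratum_of(s) for s in tiny_sheet.samples]
        ev = ik.evaluate_model(self._scores(tiny_sheet, truth), tiny_sheet)
        assert ev.accuracy == 1.0
        inverted = ["severe" if t == "non_severe" else "non_severe"
                    for t in truth]
        ev = ik.evaluate_model(self._scores(tiny_sheet, inverted), tiny_sheet)
        assert ev.accuracy == 0.0
        assert int(ev.confusion.to_numpy().sum()) == len(truth)

    def test_unknown_sample_rejected(self, tiny_sheet):
        scores = self._scores(tiny_sheet, ["severe"] * 11)
        scores.index = [f"zz{i}" for i in range(11)]
        with pytest.raises(ValidationError, match="unknown"):
            ik.evaluate_model(scores, tiny_sheet)

    def test_random_predictions_hit_chance_level(self, rng):
        """Accuracy of random predictions vs balanced random strata averages
        0.5 within 3 SE over 500 replicates."""
        n = 100
        rows = [{"sample_id": f"s{i}", "patient_id": f"p{i}", "group": "IPF",
                 "ashcroft_score": 7 if i % 2 else 3, "segment_label": "x"}
                for i in range(n)]
        sheet = ik.SampleSheet(pd.DataFrame(rows).set_index("sample_id"))
        accs = np.empty(500)
        for r in range(500):
            predicted = np.where(rng.random(n) < 0.5, "severe", "non_severe")
            scores = pd.DataFrame({
                "total_score": np.where(predicted == "severe", 1.0, -1.0),
                "predicted_class": predicted, "tie": False,
            }, index=sheet.samples)
            accs[r] = ik.evaluate_model(scores, sheet).accuracy
        se = accs.std(ddof=1) / np.sqrt(500)
        assert abs(accs.mean() - 0.5) < 3 * se
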