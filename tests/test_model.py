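"""Classifier training, the probability blend, alpha search, feature selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncm6a.features import DEFAULT_CATALOG, FeatureCatalog
from lncm6a.metrics import evaluate, roc_auc
from lncm6a.model import (
    ALPHA_GRID,
    EnsembleModel,
    EnsemblePredictor,
    FeatureSelectionResult,
    RandomForestConfig,
    SiteClassifier,
    cv_auc,
    ensemble_probability,
    greedy_forward_selection,
    kfold_cv,
    load_model,
    predict_probability,
    rank_features,
    save_model,
    select_alpha_from_probs,
    train_classifier,
)

FAST = RandomForestConfig(n_estimators=60, seed=0)


def planted_data(rng, n=300, n_noise=10, effect=2.0):
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, n_noise + 1))
    X[:, 0] += effect * y
    cols = ["signal"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestTraining:
    def test_separable_feature_perfect_training_auc(self, rng):
        X, y = planted_data(rng, effect=50.0)
        clf = train_classifier(X, y, FAST)
        auc, _ = roc_auc(y, predict_probability(clf, X))
        assert auc == 1.0

    def test_label_permutation_gives_null_cv_auc(self, rng):
        X, y = planted_data(rng, n=500, effect=2.0)
        y_perm = rng.permutation(y)
        auc = cv_auc(X, y_perm, k=10, seed=0,
                     trainer=lambda a, b: train_classifier(a, b, FAST))
        assert 0.4 <= auc <= 0.6

    def test_seed_reproducible(self, rng):
        X, y = planted_data(rng)
        p1 = predict_probability(train_classifier(X, y, FAST), X)
        p2 = predict_probability(train_classifier(X, y, FAST), X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        X, _ = planted_data(rng, n=20)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, np.ones(20), FAST)


class TestEnsembleBlend:
    def test_degenerate_alphas(self, rng):
        p_m, p_lnc = rng.random(50), rng.random(50)
        assert np.array_equal(ensemble_probability(p_m, p_lnc, 0.0), p_lnc)
        assert np.array_equal(ensemble_probability(p_m, p_lnc, 1.0), p_m)

    def test_direct_substitution(self):
        assert ensemble_probability([0.5], [1.0], 0.3)[0] == pytest.approx(0.85)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ensemble_probability([0.5], [0.5], 1.2)
        with pytest.raises(ValueError):
            ensemble_probability([1.5], [0.5], 0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_bounded(self, pm, pl, pm2, alpha):
        base = ensemble_probability([pm], [pl], alpha)[0]
        assert 0.0 <= base <= 1.0
        bigger = ensemble_probability([max(pm, pm2)], [pl], alpha)[0]
        assert bigger >= base - 1e-12 or pm2 < pm


class TestSelectAlpha:
    def test_perfect_mrna_model_wins(self, rng):
        # p_m equal to the labels is perfect at alpha=1; any blend with at
        # least half its weight on p_m is perfect too, so the smaller-alpha
        # tie rule lands on the smallest perfect grid member.
        y = rng.integers(0, 2, 200)
        alpha, curve = select_alpha_from_probs(
            y.astype(float), rng.random(200), y, ALPHA_GRID)
        assert curve[1.0] == 1.0
        assert curve[alpha] == max(curve.values()) == 1.0
        assert alpha == min(a for a, v in curve.items() if v == 1.0)

    def test_identical_models_tie_break_to_zero(self, rng):
        y = rng.integers(0, 2, 100)
        p = rng.random(100)
        alpha, _ = select_alpha_from_probs(p, p, y, ALPHA_GRID)
        assert alpha == 0.0

    def test_alpha_in_grid_and_beats_endpoints(self, rng):
        y = rng.integers(0, 2, 300)
        p_m = np.clip(y * 0.4 + rng.random(300) * 0.6, 0, 1)
        p_lnc = np.clip(y * 0.4 + rng.random(300) * 0.6, 0, 1)
        alpha, curve = select_alpha_from_probs(p_m, p_lnc, y, ALPHA_GRID)
        assert alpha in ALPHA_GRID
        assert curve[alpha] >= max(curve[0.0], curve[1.0]) - 1e-12

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            select_alpha_from_probs([0.5], [0.5], [1], grid=[])


class TestKFold:
    def test_leave_one_out_covers_each_row_once(self, rng):
        X, y = planted_data(rng, n=24)
        oof, folds = kfold_cv(X, y, k=24, seed=0,
                              trainer=lambda a, b: train_classifier(a, b, FAST))
        assert len(oof) == 24 and not np.isnan(oof).any()
        assert all(f["n"] == 1 for f in folds)

    def test_fold_sizes_differ_by_at_most_one(self, rng):
        X, y = planted_data(rng, n=103)
        _, folds = kfold_cv(X, y, k=10, seed=0,
                            trainer=lambda a, b: train_classifier(a, b, FAST))
        sizes = [f["n"] for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_pooled_oof_metrics_consistent_with_metrics_module(self, rng):
        X, y = planted_data(rng, n=120)
        oof, _ = kfold_cv(X, y, k=5, seed=0,
                          trainer=lambda a, b: train_classifier(a, b, FAST))
        rep = evaluate(y, oof)
        auc, _ = roc_auc(y, oof)
        assert rep.auc == auc


class TestFeatureSelection:
    def test_planted_signal_ranks_first(self, rng):
        X, y = planted_data(rng, n=250, n_noise=8, effect=3.0)
        ranked = rank_features(X, y, k=5, seed=0,
                               trainer=lambda a, b: train_classifier(a, b, FAST))
        assert ranked[0] == "signal"
        assert sorted(ranked) == sorted(X.columns)

    def test_greedy_selects_informative_prefix(self, rng):
        # Three sample clusters, each separable by exactly one informative
        # feature: all three are needed for full separation, so the AUC
        # curve rises to 1.0 at prefix 3 and the shortest-max rule stops there.
        n = 300
        y = rng.integers(0, 2, n)
        cluster = rng.integers(0, 3, n)
        informative = rng.normal(size=(n, 3))
        for i in range(3):
            informative[cluster == i, i] += 6.0 * y[cluster == i]
        noise = rng.normal(size=(n, 20))
        X = pd.DataFrame(np.hstack([informative, noise]),
                         columns=[f"inf{i}" for i in range(3)]
                         + [f"noise{i}" for i in range(20)])
        trainer = lambda a, b: train_classifier(a, b, FAST)  # noqa: E731
        ranked = rank_features(X, y, k=5, seed=0, trainer=trainer)
        res = greedy_forward_selection(ranked, X, y, k=5, seed=0, trainer=trainer)
        assert len(res.auc_curve) == X.shape[1]
        assert res.selected_size <= 10
        assert set(f"inf{i}" for i in range(3)) <= set(res.selected_features)
        assert res.auc_curve[res.selected_size - 1] == max(res.auc_curve)

    def test_single_feature_input(self, rng):
        X, y = planted_data(rng, n=100, n_noise=0)
        res = greedy_forward_selection(["signal"], X, y, k=5, seed=0,
                                       trainer=lambda a, b: train_classifier(a, b, FAST))
        assert isinstance(res, FeatureSelectionResult)
        assert res.selected_size == 1 and len(res.auc_curve) == 1


class TestModelResultsApi:
    def test_fit_evaluate_summary(self, rng):
        X, y = planted_data(rng, n=200, effect=3.0)
        res = SiteClassifier(X, y, config=FAST).fit()
        rep = res.evaluate(X, y)
        assert rep.auc > 0.9
        text = res.summary(X, y)
        assert "AUC" in text and "trees" in text
        assert res.feature_importances.idxmax() == "signal"

    def test_from_dataframe(self, rng):
        X, y = planted_data(rng, n=100)
        frame = X.assign(label=y)
        model = SiteClassifier.from_dataframe(frame, config=FAST)
        assert model.X.shape == (100, X.shape[1])

    def test_ensemble_model_blend_never_below_endpoints(self, rng):
        X, y = planted_data(rng, n=240, effect=1.5)
        half = 120
        res_m = SiteClassifier(X[:half], y[:half], config=FAST).fit()
        res_l = SiteClassifier(X[half:], y[half:], config=FAST).fit()
        X_val, y_val = planted_data(rng, n=150, effect=1.5)
        ens = EnsembleModel(res_m, res_l).fit(X_val, y_val)
        assert ens.alpha in ALPHA_GRID
        curve = ens.auc_curve
        assert curve[ens.alpha] >= max(curve[0.0], curve[1.0]) - 0.001
        assert "alpha" in ens.summary()
        rep = ens.evaluate(X_val, y_val)
        assert 0 <= rep.auc <= 1


class TestSerialization:
    def test_round_trip_and_catalog_guard(self, tmp_path, rng):
        X, y = planted_data(rng, n=80)
        clf = train_classifier(X, y, FAST)
        path = tmp_path / "model.bin"
        save_model(path, clf, DEFAULT_CATALOG, mode="full_transcript",
                   rna_class="lncRNA", alpha=0.3, seeds={"train": 0})
        loaded, meta = load_model(path, DEFAULT_CATALOG)
        assert meta["alpha"] == 0.3
        assert np.array_equal(predict_probability(loaded, X),
                              predict_probability(clf, X))

        other = FeatureCatalog()
        other.names = list(other.names)
        other.names[0] = "renamed"
        with pytest.raises(ValueError, match="catalog hash mismatch"):
            load_model(path, other)

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "junk.bin"
        p.write_bytes(b"not a model")
        with pytest.raises(ValueError, match="magic"):
            load_model(p)
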