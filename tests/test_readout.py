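import numpy as np
import pandas as pd
import pytest

from vvsreadout import (
    CategoryReadout,
    FeatureMatrix,
    ReadoutConfig,
    aggregate_morph_level,
    evaluate_random_splits,
    evaluate_sequence_holdout,
    train_readout,
)
from vvsreadout.behavior import ObserverParams, simulate_observer
from vvsreadout.readout import _select_c


def _labelled_features(n=40, d=5, signal=True, seed=0):
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    X = rng.normal(size=(n, d))
    if signal:
        X[:, 0] += 3.0 * y
    return X, y


class TestTrainReadout:
    def test_separable_feature_classified_perfectly(self):
        X = np.array([[0.0], [1.0]] * 20)
        y = np.array([0, 1] * 20)
        fitted = train_readout(X, y, ReadoutConfig(seed=0))
        assert (fitted.predict_label(X) == y).all()

    def test_permuted_labels_give_chance_accuracy(self):
        from sklearn.model_selection import train_test_split

        X, y = _labelled_features(n=40, signal=False, seed=1)
        rng = np.random.default_rng(2)
        accs = []
        for perm in range(100):
            yp = rng.permutation(y)
            # stratify so train/test base rates match (otherwise the intercept
            # tracks the train base rate and the null sits below 0.5)
            tr, te = train_test_split(np.arange(40), train_size=0.8,
                                      random_state=perm, stratify=yp)
            fitted = train_readout(X[tr], yp[tr], ReadoutConfig(seed=0))
            accs.append((fitted.predict_label(X[te]) == yp[te]).mean())
        se = np.sqrt(0.25 / (100 * 8))
        assert abs(np.mean(accs) - 0.5) < 3 * se + 0.02

    def test_all_zero_features_predict_base_rate(self):
        X = np.zeros((30, 4))
        y = np.array([1] * 20 + [0] * 10)
        fitted = train_readout(X, y, ReadoutConfig(seed=0))
        probs = fitted.predict_prob(X)
        assert np.allclose(probs, 20 / 30, atol=0.01)

    def test_single_class_error_names_missing_class(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="dog"):
            train_readout(X, np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="cat"):
            train_readout(X, np.ones(10, dtype=int))


class TestRandomSplits:
    def test_iteration_count_and_coverage_contract(self, fc6_full, morph_full):
        cfg = ReadoutConfig(n_iterations=30, seed=5)
        res = evaluate_random_splits(fc6_full, morph_full, cfg)
        # extra splits are drawn (and recorded) only until every image has
        # been held out at least once
        assert res.n_iterations >= 30
        held = res.per_iteration["image_id"].unique()
        assert set(held) == set(morph_full.image_ids)
        per_iter = res.per_iteration.groupby("iteration").size()
        n_test = len(morph_full) - int(0.8 * len(morph_full))  # train size floors
        assert (per_iter == n_test).all()

    def test_identical_seeds_identical_results(self, fc6_full, morph_full):
        cfg = ReadoutConfig(n_iterations=5, seed=6)
        a = evaluate_random_splits(fc6_full, morph_full, cfg)
        b = evaluate_random_splits(fc6_full, morph_full, cfg)
        assert a.per_iteration.equals(b.per_iteration)

    def test_no_leakage_between_train_and_test(self, fc6_full, morph_full):
        cfg = ReadoutConfig(n_iterations=8, seed=7)
        model = CategoryReadout.from_stimuli(fc6_full, morph_full, cfg)
        for it in range(8):
            train, test = model._one_random_split(it)
            assert len(np.intersect1d(train, test)) == 0

    def test_inner_cv_ignores_anything_but_training_rows(self):
        X, y = _labelled_features(n=60, seed=3)
        cfg = ReadoutConfig(seed=0)
        c1 = _select_c(X[:48], y[:48], cfg, rng_seed=1)
        # perturbing rows outside the training set cannot change the chosen C
        X2 = X.copy()
        X2[48:] = 1e6
        c2 = _select_c(X2[:48], y[:48], cfg, rng_seed=1)
        assert c1 == c2

    def test_too_few_images_rejected(self):
        X, y = _labelled_features(n=8, seed=4)
        fm = FeatureMatrix(X, [f"i{k}" for k in range(8)], "toy")
        model = CategoryReadout(fm, y, morph_levels=np.where(y == 1, 100, 0),
                                config=ReadoutConfig(seed=0))
        with pytest.raises(ValueError, match="at least 10"):
            model.fit()


class TestSequenceHoldout:
    def test_rotation_holds_every_image_out_exactly_once(self, fc6_full, morph_full):
        res = evaluate_sequence_holdout(fc6_full, morph_full, ReadoutConfig(seed=8))
        counts = res.per_iteration.groupby("image_id").size()
        assert (counts == 1).all()
        assert len(counts) == len(morph_full)
        assert res.n_iterations == 7  # one fold per sequence

    def test_train_and_test_sequences_disjoint(self, fc6_full, morph_full):
        res = evaluate_sequence_holdout(fc6_full, morph_full, ReadoutConfig(seed=8))
        seq_of = {iid: morph_full.index[iid][1] for iid in morph_full.image_ids}
        for it, grp in res.per_iteration.groupby("iteration"):
            held = {seq_of[i] for i in grp["image_id"]}
            assert len(held) == 1

    def test_single_sequence_rejected(self):
        X, y = _labelled_features(n=20, seed=5)
        fm = FeatureMatrix(X, [f"i{k}" for k in range(20)], "toy")
        model = CategoryReadout(
            fm, y, morph_levels=np.where(y == 1, 100, 0),
            sequence_ids=np.array(["A"] * 20),
            config=ReadoutConfig(split_mode="sequence_holdout", seed=0),
        )
        with pytest.raises(ValueError, match="2 sequences"):
            model.fit()


class TestAggregation:
    def test_simple_proportion(self):
        df = pd.DataFrame(
            {"morph_level_pct": [30] * 4, "predicted_label": [1, 0, 1, 0], "iteration": [0, 0, 1, 1]}
        )
        curve = aggregate_morph_level(df)
        assert curve.loc[0, "prop_dog"] == pytest.approx(0.5)

    def test_flat_observer_curve_is_flat(self, morph_small):
        table = simulate_observer(morph_small, ObserverParams(slope=0.0, lapse=0.0,
                                  image_effect_sd=0.0, seed=30), n_reps=200)
        curve = aggregate_morph_level(table)
        assert (np.abs(curve["prop_dog"] - 0.5) < 0.1).all()

    def test_matches_independent_groupby_oracle(self, tmp_path, morph_small):
        table = simulate_observer(morph_small, ObserverParams(seed=31), n_reps=6)
        path = table.to_csv(tmp_path / "c.csv")
        curve = aggregate_morph_level(table).set_index("morph_level_pct")
        # brute-force oracle straight off the raw CSV
        raw = pd.read_csv(path)
        for level, grp in raw.groupby("morph_level_pct"):
            assert abs(curve.loc[level, "prop_dog"] - grp["response"].mean()) < 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_morph_level(pd.DataFrame(columns=["morph_level_pct", "response"]))

    def test_missing_levels_absent_not_imputed(self):
        df = pd.DataFrame({"morph_level_pct": [0, 100], "predicted_label": [0, 1], "iteration": [0, 0]})
        curve = aggregate_morph_level(df)
        assert list(curve["morph_level_pct"]) == [0, 100]


class TestReadoutConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(c_grid=()), dict(c_grid=(1.0, -1.0)), dict(c_grid=(2.0, 1.0)),
         dict(train_fraction=1.2), dict(split_mode="bootstrap")],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            ReadoutConfig(**kwargs)
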