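import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from vvsreadout import (
    ChoiceTable,
    ObserverParams,
    between_subject_consistency,
    compare_groups,
    empirical_percentile,
    fit_model_to_behavior,
    simulate_observer,
    split_half_reliability,
)


def _extreme_only(stim, table):
    levels = {iid: stim.index[iid][2] for iid in stim.image_ids}
    keep = table.df["image_id"].map(lambda i: levels[i] in (0, 100))
    return ChoiceTable(table.df[keep])


class TestSplitHalfReliability:
    def test_deterministic_observer_perfectly_reliable(self, morph_small):
        params = ObserverParams(slope=10.0, lapse=0.0, image_effect_sd=0.0, seed=1)
        table = _extreme_only(morph_small, simulate_observer(morph_small, params, n_reps=6))
        dist = split_half_reliability(table, level="image", n_iter=20, seed=0, min_reps=2)
        assert np.allclose(dist.values, 1.0)

    def test_reliability_grows_with_image_effects(self, morph_small):
        meds = []
        for sd in (0.0, 2.0):
            params = ObserverParams(slope=0.0, lapse=0.0, image_effect_sd=sd, seed=2)
            table = simulate_observer(morph_small, params, n_reps=10)
            meds.append(split_half_reliability(table, "image", n_iter=60, seed=1, min_reps=2).median)
        assert meds[1] > meds[0]
        assert meds[1] >= 0.7  # strong image effects at 10 reps

    def test_estimator_consistency_on_repetition_ladder(self, morph_small):
        params = ObserverParams(slope=0.05, lapse=0.02, image_effect_sd=1.5, seed=3)
        meds = []
        for reps in (4, 8, 16, 64):
            table = simulate_observer(morph_small, params, n_reps=reps)
            meds.append(split_half_reliability(table, "image", n_iter=50, seed=2, min_reps=2).median)
        assert all(b > a for a, b in zip(meds, meds[1:]))

    def test_insufficient_repetitions_refused_by_default(self, morph_small):
        table = simulate_observer(morph_small, ObserverParams(seed=4), n_reps=4)
        with pytest.raises(ValueError, match="insufficient repetitions"):
            split_half_reliability(table, level="image", n_iter=5, seed=0)  # default floor 8

    def test_morph_level_analysis_pools_images(self, morph_small):
        table = simulate_observer(morph_small, ObserverParams(seed=5), n_reps=2)
        dist = split_half_reliability(table, level="morph", n_iter=10, seed=0)
        assert len(dist) == 10
        assert dist.level == "morph"


class TestBetweenSubject:
    def test_copied_subject_matches_within_distribution(self, morph_small):
        params = ObserverParams(slope=0.05, image_effect_sd=1.0, seed=6)
        a = simulate_observer(morph_small, params, n_reps=10, subject_id="a")
        clone = ChoiceTable(a.df.assign(subject_id="b"))
        within = split_half_reliability(a, "image", n_iter=150, seed=3, min_reps=2)
        between = between_subject_consistency(a, clone, "image", n_iter=150, seed=4, min_reps=2)
        assert ks_2samp(within.values, between.values).pvalue > 0.01

    def test_within_at_least_between_across_seeds(self, morph_small):
        wins = 0
        for seed in range(20):
            pa = ObserverParams(slope=0.05, image_effect_sd=1.0, seed=100 + seed)
            pb = ObserverParams(slope=0.05, image_effect_sd=1.0, seed=200 + seed)
            a = simulate_observer(morph_small, pa, n_reps=10, subject_id="a")
            b = simulate_observer(morph_small, pb, n_reps=10, subject_id="b")
            within = split_half_reliability(a, "image", n_iter=40, seed=seed, min_reps=2)
            between = between_subject_consistency(a, b, "image", n_iter=40, seed=seed, min_reps=2)
            wins += within.median >= between.median
        assert wins == 20  # independent image offsets: within dominates between

    def test_equal_power_contract(self, morph_small):
        # both halves draw the same number of trials when counts match
        params = ObserverParams(seed=7)
        a = simulate_observer(morph_small, params, n_reps=10, subject_id="a")
        b = simulate_observer(morph_small, ObserverParams(seed=8), n_reps=10, subject_id="b")
        dist = between_subject_consistency(a, b, "image", n_iter=5, seed=0, min_reps=2)
        assert len(dist) == 5  # a distribution, not a point estimate

    def test_disjoint_items_rejected(self, morph_small):
        params = ObserverParams(seed=9)
        a = simulate_observer(morph_small, params, n_reps=10, subject_id="a")
        b = ChoiceTable(a.df.assign(image_id=a.df["image_id"] + "_x", subject_id="b"))
        with pytest.raises(ValueError, match="share no items"):
            between_subject_consistency(a, b, "image", n_iter=5, seed=0, min_reps=2)


class TestModelBehaviorFit:
    def test_identity_and_affine(self):
        model = np.linspace(0.1, 0.9, 23)
        fit = fit_model_to_behavior(model, model)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.beta == pytest.approx(1.0)
        assert fit.df == 21  # 23 points -> df 21
        affine = fit_model_to_behavior(model, 2 * model + 1)
        assert affine.r_squared == pytest.approx(1.0)
        assert affine.beta == pytest.approx(2.0)

    def test_zero_variance_model_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_model_to_behavior(np.ones(10), np.linspace(0, 1, 10))


class TestEmpiricalPercentile:
    def test_direct_count_examples(self):
        ref = np.arange(0.1, 1.05, 0.1)  # 0.1 ... 1.0
        assert empirical_percentile(0.55, ref) == pytest.approx(0.5)
        assert empirical_percentile(-1.0, ref) == 0.0
        assert empirical_percentile(2.0, ref) == 1.0

    def test_median_of_odd_reference_maps_near_half(self):
        ref = np.linspace(0, 1, 101)
        assert abs(empirical_percentile(np.median(ref), ref) - 0.5) < 0.01

    def test_vector_model_reports_median_percentile(self):
        ref = np.linspace(0, 1, 100)
        fits = np.array([0.25, 0.5, 0.75])
        assert empirical_percentile(fits, ref) == pytest.approx(0.51, abs=0.02)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            empirical_percentile(0.5, np.array([]))


class TestGroupComparison:
    def test_identical_curves(self):
        curve = pd.DataFrame({"experiment_id": ["e"] * 11, "morph_level_pct": range(0, 101, 10),
                              "prop_dog": np.linspace(0, 1, 11)})
        stat = compare_groups(curve, curve)
        assert stat.r_squared == pytest.approx(1.0)
        assert stat.kind == "ols_slope_F"

    def test_df_shape_for_88_points(self):
        rng = np.random.default_rng(3)
        base = {"experiment_id": np.repeat([f"e{k}" for k in range(4)], 22),
                "morph_level_pct": np.tile(np.arange(22), 4)}
        a = pd.DataFrame({**base, "prop_dog": rng.uniform(size=88)})
        b = pd.DataFrame({**base, "prop_dog": rng.uniform(size=88)})
        stat = compare_groups(a, b)
        assert stat.df == (1, 86)

    def test_independent_flat_observers_show_no_association(self, morph_small):
        from vvsreadout import aggregate_morph_level

        pa = ObserverParams(slope=0.0, lapse=0.0, image_effect_sd=0.0, seed=10)
        pb = ObserverParams(slope=0.0, lapse=0.0, image_effect_sd=0.0, seed=11)
        a = aggregate_morph_level(simulate_observer(morph_small, pa, n_reps=30))
        b = aggregate_morph_level(simulate_observer(morph_small, pb, n_reps=30))
        a["experiment_id"] = "e"
        b["experiment_id"] = "e"
        stat = compare_groups(a, b)
        assert stat.r_squared < 0.5
        assert stat.p > 0.01

    def test_mismatched_points_rejected(self):
        a = pd.DataFrame({"morph_level_pct": [0, 10, 20], "prop_dog": [0.1, 0.2, 0.3]})
        b = pd.DataFrame({"morph_level_pct": [0, 10, 30], "prop_dog": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="different"):
            compare_groups(a, b)
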