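import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from vvsreadout import (
    OddityModel,
    OddityTrial,
    PerformanceVector,
    aggregate_objects,
    build_pseudo_experiments,
    compare_performance_vectors,
    estimate_trial_outcome,
    sample_trial,
)
from vvsreadout.oddity import synthetic_object_features


@pytest.fixture(scope="module")
def synth_pool():
    return synthetic_object_features(n_objects=4, n_views=12, dim=12, separation=2.0, seed=3)


class TestTrialConstruction:
    def test_default_trial_count(self, synth_pool):
        index, _ = synth_pool
        sample = sample_trial(index, "o00", "o01", seed=1)
        trials = build_pseudo_experiments(sample, index, n_trials=52, seed=2)
        assert len(trials) == 52

    def test_sample_images_never_reappear(self, synth_pool):
        index, _ = synth_pool
        sample = sample_trial(index, "o00", "o01", seed=1)
        trials = build_pseudo_experiments(sample, index, n_trials=52, seed=2)
        used = {iid for t in trials for iid in t.image_ids}
        assert used.isdisjoint(sample.image_ids)

    def test_every_pseudo_trial_is_well_formed(self, synth_pool):
        index, _ = synth_pool
        sample = sample_trial(index, "o02", "o03", seed=4)
        for t in build_pseudo_experiments(sample, index, n_trials=30, seed=5):
            t.validate(index)
            assert t.pair_object(index) == "o02"
            assert t.oddity_object(index) == "o03"

    def test_oddity_position_uniform(self, synth_pool):
        index, _ = synth_pool
        sample = sample_trial(index, "o00", "o01", seed=1)
        positions = []
        for s in range(20):
            positions += [t.oddity_pos for t in build_pseudo_experiments(sample, index, 50, seed=s)]
        counts = np.bincount(positions, minlength=3)
        assert chisquare(counts).pvalue > 0.01

    def test_insufficient_views_error_states_requirement(self):
        index, _ = synthetic_object_features(n_objects=2, n_views=4, dim=4, separation=1.0, seed=0)
        sample = sample_trial(index, "o00", "o01", seed=1)
        with pytest.raises(ValueError, match="at least 4"):
            build_pseudo_experiments(sample, index, n_trials=10, seed=0)

    def test_malformed_trial_rejected(self, synth_pool):
        index, _ = synth_pool
        views = sorted(i for i, info in index.items() if info[0] == "o00")
        with pytest.raises(ValueError, match="differ"):
            OddityTrial(image_ids=tuple(views[:3]), oddity_pos=0).validate(index)


class TestOutcomeEstimation:
    def test_high_separation_solved(self):
        index, fm = synthetic_object_features(2, 12, 12, separation=8.0, seed=5)
        sample = sample_trial(index, "o00", "o01", seed=6)
        out = estimate_trial_outcome(sample, fm, index, n_pseudo=20, seed=7)
        assert out >= 0.95

    def test_structure_free_features_at_chance(self):
        outs = []
        for s in range(12):
            index, fm = synthetic_object_features(2, 12, 12, separation=0.0, seed=100 + s)
            sample = sample_trial(index, "o00", "o01", seed=s)
            outs.append(estimate_trial_outcome(sample, fm, index, n_pseudo=25, seed=s))
        se = np.std(outs) / np.sqrt(len(outs))
        assert abs(np.mean(outs) - 1 / 3) < 3 * se + 0.05

    def test_same_seed_identical_outcome(self, synth_pool):
        index, fm = synth_pool
        sample = sample_trial(index, "o00", "o01", seed=1)
        a = estimate_trial_outcome(sample, fm, index, n_pseudo=10, seed=9)
        b = estimate_trial_outcome(sample, fm, index, n_pseudo=10, seed=9)
        assert a == b

    def test_missing_feature_rows_named(self, synth_pool):
        index, fm = synth_pool
        sample = sample_trial(index, "o00", "o01", seed=1)
        from vvsreadout import FeatureMatrix

        truncated = FeatureMatrix(fm.matrix[:5], fm.image_ids[:5], fm.source)
        with pytest.raises(KeyError):
            estimate_trial_outcome(sample, truncated, index, n_pseudo=2, seed=0)


class TestAggregation:
    def test_all_ones(self):
        df = pd.DataFrame({"object_i": ["a", "a", "b", "b"], "object_j": ["b", "c", "a", "c"],
                           "outcome": [1.0] * 4})
        with pytest.raises(ValueError, match="paired identity"):
            aggregate_objects(df)  # c never appears as object_i
        df2 = pd.DataFrame({"object_i": ["a", "b", "c"], "object_j": ["b", "c", "a"],
                            "outcome": [1.0] * 3})
        vec = aggregate_objects(df2)
        assert np.allclose(vec.as_array(), 1.0)

    def test_hand_built_table_matches_arithmetic(self):
        df = pd.DataFrame(
            {"object_i": ["a", "a", "b", "b", "c", "c"],
             "object_j": ["b", "c", "a", "c", "a", "b"],
             "outcome": [1.0, 0.0, 0.5, 0.5, 0.25, 0.75]}
        )
        vec = aggregate_objects(df)
        assert vec.values["a"] == pytest.approx(0.5)
        assert vec.values["b"] == pytest.approx(0.5)
        assert vec.values["c"] == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_objects(pd.DataFrame(columns=["object_i", "object_j", "outcome"]))


class TestComparison:
    def test_identity_and_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        a = PerformanceVector({f"o{i}": v for i, v in enumerate(rng.uniform(0.3, 0.9, 32))})
        same = compare_performance_vectors(a, a, mode="slope")
        assert same.beta == pytest.approx(1.0)
        assert same.df == (1, 30)  # 32 objects
        paired = compare_performance_vectors(a, a, mode="paired_difference")
        assert paired.beta == pytest.approx(0.0)
        assert paired.statistic == pytest.approx(0.0, abs=1e-9)
        assert paired.df == 31

    def test_offset_recovered_by_paired_mode(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0.2, 0.7, 32)
        a = PerformanceVector({f"o{i}": v for i, v in enumerate(base)})
        b_vals = np.clip(base + 0.2 + rng.normal(0, 0.05, 32), 0, 1)
        b = PerformanceVector({f"o{i}": v for i, v in enumerate(b_vals)})
        stat = compare_performance_vectors(a, b, mode="paired_difference")
        ci_half = 3 * 0.05 / np.sqrt(32)
        assert abs(stat.beta - 0.2) < ci_half

    def test_mismatched_objects_rejected(self):
        a = PerformanceVector({"x": 0.5, "y": 0.5, "z": 0.5})
        b = PerformanceVector({"x": 0.5, "y": 0.5, "w": 0.5})
        with pytest.raises(ValueError, match="different object sets"):
            compare_performance_vectors(a, b)


class TestFullProtocol:
    def test_monotone_in_separation(self):
        perfs = []
        for sep in (0.0, 1.0, 4.0):
            index, fm = synthetic_object_features(3, 10, 12, separation=sep, seed=11)
            res = OddityModel(fm, index).fit(n_pseudo=8, seed=11)
            perfs.append(res.mean_performance())
        assert perfs[0] < perfs[1] < perfs[2]

    def test_feature_source_substitutability(self):
        # the same entry point consumes any FeatureMatrix: rendered-image pools
        # and synthetic population responses run the identical code path
        index, fm = synthetic_object_features(3, 8, 6, separation=3.0, seed=12)
        res = OddityModel(fm, index).fit(n_pseudo=5, seed=12)
        assert set(res.performance.values) == {"o00", "o01", "o02"}
        assert res.pairwise.shape[0] == 6  # ordered pairs
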