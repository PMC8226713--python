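import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thiolkinetics as tk
from thiolkinetics.ann import (
    FeatureEncoder,
    MLPEnsemble,
    TrainedMLP,
    default_grid,
    initial_weights,
    split_indices,
)
from thiolkinetics.errors import ConfigurationError, EncodingError

from conftest import make_dataset


def constant_member(level, n_inputs=18):
    """A linear-output network whose prediction is the constant `level`
    on the scaled target axis (all weights zero, output bias = level)."""
    spec = tk.MLPSpec(n_hidden=2, output_activation="linear")
    theta = np.zeros(n_inputs * 2 + 2 * 2 + 1)
    theta[-1] = level
    return TrainedMLP(spec=spec, theta=theta, n_inputs=n_inputs)


def percent_encoder():
    return FeatureEncoder.from_dict(
        {"time_min": 0.0, "time_max": 13.0, "temp_min": 4.0, "temp_max": 20.0,
         "target_min": 0.0, "target_max": 100.0}
    )


class TestEncoding:
    def test_one_hot_blocks(self, noisy_study_small):
        enc = FeatureEncoder().fit(noisy_study_small)
        row = make_dataset([("control", "raw", 4.0, 0.0, 1, 100.0)])
        X = enc.transform(row)
        assert X.shape == (1, 18)
        np.testing.assert_array_equal(X[0, :14], np.eye(14)[0])
        np.testing.assert_array_equal(X[0, 14:16], [1.0, 0.0])

    def test_width_is_18(self, noisy_study_small):
        X, y, enc = tk.encode_features(noisy_study_small)
        assert X.shape[1] == 14 + 2 + 2 == 18
        assert enc.width == 18

    def test_min_max_scaling_endpoints(self, noisy_study_small):
        X, _, _ = tk.encode_features(noisy_study_small)
        assert X[:, -2].min() == pytest.approx(0.0)
        assert X[:, -2].max() == pytest.approx(1.0)
        assert X[:, -1].min() == pytest.approx(0.0)
        assert X[:, -1].max() == pytest.approx(1.0)

    def test_unknown_treatment_rejected(self, noisy_study_small):
        enc = FeatureEncoder().fit(noisy_study_small)
        bad = make_dataset([("mint", "raw", 4.0, 0.0, 1, 90.0)])
        with pytest.raises(EncodingError, match="mint"):
            enc.transform(bad)


class TestSplit:
    def test_exact_70_15_15(self):
        tr, va, te = split_indices(100, seed=0)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_largest_remainder_on_101(self):
        tr, va, te = split_indices(101, seed=0)
        assert (len(tr), len(va), len(te)) == (71, 15, 15)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ConfigurationError):
            split_indices(100, ratios=(70, 20, 20))

    def test_same_seed_identical(self):
        a = split_indices(57, seed=9)
        b = split_indices(57, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    @settings(derandomize=True, max_examples=30)
    @given(n=st.integers(10, 500), seed=st.integers(0, 1000))
    def test_disjoint_and_exhaustive(self, n, seed):
        parts = split_indices(n, seed=seed)
        combined = np.concatenate(parts)
        assert len(combined) == n
        assert len(np.unique(combined)) == n


class TestTraining:
    def test_representable_linear_function(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(80, 5))
        y = 0.1 + X @ np.array([0.2, -0.1, 0.3, 0.05, 0.15])
        net = tk.train_mlp(tk.MLPSpec(n_hidden=2, max_iterations=300, seed=1), (X, y))
        assert net.training_r2 >= 0.999

    def test_zero_iterations_returns_initial_weights(self):
        rng = np.random.default_rng(1)
        X, y = rng.uniform(size=(20, 4)), rng.uniform(size=20)
        spec = tk.MLPSpec(n_hidden=3, max_iterations=0, seed=5)
        net = tk.train_mlp(spec, (X, y))
        np.testing.assert_array_equal(net.theta, initial_weights(spec, 4))
        assert net.training_error == pytest.approx(net.sos_error(X, y))
        assert net.n_iterations == 0

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        X, y = rng.uniform(size=(30, 4)), rng.uniform(size=30)
        spec = tk.MLPSpec(n_hidden=4, max_iterations=50, seed=3)
        a, b = tk.train_mlp(spec, (X, y)), tk.train_mlp(spec, (X, y))
        np.testing.assert_array_equal(a.theta, b.theta)

    @pytest.mark.parametrize("hidden", ["tanh", "logistic", "exponential"])
    @pytest.mark.parametrize("output", ["linear", "logistic", "tanh"])
    def test_all_activation_pairs_train(self, hidden, output):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(60, 4))
        y = np.clip(0.5 + 0.3 * X[:, 0] - 0.2 * X[:, 1], 0.05, 0.95)
        spec = tk.MLPSpec(
            n_hidden=4, hidden_activation=hidden, output_activation=output,
            max_iterations=150, seed=0,
        )
        net = tk.train_mlp(spec, (X, y))
        assert np.isfinite(net.training_error)
        assert net.training_r2 > 0.8


class TestSearchAndEnsemble:
    def test_grid_of_five_all_retained_sorted(self, noisy_study_small):
        grid = default_grid(hidden_sizes=(2, 3, 4, 5, 6), max_iterations=30)
        ens = tk.search_architectures(noisy_study_small, grid=grid, split_seed=1)
        errors = [m.validation_error for m in ens.members]
        assert errors == sorted(errors)
        assert len(ens.members) == 5

    def test_duplicate_specs_stable_order(self, noisy_study_small):
        spec = tk.MLPSpec(n_hidden=3, max_iterations=20, seed=0)
        ens = tk.search_architectures(
            noisy_study_small, grid=[spec] * 5, split_seed=1
        )
        thetas = [m.theta for m in ens.members]
        for other in thetas[1:]:
            np.testing.assert_array_equal(thetas[0], other)

    def test_n_keep_exceeding_grid_rejected(self, noisy_study_small):
        with pytest.raises(ConfigurationError):
            tk.search_architectures(
                noisy_study_small,
                grid=[tk.MLPSpec(n_hidden=3, max_iterations=5)],
            )

    def test_good_fit_on_synthetic_design(self, noisy_study_small):
        grid = default_grid(hidden_sizes=(8, 12, 16, 20, 24), max_iterations=200)
        ens = tk.search_architectures(noisy_study_small, grid=grid, split_seed=3)
        assert ens.summary["test_r2"].max() > 0.9

    def test_ensemble_of_identical_members_equals_member(self):
        members = [constant_member(0.9) for _ in range(5)]
        ens = MLPEnsemble(members=members, encoder=percent_encoder())
        obs = make_dataset([("control", "raw", 4.0, 1.0, 1, 50.0)])
        assert tk.ensemble_predict(ens, obs)[0] == pytest.approx(90.0)

    def test_ensemble_is_arithmetic_mean(self):
        members = [constant_member(v) for v in (0.8, 0.9, 1.0, 0.9, 0.9)]
        ens = MLPEnsemble(members=members, encoder=percent_encoder())
        obs = make_dataset([("basil", "cooked", 8.0, 2.0, 1, 50.0)])
        assert tk.ensemble_predict(ens, obs)[0] == pytest.approx(90.0)

    def test_member_count_enforced(self):
        with pytest.raises(ConfigurationError):
            MLPEnsemble(members=[constant_member(0.5)] * 4,
                        encoder=percent_encoder())

    def test_ensemble_rmse_at_most_worst_member(self, noisy_study_small):
        grid = default_grid(hidden_sizes=(2, 4, 6, 8, 10), max_iterations=50)
        ens = tk.search_architectures(noisy_study_small, grid=grid, split_seed=2)
        obs = noisy_study_small
        y = obs.data["sh_value"].to_numpy()
        ens_rmse = np.sqrt(np.mean((tk.ensemble_predict(ens, obs) - y) ** 2))
        member_rmses = []
        X = ens.encoder.transform(obs)
        for m in ens.members:
            pred = ens.encoder.descale_target(m.predict_scaled(X))
            member_rmses.append(np.sqrt(np.mean((pred - y) ** 2)))
        assert ens_rmse <= max(member_rmses) + 1e-12

    def test_prediction_invariant_to_row_order(self, noisy_study_small):
        grid = default_grid(hidden_sizes=(2, 3, 4, 5, 6), max_iterations=20)
        ens = tk.search_architectures(noisy_study_small, grid=grid, split_seed=4)
        frame = noisy_study_small.data
        shuffled = frame.sample(frac=1.0, random_state=0)
        a = tk.ensemble_predict(
            ens, tk.StudyDataset(shuffled.reset_index(drop=True))
        )
        b = tk.ensemble_predict(ens, noisy_study_small)
        np.testing.assert_allclose(a, b[shuffled.index.to_numpy()])

    def test_json_round_trip(self, noisy_study_small, tmp_path):
        grid = default_grid(hidden_sizes=(2, 3, 4, 5, 6), max_iterations=20)
        ens = tk.search_architectures(noisy_study_small, grid=grid, split_seed=5)
        path = tmp_path / "ensemble.json"
        ens.to_json(path)
        back = MLPEnsemble.from_json(path)
        np.testing.assert_allclose(
            back.predict(noisy_study_small), ens.predict(noisy_study_small)
        )
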