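import math

import numpy as np
import pytest

from fiberlearn import multitask as mt
from fiberlearn import nn
from fiberlearn.io import FiberImage


@pytest.fixture
def volume():
    rng = np.random.default_rng(0)
    return FiberImage(rng.normal(0, 1, (64, 96, 64)), spacing=(0.5, 0.5, 0.5))


class TestConfiguration:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            mt.TrialConfiguration(representation="2.5D_3")
        with pytest.raises(ValueError):
            mt.TrialConfiguration(prior_integration="SomePriors")
        with pytest.raises(ValueError):
            mt.TrialConfiguration(capacity=9)
        with pytest.raises(ValueError):
            mt.TrialConfiguration(batch_size=5)

    def test_capacity_parameter_counts_strictly_increase(self):
        counts = []
        for c in mt.CAPACITIES:
            model = mt.build_model(
                mt.TrialConfiguration(capacity=c, representation="2.5D_5"),
                n_tasks=3, n_priors=5, seed=0)
            counts.append(model.n_parameters())
        assert all(a < b for a, b in zip(counts, counts[1:]))


class TestRepresentation:
    def test_slice_offsets_in_voxels(self):
        assert mt.slice_indices(50, 20.0, 0.5, 101) == [10, 50, 90]
        assert mt.slice_indices(50, 1.0, 0.5, 101) == [48, 50, 52]

    def test_25d_channels_are_center_and_peripheral_slices(self, volume):
        cfg = mt.TrialConfiguration(representation="2.5D_5")
        x = mt.build_representation(volume, cfg)
        assert x.shape == (3, 96, 64)
        c = volume.shape[0] // 2
        assert np.array_equal(x[1], np.asarray(volume.voxels[c], dtype=float))
        assert np.array_equal(x[0], np.asarray(volume.voxels[c - 10], dtype=float))

    def test_offsets_clamped_to_volume(self):
        thin = FiberImage(np.random.default_rng(1).normal(0, 1, (16, 32, 32)))
        x = mt.build_representation(
            thin, mt.TrialConfiguration(representation="2.5D_20"))
        assert np.array_equal(x[0], np.asarray(thin.voxels[0], dtype=float))
        assert np.array_equal(x[2], np.asarray(thin.voxels[15], dtype=float))

    def test_3d_downsampling_extent_arithmetic(self):
        img = FiberImage(np.zeros((100, 100, 100)), spacing=(0.5, 0.5, 0.5))
        cfg = mt.TrialConfiguration(representation="3D", downsample=True)
        x = mt.build_representation(img, cfg)
        assert x.shape[0] == 1
        assert all(abs(s - 67) <= 1 for s in x.shape[1:])


class TestAugment:
    def test_disabled_returns_input_unchanged(self):
        x = np.random.default_rng(0).normal(0, 1, (3, 24, 16))
        cfg = mt.TrialConfiguration(augment=False, random_erasing=False)
        out = mt.augment_input(x, cfg, np.random.default_rng(1))
        assert np.array_equal(out, x)

    def test_fixed_seed_reproducible(self):
        x = np.random.default_rng(0).normal(0, 1, (3, 24, 16))
        cfg = mt.TrialConfiguration(augment=True, random_erasing=True)
        a = mt.augment_input(x, cfg, np.random.default_rng(9))
        b = mt.augment_input(x, cfg, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_erased_fraction_within_bounds(self):
        x = np.ones((3, 40, 40))
        cfg = mt.TrialConfiguration(random_erasing=True)
        fractions = []
        for seed in range(20):
            out = mt.augment_input(x, cfg, np.random.default_rng(seed))
            fractions.append((out == 0).mean())
        assert min(fractions) >= 0.01  # at least one rectangle of >= 2%
        assert max(fractions) <= 0.35  # at most 3 overlapping 10% rectangles


class TestModelStructure:
    def test_output_arity_per_integration_level(self):
        n_tasks, n_priors = 3, 5
        m0 = mt.build_model(mt.TrialConfiguration(prior_integration="NoPriors"),
                            n_tasks, n_priors)
        assert m0.n_outputs == n_tasks and not m0.use_branch
        m1 = mt.build_model(mt.TrialConfiguration(prior_integration="AuxLosses"),
                            n_tasks, n_priors)
        assert m1.n_outputs == n_tasks + n_priors and not m1.use_branch
        m2 = mt.build_model(mt.TrialConfiguration(prior_integration="Branches"),
                            n_tasks, n_priors)
        assert m2.n_outputs == n_tasks and m2.use_branch
        m3 = mt.build_model(
            mt.TrialConfiguration(prior_integration="AuxLosses@Branches"),
            n_tasks, n_priors)
        assert m3.n_outputs == n_tasks + n_priors
        # branch widens the final fully connected layer by n_priors
        assert (m3.head.w.shape[0] - m1.head.w.shape[0]) == n_priors

    def test_priors_only_has_no_network(self):
        with pytest.raises(ValueError):
            mt.build_model(mt.TrialConfiguration(prior_integration="PriorsOnly"),
                           3, 5)

    def test_3d_config_builds_3d_conv(self):
        m = mt.build_model(mt.TrialConfiguration(representation="3D"), 2, 0)
        assert m.nd == 3
        x = nn.Tensor(np.zeros((2, 1, 16, 16, 16)))
        assert m(x).shape == (2, 2)


class TestMaskedUncertaintyLoss:
    def test_unit_sigma_reduces_to_plain_sum(self):
        w = mt.LossWeights.create(2)
        pred = nn.Tensor(np.array([[1.0, 0.5], [0.0, -0.5]]), True)
        tgt = np.array([[0.0, 1.0], [1.0, 0.0]])
        mask = np.ones((2, 2), bool)
        loss = mt.masked_uncertainty_loss(pred, tgt, mask, w,
                                          ["continuous", "binary"])
        mse = ((pred.data[:, 0] - tgt[:, 0]) ** 2).mean()
        z = pred.data[:, 1]
        bce = (np.logaddexp(0, z) - tgt[:, 1] * z).mean()
        assert loss.data == pytest.approx(mse + bce)

    def test_single_term_worked_value(self):
        w = mt.LossWeights.create(1)
        w.log_sigma.data[:] = 0.5 * math.log(2.0)  # sigma = sqrt(2)
        pred = nn.Tensor(np.array([[math.sqrt(2.0)]]), True)
        loss = mt.masked_uncertainty_loss(pred, np.zeros((1, 1)),
                                          np.ones((1, 1), bool), w, ["continuous"])
        # L = 2: 2/2 + log sqrt(2) = 1.3466
        assert loss.data == pytest.approx(1.3466, abs=1e-4)

    def test_masked_outputs_get_exactly_zero_gradient(self):
        rng = np.random.default_rng(0)
        model = mt.build_model(mt.TrialConfiguration(representation="2.5D_1"),
                               n_tasks=2, n_priors=0, seed=0)
        w = mt.LossWeights.create(2)
        x = nn.Tensor(rng.normal(0, 1, (4, 3, 16, 16)))
        pred = model(x)
        mask = np.zeros((4, 2), bool)
        mask[:, 0] = True  # task 1 fully masked
        loss = mt.masked_uncertainty_loss(pred, rng.normal(0, 1, (4, 2)), mask, w,
                                          ["continuous", "continuous"])
        loss.backward()
        head_grad = model.head.w.grad
        assert np.all(head_grad[:, 1] == 0)  # masked head column untouched
        assert np.any(head_grad[:, 0] != 0)
        assert w.log_sigma.grad[1] == 0

    def test_all_masked_batch_gives_zero_loss_no_graph(self):
        pred = nn.Tensor(np.ones((3, 2)), True)
        loss = mt.masked_uncertainty_loss(pred, np.ones((3, 2)),
                                          np.zeros((3, 2), bool),
                                          mt.LossWeights.create(2),
                                          ["continuous"] * 2)
        assert loss.data == 0.0 and not loss.requires_grad


class TestMetrics:
    def test_auc_by_pairwise_concordance(self):
        assert mt.roc_auc(np.array([0, 0, 1, 1]),
                          np.array([0.1, 0.4, 0.35, 0.8])) == 0.75
        assert mt.roc_auc(np.array([0, 1]), np.array([0.5, 0.5])) == 0.5

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50).astype(float)
        s = rng.normal(0, 1, 50) + y
        assert mt.roc_auc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_r2_identity_and_mean(self):
        t = np.array([1.0, 2.0, 3.0])
        assert mt.r_squared(t, t) == 1.0
        assert mt.r_squared(t, np.full(3, t.mean())) == 0.0

    def test_single_class_excluded_with_warning(self):
        preds = np.array([[0.2], [0.4]])
        targets = np.array([[1.0], [1.0]])
        mask = np.ones((2, 1), bool)
        with pytest.warns(UserWarning, match="single-class"):
            out = mt.evaluate_metrics(preds, targets, mask, ["binary"], ["t"])
        assert math.isnan(out["t"])


class TestEarlyStopping:
    def simulate(self, seq):
        """Independent scalar oracle of the MA-10 / patience-50 / warmup-75 rule."""
        smoothed, best, best_epoch = [], math.inf, 0
        for epoch, v in enumerate(seq, 1):
            smoothed.append(np.mean(seq[max(0, epoch - 10):epoch]))
            if smoothed[-1] < best:
                best, best_epoch = smoothed[-1], epoch
            if epoch > 75 and epoch - max(best_epoch, 75) >= 50:
                return epoch
        return None

    def test_constant_sequence_stops_at_exactly_125(self):
        state = mt.TrainState()
        epoch = 0
        while True:
            epoch += 1
            if state.record(1.0):
                break
        assert epoch == 125

    def test_strictly_decreasing_never_stops_within_budget(self):
        state = mt.TrainState()
        assert not any(state.record(1.0 - 0.001 * e) for e in range(200))

    @pytest.mark.parametrize("plateau_at", [40, 100, 130])
    def test_decrease_then_plateau_matches_scalar_oracle(self, plateau_at):
        seq = [1.0 - 0.001 * min(e, plateau_at) for e in range(1, 400)]
        state = mt.TrainState()
        stopped = None
        for epoch, v in enumerate(seq, 1):
            if state.record(v):
                stopped = epoch
                break
        assert stopped == self.simulate(seq)


class TestTraining:
    def _toy_data(self, n=48, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, 3, 16, 12))
        y = (rng.random(n) < 0.5).astype(float)
        X[y == 1] += 0.5
        return X, y[:, None], np.ones((n, 1), bool)

    def test_overfits_learnable_signal(self):
        X, t, m = self._toy_data()
        cfg = mt.TrialConfiguration(representation="2.5D_1", capacity=1,
                                    optimizer="adam", learning_rate=3e-3)
        res = mt.train_trial(X, t, m, None, X, t, m, None, ["t"], ["binary"],
                             cfg, budget=20, seed=0, min_epochs_rule=False)
        pred = mt._predict(res.model, X, None)
        assert mt.roc_auc(t[:, 0], pred[:, 0]) > 0.9

    def test_deterministic_loss_trajectory(self):
        X, t, m = self._toy_data()
        cfg = mt.TrialConfiguration(representation="2.5D_1", capacity=1)
        r1 = mt.train_trial(X, t, m, None, X, t, m, None, ["t"], ["binary"],
                            cfg, budget=5, seed=3, min_epochs_rule=False)
        r2 = mt.train_trial(X, t, m, None, X, t, m, None, ["t"], ["binary"],
                            cfg, budget=5, seed=3, min_epochs_rule=False)
        assert r1.state.history == r2.state.history

    def test_sigma_grows_for_noisier_task(self):
        # two regression tasks sharing the signal, one with much more label noise
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 64
            X = rng.normal(0, 1, (n, 3, 12, 8))
            signal = X.mean(axis=(1, 2, 3)) * 5
            t = np.stack([signal + rng.normal(0, 0.05, n),
                          signal + rng.normal(0, 2.0, n)], axis=1)
            m = np.ones((n, 2), bool)
            cfg = mt.TrialConfiguration(representation="2.5D_1", capacity=1,
                                        optimizer="adam", learning_rate=3e-3)
            res = mt.train_trial(X, t, m, None, X, t, m, None, ["a", "b"],
                                 ["continuous", "continuous"], cfg, budget=30,
                                 seed=seed, min_epochs_rule=False)
            sigma = res.weights.sigma
            wins += sigma[1] > sigma[0]
        assert wins >= 3

    def test_divergence_marks_failure(self):
        X, t, m = self._toy_data(n=16)
        cfg = mt.TrialConfiguration(representation="2.5D_1", capacity=1,
                                    optimizer="sgd", learning_rate=1e-1,
                                    momentum=0.95)
        res = mt.train_trial(X, t * 1e6, m, None, X, t, m, None, ["t"],
                             ["continuous"], cfg, budget=30, seed=0,
                             min_epochs_rule=False)
        # either diverges (failed) or survives; the flag must be consistent
        assert res.failed == (not np.isfinite(res.best_total_meta)
                              or res.epochs_run < 30)
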