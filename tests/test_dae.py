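"""Initialisation, corruption, forward passes, gradients and training."""

import numpy as np
import pytest

from acidae.dae import (
    DAEEnsemble,
    DenoisingAutoencoder,
    corrupt,
    glorot_init,
    sigmoid,
    split_samples,
)


class TestGlorot:
    def test_bound_from_formula(self):
        W = glorot_init(3, 3, seed=0)
        assert np.all(np.abs(W) <= 1.0)  # sqrt(6/6)

    def test_empirical_variance(self):
        W = glorot_init(50, 50, seed=1)
        # uniform(+-a) variance a^2/3 = 2/(fan_in+fan_out) = 0.02
        n = 100
        Ws = np.concatenate([glorot_init(50, 50, seed=s).ravel() for s in range(4)])
        assert Ws.var() == pytest.approx(0.02, rel=0.1)

    def test_determinism(self):
        np.testing.assert_array_equal(glorot_init(10, 7, seed=5), glorot_init(10, 7, seed=5))

    def test_invalid_fans(self):
        with pytest.raises(ValueError):
            glorot_init(0, 5)


class TestCorrupt:
    def test_rate_zero_is_identity(self, rng):
        X = rng.random((20, 30))
        np.testing.assert_array_equal(corrupt(X, 0.0, seed=0), X)

    def test_rate_one_zeroes_everything(self, rng):
        X = rng.random((20, 30))
        assert corrupt(X, 1.0, seed=0).sum() == 0.0

    def test_untouched_entries_bit_identical(self, rng):
        X = rng.random((50, 40))
        C = corrupt(X, 0.3, seed=1)
        mask = C != 0
        np.testing.assert_array_equal(C[mask], X[mask])

    def test_binomial_calibration(self, rng):
        X = rng.random((100, 1000)) + 0.5  # no accidental zeros
        C = corrupt(X, 0.10, seed=2)
        frac = np.mean(C == 0)
        sigma = np.sqrt(0.1 * 0.9 / X.size)
        assert abs(frac - 0.10) < 3 * sigma

    def test_exact_mode_counts(self, rng):
        X = rng.random((10, 100)) + 0.5
        C = corrupt(X, 0.10, seed=3, exact=True)
        assert np.all((C == 0).sum(axis=1) == 10)

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            corrupt(np.ones((2, 2)), 1.5)


def toy_dae(n_genes, h1=3, h2=2, bottleneck=2, seed=0, **kw):
    m = DenoisingAutoencoder(hidden1=h1, hidden2=h2, bottleneck=bottleneck,
                             random_state=seed, **kw)
    m.n_features_in_ = n_genes
    m._init_params(n_genes, np.random.default_rng(seed))
    return m


class TestForward:
    def test_zero_network_encodes_to_half(self):
        m = toy_dae(5)
        for p in m._params():
            p[...] = 0.0
        np.testing.assert_allclose(m.transform(np.zeros(5)), 0.5)
        np.testing.assert_allclose(m.transform(np.ones(5)), 0.5)

    def test_large_bias_saturates(self):
        m = toy_dae(5)
        for p in m._params():
            p[...] = 0.0
        m.b3_[...] = 10.0
        assert np.all(m.transform(np.zeros(5)) > 0.999)

    def test_hand_computed_toy_network(self):
        # 2-2-1 encoder with fixed weights, evaluated by hand
        m = toy_dae(2, h1=2, h2=2, bottleneck=1)
        m.W1_[...] = [[1.0, -1.0], [0.5, 0.25]]
        m.b1_[...] = [0.1, -0.1]
        m.W2_[...] = [[1.0, 0.0], [0.0, 1.0]]
        m.b2_[...] = 0.0
        m.W3_[...] = [[2.0], [-1.0]]
        m.b3_[...] = [0.3]
        x = np.array([0.2, 0.8])
        s = lambda z: 1 / (1 + np.exp(-z))
        h1 = s(np.array([0.2 * 1 + 0.8 * 0.5 + 0.1, 0.2 * -1 + 0.8 * 0.25 - 0.1]))
        h2 = s(h1)  # identity weights, zero bias
        a = s(np.array([2 * h2[0] - 1 * h2[1] + 0.3]))
        np.testing.assert_allclose(m.transform(x)[0], a)

    def test_decode_zero_network_flat_half(self):
        m = toy_dae(5)
        for p in m._params():
            p[...] = 0.0
        np.testing.assert_allclose(m.inverse_transform(np.array([0.7, 0.2])), 0.5)

    def test_tied_weights_alias_both_paths(self):
        m = toy_dae(4)
        x = np.linspace(0.1, 0.9, 4)
        a = np.array([0.3, 0.6])
        enc0, dec0 = m.transform(x).copy(), m.inverse_transform(a).copy()
        m.W1_[0, 0] += 0.5  # one shared parameter
        assert not np.allclose(m.transform(x), enc0)
        assert not np.allclose(m.inverse_transform(a), dec0)

    def test_dimension_mismatch_named(self):
        m = toy_dae(4)
        with pytest.raises(ValueError, match="genes"):
            m.transform(np.zeros(7))
        with pytest.raises(ValueError, match="bottleneck"):
            m.inverse_transform(np.zeros(5))


class TestGradients:
    @pytest.mark.parametrize("loss", ["mse", "bce"])
    def test_matches_finite_differences(self, loss, rng):
        m = toy_dae(6, h1=4, h2=3, bottleneck=2, loss=loss, dtype="float64")
        Xc = rng.random((5, 6))
        X = rng.random((5, 6))
        _, grads = m._gradients(Xc, X)
        eps = 1e-6
        for p, g in zip(m._params(), grads):
            flat = p.ravel()
            idx = rng.integers(0, flat.size, size=min(6, flat.size))
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = m._loss_value(m._decode(m._encode(Xc)[2])[2], X)
                flat[i] = orig - eps
                lm = m._loss_value(m._decode(m._encode(Xc)[2])[2], X)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert g.ravel()[i] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTraining:
    def small_data(self, rng, n=24, g=40):
        base = rng.random((4, g))
        return np.clip(base[rng.integers(0, 4, n)] + 0.05 * rng.standard_normal((n, g)),
                       0, 1)

    def test_loss_decreases(self, rng):
        X = self.small_data(rng)
        m = DenoisingAutoencoder(hidden1=16, hidden2=8, bottleneck=4,
                                 max_epochs=50, patience=50, random_state=0).fit(X)
        assert m.history_["train_loss"][-1] < m.history_["train_loss"][0]

    def test_overfits_tiny_dataset_without_corruption(self, rng):
        X = self.small_data(rng, n=6, g=20)
        m = DenoisingAutoencoder(hidden1=32, hidden2=16, bottleneck=8,
                                 corruption_rate=0.0, learning_rate=5e-3,
                                 max_epochs=2000, patience=2000,
                                 random_state=0).fit(X)
        assert m.reconstruction_error(X) < 0.01

    def test_determinism(self, rng):
        X = self.small_data(rng)
        kw = dict(hidden1=16, hidden2=8, bottleneck=4, max_epochs=30,
                  patience=30, random_state=7)
        m1 = DenoisingAutoencoder(**kw).fit(X)
        m2 = DenoisingAutoencoder(**kw).fit(X)
        for p1, p2 in zip(m1._params(), m2._params()):
            np.testing.assert_array_equal(p1, p2)

    def test_early_stopping_returns_best_validation_weights(self, rng):
        X = self.small_data(rng)
        Xv = self.small_data(rng, n=4)
        m = DenoisingAutoencoder(hidden1=16, hidden2=8, bottleneck=4,
                                 max_epochs=100, patience=5,
                                 random_state=1).fit(X, X_val=Xv)
        assert m.best_val_loss_ <= m.history_["val_loss"][-1] + 1e-12
        assert m.reconstruction_error(Xv) == pytest.approx(m.best_val_loss_)

    def test_activations_and_reconstructions_in_unit_interval(self, rng):
        X = self.small_data(rng)
        m = DenoisingAutoencoder(hidden1=16, hidden2=8, bottleneck=4,
                                 max_epochs=20, patience=20, random_state=0).fit(X)
        a = m.transform(X)
        r = m.reconstruct(X)
        assert np.all((a > 0) & (a < 1)) and np.all((r > 0) & (r < 1))

    def test_denoising_beats_untrained_on_corrupted_input(self, rng):
        X = self.small_data(rng, n=20)
        m = DenoisingAutoencoder(hidden1=16, hidden2=8, bottleneck=4,
                                 max_epochs=200, patience=200,
                                 random_state=2).fit(X)
        fresh = toy_dae(X.shape[1], h1=16, h2=8, bottleneck=4, seed=2)
        Xc = corrupt(X, 0.1, seed=3)
        err_trained = np.mean((m.inverse_transform(m.transform(Xc)) - X) ** 2)
        err_fresh = np.mean((fresh.inverse_transform(fresh.transform(Xc)) - X) ** 2)
        assert err_trained < err_fresh


class TestEnsemble:
    def test_members_have_distinct_initialisations(self, rng):
        X = rng.random((20, 30))
        ens = DAEEnsemble(n_members=3, hidden1=8, hidden2=6, bottleneck=3,
                          max_epochs=5, patience=5, lr_grid=(1e-3,),
                          batch_grid=(8,), base_seed=0).fit(X)
        w = [m.W1_ for m in ens.members_]
        assert not np.allclose(w[0], w[1]) and not np.allclose(w[1], w[2])

    def test_single_point_grid_selected(self, rng):
        X = rng.random((20, 30))
        ens = DAEEnsemble(n_members=1, hidden1=8, hidden2=6, bottleneck=3,
                          max_epochs=5, patience=5, lr_grid=(2e-3,),
                          batch_grid=(4,), base_seed=0).fit(X)
        assert ens.best_params_ == (2e-3, 4)

    def test_empty_grid_warns_and_uses_defaults(self, rng):
        X = rng.random((20, 30))
        with pytest.warns(UserWarning, match="grid"):
            ens = DAEEnsemble(n_members=1, hidden1=8, hidden2=6, bottleneck=3,
                              max_epochs=3, patience=3, lr_grid=(),
                              batch_grid=(), base_seed=0).fit(X)
        assert ens.best_params_ == (1e-3, 16)

    def test_rerun_determinism(self, rng):
        X = rng.random((20, 30))
        kw = dict(n_members=2, hidden1=8, hidden2=6, bottleneck=3,
                  max_epochs=10, patience=10, lr_grid=(1e-3,), batch_grid=(8,),
                  base_seed=4)
        e1 = DAEEnsemble(**kw).fit(X)
        e2 = DAEEnsemble(**kw).fit(X)
        for m1, m2 in zip(e1.members_, e2.members_):
            assert m1.history_ == m2.history_
            np.testing.assert_array_equal(m1.W1_, m2.W1_)

    def test_save_load_round_trip(self, rng, tmp_path):
        X = rng.random((20, 30))
        ens = DAEEnsemble(n_members=2, hidden1=8, hidden2=6, bottleneck=3,
                          max_epochs=10, patience=10, lr_grid=(1e-3,),
                          batch_grid=(8,), base_seed=1).fit(X)
        ens.save(tmp_path / "ens")
        back = DAEEnsemble.load(tmp_path / "ens")
        np.testing.assert_array_equal(back.transform(X), ens.transform(X))
        assert back.split_.train == ens.split_.train
        assert back.members_[0].history_ == ens.members_[0].history_

    def test_shared_split_is_a_partition(self, rng):
        X = rng.random((30, 20))
        ids = [f"s{i}" for i in range(30)]
        split = split_samples(ids, (0.8, 0.1, 0.1), seed=0)
        assert sorted(split.train + split.validation + split.test) == sorted(ids)
        assert len(split.train) >= len(split.validation)
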