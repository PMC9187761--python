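import numpy as np
import pytest

from lshgan import (GeneratorInputSpec, TrainConfig, SamplerConfig,
                    augment_generator_input, discriminator_update_value,
                    generate, generator_update_value, train_lsh_gan,
                    train_vanilla_gan)


@pytest.fixture(scope="module")
def tiny_cfg():
    return TrainConfig(epochs=30, sampler=SamplerConfig(k=3),
                       checkpoints=(1, 30), seed=0)


class TestAugmentGeneratorInput:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.xs = rng.normal(5.0, 1.0, size=(12, 6))

    def test_all_noise_at_mix_one(self):
        spec = GeneratorInputSpec(noise_dim=6, mix_fraction=1.0)
        batch = augment_generator_input(None, 10, spec, seed=1)
        assert batch.shape == (10, 6)
        assert np.abs(batch).max() < 6  # nothing near the x_s values ~5 sigma away

    def test_all_subsample_at_mix_zero(self):
        spec = GeneratorInputSpec(mix_fraction=0.0)
        batch = augment_generator_input(self.xs, 10, spec, seed=2)
        rows = {tuple(r) for r in self.xs}
        assert all(tuple(r) in rows for r in batch)

    def test_half_mix_exact_membership_count(self):
        spec = GeneratorInputSpec(mix_fraction=0.5)
        batch = augment_generator_input(self.xs, 10, spec, seed=3)
        rows = {tuple(r) for r in self.xs}
        n_member = sum(tuple(r) in rows for r in batch)
        assert n_member == 5

    def test_deterministic_given_seed(self):
        spec = GeneratorInputSpec(mix_fraction=0.3)
        a = augment_generator_input(self.xs, 8, spec, seed=4)
        b = augment_generator_input(self.xs, 8, spec, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_dimension_mismatch_rejected(self):
        spec = GeneratorInputSpec(noise_dim=99, mix_fraction=0.5)
        with pytest.raises(ValueError):
            augment_generator_input(self.xs, 4, spec, seed=0)

    def test_missing_subsample_rejected(self):
        spec = GeneratorInputSpec(noise_dim=6, mix_fraction=0.5)
        with pytest.raises(ValueError):
            augment_generator_input(None, 4, spec, seed=0)


class TestUpdateValues:
    def test_perfect_discriminator_near_zero(self):
        eps = 1e-9
        val = discriminator_update_value(np.array([1 - eps]), np.array([eps]))
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_discriminator(self):
        val = discriminator_update_value(np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert val == pytest.approx(4 * np.log(0.5), abs=1e-12)

    def test_single_pair_hand_computed(self):
        val = discriminator_update_value(np.array([0.8]), np.array([0.3]))
        assert val == pytest.approx(np.log(0.8) + np.log(0.7), abs=1e-12)

    def test_generator_values(self):
        assert generator_update_value(np.array([0.5, 0.5])) == \
            pytest.approx(2 * np.log(0.5), abs=1e-12)
        assert generator_update_value(np.array([1e-9])) == \
            pytest.approx(0.0, abs=1e-6)
        assert generator_update_value(np.array([0.9])) == \
            pytest.approx(np.log(0.1), abs=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discriminator_update_value(np.array([1.2]), np.array([0.5]))
        with pytest.raises(ValueError):
            generator_update_value(np.array([-0.1]))

    def test_clamped_values_always_finite(self):
        assert np.isfinite(discriminator_update_value(
            np.array([0.0, 1.0]), np.array([0.0, 1.0])))
        assert np.isfinite(generator_update_value(np.array([0.0, 1.0])))


class TestTraining:
    def test_smoke_history_contract(self, small_mixture, tiny_cfg):
        model = train_lsh_gan(small_mixture.values, tiny_cfg)
        assert [r["epoch"] for r in model.history] == [1, 30]
        assert all(np.isfinite(r["delta_d"]) and np.isfinite(r["delta_g"])
                   for r in model.history)

    def test_holdout_recorded(self, small_mixture, tiny_cfg):
        X = small_mixture.values
        model = train_lsh_gan(X[:80], tiny_cfg, holdout=X[80:])
        assert all(r["wasserstein"] >= 0 for r in model.history)

    def test_reproducible_histories(self, small_mixture, tiny_cfg):
        a = train_lsh_gan(small_mixture.values, tiny_cfg)
        b = train_lsh_gan(small_mixture.values, tiny_cfg)
        assert a.history == b.history

    def test_mix_one_reduces_to_vanilla(self, small_mixture):
        from dataclasses import replace
        cfg = TrainConfig(epochs=25, checkpoints=(25,), seed=3,
                          gen_input=GeneratorInputSpec(mix_fraction=1.0))
        a = train_lsh_gan(small_mixture.values, cfg)
        b = train_vanilla_gan(small_mixture.values, replace(
            cfg, gen_input=GeneratorInputSpec(mix_fraction=0.5)))
        assert a.history == b.history
        for W1, W2 in zip(a.generator.W, b.generator.W):
            np.testing.assert_array_equal(W1, W2)

    def test_vanilla_has_no_subsample(self, small_mixture, tiny_cfg):
        model = train_vanilla_gan(small_mixture.values, tiny_cfg)
        assert model.subsample is None


class TestTrainingQuality:
    def test_wasserstein_improves_over_training(self, small_mixture):
        from lshgan import stratified_split
        tr, te = stratified_split(small_mixture.values, small_mixture.labels,
                                  0.2, seed=0)
        cfg = TrainConfig(epochs=2000, checkpoints=(100, 2000), seed=0)
        model = train_lsh_gan(small_mixture.values[tr], cfg,
                              holdout=small_mixture.values[te])
        first, last = model.history[0], model.history[-1]
        assert last["wasserstein"] < first["wasserstein"]

    def test_toy_2d_distribution_is_learned(self):
        from lshgan import make_toy_2d
        toy = make_toy_2d(200, rho=0.5, seed=9)
        cfg = TrainConfig(epochs=1000, checkpoints=(10, 1000), seed=0)
        model = train_lsh_gan(toy[:160], cfg, holdout=toy[160:])
        first, last = model.history[0], model.history[-1]
        assert last["wasserstein"] < first["wasserstein"]
        assert last["wasserstein"] < 0.5  # near the 40-sample floor


class TestGenerate:
    def test_shape_and_determinism(self, small_mixture, tiny_cfg):
        model = train_lsh_gan(small_mixture.values, tiny_cfg)
        out = generate(model, 17, seed=5)
        assert out.shape == (17, 50)
        np.testing.assert_array_equal(out, generate(model, 17, seed=5))
        assert np.all(np.isfinite(out))

    def test_invalid_n_rejected(self, small_mixture, tiny_cfg):
        model = train_lsh_gan(small_mixture.values, tiny_cfg)
        with pytest.raises(ValueError):
            generate(model, 0)
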