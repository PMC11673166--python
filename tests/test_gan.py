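"""Generator/discriminator construction, losses, training smoke tests."""

import numpy as np
import pytest

import statsynth as ss
from statsynth.gan import normalize_stats


@pytest.fixture(scope="module")
def tiny_gen_cfg(tiny_schema):
    return ss.GeneratorConfig(stat_dim=tiny_schema.stat_dim, noise_dim=16,
                              layer_widths=(32, 32, 32), output_shape=(50, 3))


@pytest.fixture(scope="module")
def tiny_disc_cfg(tiny_schema):
    return ss.DiscriminatorConfig(stat_dim=tiny_schema.stat_dim,
                                  input_shape=(50, 3), layer_widths=(32, 16))


class TestGenerator:
    def test_output_shape_and_range(self, tiny_gen_cfg, tiny_stats, tiny_schema):
        G = ss.build_generator(tiny_gen_cfg, seed=0)
        z = np.random.default_rng(0).standard_normal((4, 16))
        s = np.tile(normalize_stats(tiny_stats.values, tiny_schema), (4, 1))
        out = G.forward(z, s)
        assert out.shape == (4, 50, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_default_config_emits_766_rows(self):
        schema = ss.pima_schema()
        cfg = ss.GeneratorConfig(stat_dim=schema.stat_dim)
        G = ss.build_generator(cfg, seed=0)
        z = np.random.default_rng(1).standard_normal((1, cfg.noise_dim))
        s = np.zeros((1, schema.stat_dim))
        out = G.forward(z, s)
        assert out.shape == (1, 766, 9)

    def test_pure_function(self, tiny_gen_cfg, tiny_stats, tiny_schema):
        G = ss.build_generator(tiny_gen_cfg, seed=3)
        z = np.random.default_rng(0).standard_normal((2, 16))
        s = np.tile(normalize_stats(tiny_stats.values, tiny_schema), (2, 1))
        assert np.array_equal(G.forward(z, s), G.forward(z, s))

    def test_stat_dim_mismatch_raises(self, tiny_gen_cfg):
        G = ss.build_generator(tiny_gen_cfg)
        with pytest.raises(ss.ValidationError):
            G.forward(np.zeros((1, 16)), np.zeros((1, 3)))

    def test_reinjection_layer_out_of_range(self):
        with pytest.raises(ss.ValidationError):
            ss.GeneratorConfig(stat_dim=5, layer_widths=(8,), reinjection_layer=2)


class TestDiscriminator:
    def test_probability_output(self, tiny_disc_cfg, tiny_schema):
        D = ss.build_discriminator(tiny_disc_cfg, seed=0)
        x = np.random.default_rng(0).uniform(size=(3, 50, 3))
        s = np.zeros((3, tiny_schema.stat_dim))
        p = D.forward(x, s)
        assert p.shape == (3,)
        assert np.all((p > 0) & (p < 1))
        assert np.array_equal(p, D.forward(x, s))

    def test_injection_layer_out_of_range(self):
        with pytest.raises(ss.ValidationError):
            ss.DiscriminatorConfig(stat_dim=5, layer_widths=(8,),
                                   stat_injection_layer=2)

    def test_input_shape_mismatch(self, tiny_disc_cfg):
        D = ss.build_discriminator(tiny_disc_cfg)
        with pytest.raises(ss.ValidationError):
            D.forward(np.zeros((1, 10)), np.zeros((1, tiny_disc_cfg.stat_dim)))


class TestLosses:
    def test_perfect_discriminator_near_zero(self):
        eps = 1e-9
        assert ss.discriminator_loss([1 - eps], [eps]) == pytest.approx(0, abs=1e-5)

    def test_half_scores(self):
        assert ss.discriminator_loss([0.5], [0.5]) == pytest.approx(
            -(np.log(0.5) + np.log(0.5)))
        assert ss.discriminator_loss([0.5], [0.5]) == pytest.approx(1.3863, abs=1e-4)

    def test_reorder_invariance(self):
        r = [0.9, 0.7, 0.8]
        f = [0.2, 0.4, 0.1]
        assert ss.discriminator_loss(r, f) == pytest.approx(
            ss.discriminator_loss(r[::-1], f[::-1]))

    def test_generator_loss_values(self):
        assert ss.generator_loss([0.5], ts=0.0) == pytest.approx(np.log(0.5))
        assert ss.generator_loss([0.5], ts=0.0) == pytest.approx(-0.6931, abs=1e-4)

    def test_ts_term_additive(self):
        scores = [0.3, 0.6]
        assert (ss.generator_loss(scores, ts=1.7)
                - ss.generator_loss(scores, ts=0.0)) == pytest.approx(1.7)

    def test_saturating_limit(self):
        # fake scores near 1 drive the adversarial term far negative
        assert ss.generator_loss([1.0], ts=0.0) < -10


def test_iteration_arithmetic():
    assert ss.iterations_per_epoch(10_000, 64) == 156
    assert 70 * ss.iterations_per_epoch(10_000, 64) == 10_920
    assert ss.iterations_per_epoch(10_000, 64, drop_last=False) == 157
    assert ss.iterations_per_epoch(64, 64) == 1


@pytest.fixture(scope="module")
def tiny_corpus(tmp_path_factory, tiny_stats, tiny_schema):
    out = tmp_path_factory.mktemp("corpus")
    return ss.build_training_corpus(tiny_stats, tiny_schema, n_tables=40,
                                    amplitude=0.01, seed=2, out_dir=out)


class TestTraining:
    def test_smoke_all_losses_finite(self, tiny_corpus, tiny_gen_cfg,
                                     tiny_disc_cfg):
        cfg = ss.TrainConfig(batch_size=16, max_epochs=4, seed=0,
                             monitor_feature_pair=(0, 1))
        G, hist = ss.train(tiny_corpus, tiny_gen_cfg, tiny_disc_cfg, cfg)
        assert hist.n_iterations == 4 * (40 // 16)
        assert np.isfinite(hist.disc_loss).all()
        assert np.isfinite(hist.gen_loss).all()
        assert np.isfinite(hist.ts_loss).all()
        assert len(hist.scatter) == 4

    def test_stat_dim_mismatch_rejected(self, tiny_corpus, tiny_disc_cfg):
        bad = ss.GeneratorConfig(stat_dim=99, noise_dim=16,
                                 layer_widths=(8, 8, 8), output_shape=(50, 3))
        with pytest.raises(ss.ValidationError):
            ss.train(tiny_corpus, bad, tiny_disc_cfg, ss.TrainConfig(batch_size=16))


class TestGenerateTable:
    def test_postprocessed_table_satisfies_invariants(self, tiny_gen_cfg,
                                                      tiny_stats, tiny_schema):
        G = ss.build_generator(tiny_gen_cfg, seed=1)
        t = ss.generate_table(G, tiny_stats, tiny_schema, seed=0)
        assert t.values.shape == (50, 3)
        assert t.check_invariants() == []
        # count column integral
        assert np.array_equal(t.column("B"), np.round(t.column("B")))

    def test_deterministic_given_seed(self, tiny_gen_cfg, tiny_stats, tiny_schema):
        G = ss.build_generator(tiny_gen_cfg, seed=1)
        a = ss.generate_table(G, tiny_stats, tiny_schema, seed=9)
        b = ss.generate_table(G, tiny_stats, tiny_schema, seed=9)
        assert np.array_equal(a.values, b.values)


def test_checkpoint_roundtrip(tmp_path, tiny_gen_cfg, tiny_stats, tiny_schema):
    G = ss.build_generator(tiny_gen_cfg, seed=5)
    path = tmp_path / "ck.npz"
    ss.save_checkpoint(path, G, tiny_schema)
    G2, schema2 = ss.load_checkpoint(path)
    assert schema2.column_names == tiny_schema.column_names
    a = ss.generate_table(G, tiny_stats, tiny_schema, seed=3)
    b = ss.generate_table(G2, tiny_stats, schema2, seed=3)
    assert np.array_equal(a.values, b.values)
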