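"""Two-fold training loop: schedule, variants, DES, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from imbalsim2real import (
    DomainSample,
    ImbalSim2Real,
    SelfSensingConfig,
    TrainingConfig,
    TrainingVariant,
    assemble_dataset,
    build_generator,
    fold_schedule,
    generate_benchmark,
    make_des,
    train,
    train_self_sensing,
    train_supervised,
)


def _short(seed=0, **kw):
    return TrainingConfig(epochs_phase1=30, epochs_phase2=15, seed=seed, **kw)


@pytest.fixture(scope="module")
def small_dataset():
    ds, _ = generate_benchmark("A", seed=0)
    # shrink for speed: 40 source (10 paired), 10 target
    source = ds.source_samples()[:40]
    target = ds.target_samples()[:10]
    pairing = [(i, i) for i in range(10)]
    return assemble_dataset(
        [replace_pair_id(s) for s in source], [replace_pair_id(t) for t in target], pairing
    )


def replace_pair_id(s):
    from dataclasses import replace as dc_replace

    return dc_replace(s, pair_id=None)


class TestSchedule:
    def test_two_to_one_cycle(self):
        cfg = TrainingConfig(epochs_phase1=3, epochs_phase2=0)
        assert fold_schedule(cfg, True).tolist() == [1, 1, 2]

    def test_ratio_honored_over_long_runs(self):
        cfg = TrainingConfig(epochs_phase1=600, epochs_phase2=300)
        folds = fold_schedule(cfg, True)
        assert len(folds) == 900
        assert np.sum(folds == 1) == 2 * np.sum(folds == 2)

    def test_trl_off_gives_all_fold1(self):
        cfg = TrainingConfig(
            epochs_phase1=6, epochs_phase2=0, variant=TrainingVariant.original_cyclegan()
        )
        assert set(fold_schedule(cfg, True)) == {1}

    def test_no_pairs_skips_fold2(self):
        cfg = TrainingConfig(epochs_phase1=6, epochs_phase2=0)
        assert set(fold_schedule(cfg, False)) == {1}

    def test_history_covers_both_phases(self, small_dataset):
        res = train(small_dataset, _short())
        h = res.history
        assert len(h) == 45
        assert np.all(h.lr[:30] == 1e-4)
        assert np.all(h.lr[30:] == 1e-5)
        # every epoch recorded exactly one fold's losses
        fold1 = h.fold == 1
        assert np.all(np.isfinite(h.d_sim[fold1]))
        assert np.all(np.isnan(h.trl[fold1]))
        assert np.all(np.isfinite(h.trl[~fold1]))


class TestFlagReductions:
    def test_proposed_with_flags_off_equals_original_cyclegan(self, small_dataset):
        cfg_a = _short(variant=TrainingVariant(use_trl=False, use_des=False, adversarial=True))
        cfg_b = _short(variant=TrainingVariant.original_cyclegan())
        res_a = train(small_dataset, cfg_a)
        res_b = train(small_dataset, cfg_b)
        np.testing.assert_array_equal(res_a.history.d_sim, res_b.history.d_sim)
        np.testing.assert_array_equal(res_a.history.g_adv, res_b.history.g_adv)
        np.testing.assert_array_equal(res_a.g_s2r.theta, res_b.g_s2r.theta)

    def test_supervised_wrapper_equals_supervised_variant(self, small_dataset):
        cfg = _short()
        sup = train_supervised(small_dataset, cfg)
        res = train(small_dataset, replace(cfg, variant=TrainingVariant.supervised()))
        np.testing.assert_array_equal(sup.net.theta, res.g_s2r.theta)

    def test_same_seed_bit_identical(self, small_dataset):
        res_a = train(small_dataset, _short(seed=3))
        res_b = train(small_dataset, _short(seed=3))
        np.testing.assert_array_equal(res_a.g_s2r.theta, res_b.g_s2r.theta)
        np.testing.assert_array_equal(res_a.history.d_real, res_b.history.d_real)


class TestDes:
    def test_reconstructed_counts(self):
        g1, g2 = build_generator(3, seed=0), build_generator(3, seed=1)
        batch = np.random.default_rng(0).normal(size=(10, 3))
        des = make_des(g1, g2, batch, "reconstructed")
        assert des.shape == (10, 3)
        both = make_des(g1, g2, batch, "reconstructed_plus_raw")
        assert both.shape == (20, 3)
        assert make_des(g1, g2, batch, "off").shape == (0, 3)

    def test_identity_generators_reproduce_raw_tuples(self):
        class Identity:
            def forward(self, X, need_cache=False):
                out = np.asarray(X)[:, -1:]
                return (out, None) if need_cache else out

        batch = np.random.default_rng(1).normal(size=(6, 3))
        des = make_des(Identity(), Identity(), batch, "reconstructed")
        np.testing.assert_allclose(des, batch)

    def test_empty_batch_rejected(self):
        g = build_generator(3, seed=0)
        with pytest.raises(ValueError):
            make_des(g, g, np.empty((0, 3)))

    def test_des_enlarges_fake_pool_loss_differs(self, small_dataset):
        # same seed, DES on vs off: D_real sees a strictly larger fake pool,
        # so its loss trajectory must diverge while D_sim's first epoch agrees
        on = train(small_dataset, _short(variant=TrainingVariant.fake_provided_cyclegan()))
        off = train(small_dataset, _short(variant=TrainingVariant.original_cyclegan()))
        assert on.history.d_sim[0] == off.history.d_sim[0]
        assert not np.array_equal(on.history.d_real, off.history.d_real)


class TestFoldIsolation:
    def test_fold2_never_touches_discriminators(self, small_dataset):
        model = ImbalSim2Real(small_dataset, _short())
        d_sim_before = model.d_sim.theta.copy()
        d_real_before = model.d_real.theta.copy()
        from imbalsim2real.networks import Adam

        opt = {
            n: Adam(getattr(model, n).n_params)
            for n in ("g_s2r", "g_r2s", "d_sim", "d_real")
        }
        model._fold2_epoch(opt, 1e-4)
        np.testing.assert_array_equal(model.d_sim.theta, d_sim_before)
        np.testing.assert_array_equal(model.d_real.theta, d_real_before)

    def test_empty_paired_with_trl_degrades_to_fold1(self):
        ds, _ = generate_benchmark("B", seed=0, n_paired=0)
        res = train(ds, _short())
        assert set(res.history.fold) == {1}

    def test_supervised_without_pairs_rejected(self):
        ds, _ = generate_benchmark("B", seed=0, n_paired=0)
        with pytest.raises(ValueError, match="paired"):
            train_supervised(ds, _short())


class TestSupervised:
    def test_overfits_trivially_learnable_data(self):
        source = [
            DomainSample((0.0, 0.0), 0.0, "sim"),
            DomainSample((1.0, 1.0), 1.0, "sim"),
        ]
        target = [
            DomainSample((0.0, 0.0), 1.0, "real"),
            DomainSample((1.0, 1.0), 2.0, "real"),
        ]
        ds = assemble_dataset(source, target, [(0, 0), (1, 1)])
        cfg = TrainingConfig(epochs_phase1=10_000, epochs_phase2=0, seed=0)
        sup = train_supervised(ds, cfg)
        assert sup.history[-1] < 1e-3


class TestSelfSensing:
    def test_history_length_and_constant_fit(self):
        P = np.arange(5.0, 105.0, 5.0)
        theta = np.linspace(2, 40, 20)
        est = train_self_sensing(
            P, theta, np.full(20, 1.19), SelfSensingConfig(epochs=500, seed=0)
        )
        assert est.history.shape == (500,)
        pred = est.predict(P, theta)
        np.testing.assert_allclose(pred, 1.19, atol=0.05)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            train_self_sensing([], [], [], SelfSensingConfig(epochs=10))


def test_nan_abort_diagnostic(small_dataset):
    # a poisoned parameter must abort the loop with a diagnostic, not train on
    model = ImbalSim2Real(small_dataset, _short())
    model.g_s2r.theta[-1] = np.nan  # output-layer bias
    with pytest.raises(RuntimeError, match="epoch"):
        model.fit()
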