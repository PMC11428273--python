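import numpy as np
import pytest

from boldcast import (DiscriminatorSpec, GeneratorSpec, TrainConfig,
                      WindowSpec, extend_series, fit, init_model, load_task,
                      persistence_forecast, predict, prepare_task, rmse,
                      save_task, train_subject_models)
from boldcast.training import TaskModel


@pytest.fixture(scope="module")
def tiny_task(small_decomp_module):
    decomp, cohort = small_decomp_module
    sid = cohort.subjects[0].subject_id
    block = decomp.imf_block(sid, 0)
    return prepare_task(block, 0, WindowSpec(16, 8))


@pytest.fixture(scope="module")
def small_decomp_module():
    from boldcast import SyntheticConfig, VmdConfig, decompose_cohort, \
        generate_cohort
    cohort = generate_cohort(SyntheticConfig(n_subjects=1, m=4, T=300,
                                             noise_sigma=0.15, seed=21))
    return decompose_cohort(cohort, VmdConfig(K=2), 0.05), cohort


GEN_KW = dict(gru_hidden=16, fc_nodes=16, cbam_reduction=2)


def _spec(m=4, D=16, H=8, target=0):
    return GeneratorSpec(m=m, D=D, H=H, target_index=target, **GEN_KW)


class TestFit:
    def test_sanity_run_reduces_validation_rmse(self, tiny_task):
        train, val, test, _ = tiny_task
        st = fit(train, val, _spec(),
                 config=TrainConfig(supervised_epochs=3, joint_epochs=2,
                                    batch_size=32, seed=1))
        trace = [h["val_rmse"] for h in st.history]
        assert len(trace) == 5
        assert all(np.isfinite(trace))
        assert min(trace) <= trace[0]

    def test_zero_epochs_returns_initialized_state(self, tiny_task):
        train, val, _, _ = tiny_task
        cfg = TrainConfig(supervised_epochs=0, joint_epochs=0, seed=3)
        st = fit(train, val, _spec(), config=cfg)
        ref = init_model(_spec(), DiscriminatorSpec(H=8, gru_hidden=16),
                         seed=3)
        for k, v in ref.gen_params.items():
            np.testing.assert_array_equal(st.gen_params[k], v)
        assert st.history == []

    def test_seed_determinism(self, tiny_task):
        train, val, _, _ = tiny_task
        cfg = TrainConfig(supervised_epochs=2, joint_epochs=1, batch_size=32,
                          seed=7)
        a = fit(train, val, _spec(), config=cfg)
        b = fit(train, val, _spec(), config=cfg)
        assert [h["val_rmse"] for h in a.history] == \
            [h["val_rmse"] for h in b.history]
        for k, v in a.gen_params.items():
            np.testing.assert_array_equal(b.gen_params[k], v)

    def test_empty_split_rejected(self, tiny_task):
        train, val, _, _ = tiny_task
        from boldcast.windowing import WindowSet
        empty = WindowSet(train.inputs[:0], train.targets[:0],
                          train.target_region_index,
                          train.last_step_index[:0], train.spec)
        with pytest.raises(ValueError, match="non-empty"):
            fit(empty, val, _spec())

    def test_learning_rate_schedule_monotone(self):
        cfg = TrainConfig()
        lrs = [cfg.lr(s) for s in range(0, 2000, 100)]
        assert lrs[0] == 0.01
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


class TestPredict:
    def test_forecast_length_and_determinism(self, tiny_task):
        train, val, _, _ = tiny_task
        st = fit(train, val, _spec(),
                 config=TrainConfig(supervised_epochs=1, joint_epochs=0,
                                    batch_size=32, seed=5))
        x = train.inputs[0]
        y1, y2 = predict(st, x), predict(st, x)
        assert y1.shape == (8,)
        np.testing.assert_array_equal(y1, y2)

    def test_beats_persistence_on_noiseless_tone(self):
        """On a smooth low-frequency task the model must outdo repeat-last."""
        from boldcast import SyntheticConfig, generate_subject
        cfg = SyntheticConfig(n_subjects=1, m=3, T=500, noise_sigma=0.0,
                              band_freqs_hz=((0.01, 0.02),),
                              amplitudes=(1.0,), seed=13)
        subj = generate_subject(cfg, 0)
        train, val, test, _ = prepare_task(subj.data, 0, WindowSpec(16, 8))
        st = fit(train, val, _spec(m=3),
                 config=TrainConfig(supervised_epochs=6, joint_epochs=0,
                                    batch_size=32, seed=2))
        y_hat = predict(st, test.inputs)
        pers = persistence_forecast(test.inputs, 0, 8)
        assert rmse(test.targets.ravel(), y_hat.ravel()) < \
            rmse(test.targets.ravel(), pers.ravel())


class TestPersistence:
    def test_repeats_last_value(self):
        X = np.arange(12.0).reshape(1, 2, 6)
        out = persistence_forecast(X, 1, 3)
        np.testing.assert_array_equal(out, [[11.0, 11.0, 11.0]])


@pytest.fixture(scope="module")
def trained(small_decomp_module):
    decomp, cohort = small_decomp_module
    models = train_subject_models(
        decomp, cohort.subjects[0].subject_id, WindowSpec(16, 8),
        gen_spec_kw=GEN_KW,
        config=TrainConfig(supervised_epochs=1, joint_epochs=0,
                           batch_size=64, seed=4))
    return models, decomp, cohort.subjects[0]


class TestExtendSeries:
    def test_extension_length(self, trained):
        models, decomp, subj = trained
        ext = extend_series(models, subj, decomp, 24)
        assert ext.n_timepoints == subj.n_timepoints + 24
        np.testing.assert_array_equal(ext.data[:, :subj.n_timepoints],
                                      subj.data)

    def test_single_pass_when_extension_equals_horizon(self, trained):
        models, decomp, subj = trained
        ext = extend_series(models, subj, decomp, 8)
        assert ext.n_timepoints == subj.n_timepoints + 8

    def test_missing_model_rejected(self, trained):
        models, decomp, subj = trained
        partial = dict(models)
        partial.pop((subj.region_labels[0], 0))
        with pytest.raises(ValueError, match="missing trained model"):
            extend_series(partial, subj, decomp, 8)

    def test_bad_length_rejected(self, trained):
        models, decomp, subj = trained
        with pytest.raises(ValueError, match="positive"):
            extend_series(models, subj, decomp, 0)

    def test_extension_amplitude_bounded(self, trained):
        models, decomp, subj = trained
        ext = extend_series(models, subj, decomp, 24)
        tail = ext.data[:, subj.n_timepoints:]
        lo = subj.data.min(axis=1)
        hi = subj.data.max(axis=1)
        rng_ = hi - lo
        assert np.all(tail >= (lo - 0.5 * rng_)[:, None])
        assert np.all(tail <= (hi + 0.5 * rng_)[:, None])

    def test_task_serialization_round_trip(self, trained, tmp_path):
        models, _, subj = trained
        key = (subj.region_labels[0], 0)
        path = tmp_path / "task.h5"
        save_task(models[key], path)
        back = load_task(path)
        assert isinstance(back, TaskModel)
        assert back.target_region == key[0]
        assert back.imf_index == 0
        assert [(p.y_min, p.y_max) for p in back.norm_params] == \
            [(p.y_min, p.y_max) for p in models[key].norm_params]
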