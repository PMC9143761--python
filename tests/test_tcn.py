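"""Network architecture, gradients, locality, training, and the search."""

import numpy as np
import pytest

from gaitevents import (TcnConfig, TrainConfig, build_model, count_params,
                        load_model, make_windows, predict_trial,
                        probe_receptive_field, random_search, receptive_field,
                        save_model, train_model)
from gaitevents.tcn import DEFAULT_SEARCH_SPACE, InvalidConfigError


def _table_config():
    return TcnConfig(n_filters=16, kernel_size=5, dilations=(1, 2, 4))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(dilations=(1, 3)),           # not powers of two
        dict(dilations=(2, 4)),           # must start at 1
        dict(dilations=()),
        dict(kernel_size=4),              # even kernel
        dict(kernel_size=-1),
        dict(dropout_rate=1.0),
        dict(n_filters=0),
    ])
    def test_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            TcnConfig(**kwargs)

    def test_train_config_positive(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestReceptiveField:
    def test_pointwise_kernel(self):
        assert receptive_field(TcnConfig(kernel_size=1, dilations=(1, 2, 4))) == 1

    def test_reference_architecture(self):
        assert receptive_field(_table_config()) == 57

    @pytest.mark.parametrize("cfg", [
        TcnConfig(n_filters=4, kernel_size=3, dilations=(1,)),
        TcnConfig(n_filters=4, kernel_size=3, dilations=(1, 2)),
        TcnConfig(n_filters=8, kernel_size=5, dilations=(1, 2, 4)),
    ])
    def test_formula_matches_perturbation_probe(self, cfg):
        model = build_model(
            TcnConfig(**{**cfg.__dict__, "dropout_rate": 0.0}), seed=0)
        assert probe_receptive_field(model) == receptive_field(cfg)


class TestBuildModel:
    def test_parameter_count_closed_form(self):
        # independent layer-wise sum: kernel*Cin*Cout + Cout per conv,
        # 2*Cout per batch-norm affine pair, Cin+1 per dense unit
        def conv(k, cin, cout):
            return k * cin * cout + cout

        expected = (
            conv(5, 6, 16) + conv(1, 6, 16)          # block 1 conv + shortcut
            + conv(5, 16, 16) * 5                     # remaining dilated convs
            + 6 * (2 * 16)                            # six BatchNorm layers
            + 2 * (16 + 1)                            # two 1-unit dense heads
        )
        assert count_params(build_model(_table_config())) == expected == 7314

    @pytest.mark.parametrize("n", [1, 57, 400, 997])
    def test_fully_convolutional_lengths(self, n, rng):
        model = build_model(_table_config(), seed=0)
        yic, yfc = model.forward(rng.normal(size=(1, n, 6)))
        assert yic.shape == yfc.shape == (1, n)
        assert 0.0 <= yic.min() and yic.max() <= 1.0
        assert 0.0 <= yfc.min() and yfc.max() <= 1.0

    def test_gradients_match_finite_differences(self, rng):
        cfg = TcnConfig(n_filters=4, kernel_size=3, dilations=(1, 2),
                        dropout_rate=0.0, in_channels=3)
        model = build_model(cfg, seed=1, dtype=np.float64)
        x = rng.normal(size=(2, 17, 3))
        t = rng.random((2, 17, 2))
        model.zero_grad()
        model.loss_and_grad(x, t, training=True)
        grads = [p.grad.copy() for p in model.params()]

        def loss():
            yic, yfc = model.forward(x, training=True)
            return 0.5 * (np.mean((yic - t[..., 0]) ** 2)
                          + np.mean((yfc - t[..., 1]) ** 2))

        eps = 1e-6
        for p, g in zip(model.params(), grads):
            flat, gf = p.value.ravel(), g.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size),
                                replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                if abs(num) + abs(gf[i]) > 1e-7:
                    assert abs(num - gf[i]) / (abs(num) + abs(gf[i])) < 1e-5


class TestPredictTrial:
    def test_deterministic_inference(self, rng):
        model = build_model(_table_config(), seed=2)
        x = rng.normal(size=(600, 6))
        a = predict_trial(model, x)
        b = predict_trial(model, x)
        assert np.array_equal(a.yic, b.yic) and np.array_equal(a.yfc, b.yfc)

    def test_arbitrary_lengths_accepted(self, rng):
        model = build_model(_table_config(), seed=2)
        for n in (400, 731):
            traces = predict_trial(model, rng.normal(size=(n, 6)))
            assert len(traces.yic) == len(traces.yfc) == n

    def test_wrong_channel_count_rejected(self, rng):
        model = build_model(_table_config(), seed=2)
        with pytest.raises(ValueError):
            predict_trial(model, rng.normal(size=(400, 5)))

    def test_short_trial_warns(self, rng):
        model = build_model(_table_config(), seed=2)
        with pytest.warns(UserWarning, match="receptive"):
            predict_trial(model, rng.normal(size=(10, 6)))

    def test_prediction_is_local(self, rng):
        # perturbing beyond the receptive-field half-width leaves the
        # probe sample untouched; perturbing at the half-width changes it
        cfg = TcnConfig(dropout_rate=0.0)
        model = build_model(cfg, seed=3)
        half = (receptive_field(cfg) - 1) // 2
        x = rng.normal(size=(400, 6))
        probe = 200
        y0 = predict_trial(model, x).yic[probe]
        far = x.copy()
        far[probe + half + 1] += 10.0
        assert predict_trial(model, far).yic[probe] == y0
        near = x.copy()
        near[probe + half] += 10.0
        assert predict_trial(model, near).yic[probe] != y0


def _tiny_window_set(rng, n_trials=1, n=600):
    from gaitevents import FootEvents, encode_event_labels
    xs = []
    for i in range(n_trials):
        x = rng.normal(size=(n, 6))
        labels = encode_event_labels(FootEvents([0.8 + i * 0.01, 2.4], [1.6]),
                                     n, 200.0)
        xs.append(make_windows(x, labels.stacked, trial_id=f"t{i}"))
    from gaitevents.preprocessing import concat_window_sets
    return concat_window_sets(xs)


class TestTrainModel:
    def test_memorizes_two_windows(self, rng):
        train = _tiny_window_set(rng)
        assert len(train) == 2
        cfg = TcnConfig(n_filters=8, dropout_rate=0.0)
        model = build_model(cfg, seed=4)
        hist = train_model(model, train, None,
                           TrainConfig(learning_rate=1e-2, max_epochs=200,
                                       patience=200, seed=0))
        assert hist.train_loss[-1] < 1e-3

    def test_validation_loss_finite_and_improves(self):
        # learnable synthetic walking data: held-out subjects' loss drops
        from gaitevents import generate_cohort, simulate_trial
        from gaitevents.pipeline import _window_sets_for_trial, reference_events
        from gaitevents.preprocessing import concat_window_sets

        cohort = generate_cohort(5, seed=3)
        sets = {"train": [], "val": []}
        for i, subj in enumerate(cohort):
            for j, speed in enumerate(("preferred", "fast")):
                trial = simulate_trial(subj, speed, seed=100 + 2 * i + j)
                events = reference_events(trial)
                sets["train" if i < 3 else "val"] += _window_sets_for_trial(
                    trial, events, subj.subject_id, ("left_ankle",),
                    400, 0.5, 5.0, n_augment=0, seed=0)
        train = concat_window_sets(sets["train"])
        val = concat_window_sets(sets["val"])
        model = build_model(TcnConfig(), seed=5)
        hist = train_model(model, train, val,
                           TrainConfig(max_epochs=10, patience=10, seed=1))
        assert np.all(np.isfinite(hist.val_loss))
        assert min(hist.val_loss) < hist.val_loss[0]

    def test_empty_training_set_rejected(self, rng):
        val = _tiny_window_set(rng)
        empty = type(val)(windows=val.windows[:0], targets=val.targets[:0],
                          trial_ids=val.trial_ids[:0],
                          start_samples=val.start_samples[:0])
        with pytest.raises(ValueError):
            train_model(build_model(_table_config()), empty, val)


class TestRandomSearch:
    def test_budget_one_returns_single_config(self, rng):
        train = _tiny_window_set(rng, n_trials=2)
        val = _tiny_window_set(rng)
        cfg, model, log = random_search(
            train, val, budget=1, seed=7,
            train_cfg=TrainConfig(max_epochs=1, patience=1, seed=0),
            retrain_on_combined=False)
        assert len(log) == 1 and log[0]["config"] == cfg

    def test_samples_lie_in_grid_and_argmin_wins(self, rng):
        train = _tiny_window_set(rng, n_trials=2)
        val = _tiny_window_set(rng)
        space = {"n_filters": (4, 8), "kernel_size": (3, 5),
                 "dilations": ((1,), (1, 2))}
        cfg, _, log = random_search(
            train, val, budget=4, seed=8,
            train_cfg=TrainConfig(max_epochs=1, patience=1, seed=0),
            space=space, retrain_on_combined=False)
        losses = [t["val_loss"] for t in log]
        for t in log:
            c = t["config"]
            assert c.n_filters in space["n_filters"]
            assert c.kernel_size in space["kernel_size"]
            assert tuple(c.dilations) in space["dilations"]
        best = min(t["val_loss"] for t in log if t["config"] == cfg)
        assert best <= np.median(losses)

    def test_default_space_matches_candidate_grid(self):
        assert DEFAULT_SEARCH_SPACE["n_filters"] == (8, 16, 32, 64, 128)
        assert DEFAULT_SEARCH_SPACE["kernel_size"] == (3, 5, 7)
        assert DEFAULT_SEARCH_SPACE["dilations"] == ((1, 2), (1, 2, 4),
                                                     (1, 2, 4, 8))


def test_checkpoint_round_trip(tmp_path, rng):
    model = build_model(TcnConfig(n_filters=8), seed=6)
    x = rng.normal(size=(300, 6))
    save_model(model, tmp_path / "ck.npz")
    back = load_model(tmp_path / "ck.npz")
    a, b = predict_trial(model, x), predict_trial(back, x)
    assert np.allclose(a.yic, b.yic, atol=1e-7)
    assert back.config == model.config
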