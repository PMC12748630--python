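"""Optimization schedule, learnability, transfer freeze and checkpoints."""

import dataclasses

import numpy as np
import pytest

from vestgait.errors import ContractError
from vestgait.model import ModelSpec, build_model
from vestgait.normalization import apply_range, fit_range
from vestgait.segmentation import resample_cycle
from vestgait.synthetic import ActivityWindowConfig, generate_activity_windows
from vestgait.training import (
    Checkpoint,
    FinetuneConfig,
    TrainConfig,
    finetune,
    pretrain,
    train,
)

SPEC = ModelSpec(filters_per_block=(4, 8, 16, 32), dense_sizes=(32, 16), seed=0)
FAST = TrainConfig(epochs=6, batch_size=16, learning_rate=0.01, seed=0)


@pytest.fixture(scope="module")
def separable_data(tiny_dataset):
    X = tiny_dataset.X
    norm = fit_range(X)
    return apply_range(norm, X).astype(np.float32), tiny_dataset.y


def test_step_schedule_arithmetic():
    config = TrainConfig()
    assert [config.lr_at_epoch(e) for e in (1, 25, 26, 51, 76)] == pytest.approx(
        [0.1, 0.1, 0.01, 0.001, 0.0001]
    )


def test_lr_history_follows_schedule():
    config = dataclasses.replace(FAST, epochs=5, lr_step_size=2, lr_decay=0.5)
    model = build_model(SPEC)
    X = np.random.default_rng(0).standard_normal((8, 6, 512)).astype(np.float32)
    y = np.array([0, 1] * 4, dtype=np.float32)
    result = train(model, X, y, config)
    assert result.lr_history == pytest.approx(
        [0.01, 0.01, 0.005, 0.005, 0.0025]
    )
    assert len(result.loss_history) == config.epochs


def test_separable_cycles_are_learned(separable_data):
    """A strong synthetic group effect is fit to >= 95% training accuracy."""
    X, y = separable_data
    model = build_model(SPEC)
    train(model, X, y, dataclasses.replace(FAST, epochs=12))
    accuracy = ((model.predict_proba(X) >= 0.5).astype(int) == y).mean()
    assert accuracy >= 0.95


def test_label_permutation_raises_final_loss(separable_data):
    X, y = separable_data
    model_true = build_model(SPEC)
    res_true = train(model_true, X, y, FAST)
    y_perm = np.random.default_rng(5).permutation(y)
    model_perm = build_model(SPEC)
    res_perm = train(model_perm, X, y_perm, FAST)
    assert res_perm.loss_history[-1] > res_true.loss_history[-1]


def test_training_is_seed_deterministic(separable_data):
    X, y = separable_data
    runs = []
    for _ in range(2):
        model = build_model(SPEC)
        runs.append(train(model, X, y, FAST).loss_history)
    assert runs[0] == runs[1]


def test_single_class_training_rejected():
    X = np.zeros((6, 6, 512), dtype=np.float32)
    with pytest.raises(ContractError, match="single class"):
        train(build_model(SPEC), X, np.ones(6), FAST)


def test_trailing_singleton_batch_is_merged(separable_data):
    X, y = separable_data
    n = X.shape[0] - (X.shape[0] % 16 - 1) % 16  # make n % 16 == 1
    n = (n // 16) * 16 + 1
    model = build_model(SPEC)
    result = train(model, X[:n], y[:n], dataclasses.replace(FAST, epochs=1))
    assert result.n_steps == n // 16  # last lone sample folded into prior batch


# -- pretraining / fine-tuning ---------------------------------------------


def _activity_512(n_per_class, seed, **kwargs):
    windows, labels = generate_activity_windows(
        ActivityWindowConfig(n_windows_per_class=n_per_class, seed=seed, **kwargs)
    )
    X = np.stack([resample_cycle(w, method="cubic") for w in windows])
    return X.astype(np.float32), labels


def test_pretrain_separable_frequencies():
    X, y = _activity_512(24, seed=0)
    _, val_acc = pretrain(SPEC, X, y, dataclasses.replace(FAST, epochs=12), n_folds=4)
    assert val_acc >= 0.9


def test_pretrain_identical_frequencies_is_chance():
    X, y = _activity_512(16, seed=1, class_freq=(2.0, 2.0), noise_sd=1.0)
    _, val_acc = pretrain(SPEC, X, y, dataclasses.replace(FAST, epochs=8), n_folds=4)
    # 95% binomial band around 0.5 for 64 validation windows
    assert abs(val_acc - 0.5) <= 1.96 * 0.5 / np.sqrt(64) + 1e-9


def test_checkpoint_round_trip(tmp_path, separable_data):
    X, y = separable_data
    model = build_model(SPEC)
    train(model, X, y, FAST)
    ckpt = Checkpoint(spec=SPEC, state=model.state_dict(), meta={"k": "v"})
    path = ckpt.save(tmp_path / "model.npz")
    back = Checkpoint.load(path)
    np.testing.assert_array_equal(back.build().predict_proba(X),
                                  model.predict_proba(X))
    assert back.meta == {"k": "v"}


def test_finetune_freezes_conv_stage_exactly(separable_data):
    X, y = separable_data
    source_X, source_y = _activity_512(12, seed=2)
    ckpt, _ = pretrain(SPEC, source_X, source_y,
                       dataclasses.replace(FAST, epochs=4), n_folds=3)
    cfg = FinetuneConfig(epochs=5, batch_size=16, learning_rate=0.01, seed=1)
    model, result = finetune(ckpt, X, y, cfg)
    after = model.state_dict()
    for name, value in ckpt.state.items():
        if name.startswith("branches."):
            np.testing.assert_array_equal(after[name], value, err_msg=name)
    # dense stage did move
    assert any(
        np.abs(after[name] - value).max() > 0
        for name, value in ckpt.state.items()
        if name.startswith(("dense", "out."))
    )
    # bookkeeping: steps = epochs x batches per epoch
    n_batches = int(np.ceil(X.shape[0] / cfg.batch_size))
    if X.shape[0] % cfg.batch_size == 1:
        n_batches -= 1
    assert result.n_steps == cfg.epochs * n_batches


def test_finetune_shape_mismatch_rejected(separable_data):
    X, y = separable_data
    bad_spec = dataclasses.replace(SPEC, input_shape=(6, 256))
    ckpt = Checkpoint(spec=bad_spec, state=build_model(bad_spec).state_dict())
    with pytest.raises(ContractError, match="shape"):
        finetune(ckpt, X, y, FinetuneConfig())
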