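"""Training, pretraining and freeze-then-fine-tune transfer learning.

Baseline training follows the published recipe: binary cross-entropy loss,
the Adam optimizer, 100 epochs at batch size 64, initial learning rate 0.1
and a step scheduler that multiplies the rate by 0.1 after every 25 epochs
(epochs 1/26/51/76 run at 0.1/0.01/0.001/0.0001).  Pretraining on a source
dataset reports cross-validated source performance and returns a checkpoint;
fine-tuning restores the checkpoint, freezes the convolutional stage
bit-for-bit (including its batch-norm statistics) and updates only the dense
stage for 20 epochs.

Runs are deterministic given the config seed: shuffling, dropout and
parameter initialization all derive from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .errors import ContractError
from .model import GaitClassifier, ModelSpec, build_model
from .nn import Adam, bce_with_logits, clip_grad_norm
from .normalization import NormalizationParams, apply_range, fit_range

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    """Baseline optimization hyperparameters."""

    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 0.1
    lr_step_size: int = 25
    lr_decay: float = 0.1
    seed: int = 0
    shuffle: bool = True
    #: optional global gradient-norm cap; None disables clipping
    grad_clip: float | None = None

    def validate(self) -> None:
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ContractError("batch_size must be >= 2")
        if self.learning_rate <= 0:
            raise ContractError("learning_rate must be > 0")
        if self.lr_step_size < 1 or not 0 < self.lr_decay <= 1:
            raise ContractError("invalid learning-rate schedule")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index."""
        return self.learning_rate * self.lr_decay ** ((epoch - 1) // self.lr_step_size)


@dataclass
class FinetuneConfig:
    """Transfer-learning settings: frozen convolutional stage, 20 dense epochs."""

    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 0.1
    lr_step_size: int = 25
    lr_decay: float = 0.1
    seed: int = 0
    shuffle: bool = True
    grad_clip: float | None = None
    #: learning rate used when pretraining on activity-window sources
    pretrain_learning_rate_activity: float = 0.001


@dataclass
class TrainResult:
    loss_history: list[float]
    lr_history: list[float]
    n_steps: int


def _batches(n: int, batch_size: int, rng: np.random.Generator, shuffle: bool):
    idx = rng.permutation(n) if shuffle else np.arange(n)
    batches = [idx[s : s + batch_size] for s in range(0, n, batch_size)]
    # a trailing singleton cannot feed batch normalization; fold it into the
    # previous batch (documented minimum effective batch of 2)
    if len(batches) > 1 and len(batches[-1]) == 1:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    if len(batches) == 1 and len(batches[0]) < 2:
        raise ContractError("training needs at least 2 samples")
    return batches


def train(
    model: GaitClassifier,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    trainable: str = "all",
) -> TrainResult:
    """Mini-batch gradient descent; mutates the model in place.

    ``trainable`` is ``"all"`` or ``"dense"`` (convolutional stage frozen and
    run in eval mode, as in fine-tuning).
    """
    config.validate()
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if X.shape[0] != y.shape[0]:
        raise ContractError("X and y disagree in sample count")
    if np.unique(y).size < 2:
        raise ContractError("training set contains a single class")
    if trainable == "all":
        params = model.parameters()
        branch_mode = None
        through_branches = True
    elif trainable == "dense":
        params = model.dense_parameters()
        branch_mode = "eval"
        through_branches = False
    else:
        raise ContractError(f"unknown trainable selection {trainable!r}")
    optimizer = Adam(params)
    model.reseed_dropout(config.seed + 1)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    loss_history: list[float] = []
    lr_history: list[float] = []
    n_steps = 0
    for epoch in range(1, config.epochs + 1):
        lr = config.lr_at_epoch(epoch)
        lr_history.append(lr)
        epoch_loss = 0.0
        for batch in _batches(X.shape[0], config.batch_size, shuffle_rng, config.shuffle):
            logits = model.forward_logits(X[batch], mode="train", branch_mode=branch_mode)
            loss, dlogits = bce_with_logits(logits, y[batch])
            optimizer.zero_grad()
            model.backward(dlogits, through_branches=through_branches)
            if config.grad_clip is not None:
                clip_grad_norm(params, config.grad_clip)
            optimizer.step(lr)
            n_steps += 1
            epoch_loss += loss * batch.size
        loss_history.append(epoch_loss / X.shape[0])
    return TrainResult(loss_history, lr_history, n_steps)


# ---------------------------------------------------------------------------
# checkpoints


@dataclass
class Checkpoint:
    """A trained model snapshot: spec, parameters, normalization, metadata."""

    spec: ModelSpec
    state: dict[str, np.ndarray]
    norm_params: NormalizationParams | None = None
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix != ".npz":  # np.savez appends .npz silently
            path = path.with_suffix(path.suffix + ".npz")
        path.parent.mkdir(parents=True, exist_ok=True)
        header = {
            "version": CHECKPOINT_VERSION,
            "spec": self.spec.to_dict(),
            "meta": self.meta,
            "norm": None
            if self.norm_params is None
            else {
                "minimum": self.norm_params.minimum.tolist(),
                "maximum": self.norm_params.maximum.tolist(),
                "mode": self.norm_params.mode,
            },
        }
        hdr = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
        np.savez(path, __header__=hdr, **self.state)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            if header.get("version") != CHECKPOINT_VERSION:
                raise ContractError(
                    f"unsupported checkpoint version {header.get('version')}"
                )
            state = {k: data[k] for k in data.files if k != "__header__"}
        norm = None
        if header["norm"] is not None:
            norm = NormalizationParams(
                minimum=np.array(header["norm"]["minimum"]),
                maximum=np.array(header["norm"]["maximum"]),
                mode=header["norm"]["mode"],
            )
        return cls(
            spec=ModelSpec.from_dict(header["spec"]),
            state=state,
            norm_params=norm,
            meta=header["meta"],
        )

    def build(self) -> GaitClassifier:
        model = build_model(self.spec)
        model.load_state_dict(self.state)
        return model


# ---------------------------------------------------------------------------
# pretraining and fine-tuning


def pretrain(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    n_folds: int = 5,
    subject_ids: np.ndarray | None = None,
) -> tuple[Checkpoint, float]:
    """Train on a source dataset; returns (checkpoint, validation accuracy).

    Validation accuracy is the mean held-out accuracy over ``n_folds``
    cross-validation folds of the source: grouped by subject when
    ``subject_ids`` is given (segmented pathological sources), plain
    stratified sample-level folds otherwise (unsegmented activity windows).
    The checkpoint itself is trained on the full source with normalization
    fitted on all source samples.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    accuracies: list[float] = []
    if subject_ids is not None:
        splitter = GroupKFold(n_splits=n_folds)
        splits = splitter.split(X, y, groups=subject_ids)
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=config.seed % 2**31)
        splits = splitter.split(X, y)
    for fold, (train_idx, val_idx) in enumerate(splits):
        norm = fit_range(X[train_idx])
        fold_spec = replace(spec, seed=spec.seed + fold)
        fold_model = build_model(fold_spec)
        fold_cfg = replace(config, seed=config.seed + fold)
        train(fold_model, apply_range(norm, X[train_idx]), y[train_idx], fold_cfg)
        probs = fold_model.predict_proba(apply_range(norm, X[val_idx]))
        preds = probs >= spec.decision_threshold
        accuracies.append(float((preds == (y[val_idx] == 1)).mean()))
    norm = fit_range(X)
    model = build_model(spec)
    result = train(model, apply_range(norm, X), y, config)
    checkpoint = Checkpoint(
        spec=spec,
        state=model.state_dict(),
        norm_params=norm,
        meta={
            "kind": "pretrained",
            "validation_accuracy": float(np.mean(accuracies)),
            "n_folds": n_folds,
            "final_loss": result.loss_history[-1],
        },
    )
    return checkpoint, float(np.mean(accuracies))


def finetune(
    checkpoint: Checkpoint,
    X: np.ndarray,
    y: np.ndarray,
    config: FinetuneConfig,
) -> tuple[GaitClassifier, TrainResult]:
    """Restore a checkpoint, freeze the convolutional stage, train the dense
    stage for ``config.epochs`` epochs on the (already normalized) target data.

    Frozen parameters — every convolutional branch weight, bias, batch-norm
    affine and running statistic — are bit-identical before and after.
    """
    if tuple(checkpoint.spec.input_shape) != tuple(np.asarray(X).shape[1:]):
        raise ContractError(
            f"checkpoint input shape {checkpoint.spec.input_shape} does not "
            f"match target data {np.asarray(X).shape[1:]}"
        )
    model = checkpoint.build()
    train_cfg = TrainConfig(
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        lr_step_size=config.lr_step_size,
        lr_decay=config.lr_decay,
        seed=config.seed,
        shuffle=config.shuffle,
        grad_clip=config.grad_clip,
    )
    result = train(model, X, y, train_cfg, trainable="dense")
    return model, result
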