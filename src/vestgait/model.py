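"""The six-branch parallel 1-D convolutional gait classifier.

Each of the six input channels (one row of the 6 x 512 cycle matrix) is
processed by its own convolutional branch with no weight sharing; a branch is
four repetitions of [Conv1d(kernel 3, pad 1, stride 1) -> ReLU ->
BatchNorm1d -> MaxPool1d(2, 2)].  Branch outputs are flattened, concatenated
and passed to a dense stage of two [Linear -> ReLU -> BatchNorm1d ->
Dropout(0.5)] blocks, then a final single-unit affine layer whose logistic
output is the probability of the patient class.  A probability at or above
the decision threshold (default 0.5; ties count as positive) predicts
"patient".

Filter counts and dense widths default to [8, 16, 32, 64] and [128, 64] and
are fully configurable through :class:`ModelSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ContractError
from .nn import BatchNorm1d, Dropout, GroupedConv1d, Layer, Linear, MaxPool1d, ReLU

POSITIVE_LABEL = "patient"
NEGATIVE_LABEL = "control"


@dataclass
class ModelSpec:
    """Architecture hyperparameters of the classifier."""

    n_branches: int = 6
    conv_blocks_per_branch: int = 4
    kernel_size: int = 3
    padding: int = 1
    conv_stride: int = 1
    pool_size: int = 2
    pool_stride: int = 2
    filters_per_block: tuple[int, ...] = (8, 16, 32, 64)
    dense_sizes: tuple[int, ...] = (128, 64)
    dropout_rate: float = 0.5
    output_units: int = 1
    input_shape: tuple[int, int] = (6, 512)
    decision_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_branches != self.input_shape[0]:
            raise ContractError("n_branches must equal the input channel count")
        if len(self.filters_per_block) != self.conv_blocks_per_branch:
            raise ContractError("filters_per_block must list one count per block")
        if self.conv_stride != 1:
            raise ContractError("only conv stride 1 is supported")
        if self.pool_size != self.pool_stride:
            raise ContractError("pooling uses kernel == stride")
        divisor = self.pool_size**self.conv_blocks_per_branch
        if self.input_shape[1] % divisor != 0:
            raise ContractError(
                f"time axis {self.input_shape[1]} not divisible by "
                f"{divisor} (pool_size^blocks)"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ContractError("dropout_rate must be in [0, 1)")
        if not 0 < self.decision_threshold < 1:
            raise ContractError("decision_threshold must be in (0, 1)")

    @property
    def branch_time_axis(self) -> int:
        """Time-axis length after the branch's pooling stages (512 -> 32)."""
        return self.input_shape[1] // self.pool_size**self.conv_blocks_per_branch

    @property
    def flattened_features(self) -> int:
        return self.n_branches * self.filters_per_block[-1] * self.branch_time_axis

    def to_dict(self) -> dict:
        return {
            "n_branches": self.n_branches,
            "conv_blocks_per_branch": self.conv_blocks_per_branch,
            "kernel_size": self.kernel_size,
            "padding": self.padding,
            "conv_stride": self.conv_stride,
            "pool_size": self.pool_size,
            "pool_stride": self.pool_stride,
            "filters_per_block": list(self.filters_per_block),
            "dense_sizes": list(self.dense_sizes),
            "dropout_rate": self.dropout_rate,
            "output_units": self.output_units,
            "input_shape": list(self.input_shape),
            "decision_threshold": self.decision_threshold,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        data = dict(data)
        data["filters_per_block"] = tuple(data["filters_per_block"])
        data["dense_sizes"] = tuple(data["dense_sizes"])
        data["input_shape"] = tuple(data["input_shape"])
        return cls(**data)


def conv_parameter_count(spec: ModelSpec) -> int:
    """Weights + biases of one branch's convolutions: sum(c_in*c_out*k + c_out)."""
    count = 0
    c_in = 1
    for c_out in spec.filters_per_block:
        count += c_in * c_out * spec.kernel_size + c_out
        c_in = c_out
    return count


def parameter_count(spec: ModelSpec) -> int:
    """Closed-form total trainable parameter count (conv + BN + dense)."""
    per_branch = conv_parameter_count(spec) + 2 * sum(spec.filters_per_block)
    total = spec.n_branches * per_branch
    width = spec.flattened_features
    for size in spec.dense_sizes:
        total += width * size + size  # linear
        total += 2 * size  # batch norm
        width = size
    total += width * spec.output_units + spec.output_units
    return total


class GaitClassifier:
    """The assembled network; build with :func:`build_model`.

    The six branches are mathematically independent (no weight sharing; the
    joint convolutional stage is block-diagonal across branches) but are
    evaluated as stacked grouped operations for speed.
    """

    def __init__(self, spec: ModelSpec):
        spec.validate()
        self.spec = spec
        init_rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        #: rng consumed by dropout during training; reseeded by the trainer.
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence(spec.seed + 1))
        b = spec.n_branches
        self.conv_stage: list[Layer] = []
        c_in = 1
        for i, c_out in enumerate(spec.filters_per_block):
            self.conv_stage.append(
                GroupedConv1d(b, c_in, c_out, spec.kernel_size, spec.padding,
                              init_rng, f"branches.conv{i}")
            )
            self.conv_stage.append(ReLU())
            self.conv_stage.append(BatchNorm1d((b, c_out), f"branches.bn{i}"))
            self.conv_stage.append(MaxPool1d(spec.pool_size))
            c_in = c_out
        self.dense: list[Layer] = []
        width = spec.flattened_features
        for i, size in enumerate(spec.dense_sizes):
            self.dense.append(Linear(width, size, init_rng, f"dense{i}"))
            self.dense.append(ReLU())
            self.dense.append(BatchNorm1d(size, f"dense{i}.bn"))
            self.dense.append(Dropout(spec.dropout_rate, self.dropout_rng))
            width = size
        self.output = Linear(width, spec.output_units, init_rng, "out")

    def reseed_dropout(self, seed: int) -> None:
        """Re-seed the dropout stream in place (shared by all dropout layers)."""
        fresh = np.random.default_rng(np.random.SeedSequence(seed))
        self.dropout_rng.bit_generator.state = fresh.bit_generator.state

    # -- parameter access ---------------------------------------------------

    def conv_parameters(self) -> list[nn.Parameter]:
        return [p for layer in self.conv_stage for p in layer.params()]

    def dense_parameters(self) -> list[nn.Parameter]:
        params = [p for layer in self.dense for p in layer.params()]
        return params + self.output.params()

    def parameters(self) -> list[nn.Parameter]:
        return self.conv_parameters() + self.dense_parameters()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for layer in self.conv_stage + self.dense:
            for name, buf in layer.buffers().items():
                state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise ContractError(f"checkpoint misses parameter {p.name}")
            if p.value.shape != state[p.name].shape:
                raise ContractError(f"shape mismatch for {p.name}")
            p.value = state[p.name].astype(np.float32).copy()
        for layer in self.conv_stage + self.dense:
            for name in layer.buffers():
                if name in state:
                    attr = name.rsplit(".", 1)[1]
                    setattr(layer, attr, state[name].astype(np.float32).copy())

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != tuple(self.spec.input_shape):
            raise ContractError(
                f"expected input (n, {self.spec.input_shape[0]}, "
                f"{self.spec.input_shape[1]}), got {x.shape}"
            )
        return x

    def _conv_features(self, x: np.ndarray, mode: str) -> np.ndarray:
        """Convolutional-stage output, shape (n, branches, filters, time)."""
        h = x[:, :, None, :]  # (n, branches, 1, time)
        for layer in self.conv_stage:
            h = layer.forward(h, mode)
        return h

    def branch_features(self, x: np.ndarray, mode: str = "eval") -> list[np.ndarray]:
        """Per-branch flattened feature vectors (pre-concatenation)."""
        x = self._check_input(x)
        h = self._conv_features(x, mode)
        return [h[:, b].reshape(h.shape[0], -1) for b in range(self.spec.n_branches)]

    def forward_logits(
        self, x: np.ndarray, mode: str = "eval", branch_mode: str | None = None
    ) -> np.ndarray:
        """Logits of the patient class.  ``branch_mode`` overrides the mode of
        the convolutional stage (used to freeze it during fine-tuning)."""
        x = self._check_input(x)
        h = self._conv_features(x, branch_mode or mode)
        self._feature_shape = h.shape[1:]
        h = h.reshape(h.shape[0], -1)
        for layer in self.dense:
            h = layer.forward(h, mode)
        z = self.output.forward(h, mode)
        return z[:, 0]

    def backward(self, dlogits: np.ndarray, through_branches: bool = True) -> None:
        grad = self.output.backward(dlogits[:, None].astype(np.float32))
        for layer in reversed(self.dense):
            grad = layer.backward(grad)
        if not through_branches:
            return
        grad = grad.reshape(grad.shape[0], *self._feature_shape)
        for layer in reversed(self.conv_stage):
            grad = layer.backward(grad)

    def forward(self, x: np.ndarray, mode: str = "eval") -> np.ndarray:
        """Per-sample probabilities of the patient class, strictly in (0, 1)."""
        return nn.sigmoid(self.forward_logits(x, mode))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic eval-mode probabilities, computed in batches."""
        x = self._check_input(x)
        chunks = [
            self.forward(x[i : i + batch_size], mode="eval")
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(chunks)


def build_model(spec: ModelSpec | None = None) -> GaitClassifier:
    """Construct the classifier with parameters initialized from spec.seed."""
    return GaitClassifier(spec or ModelSpec())


def predict_label(probability: float, threshold: float = 0.5) -> str:
    """Map a patient-class probability to a group label; ties are positive."""
    if not 0 <= probability <= 1:
        raise ContractError("probability must lie in [0, 1]")
    return POSITIVE_LABEL if probability >= threshold else NEGATIVE_LABEL
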