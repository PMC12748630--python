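"""Preset study conditions for the packaged synthetic-cohort experiments.

The property studies shipped with the package (chance-level behaviour on a
null cohort, effect recovery across the amplitude-effect ladder, subsampling
ablations) run on small synthetic cohorts, so they use a proportionally
scaled-down instance of the classifier and a short training schedule.  The
architecture keeps the published topology exactly — six independent branches
of four conv/ReLU/batch-norm/max-pool blocks, two dense blocks with 50%
dropout, logistic output — with narrower layers (filters 4/8/16/32, dense
64/32), and training runs 12 epochs of Adam at learning rate 0.01 with batch
size 24.  These are the package's chosen study conditions for cohorts of
8 subjects per group with ~7 cycles each; the full-scale defaults of
:class:`~vestgait.model.ModelSpec` and :class:`~vestgait.training.TrainConfig`
remain the published recipe.
"""

from __future__ import annotations

from .model import ModelSpec
from .synthetic import fixture_cohort_config  # noqa: F401  (re-export)
from .training import FinetuneConfig, TrainConfig

#: Placement carrying the strongest default group effect (restricted head
#: rotation); used by the effect-recovery studies.
EFFECT_PLACEMENT = "head"
#: The ablation studies subsample the fixture's best-performing sensor,
#: mirroring the published design of ablating the best sensor; under the
#: default effect map that is the head placement.
ABLATION_PLACEMENT = "head"


def fixture_model_spec(seed: int = 0) -> ModelSpec:
    """Scaled-down classifier for the synthetic-cohort studies."""
    return ModelSpec(filters_per_block=(4, 8, 16, 32), dense_sizes=(64, 32), seed=seed)


def fixture_train_config(seed: int = 0) -> TrainConfig:
    """Short small-sample training schedule for the synthetic-cohort studies."""
    return TrainConfig(epochs=12, batch_size=24, learning_rate=0.01, seed=seed)


def fixture_finetune_config(seed: int = 0) -> FinetuneConfig:
    """Fine-tuning schedule for the synthetic transfer studies (20 dense epochs)."""
    return FinetuneConfig(epochs=20, batch_size=24, learning_rate=0.01, seed=seed)
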