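"""Packaged synthetic-cohort studies.

Self-contained drivers that generate a synthetic cohort under the preset
study conditions (see :mod:`vestgait.fixtures`) and measure one property of
the pipeline end-to-end:

* ``chance_study`` — LOOCV on a null cohort (zero group effect) repeated
  over seeds; the mean accuracy should sit inside the 95% binomial band
  around 0.5 expected when per-subject outcomes are coin flips.
* ``effect_ladder_study`` — LOOCV accuracy across the amplitude-effect
  ladder (weak/medium/strong), seed-averaged.
* ``ablation_study`` — subject-fraction ablation on the strong-effect
  cohort (wrist sensor, the ablation default).
* ``segmentation_oracle_study`` — detected cycle counts on zero-jitter
  trials versus the generator's known stride count, and boundary
  invariance across all six placements.
* ``freeze_study`` — pretrain/fine-tune round trip reporting the maximum
  absolute change of any frozen convolutional parameter (exactly 0).

Problem sizes (8 subjects/group, ~7 cycles each, 12 training epochs) are the
package's chosen conditions for these small-cohort studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import run_loocv
from .experiments import AblationConfig, ablate
from .fixtures import (
    ABLATION_PLACEMENT,
    EFFECT_PLACEMENT,
    fixture_cohort_config,
    fixture_finetune_config,
    fixture_model_spec,
    fixture_train_config,
)
from .io import PLACEMENTS
from .segmentation import build_cycle_dataset, detect_cycles, resample_cycle
from .synthetic import (
    ActivityWindowConfig,
    generate_activity_windows,
    generate_cohort,
)
from .training import finetune, pretrain


def _loocv_overall(effect: str, seed: int, placement: str) -> float:
    cohort = generate_cohort(fixture_cohort_config(effect, seed=seed))
    dataset = build_cycle_dataset(cohort, "level_walk_short", placement)
    report = run_loocv(dataset, fixture_model_spec(seed), fixture_train_config(seed))
    return report.overall_mean


def binomial_band(n_trials: int, level_sd: float = 1.96) -> tuple[float, float]:
    """Central 95% band around 0.5 for the mean of n Bernoulli(0.5) outcomes."""
    half = level_sd * 0.5 / np.sqrt(n_trials)
    return 0.5 - half, 0.5 + half


def chance_study(
    n_seeds: int = 10, seed0: int = 0, placement: str = EFFECT_PLACEMENT
) -> dict:
    """Mean LOOCV accuracy over seeds on zero-effect cohorts.

    The band treats each held-out subject's accuracy as one Bernoulli(0.5)
    outcome (under the null a subject tends to be classified wholesale), so
    n = n_seeds x n_subjects.
    """
    values = [_loocv_overall("none", seed0 + i, placement) for i in range(n_seeds)]
    n_subjects = 16  # 8 per group under the fixture conditions
    lo, hi = binomial_band(n_seeds * n_subjects)
    return {
        "per_seed": values,
        "mean": float(np.mean(values)),
        "band": (lo, hi),
        "n_seeds": n_seeds,
    }


def effect_ladder_study(
    n_seeds: int = 3, seed0: int = 0, placement: str = EFFECT_PLACEMENT
) -> dict[str, float]:
    """Seed-averaged LOOCV accuracy for the weak/medium/strong effect ladder."""
    out: dict[str, float] = {}
    for effect in ("weak", "medium", "strong"):
        vals = [_loocv_overall(effect, seed0 + i, placement) for i in range(n_seeds)]
        out[effect] = float(np.mean(vals))
    return out


def ablation_study(
    iterations: int = 5,
    seed: int = 0,
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Subject-fraction ablation on the strong-effect cohort (wrist sensor)."""
    cohort = generate_cohort(fixture_cohort_config("strong", seed=seed))
    dataset = build_cycle_dataset(cohort, "level_walk_short", ABLATION_PLACEMENT)
    config = AblationConfig(
        mode="subjects", fractions=fractions, iterations=iterations,
        placement=ABLATION_PLACEMENT, seed=seed,
    )
    return ablate(dataset, config, fixture_model_spec(seed), fixture_train_config(seed))


def segmentation_oracle_study(seed: int = 0) -> dict:
    """Cycle counts on zero-jitter trials vs. the generator's known count.

    With jitter, noise and stride scatter all zero and stride 1 Hz over a
    10 s trial the pitch channel peaks exactly 10 times, so 9 interior
    [peak, next peak) cycles must be detected, identically at all placements.
    """
    cfg = fixture_cohort_config(
        "none", seed=seed, trial_duration_s=10.0, cycle_jitter_sd=0.0,
        noise_sd=0.0, stride_freq_subject_sd=0.0, subject_random_effect_sd=0.0,
    )
    cohort = generate_cohort(cfg)
    expected = int(cfg.trial_duration_s * cfg.stride_freq_mean) - 1
    counts = {}
    for sid in cohort.subject_ids():
        boundaries = detect_cycles(cohort.trials[(sid, cfg.task, "ankle_right")])
        counts[sid] = len(boundaries)
    per_placement = {
        p: len(build_cycle_dataset(cohort, cfg.task, p).samples) for p in PLACEMENTS
    }
    return {
        "expected_per_subject": expected,
        "detected_per_subject": counts,
        "all_match": all(c == expected for c in counts.values()),
        "per_placement_totals": per_placement,
        "boundary_invariant": len(set(per_placement.values())) == 1,
    }


def freeze_study(seed: int = 0) -> dict:
    """Pretrain on activity windows, fine-tune on a cohort, audit the freeze.

    Returns the maximum absolute difference of any convolutional-stage
    parameter or batch-norm statistic between checkpoint and fine-tuned
    model (the freeze contract demands exactly 0), plus the source
    validation accuracy.
    """
    windows, labels = generate_activity_windows(
        ActivityWindowConfig(n_windows_per_class=24, seed=seed)
    )
    X = np.stack([resample_cycle(w, method="cubic") for w in windows])
    spec = fixture_model_spec(seed)
    cfg = fixture_train_config(seed)
    checkpoint, val_acc = pretrain(spec, X, labels, cfg, n_folds=4)

    cohort = generate_cohort(fixture_cohort_config("strong", seed=seed))
    dataset = build_cycle_dataset(cohort, "level_walk_short", EFFECT_PLACEMENT)
    from .normalization import apply_range, fit_range

    norm = fit_range(dataset.X)
    Xt = apply_range(norm, dataset.X).astype(np.float32)
    model, result = finetune(checkpoint, Xt, dataset.y, fixture_finetune_config(seed))
    after = model.state_dict()
    max_diff = 0.0
    for name, value in checkpoint.state.items():
        if name.startswith("branches."):
            max_diff = max(max_diff, float(np.abs(after[name] - value).max()))
    return {
        "max_frozen_param_diff": max_diff,
        "source_validation_accuracy": val_acc,
        "finetune_steps": result.n_steps,
    }
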