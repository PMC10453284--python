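"""Desk-scale end-to-end experiments on synthetic data.

These helpers train a reduced-width network on a small generated dataset and
report held-out metrics.  They back both the acceptance tests and the
acceptance report script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .io_datasets import read_sample
from .model import ModelConfig, load_checkpoint
from .objectives_metrics import confusion, metrics
from .pipeline_cli import TrainConfig, predict_arrays, train
from .synthetic_fundus import SynthConfig, generate_dataset, generate_sample, sample_seed


def reduced_model_config(seed: int = 0, use_mfi: bool = True,
                         mve_style: str = "res2net",
                         mae_style: str = "cot") -> ModelConfig:
    return ModelConfig(base_width=8, depth=3, n_subsets=4, cot_groups=4,
                       fuse_hidden=8, use_mfi=use_mfi, mve_style=mve_style,
                       mae_style=mae_style, seed=seed)


def synthetic_config(seed: int, size: int = 128) -> SynthConfig:
    return SynthConfig(height=size, width=size, n_trees=4, branch_depth=4,
                       root_caliber=4, seed=seed)


def train_on_synthetic(seed: int, n_train: int = 8, steps: int = 300,
                       size: int = 128, patch: int = 64,
                       model_cfg: ModelConfig | None = None,
                       work_dir=None):
    """Generate a dataset, train a reduced model, return the trained model."""
    own_tmp = work_dir is None
    tmp = Path(tempfile.mkdtemp(prefix="mscnet_exp_")) if own_tmp else Path(work_dir)
    data_dir = tmp / "data"
    generate_dataset(synthetic_config(seed, size), n_train, data_dir)
    cfg = TrainConfig(
        learning_rate=1e-3,
        epochs=steps // 10,
        steps_per_epoch=10,
        batch_size=4,
        patch_size=patch,
        val_fraction=0.0,
        seed=seed,
        model=model_cfg or reduced_model_config(seed=seed),
    )
    ckpt, history = train(data_dir / "manifest.json", cfg, tmp / "run")
    return load_checkpoint(ckpt), history


def evaluate_on_synthetic(model, seed: int, n_test: int = 2,
                          n_train: int = 8, size: int = 128) -> dict:
    """Held-out metrics on freshly generated samples (indices past n_train)."""
    vessel_counts = None
    av_counts = None
    base = synthetic_config(seed, size)
    for i in range(n_train, n_train + n_test):
        cfg = synthetic_config(seed, size)
        cfg.seed = sample_seed(base.seed, i)
        s = generate_sample(cfg)
        vp, logits = predict_arrays(s.image, model, patch_size=size)
        vc = confusion(vp >= 0.5, s.vessel_mask, "VESSEL")
        ac = confusion(logits.transpose(2, 0, 1), s.av_labels, "AV")
        vessel_counts = vc if vessel_counts is None else vessel_counts + vc
        av_counts = ac if av_counts is None else av_counts + ac
    return {"vessel": metrics(vessel_counts), "av": metrics(av_counts)}


def parameter_recovery(seed: int, steps: int = 300, use_mfi: bool = True) -> dict:
    """Train on 8 synthetic samples, evaluate on 2 held-out ones."""
    model, _ = train_on_synthetic(
        seed, steps=steps,
        model_cfg=reduced_model_config(seed=seed, use_mfi=use_mfi))
    return evaluate_on_synthetic(model, seed)


__all__ = ["reduced_model_config", "synthetic_config", "train_on_synthetic",
           "evaluate_on_synthetic", "parameter_recovery"]
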