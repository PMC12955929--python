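"""Canned desk-scale studies: end-to-end learnability and the spectral-path
ablation on the activity-cliff task.

Problem sizes are chosen so each study runs in minutes on one CPU:
32 molecules for the overfit study, 100 cliff pairs (200 molecules, 1/5 of
pairs held out pair-wise) with three seeds for the ablation comparison, and
a depth-1 encoder (one attention block, one transformer layer, 32-wide
embeddings) throughout.
"""

from __future__ import annotations

import numpy as np

from .fixtures import cliff_pairs_table, make_fixture_table
from .molgraph import DatasetTable
from .network import EncoderConfig, Model
from .training import TrainConfig, Trainer

__all__ = ["desk_config", "overfit_study", "pretrain_study",
           "cliff_ablation_study"]


def desk_config(**overrides) -> EncoderConfig:
    """Depth-1 desk-scale architecture used by the canned studies."""
    base = dict(d_model=32, n_heads=4, n_layers=1, transformer_layers=1)
    base.update(overrides)
    return EncoderConfig(**base)


def overfit_study(seed: int = 0, n_molecules: int = 32,
                  max_epochs: int = 500) -> dict:
    """Train on noiseless structure-derived labels until train RMSE falls
    below 0.1x its initial value (or the epoch cap)."""
    table = make_fixture_table(seed=seed, n_molecules=n_molecules,
                               noise_sd=0.0)
    model = Model(desk_config(), table.n_tasks, table.task_types, seed=seed)
    trainer = Trainer(model, table,
                      TrainConfig(epochs=max_epochs, batch_size=8, lr=3e-3,
                                  seed=seed))
    log = trainer.train(target_rmse_ratio=0.1)
    series = log.series("rmse/train")
    return {"n_molecules": len(table), "epochs_run": len(series),
            "initial_rmse": series[0], "final_rmse": series[-1],
            "rmse_ratio": series[-1] / series[0]}


def pretrain_study(seed: int = 0, n_molecules: int = 32,
                   epochs: int = 30) -> dict:
    """Masked-reconstruction pre-training on the fixtures."""
    table = make_fixture_table(seed=seed, n_molecules=n_molecules,
                               noise_sd=0.0)
    model = Model(desk_config(), table.n_tasks, table.task_types, seed=seed)
    trainer = Trainer(model, table,
                      TrainConfig(epochs=epochs, batch_size=8, lr=3e-3,
                                  seed=seed))
    log = trainer.pretrain()
    s = log.series("loss/pretrain")
    return {"n_molecules": len(table), "epochs": epochs,
            "initial_loss": s[0], "final_loss": s[-1],
            "reduction": 1.0 - s[-1] / s[0]}


def _pair_split(table: DatasetTable, seed: int):
    """Hold out whole cliff pairs (1 in 5) for validation."""
    n_pairs = len(table) // 2
    rng = np.random.Generator(np.random.PCG64(seed + 1000))
    val_pairs = set(rng.choice(n_pairs, size=n_pairs // 5,
                               replace=False).tolist())
    tr = [i for i in range(len(table)) if i // 2 not in val_pairs]
    va = [i for i in range(len(table)) if i // 2 in val_pairs]

    def sub(idx):
        return DatasetTable([table.molecules[i] for i in idx],
                            table.labels[idx], table.task_names,
                            table.task_types)
    return sub(tr), sub(va)


def cliff_ablation_study(seeds=(0, 1, 2), n_pairs: int = 100,
                         epochs: int = 25) -> dict:
    """Full model vs the variant without both frequency paths (w/o HF&LF)
    on the cliff-pair regression task; reports per-seed and median final
    train/validation RMSE for both variants."""
    table = cliff_pairs_table(n_pairs, seed=0)
    results = {"full": {"train": [], "val": []},
               "wo_hflf": {"train": [], "val": []}}
    for seed in seeds:
        train_t, val_t = _pair_split(table, seed)
        for name, cfg in (("full", desk_config()),
                          ("wo_hflf", desk_config(use_HF=False,
                                                  use_LF=False))):
            model = Model(cfg, 1, ["regression"], seed=seed)
            trainer = Trainer(model, train_t,
                              TrainConfig(epochs=epochs, batch_size=16,
                                          lr=3e-3, seed=seed))
            log = trainer.train(val_table=val_t)
            results[name]["train"].append(log.series("rmse/train")[-1])
            results[name]["val"].append(log.series("rmse/val")[-1])
    out = {"n_molecules": len(table), "seeds": list(seeds),
           "epochs": epochs}
    for name in ("full", "wo_hflf"):
        out[f"{name}_train_rmse"] = results[name]["train"]
        out[f"{name}_val_rmse"] = results[name]["val"]
        out[f"{name}_median_train_rmse"] = float(np.median(
            results[name]["train"]))
        out[f"{name}_median_val_rmse"] = float(np.median(
            results[name]["val"]))
    return out
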