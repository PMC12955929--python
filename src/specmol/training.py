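"""Training loops: masked-node pre-training and multi-task fine-tuning.

Fine-tuning minimizes the total objective
``L_total = sum_i lambda_i L_i + lambda_c L_contrastive`` where the task
weights follow the dynamic task weighting rule, classification tasks use
effective-number class-balanced cross-entropy, regression tasks use masked
MSE, and the contrastive term acts on graph embeddings within each batch.

Molecules are processed one graph at a time inside a batch (graphs are tiny;
there is no padding), gradients are accumulated across the batch, and one
Adam step is taken per batch.  All shuffling and masking randomness is
seeded, so a run is deterministic given its seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from . import objectives as obj
from .autograd import Tensor, concat, no_grad, stack
from .molgraph import DatasetTable, build_graph
from .network import Model

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "Trainer", "rmse"]


@dataclass
class TrainConfig:
    """Optimization and objective hyperparameters for one run."""

    epochs: int = 100
    batch_size: int = 32
    lr: float = 3e-3
    seed: int = 0
    use_DTW: bool = True
    use_CIH: bool = True
    use_CL: bool = True
    gamma: float = 0.1              # DTW adjustment magnitude
    epsilon: float = 1e-8           # DTW stabilizer
    tau: float = 0.1                # contrastive temperature
    lambda_contrastive: float = 0.1
    beta_cb: float = 0.99           # class-balance hyperparameter
    mask_fraction: float = 0.15     # pre-training atom mask rate
    patience: int | None = None     # stop if train loss stalls this long


def rmse(pred: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared error over observed labels."""
    obs = ~np.isnan(y)
    return float(np.sqrt(np.mean((pred[obs] - y[obs]) ** 2)))


class MetricsLog:
    """Long-format (epoch, component, value) metric sink with optional CSV."""

    def __init__(self, path=None):
        self.rows: list[tuple[int, str, float]] = []
        self.path = path

    def add(self, epoch: int, component: str, value: float) -> None:
        self.rows.append((epoch, component, float(value)))

    def flush(self) -> None:
        if self.path is None:
            return
        with open(self.path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "component", "value"])
            w.writerows(self.rows)

    def series(self, component: str) -> list[float]:
        return [v for _, c, v in self.rows if c == component]


class Trainer:
    """Drives pre-training and fine-tuning of one :class:`Model`."""

    def __init__(self, model: Model, table: DatasetTable,
                 cfg: TrainConfig, metrics_path=None):
        self.model = model
        self.table = table
        self.cfg = cfg
        self.metrics = MetricsLog(metrics_path)
        self.records = [model.prepare(build_graph(m))
                        for m in table.molecules]
        self.task_state = obj.TaskState.initial(
            table.n_tasks, gamma=cfg.gamma if cfg.use_DTW else 0.0,
            epsilon=cfg.epsilon)
        self._class_w = self._compute_class_weights()
        self.last_report: obj.LossReport | None = None

    # -- class imbalance ------------------------------------------------------
    def _compute_class_weights(self) -> list[tuple[float, float]]:
        """Per classification task: (w1_norm, w0_norm); (1,1) when disabled."""
        out = []
        for j, kind in enumerate(self.table.task_types):
            if kind != "classification" or not self.cfg.use_CIH:
                out.append((1.0, 1.0))
                continue
            col = self.table.labels[:, j]
            col = col[~np.isnan(col)]
            counts = np.array([(col == 0).sum(), (col == 1).sum()])
            cw = obj.class_weights(counts, beta_cb=self.cfg.beta_cb)
            out.append((float(cw.w_norm[1]), float(cw.w_norm[0])))
        return out

    # -- shared batch machinery -----------------------------------------------
    def _task_losses(self, idx: np.ndarray,
                     reps: list[Tensor]) -> list[Tensor]:
        losses = []
        for j, kind in enumerate(self.table.task_types):
            y = self.table.labels[idx, j]
            preds = concat([self.model.predict(r)[j].reshape(1)
                            for r in reps])
            if kind == "classification":
                w1, w0 = self._class_w[j]
                _, task_loss = obj.weighted_bce(preds, y, w1=w1, w0=w0)
            else:
                task_loss = obj.masked_mse(preds, y)
            losses.append(task_loss)
        return losses

    def _contrastive(self, idx: np.ndarray, embs: list[Tensor]) -> Tensor:
        """SupCon labels: first classification task if present, otherwise a
        median split of the first regression task within the batch."""
        j_cls = next((j for j, k in enumerate(self.table.task_types)
                      if k == "classification"), None)
        if j_cls is not None:
            labels = self.table.labels[idx, j_cls]
        else:
            y = self.table.labels[idx, 0]
            labels = (y > np.nanmedian(y)).astype(float)
            labels[np.isnan(y)] = np.nan
        obs = ~np.isnan(labels)
        if obs.sum() < 2:
            return Tensor(0.0)
        H = stack([e for e, o in zip(embs, obs) if o])
        return obj.supcon_loss(H, labels[obs], tau=self.cfg.tau)

    # -- fine-tuning ----------------------------------------------------------
    def train(self, val_table: DatasetTable | None = None,
              target_rmse_ratio: float | None = None) -> MetricsLog:
        """Minimize the total loss; logs per-epoch components and weights.

        ``target_rmse_ratio`` stops early once train RMSE of the first
        regression task drops below that fraction of its initial value.
        """
        cfg = self.cfg
        rng = np.random.Generator(np.random.PCG64(cfg.seed))
        opt = self.model.optimizer(lr=cfg.lr)
        n = len(self.records)
        j_reg = next((j for j, k in enumerate(self.table.task_types)
                      if k == "regression"), None)
        initial_rmse = None
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_task_losses = np.zeros(self.table.n_tasks)
            epoch_contrastive = 0.0
            epoch_total = 0.0
            n_batches = 0
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                outs = [self.model.forward(self.records[i]) for i in idx]
                reps = [o["representation"] for o in outs]
                task_losses = self._task_losses(idx, reps)
                weights = obj.normalize_task_weights(self.task_state)
                cls_loss = obj.classification_loss(task_losses, weights)
                if cfg.use_CL and len(idx) >= 2:
                    con = self._contrastive(
                        idx, [o["graph_embedding"] for o in outs])
                else:
                    con = Tensor(0.0)
                total = obj.total_loss(cls_loss, con,
                                       cfg.lambda_contrastive)
                opt.zero_grad()
                total.backward()
                opt.step()
                epoch_task_losses += np.array([float(t.data)
                                               for t in task_losses])
                epoch_contrastive += float(con.data)
                epoch_total += float(total.data)
                n_batches += 1
            epoch_task_losses /= n_batches
            if cfg.use_DTW:
                self.task_state = obj.update_task_weights(
                    self.task_state, epoch_task_losses)
            weights = obj.normalize_task_weights(self.task_state)
            for j, name in enumerate(self.table.task_names):
                self.metrics.add(epoch, f"loss/{name}", epoch_task_losses[j])
                self.metrics.add(epoch, f"weight/{name}", weights[j])
            self.metrics.add(epoch, "loss/contrastive",
                             epoch_contrastive / n_batches)
            self.metrics.add(epoch, "loss/total", epoch_total / n_batches)
            self.last_report = obj.LossReport(
                per_task=epoch_task_losses,
                classification=float(cls_loss.data),
                contrastive=float(con.data),
                total=float(total.data),
                lambda_contrastive=cfg.lambda_contrastive)

            stop = False
            if j_reg is not None:
                pred = self.predict_table_records(self.records)[:, j_reg]
                train_rmse = rmse(pred, self.table.labels[:, j_reg])
                self.metrics.add(epoch, "rmse/train", train_rmse)
                if initial_rmse is None:
                    initial_rmse = self.metrics.series("rmse/train")[0]
                if target_rmse_ratio is not None and \
                        train_rmse < target_rmse_ratio * initial_rmse:
                    stop = True
            if val_table is not None:
                vp = self.predict_table(val_table)
                if j_reg is not None:
                    self.metrics.add(epoch, "rmse/val",
                                     rmse(vp[:, j_reg],
                                          val_table.labels[:, j_reg]))
            if stop:
                logger.info("early stop at epoch %d (train RMSE target met)",
                            epoch)
                break
        self.metrics.flush()
        return self.metrics

    # -- pre-training ---------------------------------------------------------
    def pretrain(self) -> MetricsLog:
        """Masked-node reconstruction: zero + flag a seeded 15% atom subset
        per molecule per epoch; reconstruct their pre-masking feature rows
        and the graph descriptor at the global token."""
        cfg = self.cfg
        rng = np.random.Generator(np.random.PCG64(cfg.seed))
        opt = self.model.optimizer(lr=cfg.lr)
        n = len(self.records)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                terms = []
                for i in idx:
                    rec = self.records[i]
                    g = rec["graph"]
                    n_mask = max(1, int(round(cfg.mask_fraction * g.n_atoms)))
                    mask = np.zeros(g.n_atoms, dtype=bool)
                    mask[rng.choice(g.n_atoms, size=n_mask,
                                    replace=False)] = True
                    out = self.model.forward(rec, mask_atoms=mask)
                    node_pred, glob_pred = self.model.pretrain_heads(
                        out["H_out"], g.n_atoms)
                    terms.append(obj.pretrain_loss(
                        node_pred, g.atom_features, mask,
                        glob_pred, rec["descriptor"]).reshape(1))
                loss = concat(terms).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            self.metrics.add(epoch, "loss/pretrain", epoch_loss / n_batches)
        self.metrics.flush()
        return self.metrics

    # -- inference ------------------------------------------------------------
    def predict_table_records(self, records) -> np.ndarray:
        with no_grad():
            rows = []
            for rec in records:
                rep = self.model.forward(rec)["representation"]
                rows.append([p.data.item()
                             for p in self.model.predict(rep)])
        return np.asarray(rows)

    def predict_table(self, table: DatasetTable) -> np.ndarray:
        recs = [self.model.prepare(build_graph(m)) for m in table.molecules]
        return self.predict_table_records(recs)

    def embed_table(self, table: DatasetTable) -> np.ndarray:
        with no_grad():
            rows = []
            for m in table.molecules:
                rec = self.model.prepare(build_graph(m))
                rows.append(self.model.forward(rec)["graph_embedding"].data)
        return np.asarray(rows)
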