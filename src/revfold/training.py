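"""Bidirectional training loop with the dynamic distance-mask schedule.

Training minimizes the combined fold + design objective with Adam.  The
distance mask of the fold loss starts by admitting all native pairs of a
sample and linearly tightens to the training cutoff (26.6 Å) over the first
part of training, so optimization first captures global shape and then
refines local interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AMINO_ACIDS, ModelConfig
from .autodiff import Tensor
from . import autodiff as ad
from . import losses, network


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 250
    beta: float = 1e-4
    train_cutoff: float = losses.TRAIN_CUTOFF   # 26.6 Å
    eval_cutoff: float = losses.EVAL_CUTOFF     # 22.8 Å
    schedule_fraction: float = 0.5
    direction_mode: str = "both"                # both | fold_only | design_only
    design_loss_content: str = "P/O"            # P | O | P/O
    grad_clip: float = 10.0
    checkpoint_interval: int = 0                # epochs; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("learning_rate, batch_size positive; epochs >= 0")
        if not (0.0 < self.schedule_fraction <= 1.0):
            raise ValueError("schedule_fraction must be in (0, 1]")
        if self.direction_mode not in ("both", "fold_only", "design_only"):
            raise ValueError(f"unknown direction_mode {self.direction_mode!r}")
        if self.design_loss_content not in ("P", "O", "P/O"):
            raise ValueError(f"unknown design_loss_content {self.design_loss_content!r}")


@dataclass
class MaskSchedule:
    """Linear decay of the per-sample mask cutoff to the training cutoff."""

    epochs: int
    final_cutoff: float = losses.TRAIN_CUTOFF
    schedule_fraction: float = 0.5

    @property
    def decay_end(self) -> int:
        return int(np.floor(self.schedule_fraction * self.epochs))


def mask_cutoff_at_epoch(epoch: int, schedule: MaskSchedule,
                         sample_max_distance: float) -> float:
    """Cutoff in Å at ``epoch``: from the sample's maximum native distance at
    epoch 0 down to the final cutoff at the decay end, constant afterwards."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    end = schedule.decay_end
    start = max(sample_max_distance, schedule.final_cutoff)
    if end <= 0 or epoch >= end:
        return schedule.final_cutoff
    t = epoch / end
    return (1.0 - t) * start + t * schedule.final_cutoff


class Adam:
    """Standard Adam optimizer over a dict of parameter arrays."""

    def __init__(self, weights: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            weights[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_grads(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        s = max_norm / total
        for k in grads:
            grads[k] *= s


def _sample_max_distances(dataset) -> dict[str, float]:
    out = {}
    for rec in dataset:
        coords = losses.fill_unobserved_coords(rec.coords, rec.mask)
        from .graph_ops import pairwise_distances
        D = pairwise_distances(coords)
        obs = np.outer(rec.mask, rec.mask)
        out[rec.id] = float(D[obs].max()) if obs.any() else losses.TRAIN_CUTOFF
    return out


def train(dataset, model_config: ModelConfig, train_config: TrainConfig,
          weights: dict | None = None, log_path=None, checkpoint_dir=None):
    """Train on a list of :class:`ProteinRecord`.

    Returns ``(weights, log)`` where ``log`` is one :class:`LossReport` per
    epoch (averaged over records).  Fully deterministic given the seeds in
    both configs.  Batches larger than one record accumulate gradients over
    the batch before each optimizer step.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    for rec in dataset:
        rec.validate()
    if weights is None:
        weights = network.init_weights(model_config)
    else:
        weights = {k: np.array(v, float) for k, v in weights.items()}
    opt = Adam(weights, train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    schedule = MaskSchedule(train_config.epochs, train_config.train_cutoff,
                            train_config.schedule_fraction)
    max_dist = _sample_max_distances(dataset)
    log: list[losses.LossReport] = []
    log_file = open(log_path, "w") if log_path else None
    if log_file:
        log_file.write("epoch\tfold_loss\tdrmsd\tkl_pssm\tkl_seq\ttv\ttotal\n")
    try:
        for epoch in range(train_config.epochs):
            order = rng.permutation(len(dataset))
            ep = losses.LossReport()
            nrec = len(dataset)
            for bstart in range(0, nrec, train_config.batch_size):
                batch = [dataset[i] for i in order[bstart:bstart + train_config.batch_size]]
                wT = {k: Tensor(v) for k, v in weights.items()}
                totals = []
                for rec in batch:
                    cutoff = mask_cutoff_at_epoch(epoch, schedule, max_dist[rec.id])
                    tot, rep = losses.objective_graph(
                        rec, wT, model_config, cutoff,
                        train_config.direction_mode,
                        train_config.design_loss_content, train_config.beta)
                    if not np.isfinite(rep.total):
                        raise FloatingPointError(
                            f"non-finite loss at epoch {epoch}, record {rec.id!r}")
                    totals.append(tot)
                    ep.fold_loss += rep.fold_loss / nrec
                    ep.design_kl_pssm += rep.design_kl_pssm / nrec
                    ep.design_kl_seq += rep.design_kl_seq / nrec
                    ep.total += rep.total / nrec
                batch_total = ad.scale(totals[0], 1.0 / len(batch))
                for t in totals[1:]:
                    batch_total = ad.add(batch_total, ad.scale(t, 1.0 / len(batch)))
                if model_config.T >= 2 and train_config.beta > 0:
                    layersT = [network.layer_params(wT, j, model_config)
                               for j in range(model_config.T)]
                    batch_total = ad.add(batch_total,
                                         ad.scale(losses._tv_t(layersT),
                                                  train_config.beta))
                batch_total.backward()
                grads = {k: (wT[k].grad if wT[k].grad is not None
                             else np.zeros_like(weights[k]))
                         for k in weights}
                _clip_grads(grads, train_config.grad_clip)
                opt.step(weights, grads)
            if model_config.T >= 2:
                ep.tv_reg = losses.tv_regularization(
                    [network.layer_params(weights, j, model_config)
                     for j in range(model_config.T)])
            ep.total += train_config.beta * ep.tv_reg
            ep.drmsd = float(np.sqrt(ep.fold_loss))
            log.append(ep)
            if log_file:
                log_file.write(
                    f"{epoch}\t{ep.fold_loss:.6f}\t{ep.drmsd:.6f}\t"
                    f"{ep.design_kl_pssm:.6f}\t{ep.design_kl_seq:.6f}\t"
                    f"{ep.tv_reg:.6f}\t{ep.total:.6f}\n")
            if (checkpoint_dir and train_config.checkpoint_interval
                    and (epoch + 1) % train_config.checkpoint_interval == 0):
                network.save_checkpoint(
                    f"{checkpoint_dir}/epoch{epoch + 1:04d}.ckpt",
                    weights, model_config)
    finally:
        if log_file:
            log_file.close()
    return weights, log


def evaluate(dataset, weights: dict, model_config: ModelConfig,
             eval_cutoff: float = losses.EVAL_CUTOFF):
    """Per-record dRMSD, design KL terms and sequence recovery accuracy.

    Accuracy is the fraction of observed positions whose predicted top
    residue matches the native one.  Returns ``(per_record, aggregates)``
    where ``per_record`` is a list of dicts (a per-target table) and
    ``aggregates`` holds the means.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    rows = []
    for rec in dataset:
        rec.validate()
        coords = losses.fill_unobserved_coords(rec.coords, rec.mask)
        row = {"id": rec.id, "n": rec.n}
        Xp = network.fold(rec, weights, model_config)
        from .graph_ops import pairwise_distances
        M = losses.build_distance_mask(pairwise_distances(coords),
                                       rec.mask, eval_cutoff)
        _, row["drmsd"] = losses.fold_loss(Xp, coords, M)
        from .core import decode_outputs, softmax_columns
        logits = np.asarray(network.design_logits(coords, weights, model_config))
        onehot, pssm = decode_outputs(logits)
        seq_probs = softmax_columns(logits[:20])
        row["kl_pssm"], row["kl_seq"] = losses.design_loss(
            pssm, rec.pssm, seq_probs, rec.sequence, rec.mask)
        pred_seq = np.argmax(onehot, axis=0)
        true_seq = np.array([AMINO_ACIDS.index(a) for a in rec.sequence])
        obs = rec.mask
        row["n_observed"] = int(obs.sum())
        row["n_correct"] = int(np.sum((pred_seq == true_seq) & obs))
        row["accuracy"] = row["n_correct"] / max(row["n_observed"], 1)
        rows.append(row)
    agg = {
        "drmsd": float(np.mean([r["drmsd"] for r in rows])),
        "kl_pssm": float(np.mean([r["kl_pssm"] for r in rows])),
        "kl_seq": float(np.mean([r["kl_seq"] for r in rows])),
        "accuracy": float(np.mean([r["accuracy"] for r in rows])),
        "n_observed": int(sum(r["n_observed"] for r in rows)),
        "n_correct": int(sum(r["n_correct"] for r in rows)),
    }
    return rows, agg
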