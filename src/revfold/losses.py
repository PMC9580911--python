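"""Loss terms and the combined bidirectional training objective.

The folding loss compares masked pairwise-distance matrices (dRMSD²), which
makes it invariant to rotation, translation — and, as a known limitation, to
mirror reflection.  The design loss is the KL divergence KL(true ‖ predicted)
between per-position residue distributions, applied to the PSSM block and to
the one-hot sequence block.  A total-variation penalty on layer-to-layer
parameter differences keeps the learnt dynamics smooth in pseudo-time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core import (
    ModelConfig,
    N_RESIDUE_TYPES,
    encode_inputs,
    sequence_to_onehot,
)
from .graph_ops import pairwise_distances, pairwise_distances_t
from . import network

#: Training-time distance cutoff: 7 consecutive-Cα spacings (7 × 3.8 Å).
TRAIN_CUTOFF: float = 7 * 3.8
#: Evaluation cutoff: 6 spacings (6 × 3.8 Å), the convention used by prior
#: distance-matrix folding losses.
EVAL_CUTOFF: float = 6 * 3.8

_EPS_SMOOTH = 1e-9


@dataclass
class MaskMatrix:
    """Symmetric 0/1 matrix selecting distance pairs for the fold loss."""

    M: np.ndarray
    n_M: int


@dataclass
class LossReport:
    fold_loss: float = 0.0          # Å², mean masked squared distance error
    drmsd: float = 0.0              # Å
    design_kl_pssm: float = 0.0     # nats per observed position
    design_kl_seq: float = 0.0      # nats per observed position
    tv_reg: float = 0.0
    total: float = 0.0


def build_distance_mask(D_native: np.ndarray, residue_mask: np.ndarray,
                        cutoff: float) -> MaskMatrix:
    """M_ij = 1 iff i≠j, both residues observed, and D_native_ij ≤ cutoff.

    Far pairs are dropped so that the loss resolves local geometry rather
    than being dominated by the largest inter-residue distances.
    """
    D_native = np.asarray(D_native, float)
    residue_mask = np.asarray(residue_mask, bool)
    n = D_native.shape[0]
    if D_native.shape != (n, n) or residue_mask.shape != (n,):
        raise ValueError("inconsistent mask/distance shapes")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive (may be inf)")
    obs = np.outer(residue_mask, residue_mask)
    # absolute slack so distances sitting exactly at the cutoff are kept
    # despite Gram-identity round-off
    M = (obs & (D_native <= cutoff + 1e-9)).astype(float)
    np.fill_diagonal(M, 0.0)
    return MaskMatrix(M=M, n_M=int(M.sum()))


def fold_loss(X_pred: np.ndarray, X_native: np.ndarray,
              M: MaskMatrix) -> tuple[float, float]:
    """Mean masked squared distance difference (Å²) and its root, the dRMSD (Å)."""
    if M.n_M == 0:
        raise ValueError("empty distance mask: fold loss undefined")
    Dp = pairwise_distances(X_pred)
    Dn = pairwise_distances(X_native)
    loss = float(np.sum(M.M * (Dp - Dn) ** 2) / M.n_M)
    return loss, float(np.sqrt(loss))


def _smooth_columns(P: np.ndarray) -> np.ndarray:
    return (P + _EPS_SMOOTH) / (1.0 + N_RESIDUE_TYPES * _EPS_SMOOTH)


def _kl_columns(P_true: np.ndarray, P_pred: np.ndarray) -> np.ndarray:
    """Per-column KL(true ‖ pred) in nats, after ε-smoothing both."""
    t = _smooth_columns(np.asarray(P_true, float))
    p = _smooth_columns(np.asarray(P_pred, float))
    return np.sum(t * (np.log(t) - np.log(p)), axis=0)


def design_loss(pssm_pred, pssm_true, seq_onehot_pred_probs, seq_true,
                observed) -> tuple[float, float]:
    """KL divergences of the predicted PSSM and sequence distributions.

    ``seq_true`` may be a sequence string or a 20×n one-hot matrix.  Both KL
    terms are means over observed positions; PSSM columns that are entirely
    zero in the ground truth (fully masked) are excluded.
    """
    pssm_pred = np.asarray(pssm_pred, float)
    pssm_true = np.asarray(pssm_true, float)
    seq_probs = np.asarray(seq_onehot_pred_probs, float)
    if isinstance(seq_true, str):
        seq_true = sequence_to_onehot(seq_true)
    seq_true = np.asarray(seq_true, float)
    observed = np.asarray(observed, bool)
    for name, P in (("pssm_pred", pssm_pred), ("seq_onehot_pred_probs", seq_probs)):
        s = _smooth_columns(P).sum(axis=0)
        if np.any(np.abs(s - 1.0) > 1e-4):
            raise ValueError(f"{name} columns do not sum to 1 after smoothing")

    pssm_cols = observed & (pssm_true.sum(axis=0) > 0)
    if not pssm_cols.any() or not observed.any():
        raise ValueError("no observed positions to average the design loss over")
    kl_pssm = float(np.mean(_kl_columns(pssm_true, pssm_pred)[pssm_cols]))
    kl_seq = float(np.mean(_kl_columns(seq_true, seq_probs)[observed]))
    return kl_pssm, kl_seq


def tv_regularization(layer_weights: list) -> float:
    """Σ_j ‖θ_{j+1} − θ_j‖₁ over all corresponding weight arrays.

    ``layer_weights`` is the ordered list of per-layer parameter dicts (or
    sequences of arrays); consecutive layers must have matching shapes.
    """
    if len(layer_weights) < 2:
        raise ValueError("total variation needs at least 2 layers")

    def arrays(lw):
        if isinstance(lw, dict):
            return [np.asarray(lw[k]) for k in sorted(lw)]
        return [np.asarray(a) for a in lw]

    total = 0.0
    prev = arrays(layer_weights[0])
    for lw in layer_weights[1:]:
        cur = arrays(lw)
        if len(cur) != len(prev) or any(a.shape != b.shape for a, b in zip(prev, cur)):
            raise ValueError("mismatched layer parameter shapes across layers")
        total += sum(float(np.abs(a - b).sum()) for a, b in zip(prev, cur))
        prev = cur
    return total


# ---------------------------------------------------------------------------
# tape versions used by training


def _softmax_logp_t(Z: Tensor) -> Tensor:
    m = np.max(Z.data, axis=0, keepdims=True)  # constant shift, gradient-free
    e = ad.exp(ad.sub(Z, m))
    s = ad.tsum(e, axis=0, keepdims=True)
    return ad.sub(ad.sub(Z, m), ad.log(s))


def _kl_mean_t(P_true: np.ndarray, logp_pred: Tensor, cols: np.ndarray) -> Tensor:
    """Mean over selected columns of KL(true ‖ softmax(pred))."""
    t = _smooth_columns(P_true)
    w = cols.astype(float) / max(int(cols.sum()), 1)
    const_entropy = float(np.sum((t * np.log(t)).sum(axis=0) * w))
    cross = ad.tsum(ad.mul(ad.mul(Tensor(t, requires_grad=False), logp_pred),
                           Tensor(w[None, :], requires_grad=False)))
    return ad.add(ad.scale(cross, -1.0), const_entropy)


def _fold_loss_t(X_pred: Tensor, X_native: np.ndarray, M: MaskMatrix) -> Tensor:
    Dp = pairwise_distances_t(X_pred)
    Dn = pairwise_distances(X_native)
    diff = ad.sub(Dp, Tensor(Dn, requires_grad=False))
    masked = ad.mul(ad.square(diff), Tensor(M.M, requires_grad=False))
    return ad.scale(ad.tsum(masked), 1.0 / M.n_M)


def _tv_t(layer_tensors: list[dict]) -> Tensor:
    terms = []
    for a, b in zip(layer_tensors[:-1], layer_tensors[1:]):
        for k in sorted(a):
            terms.append(ad.tsum(ad.absolute(ad.sub(b[k], a[k]))))
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    return total


def fill_unobserved_coords(coords: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace non-finite unobserved coordinates by chain-linear interpolation."""
    coords = np.array(coords, float)
    mask = np.asarray(mask, bool)
    finite = np.all(np.isfinite(coords), axis=0) & mask
    if finite.all():
        return coords
    if not finite.any():
        raise ValueError("record has no observed coordinates")
    idx = np.arange(coords.shape[1])
    for r in range(3):
        coords[r] = np.interp(idx, idx[finite], coords[r, finite])
    return coords


def objective_graph(record, weight_tensors: dict, config: ModelConfig,
                    mask_cutoff: float, direction_mode: str = "both",
                    design_loss_content: str = "P/O", beta: float = 1e-4,
                    include_tv: bool = True):
    """Build the per-record training objective on the autodiff tape.

    Returns ``(total_tensor, LossReport)``; the TV term is added by the
    caller when batching (it does not depend on the record).
    """
    report = LossReport()
    terms = []
    coords = fill_unobserved_coords(record.coords, record.mask)

    if direction_mode in ("both", "fold_only"):
        x = encode_inputs(record)
        Y0 = network.embed_inputs(Tensor(x, requires_grad=False),
                                  weight_tensors["emb/theta_e"])
        layers = network.all_layer_params(weight_tensors, config)
        YT, _ = network.verlet_forward(Y0, layers, config.h, config)
        Xp = network.project_coords(YT, weight_tensors["emb/theta_f"],
                                    constrain=config.constrain,
                                    spacing=config.spacing)
        Dn = pairwise_distances(coords)
        M = build_distance_mask(Dn, record.mask, mask_cutoff)
        lf = _fold_loss_t(Xp, coords, M)
        report.fold_loss = float(lf.data)
        report.drmsd = float(np.sqrt(report.fold_loss))
        terms.append(lf)

    if direction_mode in ("both", "design_only"):
        logits = network.design_logits(Tensor(coords, requires_grad=False),
                                       weight_tensors, config)
        # split rows: sequence block 0-19, PSSM block 20-39
        Zs = _row_block(logits, 0, N_RESIDUE_TYPES)
        Zp = _row_block(logits, N_RESIDUE_TYPES, 2 * N_RESIDUE_TYPES)
        observed = record.mask
        pssm_cols = observed & (record.pssm.sum(axis=0) > 0)
        kl_p = _kl_mean_t(record.pssm, _softmax_logp_t(Zp), pssm_cols)
        kl_s = _kl_mean_t(sequence_to_onehot(record.sequence),
                          _softmax_logp_t(Zs), observed)
        report.design_kl_pssm = float(kl_p.data)
        report.design_kl_seq = float(kl_s.data)
        if design_loss_content in ("P", "P/O"):
            terms.append(kl_p)
        if design_loss_content in ("O", "P/O"):
            terms.append(kl_s)

    if not terms:
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    report.total = float(total.data)
    return total, report


def _row_block(t: Tensor, start: int, stop: int) -> Tensor:
    return ad.transpose(ad.slice_cols(ad.transpose(t), start, stop))


def total_objective(records_batch, weights: dict, config: ModelConfig,
                    mask_cutoff: float = TRAIN_CUTOFF, *,
                    direction_mode: str = "both",
                    design_loss_content: str = "P/O",
                    beta: float = 1e-4) -> LossReport:
    """Evaluate the full objective (Å² fold + nats design + β·TV) over a batch.

    Directional ablation modes restrict the objective to one direction;
    ``design_loss_content`` selects the PSSM ("P"), one-hot ("O") or combined
    ("P/O") design terms.
    """
    if direction_mode not in ("both", "fold_only", "design_only"):
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    if design_loss_content not in ("P", "O", "P/O"):
        raise ValueError(f"unknown design_loss_content {design_loss_content!r}")
    records = list(records_batch)
    if not records:
        raise ValueError("empty batch")
    wT = {k: Tensor(v, requires_grad=False) for k, v in weights.items()}
    agg = LossReport()
    for rec in records:
        _, rep = objective_graph(rec, wT, config, mask_cutoff,
                                 direction_mode, design_loss_content, beta)
        agg.fold_loss += rep.fold_loss / len(records)
        agg.design_kl_pssm += rep.design_kl_pssm / len(records)
        agg.design_kl_seq += rep.design_kl_seq / len(records)
        agg.total += rep.total / len(records)
    agg.drmsd = float(np.sqrt(agg.fold_loss))
    if config.T >= 2:
        agg.tv_reg = tv_regularization(
            [network.layer_params(weights, j, config) for j in range(config.T)])
    agg.total += beta * agg.tv_reg
    return agg
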