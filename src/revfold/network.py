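"""The reversible bidirectional model.

One set of weights serves two directions.  The folding direction embeds the
sequence+PSSM input into an ``nf``-channel latent chain, propagates it through
``T`` layers of a leapfrog (Verlet) recursion whose force term is a symmetric
multiscale graph U-net, and projects the final state to 3D Cα coordinates.
The design direction embeds coordinates with the exact adjoint of the
projection, runs the same recursion in reverse layer order from a
zero-terminal-velocity boundary, and recovers sequence space with the adjoint
of the input embedding.

The leapfrog update

    Y_{j+1} = 2 Y_j − Y_{j−1} + h² f(Y_j, θ_j),        Y_{−1} = Y_0,

is algebraically reversible for any force f: given the final state pair the
whole trajectory can be reconstructed exactly (see :func:`invert_trajectory`).
The force is f(Y) = −C*(σ(C(Y))): an encoder C of graph-convolution blocks and
chain poolings, and a decoder C* applying the transposed convolutions and
unpoolings with the same weights, which makes −f negative(-semidefinite-like)
and the dynamics non-amplifying.  A ResNet ablation (Y_{j+1} = Y_j + h f(Y_j))
shares every component behind ``ModelConfig.resnet``.
"""

from __future__ import annotations

import io
import json
import zipfile

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core import ModelConfig, ProteinRecord, decode_outputs, encode_inputs
from .graph_ops import graph_laplacian_t, pool_chain, unpool_chain

# ---------------------------------------------------------------------------
# weights


def _rng_normal(rng, shape, fan_in, taps=1):
    return rng.standard_normal(shape) / np.sqrt(fan_in * taps)


def init_weights(config: ModelConfig) -> dict[str, np.ndarray]:
    """Initialize all parameter arrays from the configured seed.

    Keys: ``emb/theta_e`` (nf×40), ``emb/theta_f`` (nf×3), and per layer j
    and U-net level, convolution kernels ``layer{j}/.../K`` (nf×nf×k) with
    instance-norm gain/shift.  All layers have identical shapes, which the
    total-variation regularizer relies on.
    """
    rng = np.random.default_rng(config.seed)
    nf, k = config.nf, config.kernel_size
    w: dict[str, np.ndarray] = {
        "emb/theta_e": _rng_normal(rng, (nf, config.in_channels), config.in_channels),
        "emb/theta_f": _rng_normal(rng, (nf, 3), nf),
    }
    for j in range(config.T):
        for name in _block_names(config):
            w[f"layer{j}/{name}/K"] = _rng_normal(rng, (nf, nf, k), nf, k)
            w[f"layer{j}/{name}/gamma"] = np.ones((nf, 1))
            w[f"layer{j}/{name}/beta"] = np.zeros((nf, 1))
    return w


def _block_names(config: ModelConfig) -> list[str]:
    names = [f"enc{l}" for l in range(config.nLevels - 1)]
    names += ["coarse0", "coarse1"]
    return names


def layer_params(weights: dict, j: int, config: ModelConfig) -> dict:
    """Extract the θ_j sub-dictionary for one layer (keys without prefix)."""
    prefix = f"layer{j}/"
    return {k[len(prefix):]: v for k, v in weights.items() if k.startswith(prefix)}


def all_layer_params(weights: dict, config: ModelConfig) -> list[dict]:
    return [layer_params(weights, j, config) for j in range(config.T)]


# ---------------------------------------------------------------------------
# embeddings and their adjoints (no bias terms, so adjoints are exact)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, float), requires_grad=False)


def _unwrap(out, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return out.data


def embed_inputs(x40, theta_e):
    """Y0 = θ_e · x, a 40→nf linear map applied per column (1×1 convolution)."""
    xt, th = _wrap(x40), _wrap(theta_e)
    if th.shape[1] != xt.shape[0]:
        raise ValueError(f"theta_e maps {th.shape[1]} channels, input has {xt.shape[0]}")
    return _unwrap(ad.matmul(th, xt), x40, theta_e)


def recover_sequence_adjoint(Y0, theta_e):
    """θ_eᵀ · Y0, the exact adjoint of :func:`embed_inputs` (nf→40)."""
    yt, th = _wrap(Y0), _wrap(theta_e)
    if th.shape[0] != yt.shape[0]:
        raise ValueError(f"theta_e has {th.shape[0]} rows, latent has {yt.shape[0]}")
    return _unwrap(ad.matmul(ad.transpose(th), yt), Y0, theta_e)


def project_coords(YT, theta_f, constrain: bool = False, spacing: float = 3.8):
    """X̂ = θ_fᵀ · Y_T (nf→3), optionally followed by the chain constraint."""
    yt, th = _wrap(YT), _wrap(theta_f)
    if th.shape[0] != yt.shape[0]:
        raise ValueError(f"theta_f has {th.shape[0]} rows, latent has {yt.shape[0]}")
    X = ad.matmul(ad.transpose(th), yt)
    if constrain:
        X = _chain_constraint_t(X, spacing)
    return _unwrap(X, YT, theta_f)


def embed_coords_adjoint(X, theta_f):
    """Y_T = θ_f · X (3→nf), the adjoint of the linear part of the projection."""
    xt, th = _wrap(X), _wrap(theta_f)
    if xt.shape[0] != 3:
        raise ValueError(f"coordinates must have 3 rows, got {xt.shape[0]}")
    return _unwrap(ad.matmul(th, xt), X, theta_f)


def _chain_constraint_t(X: Tensor, c: float) -> Tensor:
    n = X.shape[1]
    if n < 2:
        return X
    d = ad.sub(ad.slice_cols(X, 1, n), ad.slice_cols(X, 0, n - 1))
    len2 = ad.tsum(ad.square(d), axis=0, keepdims=True)
    if np.any(len2.data < 1e-16):
        bad = int(np.argmin(len2.data))
        raise ValueError(
            f"coincident consecutive positions at index {bad}: displacement direction undefined"
        )
    lens = ad.safe_sqrt(len2)
    unit_steps = ad.scale(ad.div(d, lens), c)
    X0 = ad.slice_cols(X, 0, 1)
    rest = ad.add(X0, ad.cumsum_cols(unit_steps))
    return ad.concat_cols([X0, rest])


def apply_chain_constraint(X, c: float = 3.8):
    """Rescale every consecutive displacement to length ``c``, keeping directions.

    The first residue is fixed and displacements accumulate along the chain,
    so the output has exactly |X_i − X_{i−1}| = c everywhere.  A chain already
    at spacing c is a fixed point.
    """
    return _unwrap(_chain_constraint_t(_wrap(X), c), X)


# ---------------------------------------------------------------------------
# graph-convolution block and the symmetric U-net force


def _instance_norm(z: Tensor, gamma, beta, eps: float = 1e-5) -> Tensor:
    mu = ad.tmean(z, axis=1, keepdims=True)
    centered = ad.sub(z, mu)
    var = ad.tmean(ad.square(centered), axis=1, keepdims=True)
    xhat = ad.div(centered, ad.safe_sqrt(ad.add(var, eps)))
    if gamma is None:
        return xhat
    return ad.add(ad.mul(_wrap(gamma), xhat), _wrap(beta))


def gcn_block(Y, L, K, omega, gamma=None, beta=None, normalize=True, adjoint=False):
    """One graph-convolution block: ω·Y + ReLU(Norm(K∗Y + Y·L)).

    ``K`` couples sequence neighbours (1D convolution along the chain) and
    ``L`` couples spatial neighbours via the dynamic graph Laplacian.  ω is 1
    except immediately before a pooling step.  ``adjoint=True`` applies the
    transposed convolution with the same kernel (decoder half of the U-net).
    """
    Yt, Lt, Kt = _wrap(Y), _wrap(L), _wrap(K)
    if Lt.shape != (Yt.shape[1], Yt.shape[1]):
        raise ValueError(f"Laplacian shape {Lt.shape} does not match chain length {Yt.shape[1]}")
    z = ad.add(ad.conv1d(Kt, Yt, adjoint=adjoint), ad.matmul(Yt, Lt))
    if normalize:
        z = _instance_norm(z, gamma, beta)
    act = ad.relu(z)
    out = act if omega == 0 else ad.add(ad.scale(Yt, float(omega)), act)
    return _unwrap(out, Y)


def min_chain_length(config: ModelConfig) -> int:
    return 2 ** (config.nLevels - 1)


def symmetric_unet(Y, lw: dict, config: ModelConfig):
    """The force term f(Y) = −C*(σ(C(Y))) of the leapfrog dynamics.

    Encoder C: at each of ``nLevels − 1`` fine levels a gcn_block (ω=0)
    followed by pair-average pooling; two gcn_blocks at the coarsest level.
    Decoder C*: unpooling and transposed-kernel blocks in reverse order with
    the same weight arrays, plus long skip connections from matching encoder
    levels.  The graph Laplacian is rebuilt from the current features at
    every level.

    In strict-symmetric mode (single level, no normalization/skips, the
    activation applied once between a purely linear C and its exact adjoint)
    the negativity ⟨Y, f(Y)⟩ ≤ 0 holds exactly.
    """
    Yt = _wrap(Y)
    n = Yt.shape[1]
    need = min_chain_length(config)
    if n < need:
        raise ValueError(
            f"chain length {n} too short for {config.nLevels} U-net levels; need >= {need}"
        )
    alpha = config.alpha
    if config.strict_symmetric:
        K = _wrap(lw["coarse0/K"])
        L = graph_laplacian_t(Yt, alpha)
        z = ad.add(ad.conv1d(K, Yt), ad.matmul(Yt, L))
        s = ad.relu(z)
        out = ad.add(ad.conv1d(K, s, adjoint=True), ad.matmul(s, L))
        return _unwrap(ad.scale(out, -1.0), Y)

    skips, lens = [], []
    A = Yt
    for l in range(config.nLevels - 1):
        L = graph_laplacian_t(A, alpha)
        A = gcn_block(A, L, lw[f"enc{l}/K"], 0, lw[f"enc{l}/gamma"],
                      lw[f"enc{l}/beta"], config.normalize)
        skips.append(A)
        lens.append(A.shape[1])
        A = pool_chain(A)
    for name in ("coarse0", "coarse1"):
        L = graph_laplacian_t(A, alpha)
        A = gcn_block(A, L, lw[f"{name}/K"], 1, lw[f"{name}/gamma"],
                      lw[f"{name}/beta"], config.normalize)
    for l in reversed(range(config.nLevels - 1)):
        A = unpool_chain(A, lens[l])
        L = graph_laplacian_t(A, alpha)
        A = gcn_block(A, L, lw[f"enc{l}/K"], 1, lw[f"enc{l}/gamma"],
                      lw[f"enc{l}/beta"], config.normalize, adjoint=True)
        if config.skip_connections:
            A = ad.add(A, skips[l])
    return _unwrap(ad.scale(A, -1.0), Y)


# ---------------------------------------------------------------------------
# leapfrog propagation


def _check_finite(state, j):
    data = state.data if isinstance(state, Tensor) else state
    if not np.all(np.isfinite(data)):
        raise FloatingPointError(f"non-finite state at layer {j} (dynamics blow-up)")


def verlet_forward(Y0, layers: list[dict], h: float, config: ModelConfig):
    """Propagate Y_0 → Y_T with Y_{−1} = Y_0 (zero initial velocity).

    Returns ``(Y_T, states)`` where ``states`` is the full trajectory
    [Y_0, …, Y_T].  In ResNet ablation mode the first-order update
    Y_{j+1} = Y_j + h·f(Y_j) is used instead.
    """
    if len(layers) < 1:
        raise ValueError("need at least one layer")
    Yt = _wrap(Y0)
    states = [Yt]
    prev = Yt
    cur = Yt
    h2 = h * h
    for j, lw in enumerate(layers):
        f = symmetric_unet(cur, lw, config)
        if config.resnet:
            nxt = ad.add(cur, ad.scale(f, h))
        else:
            nxt = ad.add(ad.sub(ad.scale(cur, 2.0), prev), ad.scale(f, h2))
        _check_finite(nxt, j + 1)
        states.append(nxt)
        prev, cur = cur, nxt
    out = (states[-1], states)
    if isinstance(Y0, Tensor):
        return out
    return states[-1].data, [s.data for s in states]


def verlet_backward(YT, layers: list[dict], h: float, config: ModelConfig):
    """Propagate Y_T → Y_0 from the zero-terminal-velocity boundary Y_{T+1} = Y_T.

    This is the design-direction pass: the same recursion run with the layer
    order reversed, mirroring the forward pass's zero-initial-velocity start.
    Returns ``(Y_0, states)`` with states ordered [Y_T, …, Y_0].
    """
    if len(layers) < 1:
        raise ValueError("need at least one layer")
    Zt = _wrap(YT)
    states = [Zt]
    prev = Zt
    cur = Zt
    h2 = h * h
    for step, lw in enumerate(reversed(layers)):
        f = symmetric_unet(cur, lw, config)
        if config.resnet:
            nxt = ad.add(cur, ad.scale(f, h))
        else:
            nxt = ad.add(ad.sub(ad.scale(cur, 2.0), prev), ad.scale(f, h2))
        _check_finite(nxt, len(layers) - 1 - step)
        states.append(nxt)
        prev, cur = cur, nxt
    if isinstance(YT, Tensor):
        return states[-1], states
    return states[-1].data, [s.data for s in states]


def invert_trajectory(YT, YT_minus1, layers: list[dict], h: float,
                      config: ModelConfig) -> list[np.ndarray]:
    """Exactly reconstruct a forward trajectory from its final state pair.

    Solves the leapfrog recursion for Y_{j−1} = 2 Y_j − Y_{j+1} + h² f(Y_j, θ_j),
    iterating j = T−1 … 1.  Returns [Y_0, …, Y_T].  Only defined for the
    reversible dynamics (not the ResNet ablation, which discards state).
    """
    if config.resnet:
        raise ValueError("trajectory inversion requires the reversible dynamics")
    T = len(layers)
    states: list[np.ndarray] = [None] * (T + 1)
    states[T] = np.asarray(YT, float)
    states[T - 1] = np.asarray(YT_minus1, float)
    h2 = h * h
    for j in range(T - 1, 0, -1):
        f = symmetric_unet(states[j], layers[j], config)
        states[j - 1] = 2.0 * states[j] - states[j + 1] + h2 * f
        _check_finite(states[j - 1], j - 1)
    return states


# ---------------------------------------------------------------------------
# end-to-end passes


def fold(record: ProteinRecord, weights: dict, config: ModelConfig) -> np.ndarray:
    """Sequence + PSSM → Cα coordinates (3×n)."""
    x = encode_inputs(record)
    Y0 = embed_inputs(x, weights["emb/theta_e"])
    YT, _ = verlet_forward(Y0, all_layer_params(weights, config), config.h, config)
    return project_coords(YT, weights["emb/theta_f"], constrain=config.constrain,
                          spacing=config.spacing)


def design_logits(X, weights: dict, config: ModelConfig):
    """Coordinates → raw 40×n sequence-space output (pre-softmax).

    Input coordinates are centered first: the design problem is invariant to
    the arbitrary frame a structure is reported in, so the network should
    never see absolute positions.
    """
    center = (X.data if isinstance(X, Tensor) else np.asarray(X, float)).mean(
        axis=1, keepdims=True)
    X = ad.sub(X, center) if isinstance(X, Tensor) else np.asarray(X, float) - center
    YT = embed_coords_adjoint(X, weights["emb/theta_f"])
    Y0, _ = verlet_backward(YT, all_layer_params(weights, config), config.h, config)
    return recover_sequence_adjoint(Y0, weights["emb/theta_e"])


def design(X: np.ndarray, weights: dict, config: ModelConfig):
    """Coordinates → (one-hot sequence, PSSM), both 20×n."""
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("design requires finite coordinates")
    return decode_outputs(design_logits(X, weights, config))


# ---------------------------------------------------------------------------
# checkpointing: one archive holding all weight arrays + the config as JSON


def save_checkpoint(path, weights: dict, config: ModelConfig) -> None:
    cfg = {k: v for k, v in vars(config).items()}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(cfg, indent=1))
        for name, arr in weights.items():
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr))
            zf.writestr(name.replace("/", "__") + ".npy", buf.getvalue())


def load_checkpoint(path) -> tuple[dict, ModelConfig]:
    with zipfile.ZipFile(path) as zf:
        cfg = json.loads(zf.read("config.json"))
        config = ModelConfig(**cfg)
        weights = {}
        for info in zf.infolist():
            if info.filename.endswith(".npy"):
                name = info.filename[:-4].replace("__", "/")
                weights[name] = np.load(io.BytesIO(zf.read(info.filename)))
    expected = init_weights(config)
    if set(expected) != set(weights):
        raise ValueError("checkpoint weight names do not match its model config")
    for k in expected:
        if expected[k].shape != weights[k].shape:
            raise ValueError(
                f"checkpoint array {k} has shape {weights[k].shape}, "
                f"config implies {expected[k].shape}"
            )
    return weights, config
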