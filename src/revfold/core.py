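"""Domain types shared across the package, input encoding and output decoding.

A protein is represented at desk scale by a single interaction point per
residue, the Cα atom.  The network consumes the concatenation of a one-hot
sequence encoding and a PSSM (40 rows total) and emits either Cα coordinates
(folding direction) or a predicted PSSM plus a one-hot sequence (design
direction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Canonical one-letter amino-acid alphabet, alphabetical order.  This is the
#: single source of truth for residue indexing in every module.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUE_TYPES: int = len(AMINO_ACIDS)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ideal trans-peptide spacing between consecutive Cα atoms, in Å.
CA_SPACING: float = 3.8


@dataclass
class ProteinRecord:
    """One protein: sequence, PSSM, Cα trace and observation mask.

    Attributes
    ----------
    id : str
        Record identifier.
    sequence : str
        Length-``n`` string over the 20-letter alphabet.
    pssm : (20, n) ndarray
        Per-position residue probability distributions; columns sum to 1.
    coords : (3, n) ndarray
        Cα coordinates in Å.  Entries may be undefined (non-finite) only
        where ``mask`` is False.
    mask : (n,) bool ndarray
        True where the native structure observes the residue.
    """

    id: str
    sequence: str
    pssm: np.ndarray
    coords: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.sequence)

    def validate(self) -> "ProteinRecord":
        """Check all record invariants, raising ``ValueError`` on violation."""
        n = self.n
        if self.pssm.shape != (N_RESIDUE_TYPES, n):
            raise ValueError(
                f"record {self.id!r}: pssm shape {self.pssm.shape} != (20, {n})"
            )
        if self.coords.shape != (3, n):
            raise ValueError(
                f"record {self.id!r}: coords shape {self.coords.shape} != (3, {n})"
            )
        if self.mask.shape != (n,):
            raise ValueError(
                f"record {self.id!r}: mask length {self.mask.shape} != ({n},)"
            )
        for pos, aa in enumerate(self.sequence):
            if aa not in _AA_INDEX:
                raise ValueError(
                    f"record {self.id!r}: unknown residue {aa!r} at position {pos}"
                )
        if np.any(self.pssm < 0):
            raise ValueError(f"record {self.id!r}: negative PSSM entries")
        colsums = self.pssm.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-5):
            bad = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"record {self.id!r}: PSSM column {bad} sums to {colsums[bad]:.6g}"
            )
        if not np.all(np.isfinite(self.coords[:, self.mask])):
            raise ValueError(
                f"record {self.id!r}: non-finite coordinates at observed positions"
            )
        return self


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``nf`` channels, ``T`` reversible layers and ``nLevels`` U-net scales
    default to the published operating point (128 / 6 / 3); the pseudo-time
    step ``h`` defaults to ``1/T`` so the dynamics integrate over unit time.
    ``alpha`` scales the exponential edge weights of the dynamic graph (Å in
    coordinate space, feature units in latent space).
    """

    nf: int = 128
    T: int = 6
    nLevels: int = 3
    h: float | None = None
    alpha: float = 10.0
    kernel_size: int = 9
    in_channels: int = 40
    seed: int = 0
    # geometry
    constrain: bool = True
    spacing: float = CA_SPACING
    # ablation / test modes
    resnet: bool = False
    strict_symmetric: bool = False
    normalize: bool = True
    skip_connections: bool = True

    def __post_init__(self) -> None:
        if self.nf <= 0 or self.T <= 0 or self.nLevels <= 0 or self.kernel_size <= 0:
            raise ValueError("nf, T, nLevels and kernel_size must be positive")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.in_channels != 2 * N_RESIDUE_TYPES:
            raise ValueError("in_channels must be 40 (20 sequence + 20 PSSM rows)")
        if self.h is None:
            self.h = 1.0 / self.T
        if self.h < 0:
            raise ValueError("time step h must be nonnegative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.strict_symmetric:
            # strict mode asserts the negativity property literally: single
            # level, purely linear C, no normalization, no skips
            self.nLevels = 1
            self.normalize = False
            self.skip_connections = False

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


def sequence_to_onehot(sequence: str) -> np.ndarray:
    """One-hot encode a sequence as a (20, n) matrix.

    Raises ``ValueError`` naming the first offending position for residues
    outside the 20-letter alphabet.
    """
    n = len(sequence)
    out = np.zeros((N_RESIDUE_TYPES, n))
    for pos, aa in enumerate(sequence):
        idx = _AA_INDEX.get(aa)
        if idx is None:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
        out[idx, pos] = 1.0
    return out


def onehot_to_sequence(onehot: np.ndarray) -> str:
    """Inverse of :func:`sequence_to_onehot` (argmax per column)."""
    return "".join(AMINO_ACIDS[i] for i in np.argmax(onehot, axis=0))


def encode_inputs(record: ProteinRecord) -> np.ndarray:
    """Stack one-hot sequence (rows 0-19) and PSSM (rows 20-39) into 40×n."""
    record.validate()
    return np.vstack([sequence_to_onehot(record.sequence), record.pssm])


def softmax_columns(block: np.ndarray) -> np.ndarray:
    """Numerically stable per-column softmax."""
    z = block - block.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def decode_outputs(latent_output: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 40×n output into (one-hot sequence, PSSM).

    Both 20-row blocks are mapped to per-column probability distributions by
    softmax; the sequence block is then collapsed to a one-hot matrix at each
    column's maximal-probability row.  Argmax ties break to the lowest residue
    index (a fixed, platform-independent rule).
    """
    latent_output = np.asarray(latent_output, dtype=float)
    if latent_output.ndim != 2 or latent_output.shape[0] != 2 * N_RESIDUE_TYPES:
        raise ValueError(
            f"expected 40 rows, got shape {latent_output.shape}"
        )
    seq_probs = softmax_columns(latent_output[:N_RESIDUE_TYPES])
    pssm = softmax_columns(latent_output[N_RESIDUE_TYPES:])
    onehot = np.zeros_like(seq_probs)
    onehot[np.argmax(seq_probs, axis=0), np.arange(seq_probs.shape[1])] = 1.0
    return onehot, pssm
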