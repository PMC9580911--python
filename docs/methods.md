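# Methods

## Model

The network is a time-reversible, bidirectional graph neural network over the
protein chain. Both tasks share one parameter set θ = (θₑ, θ_f, θ₀…θ_{T−1}):

* **Embeddings.** θₑ (n_f×40) maps the stacked one-hot sequence and PSSM to
  the latent chain; θ_f (n_f×3) projects the final latent state to Cα
  coordinates. Neither carries a bias, so their adjoints are exact
  transposes and the design direction can re-enter latent space with θ_f and
  leave it with θₑᵀ without any extra parameters.
* **Dynamics.** The leapfrog recursion
  Y_{j+1} = 2Y_j − Y_{j−1} + h²f(Y_j, θ_j) with Y_{−1} = Y₀ (zero initial
  velocity) is reversible for any force f: given (Y_T, Y_{T−1}) the entire
  trajectory is reconstructed exactly (`invert_trajectory`; verified to
  <1e-8 in double precision for random weights). The design pass uses the
  mirrored boundary Y_{T+1} = Y_T — zero terminal velocity, symmetric to the
  forward initialization — and visits the layers in reverse order.
* **Force.** f(Y) = −C*(σ(C(Y))), a symmetric graph U-net. The encoder
  applies a graph-convolution block then pair-average pooling at each fine
  level and two blocks at the coarsest level; the decoder applies
  linear-interpolation unpooling and the *transposed* convolutions with the
  same kernels, plus long skip connections. Unpooling places coarse nodes at
  the fine positions pooling drew them from (2j + 0.5, carried odd tail at
  n−1), which makes pool→unpool the identity on features linear in the chain
  index — the property that keeps coarse corrections unbiased along the
  chain.
* **Dynamic graph.** Each block couples nodes through
  L = diag(W·1) − W with W = exp(−D(Y)/α) and D(Y) the Euclidean
  column-distance matrix of the *current* features, recomputed at every
  U-net level of every layer. The graph is fully connected and smoothly
  weighted (no k-NN sparsification), so connectivity strengthens as residues
  approach in feature space. L is built from the affinity weights W, not
  from raw distances: affinities must decay with distance for near residues
  to interact most strongly. W's unit diagonal cancels in the construction.
* **Negativity.** With a linear C and exact adjoint C*, ⟨Y, f(Y)⟩ =
  −⟨C(Y), σ(C(Y))⟩ ≤ 0 because ReLU preserves sign. Instance normalization,
  in-block activations and skip connections break exact adjointness, so the
  package provides a strict-symmetric mode (single level, no normalization
  or skips, one activation between C and C*) in which the inequality is
  asserted literally, 100/100 random draws.

## Losses

* Fold: ℓ = (1/n_M)·Σ M⊙(D(X̂) − D(X))², reported with its root (dRMSD).
  The mask excludes the diagonal, unobserved residues, and native distances
  above a cutoff; distances landing exactly on the cutoff are kept via a
  1e-9 slack (Gram-identity round-off otherwise drops them). The loss is
  invariant to rotation, translation and **mirror reflection** — inverted
  geometry cannot be detected, a documented limitation of distance-based
  losses.
* Design: KL(true ‖ predicted) per observed position, in nats, for the PSSM
  block and for the one-hot sequence block (cross-entropy up to the
  zero-entropy reference). Both distributions are smoothed with ε = 1e-9 and
  renormalized before the log; fully masked PSSM columns are excluded from
  the mean. Per-position averaging keeps values comparable across lengths.
* Regularization: R(θ) = Σⱼ ‖θ_{j+1} − θⱼ‖₁ over corresponding arrays of
  consecutive layers (all layers share shapes), weight β = 1e-4 by default.
  Total-variation-in-depth favours smooth pseudo-time dynamics; Tikhonov
  decay would not.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| n_f | 128 | latent channels (16 in desk-scale tests) |
| T | 6 | leapfrog layers |
| nLevels | 3 | U-net scales (factor-2 chain coarsening) |
| h | 1/T | pseudo-time step; unit total integration time |
| α | 10 | affinity decay scale (Å / feature units) |
| kernel_size | 9 | 1D convolution width along the chain |
| c | 3.8 Å | consecutive-Cα spacing enforced by the constraint layer |
| train / eval cutoff | 26.6 / 22.8 Å | 7 and 6 spacings |
| lr, batch, epochs | 1e-4, 1, 250 | benchmark-scale optimizer defaults |

The dynamic mask schedule interpolates each sample's cutoff linearly from
its own maximum native distance down to the training cutoff over the first
`schedule_fraction` (default 0.5) of the epochs: optimization captures the
global fold first, then local geometry. Gradient clipping uses global norm
10: the fold term is O(10²) Å² early in training, and a tighter clip rescales
the combined gradient so strongly that the design direction barely moves.
The design pass centers input coordinates before embedding (the task is
translation invariant; frames in real data are arbitrary). Batches larger
than one record accumulate per-record gradients rather than padding —
identical for a mean objective, with no padded-position bookkeeping.

## Numerical choices

Convolutions use zero same-padding of (kernel−1)/2. Instance normalization
is per channel over chain positions with ε = 1e-5; a length-1 chain
normalizes to zero. Softmax decoding subtracts the per-column maximum;
argmax ties break to the lowest residue index. Square roots of squared
distances are clamped at zero with gradients defined as zero at the origin
(self-distances carry no signal). Weights initialize to
N(0, 1/(fan_in·kernel)) draws from the configured seed; norm gains start at
1, shifts at 0. The training loop, generator and CLI consume explicit seeds
and are bit-reproducible on one machine.

## Synthetic data

The generator emulates the statistical shape of sequence/PSSM/structure
records with a *genuine* geometry↔sequence coupling: chains are built from
helix (ideal α-helix Cα geometry, rescaled to exact 3.8 Å steps), strand
(near-extended) and coil (random-turn) segments, with a 4.0 Å self-avoidance
floor enforced by rejection sampling (budget 1000 per chain). Each segment
class has a fixed residue-propensity table (helix-formers vs strand-formers
vs coil residues; the exact numbers are arbitrary, only the contrast
matters); per-position PSSM columns are Dirichlet draws with concentration
`pssm_concentration × 20 × propensity` (default sharpness 8), sequences are
sampled from the PSSM, and a configurable fraction of residues (default 5%)
is marked unobserved. Exact spacing makes the constraint layer a no-op on
generated backbones, a fixed-point test.

What this does *not* emulate: Ramachandran statistics, side-chain packing,
long-range contact patterns, evolutionary covariance, or the length and
redundancy structure of curated benchmark sets. Passing tests therefore
demonstrate that the architecture and losses learn a planted
geometry→residue signal — not benchmark-level folding or design accuracy.

## Desk-scale problem sizes

The test suite trains a 16-channel, 2-layer, 2-level model on 50 length-32
proteins for 30 epochs at lr 3e-3 (the benchmark-scale 1e-4 is matched to
hundreds of thousands of optimizer steps; at ~1.5k steps it stays in the
transient). Held-out sequence recovery is evaluated on 100 proteins (~3000
observed positions) so the binomial comparison against the 1/20 baseline has
adequate power for the few-percent effect a smoke run produces. The
reversible-vs-ResNet comparison uses the standard depth T = 6 (20 proteins,
10 epochs, five fixed seeds): depth is what separates the second-order
dynamics from a first-order ResNet — at T = 2 the two updates are nearly
indistinguishable and the trend is not expected to resolve.

## Limitations

* Cα-only representation; no full-atom reconstruction or side chains.
* Mirror ambiguity inherited from the distance-matrix loss.
* The general leapfrog with a learnable velocity map is not implemented;
  the identity-velocity specialization is.
* Single-chain records only; the ProteinNet reader supports the text
  dialect (not binary variants) and drops the information-content row.
* The PSSM row order of third-party ProteinNet files is configurable
  (`residue_order=`) and defaults to alphabetical one-letter order; confirm
  against the source of any external file.
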