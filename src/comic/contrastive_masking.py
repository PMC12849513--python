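"""The contrastive gate (Z, M), the InfoNCE estimator, and branch losses.

The gate is a 3-layer layer-normalized GELU network ``g`` with a learnable
scalar threshold ``tau`` and an externally scheduled temperature ``T``:

    M = sigmoid((g(X) - tau) / T),   Z = X * M + 0.1 * X

The residual 0.1*X keeps gradients flowing even when the mask closes.
Mutual information between batches is estimated with InfoNCE using a
critic ``f(u, v) = exp(u' W v)`` (strictly positive by construction); the
estimate is bounded above by log N.

Discrete labels enter the (Z; Y) terms through two learned label
embeddings: sample i is aligned with the embedding of its own class and
contrasted against every other sample's class embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import GatedMLP, Module, Tensor, constant, logsumexp, parameter, xavier_uniform


class MaskGate(Module):
    """Learnable filter producing (Z, M) from a representation batch."""

    def __init__(self, rng: np.random.Generator, dim: int):
        self.dim = dim
        self.scorer = GatedMLP(rng, dim)
        self.tau = parameter(np.zeros(()))

    def __call__(self, X: Tensor, temperature: float) -> tuple[Tensor, Tensor]:
        return apply_mask(X, self, temperature)


def apply_mask(X: Tensor, gate: MaskGate, temperature: float) -> tuple[Tensor, Tensor]:
    """M = sigmoid((g(X) - tau)/T); Z = X*M + 0.1*X. Returns (Z, M)."""
    if not np.all(np.isfinite(X.data)):
        raise ValueError("non-finite input to mask gate")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    logits = (gate.scorer(X) - gate.tau) * (1.0 / temperature)
    M = logits.sigmoid()
    Z = X * M + 0.1 * X
    return Z, M


class Critic(Module):
    """Bilinear critic: f(u, v) = exp(s * tanh(u' W v / s)) > 0.

    The scaled tanh soft-bounds the log-score to (-s, s); without it the
    compression term of the bottleneck objective can push the InfoNCE
    estimate to -inf by gaming the critic, and its runaway gradients starve
    the prediction loss under global norm clipping.
    """

    def __init__(self, rng: np.random.Generator, dim: int, scale: float = 5.0):
        self.W = parameter(xavier_uniform(rng, dim, dim))
        self.scale = scale

    def _bound(self, raw: Tensor) -> Tensor:
        s = self.scale
        t = (raw * (2.0 / s)).sigmoid() * 2.0 - 1.0  # tanh(raw/s)
        return t * s

    def log_score_matrix(self, left: Tensor, right: Tensor) -> Tensor:
        """(N, N) matrix of log f(left_i, right_j)."""
        return self._bound((left @ self.W) @ right.swapaxes(-1, -2))

    def log_score_pairs(self, left: Tensor, right: Tensor) -> Tensor:
        """(N,) vector of log f(left_i, right_i)."""
        return self._bound(((left @ self.W) * right).sum(axis=-1))

    def score_matrix(self, left: Tensor, right: Tensor) -> Tensor:
        return self.log_score_matrix(left, right).exp()


def info_nce_from_logits(logits: Tensor) -> Tensor:
    """InfoNCE estimate from an (N, N) log-score table whose diagonal holds
    the aligned pairs: mean_i [ log f_ii - log mean_j f_ij ]."""
    n = logits.shape[0]
    if n < 1 or logits.shape[0] != logits.shape[1]:
        raise ValueError("logits must be a nonempty square matrix")
    aligned = logits.diag()
    denom = logsumexp(logits, axis=1) - float(np.log(n))
    return (aligned - denom).mean()


def info_nce(left: Tensor, right: Tensor, critic: Critic) -> Tensor:
    """Batch InfoNCE estimate; value <= log N always."""
    if left.shape[0] == 0:
        raise ValueError("empty batch")
    if left.shape[0] != right.shape[0]:
        raise ValueError("left/right batches must be aligned")
    return info_nce_from_logits(critic.log_score_matrix(left, right))


@dataclass
class ContrastiveConfig:
    beta: float = 0.1

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


class MaskingBranch(Module):
    """One branch: gate + two critics + per-class label embeddings."""

    def __init__(self, rng: np.random.Generator, dim: int):
        self.gate = MaskGate(rng, dim)
        self.critic_xz = Critic(rng, dim)
        self.critic_zy = Critic(rng, dim)
        emb = xavier_uniform(rng, 2, dim, shape=(2, dim))
        emb /= np.linalg.norm(emb, axis=1, keepdims=True)
        self.label_embeddings = parameter(emb)

    def mask(self, X: Tensor, temperature: float) -> tuple[Tensor, Tensor]:
        return apply_mask(X, self.gate, temperature)

    def loss(self, X: Tensor, Z: Tensor, labels: np.ndarray,
             cfg: ContrastiveConfig) -> Tensor:
        return contrastive_loss(X, Z, labels, self.critic_xz, self.critic_zy,
                                self.label_embeddings, cfg)


def contrastive_loss(X: Tensor, Z: Tensor, labels: np.ndarray,
                     critic_xz: Critic, critic_zy: Critic,
                     label_embeddings: Tensor,
                     cfg: ContrastiveConfig) -> Tensor:
    """-I_NCE(Z; Y) + beta * I_NCE(X; Z).

    Y enters through the label-embedding construction; an all-one-class
    batch degenerates the (Z; Y) term to 0 and is computed as-is.
    """
    labels = np.asarray(labels, dtype=np.intp)
    if labels.shape[0] != Z.shape[0]:
        raise ValueError("labels must align with the batch")
    y_emb = label_embeddings.take_rows(labels)
    relevance = info_nce(Z, y_emb, critic_zy)
    # the compression estimator sees a detached X: the encoder must not be
    # able to shrink I(X;Z) by degenerating its own output, only the gate
    # (through Z) and the critic carry compression gradients
    compression = info_nce(X.detach(), Z, critic_xz)
    return -relevance + cfg.beta * compression


def triple_loss(X_t: Tensor, Z_t: Tensor, labels: np.ndarray,
                critic_xz: Critic, critic_zy: Critic,
                label_embeddings: Tensor, cfg: ContrastiveConfig) -> Tensor:
    return contrastive_loss(X_t, Z_t, labels, critic_xz, critic_zy,
                            label_embeddings, cfg)


def path_loss(X_p: Tensor, Z_p: Tensor, labels: np.ndarray,
              critic_xz: Critic, critic_zy: Critic,
              label_embeddings: Tensor, cfg: ContrastiveConfig) -> Tensor:
    """Identical formula to the triple branch, applied to path batches.
    Path labels are 1 for uncorrupted paths of positive pairs, 0 otherwise."""
    return contrastive_loss(X_p, Z_p, labels, critic_xz, critic_zy,
                            label_embeddings, cfg)
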