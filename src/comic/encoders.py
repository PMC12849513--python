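"""Embedding tables and the position-aware triple / path encoders.

Both encoders add fixed sinusoidal positional encodings, run one
single-head self-attention block and compress to ``dim`` (default 256).
The triple encoder pools attended tokens by mean AND max before the
compression affine; the path encoder pools by mean only — the asymmetry is
deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Linear,
    Module,
    SelfAttentionBlock,
    Tensor,
    concat,
    constant,
    parameter,
    positional_encoding,
    xavier_uniform,
)

DEFAULT_DIM = 256


@dataclass
class EmbeddingTables:
    entity_vectors: Tensor   # (n_entities, dim), learnable
    relation_vectors: Tensor  # (n_relations, dim), learnable
    dim: int = DEFAULT_DIM


def init_embeddings(n_entities: int, n_relations: int, seed: int,
                    dim: int = DEFAULT_DIM) -> EmbeddingTables:
    """Xavier-uniform initialization followed by per-vector L2 normalization.

    Normalization is applied once at init; vectors are free to drift during
    training.
    """
    if n_entities <= 0 or n_relations <= 0:
        raise ValueError("entity and relation counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    ent = xavier_uniform(rng, n_entities, dim, shape=(n_entities, dim))
    rel = xavier_uniform(rng, n_relations, dim, shape=(n_relations, dim))
    ent /= np.linalg.norm(ent, axis=1, keepdims=True)
    rel /= np.linalg.norm(rel, axis=1, keepdims=True)
    return EmbeddingTables(parameter(ent), parameter(rel), dim)


class TripleEncoder(Module):
    """PE + self-attention over the 3 triple tokens, mean & max pooling,
    concatenation (-> 2*dim) and one affine+GELU compression to dim."""

    def __init__(self, rng: np.random.Generator, dim: int = DEFAULT_DIM):
        self.dim = dim
        self.attention = SelfAttentionBlock(rng, dim)
        self.compress = Linear(rng, 2 * dim, dim)
        self._pe = constant(positional_encoding(3, dim))
        self._scale = float(np.sqrt(dim))  # unit-norm rows -> unit RMS coords

    def __call__(self, tokens: Tensor) -> Tensor:
        """tokens: (..., 3, dim) — head, relation, tail embeddings in order."""
        if tokens.shape[-1] != self.dim or tokens.shape[-2] != 3:
            raise ValueError(f"expected (..., 3, {self.dim}) tokens, "
                             f"got {tokens.shape}")
        att = self.attention(tokens * self._scale + self._pe)
        pooled = concat([att.mean(axis=-2), att.max(axis=-2)], axis=-1)
        return self.compress(pooled).gelu()


class PathEncoder(Module):
    """Projects each path triple (concat of its 3 embeddings) to dim, then
    PE + self-attention across path positions, mean pooling, compression."""

    def __init__(self, rng: np.random.Generator, dim: int = DEFAULT_DIM,
                 max_len: int = 5):
        self.dim = dim
        self.max_len = max_len
        self.token_proj = Linear(rng, 3 * dim, dim)
        self.attention = SelfAttentionBlock(rng, dim)
        self.compress = Linear(rng, dim, dim)
        self._pe = positional_encoding(max_len, dim)
        self._scale = float(np.sqrt(dim))

    def __call__(self, triple_tokens: Tensor) -> Tensor:
        """triple_tokens: (..., L, 3*dim) with 1 <= L <= max_len."""
        n_tok = triple_tokens.shape[-2]
        if n_tok < 1:
            raise ValueError("empty path")
        if n_tok > self.max_len:
            raise ValueError(f"path has {n_tok} tokens, cap is {self.max_len}")
        if triple_tokens.shape[-1] != 3 * self.dim:
            raise ValueError(f"expected token width {3 * self.dim}, "
                             f"got {triple_tokens.shape[-1]}")
        x = self.token_proj(triple_tokens * self._scale) + constant(self._pe[:n_tok])
        att = self.attention(x)
        return self.compress(att.mean(axis=-2)).gelu()
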