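"""Stacked gated attention (StockenAttention).

A cascade of multi-head self-attention layers where each layer's output is
fused with the previous state through an elementwise learned gate,

    Attn_i = Attention(Q_i, K_i, V_i)
    H_i    = Gate(Attn_i, H_{i-1}) = g ⊙ Attn_i + (1 − g) ⊙ H_{i-1},
    g      = sigmoid(Linear([Attn_i ; H_{i-1}]))

so every fused element is a convex combination of the attended and carried
values. A final learned softmax weighting fuses the per-layer states into
the output. Spatial feature maps are tokenized by flattening the grid
(n = h·w tokens of d = c channels) and restored on exit.
"""

from __future__ import annotations

import numpy as np

from ._nn import Linear, sigmoid, softmax


class MultiHeadAttention:
    """Standard scaled dot-product self-attention with ``heads`` heads."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by head count {heads}")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens, dtype=np.float64)
        if tokens.ndim != 2 or tokens.shape[0] < 1:
            raise ValueError(f"expected (n, d) tokens with n >= 1, got {tokens.shape}")
        n = tokens.shape[0]
        def split(x):  # (n, d) -> (heads, n, head_dim)
            return x.reshape(n, self.heads, self.head_dim).transpose(1, 0, 2)
        q, k, v = split(self.q(tokens)), split(self.k(tokens)), split(self.v(tokens))
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(self.head_dim)
        weights = softmax(scores, axis=-1)  # rows sum to 1
        mixed = weights @ v
        merged = mixed.transpose(1, 0, 2).reshape(n, self.dim)
        return self.out(merged)


class GateFuse:
    """Elementwise convex gate between the attended output and carried state."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.gate = Linear(2 * dim, dim, rng)

    def __call__(self, attn: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
        attn = np.asarray(attn, dtype=np.float64)
        h_prev = np.asarray(h_prev, dtype=np.float64)
        if attn.shape != h_prev.shape:
            raise ValueError(
                f"shape mismatch: attn {attn.shape} vs state {h_prev.shape}"
            )
        g = sigmoid(self.gate(np.concatenate([attn, h_prev], axis=-1)))
        return g * attn + (1.0 - g) * h_prev


class StockenAttention:
    """Depth-``L`` cascade of attention + gate fusion over (n, d) tokens.

    Parameters
    ----------
    dim
        Token channel width; must be divisible by ``heads``.
    depth
        Number of stacked attention layers (L >= 1).
    heads
        Attention heads per layer.
    fuse_layers
        If True (default), the output is a learned softmax-weighted sum of
        the per-layer fused states; otherwise the last state is returned.
    seed
        Seeds all weight initialization.
    """

    def __init__(self, dim: int, depth: int = 2, heads: int = 4,
                 fuse_layers: bool = True, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.depth = depth
        self.fuse_layers = fuse_layers
        self.layers = [
            (MultiHeadAttention(dim, heads, rng), GateFuse(dim, rng))
            for _ in range(depth)
        ]
        self.fusion_logits = np.zeros(depth)  # uniform fusion at init

    def __call__(self, h0: np.ndarray) -> np.ndarray:
        return self.forward(h0)

    def forward(self, h0: np.ndarray) -> np.ndarray:
        h = np.asarray(h0, dtype=np.float64)
        if h.ndim != 2 or h.shape[1] != self.dim:
            raise ValueError(f"expected (n, {self.dim}) tokens, got {h.shape}")
        states = []
        for attn_layer, gate in self.layers:
            attn = attn_layer(h)
            h = gate(attn, h)
            states.append(h)
        if not self.fuse_layers:
            return states[-1]
        w = softmax(self.fusion_logits)
        return np.tensordot(w, np.stack(states), axes=1)

    def forward_map(self, feat: np.ndarray) -> np.ndarray:
        """Apply to a (c, h, w) feature map via flatten-to-tokens round trip."""
        feat = np.asarray(feat, dtype=np.float64)
        if feat.ndim != 3 or feat.shape[0] != self.dim:
            raise ValueError(f"expected ({self.dim}, h, w) map, got {feat.shape}")
        c, h, w = feat.shape
        tokens = feat.reshape(c, h * w).T
        out = self.forward(tokens)
        return out.T.reshape(c, h, w)
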