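"""Message-passing primitives: GCN and GAT layers, pooling and heads.

Both layer types aggregate over the closed neighborhood N(i) ∪ {i}. The GCN
layer applies the symmetrically-normalized propagation operator,

    H' = ReLU(A_hat H W),    A_hat = D_hat^(-1/2) (M + I) D_hat^(-1/2),

equivalently per node i: ReLU(sum_{j in N(i)∪{i}} h_j / sqrt(d_i d_j) W). The
GAT layer weights neighbors by single-head attention coefficients

    alpha_ij = softmax_j LeakyReLU(a^T [W h_i || W h_j]),

then H'_i = ReLU(sum_j alpha_ij W h_j). ReLU is applied after every layer,
including the last message-passing layer. Layers operate on a single graph
(nodes x dim) or a batch of patient copies of one shared graph
(batch x nodes x dim).

Plain-ndarray functional wrappers (``gcn_forward`` etc.) expose the forward
passes for direct numerical checking.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Adam, Tensor, constant, parameter

LEAKY_SLOPE = 0.2  # conventional negative slope for attention scoring


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Minimal parameter container."""

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


class GCNLayer(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = parameter(glorot(rng, (in_dim, out_dim)))

    def parameters(self) -> list[Tensor]:
        return [self.W]

    def forward(self, H: Tensor, A_hat: np.ndarray) -> Tensor:
        return (constant(A_hat) @ H @ self.W).relu()


class GATLayer(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 leaky_slope: float = LEAKY_SLOPE):
        self.W = parameter(glorot(rng, (in_dim, out_dim)))
        self.a_src = parameter(glorot(rng, (out_dim, 1)))
        self.a_dst = parameter(glorot(rng, (out_dim, 1)))
        self.leaky_slope = leaky_slope

    def parameters(self) -> list[Tensor]:
        return [self.W, self.a_src, self.a_dst]

    def attention(self, H: Tensor, mask: np.ndarray) -> Tensor:
        """alpha over the closed neighborhood; rows sum to 1 on the mask.

        ``mask`` is the self-looped adjacency (M + I) as a 0/1 array.
        """
        S = H @ self.W
        f_src = S @ self.a_src  # (..., n, 1): a^T W h_i contribution
        f_dst = (S @ self.a_dst).swapaxes(-1, -2)  # (..., 1, n)
        scores = (f_src + f_dst).leaky_relu(self.leaky_slope)
        masked = np.where(mask > 0, scores.data, -np.inf)
        row_max = masked.max(axis=-1, keepdims=True)
        exp_scores = (scores - row_max).exp() * mask
        return exp_scores / exp_scores.sum(axis=-1, keepdims=True)

    def forward(self, H: Tensor, mask: np.ndarray) -> Tensor:
        alpha = self.attention(H, mask)
        return (alpha @ (H @ self.W)).relu()


class LinearSoftmaxHead(Module):
    """Pseudo-label classifier: one linear map followed by softmax."""

    def __init__(self, in_dim: int, n_classes: int, rng: np.random.Generator):
        self.Theta = parameter(glorot(rng, (in_dim, n_classes)))
        self.bias = parameter(np.zeros(n_classes))

    def parameters(self) -> list[Tensor]:
        return [self.Theta, self.bias]

    def forward(self, pooled: Tensor) -> Tensor:
        logits = pooled @ self.Theta + self.bias
        shifted = logits - logits.detached_max(axis=-1, keepdims=True)
        exp = shifted.exp()
        return exp / exp.sum(axis=-1, keepdims=True)


class MLPHead(Module):
    """Survival regressor: fully-connected ReLU network with scalar output."""

    def __init__(self, layer_sizes: list[int], rng: np.random.Generator):
        if layer_sizes[-1] != 1:
            raise ValueError("MLP head must end in a single output")
        self.weights = [
            parameter(glorot(rng, (a, b)))
            for a, b in zip(layer_sizes[:-1], layer_sizes[1:])
        ]
        self.biases = [parameter(np.zeros(b)) for b in layer_sizes[1:]]

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def forward(self, z: Tensor) -> Tensor:
        h = z
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < len(self.weights) - 1:
                h = h.relu()
        return h


def make_layer(layer_type: str, in_dim: int, out_dim: int, rng: np.random.Generator):
    if layer_type == "GCN":
        return GCNLayer(in_dim, out_dim, rng)
    if layer_type == "GAT":
        return GATLayer(in_dim, out_dim, rng)
    raise ValueError(f"unknown layer type {layer_type!r}; use 'GCN' or 'GAT'")


def global_mean_pool(H: Tensor) -> Tensor:
    """Mean over the node axis (second-to-last)."""
    if H.data.ndim < 2 or H.data.shape[-2] == 0:
        raise ValueError("cannot pool an empty graph")
    return H.mean(axis=-2)


# --------------------------------------------------------------------------
# Plain-ndarray functional forms (forward only)
# --------------------------------------------------------------------------

def gcn_forward(H: np.ndarray, A_hat: np.ndarray, W: np.ndarray) -> np.ndarray:
    """ReLU(A_hat H W) on plain arrays."""
    return np.maximum(A_hat @ H @ W, 0.0)


def gat_attention_forward(
    H: np.ndarray, adjacency: np.ndarray, W: np.ndarray, a: np.ndarray,
    leaky_slope: float = LEAKY_SLOPE,
) -> np.ndarray:
    """Attention coefficient matrix over closed neighborhoods.

    ``a`` has length 2*out_dim: the first half scores the center node, the
    second half the neighbor ([W h_i || W h_j] concatenation order).
    """
    n = H.shape[0]
    mask = np.asarray(adjacency, dtype=float) + np.eye(n)
    S = H @ W
    out_dim = W.shape[1]
    f_src = S @ a[:out_dim]
    f_dst = S @ a[out_dim:]
    scores = f_src[:, None] + f_dst[None, :]
    scores = np.where(scores > 0, scores, leaky_slope * scores)
    masked = np.where(mask > 0, scores, -np.inf)
    shifted = np.exp(masked - masked.max(axis=1, keepdims=True))
    return shifted / shifted.sum(axis=1, keepdims=True)


def gat_forward(
    H: np.ndarray, adjacency: np.ndarray, W: np.ndarray, a: np.ndarray,
    leaky_slope: float = LEAKY_SLOPE,
) -> np.ndarray:
    alpha = gat_attention_forward(H, adjacency, W, a, leaky_slope)
    return np.maximum(alpha @ (H @ W), 0.0)


def mean_pool_forward(H: np.ndarray) -> np.ndarray:
    if H.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    return H.mean(axis=0)


def softmax_forward(logits: np.ndarray) -> np.ndarray:
    shifted = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return shifted / shifted.sum(axis=-1, keepdims=True)


def concat_gene_reps(reps: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-gene final-layer representations into one vector."""
    dims = {r.shape for r in reps}
    if len(dims) != 1:
        raise ValueError(f"inconsistent per-gene representation shapes: {dims}")
    return np.concatenate(reps)


def mlp_forward(z: np.ndarray, weights: list[np.ndarray], biases: list[np.ndarray]) -> np.ndarray:
    h = np.asarray(z, dtype=float)
    for i, (W, b) in enumerate(zip(weights, biases)):
        h = h @ W + b
        if i < len(weights) - 1:
            h = np.maximum(h, 0.0)
    return h
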