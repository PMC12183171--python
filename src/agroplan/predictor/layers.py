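"""Building blocks of the spatiotemporal predictor.

Every operation here is written against the in-repo autodiff
(:mod:`agroplan.autodiff`) and takes a leading batch dimension; single-sample
callers simply pass a batch of one.  Each block mirrors a textbook form:

* ``conv_forward`` — same-padded, stride-1 2-D convolution with an activation;
* ``max_pool`` — non-overlapping window maximum (divisibility enforced);
* ``spatial_attention`` — softmax(Q K^T / sqrt(d)) V over grid positions;
* ``gru_step`` — reset/update-gated recurrent update, a convex combination of
  the previous hidden state and a tanh candidate;
* ``fuse_modalities`` — softmax over bilinear relevance scores q^T W_k M_k,
  giving a convex combination of modality embeddings;
* ``predict_head`` / ``classify`` — fully connected heads for the (Y, C, E)
  regression triple and for class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..autodiff import Tensor, as_tensor, concatenate, stack

__all__ = [
    "ConvStackParams",
    "SpatialAttentionParams",
    "GruParams",
    "FusionParams",
    "conv_forward",
    "max_pool",
    "spatial_attention",
    "gru_step",
    "fuse_modalities",
    "linear",
    "mlp_forward",
    "classify",
]

_ACTIVATIONS = ("relu", "leaky_relu", "identity")


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "leaky_relu":
        return x.leaky_relu(0.01)
    if name == "identity":
        return x
    raise ValueError(f"unknown activation {name!r}; expected one of {_ACTIVATIONS}")


def _init(rng: np.random.Generator, *shape: int, scale: float | None = None) -> Tensor:
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    scale = scale if scale is not None else 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(scale * rng.standard_normal(shape), requires_grad=True)


# ---------------------------------------------------------------------------
# convolution stack
# ---------------------------------------------------------------------------

@dataclass
class ConvStackParams:
    """Kernels/biases for an L-layer same-padded convolution stack."""

    kernels: list[Tensor]   # each (k, k, C_in, C_out)
    biases: list[Tensor]    # each (C_out,)
    activation: str = "leaky_relu"
    pool_size: int = 2

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("conv stack needs at least one layer")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        for l in range(1, len(self.kernels)):
            if self.kernels[l].shape[2] != self.kernels[l - 1].shape[3]:
                raise ValueError(f"kernel channel chain broken at layer {l}")

    @property
    def n_layers(self) -> int:
        return len(self.kernels)

    @property
    def out_channels(self) -> int:
        return self.kernels[-1].shape[3]

    @classmethod
    def create(cls, rng: np.random.Generator, in_channels: int,
               channels: tuple[int, ...] = (4,), kernel_size: int = 3,
               activation: str = "leaky_relu", pool_size: int = 2) -> "ConvStackParams":
        kernels, biases = [], []
        prev = in_channels
        for c in channels:
            kernels.append(_init(rng, kernel_size, kernel_size, prev, c))
            biases.append(Tensor(np.zeros(c), requires_grad=True))
            prev = c
        return cls(kernels=kernels, biases=biases, activation=activation,
                   pool_size=pool_size)

    def parameters(self, prefix: str = "conv") -> dict[str, Tensor]:
        out = {}
        for l, (k, b) in enumerate(zip(self.kernels, self.biases)):
            out[f"{prefix}.k{l}"] = k
            out[f"{prefix}.b{l}"] = b
        return out


def conv_forward(x: Tensor | np.ndarray, params: ConvStackParams,
                 layer: int) -> Tensor:
    """One convolution layer: Z^(l) = act(W^(l) * Z^(l-1) + b^(l)).

    ``x`` has shape (B, H, W, C_in); "same" zero padding with stride 1 keeps
    the spatial dimensions.  Implemented as an im2col gather followed by a
    matrix multiply, so gradients flow through standard autodiff ops.
    """
    x = as_tensor(x)
    kern, bias = params.kernels[layer], params.biases[layer]
    k, _, c_in, c_out = kern.shape
    if x.shape[-1] != c_in:
        raise ValueError(
            f"layer {layer} expects {c_in} input channels, got {x.shape[-1]}")
    b_sz, h, w, _ = x.shape
    pad = (k - 1) // 2
    xp = x.pad2d(pad, axes=(1, 2))

    # im2col indices: output position (i, j) reads rows i..i+k-1, cols j..j+k-1
    ii = (np.arange(h)[:, None, None, None] + np.arange(k)[None, None, :, None])
    jj = (np.arange(w)[None, :, None, None] + np.arange(k)[None, None, None, :])
    ii = np.broadcast_to(ii, (h, w, k, k))
    jj = np.broadcast_to(jj, (h, w, k, k))
    patches = xp[:, ii, jj, :]                     # (B, H, W, k, k, C_in)
    flat = patches.reshape(b_sz, h, w, k * k * c_in)
    out = flat @ kern.reshape(k * k * c_in, c_out) + bias
    return _activate(out, params.activation)


def conv_stack_forward(x: Tensor | np.ndarray, params: ConvStackParams) -> Tensor:
    out = as_tensor(x)
    for l in range(params.n_layers):
        out = conv_forward(out, params, l)
    return out


def max_pool(x: Tensor | np.ndarray, pool_size: int) -> Tensor:
    """Non-overlapping max pooling; spatial dims must divide the kernel size."""
    x = as_tensor(x)
    b, h, w, c = x.shape
    k = pool_size
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h}, {w}) not divisible by pool size {k}")
    return (x.reshape(b, h // k, k, w // k, k, c)
            .max(axis=2).max(axis=3))


# ---------------------------------------------------------------------------
# spatial self-attention
# ---------------------------------------------------------------------------

@dataclass
class SpatialAttentionParams:
    """Q/K/V projections over flattened grid positions."""

    w_q: Tensor   # (C, d)
    w_k: Tensor   # (C, d)
    w_v: Tensor   # (C, d_v)

    def __post_init__(self) -> None:
        if self.w_q.shape != self.w_k.shape:
            raise ValueError("Q and K projections must share shape")
        if self.w_q.shape[1] < 1:
            raise ValueError("attention dimension d must be >= 1")

    @property
    def d(self) -> int:
        return self.w_q.shape[1]

    @classmethod
    def create(cls, rng: np.random.Generator, channels: int, d: int,
               d_v: int | None = None) -> "SpatialAttentionParams":
        if d < 1:
            raise ValueError("attention dimension d must be >= 1")
        d_v = channels if d_v is None else d_v
        return cls(w_q=_init(rng, channels, d), w_k=_init(rng, channels, d),
                   w_v=_init(rng, channels, d_v))

    def parameters(self, prefix: str = "attn") -> dict[str, Tensor]:
        return {f"{prefix}.wq": self.w_q, f"{prefix}.wk": self.w_k,
                f"{prefix}.wv": self.w_v}


def spatial_attention(pooled: Tensor | np.ndarray,
                      params: SpatialAttentionParams) -> tuple[Tensor, Tensor]:
    """Self-attention over grid positions.

    ``pooled`` is (B, H', W', C) or already flattened (B, N, C).  Returns the
    attended features (B, N, d_v) and the attention weights (B, N, N); each
    weight row is a softmax and sums to 1.
    """
    p = as_tensor(pooled)
    if p.ndim == 4:
        b, h, w, c = p.shape
        p = p.reshape(b, h * w, c)
    q = p @ params.w_q                      # (B, N, d)
    k = p @ params.w_k
    v = p @ params.w_v
    scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(params.d))
    weights = scores.softmax(axis=-1)       # rows sum to 1
    return weights @ v, weights


# ---------------------------------------------------------------------------
# GRU
# ---------------------------------------------------------------------------

@dataclass
class GruParams:
    """Gated recurrent unit weights (input maps W, recurrent maps U, biases b)."""

    w_r: Tensor
    w_u: Tensor
    w_h: Tensor
    u_r: Tensor
    u_u: Tensor
    u_h: Tensor
    b_r: Tensor
    b_u: Tensor
    b_h: Tensor

    def __post_init__(self) -> None:
        dh, dz = self.w_r.shape
        for name in ("w_u", "w_h"):
            if getattr(self, name).shape != (dh, dz):
                raise ValueError(f"{name} must have shape ({dh}, {dz})")
        for name in ("u_r", "u_u", "u_h"):
            if getattr(self, name).shape != (dh, dh):
                raise ValueError(f"{name} must have shape ({dh}, {dh})")
        for name in ("b_r", "b_u", "b_h"):
            if getattr(self, name).shape != (dh,):
                raise ValueError(f"{name} must have shape ({dh},)")

    @property
    def hidden_size(self) -> int:
        return self.w_r.shape[0]

    @property
    def input_size(self) -> int:
        return self.w_r.shape[1]

    @classmethod
    def create(cls, rng: np.random.Generator, input_size: int,
               hidden_size: int) -> "GruParams":
        mk_w = lambda: _init(rng, hidden_size, input_size)
        mk_u = lambda: _init(rng, hidden_size, hidden_size)
        mk_b = lambda: Tensor(np.zeros(hidden_size), requires_grad=True)
        return cls(w_r=mk_w(), w_u=mk_w(), w_h=mk_w(),
                   u_r=mk_u(), u_u=mk_u(), u_h=mk_u(),
                   b_r=mk_b(), b_u=mk_b(), b_h=mk_b())

    def parameters(self, prefix: str = "gru") -> dict[str, Tensor]:
        return {f"{prefix}.{n}": getattr(self, n)
                for n in ("w_r", "w_u", "w_h", "u_r", "u_u", "u_h",
                          "b_r", "b_u", "b_h")}


def gru_step(z: Tensor | np.ndarray, h_prev: Tensor | np.ndarray,
             params: GruParams) -> Tensor:
    """One GRU update.

    r = sigmoid(W_r z + U_r h + b_r),  u = sigmoid(W_u z + U_u h + b_u),
    h~ = tanh(W_h z + U_h (r*h) + b_h),  h' = u*h + (1-u)*h~.

    ``z`` is (B, d_z), ``h_prev`` (B, d_h).
    """
    z, h_prev = as_tensor(z), as_tensor(h_prev)
    if z.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ValueError(
            f"shape mismatch: z {z.shape}, h {h_prev.shape} vs "
            f"(d_z={params.input_size}, d_h={params.hidden_size})")
    wt = lambda m: m.transpose()
    r = (z @ wt(params.w_r) + h_prev @ wt(params.u_r) + params.b_r).sigmoid()
    u = (z @ wt(params.w_u) + h_prev @ wt(params.u_u) + params.b_u).sigmoid()
    cand = (z @ wt(params.w_h) + (r * h_prev) @ wt(params.u_h)
            + params.b_h).tanh()
    return u * h_prev + (1.0 - u) * cand


# ---------------------------------------------------------------------------
# modality fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionParams:
    """Query vector and per-modality bilinear maps for attention fusion."""

    query: Tensor            # (d_q,)
    maps: list[Tensor]       # each (d_q, d_e)

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("fusion needs at least one modality (K >= 1)")
        dq = self.query.shape[0]
        for k, w in enumerate(self.maps):
            if w.shape[0] != dq:
                raise ValueError(f"modality map {k} incompatible with query")

    @property
    def n_modalities(self) -> int:
        return len(self.maps)

    @classmethod
    def create(cls, rng: np.random.Generator, n_modalities: int, embed_dim: int,
               query_dim: int | None = None) -> "FusionParams":
        dq = embed_dim if query_dim is None else query_dim
        return cls(query=_init(rng, dq, scale=1.0 / np.sqrt(dq)),
                   maps=[_init(rng, dq, embed_dim) for _ in range(n_modalities)])

    def parameters(self, prefix: str = "fuse") -> dict[str, Tensor]:
        out = {f"{prefix}.q": self.query}
        for k, w in enumerate(self.maps):
            out[f"{prefix}.w{k}"] = w
        return out


def fuse_modalities(modalities: list[Tensor | np.ndarray],
                    params: FusionParams) -> tuple[Tensor, Tensor]:
    """Attention-weighted fusion of K equal-length modality embeddings.

    Scores s_k = q^T W_k M_k; weights a = softmax_k(s); fused f = sum_k a_k M_k.
    Each modality is (B, d_e); returns fused (B, d_e) and weights (B, K).
    """
    mods = [as_tensor(m) for m in modalities]
    if len(mods) != params.n_modalities:
        raise ValueError(f"expected {params.n_modalities} modalities, got {len(mods)}")
    d_e = mods[0].shape[-1]
    for k, m in enumerate(mods):
        if m.shape[-1] != d_e:
            raise ValueError(f"modality {k} length {m.shape[-1]} != {d_e}")
    scores = stack([(m @ w.transpose()) @ params.query
                    for m, w in zip(mods, params.maps)], axis=-1)   # (B, K)
    weights = scores.softmax(axis=-1)
    fused = None
    for k, m in enumerate(mods):
        term = weights[:, k].reshape(-1, 1) * m
        fused = term if fused is None else fused + term
    return fused, weights


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------

def linear(x: Tensor | np.ndarray, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = as_tensor(x) @ w
    return out if b is None else out + b


def mlp_forward(x: Tensor | np.ndarray, weights: list[Tensor], biases: list[Tensor],
                activation: str = "leaky_relu") -> Tensor:
    """Fully connected network; the final layer is linear."""
    out = as_tensor(x)
    for i, (w, b) in enumerate(zip(weights, biases)):
        out = out @ w + b
        if i < len(weights) - 1:
            out = _activate(out, activation)
    return out


def classify(fused: Tensor | np.ndarray, class_weights: Tensor) -> Tensor:
    """Class probabilities P(y=c|f) = softmax_c(W_c^T f); rows sum to 1."""
    f = as_tensor(fused)
    if class_weights.shape[1] < 2:
        raise ValueError("classification needs at least 2 classes")
    return (f @ class_weights).softmax(axis=-1)
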