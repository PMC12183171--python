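"""The spatiotemporal fusion predictor.

Per time step, the gridded observation passes through a convolution stack,
max pooling and spatial self-attention; the flattened attended features drive
a GRU across the season.  The final hidden state is encoded alongside the
sensor and weather modalities, fused by modality attention, and a fully
connected head emits the (yield, cost, environmental-impact) triple.

``gru_input`` selects what feeds the recurrence: ``"p_att"`` (default) uses
the attended pooled features so the pooling/attention stages sit on the data
path; ``"z1"`` feeds the flattened first convolution output directly,
bypassing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..autodiff import Tensor, as_tensor
from . import layers
from .layers import (ConvStackParams, FusionParams, GruParams,
                     SpatialAttentionParams)

__all__ = ["PredictorConfig", "SpatioTemporalPredictor"]


@dataclass(frozen=True)
class PredictorConfig:
    grid_h: int = 8
    grid_w: int = 8
    in_channels: int = 5
    conv_channels: tuple[int, ...] = (4,)
    kernel_size: int = 3
    pool_size: int = 2
    attention_dim: int = 8
    gru_hidden: int = 16
    embed_dim: int = 16
    head_hidden: tuple[int, ...] = (16,)
    sensor_dim: int = 8
    weather_dim: int = 3
    activation: str = "leaky_relu"
    gru_input: str = "p_att"    # "p_att" | "z1"
    n_outputs: int = 3

    def __post_init__(self) -> None:
        if self.gru_input not in ("p_att", "z1"):
            raise ValueError("gru_input must be 'p_att' or 'z1'")
        if self.grid_h % self.pool_size or self.grid_w % self.pool_size:
            raise ValueError("grid dims must be divisible by the pool size")


class SpatioTemporalPredictor:
    """Conv + pool + attention -> GRU -> modality fusion -> FC head."""

    def __init__(self, config: PredictorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config

        self.conv = ConvStackParams.create(
            rng, c.in_channels, c.conv_channels, c.kernel_size,
            c.activation, c.pool_size)
        c_l = self.conv.out_channels
        self.attention = SpatialAttentionParams.create(rng, c_l, c.attention_dim)

        hp = c.grid_h // c.pool_size
        wp = c.grid_w // c.pool_size
        if c.gru_input == "p_att":
            gru_in = hp * wp * c_l
        else:  # z1: flattened first conv layer output, full resolution
            gru_in = c.grid_h * c.grid_w * c.conv_channels[0]
        self.gru = GruParams.create(rng, gru_in, c.gru_hidden)

        # one-layer modality encoders to a shared embedding length
        def enc(d_in):
            return (layers._init(rng, d_in, c.embed_dim),
                    Tensor(np.zeros(c.embed_dim), requires_grad=True))

        self.enc_grid = enc(c.gru_hidden)
        self.enc_sensor = enc(c.sensor_dim)
        self.enc_weather = enc(c.weather_dim)
        self.fusion = FusionParams.create(rng, n_modalities=3,
                                          embed_dim=c.embed_dim)

        dims = (c.embed_dim, *c.head_hidden, c.n_outputs)
        self.head_w = [layers._init(rng, a, b) for a, b in zip(dims, dims[1:])]
        self.head_b = [Tensor(np.zeros(b), requires_grad=True) for b in dims[1:]]

    # ------------------------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        out.update(self.conv.parameters())
        out.update(self.attention.parameters())
        out.update(self.gru.parameters())
        for name, (w, b) in (("enc_grid", self.enc_grid),
                             ("enc_sensor", self.enc_sensor),
                             ("enc_weather", self.enc_weather)):
            out[f"{name}.w"], out[f"{name}.b"] = w, b
        out.update(self.fusion.parameters())
        for i, (w, b) in enumerate(zip(self.head_w, self.head_b)):
            out[f"head.w{i}"], out[f"head.b{i}"] = w, b
        return out

    # ------------------------------------------------------------------
    def spatial_step(self, grid: Tensor | np.ndarray) -> Tensor:
        """Spatial pipeline for one time step: (B, H, W, C) -> (B, d_z)."""
        c = self.config
        z = as_tensor(grid)
        z1 = layers.conv_forward(z, self.conv, 0)
        if c.gru_input == "z1":
            b = z1.shape[0]
            return z1.reshape(b, -1)
        out = z1
        for l in range(1, self.conv.n_layers):
            out = layers.conv_forward(out, self.conv, l)
        pooled = layers.max_pool(out, c.pool_size)
        attended, _ = layers.spatial_attention(pooled, self.attention)
        b = attended.shape[0]
        return attended.reshape(b, -1)

    def forward(self, grids: np.ndarray, sensors: np.ndarray,
                weather: np.ndarray) -> Tensor:
        """Full forward pass over a batch of observation sequences.

        ``grids`` is (B, T, H, W, C); ``sensors`` (B, T, d_s); ``weather``
        (B, T, d_w).  Returns (B, 3) predictions (Yhat, Chat, Ehat).
        """
        pred, _, _ = self.forward_detailed(grids, sensors, weather)
        return pred

    def forward_detailed(self, grids, sensors, weather):
        """Forward pass also returning the final hidden state and fusion weights."""
        grids = np.asarray(grids, dtype=float)
        if not np.all(np.isfinite(grids)):
            raise FloatingPointError("non-finite values in the observation grids")
        b, t_steps = grids.shape[:2]
        h = Tensor(np.zeros((b, self.config.gru_hidden)))
        for t in range(t_steps):
            z = self.spatial_step(grids[:, t])
            h = layers.gru_step(z, h, self.gru)

        mods = [
            (h @ self.enc_grid[0] + self.enc_grid[1]).tanh(),
            (as_tensor(np.asarray(sensors, dtype=float)[:, -1])
             @ self.enc_sensor[0] + self.enc_sensor[1]).tanh(),
            (as_tensor(np.asarray(weather, dtype=float)[:, -1])
             @ self.enc_weather[0] + self.enc_weather[1]).tanh(),
        ]
        fused, fusion_weights = layers.fuse_modalities(mods, self.fusion)
        pred = layers.mlp_forward(fused, self.head_w, self.head_b,
                                  self.config.activation)
        return pred, h, fusion_weights

    def predict(self, grids, sensors, weather) -> np.ndarray:
        """Deterministic (Yhat, Chat, Ehat) for a batch of sequences."""
        return self.forward(grids, sensors, weather).numpy()

    # ------------------------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"checkpoint/model parameter mismatch: {sorted(missing)}")
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=float).reshape(p.shape).copy()
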