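"""The learned denoiser g(x_t, x_LR, t) -> estimated clean HR image.

An encoder-decoder with skip connections in which windowed shifted-attention
blocks (see :class:`~shiftsr.nn.layers.WindowAttention`) stand in for
conventional global attention; they are placed at the two coarsest
resolution levels, and an ablation switch removes them entirely.

Conditioning: the noisy state ``x_t`` and the (pre-upsampled) LR image are
concatenated along channels; the integer timestep enters through a
sinusoidal embedding added per-channel inside every residual block.  The
final convolution is zero-initialized and the output carries a global skip
from the LR channel, so an untrained network is the identity on the LR
input and training only has to learn the correction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .autodiff import Tensor, concat
from .layers import (
    Conv2d,
    GroupNorm,
    Linear,
    Module,
    ResBlock,
    WindowAttention,
    sinusoidal_embedding,
)

__all__ = ["DenoiserSpec", "ShiftUNet", "count_parameters", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class DenoiserSpec:
    """Configuration of the denoiser network.

    ``channel_mults`` gives the per-level width multiplier (defaults to
    ``(1, 2, 2, ...)`` truncated to ``depth``); attention, when enabled, is
    applied at the two coarsest levels and in the bottleneck (where the
    window is shifted by half its size, alternating with the unshifted
    encoder/decoder windows).
    """

    base_channels: int = 32
    depth: int = 3
    use_windowed_attention: bool = True
    window_size: int = 4
    time_embed_dim: int = 64
    in_channels: int = 2
    out_channels: int = 1
    channel_mults: Optional[tuple[int, ...]] = None
    num_heads: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.channel_mults is not None and len(self.channel_mults) != self.depth:
            raise ValueError(
                f"channel_mults has {len(self.channel_mults)} entries for depth {self.depth}"
            )

    @property
    def mults(self) -> tuple[int, ...]:
        if self.channel_mults is not None:
            return tuple(self.channel_mults)
        return (1,) + (2,) * (self.depth - 1)

    @property
    def level_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * m for m in self.mults)

    def attention_levels(self) -> tuple[int, ...]:
        """Indices of resolution levels that carry attention blocks."""
        if not self.use_windowed_attention:
            return ()
        return tuple(range(max(0, self.depth - 2), self.depth))


class ShiftUNet(Module):
    """Encoder-decoder denoiser; see module docstring for the layout."""

    def __init__(self, spec: DenoiserSpec, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(spec.seed)
        ch = spec.level_channels
        te = spec.time_embed_dim
        attn_lvls = set(spec.attention_levels())

        self.time_mlp1 = Linear(te, te, rng, dtype)
        self.time_mlp2 = Linear(te, te, rng, dtype)
        self.stem = Conv2d(spec.in_channels, ch[0], 3, rng, dtype)

        self.enc_res = []
        self.enc_attn = []
        prev = ch[0]
        for lvl in range(spec.depth):
            self.enc_res.append(ResBlock(prev, ch[lvl], te, rng, dtype))
            self.enc_attn.append(
                WindowAttention(ch[lvl], spec.window_size, rng,
                                heads=spec.num_heads, shifted=False, dtype=dtype)
                if lvl in attn_lvls else None
            )
            prev = ch[lvl]

        self.mid_res1 = ResBlock(ch[-1], ch[-1], te, rng, dtype)
        self.mid_attn = (
            WindowAttention(ch[-1], spec.window_size, rng,
                            heads=spec.num_heads, shifted=True, dtype=dtype)
            if spec.use_windowed_attention else None
        )
        self.mid_res2 = ResBlock(ch[-1], ch[-1], te, rng, dtype)

        self.dec_res = []
        self.dec_attn = []
        for lvl in range(spec.depth):
            c_in = (ch[lvl + 1] if lvl + 1 < spec.depth else ch[-1]) + ch[lvl]
            self.dec_res.append(ResBlock(c_in, ch[lvl], te, rng, dtype))
            self.dec_attn.append(
                WindowAttention(ch[lvl], spec.window_size, rng,
                                heads=spec.num_heads, shifted=True, dtype=dtype)
                if lvl in attn_lvls else None
            )

        self.out_norm = GroupNorm(ch[0], dtype=dtype)
        self.out_conv = Conv2d(ch[0], spec.out_channels, 3, rng, dtype, zero_init=True)

    # ------------------------------------------------------------- forward
    def _validate_shape(self, h: int, w: int) -> None:
        d = self.spec.depth
        down = 2 ** (d - 1)
        for name, extent in (("height", h), ("width", w)):
            if extent % down:
                raise ValueError(
                    f"input {name} {extent} is not divisible by 2**(depth-1)={down}"
                )
        if self.spec.use_windowed_attention:
            for lvl in self.spec.attention_levels():
                res_h, res_w = h >> lvl, w >> lvl
                if res_h % self.spec.window_size or res_w % self.spec.window_size:
                    raise ValueError(
                        f"window size {self.spec.window_size} does not divide the "
                        f"{res_h}x{res_w} extent at level {lvl}"
                    )

    def forward(self, x: Tensor, t: np.ndarray) -> Tensor:
        """Batched forward pass.

        Parameters
        ----------
        x : Tensor, shape ``(N, H, W, 2)`` — channels are ``(x_t, lr)``.
        t : integer array of shape ``(N,)``.
        """
        n, hh, ww, c_in = x.shape
        if c_in != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channels, got {c_in}")
        self._validate_shape(hh, ww)
        temb = Tensor(sinusoidal_embedding(t, self.spec.time_embed_dim, self.dtype))
        temb = self.time_mlp2(self.time_mlp1(temb).silu())

        h = self.stem(x)
        skips = []
        for lvl in range(self.spec.depth):
            h = self.enc_res[lvl](h, temb)
            if self.enc_attn[lvl] is not None:
                h = self.enc_attn[lvl](h)
            skips.append(h)
            if lvl < self.spec.depth - 1:
                h = h.avg_pool2x2()

        h = self.mid_res1(h, temb)
        if self.mid_attn is not None:
            h = self.mid_attn(h)
        h = self.mid_res2(h, temb)

        for lvl in reversed(range(self.spec.depth)):
            h = concat([h, skips[lvl]], axis=-1)
            h = self.dec_res[lvl](h, temb)
            if self.dec_attn[lvl] is not None:
                h = self.dec_attn[lvl](h)
            if lvl > 0:
                h = h.upsample_nearest2x()

        out = self.out_conv(self.out_norm(h).silu())
        # global skip from the LR conditioning channel (constant w.r.t. weights)
        lr = Tensor(x.data[..., 1:2])
        return out + lr

    def predict_x0(self, x_t: np.ndarray, lr: np.ndarray, t: int) -> np.ndarray:
        """Single-slice convenience wrapper: 2-D arrays in, 2-D array out."""
        x_t = np.asarray(x_t)
        lr = np.asarray(lr)
        if x_t.shape != lr.shape:
            raise ValueError(f"x_t shape {x_t.shape} != lr shape {lr.shape}")
        x = np.stack([x_t, lr], axis=-1)[None].astype(self.dtype)
        out = self.forward(Tensor(x), np.array([t]))
        return out.data[0, :, :, 0].astype(np.float64)


def count_parameters(spec_or_model) -> int:
    """Total number of trainable scalars, introspected from the weights."""
    model = spec_or_model if isinstance(spec_or_model, Module) else ShiftUNet(spec_or_model)
    return model.n_parameters()


# ------------------------------------------------------------- checkpoints
def save_checkpoint(path, model: ShiftUNet, schedule_fingerprint: str,
                    extra: Optional[dict] = None) -> None:
    """Write weights + spec + schedule fingerprint to an ``.npz`` file."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "spec": asdict(model.spec),
        "schedule_fingerprint": schedule_fingerprint,
        "dtype": np.dtype(model.dtype).name,
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[ShiftUNet, dict]:
    """Load a checkpoint; returns ``(model, meta)``."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
        spec_d = dict(meta["spec"])
        if spec_d.get("channel_mults") is not None:
            spec_d["channel_mults"] = tuple(spec_d["channel_mults"])
        spec = DenoiserSpec(**spec_d)
        model = ShiftUNet(spec, dtype=np.dtype(meta["dtype"]))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model, meta
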