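"""Contour detection and alignment (CDA) layer.

Sits at the entrance of the denoising U-Net.  The soft-mask stream is
expanded by pyramidal pooling — parallel 3x3 atrous (dilated) convolutions
at rates 2, 4, 6, 8 with 'same' padding, concatenated and projected back —
and its contour features are merged into the pressure stream by
cross-attention: queries come from pressure-stream pixels, keys and values
from the mask-stream feature map after non-overlapping spatial average
pooling.  The attention output is residual-added to the pressure stream,
and a sinusoidal embedding of the diffusion step t conditions both stems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class CDAConfig:
    atrous_rates: tuple[int, ...] = (2, 4, 6, 8)
    channels: int = 16
    pool_size: int = 4
    n_heads: int = 4

    def __post_init__(self):
        r = tuple(self.atrous_rates)
        if len(r) == 0 or any(x <= 0 for x in r) or any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("atrous_rates must be strictly increasing positive integers")
        if self.channels % self.n_heads:
            raise ValueError("channels must be divisible by n_heads")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        self.atrous_rates = r


def _as_nchw(x: Tensor) -> Tensor:
    if x.ndim == 2:
        return x.reshape(1, 1, *x.shape)
    if x.ndim == 3:
        N, H, W = x.shape
        return x.reshape(N, 1, H, W)
    return x


class PyramidalPool(nn.Module):
    """One dilated 3x3 branch per atrous rate, concatenated then projected
    back to ``channels`` by a 1x1 convolution."""

    def __init__(self, cfg: CDAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.branches = nn.ModuleList(
            nn.Conv2d(cfg.channels, cfg.channels, 3, rng, dilation=r)
            for r in cfg.atrous_rates
        )
        self.project = nn.Conv2d(cfg.channels * len(cfg.atrous_rates), cfg.channels, 1, rng)

    def min_input_size(self) -> int:
        return 2 * max(self.cfg.atrous_rates) + 1

    def forward(self, x: Tensor) -> Tensor:
        x = _as_nchw(x)
        m = self.min_input_size()
        H, W = x.shape[-2:]
        if H < m or W < m:
            raise ValueError(
                f"input {H}x{W} too small for atrous rates {self.cfg.atrous_rates}; "
                f"minimum input size is {m}x{m}"
            )
        outs = [br(x) for br in self.branches]
        return self.project(nn.concatenate(outs, axis=1))


class CrossAttention(nn.Module):
    """Spatial-pooling-based multi-head cross-attention.

    Queries are the pixels of the query feature map; keys/values are tokens
    of the key/value map after non-overlapping average pooling by
    ``pool_size`` (zero-padded up to a multiple).  Output is residual-added
    to the query map.
    """

    def __init__(self, cfg: CDAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.wq = nn.Linear(c, c, rng)
        self.wk = nn.Linear(c, c, rng)
        self.wv = nn.Linear(c, c, rng)
        self.wo = nn.Linear(c, c, rng)
        # residual-branch output starts near zero so the fused model begins
        # as the pure query-stream function and grows attention use by need
        self.wo.weight.data *= 0.05

    def _tokens(self, x: Tensor) -> Tensor:
        """[N, C, H, W] -> [N, H*W, C]"""
        N, C, H, W = x.shape
        return x.reshape(N, C, H * W).transpose(0, 2, 1)

    def forward(self, query_src: Tensor, kv_src: Tensor,
                return_weights: bool = False):
        query_src = _as_nchw(query_src)
        kv_src = _as_nchw(kv_src)
        if query_src.shape[-2:] != kv_src.shape[-2:]:
            raise ValueError("query and key/value maps must share H x W")
        N, C, H, W = query_src.shape
        p = self.cfg.pool_size
        if p > 1:
            ph = (-H) % p
            pw = (-W) % p
            kv = nn.pad2d(kv_src, (0, ph, 0, pw)) if (ph or pw) else kv_src
            kv = nn.avg_pool2d(kv, p)
        else:
            kv = kv_src
        q = self.wq(self._tokens(query_src))          # [N, Tq, C]
        k = self.wk(self._tokens(kv))                 # [N, Tk, C]
        v = self.wv(self._tokens(kv))
        h = self.cfg.n_heads
        dh = C // h

        def split(t: Tensor) -> Tensor:
            Nb, T, _ = t.shape
            return t.reshape(Nb, T, h, dh).transpose(0, 2, 1, 3)  # [N, h, T, dh]

        qh, kh, vh = split(q), split(k), split(v)
        logits = qh @ kh.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
        attn = nn.softmax(logits, axis=-1)
        out = attn @ vh                                # [N, h, Tq, dh]
        out = out.transpose(0, 2, 1, 3).reshape(N, H * W, C)
        out = self.wo(out)
        out = out.transpose(0, 2, 1).reshape(N, C, H, W)
        fused = query_src + out
        if return_weights:
            return fused, attn.data
        return fused


class CDALayer(nn.Module):
    """The full conditioned entrance: 1x1 stems lift the two single-channel
    grids, the diffusion step is added as a sinusoidal channel embedding,
    the mask stream goes through pyramidal pooling, and cross-attention
    merges it into the pressure stream.

    ``use_mask_stream`` / ``use_pp`` switch off the RMFD+CA and PP elements
    for ablation runs (pressure-stream-only when the mask stream is off).
    """

    def __init__(self, cfg: CDAConfig, rng: np.random.Generator,
                 use_mask_stream: bool = True, use_pp: bool = True):
        super().__init__()
        self.cfg = cfg
        self.use_mask_stream = use_mask_stream
        self.use_pp = use_pp
        self.stem_p = nn.Conv2d(1, cfg.channels, 1, rng)
        self.t_proj = nn.Linear(cfg.channels, cfg.channels, rng)
        self.t_proj.weight.data *= 0.05  # embedding starts as a small perturbation
        if use_mask_stream:
            self.stem_m = nn.Conv2d(1, cfg.channels, 1, rng)
            self.attend = CrossAttention(cfg, rng)
            if use_pp:
                self.pp = PyramidalPool(cfg, rng)

    def _embed_t(self, x: Tensor, t) -> Tensor:
        """Add a sinusoidal step embedding; t may be None (skip), a scalar,
        or a per-sample vector of length N."""
        if t is None:
            return x
        emb = nn.sinusoidal_embedding(t, self.cfg.channels)
        if emb.ndim == 1:
            emb = emb[None]
        proj = self.t_proj(Tensor(emb))  # [N, C]
        return x + proj.reshape(proj.shape[0], -1, 1, 1)

    def forward(self, p_t: Tensor, m_t: Tensor | None, t: int | None) -> Tensor:
        p_t = _as_nchw(p_t if isinstance(p_t, Tensor) else Tensor(p_t))
        hp = self._embed_t(self.stem_p(p_t), t)
        if not self.use_mask_stream or m_t is None:
            return hp
        m_t = _as_nchw(m_t if isinstance(m_t, Tensor) else Tensor(m_t))
        if p_t.shape[-2:] != m_t.shape[-2:]:
            raise ValueError("pressure and mask grids must share H x W")
        hm = self._embed_t(self.stem_m(m_t), t)
        if self.use_pp:
            hm = self.pp(hm)
        return self.attend(hp, hm)
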