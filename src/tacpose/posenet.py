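"""Stage 2: 3D pose prediction from a (restored) pressure frame.

A patch-tokenised transformer encoder (pre-norm blocks of layer
normalisation, multi-head self-attention and an MLP, all with residuals)
reads the frame; a deconvolutional decoder (stride-2 transposed
convolution, batch normalisation, ReLU per block) re-spatialises the
tokens; a single affine head maps the flattened feature map to J x 3 joint
coordinates in millimetres.

Joint coordinates are standardised internally (per-joint mean, global
standard deviation over the training poses); the statistics are stored as
buffers so a reloaded checkpoint predicts identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from ._seeding import rng as _rng
from .nn import Tensor


@dataclass
class PoseNetConfig:
    patch_size: int = 8
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    decoder_blocks: int = 2
    n_joints: int = 12
    mlp_ratio: int = 2
    frame_h: int = 64
    frame_w: int = 40
    pressure_scale: float = 15.0

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.frame_h % self.patch_size or self.frame_w % self.patch_size:
            raise ValueError("frame dims must be divisible by patch_size")
        if self.d_model >> self.decoder_blocks < 1:
            raise ValueError("d_model too small for decoder_blocks halvings")

    @property
    def grid(self) -> tuple[int, int]:
        return self.frame_h // self.patch_size, self.frame_w // self.patch_size


class SelfAttention(nn.Module):
    def __init__(self, d: int, n_heads: int, rng):
        super().__init__()
        self.h = n_heads
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)

    def forward(self, x: Tensor, return_weights: bool = False):
        N, T, d = x.shape
        h, dh = self.h, d // self.h

        def split(t):
            return t.reshape(N, T, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        logits = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
        attn = nn.softmax(logits, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(N, T, d)
        out = self.wo(out)
        if return_weights:
            return out, attn.data
        return out


class EncoderBlock(nn.Module):
    def __init__(self, d: int, n_heads: int, mlp_ratio: int, rng):
        super().__init__()
        self.ln1 = nn.LayerNorm(d)
        self.attn = SelfAttention(d, n_heads, rng)
        self.ln2 = nn.LayerNorm(d)
        self.fc1 = nn.Linear(d, d * mlp_ratio, rng)
        self.fc2 = nn.Linear(d * mlp_ratio, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).relu())


class PoseNet(nn.Module):
    def __init__(self, cfg: PoseNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        gh, gw = cfg.grid
        ps = cfg.patch_size
        self.patch_embed = nn.Linear(ps * ps, cfg.d_model, rng)
        self.pos_emb = nn.Parameter(rng.normal(0, 0.02, size=(gh * gw, cfg.d_model)))
        self.blocks = nn.ModuleList(
            EncoderBlock(cfg.d_model, cfg.n_heads, cfg.mlp_ratio, rng)
            for _ in range(cfg.n_layers)
        )
        dec, bns = [], []
        ch = cfg.d_model
        for _ in range(cfg.decoder_blocks):
            dec.append(nn.ConvTranspose2x2(ch, ch // 2, rng))
            bns.append(nn.BatchNorm2d(ch // 2))
            ch //= 2
        self.deconvs = nn.ModuleList(dec)
        self.bns = nn.ModuleList(bns)
        flat = ch * (gh * 2 ** cfg.decoder_blocks) * (gw * 2 ** cfg.decoder_blocks)
        self.head = nn.Linear(flat, cfg.n_joints * 3, rng)
        self.register_buffer("target_mean", np.zeros((cfg.n_joints, 3)))
        self.register_buffer("target_std", np.ones(1))

    # -- pieces ---------------------------------------------------------------
    def patchify(self, frames: np.ndarray) -> np.ndarray:
        """[N, H, W] -> [N, T, ps*ps] raster-ordered patches."""
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        N = frames.shape[0]
        gh, gw = self.cfg.grid
        ps = self.cfg.patch_size
        if frames.shape[1:] != (self.cfg.frame_h, self.cfg.frame_w):
            raise ValueError(
                f"expected frames {self.cfg.frame_h}x{self.cfg.frame_w}, got {frames.shape[1:]}"
            )
        x = frames.reshape(N, gh, ps, gw, ps).transpose(0, 1, 3, 2, 4)
        return x.reshape(N, gh * gw, ps * ps)

    def encode(self, frames: np.ndarray) -> Tensor:
        """Patch-tokenise, add positional embeddings, run the encoder blocks.
        Returns [N, T, d_model]."""
        tok = Tensor(self.patchify(frames) / self.cfg.pressure_scale)
        x = self.patch_embed(tok) + self.pos_emb
        for blk in self.blocks:
            x = blk(x)
        return x

    def decode(self, tokens: Tensor) -> Tensor:
        """Tokens -> feature map via deconv/BN/ReLU blocks; output >= 0."""
        N, T, d = tokens.shape
        gh, gw = self.cfg.grid
        x = tokens.transpose(0, 2, 1).reshape(N, d, gh, gw)
        for deconv, bn in zip(self.deconvs, self.bns):
            x = bn(deconv(x)).relu()
        return x

    def predict_keypoints(self, k: Tensor) -> Tensor:
        """Flatten row-major and apply the affine head -> [N, J, 3]
        (standardised coordinates)."""
        N = k.shape[0]
        flat = k.reshape(N, -1)
        out = self.head(flat)
        return out.reshape(N, self.cfg.n_joints, 3)

    def forward(self, frames: np.ndarray) -> Tensor:
        return self.predict_keypoints(self.decode(self.encode(frames)))

    def predict_mm(self, frames: np.ndarray) -> np.ndarray:
        """Predicted keypoints in millimetres, [N, J, 3]."""
        self.eval()
        out = self.forward(frames).data
        self.train()
        return out * self.target_std[0] + self.target_mean[None]

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        cfgd = self.cfg.__dict__.copy()
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfgd, sort_keys=True).encode(), dtype=np.uint8
        ), **self.state_dict())

    @classmethod
    def load(cls, path) -> "PoseNet":
        with np.load(path) as z:
            cfgd = json.loads(bytes(z["__config__"].tobytes()).decode())
            state = {k: z[k] for k in z.files if k != "__config__"}
        model = cls(PoseNetConfig(**cfgd), _rng(0, "load"))
        model.load_state_dict(state)
        return model


@dataclass
class Stage2TrainConfig:
    lr: float = 1e-3
    epochs: int = 10
    batch: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be nonnegative")


def mean_pose(poses: np.ndarray) -> np.ndarray:
    """The constant mean-pose predictor: per-joint mean over samples."""
    return np.asarray(poses, dtype=float).mean(axis=0)


def train_stage2(
    frames: np.ndarray,
    poses: np.ndarray,
    cfg: PoseNetConfig,
    tcfg: Stage2TrainConfig,
) -> tuple[PoseNet, list[float]]:
    """Train the pose regressor on (frame, pose-mm) pairs with MSE/Adam.

    Targets are standardised with training-set statistics (stored on the
    model).  Returns the model and the per-epoch mean loss history.
    """
    frames = np.asarray(frames, dtype=float)
    poses = np.asarray(poses, dtype=float)
    n = frames.shape[0]
    model = PoseNet(cfg, _rng(tcfg.seed, "init"))
    mu = poses.mean(axis=0)
    sd = float(poses.std()) or 1.0
    model.target_mean[...] = mu
    model.target_std[...] = sd
    targets = (poses - mu) / sd
    opt = nn.Adam(model.parameters(), lr=tcfg.lr)

    history: list[float] = []
    for epoch in range(tcfg.epochs):
        order = np.arange(n)
        _rng(tcfg.seed, "shuffle", epoch).shuffle(order)
        total = 0.0
        for b0 in range(0, n, tcfg.batch):
            idx = order[b0 : b0 + tcfg.batch]
            pred = model(frames[idx])
            diff = pred - Tensor(targets[idx])
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        history.append(total / n)
    return model, history
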