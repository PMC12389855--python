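"""Dual-diffusion signal enhancement (DDSE): the modified U-Net denoiser
with the CDA layer at its entrance, Stage-1 training, and the reverse
denoising loop.

The reverse chain restores a *specific* observed frame: the noisy input and
its refined mask are forward-diffused to step D (stored trajectories, one
shared schedule, independent noise), then the U-Net iterates
P_{t-1} = U(P_t, M_t, t) from t = D down to 1, conditioning on the stored
soft mask at each step.  Training supervises each step against the
closed-form marginal mean of the clean frame at t-1 under MSE, with Adam.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from ._seeding import rng as _rng, spawn_seed
from .cda import CDAConfig, CDALayer
from .diffusion import NoiseSchedule, forward_trajectory, marginal_sample, marginal_stats
from .mask import MaskParams, refine
from .nn import Tensor
from .synthetic import SyntheticScene


@dataclass
class UNetConfig:
    depth: int = 3
    base_channels: int = 32
    cda: CDAConfig = field(default_factory=CDAConfig)

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")


@dataclass
class Stage1TrainConfig:
    lr: float = 5e-3
    epochs: int = 5
    batch: int = 8
    draws: int = 3  # diffusion-step draws per scene per epoch
    grad_clip: float = 1.0  # global gradient-norm ceiling (0 disables)
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be nonnegative")
        if self.loss != "mse":
            raise ValueError("only mse loss is supported")


class _DoubleConv(nn.Module):
    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.c1 = nn.Conv2d(c_in, c_out, 3, rng)
        self.c2 = nn.Conv2d(c_out, c_out, 3, rng)

    def forward(self, x):
        return self.c2(self.c1(x).relu()).relu()


class UNet(nn.Module):
    """Symmetric encoder-decoder with skip connections merging feature maps
    of equal resolution; inputs whose H/W do not divide 2**depth are
    symmetrically zero-padded and the output cropped back."""

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        b = cfg.base_channels
        c_in = cfg.cda.channels
        self.inc = _DoubleConv(c_in, b, rng)
        downs, ups, upconvs = [], [], []
        ch = b
        for _ in range(cfg.depth):
            downs.append(_DoubleConv(ch, ch * 2, rng))
            ch *= 2
        for _ in range(cfg.depth):
            upconvs.append(nn.ConvTranspose2x2(ch, ch // 2, rng))
            ups.append(_DoubleConv(ch, ch // 2, rng))
            ch //= 2
        self.downs = nn.ModuleList(downs)
        self.upconvs = nn.ModuleList(upconvs)
        self.ups = nn.ModuleList(ups)
        self.outc = nn.Conv2d(b, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: [N, C, H, W] from the CDA layer -> [N, H, W] single-channel grid."""
        N, C, H, W = x.shape
        m = 2 ** self.cfg.depth
        ph, pw = (-H) % m, (-W) % m
        if ph or pw:
            x = nn.pad2d(x, (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2))
        h = self.inc(x)
        skips = [h]
        for down in self.downs:
            h = down(nn.avg_pool2d(h, 2))
            skips.append(h)
        for upconv, up, skip in zip(self.upconvs, self.ups, reversed(skips[:-1])):
            h = upconv(h)
            h = up(nn.concatenate([skip, h], axis=1))
        out = self.outc(h)
        if ph or pw:
            out = out[:, :, ph // 2 : ph // 2 + H, pw // 2 : pw // 2 + W]
        return out.reshape(N, H, W)


class DDSEModel(nn.Module):
    """CDA entrance + U-Net body; predicts the less-noisy signal directly.

    A learned scalar gain feeds the input frame straight to the output, so
    the U-Net only has to regress the correction — the usual residual
    formulation for restoration networks."""

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator,
                 use_mask_stream: bool = True, use_pp: bool = True,
                 pressure_scale: float = 15.0):
        super().__init__()
        self.cfg = cfg
        self.use_mask_stream = use_mask_stream
        self.use_pp = use_pp
        self.pressure_scale = pressure_scale
        self.mask_zeroed = False  # trained with an uninformative (zero) mask stream
        self.trained_D: int | None = None
        self.cda = CDALayer(cfg.cda, rng, use_mask_stream=use_mask_stream, use_pp=use_pp)
        self.unet = UNet(cfg, rng)

    def forward(self, p_t, m_t, t, gain=1.0) -> Tensor:
        """gain: scalar or per-sample [N] residual coefficient on the input
        frame (the per-step marginal scale ratio during the reverse walk)."""
        p_t = p_t if isinstance(p_t, Tensor) else Tensor(p_t)
        if p_t.ndim == 2:
            x = p_t.reshape(1, *p_t.shape)
        elif p_t.ndim == 4:  # [N, 1, H, W] -> [N, H, W]
            x = p_t.reshape(p_t.shape[0], *p_t.shape[2:])
        else:
            x = p_t
        g = np.asarray(gain, dtype=float)
        if g.ndim == 1:
            g = g[:, None, None]
        return self.unet(self.cda(p_t, m_t, t)) + x * Tensor(g)

    # -- persistence ----------------------------------------------------------
    def config_dict(self) -> dict:
        return {
            "unet": {"depth": self.cfg.depth, "base_channels": self.cfg.base_channels},
            "cda": asdict(self.cfg.cda),
            "use_mask_stream": self.use_mask_stream,
            "use_pp": self.use_pp,
            "mask_zeroed": self.mask_zeroed,
            "pressure_scale": self.pressure_scale,
            "trained_D": self.trained_D,
        }

    def save(self, path) -> None:
        state = self.state_dict()
        np.savez(path, __config__=np.frombuffer(
            json.dumps(self.config_dict(), sort_keys=True).encode(), dtype=np.uint8
        ), **state)

    @classmethod
    def load(cls, path) -> "DDSEModel":
        with np.load(path) as z:
            cfgd = json.loads(bytes(z["__config__"].tobytes()).decode())
            state = {k: z[k] for k in z.files if k != "__config__"}
        cda = CDAConfig(**{**cfgd["cda"], "atrous_rates": tuple(cfgd["cda"]["atrous_rates"])})
        ucfg = UNetConfig(depth=cfgd["unet"]["depth"],
                          base_channels=cfgd["unet"]["base_channels"], cda=cda)
        model = cls(ucfg, _rng(0, "load"), use_mask_stream=cfgd["use_mask_stream"],
                    use_pp=cfgd["use_pp"], pressure_scale=cfgd["pressure_scale"])
        model.load_state_dict(state)
        model.mask_zeroed = cfgd.get("mask_zeroed", False)
        model.trained_D = cfgd["trained_D"]
        return model


def train_stage1(
    scenes: Sequence[SyntheticScene],
    sched: NoiseSchedule,
    params: MaskParams,
    ucfg: UNetConfig,
    tcfg: Stage1TrainConfig,
    use_mask_stream: bool = True,
    use_pp: bool = True,
    pressure_scale: float = 15.0,
    zero_mask: bool = False,
) -> tuple[DDSEModel, list[float]]:
    """Train the DDSE denoiser on (clean, noisy) scene pairs.

    ``zero_mask`` keeps the full dual-stream architecture but feeds an
    all-zero mask, ablating the refined-mask *information* while holding
    capacity and optimisation dynamics fixed.

    For each sample a diffusion step t is drawn; the input is the noisy
    frame (and its refined mask) sampled at step t from the closed-form
    forward marginal, and the regression target is the marginal mean of the
    *clean* frame at step t-1.  Per-sample draws are keyed on the sample
    index only, so the epoch-mean loss is a deterministic function of the
    weights.  Returns the model and the per-epoch mean loss history.
    """
    model = DDSEModel(ucfg, _rng(tcfg.seed, "init"), use_mask_stream=use_mask_stream,
                      use_pp=use_pp, pressure_scale=pressure_scale)
    model.trained_D = sched.D
    model.mask_zeroed = zero_mask
    opt = nn.Adam(model.parameters(), lr=tcfg.lr)
    s = pressure_scale

    clean = [sc.clean / s for sc in scenes]
    noisy = [sc.noisy / s for sc in scenes]
    if zero_mask:
        masks = [np.zeros_like(sc.noisy) for sc in scenes]
    else:
        masks = [refine(sc.noisy, params).astype(float) for sc in scenes]
    n = len(scenes)
    tg = _rng(tcfg.seed, "steps")
    # each scene contributes `draws` (t, noise) realisations, fixed across
    # epochs so the epoch-mean loss is a deterministic function of the weights
    samples = [(i, d) for i in range(n) for d in range(tcfg.draws)]
    steps = tg.integers(1, sched.D + 1, size=len(samples))
    scale_at = np.array([marginal_stats(sched, t)[0] for t in range(sched.D + 1)])
    var_at = np.array([marginal_stats(sched, t)[1] for t in range(sched.D + 1)])
    # inverse-variance weighting: early (low-noise) steps decide the final
    # reconstruction, so their regression error is weighted up
    w_at = 1.0 / (var_at + var_at[1])
    w_at /= w_at[1:].mean()

    history: list[float] = []
    for epoch in range(tcfg.epochs):
        if tcfg.epochs > 2 and epoch == tcfg.epochs - max(1, tcfg.epochs // 3):
            opt.lr = tcfg.lr * 0.2  # refinement phase
        order = np.arange(len(samples))
        _rng(tcfg.seed, "shuffle", epoch).shuffle(order)
        total = 0.0
        for b0 in range(0, len(order), tcfg.batch):
            idx = order[b0 : b0 + tcfg.batch]
            ts = steps[idx]
            xp = np.stack([
                marginal_sample(noisy[samples[k][0]], int(steps[k]), sched,
                                spawn_seed(tcfg.seed, "xp", int(k)))
                for k in idx
            ])
            xm = np.stack([
                marginal_sample(masks[samples[k][0]], int(steps[k]), sched,
                                spawn_seed(tcfg.seed, "xm", int(k)))
                for k in idx
            ])
            target = np.stack([scale_at[steps[k] - 1] * clean[samples[k][0]] for k in idx])
            gains = scale_at[ts - 1] / scale_at[ts]
            pred = model(Tensor(xp[:, None]), Tensor(xm[:, None]), ts, gain=gains)
            diff = pred - Tensor(target)
            w = Tensor(w_at[ts][:, None, None])
            loss = (diff * diff * w).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}; "
                    "reduce the learning rate or the schedule depth"
                )
            opt.zero_grad()
            loss.backward()
            if tcfg.grad_clip:
                opt.clip_grad_norm(tcfg.grad_clip)
            opt.step()
            total += float(loss.data) * len(idx)
        history.append(total / len(samples))
    return model, history


def reverse_denoise(
    p_noisy: np.ndarray,
    sched: NoiseSchedule | None,
    params: MaskParams,
    model: DDSEModel,
    rng_seed: int = 0,
    max_pressure: float | None = None,
    stepping: str = "anchored",
) -> np.ndarray:
    """Restore one pressure frame.

    (i) the refined mask is computed from the raw input (t=0); (ii) the
    frame and the mask are forward-diffused to step D with the shared
    schedule but independent noise; (iii) the U-Net walks back t = D..1
    conditioning on the stored soft-mask trajectory.  Output clipped to
    [0, ceiling].  A missing/empty schedule returns the clipped input.

    ``stepping`` selects how the network's per-step estimate becomes the
    next state: "anchored" (default) re-anchors each step to the carried
    diffusion state, so the implied noise direction is preserved and
    per-step regression biases do not compound; "direct" feeds the raw
    estimate back in.
    """
    if stepping not in ("anchored", "direct"):
        raise ValueError("stepping must be 'anchored' or 'direct'")
    p_noisy = np.asarray(p_noisy, dtype=float)
    if not np.all(np.isfinite(p_noisy)):
        raise ValueError("input frame must be finite")
    ceil = model.pressure_scale if max_pressure is None else max_pressure
    if sched is None or sched.D == 0:
        return np.clip(p_noisy, 0.0, ceil)
    if model.trained_D is not None and model.trained_D != sched.D:
        raise ValueError(
            f"model was trained for D={model.trained_D} but schedule has D={sched.D}"
        )
    s = model.pressure_scale
    if model.mask_zeroed:
        m0 = np.zeros_like(p_noisy)
    else:
        m0 = refine(p_noisy, params).astype(float)
    traj_p = forward_trajectory(p_noisy / s, sched, spawn_seed(rng_seed, "psfd"))
    traj_m = forward_trajectory(m0, sched, spawn_seed(rng_seed, "rmfd"))
    x = traj_p[sched.D]
    scale_at = np.array([marginal_stats(sched, t)[0] for t in range(sched.D + 1)])
    var_at = np.array([marginal_stats(sched, t)[1] for t in range(sched.D + 1)])
    model.eval()
    for t in range(sched.D, 0, -1):
        g = scale_at[t - 1] / scale_at[t]
        est = model(Tensor(x[None]), Tensor(traj_m[t][None]), t, gain=g).data[0]
        if stepping == "direct" or t == 1:
            x = est
        else:
            x0_hat = est / scale_at[t - 1]
            eps_hat = (x - scale_at[t] * x0_hat) / np.sqrt(var_at[t])
            x = scale_at[t - 1] * x0_hat + np.sqrt(var_at[t - 1]) * eps_hat
    model.train()
    return np.clip(x * s, 0.0, ceil)


def restoration_mse(
    model: DDSEModel,
    scenes: Sequence[SyntheticScene],
    sched: NoiseSchedule,
    params: MaskParams,
    rng_seed: int = 0,
) -> float:
    """Mean squared error between restored and clean frames over scenes."""
    errs = [
        np.mean((reverse_denoise(sc.noisy, sched, params, model,
                                 rng_seed=spawn_seed(rng_seed, "val", i)) - sc.clean) ** 2)
        for i, sc in enumerate(scenes)
    ]
    return float(np.mean(errs))
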