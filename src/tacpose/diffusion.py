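"""Forward diffusion for the pressure signal (PSFD) and the refined mask
(RMFD), plus the linear-decay noise schedule shared by both streams.

Two step conventions are supported:

* ``paper_literal`` — x_t = a_t * x_{t-1} + sqrt(1 - a_t) * eps
* ``variance_preserving`` — x_t = sqrt(a_t) * x_{t-1} + sqrt(1 - a_t) * eps
  (the standard DDPM form; default)

Both streams of one scene use the SAME schedule but independent noise
draws, which is what keeps the soft mask synchronised with the pressure
signal step-for-step during the reverse pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import rng as _rng

MODES = ("paper_literal", "variance_preserving")


@dataclass
class NoiseSchedule:
    D: int
    alphas: np.ndarray
    mode: str = "variance_preserving"

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.alphas.shape != (self.D,):
            raise ValueError("alphas must have length D")
        if np.any(self.alphas <= 0) or np.any(self.alphas > 1):
            raise ValueError("alphas must lie in (0, 1]")
        if np.any(np.diff(self.alphas) > 1e-12):
            raise ValueError("alphas must be non-increasing")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def alpha(self, t: int) -> float:
        """alpha_t for t in 1..D."""
        if not 1 <= t <= self.D:
            raise ValueError(f"step t={t} outside 1..{self.D}")
        return float(self.alphas[t - 1])


def make_schedule(
    D: int,
    alpha_start: float = 0.999,
    alpha_end: float = 0.95,
    mode: str = "variance_preserving",
) -> NoiseSchedule:
    """Linear decay from alpha_start (t=1) to alpha_end (t=D)."""
    if D < 1:
        raise ValueError("D must be >= 1")
    if not (0 < alpha_end <= alpha_start <= 1):
        raise ValueError("require 0 < alpha_end <= alpha_start <= 1")
    alphas = np.linspace(alpha_start, alpha_end, D)
    return NoiseSchedule(D=D, alphas=alphas, mode=mode)


def _coeffs(sched: NoiseSchedule, t: int) -> tuple[float, float]:
    a = sched.alpha(t)
    if sched.mode == "paper_literal":
        return a, np.sqrt(1.0 - a)
    return np.sqrt(a), np.sqrt(1.0 - a)


def forward_step(
    x_prev: np.ndarray, t: int, sched: NoiseSchedule, rng_seed: int
) -> np.ndarray:
    """One forward-diffusion step applied to a grid; eps ~ N(0, I) per pixel,
    deterministic given ``rng_seed``."""
    x_prev = np.asarray(x_prev, dtype=float)
    ca, ce = _coeffs(sched, t)
    eps = _rng(rng_seed, "eps", t).standard_normal(x_prev.shape)
    return ca * x_prev + ce * eps


def forward_trajectory(
    x0: np.ndarray, sched: NoiseSchedule, rng_seed: int
) -> list[np.ndarray]:
    """The full noising trajectory [x0, x1, ..., xD] with independent eps per
    step (all derived from ``rng_seed``)."""
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")
    traj = [x0.copy()]
    x = x0
    for t in range(1, sched.D + 1):
        x = forward_step(x, t, sched, rng_seed)
        traj.append(x)
    return traj


def marginal_stats(sched: NoiseSchedule, t: int) -> tuple[float, float]:
    """Closed-form marginal of x_t given x0: returns (scale, variance) such
    that x_t ~ N(scale * x0, variance) per pixel.

    Obtained by unrolling the step recursion: the mean scale is the product
    of the per-step signal coefficients and the variance accumulates each
    step's noise variance attenuated by all later signal coefficients
    squared.
    """
    if t == 0:
        return 1.0, 0.0
    scale = 1.0
    var = 0.0
    for s in range(1, t + 1):
        ca, ce = _coeffs(sched, s)
        scale *= ca
        var = ca * ca * var + ce * ce
    return scale, var


def marginal_sample(
    x0: np.ndarray, t: int, sched: NoiseSchedule, rng_seed: int
) -> np.ndarray:
    """Draw x_t directly from its closed-form marginal (one Gaussian draw);
    equal in distribution to running the trajectory to step t."""
    x0 = np.asarray(x0, dtype=float)
    if t == 0:
        return x0.copy()
    scale, var = marginal_stats(sched, t)
    eps = _rng(rng_seed, "marg", t).standard_normal(x0.shape)
    return scale * x0 + np.sqrt(var) * eps
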