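"""Group Relative Policy Optimization: objective, KL estimator, advantages.

Pure sequence-level numerics, usable as a drop-in reward/advantage component
for an external RL trainer.  For a group of G sampled outputs with raw
rewards r_i, advantages are the group-standardized rewards

    A_i = (r_i - mean(r)) / std_pop(r),

the per-output surrogate is min(rho_i * A_i, clip(rho_i, 1-eps, 1+eps) * A_i)
with rho_i the current/old policy probability ratio, and the objective is the
group mean of the surrogate minus beta times the mean of the low-variance KL
estimator k3(r) = r - log r - 1 evaluated at reference/current ratios.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

ArrayLike = Union[Sequence[float], np.ndarray]


class GroupSample(BaseModel):
    """Rewards and probability ratios for one group of G sampled outputs."""

    model_config = ConfigDict(frozen=True)

    rewards: tuple[float, ...]
    ratios: tuple[float, ...]
    ref_ratios: tuple[float, ...]

    @model_validator(mode="after")
    def _consistent(self) -> "GroupSample":
        g = len(self.rewards)
        if g < 2:
            raise ValueError("group size G must be at least 2")
        if len(self.ratios) != g or len(self.ref_ratios) != g:
            raise ValueError("rewards, ratios and ref_ratios must share length G")
        if any(r <= 0 for r in self.ratios) or any(r <= 0 for r in self.ref_ratios):
            raise ValueError("ratios and ref_ratios must be strictly positive")
        return self


class GRPOConfig(BaseModel):
    """Clip half-width and KL coefficient are mandatory; no silent defaults."""

    model_config = ConfigDict(frozen=True)

    clip_epsilon: float
    kl_beta: float
    std_floor: float = 1e-8

    @model_validator(mode="after")
    def _positive(self) -> "GRPOConfig":
        if self.clip_epsilon <= 0:
            raise ValueError("clip_epsilon must be positive")
        if self.kl_beta < 0 or self.std_floor < 0:
            raise ValueError("kl_beta and std_floor must be non-negative")
        return self


def group_advantages(rewards: ArrayLike, std_floor: float = 1e-8) -> np.ndarray:
    """Group-standardized advantages A_i = (r_i - mean) / population std.

    Degenerate groups (std <= std_floor) yield all-zero advantages: a
    uniform-reward group carries no preference signal rather than an error.
    """
    r = np.asarray(rewards, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("rewards must be a 1-D group of length >= 2")
    std = float(r.std(ddof=0))
    if std <= std_floor:
        return np.zeros_like(r)
    return (r - r.mean()) / std


def kl_estimate(ref_ratio: Union[float, ArrayLike]) -> Union[float, np.ndarray]:
    """k3 KL estimator: r - log r - 1 for r = pi_ref / pi_theta.

    Non-negative everywhere, zero iff r = 1 (identical policies).
    """
    r = np.asarray(ref_ratio, dtype=float)
    if np.any(r <= 0):
        raise ValueError("reference ratio must be strictly positive")
    out = r - np.log(r) - 1.0
    return float(out) if out.ndim == 0 else out


def grpo_objective(sample: GroupSample, cfg: GRPOConfig) -> float:
    """Clipped-surrogate group objective minus the KL penalty.

    With all ratios inside [1-eps, 1+eps] this reduces exactly to
    mean(ratio * A) - kl_beta * mean(k3(ref_ratio)).
    """
    adv = group_advantages(sample.rewards, cfg.std_floor)
    rho = np.asarray(sample.ratios, dtype=float)
    clipped = np.clip(rho, 1.0 - cfg.clip_epsilon, 1.0 + cfg.clip_epsilon)
    surrogate = np.minimum(rho * adv, clipped * adv)
    kl = np.mean(kl_estimate(np.asarray(sample.ref_ratios, dtype=float)))
    return float(surrogate.mean() - cfg.kl_beta * kl)
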