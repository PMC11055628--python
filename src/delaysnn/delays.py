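"""Per-synapse propagation delays and their learning rule.

Each synapse (i, j) carries, besides a weight, a continuous delay value
``d_ij`` in timestep units.  The forward pass shifts the presynaptic train
by the nearest integer, ``p_ij[t] = s_j[t - round(d_ij)]``, so a spike
emitted at time t arrives at the postsynaptic neuron at ``t + round(d)``.
The continuous value is the trainable shadow variable; it is clipped to
``[0, d_max]`` after every optimizer step.

Delays are trained with a temporal-context pseudo-gradient: the
derivative of the delayed train with respect to the delay is replaced by
the window difference

    g[t] = sum_{k=1..c}  p[t-k] - p[t+k]

(past minus future, out-of-range terms zero).  Shifting a spike later
raises p after the spike and lowers it before, so ``g`` has the sign of
dp/dd and the applied update is ``d <- d - lr_d * sum_t dL/dp[t] * g[t]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "D_MAX_DEFAULT",
    "CONTEXT_DEFAULT",
    "DelayMatrix",
    "DelayContext",
    "init_delays",
    "clip_delays",
    "round_delays",
    "shift_time",
    "apply_delays",
    "delay_pseudo_gradient",
]

#: Default delay cap, in timesteps.
D_MAX_DEFAULT = 25

#: Default temporal-context half-width (timesteps); 3 found optimal.
CONTEXT_DEFAULT = 3

DELAY_MODES = ("learnable_zero", "fixed_random")


@dataclass
class DelayMatrix:
    """Continuous per-synapse delays with a hard cap.

    ``d`` has shape ``(n_post, n_pre)``; ``trainable`` is False for the
    fixed-random ablation (fd- models) where delays stay frozen.
    """

    d: np.ndarray
    d_max: float = D_MAX_DEFAULT
    trainable: bool = True

    @property
    def effective_shift(self) -> np.ndarray:
        """Integer shifts used by the forward pass, in {0, ..., d_max}."""
        return round_delays(self.d)

    def copy(self) -> "DelayMatrix":
        return DelayMatrix(self.d.copy(), self.d_max, self.trainable)


@dataclass(frozen=True)
class DelayContext:
    """Temporal-context half-width for the delay pseudo-gradient."""

    c: int = CONTEXT_DEFAULT

    def __post_init__(self):
        if self.c < 1:
            raise ValueError("temporal context half-width c must be >= 1")


def round_delays(d: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties toward zero (d is non-negative)."""
    return np.ceil(np.asarray(d) - 0.5).astype(np.int64)


def init_delays(
    shape: tuple[int, int],
    mode: str = "learnable_zero",
    d_max: float = D_MAX_DEFAULT,
    rng_seed: int | np.random.Generator = 0,
) -> DelayMatrix:
    """Create a delay matrix.

    ``learnable_zero`` starts every delay at zero (the network is born
    delay-free and grows delays during training); ``fixed_random`` draws
    frozen delays uniformly over ``[0, d_max]``.
    """
    if mode == "learnable_zero":
        return DelayMatrix(np.zeros(shape), d_max=d_max, trainable=True)
    if mode == "fixed_random":
        rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
        return DelayMatrix(rng.uniform(0.0, d_max, size=shape), d_max=d_max, trainable=False)
    raise ValueError(f"unknown delay mode {mode!r}; expected one of {DELAY_MODES}")


def clip_delays(delays: DelayMatrix) -> DelayMatrix:
    """Project delays onto [0, d_max] (in place; idempotent)."""
    np.clip(delays.d, 0.0, delays.d_max, out=delays.d)
    return delays


def shift_time(x: np.ndarray, shift: int) -> np.ndarray:
    """Shift an array along its time axis (axis -2), zero-filling.

    Positive ``shift`` delays content (moves it later); negative advances
    it.  Content shifted past either end of the horizon is dropped.
    """
    if shift == 0:
        return x
    out = np.zeros_like(x)
    if shift > 0:
        out[..., shift:, :] = x[..., :-shift or None, :]
    else:
        out[..., :shift, :] = x[..., -shift:, :]
    return out


def apply_delays(s_pre: np.ndarray, delays: DelayMatrix) -> np.ndarray:
    """Delay each presynaptic train per synapse.

    Parameters
    ----------
    s_pre
        Presynaptic spikes or currents, shape ``(..., T, n_pre)``.
    delays
        Delay matrix of shape ``(n_post, n_pre)``.

    Returns
    -------
    ``p`` of shape ``(..., n_post, T, n_pre)``: for each postsynaptic
    neuron i, ``p[..., i, t, j] = s_pre[..., t - round(d_ij), j]`` with
    zeros before the delayed onset.
    """
    if np.any(delays.d < 0) or np.any(delays.d > delays.d_max):
        raise ValueError("delays outside [0, d_max]; run clip_delays after updates")
    shifts = delays.effective_shift
    n_post, n_pre = shifts.shape
    p = np.zeros(s_pre.shape[:-2] + (n_post,) + s_pre.shape[-2:], dtype=s_pre.dtype)
    for k in np.unique(shifts):
        mask = shifts == k  # (n_post, n_pre)
        shifted = shift_time(s_pre, int(k))[..., None, :, :]
        p += np.where(mask[:, None, :], shifted, 0)
    return p


def delay_pseudo_gradient(p: np.ndarray, ctx: DelayContext = DelayContext()) -> np.ndarray:
    """Temporal-context factor replacing dp/dd, per synapse and timestep.

    ``g[..., t] = sum_{k=1..c} p[..., t-k] - p[..., t+k]`` along the time
    axis (axis -2), with out-of-range terms treated as zero.
    """
    g = np.zeros_like(np.asarray(p, dtype=float))
    for k in range(1, ctx.c + 1):
        g += shift_time(p, k) - shift_time(p, -k)
    return g
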