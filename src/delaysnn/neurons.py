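"""Discrete-time adaptive leaky integrate-and-fire neurons.

The neuron model keeps two internal states per neuron: the membrane
potential ``u`` and an adaptation current ``w``.  With a 1 ms timestep the
update reads

    u[t] = alpha * u[t-1] + (1 - alpha) * (I[t] - w[t-1]) - theta * s[t-1]
    w[t] = beta * w[t-1] + (1 - beta) * a * u[t-1] + b * s[t-1]
    s[t] = 1  if u[t] >= theta  else 0

``alpha`` and ``beta`` are the decay factors of ``u`` and ``w``; ``a``
couples the sub-threshold potential into the adaptation current and ``b``
is the spike-triggered adaptation increment.  A spike triggers a *soft*
reset (theta is subtracted, the potential is never clamped).

Three variants are supported:

``LIF``
    no adaptation: ``a = b = 0`` fixed, only ``alpha`` is trainable.
``AdLIF``
    all four parameters trainable, ``a`` may be negative (this admits a
    self-exciting, chaotic firing regime -- see :mod:`delaysnn.analysis`).
``cAdLIF``
    the constrained variant: ``a`` and ``b`` restricted to be
    non-negative, which excludes the chaotic regime for sparse input.

All parameters are drawn uniformly inside their bounds at initialization
and are clipped back inside the bounds after every optimizer step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "THETA",
    "PARAM_BOUNDS",
    "NeuronParams",
    "NeuronState",
    "SurrogateConfig",
    "init_neuron_params",
    "clip_params",
    "step",
    "simulate",
    "surrogate_derivative",
]

#: Firing threshold (dimensionless, non-trainable).
THETA = 1.0

#: Closed parameter bounds per variant, ``{name: (low, high)}``.
#: ``a`` for the unconstrained AdLIF uses a symmetric [-1, 1] interval so the
#: negative-coupling (chaotic) region is reachable; cAdLIF restricts both
#: adaptation parameters to the stable non-negative quadrant.
PARAM_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "LIF": {"alpha": (0.36, 0.96), "beta": (0.96, 0.99), "a": (0.0, 0.0), "b": (0.0, 0.0)},
    "AdLIF": {"alpha": (0.36, 0.96), "beta": (0.96, 0.99), "a": (-1.0, 1.0), "b": (0.0, 2.0)},
    "cAdLIF": {"alpha": (0.36, 0.96), "beta": (0.96, 0.99), "a": (0.0, 1.0), "b": (0.0, 2.0)},
}

VARIANTS = tuple(PARAM_BOUNDS)


@dataclass
class NeuronParams:
    """Per-neuron trainable constants with their clipping bounds."""

    alpha: np.ndarray
    beta: np.ndarray
    a: np.ndarray
    b: np.ndarray
    variant: str = "cAdLIF"
    theta: float = THETA

    @property
    def n_neurons(self) -> int:
        return self.alpha.shape[0]

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return PARAM_BOUNDS[self.variant]

    def trainable_names(self) -> tuple[str, ...]:
        """Names of the trainable parameter arrays for this variant."""
        if self.variant == "LIF":
            return ("alpha",)
        return ("alpha", "beta", "a", "b")

    def n_trainable(self) -> int:
        return len(self.trainable_names()) * self.n_neurons

    def copy(self) -> "NeuronParams":
        return replace(
            self,
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
            a=self.a.copy(),
            b=self.b.copy(),
        )


@dataclass
class NeuronState:
    """Membrane potential, adaptation current and spike indicator at one step."""

    u: np.ndarray
    w: np.ndarray
    s: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "NeuronState":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape))


@dataclass(frozen=True)
class SurrogateConfig:
    """Boxcar surrogate for the Heaviside derivative in the backward pass."""

    half_width: float = 0.5
    height: float = 0.5

    def __post_init__(self):
        if self.half_width <= 0 or self.height <= 0:
            raise ValueError("surrogate half_width and height must be positive")


def init_neuron_params(
    n_neurons: int,
    variant: str = "cAdLIF",
    rng_seed: int | np.random.Generator = 0,
) -> NeuronParams:
    """Draw per-neuron parameters uniformly inside their variant bounds.

    For ``LIF`` the adaptation parameters are pinned to zero (the zero-width
    bound) and excluded from training.
    """
    if variant not in PARAM_BOUNDS:
        raise ValueError(f"unknown neuron variant {variant!r}; expected one of {VARIANTS}")
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    bounds = PARAM_BOUNDS[variant]
    draws = {
        name: rng.uniform(lo, hi, size=n_neurons) if hi > lo else np.full(n_neurons, lo)
        for name, (lo, hi) in bounds.items()
    }
    return NeuronParams(variant=variant, **draws)


def clip_params(params: NeuronParams) -> NeuronParams:
    """Project every parameter onto its closed bounds (in place; idempotent)."""
    for name, (lo, hi) in params.bounds.items():
        np.clip(getattr(params, name), lo, hi, out=getattr(params, name))
    return params


def step(state_prev: NeuronState, I_t: np.ndarray, params: NeuronParams) -> NeuronState:
    """Advance the neuron dynamics by one timestep.

    ``u[t]`` is computed from the *previous* adaptation current and spike;
    ``w[t]`` from the *previous* potential -- the evaluation order matters
    and is exactly the discrete-time update above.
    """
    I_t = np.asarray(I_t)
    if I_t.shape[-1] != params.n_neurons:
        raise ValueError(
            f"input current has {I_t.shape[-1]} channels but params describe "
            f"{params.n_neurons} neurons"
        )
    u = (
        params.alpha * state_prev.u
        + (1.0 - params.alpha) * (I_t - state_prev.w)
        - params.theta * state_prev.s
    )
    w = (
        params.beta * state_prev.w
        + (1.0 - params.beta) * params.a * state_prev.u
        + params.b * state_prev.s
    )
    s = (u >= params.theta).astype(u.dtype)
    return NeuronState(u=u, w=w, s=s)


def simulate(I: np.ndarray, params: NeuronParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the recurrence over a full input current array.

    Parameters
    ----------
    I
        Input currents, shape ``(..., T, n_neurons)``.
    params
        Neuron parameters (broadcast over leading axes).

    Returns
    -------
    (u, w, s) trajectories, each of shape ``(..., T, n_neurons)``.
    """
    I = np.asarray(I, dtype=float)
    T = I.shape[-2]
    u = np.empty_like(I)
    w = np.empty_like(I)
    s = np.empty_like(I)
    state = NeuronState.zeros(I.shape[:-2] + I.shape[-1:])
    for t in range(T):
        state = step(state, I[..., t, :], params)
        u[..., t, :] = state.u
        w[..., t, :] = state.w
        s[..., t, :] = state.s
    return u, w, s


def surrogate_derivative(u_t: np.ndarray, cfg: SurrogateConfig = SurrogateConfig()) -> np.ndarray:
    """Boxcar stand-in for d(spike)/d(potential), used only in backward passes.

    Returns ``height`` where ``|u - theta| <= half_width`` (boundary
    inclusive) and 0 elsewhere.
    """
    u_t = np.asarray(u_t)
    return np.where(np.abs(u_t - THETA) <= cfg.half_width, cfg.height, 0.0)
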