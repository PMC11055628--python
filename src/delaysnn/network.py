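"""Two-hidden-layer feed-forward spiking network, trained with BPTT.

The architecture is fixed: input -> hidden spiking layer -> hidden spiking
layer -> memoryless readout.  Hidden layers run the adaptive LIF dynamics
of :mod:`delaysnn.neurons`; the readout neurons have infinite threshold,
so their per-timestep potential is just the (possibly delayed) weighted
input.  Class scores are per-timestep softmaxes of the readout potentials
summed over time, and the loss is the cross-entropy of the normalized
summed scores.

Every synapse may additionally carry a trainable propagation delay
(:mod:`delaysnn.delays`).  Training is reverse-mode backpropagation
through time, written out in closed form for this architecture: the spike
nonlinearity's derivative is replaced by a boxcar surrogate in the
backward pass, and the delay derivative by the temporal-context
pseudo-gradient.  Optimization is Adam with a reduce-on-plateau scheduler
(factor 0.7, patience 5 epochs, monitoring validation accuracy); neuron
parameters and delays are clipped to their bounds after every step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .delays import (
    D_MAX_DEFAULT,
    DelayContext,
    DelayMatrix,
    clip_delays,
    init_delays,
    round_delays,
    shift_time,
)
from .neurons import (
    THETA,
    NeuronParams,
    SurrogateConfig,
    clip_params,
    init_neuron_params,
    surrogate_derivative,
)

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "LayerWeights",
    "SNNModel",
    "HeavisideBoxcar",
    "SigmoidSpike",
    "aggregate_readout",
    "loss",
    "loss_and_delta",
    "train",
    "evaluate",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

DELAY_MODES = ("none", "learnable", "fixed_random")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description: sizes, neuron variant and delay mode."""

    n_in: int
    hidden_sizes: tuple[int, int]
    n_out: int
    variant: str = "cAdLIF"
    delay_mode: str = "none"
    d_max: float = D_MAX_DEFAULT
    dropout_rate: float = 0.0
    context_c: int = 3
    input_gain: float = 1.0

    def __post_init__(self):
        if len(self.hidden_sizes) != 2:
            raise ValueError("the architecture has exactly two hidden layers")
        if min(self.n_in, self.n_out, *self.hidden_sizes) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.delay_mode not in DELAY_MODES:
            raise ValueError(f"delay_mode must be one of {DELAY_MODES}")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.n_in, *self.hidden_sizes, self.n_out]


@dataclass
class TrainingConfig:
    """Optimizer and schedule hyperparameters.

    The delay learning rate defaults to 10x the weight learning rate.
    ``scheduler_factor``/``scheduler_patience`` implement a
    reduce-on-plateau schedule on the validation accuracy, applied to
    both learning rates.
    """

    lr_weights: float = 1e-3
    lr_delays: float | None = None
    epochs: int = 20
    batch_size: int = 32
    scheduler_factor: float = 0.7
    scheduler_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.lr_delays is None:
            self.lr_delays = 10.0 * self.lr_weights
        if min(self.lr_weights, self.lr_delays, self.epochs, self.batch_size) <= 0:
            raise ValueError("learning rates, epochs and batch size must be positive")


# ---------------------------------------------------------------------------
# spike nonlinearities (forward function + backward derivative)


class HeavisideBoxcar:
    """Hard threshold forward; boxcar surrogate derivative backward."""

    def __init__(self, cfg: SurrogateConfig = SurrogateConfig()):
        self.cfg = cfg

    def forward(self, u: np.ndarray) -> np.ndarray:
        return (u >= THETA).astype(u.dtype)

    def backward(self, u: np.ndarray) -> np.ndarray:
        return surrogate_derivative(u, self.cfg)


class SigmoidSpike:
    """Smooth sigmoidal spike function with its exact derivative.

    Used for gradient verification: with a smooth forward nonlinearity the
    analytic BPTT gradients must match finite differences exactly, which
    validates the shared reverse-mode recurrences.
    """

    def __init__(self, slope: float = 4.0):
        self.slope = slope

    def forward(self, u: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.slope * (u - THETA)))

    def backward(self, u: np.ndarray) -> np.ndarray:
        s = self.forward(u)
        return self.slope * s * (1.0 - s)


# ---------------------------------------------------------------------------
# model


@dataclass
class LayerWeights:
    """One fully connected projection: weights, bias and optional delays."""

    F: np.ndarray
    bias: np.ndarray
    delays: DelayMatrix | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.F.shape


def _xavier_uniform(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    fan_out, fan_in = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class SNNModel:
    """The feed-forward SNN: two spiking hidden layers plus readout.

    Weight matrices follow the ``(post, pre)`` convention.  Biases start
    at zero, weights are Xavier-uniform, neuron parameters uniform within
    bounds, and learnable delays start at zero (the network is born
    delay-free and grows delays during training).
    """

    def __init__(self, config: NetworkConfig, seed: int = 0, spike_fn=None):
        self.config = config
        self.spike_fn = spike_fn if spike_fn is not None else HeavisideBoxcar()
        rng = np.random.default_rng(seed)
        sizes = config.layer_sizes
        self.layers: list[LayerWeights] = []
        self.neuron_params: list[NeuronParams] = []
        for li in range(3):
            shape = (sizes[li + 1], sizes[li])
            delays = None
            if config.delay_mode == "learnable":
                delays = init_delays(shape, "learnable_zero", config.d_max, rng)
            elif config.delay_mode == "fixed_random":
                delays = init_delays(shape, "fixed_random", config.d_max, rng)
            F = _xavier_uniform(shape, rng)
            if li < 2:
                # sparse few-channel spiking activity needs extra drive to
                # reach the surrogate window; 1.0 leaves Xavier untouched
                F *= config.input_gain
            self.layers.append(
                LayerWeights(F=F, bias=np.zeros(shape[0]), delays=delays)
            )
            if li < 2:  # hidden layers only; the readout is memoryless
                self.neuron_params.append(init_neuron_params(shape[0], config.variant, rng))

    # -- parameter bookkeeping ------------------------------------------------

    def weight_arrays(self) -> list[np.ndarray]:
        """All arrays updated at the weight learning rate."""
        out: list[np.ndarray] = []
        for li, layer in enumerate(self.layers):
            out += [layer.F, layer.bias]
            if li < 2:
                p = self.neuron_params[li]
                out += [getattr(p, name) for name in p.trainable_names()]
        return out

    def delay_arrays(self) -> list[np.ndarray]:
        """Delay arrays updated at the delay learning rate (if trainable)."""
        return [
            layer.delays.d
            for layer in self.layers
            if layer.delays is not None and layer.delays.trainable
        ]

    def clip(self) -> None:
        """Project neuron parameters and delays back onto their bounds."""
        for p in self.neuron_params:
            clip_params(p)
        for layer in self.layers:
            if layer.delays is not None:
                clip_delays(layer.delays)

    # -- forward --------------------------------------------------------------

    def _project(self, s_pre: np.ndarray, layer: LayerWeights) -> np.ndarray:
        """I[b,t,i] = sum_j F[i,j] * s_pre[b, t - round(d_ij), j] + bias[i].

        Delayed projections are grouped by the (few) unique integer shifts
        so no per-synapse time tensor is materialized.
        """
        if layer.delays is None:
            return s_pre @ layer.F.T + layer.bias
        shifts = layer.delays.effective_shift
        I = np.zeros(s_pre.shape[:-1] + (layer.F.shape[0],))
        for k in np.unique(shifts):
            Fk = np.where(shifts == k, layer.F, 0.0)
            I += shift_time(s_pre, int(k)) @ Fk.T
        return I + layer.bias

    def forward(self, x: np.ndarray, training: bool = False, dropout_rng=None):
        """Run the network over a batch.

        Parameters
        ----------
        x
            Input array ``(B, T, n_in)``; binary spikes or real-valued
            feature frames treated as input currents.  Must already be
            right-padded when delays are enabled.
        training
            If True, apply dropout to hidden spike trains (inverted
            scaling) and keep the caches needed for :meth:`backward`.

        Returns
        -------
        ``(u_out, cache)`` -- readout potentials ``(B, T, n_out)`` and a
        cache dict holding hidden spike records (``cache["spikes"]``).
        """
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[-1] != self.config.n_in:
            raise ValueError(
                f"input must be (batch, T, {self.config.n_in}); got {x.shape}"
            )
        cache: dict = {"inputs": [], "I": [], "u": [], "w": [], "s": [], "masks": [], "spikes": []}
        s_pre = x
        rate = self.config.dropout_rate
        for li in range(2):
            layer = self.layers[li]
            params = self.neuron_params[li]
            I = self._project(s_pre, layer)
            u, w, s = _simulate_layer(I, params, self.spike_fn)
            cache["spikes"].append(s)
            if training and rate > 0.0:
                if dropout_rng is None:
                    raise ValueError("training forward with dropout requires dropout_rng")
                mask = (dropout_rng.random(s.shape) >= rate) / (1.0 - rate)
            else:
                mask = None
            s_out = s if mask is None else s * mask
            cache["inputs"].append(s_pre)
            cache["I"].append(I)
            cache["u"].append(u)
            cache["w"].append(w)
            cache["s"].append(s)
            cache["masks"].append(mask)
            s_pre = s_out
        cache["inputs"].append(s_pre)
        u_out = self._project(s_pre, self.layers[2])
        return u_out, cache

    # -- backward -------------------------------------------------------------

    def backward(self, delta_uout: np.ndarray, cache: dict) -> dict:
        """Reverse-mode BPTT from d(loss)/d(u_out) to every parameter.

        Returns a dict with per-layer gradients: ``F``, ``bias``,
        neuron-parameter gradients, and ``d`` for trainable delays.
        """
        grads: dict = {"layers": [None, None, None]}
        ctx = DelayContext(self.config.context_c)
        # readout projection
        gF, gb, gd, delta_s = _project_backward(
            delta_uout, cache["inputs"][2], self.layers[2], ctx
        )
        grads["layers"][2] = {"F": gF, "bias": gb, "d": gd}
        for li in (1, 0):
            layer = self.layers[li]
            params = self.neuron_params[li]
            mask = cache["masks"][li]
            if mask is not None:
                delta_s = delta_s * mask
            delta_I, gparams = _neuron_backward(
                delta_s, cache["I"][li], cache["u"][li], cache["w"][li], cache["s"][li],
                params, self.spike_fn,
            )
            gF, gb, gd, delta_s = _project_backward(
                delta_I, cache["inputs"][li], layer, ctx
            )
            grads["layers"][li] = {"F": gF, "bias": gb, "d": gd, **gparams}
        return grads


def _simulate_layer(I: np.ndarray, params: NeuronParams, spike_fn):
    """Forward recurrence of one hidden layer over (B, T, n)."""
    B, T, n = I.shape
    u = np.empty_like(I)
    w = np.empty_like(I)
    s = np.empty_like(I)
    u_prev = np.zeros((B, n))
    w_prev = np.zeros((B, n))
    s_prev = np.zeros((B, n))
    alpha, beta, a, b = params.alpha, params.beta, params.a, params.b
    for t in range(T):
        u_t = alpha * u_prev + (1.0 - alpha) * (I[:, t] - w_prev) - params.theta * s_prev
        w_t = beta * w_prev + (1.0 - beta) * a * u_prev + b * s_prev
        s_t = spike_fn.forward(u_t)
        u[:, t], w[:, t], s[:, t] = u_t, w_t, s_t
        u_prev, w_prev, s_prev = u_t, w_t, s_t
    return u, w, s


def _neuron_backward(delta_s_ext, I, u, w, s, params: NeuronParams, spike_fn):
    """Adjoint recurrence of the hidden-layer dynamics, reverse in time.

    ``delta_s_ext`` is the loss gradient arriving at the emitted spikes.
    Returns d(loss)/d(I) and the neuron-parameter gradients.
    """
    B, T, n = u.shape
    alpha, beta, a, b = params.alpha, params.beta, params.a, params.b
    lam_u_next = np.zeros((B, n))
    lam_w_next = np.zeros((B, n))
    delta_I = np.empty_like(u)
    g_alpha = np.zeros(n)
    g_beta = np.zeros(n)
    g_a = np.zeros(n)
    g_b = np.zeros(n)
    sg = spike_fn.backward(u)
    for t in range(T - 1, -1, -1):
        lam_s = delta_s_ext[:, t] - params.theta * lam_u_next + b * lam_w_next
        lam_u = lam_s * sg[:, t] + alpha * lam_u_next + (1.0 - beta) * a * lam_w_next
        lam_w = beta * lam_w_next - (1.0 - alpha) * lam_u_next
        delta_I[:, t] = (1.0 - alpha) * lam_u
        u_prev = u[:, t - 1] if t > 0 else np.zeros((B, n))
        w_prev = w[:, t - 1] if t > 0 else np.zeros((B, n))
        s_prev = s[:, t - 1] if t > 0 else np.zeros((B, n))
        g_alpha += np.sum(lam_u * (u_prev - (I[:, t] - w_prev)), axis=0)
        g_beta += np.sum(lam_w * (w_prev - a * u_prev), axis=0)
        g_a += np.sum(lam_w * (1.0 - beta) * u_prev, axis=0)
        g_b += np.sum(lam_w * s_prev, axis=0)
        lam_u_next, lam_w_next = lam_u, lam_w
    gparams = {"alpha": g_alpha}
    if params.variant != "LIF":
        gparams.update({"beta": g_beta, "a": g_a, "b": g_b})
    return delta_I, gparams


def _project_backward(delta_I, s_pre, layer: LayerWeights, ctx: DelayContext):
    """Gradients of the (possibly delayed) projection.

    Returns (gF, gbias, gdelays-or-None, delta_s_pre).  All gradients are
    expressed through lag-correlation matrices
    ``C_m[i,j] = sum_{b,t} delta_I[b,t,i] * s_pre[b,t-m,j]``:
    the weight gradient is ``C`` at each synapse's own shift, and the
    delay pseudo-gradient is ``F * sum_k (C_{v+k} - C_{v-k})``.
    """
    gbias = delta_I.sum(axis=(0, 1))
    if layer.delays is None:
        gF = np.einsum("bti,btj->ij", delta_I, s_pre)
        return gF, gbias, None, delta_I @ layer.F

    shifts = layer.delays.effective_shift
    unique = [int(k) for k in np.unique(shifts)]
    want_delays = layer.delays.trainable
    lags = set(unique)
    if want_delays:
        for v in unique:
            for k in range(1, ctx.c + 1):
                lags.add(v + k)
                lags.add(v - k)
    C = {
        m: np.einsum("bti,btj->ij", delta_I, shift_time(s_pre, m))
        for m in sorted(lags)
    }
    gF = np.zeros_like(layer.F)
    gd = np.zeros_like(layer.F) if want_delays else None
    delta_s = np.zeros_like(s_pre, dtype=float)
    for v in unique:
        mask = shifts == v
        gF[mask] = C[v][mask]
        if want_delays:
            acc = np.zeros_like(layer.F)
            for k in range(1, ctx.c + 1):
                acc += C[v + k] - C[v - k]
            gd[mask] = (layer.F * acc)[mask]
        Fv = np.where(mask, layer.F, 0.0)
        delta_s += shift_time(delta_I, -v) @ Fv
    return gF, gbias, gd, delta_s


# ---------------------------------------------------------------------------
# readout aggregation and loss


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def aggregate_readout(u_out: np.ndarray) -> np.ndarray:
    """Per-timestep softmax over classes, summed over time.

    Scores are positive and sum to T for every sample.
    """
    return _softmax(u_out, axis=-1).sum(axis=-2)


def loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cross-entropy of the normalized aggregated scores.

    ``-log(score_c / sum_j score_j)`` averaged over the batch.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite class scores")
    share = scores / scores.sum(axis=-1, keepdims=True)
    n = scores.shape[0]
    return float(-np.log(share[np.arange(n), labels]).mean())


def loss_and_delta(u_out: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss value plus its exact gradient with respect to ``u_out``.

    The sum of scores over classes is T identically, so only the true-class
    score carries gradient; chaining through the per-timestep softmax gives
    ``delta[b,t,k] = -(sm[b,t,y]*(1[y=k] - sm[b,t,k])) / (N * score_y)``.
    """
    sm = _softmax(u_out, axis=-1)
    scores = sm.sum(axis=-2)
    L = loss(scores, labels)
    B, T, K = u_out.shape
    idx = np.arange(B)
    sy = scores[idx, labels]  # (B,)
    smy = sm[idx, :, labels]  # (B, T)
    delta = sm * smy[:, :, None]  # -d(score_y)/du for k != y, before sign
    delta[idx, :, labels] -= smy
    delta /= (B * sy)[:, None, None]
    return L, delta


# ---------------------------------------------------------------------------
# optimizer, scheduler, training loop


class Adam:
    """Adam over a fixed list of parameter arrays (updated in place)."""

    def __init__(self, arrays: list[np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.arrays = arrays
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            a -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _collect_weight_grads(model: SNNModel, grads: dict) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for li in range(3):
        g = grads["layers"][li]
        out += [g["F"], g["bias"]]
        if li < 2:
            p = model.neuron_params[li]
            out += [g[name] for name in p.trainable_names()]
    return out


def _collect_delay_grads(model: SNNModel, grads: dict) -> list[np.ndarray]:
    out = []
    for li in range(3):
        layer = model.layers[li]
        if layer.delays is not None and layer.delays.trainable:
            out.append(grads["layers"][li]["d"])
    return out


def train(
    model: SNNModel,
    dataset,
    cfg: TrainingConfig,
    val_dataset=None,
    verbose: bool = False,
):
    """Train a model with Adam + BPTT; returns ``(model, history)``.

    ``dataset`` and ``val_dataset`` are ``(inputs, labels)`` tuples with
    inputs of shape ``(n, T, n_in)`` (already padded for delays).  After
    every optimizer step neuron parameters and delays are clipped back to
    their bounds; the plateau scheduler monitors validation accuracy
    (training accuracy when no validation split is given) and scales both
    learning rates by ``scheduler_factor`` after ``scheduler_patience``
    epochs without improvement.  Fully deterministic for a fixed seed.
    """
    X, y = np.asarray(dataset[0], dtype=float), np.asarray(dataset[1])
    rng = np.random.default_rng(cfg.seed)
    opt_w = Adam(model.weight_arrays(), cfg.lr_weights)
    delay_arrays = model.delay_arrays()
    opt_d = Adam(delay_arrays, cfg.lr_delays) if delay_arrays else None
    history = {"epoch": [], "train_loss": [], "train_acc": [], "val_acc": [],
               "spikes_per_neuron": [], "lr_weights": [], "lr_delays": []}
    best_metric = -np.inf
    stale = 0
    n = X.shape[0]
    n_hidden = sum(model.config.hidden_sizes)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_spikes = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            u_out, cache = model.forward(xb, training=True, dropout_rng=rng)
            L, delta = loss_and_delta(u_out, yb)
            if not np.isfinite(L):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={L}")
            grads = model.backward(delta, cache)
            opt_w.step(_collect_weight_grads(model, grads))
            if opt_d is not None:
                opt_d.step(_collect_delay_grads(model, grads))
            model.clip()
            epoch_loss += L * len(idx)
            epoch_spikes += sum(float(s.sum()) for s in cache["spikes"])
            correct += int((aggregate_readout(u_out).argmax(-1) == yb).sum())
        train_acc = correct / n
        spn = epoch_spikes / (n_hidden * n)
        if val_dataset is not None:
            val_acc, _ = evaluate(model, val_dataset)
        else:
            val_acc = train_acc
        metric = val_acc
        if metric > best_metric:
            best_metric = metric
            stale = 0
        else:
            stale += 1
            if stale > cfg.scheduler_patience:
                opt_w.lr *= cfg.scheduler_factor
                if opt_d is not None:
                    opt_d.lr *= cfg.scheduler_factor
                stale = 0
        history["epoch"].append(epoch)
        history["train_loss"].append(epoch_loss / n)
        history["train_acc"].append(train_acc)
        history["val_acc"].append(val_acc)
        history["spikes_per_neuron"].append(spn)
        history["lr_weights"].append(opt_w.lr)
        history["lr_delays"].append(opt_d.lr if opt_d is not None else 0.0)
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {epoch_loss / n:.4f}  "
                f"train_acc {train_acc:.3f}  val_acc {val_acc:.3f}"
            )
    return model, history


def evaluate(model: SNNModel, dataset, batch_size: int = 256) -> tuple[float, float]:
    """Accuracy and spikes-per-neuron-per-sample on a dataset (no dropout)."""
    X, y = np.asarray(dataset[0], dtype=float), np.asarray(dataset[1])
    if X.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    correct = 0
    total_spikes = 0.0
    n_hidden = sum(model.config.hidden_sizes)
    for start in range(0, X.shape[0], batch_size):
        xb, yb = X[start:start + batch_size], y[start:start + batch_size]
        u_out, cache = model.forward(xb, training=False)
        correct += int((aggregate_readout(u_out).argmax(-1) == yb).sum())
        total_spikes += sum(float(s.sum()) for s in cache["spikes"])
    accuracy = correct / X.shape[0]
    spikes_per_neuron = total_spikes / (n_hidden * X.shape[0])
    return accuracy, spikes_per_neuron


def count_parameters(config: NetworkConfig) -> int:
    """Trainable-parameter count for an architecture.

    Counts feed-forward weights, per-neuron biases, trainable neuron
    parameters (1 per hidden neuron for LIF: alpha; 4 for AdLIF/cAdLIF:
    alpha, beta, a, b), and one delay per synapse -- on every layer,
    readout included -- when delays are learnable.  Fixed-random delays
    are not trainable and are not counted.
    """
    sizes = config.layer_sizes
    n_weights = sum(sizes[i] * sizes[i + 1] for i in range(3))
    n_bias = sum(sizes[1:])
    n_hidden = sum(config.hidden_sizes)
    per_neuron = 1 if config.variant == "LIF" else 4
    total = n_weights + n_bias + per_neuron * n_hidden
    if config.delay_mode == "learnable":
        total += n_weights
    return total


# ---------------------------------------------------------------------------
# checkpointing


CHECKPOINT_VERSION = 1


def save_checkpoint(model: SNNModel, path, extra: dict | None = None) -> None:
    """Write config + all parameter arrays to a single ``.npz`` archive."""
    arrays: dict[str, np.ndarray] = {}
    for li, layer in enumerate(model.layers):
        arrays[f"F{li}"] = layer.F
        arrays[f"bias{li}"] = layer.bias
        if layer.delays is not None:
            arrays[f"d{li}"] = layer.delays.d
    for li, p in enumerate(model.neuron_params):
        for name in ("alpha", "beta", "a", "b"):
            arrays[f"np{li}_{name}"] = getattr(p, name)
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.config),
            "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> SNNModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfgdict = meta["config"]
        cfgdict["hidden_sizes"] = tuple(cfgdict["hidden_sizes"])
        model = SNNModel(NetworkConfig(**cfgdict), seed=0)
        for li, layer in enumerate(model.layers):
            layer.F = data[f"F{li}"]
            layer.bias = data[f"bias{li}"]
            if layer.delays is not None:
                layer.delays.d = data[f"d{li}"]
        for li, p in enumerate(model.neuron_params):
            p.alpha = data[f"np{li}_alpha"]
            p.beta = data[f"np{li}_beta"]
            p.a = data[f"np{li}_a"]
            p.b = data[f"np{li}_b"]
    return model
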