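"""Single-neuron adaptation-regime mapping and model introspection.

The adaptation parameters a (sub-threshold coupling) and b (spike-
triggered increment) qualitatively change how a neuron responds to a
fixed input train.  With a >= 0 the adaptation current opposes sustained
depolarization (a homeostatic, spike-limiting mechanism).  With a < 0 the
coupling becomes positive feedback: the adaptation current amplifies the
potential that created it, and the neuron can keep firing after the
input has stopped -- a chaotic regime producing more output spikes than
input spikes.  The regime map sweeps an (a, b) grid with one probe train
and counts output spikes per cell; this is the analysis that motivates
constraining the trained neuron model to the a, b >= 0 quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delays import DelayMatrix
from .neurons import NeuronParams, simulate
from .network import SNNModel

__all__ = [
    "RegimeMap",
    "default_probe",
    "regime_map",
    "parameter_distributions",
    "spike_rate_report",
]


@dataclass
class RegimeMap:
    """Output spike counts over an (a, b) grid for one probe train."""

    a_grid: np.ndarray
    b_grid: np.ndarray
    counts: np.ndarray  # (len(a_grid), len(b_grid)) integer spike counts
    tail_counts: np.ndarray  # spikes emitted after the last input spike
    n_input_spikes: int

    @property
    def chaotic(self) -> np.ndarray:
        """Cells producing more spikes than arrived (positive-feedback regime)."""
        return self.counts > self.n_input_spikes

    def to_table(self):
        """Rows of (a, b, count, tail_count, chaotic) for CSV export."""
        rows = []
        for i, a in enumerate(self.a_grid):
            for j, b in enumerate(self.b_grid):
                rows.append((float(a), float(b), int(self.counts[i, j]),
                             int(self.tail_counts[i, j]), bool(self.chaotic[i, j])))
        return rows


def default_probe(
    n_spikes: int = 12, period: int = 8, t_first: int = 2, input_weight: float = 15.0
) -> tuple[np.ndarray, float]:
    """The default probe: 12 input spikes, one every 8 steps, weight 15.

    The weight is chosen just supra-threshold: with the default membrane
    decay alpha = 0.9, one incoming spike deposits (1 - alpha) * 15 = 1.5,
    enough for exactly one output spike, and the soft-reset residual (0.5)
    decays away well before the next input arrives.  A plain LIF neuron
    therefore answers the probe one-for-one (12 spikes in, 12 out), which
    makes the anchor exact: any cell exceeding the input count does so
    purely through the adaptation feedback, and any cell below it is
    spike-limited by adaptation.  A strictly sub-threshold probe cannot
    separate the regimes here: for a >= -1 and b >= 0 each output spike
    drains the marginal (u = -w) mode by theta while a sub-threshold input
    pumps it by less than theta, so the output count could never exceed
    the input count anywhere on the tested grid.  Returns
    ``(binary train, weight)``.
    """
    T = t_first + period * (n_spikes - 1) + 1
    probe = np.zeros(T)
    probe[t_first + period * np.arange(n_spikes)] = 1.0
    return probe, input_weight


def regime_map(
    probe: np.ndarray,
    a_grid: np.ndarray,
    b_grid: np.ndarray,
    alpha: float = 0.9,
    beta: float = 0.96,
    input_weight: float = 15.0,
    T_extra: int = 100,
) -> RegimeMap:
    """Count output spikes per (a, b) cell for one fixed probe train.

    Every cell simulates the full adaptive dynamics with (a, b) replacing
    the base parameters; the simulation runs ``T_extra`` silent steps past
    the last input spike so self-sustained firing is visible in
    ``tail_counts``.  The (0, 0) cell is the plain LIF response.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    b_grid = np.asarray(b_grid, dtype=float)
    if a_grid.size == 0 or b_grid.size == 0:
        raise ValueError("a_grid and b_grid must be non-empty")
    probe = np.asarray(probe, dtype=float)
    n_input = int(probe.sum())
    if n_input < 1:
        raise ValueError("probe must contain at least one spike")
    aa, bb = np.meshgrid(a_grid, b_grid, indexing="ij")
    n_cells = aa.size
    params = NeuronParams(
        alpha=np.full(n_cells, alpha),
        beta=np.full(n_cells, beta),
        a=aa.ravel().copy(),
        b=bb.ravel().copy(),
        variant="AdLIF",
    )
    I_train = np.concatenate([probe, np.zeros(T_extra)]) * input_weight
    I = np.broadcast_to(I_train[:, None], (I_train.size, n_cells))
    _, _, s = simulate(I, params)
    last_input = int(np.flatnonzero(probe)[-1])
    counts = s.sum(axis=0).reshape(aa.shape)
    tail = s[last_input + 1:].sum(axis=0).reshape(aa.shape)
    return RegimeMap(
        a_grid=a_grid,
        b_grid=b_grid,
        counts=counts.astype(int),
        tail_counts=tail.astype(int),
        n_input_spikes=n_input,
    )


def parameter_distributions(model: SNNModel, bins: int = 20) -> dict:
    """Histograms of the neuron parameters per hidden layer, and of delays.

    Returns ``{"neuron": [{name: (hist, edges)} per hidden layer],
    "delays": [(hist, edges) per layer with delays]}``.  Delay histograms
    use integer-aligned edges over [0, d_max] so the mass at zero (the
    initialization point) is its own bin.
    """
    out: dict = {"neuron": [], "delays": []}
    for p in model.neuron_params:
        layer_hists = {}
        for name in ("alpha", "beta", "a", "b"):
            lo, hi = p.bounds[name]
            if hi <= lo:
                hi = lo + 1e-9
            layer_hists[name] = np.histogram(getattr(p, name), bins=bins, range=(lo, hi))
        out["neuron"].append(layer_hists)
    for layer in model.layers:
        if layer.delays is not None:
            d_max = layer.delays.d_max
            edges = np.arange(-0.5, d_max + 1.0, 1.0)
            out["delays"].append(np.histogram(layer.delays.effective_shift, bins=edges))
    return out


def spike_rate_report(spike_records: list[np.ndarray], n_samples: int) -> dict:
    """Average spikes per neuron per sample from hidden spike records.

    ``spike_records`` holds one ``(n_samples, T, n_neurons)`` array per
    hidden layer.  Returns the overall figure plus a per-layer breakdown.
    """
    per_layer = [float(s.sum()) / (s.shape[-1] * n_samples) for s in spike_records]
    total_spikes = sum(float(s.sum()) for s in spike_records)
    n_neurons = sum(s.shape[-1] for s in spike_records)
    return {
        "spikes_per_neuron": total_spikes / (n_neurons * n_samples),
        "per_layer": per_layer,
    }
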