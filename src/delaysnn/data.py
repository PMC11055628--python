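"""Synthetic spike-train tasks and event-stream preprocessing.

The synthetic lag task is a controlled stand-in for neuromorphic speech
data: every sample has spikes on a *reference* channel at random times and
echo spikes on a *partner* channel offset by a class-specific lag, on top
of Poisson background noise.  Classes are separable only through the
inter-channel lag, so a classifier must either hold the reference spike
in memory across the lag or learn a compensating synaptic delay -- which
makes the task a direct probe of delay learning, with known ground truth.

Event streams (time, channel) in the style of neuromorphic audio datasets
are binned onto a binary (timestep x channel) grid: 700 input channels
merged to 140 in contiguous groups of 5, 10 ms bins over 1 s -> 100
timesteps, a bin set to 1 when at least one event falls in its cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "SyntheticLagTask",
    "EventStream",
    "generate_lag_task",
    "bin_events",
    "pad_for_delays",
    "read_event_file",
    "write_event_file",
]


@dataclass
class SyntheticLagTask:
    """Labeled binary spike arrays with recorded ground-truth lags."""

    inputs: np.ndarray  # (n_samples, T, n_channels) in {0, 1}
    labels: np.ndarray  # (n_samples,) int class ids
    true_lags: tuple[int | None, ...]  # lag per class (None: uncorrelated partner)
    noise_rate: float
    seed: int
    reference_channel: int = 0
    partner_channel: int = 1

    def split(self, frac: float = 0.8) -> tuple[tuple, tuple]:
        """Deterministic train/validation split (first frac / rest)."""
        n_train = int(round(frac * len(self.labels)))
        return (
            (self.inputs[:n_train], self.labels[:n_train]),
            (self.inputs[n_train:], self.labels[n_train:]),
        )


def generate_lag_task(
    n_samples: int,
    n_channels: int = 8,
    T: int = 40,
    lags: tuple[int, ...] = (0, 6),
    noise_rate: float = 0.01,
    seed: int = 0,
    n_ref_spikes: int = 4,
) -> SyntheticLagTask:
    """Generate a lag-discrimination dataset.

    Per sample: a class is drawn uniformly; ``n_ref_spikes`` reference
    spikes are placed uniformly at random on channel 0 within
    ``[0, T - 1 - max(lags)]``; channel 1 receives the same spikes offset
    by the class lag; every (channel, timestep) cell additionally fires
    with probability ``noise_rate`` (binned Poisson background).  With
    zero noise the classes are perfectly separable by the lag structure.

    A class lag of ``None`` means the partner channel is *uncorrelated*:
    it receives the same number of spikes at random times constrained to
    fall more than one timestep away from every reference spike.  (Without
    that constraint chance zero-lag coincidences would leak alignment
    information into the supposedly unaligned class.)  Such a class is
    distinguishable from a lagged class only through the presence/absence
    of the fixed inter-channel lag -- first-order spike statistics are
    identical -- which forces a classifier to detect temporally aligned
    coincidences rather than rate differences.
    """
    lags = tuple(None if l is None else int(l) for l in lags)
    int_lags = [l for l in lags if l is not None]
    if any(l < 0 or l >= T for l in int_lags):
        raise ValueError(f"lags must lie in [0, T); got {lags} with T={T}")
    if n_channels < 2:
        raise ValueError("need at least reference and partner channels")
    rng = np.random.default_rng(seed)
    max_lag = max(int_lags, default=0)
    X = np.zeros((n_samples, T, n_channels))
    y = rng.integers(0, len(lags), size=n_samples)
    for i in range(n_samples):
        lag = lags[y[i]]
        n_spk = min(n_ref_spikes, T - max_lag)
        ref_times = rng.choice(T - max_lag, size=n_spk, replace=False)
        X[i, ref_times, 0] = 1.0
        if lag is None:
            near_ref = np.zeros(T - max_lag, dtype=bool)
            for dt in (-1, 0, 1):
                shifted = ref_times + dt
                near_ref[shifted[(shifted >= 0) & (shifted < T - max_lag)]] = True
            candidates = np.flatnonzero(~near_ref)
            par_times = rng.choice(candidates, size=min(n_spk, len(candidates)),
                                   replace=False)
            X[i, par_times, 1] = 1.0
        else:
            X[i, ref_times + lag, 1] = 1.0
    noise = rng.random(X.shape) < noise_rate
    X = np.maximum(X, noise.astype(float))
    return SyntheticLagTask(
        inputs=X, labels=y, true_lags=lags, noise_rate=noise_rate, seed=seed
    )


@dataclass
class EventStream:
    """One neuromorphic recording: spike times (s) and source channels."""

    times: np.ndarray
    units: np.ndarray
    label: int

    def validate(self, n_units: int = 700, duration_s: float = 1.0) -> "EventStream":
        if len(self.times) != len(self.units):
            raise ValueError("times and units must have equal length")
        if len(self.times) and (self.times.min() < 0 or self.times.max() > duration_s):
            raise ValueError(f"event times must lie in [0, {duration_s}] s")
        if len(self.units) and (self.units.min() < 0 or self.units.max() >= n_units):
            raise ValueError(f"unit index out of range [0, {n_units})")
        return self


def bin_events(
    stream: EventStream,
    n_units: int = 700,
    out_channels: int = 140,
    bin_ms: float = 10.0,
    duration_s: float = 1.0,
) -> np.ndarray:
    """Bin an event stream to a binary (T x out_channels) array.

    Units are merged in contiguous groups (700 -> 140 merges groups of 5);
    time is cut into ``bin_ms`` bins over ``duration_s``.  A cell is 1
    when at least one event falls into it (binary OR, not a count), and
    events at exactly ``t = duration_s`` land in the last bin.
    """
    if n_units % out_channels != 0:
        raise ValueError("n_units must be an integer multiple of out_channels")
    stream.validate(n_units=n_units, duration_s=duration_s)
    group = n_units // out_channels
    T = int(round(duration_s * 1000.0 / bin_ms))
    out = np.zeros((T, out_channels))
    if len(stream.times) == 0:
        return out
    t_idx = np.minimum((stream.times * 1000.0 / bin_ms).astype(int), T - 1)
    c_idx = stream.units // group
    out[t_idx, c_idx] = 1.0
    return out


def pad_for_delays(x: np.ndarray, d_max: int) -> np.ndarray:
    """Right-pad the time axis (axis -2) with d_max all-zero steps.

    Delayed content shifted up to d_max steps later then stays inside the
    simulation horizon.
    """
    if d_max == 0:
        return x
    pad = [(0, 0)] * x.ndim
    pad[-2] = (0, int(d_max))
    return np.pad(x, pad)


def write_event_file(path, streams: list[EventStream], n_units: int = 700) -> None:
    """Write streams to an HDF5 container (spikes/times, spikes/units, labels)."""
    vlen_f = h5py.special_dtype(vlen=np.dtype("float64"))
    vlen_i = h5py.special_dtype(vlen=np.dtype("int64"))
    with h5py.File(path, "w") as f:
        f.attrs["n_units"] = n_units
        grp = f.create_group("spikes")
        dt = grp.create_dataset("times", (len(streams),), dtype=vlen_f)
        du = grp.create_dataset("units", (len(streams),), dtype=vlen_i)
        for i, s in enumerate(streams):
            dt[i] = np.asarray(s.times, dtype=float)
            du[i] = np.asarray(s.units, dtype=np.int64)
        f.create_dataset("labels", data=np.array([s.label for s in streams], dtype=np.int64))


def read_event_file(path) -> list[EventStream]:
    """Read an HDF5 event container; validates every stream's invariants."""
    try:
        with h5py.File(path, "r") as f:
            if "spikes" not in f or "labels" not in f:
                raise KeyError("missing 'spikes' group or 'labels' dataset")
            n_units = int(f.attrs.get("n_units", 700))
            times = f["spikes/times"][:]
            units = f["spikes/units"][:]
            labels = f["labels"][:]
    except (OSError, KeyError) as e:
        raise ValueError(f"malformed event container {path}: {e}") from e
    return [
        EventStream(np.asarray(t, dtype=float), np.asarray(u, dtype=np.int64), int(l)).validate(n_units)
        for t, u, l in zip(times, units, labels)
    ]
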