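# Methods

## The neuron model

`delaysnn` simulates networks of discrete-time adaptive leaky
integrate-and-fire neurons with a 1 ms step.  Each neuron keeps a
membrane potential `u` and an adaptation current `w`:

    u[t] = alpha * u[t-1] + (1 - alpha) * (I[t] - w[t-1]) - theta * s[t-1]
    w[t] = beta  * w[t-1] + (1 - beta) * a * u[t-1] + b * s[t-1]
    s[t] = [ u[t] >= theta ]

with a fixed threshold `theta = 1` and a *soft* reset: a spike subtracts
theta; the potential is never clamped or reset to a constant.  The
evaluation order matters and is exactly as written: `u[t]` reads the
previous adaptation current, `w[t]` the previous potential.

Four per-neuron constants are trainable, each drawn uniformly within
closed bounds at initialization and projected back onto them after every
optimizer step:

| parameter | role                                    | bounds          |
|-----------|-----------------------------------------|-----------------|
| `alpha`   | membrane decay per step                 | [0.36, 0.96]    |
| `beta`    | adaptation-current decay per step       | [0.96, 0.99]    |
| `a`       | sub-threshold coupling of `u` into `w`  | cAdLIF [0, 1]; AdLIF [-1, 1] |
| `b`       | spike-triggered adaptation increment    | [0, 2]          |

Three variants: **LIF** (`a = b = 0` fixed, only `alpha` trainable),
**AdLIF** (all four trainable, `a` may be negative) and **cAdLIF** (the
constrained model: `a, b >= 0`).  The constraint matters because for
`a < 0` the coupling between `u` and `w` becomes positive feedback and
the neuron can fire more spikes than it receives -- the chaotic regime
mapped by the analysis module (below).  The AdLIF bound for `a` is a
package choice ([-1, 1], symmetric around the cAdLIF cap): it reaches the
unstable region while keeping the linear subthreshold map non-expansive.

## Network, readout and loss

The architecture is a fixed two-hidden-layer fully connected feed-forward
net.  Hidden layers run the neuron dynamics; dropout (binary masks,
inverted scaling) is applied to emitted spike trains during training
only.  The readout layer is memoryless with infinite threshold: its
potential is just the (possibly delayed) weighted input at each step.
Class scores are per-timestep softmaxes of the readout potentials summed
over time (scores sum to T per sample), and the loss is the cross-entropy
of the normalized summed scores.  The implementation backpropagates the
*exact* gradient of that loss; the conventional 1/T factor of unrolled-
in-time formulations is a constant absorbed by the learning rate.

Weights are Xavier-uniform, biases zero, initial `u`/`w` zero.
`NetworkConfig.input_gain` (default 1.0, i.e. untouched Xavier) scales
the two non-readout projections; the few-channel synthetic tasks use a
gain of 6 because at Xavier scale their sparse inputs never push any
membrane potential into the surrogate window and every gradient is zero.
Speech-scale inputs (140 channels, dense spiking) do not need it.

## Synaptic delays

Every synapse carries, besides its weight, a continuous delay value
`d in [0, d_max]` (default cap 25 steps).  The forward pass shifts the
presynaptic train by `round(d)` (nearest integer, ties toward zero):
`p_ij[t] = s_j[t - round(d_ij)]`.  The continuous value is the trainable
shadow variable, clipped to the cap after every step.  Learnable delays
start at zero — the network is born delay-free — and inputs are
right-padded by `d_max` steps so shifted content stays in the horizon.
Fixed-random mode (the fd- ablation) draws frozen delays uniformly over
`[0, d_max]`.  Delays sit on all three projections, readout included.

Delays are trained with a temporal-context pseudo-gradient.  The
derivative of the delayed train with respect to the delay is replaced,
per synapse and timestep, by the window difference

    g[t] = sum_{k=1..c} ( p[t-k] - p[t+k] ),      c = 3 by default,

zero-padded at sequence boundaries.  The window sum is unnormalized; any
constant factor would fold into the delay learning rate.  Sign
convention: shifting a spike later raises `p` after the spike and lowers
it before, so `g` carries the sign of dp/dd and the applied update is
`d <- d - lr_d * sum_t dL/dp[t] * g[t]`.  This convention is *verified*,
not assumed: a brute-force oracle evaluates the loss of one-synapse
micro-instances at every integer delay and checks that the
pseudo-gradient's update direction agrees with the finite-difference
loss change in >= 90% of nonzero cases (it measures ~97-99%).

## Training

Optimization is Adam (beta1 0.9, beta2 0.999, eps 1e-8) with two
parameter groups: weights, biases and neuron parameters at `lr_weights`,
delays at `lr_delays = 10 * lr_weights` by default.  The backward pass is
reverse-mode backpropagation through time written in closed form for
this architecture; the Heaviside derivative is replaced by a boxcar
surrogate (0.5 on `|u - theta| <= 0.5`, boundary inclusive, 0
elsewhere).  After every step neuron parameters and delays are clipped
(the strictest reading of "clipped during training", and the one that
keeps the dynamics well-posed at all times); optimizer moments are not
reset on clipping.  A reduce-on-plateau schedule (factor 0.7, patience 5
epochs) monitors validation accuracy and scales both learning rates.
Training is fully deterministic given the seed: data shuffling and
dropout masks come from one seeded generator.

Gradient correctness is established by swapping the spike nonlinearity
for a smooth sigmoid stand-in (forward *and* backward) and comparing
analytic BPTT gradients of all weights, biases and neuron parameters
against central finite differences on a 3-neuron, T=5 network; the
shared reverse-mode code path is exercised end to end (max relative
error ~1e-6, asserted < 1e-3).

## Parameter accounting

`count_parameters` counts feed-forward weights, per-neuron biases,
trainable neuron parameters (1 per hidden neuron for LIF, 4 for
AdLIF/cAdLIF) and, when delays are learnable, one delay per synapse on
all layers including the readout.  On the 40 -> 512 -> 512 -> 35
architecture this gives 0.30 M (LIF), 0.60 M (d-LIF) and 0.61 M
(d-cAdLIF) at two-decimal-million precision.  Frozen random delays are
not trainable and are not counted.

## The adaptation regime map

The analysis module drives a single neuron with a fixed probe train and
counts output spikes over an (a, b) grid, with 100 extra silent steps
appended to expose self-sustained firing.  The default probe: 12 spikes,
one every 8 steps, input weight 15, base `alpha = 0.9`, `beta = 0.96`.
The weight is chosen *just supra-threshold* — one arriving spike deposits
(1 - alpha) * 15 = 1.5 and triggers exactly one output spike, whose
soft-reset residual decays before the next input — so the plain LIF cell
(a = b = 0) answers the probe one-for-one (12 in, 12 out) and acts as an
exact anchor.  Any cell above 12 exceeds its input purely through
adaptation feedback; cells below 12 are spike-limited by it.

A strictly sub-threshold probe cannot exhibit the chaotic regime on this
grid at all: for `a >= -1`, `b >= 0`, `theta = 1` the subthreshold
(u, w) map has spectral radius <= 1 (the eigenvalue reaches 1 exactly at
a = -1, along the mode u = -w), each output spike drains that mode by
theta, and a sub-threshold input pumps it by less than theta — so the
output count can never exceed the input count.  The same argument shows
self-sustained firing cannot persist indefinitely for `a >= -1`; chaotic
cells here fire a small number of extra spikes, including at least one
after the input has ceased.  On the default 41 x 41 grid over
[-1, 1] x [0, 2]: the constrained quadrant never exceeds 12 spikes,
while ~22 cells with a < 0 do, 6 of them with post-input spikes.

## The synthetic lag task

The generator emulates the one property of neuromorphic audio that delay
learning targets: class-discriminative inter-channel spike lags.  Each
sample has `n_ref_spikes` (default 4) reference spikes at random times on
channel 0; channel 1 either repeats them offset by the class lag, or —
for a class lag of `None` — receives the same number of spikes at random
times placed more than one step away from every reference spike
(otherwise chance zero-lag coincidences leak alignment information into
the supposedly unaligned class).  All channels receive Bernoulli
background noise at `noise_rate` per cell (the binned view of a Poisson
background).  Classes are separable by lag structure by construction;
with zero noise the Bayes accuracy is 1.

The default delay-recovery study contrasts an uncorrelated class against
lag 6: 400 samples, 4 channels, T = 40, noise 0.01, LIF variant (so
delay learning is isolated from adaptation memory), hidden sizes
(24, 24), delay cap 12, 60 epochs of Adam at lr 5e-3 (delays 5e-2).
This contrast is deliberate: with a lag-0 class as the alternative,
networks discriminate by zero-delay cancellation (+reference/−partner)
and never need delays.  Against the uncorrelated class the only robust
solutions are delay-compensating: a coincidence detector with both
weights positive and delay difference `d_ref - d_par = L`, or an
aligned-cancellation detector (opposite-sign weights) with the same
difference.  The recovery measurement therefore weights each
first-hidden-layer neuron by the *absolute* difference in mean spike
count between classes and reports the weighted mode of the per-neuron
effective-shift differences.  Across seeded runs the true lag is
recovered within +/-1 step in >= 80% of runs, and mean validation
accuracy with learnable delays (~0.94-0.97) far exceeds the no-delay
control (~0.55, near chance) on the same task.

What the generator does *not* emulate: realistic channel counts and
firing statistics of cochlear front-ends, speaker variability,
multi-scale temporal structure, or any audio content.  Passing these
tests shows the learning rules work as specified on data whose
ground-truth temporal structure is known — not that the reported speech
benchmark accuracies are reproduced, which would require the external
datasets and long training runs deliberately out of scope here.

## Event-stream preprocessing

HDF5 event containers (per-sample `times`/`units` plus labels) are
binned to binary arrays: 700 units merged to 140 channels in contiguous
groups of 5, 10 ms bins over 1 s -> 100 steps; a cell is 1 when at least
one event falls in it (binary presence, matching the spike-domain
definition `s[t] in {0, 1}`, rather than counts), and events at exactly
t = 1 s land in the last bin.  Real-valued feature frames (e.g. 40 Mel
bins per 10 ms frame) are accepted directly as input currents; computing
such features from raw audio is outside the package's scope.

## Numerical notes and limitations

- All state is float64 numpy; simulations are exact recurrences, no
  solver tolerances are involved.
- `round(d)` uses ties-toward-zero (`ceil(d - 0.5)`); delays are
  non-negative so this differs from ties-away only at exact .5 values.
- The per-timestep softmax is computed in a max-shifted form; aggregated
  scores sum to T identically, which the loss exploits.
- Non-finite losses abort training with a diagnostic rather than being
  clamped.
- Biases are trainable but unbounded (no printed bounds exist for them);
  clipping does not touch them.
- The readout weight group uses the base learning rate; only delay
  values get the 10x multiplier.
- Checkpoints are single `.npz` archives (versioned JSON header plus all
  parameter arrays); bytes are reproducible for identical runs.
- Known limitation: with one CPU and pure-numpy BPTT, speech-scale runs
  (512-wide layers, 100 epochs, 10^5 samples) are out of reach; all
  bundled studies use the synthetic task at the sizes stated above.
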