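# Methods

## Model

The simulated system is a single hidden layer of leaky integrate-and-fire
(LIF) neurons driven by binary spike rasters, optionally with recurrent
connections, feeding a layer of non-spiking leaky integrators (LI) whose
softmax over time defines a classifier.  With membrane decay
`alpha = exp(-dt/tau_m)` and readout decay `kappa = exp(-dt/tau_out)`, one
update (state index t to t+1, all-zero initial state) is

    v[t+1] = alpha*v[t] + W_in @ x[t - D_in] (+ W_rec @ z[t-1-D_rec]) - z[t]*v_th
    z[t+1] = H(v[t+1] > v_th)
    y[t+1] = kappa*y[t] + W_out @ z[t+1]

The loss is the time-summed cross entropy of the per-step softmax of `y`
against a one-hot label; the prediction is the argmax of the time-summed
softmax (the standard readout for this loss — the aggregation rule is not
uniquely dictated by the formulation, so it is an implementation choice).

Conventions, all configurable but fixed as defaults:

* `v_th = 1` (threshold-normalized units), strict inequality at threshold,
  soft reset by threshold subtraction, reset potential 0, no bias terms.
* `alpha = 0.6` (the published operating point); `kappa = exp(-0.01) ≈
  0.990` from `tau_out = 1 s` at `dt = 10 ms` (only `tau_out >= 1 s` is
  stated; the smallest such constant is used).
* Continuous delay parameters `d` live in `[-(D_max-1)/2, +(D_max-1)/2]`;
  the lower bound is "no delay" and the upper bound the maximum delay.
  The forward pass uses only the integer `round(d + (D_max-1)/2)` clipped
  to `[0, D_max-1]`, with `floor(x+0.5)` rounding so half-integer ties
  break upward deterministically.  `D_max = 25` steps at 10 ms gives a
  maximum latency of 250 ms.
* Recurrence carries one mandatory extra step of latency (`z[t-1-D]`), so
  at the no-delay setting the recurrent input is the previous step's spike.
* Weights initialize zero-mean uniform scaled by `1/sqrt(fan-in)`; delays
  initialize uniformly over the legal range (or at the midpoint / at
  uniformly random integers for specific experiments); sparsity is a fixed
  seeded Bernoulli mask applied to input and recurrent weight matrices.
* The forward pass is strictly binary.  No smoothing of any kind enters
  simulation; the Gaussian machinery below exists only inside parameter
  updates.

## Three-factor learning rules

Every parameter update is a product of three locally available factors: a
top-down learning signal `L_j^t = dE/dz_j^t`, the threshold
pseudo-derivative `psi_j^t`, and a low-pass eligibility vector.  The
pseudo-derivative is the piecewise-linear kernel
`(gamma_pd/v_th) * max(0, 1 - |v - v_th|/v_th)` with `gamma_pd = 0.3`.

For weights the eligibility vector filters the delayed presynaptic
activity with the membrane decay:

    eps_w <- alpha*eps_w + x[t-D],      e_w = psi * eps_w

For delays the same recursion filters the weighted derivative of a
Gaussian-smoothed delayed spike train with respect to the delay parameter:

    eps_d <- alpha*eps_d + W * dxhat(t-D)/dD,   e_d = psi * eps_d

where `xhat` replaces each spike by a normal density of width `sigma`
centered at the (continuous) delayed spike time, truncated to a window of
`k` taps without renormalization, and
`dxhat/dD = +u/(sqrt(2*pi)*sigma^3) * exp(-u^2/(2*sigma^2))` at offset `u`.
Two sign conventions circulate for this derivative (with respect to time
versus with respect to the delay); this package defines it with respect to
the delay parameter — positive for `u > 0` — which is the direction under
which gradient descent recovers planted latencies (verified by the
delay-recovery experiment and by finite differences against the oracle).

Axonal delays share one parameter per presynaptic neuron: the eligibility
then factorizes into a per-channel trace and the gradient sums the
contributions of all postsynaptic neurons.  Per-synapse (synaptic) delays
keep a full per-synapse trace.  Recurrent projections treat the hidden
spike record as the presynaptic train with the extra step of latency.

The exact learning signal discounts future readout errors with `kappa`.
Online, that acausal sum is refactorized into a `kappa`-filtered
eligibility trace multiplied by the instantaneous readout error
`W_out^T (pihat - pistar)` — an exact rearrangement, verified numerically
against the literal (stored-trajectory) evaluation.  Readout weights use
the standard filtered-spike rule.  The reset term is treated as constant
in all gradient paths, and on recurrent networks credit flowing through
recurrent spikes is dropped; both are the standard locality approximations
of eligibility propagation, and the unrolled oracle quantifies the gap.

Because the Gaussian kernel is non-causal, updates need spikes up to
`ceil(k/2)` steps ahead of the delayed spike time.  For input projections
the raster provides them; for learnable recurrent delays the learning-side
computation simply runs `ceil(k/2)` steps behind the dynamics with a small
bounded queue — the extra buffering equal to half the kernel size.  All
learning state is bounded by `D_max` and the kernel window; nothing scales
with the sequence length.  (Input-side quantities are precomputed in
fixed 64-step blocks purely to amortize array overhead.)

Kernel defaults: `sigma = 2` steps, `k = 12` taps.  The width is not
critical (symmetry is); `k = 12` is the unique tap count consistent with
both published totals of the memory model below, and `sigma = 2` keeps
about 99.7% of the kernel mass inside that window.  Delay derivatives are
evaluated at the continuous delay by default so gradients vary smoothly
between integer settings; a switch (`use_rounded_shift`) evaluates them at
the rounded delay instead.

Optimization is plain minibatch SGD: mean gradient over batches of 16,
learning rates 1e-4 (weights) and 1e-2 (delays), gradient descent with
delays clamped to the legal range after each update.  Masked weights, the
recurrent diagonal, and masked synapses' delay parameters are never
updated.  Eligibility and filtered traces reset between sequences.

## Gradient oracle

`oracle.unrolled_gradient` differentiates the full unrolled graph in
reverse mode with the same surrogate substitutions.  Mode
`locality_matched` detaches the reset and recurrent-spike credit paths and
must agree with the online rules to floating point on any configuration
(the acceptance tests require 1e-9 relative on feedforward networks);
mode `full` propagates through everything the surrogates allow, and the
difference between the two modes on recurrent networks is the
approximation gap, reported rather than asserted.  A `relaxed` forward
variant replaces the Heaviside by the C1 integral of the pseudo-derivative
and binary delayed inputs by the smoothed train, making the loss
differentiable so central finite differences converge to the `full`-mode
gradient at O(h^2); it supports feedforward networks, which is where the
delay-gradient path it validates lives.  An explicit size guard rejects
graphs beyond test scale.

## On-chip memory model

For a hardware implementation, delaying the input train costs
`M_axonal = n_in * 2^B_d` bits (the buffer length is the addressable
delay range `2^B_d`; the alternative `2*B_d` reading is inconsistent with
every published total).  Per-synapse delays additionally need ring buffers
of delayed synaptic current: `M_synaptic = n_in*2^B_d +
n_hidden*2^B_d*B_v`.  Learning needs the surrogate look-up table
`M_trace = n_hidden*k*B_v`.  At the reference configuration (116-128-20,
`B_w=8`, `B_d=5`, `B_v=16`, `k=12`) the model reproduces, bit for bit:
141.632k bits for the dense weights-only network, 28.288k / 93.824k bits
of learning-support memory for axonal / synaptic delays, the remaining
budgets 113.344k / 47.808k bits, and 580 bits of axonal delay parameters.

The minimum-sparsity calculation asks what density lets the delayed,
learning-enabled model fit the dense weights-only budget.  The accounting
that reproduces the published thresholds applies the density to both the
hidden and readout weight matrices (hidden parameters cost 13 = 8+5 bits
each when per-synapse delays share the mask), counts membrane state inside
the budget, and treats axonal delay parameters as a fixed cost: minimum
sparsity 20.7% (axonal) and 78.7% (synaptic).  Parameter counts follow the
same convention, with the density scaling every parameter group.

## Synthetic tasks and experiment design

The generators produce tasks in which classes have identical per-channel
spike counts and differ only in relative spike latencies, so rate codes
carry no class information and temporal alignment through delays is the
intended solution.  Each sample draws a few volley onsets; every channel
fires once per volley at onset + planted latency, optionally with
integer-rounded Gaussian jitter.  The two-channel coincidence pair
reproduces the canonical demonstration: with a 3-step offset and two
subthreshold synapses (w = 0.7, v_th = 1, alpha = 0.6) the output neuron
is silent, and delaying the early channel by the offset makes the inputs
coincide and the neuron fire.

What the generators do not emulate: cochlear channel correlations,
realistic channel counts (hundreds), utterance-length variability, or
speaker variability.  Passing the synthetic suite therefore demonstrates
the mechanics of online delay learning — gradient correctness, latency
recovery, the learnable-vs-fixed advantage — not keyword-spotting
accuracy; the shipped SHD configurations cover the latter as long-running
optional runs.

Two scales of learning rate appear.  The benchmark rates (1e-4 weights,
1e-2 delays, batch 16, 60 epochs) belong to the full keyword-spotting
runs, roughly 30,000 parameter updates; they remain the package defaults
and are used verbatim in the loss-descent check.  The desk-scale
experiments see about two orders of magnitude fewer updates, so their
rates were scaled up once, as part of the experiment design, and frozen;
concretely:

* Delay recovery: 4 channels, 2 classes with mirrored latency ramps
  (0/2/4/6 steps), 4 volleys in 60 steps, 64 training sequences.  Weights
  fixed at w = 0.45 (so full coincidence fires, partial alignment does
  not), identity readout, delays start at the range midpoint and learn
  alone at lr_d = 3e-2 for 100 epochs.  Success: each class neuron's
  learned relative delays within ±1 step of the planted compensating
  offsets, test accuracy 100%.
* Learnable-vs-fixed control: 16 hidden units on a latency task hard
  enough that frozen random delays rarely align by luck — four classes on
  six channels with distinct latency patterns (spread 10 steps) and one
  step of jitter.  Weights and per-synapse delays co-learn at lr_w = 5e-3,
  lr_d = 3e-2 for 100 epochs, against the same architecture with integer
  delays drawn uniformly at random and frozen; shared seeds, mean
  accuracy over 5 seeds compared directionally.  (Two-class versions of
  this task are uninformative: sixteen randomly delayed neurons almost
  always contain a projection that separates two classes, and both
  conditions saturate.)

Reporting follows the benchmark protocol: top-1 accuracy, repetition over
a seed list, mean with a t-distribution 95% confidence interval, no
validation set (fresh seeded test sets instead), full determinism given
(config, seed).

## Known limitations

* One hidden layer; the local rules do not stack into deep networks.
* On recurrent networks the gradients are approximations by construction;
  the oracle reports the gap instead of closing it.
* Axonal-delay gradients accumulate the contributions of all postsynaptic
  neurons into one shared parameter and are therefore noisier than
  per-synapse gradients.
* The memory model counts bits; it does not simulate quantized inference
  or training.
* The streaming learner peeks up to `ceil(k/2)` raster rows ahead for
  input-delay updates (a real-time system would add that much latency).
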