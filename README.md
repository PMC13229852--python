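# delayprop

Online learning of synaptic weights **and** transmission delays in spiking
neural networks, using three-factor rules built on eligibility propagation.

Spiking networks operate in time, yet most trainable parameters are static
weights.  A delay on a connection shifts *when* a presynaptic spike reaches
the postsynaptic membrane: tuned delays make inputs from different neurons
arrive coincidentally and fire a neuron that weights alone never could.
Offline methods (backpropagation through time) can learn delays but need
memory that grows with the sequence length, which rules out on-device
learning.  This package learns weights, per-synapse delays and per-neuron
(axonal) delays **online** — one forward sweep, bounded memory — for
single-hidden-layer feedforward and recurrent leaky integrate-and-fire
(LIF) networks, and includes the supporting cast needed to trust and cost
such a system: an unrolled-gradient oracle, an on-chip memory model, and
synthetic temporal-pattern tasks.  Intended users are computational
neuroscientists and neuromorphic-hardware designers studying temporal
credit assignment under memory constraints.

## The learning rule

Hidden dynamics (binary spikes `z`, membrane `v`, decay `α = e^{-Δt/τ_m}`,
input delays `D`):

    v_j^{t+1} = α v_j^t + Σ_i W_ji x_i^{t-D_ji} (+ Σ_i W^rec_ji z_i^{t-1-D^rec_ji}) − z_j^t v_th
    z_j^{t+1} = H(v_j^{t+1} > v_th)

A leaky-integrator readout `y^{t+1} = κ y^t + W_out z^{t+1}` feeds a
per-step softmax and time-summed cross entropy `E`.  Every parameter θ
updates from three locally available factors,

    dE/dθ_ji = Σ_t L_j^t · ψ_j^t · ε_ji^t,

where `L_j^t = dE/dz_j^t` is the top-down learning signal (its acausal
κ-discounted sum is folded into κ-filtered traces so the rule runs
forward-only), `ψ_j^t` is a piecewise-linear surrogate of the spike
derivative, and the eligibility vector `ε` low-pass filters, with `α`,
either the delayed presynaptic activity (weight rule) or the derivative of
a Gaussian-smoothed delayed spike train with respect to the delay (delay
rule).  The Gaussian enters *only* the updates — inference stays binary.
Axonal delays share one parameter per presynaptic neuron and sum the
contributions of all postsynaptic targets.  Full derivations, conventions
and design choices are in [docs/methods.md](docs/methods.md).

## Worked example

```python
import delayprop as dp

# Two inputs firing 3 steps apart cannot drive the output neuron; a
# compensating synaptic delay makes their arrivals coincide.
raster, no_delay, compensating = dp.make_coincidence_pair(offset=3)
sim = dp.SimParams(T=raster.T)
print("output spikes, no delays:        ", int(dp.forward_pass(raster, no_delay, sim).z.sum()))
print("output spikes, 3-step delay:     ", int(dp.forward_pass(raster, compensating, sim).z.sum()))

# Learn the delays online from labelled rasters (weights held fixed).
task = dp.SynthTaskSpec(
    n_in=4, n_classes=2, T=60,
    planted_latencies=((0., 2., 4., 6.), (6., 4., 2., 0.)),
    spikes_per_channel=4, seed=0,
)
result = dp.delay_recovery_run(task, seed=0)
print(f"max delay error after training:   {result['max_delay_error']:.2f} steps")
print(f"test accuracy:                    {result['test_acc']:.0%}")

# On-chip memory budget of the reference 116-128-20 network.
spec = dp.MemorySpec()
print("weights-only footprint:          ", dp.footprint(spec)["total"] / 1000, "kbit")
print("axonal delay learning memory:    ", (dp.mem_axonal(spec) + dp.mem_trace(spec)) / 1000, "kbit")
print(f"min sparsity to fit budget:       {dp.min_sparsity(spec, 'synaptic'):.1%}")
```

prints

```
output spikes, no delays:         0
output spikes, 3-step delay:      3
max delay error after training:   0.66 steps
test accuracy:                    100%
weights-only footprint:           141.632 kbit
axonal delay learning memory:     28.288 kbit
min sparsity to fit budget:       78.7%
```

The coincidence pair shows the mechanism delays add; the recovery run
shows the online rule finding planted latencies to sub-step precision
(delays are identified up to a common per-neuron offset, so the error is
measured on centered relative delays); the memory lines cost the same
machinery in bits for a hardware budget.

## Command line

```bash
delayprop memory                    # bit budget table + minimum sparsity
delayprop gradcheck                 # online rules vs unrolled oracle
delayprop synth --out set.npz       # generate a planted-latency dataset
delayprop train configs/<name>.yaml # run a training experiment
delayprop eval model.npz set.npz    # score a checkpoint
```

`configs/` ships ready-made configurations for the Spiking Heidelberg
Digits benchmark (116 binned channels, 10 ms steps, 25-step delays, batch
16, 60 epochs, learning rates 1e-4/1e-2).  These are long-running
integration experiments that need the externally downloaded SHD HDF5
files; they are not part of the test suite.  The test suite instead covers
the same mechanics at desk scale: gradient equivalence with the oracle,
latency recovery, and the learnable-vs-fixed-delay control.

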