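"""Spike-raster sources: synthetic temporal-pattern tasks and an SHD reader.

The synthetic generators are first-class citizens: they construct tasks in
which classes differ *only* in relative spike latencies, so that rate-based
(weights-only) discrimination is impoverished and temporal alignment via
learnable delays is the intended solution.  The coincidence pair reproduces
the canonical two-input demonstration: postsynaptic potentials that arrive
apart fail to summate above threshold, while a compensating delay makes
them coincide and the output neuron fires.

The optional reader for the Spiking Heidelberg Digits / Spiking Speech
Commands HDF5 distribution applies the standard preprocessing: channels
binned by 6 (700 -> 116 input neurons, OR-reduction keeps rasters binary)
and time subsampled at 10 ms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .core import NetworkParams, SimParams, SpikeRaster

__all__ = [
    "SynthTaskSpec",
    "make_coincidence_pair",
    "make_latency_dataset",
    "latency_oracle_network",
    "coincidence_task_spec",
    "make_sparsity_mask",
    "load_shd",
    "binned_channels",
    "max_latency_ms",
    "manifest",
]


def binned_channels(n_channels: int = 700, factor: int = 6) -> int:
    """Input neuron count after spatial binning: floor(n/factor).

    700 cochlear channels binned by 6 give 116 input neurons; remainder
    channels are dropped.
    """
    return n_channels // factor


def max_latency_ms(D_max: int, dt_ms: float) -> float:
    """Maximum latency a delay line can introduce (25 steps at 10 ms = 250 ms)."""
    return D_max * dt_ms


@dataclass(frozen=True)
class SynthTaskSpec:
    """Geometry and statistics of a planted-latency classification task.

    ``planted_latencies[c][i]`` is the spike-time offset (steps) of channel
    ``i`` relative to each volley onset for class ``c``.  Every class emits
    the same number of spikes per channel (``spikes_per_channel`` volleys),
    so classes are indistinguishable by rate and differ only in relative
    timing.  ``jitter_sd`` adds integer-rounded Gaussian timing noise.
    """

    n_in: int
    n_classes: int
    T: int
    planted_latencies: tuple  # (n_classes, n_in) nested tuples, steps
    dt: float = 10.0
    jitter_sd: float = 0.0
    spikes_per_channel: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lat = np.asarray(self.planted_latencies, dtype=float)
        if lat.shape != (self.n_classes, self.n_in):
            raise ValueError("planted_latencies must be (n_classes, n_in)")
        if lat.min() < 0 or lat.max() >= self.T:
            raise ValueError("planted latencies must lie in [0, T)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    @property
    def latencies(self) -> np.ndarray:
        return np.asarray(self.planted_latencies, dtype=float)


def make_latency_dataset(
    spec: SynthTaskSpec,
    n_samples: int,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled rasters (X: (n, T, n_in) uint8, y: (n,)) for the planted task.

    Each sample draws ``spikes_per_channel`` volley onsets; every channel
    fires once per volley at onset + planted latency (+ jitter), clipped to
    the sequence.  Labels are balanced round-robin.  Deterministic in
    (spec, seed); ``seed`` defaults to ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lat = spec.latencies
    max_lat = int(lat.max())
    X = np.zeros((n_samples, spec.T, spec.n_in), dtype=np.uint8)
    y = np.arange(n_samples) % spec.n_classes
    rng.shuffle(y)
    # volleys spaced so postsynaptic responses from consecutive volleys
    # do not overlap appreciably at alpha ~ 0.6
    hi = spec.T - max_lat - 2
    for s in range(n_samples):
        onsets = rng.integers(0, max(hi, 1), size=spec.spikes_per_channel)
        for t0 in onsets:
            times = t0 + lat[y[s]]
            if spec.jitter_sd > 0:
                times = times + np.rint(rng.normal(0.0, spec.jitter_sd, size=spec.n_in))
            times = np.clip(np.rint(times), 0, spec.T - 1).astype(int)
            X[s, times, np.arange(spec.n_in)] = 1
    return X, y


def latency_oracle_network(
    spec: SynthTaskSpec, sim: SimParams, w: float = 0.34
) -> NetworkParams:
    """Hand-constructed network that solves the planted task via coincidence.

    One hidden neuron per class; its per-synapse delays compensate the
    class's planted latencies so all arrivals coincide, each synapse weight
    ``w`` below threshold but the coincident sum above it.  The readout is
    the identity map, so the firing neuron decides the class.
    """
    lat = spec.latencies
    comp = lat.max(axis=1, keepdims=True) - lat  # compensating shift per channel
    if comp.max() > sim.D_max - 1:
        raise ValueError("planted offsets exceed the representable delay range")
    D_in = comp - sim.delay_bound  # continuous parameters, "no delay" at the low bound
    W_in = np.full((spec.n_classes, spec.n_in), w)
    W_out = np.eye(spec.n_classes)
    return NetworkParams(W_in=W_in, W_out=W_out, D_in=D_in, flavor_in="synaptic")


def make_coincidence_pair(
    offset: int,
    sim: Optional[SimParams] = None,
    w: float = 0.7,
    n_volleys: int = 3,
    spacing: int = 12,
) -> tuple[SpikeRaster, NetworkParams, NetworkParams]:
    """Two-channel raster plus wiring that fires only under coincidence.

    Channel 1 spikes ``offset`` steps after channel 0 at every volley.  Two
    single-neuron wirings are returned: one with no delay (both synapses at
    the "no delay" setting — arrivals ``offset`` apart, subthreshold, output
    silent) and one whose first synapse is delayed by ``offset`` steps
    (coincident arrival, output fires).  Weights satisfy w < v_th < 2w.
    """
    sim = sim or SimParams(T=n_volleys * spacing + offset + 2)
    if offset >= sim.D_max:
        raise ValueError("offset must be below D_max")
    T = sim.T
    X = np.zeros((T, 2), dtype=np.uint8)
    for v in range(n_volleys):
        t0 = v * spacing
        X[t0, 0] = 1
        X[min(t0 + offset, T - 1), 1] = 1
    raster = SpikeRaster(spikes=X, dt=sim.dt)
    W_in = np.array([[w, w]])
    W_out = np.array([[1.0], [-1.0]])
    lo = -sim.delay_bound
    no_delay = NetworkParams(
        W_in=W_in.copy(), W_out=W_out.copy(),
        D_in=np.array([[lo, lo]]), flavor_in="synaptic",
    )
    compensating = NetworkParams(
        W_in=W_in.copy(), W_out=W_out.copy(),
        D_in=np.array([[lo + offset, lo]]), flavor_in="synaptic",
    )
    return raster, no_delay, compensating


def coincidence_task_spec(
    offset: int = 3, T: int = 48, jitter_sd: float = 0.0, seed: int = 0
) -> SynthTaskSpec:
    """Two-class, two-channel task: class 0 leads on channel 0, class 1 on
    channel 1, with the same firing offset — two-input coincidence
    detection as a trainable classification problem."""
    return SynthTaskSpec(
        n_in=2,
        n_classes=2,
        T=T,
        planted_latencies=((0.0, float(offset)), (float(offset), 0.0)),
        jitter_sd=jitter_sd,
        seed=seed,
    )


def make_sparsity_mask(
    shape: tuple[int, ...], density: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Fixed random binary map: Bernoulli(density) mask, seeded."""
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random(shape) < density).astype(np.uint8)


def load_shd(
    path,
    bin_channels: int = 6,
    bin_time_ms: float = 10.0,
    n_channels: int = 700,
    T: Optional[int] = None,
    max_samples: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Read an SHD/SSC HDF5 file into binned binary rasters.

    The published layout stores, per sample, event times in seconds
    (``spikes/times``), unit ids (``spikes/units``) and a label vector
    (``labels``).  Channels are binned by ``bin_channels`` with OR-reduction
    (remainder channels dropped) and time is subsampled at ``bin_time_ms``.
    Returns (list of (T_i, n_binned) uint8 arrays or a (n, T, n_binned)
    array when ``T`` is fixed, labels).
    """
    import h5py

    n_binned = binned_channels(n_channels, bin_channels)
    with h5py.File(path, "r") as f:
        if "spikes" not in f or "labels" not in f:
            raise ValueError("unrecognized HDF5 layout: expected spikes/ and labels")
        times = f["spikes"]["times"]
        units = f["spikes"]["units"]
        labels = np.asarray(f["labels"], dtype=np.int64)
        n = len(labels) if max_samples is None else min(max_samples, len(labels))
        rasters = []
        for i in range(n):
            t_ev = np.asarray(times[i], dtype=float)
            u_ev = np.asarray(units[i], dtype=np.int64)
            tb = np.floor(t_ev * 1000.0 / bin_time_ms).astype(np.int64)
            cb = u_ev // bin_channels
            keep = cb < n_binned
            tb, cb = tb[keep], cb[keep]
            Ti = T if T is not None else (int(tb.max()) + 1 if tb.size else 1)
            keep = tb < Ti
            raster = np.zeros((Ti, n_binned), dtype=np.uint8)
            raster[tb[keep], cb[keep]] = 1  # OR within each bin
            rasters.append(raster)
    labels = labels[:n]
    if T is not None:
        return np.stack(rasters), labels
    return rasters, labels


def manifest(spec: SynthTaskSpec, n_samples: int, seed: Optional[int] = None) -> str:
    """JSON manifest recording the generating spec and seed, including the
    binning conventions that are implementation choices (OR-reduction,
    half-open [t, t+dt) time bins, 0-based events)."""
    doc = asdict(spec)
    doc.update(
        n_samples=n_samples,
        seed=spec.seed if seed is None else seed,
        conventions={
            "channel_binning": "floor(n/factor), remainder dropped, OR-reduction",
            "time_bins": "half-open [t, t+dt), 0-based",
        },
    )
    return json.dumps(doc, indent=2)
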