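"""Discrete-time simulation of delayed LIF hidden layers and leaky readout.

The simulated system is a single hidden layer of leaky integrate-and-fire
neurons driven by binary input spike trains, optionally with recurrent
connections, projecting to a layer of non-spiking leaky integrators whose
softmax defines a classifier.  Synaptic connections (input and recurrent)
may carry integer delays realized through ring buffers; delay parameters are
stored as continuous values ``d`` in ``[-(D_max-1)/2, +(D_max-1)/2]`` where
the lower bound represents "no delay" and the upper bound the maximum delay.
The forward pass is strictly binary: spikes are 0/1 and no smoothing of any
kind enters simulation.

Update order for one step (state index t -> t+1, all-zero initial state):

    v[t+1] = alpha * v[t] + W_in @ x[t - D_in] (+ W_rec @ z[t-1-D_rec]) - z[t]*v_th
    z[t+1] = H(v[t+1] > v_th)                (strict inequality, soft reset)
    y[t+1] = kappa * y[t] + W_out @ z[t+1]   (no threshold, no reset, no delays)

so a connection at the "no delay" setting consumes the current input row,
and recurrence always incurs one mandatory extra step of latency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.special import log_softmax, softmax

logger = logging.getLogger("delayprop")

DelayFlavor = Literal["none", "axonal", "synaptic"]

__all__ = [
    "SimParams",
    "SpikeRaster",
    "NetworkParams",
    "NeuronState",
    "Trajectory",
    "effective_delay",
    "delay_shift",
    "init_network",
    "lif_step",
    "srnn_step",
    "readout_step",
    "forward_pass",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class SimParams:
    """Simulation constants.

    alpha = exp(-dt/tau_m) is the membrane decay per step (0.6 by default,
    the published operating point); kappa = exp(-dt/tau_out) the readout
    decay, defaulting to tau_out = 1 s at dt = 10 ms.  v_th is the firing
    threshold (the model is threshold-normalized to 1), T the sequence
    length in steps and D_max the maximum representable delay in steps.
    """

    alpha: float = 0.6
    kappa: float = float(np.exp(-0.01 / 1.0))
    v_th: float = 1.0
    dt: float = 10.0
    T: int = 100
    D_max: int = 25

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.kappa < 1.0:
            raise ValueError("kappa must lie in (0, 1)")
        if not self.v_th > 0:
            raise ValueError("v_th must be positive")
        if self.D_max < 1:
            raise ValueError("D_max must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    @property
    def delay_bound(self) -> float:
        """Half-width of the legal continuous delay range, (D_max-1)/2."""
        return (self.D_max - 1) / 2.0

    @property
    def max_latency_ms(self) -> float:
        return self.D_max * self.dt


def effective_delay(d: np.ndarray | float, D_max: int) -> np.ndarray:
    """Integer delay in [0, D_max-1] used by the forward simulation.

    round(d + (D_max-1)/2) with clipping; -(D_max-1)/2 maps to no delay (0)
    and +(D_max-1)/2 to the maximum delay (D_max-1).  Rounding is
    floor(x + 0.5) so half-integers break ties upward deterministically.
    """
    shifted = np.asarray(d, dtype=float) + (D_max - 1) / 2.0
    return np.clip(np.floor(shifted + 0.5), 0, D_max - 1).astype(np.int64)


def delay_shift(d: np.ndarray | float, D_max: int) -> np.ndarray:
    """Continuous delay in steps (>= 0): d re-centered, clipped to the range."""
    shifted = np.asarray(d, dtype=float) + (D_max - 1) / 2.0
    return np.clip(shifted, 0.0, D_max - 1.0)


@dataclass
class SpikeRaster:
    """Binary time x channel spike matrix with timestep metadata."""

    spikes: np.ndarray  # (T, n_channels) in {0, 1}
    dt: float = 10.0
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be a T x n_channels matrix")
        vals = np.unique(self.spikes)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("spike entries must be binary")
        self.spikes = self.spikes.astype(np.uint8)

    @property
    def T(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spikes.shape[1]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            spikes=self.spikes,
            dt_ms=np.float64(self.dt),
            label=np.int64(-1 if self.label is None else self.label),
        )

    @classmethod
    def load(cls, path) -> "SpikeRaster":
        with np.load(path) as f:
            label = int(f["label"])
            return cls(
                spikes=f["spikes"],
                dt=float(f["dt_ms"]),
                label=None if label < 0 else label,
            )


@dataclass
class NetworkParams:
    """Weights, continuous delay parameters, masks and delay flavors.

    Delay arrays are per-synapse (shape of the weight matrix) for the
    ``synaptic`` flavor and per-presynaptic-neuron for the ``axonal``
    flavor; ``none`` means a fixed zero integer delay.  Masked weight
    entries are held at exactly zero.  The readout carries no delays.
    """

    W_in: np.ndarray
    W_out: np.ndarray
    W_rec: Optional[np.ndarray] = None
    D_in: Optional[np.ndarray] = None
    D_rec: Optional[np.ndarray] = None
    mask_in: Optional[np.ndarray] = None
    mask_rec: Optional[np.ndarray] = None
    flavor_in: DelayFlavor = "none"
    flavor_rec: DelayFlavor = "none"

    def __post_init__(self) -> None:
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        if self.W_rec is not None:
            self.W_rec = np.asarray(self.W_rec, dtype=float)
            if self.W_rec.shape != (self.n_hidden, self.n_hidden):
                raise ValueError("W_rec must be n_hidden x n_hidden")
            np.fill_diagonal(self.W_rec, 0.0)
        for name in ("D_in", "D_rec"):
            d = getattr(self, name)
            if d is not None:
                setattr(self, name, np.asarray(d, dtype=float))
        self._check_flavor("in", self.flavor_in, self.D_in, self.W_in.shape)
        if self.W_rec is not None:
            self._check_flavor("rec", self.flavor_rec, self.D_rec, self.W_rec.shape)
        for W, mask in ((self.W_in, self.mask_in), (self.W_rec, self.mask_rec)):
            if mask is not None and W is not None:
                W *= np.asarray(mask, dtype=float)

    def _check_flavor(self, proj, flavor, D, wshape) -> None:
        if flavor == "none":
            if D is not None:
                raise ValueError(f"D_{proj} given but flavor_{proj} is 'none'")
            return
        if D is None:
            raise ValueError(f"flavor_{proj}='{flavor}' requires D_{proj}")
        expect = wshape if flavor == "synaptic" else (wshape[1],)
        if D.shape != expect:
            raise ValueError(f"D_{proj} shape {D.shape} != {expect} for '{flavor}'")

    @property
    def n_in(self) -> int:
        return self.W_in.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_in.shape[0]

    @property
    def n_out(self) -> int:
        return self.W_out.shape[0]

    @property
    def recurrent(self) -> bool:
        return self.W_rec is not None

    def eff_in(self, D_max: int) -> Optional[np.ndarray]:
        return None if self.D_in is None else effective_delay(self.D_in, D_max)

    def eff_rec(self, D_max: int) -> Optional[np.ndarray]:
        return None if self.D_rec is None else effective_delay(self.D_rec, D_max)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            W_in=self.W_in.copy(),
            W_out=self.W_out.copy(),
            W_rec=None if self.W_rec is None else self.W_rec.copy(),
            D_in=None if self.D_in is None else self.D_in.copy(),
            D_rec=None if self.D_rec is None else self.D_rec.copy(),
            mask_in=None if self.mask_in is None else self.mask_in.copy(),
            mask_rec=None if self.mask_rec is None else self.mask_rec.copy(),
            flavor_in=self.flavor_in,
            flavor_rec=self.flavor_rec,
        )


def _delay_shape(flavor: DelayFlavor, wshape: tuple[int, int]):
    return None if flavor == "none" else (wshape if flavor == "synaptic" else (wshape[1],))


def init_network(
    n_in: int,
    n_hidden: int,
    n_out: int,
    sim: SimParams,
    flavor_in: DelayFlavor = "none",
    flavor_rec: DelayFlavor = "none",
    recurrent: bool = False,
    density: float = 1.0,
    rng: np.random.Generator | int | None = None,
    delay_init: Literal["uniform", "center", "uniform_integer"] = "uniform",
) -> NetworkParams:
    """Seeded initialization: zero-mean uniform weights scaled by 1/sqrt(fan-in).

    ``delay_init`` draws continuous delays uniformly over the legal range
    (default), sets them all to the range midpoint ("center"), or draws
    integer-valued delays uniformly ("uniform_integer", the fixed-delay
    control condition).  ``density`` < 1 applies fixed Bernoulli sparsity
    masks to both the input and recurrent weight matrices.
    """
    rng = np.random.default_rng(rng)
    b = sim.delay_bound

    def w(shape, fan_in):
        lim = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-lim, lim, size=shape)

    def d(shape):
        if shape is None:
            return None
        if delay_init == "center":
            return np.zeros(shape)
        if delay_init == "uniform_integer":
            return rng.integers(0, sim.D_max, size=shape).astype(float) - b
        return rng.uniform(-b, b, size=shape)

    W_in = w((n_hidden, n_in), n_in)
    W_out = w((n_out, n_hidden), n_hidden)
    W_rec = w((n_hidden, n_hidden), n_hidden) if recurrent else None
    mask_in = mask_rec = None
    if density < 1.0:
        mask_in = (rng.random((n_hidden, n_in)) < density).astype(np.uint8)
        if recurrent:
            mask_rec = (rng.random((n_hidden, n_hidden)) < density).astype(np.uint8)
    return NetworkParams(
        W_in=W_in,
        W_out=W_out,
        W_rec=W_rec,
        D_in=d(_delay_shape(flavor_in, (n_hidden, n_in))),
        D_rec=d(_delay_shape(flavor_rec, (n_hidden, n_hidden))) if recurrent else None,
        mask_in=mask_in,
        mask_rec=mask_rec,
        flavor_in=flavor_in,
        flavor_rec=flavor_rec if recurrent else "none",
    )


class _RingBuffer:
    """Fixed-depth history of binary vectors addressed by age (0 = newest)."""

    def __init__(self, depth: int, n: int):
        self.depth = depth
        self.n = n
        self.buf = np.zeros((depth, n))
        self.ptr = 0  # row holding the newest entry

    def push(self, row: np.ndarray) -> None:
        self.ptr = (self.ptr + 1) % self.depth
        self.buf[self.ptr] = row

    def get(self, age: np.ndarray | int) -> np.ndarray:
        """Entries ``age`` steps back.  Scalar or per-channel integer ages
        return vectors; an (m, n) age matrix gathers per-(row, channel)."""
        age = np.asarray(age)
        if age.ndim == 0:
            return self.buf[(self.ptr - int(age)) % self.depth]
        rows = (self.ptr - age) % self.depth
        if age.ndim == 1:
            return self.buf[rows, np.arange(self.n)]
        return self.buf[rows, np.arange(self.n)[None, :]]

    def copy(self) -> "_RingBuffer":
        out = _RingBuffer(self.depth, self.n)
        out.buf = self.buf.copy()
        out.ptr = self.ptr
        return out


@dataclass
class NeuronState:
    """Membrane, spike, readout state and delay ring buffers at one step."""

    v: np.ndarray
    z: np.ndarray
    y: np.ndarray
    in_buffer: _RingBuffer
    rec_buffer: Optional[_RingBuffer]
    t: int = 0

    @classmethod
    def zeros(cls, params: NetworkParams, sim: SimParams) -> "NeuronState":
        return cls(
            v=np.zeros(params.n_hidden),
            z=np.zeros(params.n_hidden),
            y=np.zeros(params.n_out),
            in_buffer=_RingBuffer(sim.D_max, params.n_in),
            rec_buffer=_RingBuffer(sim.D_max + 1, params.n_hidden)
            if params.recurrent
            else None,
        )

    def copy(self) -> "NeuronState":
        return NeuronState(
            v=self.v.copy(),
            z=self.z.copy(),
            y=self.y.copy(),
            in_buffer=self.in_buffer.copy(),
            rec_buffer=None if self.rec_buffer is None else self.rec_buffer.copy(),
            t=self.t,
        )


def _projected_drive(
    W: np.ndarray, buffer: _RingBuffer, eff: Optional[np.ndarray], base_age: int
) -> np.ndarray:
    """Sum_i W[j,i] * s_i[t - base_age - D] fetched from a ring buffer."""
    if eff is None:
        rows = buffer.get(base_age)
        return W @ rows
    if eff.ndim == 1:  # axonal: shared per presynaptic channel
        return W @ buffer.get(base_age + eff)
    return np.sum(W * buffer.get(base_age + eff), axis=1)  # synaptic


def lif_step(
    state: NeuronState,
    x_t: np.ndarray,
    params: NetworkParams,
    sim: SimParams,
) -> NeuronState:
    """Advance the hidden layer by one step (mutates and returns ``state``).

    ``x_t`` is the current input raster row; delayed rows are fetched from
    the input ring buffer through the integer effective delays.  The reset
    subtracts v_th on the step after a spike (soft reset).
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (params.n_in,):
        raise ValueError(
            f"input row has {x_t.shape} channels, W_in expects {params.n_in}"
        )
    state.in_buffer.push(x_t)
    drive = _projected_drive(params.W_in, state.in_buffer, params.eff_in(sim.D_max), 0)
    if params.recurrent:
        drive = drive + _projected_drive(
            params.W_rec, state.rec_buffer, params.eff_rec(sim.D_max), 1
        )
    state.v = sim.alpha * state.v + drive - state.z * sim.v_th
    state.z = (state.v > sim.v_th).astype(float)
    if state.rec_buffer is not None:
        state.rec_buffer.push(state.z)
    state.t += 1
    return state


def srnn_step(
    state: NeuronState, x_t: np.ndarray, params: NetworkParams, sim: SimParams
) -> NeuronState:
    """Recurrent step: as lif_step plus W_rec applied to z[t-1-D_rec]."""
    if not params.recurrent:
        raise ValueError("srnn_step requires W_rec")
    return lif_step(state, x_t, params, sim)


def readout_step(state: NeuronState, params: NetworkParams, sim: SimParams) -> NeuronState:
    """Leaky-integrator readout: y <- kappa*y + W_out @ z, no reset/delays."""
    state.y = sim.kappa * state.y + params.W_out @ state.z
    return state


@dataclass
class Trajectory:
    """Per-step records of a forward pass and the resulting classification."""

    v: np.ndarray  # (T, n_hidden)
    z: np.ndarray  # (T, n_hidden)
    y: np.ndarray  # (T, n_out)
    pi: np.ndarray  # (T, n_out) softmax rows
    loss_steps: np.ndarray  # (T,) per-step cross entropy (0 if no label)
    loss: float
    pred: int
    label: Optional[int]


def forward_pass(
    raster: SpikeRaster,
    params: NetworkParams,
    sim: SimParams,
    label: Optional[int] = None,
    state: Optional[NeuronState] = None,
) -> Trajectory:
    """Simulate the full sequence and evaluate loss and prediction.

    The cross-entropy loss is E = -sum_t log pi_hat[label, t] (one-hot
    target); the predicted label is the argmax of the time-summed softmax.
    Pass ``state`` to resume simulation from carried state (the update is
    Markov, so chunked simulation matches a single run).
    """
    if label is not None and not (0 <= label < params.n_out):
        raise ValueError(f"label {label} outside [0, {params.n_out})")
    X = raster.spikes
    T = X.shape[0]
    st = NeuronState.zeros(params, sim) if state is None else state
    v = np.empty((T, params.n_hidden))
    z = np.empty((T, params.n_hidden))
    y = np.empty((T, params.n_out))
    for s in range(T):
        lif_step(st, X[s], params, sim)
        readout_step(st, params, sim)
        v[s], z[s], y[s] = st.v, st.z, st.y
    pi = softmax(y, axis=1)
    logpi = log_softmax(y, axis=1)
    loss_steps = -logpi[:, label] if label is not None else np.zeros(T)
    return Trajectory(
        v=v,
        z=z,
        y=y,
        pi=pi,
        loss_steps=loss_steps,
        loss=float(loss_steps.sum()),
        pred=int(np.argmax(pi.sum(axis=0))),
        label=label,
    )


def save_checkpoint(
    path,
    params: NetworkParams,
    sim: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Single-archive model checkpoint (weights, delays, masks, SimParams, RNG)."""
    import json

    blob = {
        "W_in": params.W_in,
        "W_out": params.W_out,
        "flavor_in": np.bytes_(params.flavor_in.encode()),
        "flavor_rec": np.bytes_(params.flavor_rec.encode()),
        "sim": np.array([sim.alpha, sim.kappa, sim.v_th, sim.dt, sim.T, sim.D_max]),
    }
    for name in ("W_rec", "D_in", "D_rec", "mask_in", "mask_rec"):
        arr = getattr(params, name)
        if arr is not None:
            blob[name] = arr
    if rng is not None:
        blob["rng_state"] = np.bytes_(json.dumps(rng.bit_generator.state).encode())
    np.savez_compressed(path, **blob)


def load_checkpoint(
    path, with_rng: bool = False
) -> tuple[NetworkParams, SimParams] | tuple[NetworkParams, SimParams, np.random.Generator]:
    import json

    with np.load(path) as f:
        get = lambda k: f[k] if k in f.files else None
        a, k_, vth, dt, T, dmax = f["sim"]
        sim = SimParams(alpha=float(a), kappa=float(k_), v_th=float(vth),
                        dt=float(dt), T=int(T), D_max=int(dmax))
        params = NetworkParams(
            W_in=f["W_in"],
            W_out=f["W_out"],
            W_rec=get("W_rec"),
            D_in=get("D_in"),
            D_rec=get("D_rec"),
            mask_in=get("mask_in"),
            mask_rec=get("mask_rec"),
            flavor_in=bytes(f["flavor_in"]).decode(),
            flavor_rec=bytes(f["flavor_rec"]).decode(),
        )
        if with_rng:
            rng = np.random.default_rng()
            if "rng_state" in f.files:
                rng.bit_generator.state = json.loads(bytes(f["rng_state"]).decode())
            return params, sim, rng
    return params, sim
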