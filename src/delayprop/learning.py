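"""Online three-factor learning of weights and synaptic/axonal delays.

Every parameter update is the product of three locally available factors:

* a top-down learning signal ``L_j^t = dE/dz_j^t`` carrying task error from
  the readout back to hidden neuron ``j``,
* the threshold pseudo-derivative ``psi_j^t`` evaluated at the current
  membrane potential, and
* a low-pass eligibility vector ``eps`` that filters, with the membrane
  decay ``alpha``, either the delayed presynaptic activity (weight rule) or
  the weighted Gaussian delay-derivative drive (delay rule).

The exact learning signal involves a sum over *future* errors discounted by
the readout decay ``kappa``.  Two implementations are provided:

* :func:`train_sequence` — the true online form.  The acausal sum is
  refactorized into a ``kappa``-filtered eligibility trace multiplied by
  the instantaneous readout error (the standard eligibility-propagation
  identity), so a single forward sweep suffices and all learning state is
  bounded by the delay range and the kernel window, independent of the
  sequence length.  Because the Gaussian kernel is non-causal, the
  learning-side computation runs ``ceil(k/2)`` steps behind the dynamics
  when recurrent delays are learnable (the extra buffering equal to half
  the kernel size).
* :func:`offline_sequence_gradients` — evaluates the future sum literally
  from a stored trajectory; used as a cross-check and by the oracle tests.

Both produce identical gradients up to floating-point ordering.  On
feedforward networks they equal the locality-matched unrolled reference
gradient exactly; on recurrent networks they drop credit flowing through
recurrent spikes and the reset (the eligibility-propagation approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .core import (
    NetworkParams,
    SimParams,
    SpikeRaster,
    delay_shift,
    effective_delay,
    forward_pass,
)
from .surrogates import (
    GaussianKernel,
    SpikeSurrogateParams,
    gaussian_delay_derivative,
    spike_surrogate,
)

__all__ = [
    "LearnRates",
    "EligibilityState",
    "learning_signal",
    "offline_learning_signal",
    "weight_eligibility_update",
    "delay_eligibility_update",
    "accumulate_gradients",
    "apply_updates",
    "train_sequence",
    "offline_sequence_gradients",
]


@dataclass(frozen=True)
class LearnRates:
    """Step sizes: 1e-4 for weights, 1e-2 for delays, batches of 16."""

    lr_w: float = 1e-4
    lr_d: float = 1e-2
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.lr_w <= 0 or self.lr_d <= 0 or self.batch_size <= 0:
            raise ValueError("learning rates and batch size must be positive")


def _onehot(label: int, n_out: int) -> np.ndarray:
    pi = np.zeros(n_out)
    pi[label] = 1.0
    return pi


def learning_signal(pi_hat_t: np.ndarray, pi_star: np.ndarray, W_out: np.ndarray) -> np.ndarray:
    """Instantaneous per-hidden-neuron error signal W_out^T (pi_hat - pi*).

    In the online rule the kappa^{t'-t} discounting of the exact signal is
    absorbed into kappa-filtered eligibility traces, so this instantaneous
    form is all the update needs.
    """
    return W_out.T @ (np.asarray(pi_hat_t) - np.asarray(pi_star))


def offline_learning_signal(
    pi: np.ndarray, label: int, W_out: np.ndarray, kappa: float
) -> np.ndarray:
    """Exact learning signal L_j^t = sum_{t'>=t} kappa^{t'-t} c_j^{t'}.

    ``pi`` is the (T, n_out) softmax trajectory.  Evaluates the acausal sum
    literally (backward recursion); used by oracle and consistency tests.
    """
    c = (pi - _onehot(label, pi.shape[1])[None, :]) @ W_out  # (T, n_hidden)
    L = np.zeros_like(c)
    acc = np.zeros(c.shape[1])
    for t in range(c.shape[0] - 1, -1, -1):
        acc = c[t] + kappa * acc
        L[t] = acc
    return L


def weight_eligibility_update(
    eps: np.ndarray, psi: np.ndarray, delayed_inputs: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the weight eligibility recursion.

    eps <- alpha * eps + x[t-D]; e = psi * eps.  ``delayed_inputs`` is a
    per-synapse matrix for per-synapse delays or a per-channel vector
    otherwise (the trace then factorizes over postsynaptic neurons).
    Returns (new eps, per-synapse e matrix).
    """
    eps = alpha * eps + delayed_inputs
    e = psi[:, None] * (eps if eps.ndim == 2 else eps[None, :])
    return eps, e


def delay_eligibility_update(
    eps: np.ndarray, psi: np.ndarray, drive: np.ndarray, alpha: float, W: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the delay eligibility recursion.

    eps <- alpha * eps + drive, where drive is W_ji * d x_hat_i(t-D)/dD for
    per-synapse delays (matrix) or the shared kernel-derivative trace
    d x_hat_i/dD for axonal delays (vector; pass ``W`` so the per-synapse
    e matrix W_ji * psi_j * eps_i can be formed).  Returns (new eps, e).
    """
    eps = alpha * eps + drive
    if eps.ndim == 2:
        e = psi[:, None] * eps
    else:
        if W is None:
            raise ValueError("axonal delay eligibility needs the weight matrix")
        e = psi[:, None] * W * eps[None, :]
    return eps, e


def accumulate_gradients(grad: np.ndarray, L_t: np.ndarray, e_t: np.ndarray) -> np.ndarray:
    """dE/dtheta += L_j^t * e_ji^t; axonal (vector) accumulators sum the
    contributions of all postsynaptic neurons sharing the parameter."""
    contrib = L_t[:, None] * e_t
    if grad.ndim == 1:
        grad += contrib.sum(axis=0)
    else:
        grad += contrib
    return grad


@dataclass
class EligibilityState:
    """Per-parameter eligibility vectors, filtered traces and gradients.

    ``eps_*`` are the alpha-filtered eligibility vectors (per-synapse
    matrices for synaptic delays, per-presynaptic-channel vectors
    otherwise); ``filt_*`` the kappa-filtered per-synapse traces multiplied
    against the instantaneous error in online mode; ``filtered_z`` the
    kappa-filtered hidden spikes for the readout rule.  ``grads`` accumulate
    across a batch; traces reset between sequences.
    """

    params: NetworkParams
    eps_w_in: np.ndarray = field(init=False)
    filt_w_in: np.ndarray = field(init=False)
    eps_d_in: Optional[np.ndarray] = field(init=False, default=None)
    filt_d_in: Optional[np.ndarray] = field(init=False, default=None)
    eps_w_rec: Optional[np.ndarray] = field(init=False, default=None)
    filt_w_rec: Optional[np.ndarray] = field(init=False, default=None)
    eps_d_rec: Optional[np.ndarray] = field(init=False, default=None)
    filt_d_rec: Optional[np.ndarray] = field(init=False, default=None)
    filtered_z: np.ndarray = field(init=False)
    grads: dict = field(init=False)
    n_seq: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        p = self.params
        self.grads = {"W_in": np.zeros_like(p.W_in), "W_out": np.zeros_like(p.W_out)}
        if p.recurrent:
            self.grads["W_rec"] = np.zeros_like(p.W_rec)
        if p.D_in is not None:
            self.grads["D_in"] = np.zeros_like(p.D_in)
        if p.D_rec is not None:
            self.grads["D_rec"] = np.zeros_like(p.D_rec)
        self.reset_traces()

    def reset_traces(self) -> None:
        p = self.params
        nh, ni = p.n_hidden, p.n_in
        self.eps_w_in = np.zeros((nh, ni)) if p.flavor_in == "synaptic" else np.zeros(ni)
        self.filt_w_in = np.zeros((nh, ni))
        self.filtered_z = np.zeros(nh)
        if p.D_in is not None:
            self.eps_d_in = (
                np.zeros((nh, ni)) if p.flavor_in == "synaptic" else np.zeros(ni)
            )
            self.filt_d_in = np.zeros((nh, ni))
        if p.recurrent:
            self.eps_w_rec = (
                np.zeros((nh, nh)) if p.flavor_rec == "synaptic" else np.zeros(nh)
            )
            self.filt_w_rec = np.zeros((nh, nh))
            if p.D_rec is not None:
                self.eps_d_rec = (
                    np.zeros((nh, nh)) if p.flavor_rec == "synaptic" else np.zeros(nh)
                )
                self.filt_d_rec = np.zeros((nh, nh))

    def clear_grads(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0
        self.n_seq = 0


def apply_updates(
    params: NetworkParams,
    elig: EligibilityState,
    rates: LearnRates,
    sim: SimParams,
    learn_w: bool = True,
    learn_d: bool = True,
) -> NetworkParams:
    """Plain gradient descent on the batch-mean gradients.

    Continuous delays are clamped to [-(D_max-1)/2, +(D_max-1)/2]; masked
    weights (and the recurrent diagonal) stay exactly zero; gradient
    accumulators are cleared.
    """
    n = max(elig.n_seq, 1)
    b = sim.delay_bound
    if learn_w:
        step = rates.lr_w / n
        gW = elig.grads["W_in"]
        if params.mask_in is not None:
            gW = gW * params.mask_in
        params.W_in -= step * gW
        if params.mask_in is not None:
            params.W_in *= params.mask_in
        params.W_out -= step * elig.grads["W_out"]
        if params.recurrent:
            gR = elig.grads["W_rec"]
            if params.mask_rec is not None:
                gR = gR * params.mask_rec
            params.W_rec -= step * gR
            np.fill_diagonal(params.W_rec, 0.0)
            if params.mask_rec is not None:
                params.W_rec *= params.mask_rec
    if learn_d:
        step = rates.lr_d / n
        if params.D_in is not None:
            gD = elig.grads["D_in"]
            if params.flavor_in == "synaptic" and params.mask_in is not None:
                gD = gD * params.mask_in
            params.D_in[...] = np.clip(params.D_in - step * gD, -b, b)
        if params.D_rec is not None:
            gD = elig.grads["D_rec"]
            if params.flavor_rec == "synaptic" and params.mask_rec is not None:
                gD = gD * params.mask_rec
            params.D_rec[...] = np.clip(params.D_rec - step * gD, -b, b)
    elig.clear_grads()
    return params


# ---------------------------------------------------------------------------
# kernel-derivative drive: windowed evaluation machinery
# ---------------------------------------------------------------------------


def _kernel_table(
    shift: np.ndarray, kernel: GaussianKernel, D_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-delay-parameter derivative taps on the lag grid.

    Returns (q_grid, K) with K[q, ...] = dN/dD(q - shift) windowed to
    |u| <= k/2, so that the drive at source time s is
    sum_q source[s - q] * K[q].  q spans every lag any legal shift reaches.
    """
    half = kernel.half_window
    ch = int(np.ceil(half))
    q = np.arange(-ch, D_max - 1 + ch + 1, dtype=float)
    u = q.reshape((-1,) + (1,) * shift.ndim) - shift[None, ...]
    K = np.where(np.abs(u) <= half, gaussian_delay_derivative(u, kernel.sigma), 0.0)
    return q.astype(int), K


def _rows_or_zero(X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """X[idx] with rows outside [0, T) replaced by zeros (pre/post silence)."""
    T = X.shape[0]
    idx = np.asarray(idx)
    safe = np.clip(idx, 0, T - 1)
    if idx.ndim == 1:  # per-channel: value X[idx[i], i]
        out = X[safe, np.arange(X.shape[1])].astype(float)
    else:  # (n_h, n_src) per-synapse: value X[idx[j, i], i]
        out = X[safe, np.arange(X.shape[1])[None, :]].astype(float)
    out[(idx < 0) | (idx >= T)] = 0.0
    return out


def _drive_at(
    X: np.ndarray, s: int, q_grid: np.ndarray, K: np.ndarray
) -> np.ndarray:
    """Kernel-derivative drive at a single source time s from rows X[s - q]."""
    idx = (s - q_grid)[:, None] + np.zeros((1, X.shape[1]), dtype=int)
    win = _rows_or_zero(X, idx)  # (n_q, n_src)
    if K.ndim == 2:  # axonal: (n_q, n_src)
        return np.einsum("qi,qi->i", win, K)
    return np.einsum("qi,qji->ji", win, K)  # synaptic: (n_q, n_h, n_src)


class _SpikeWindow:
    """Bounded rolling window of hidden-spike rows, absolute-time addressed.

    Rows with index < 1 (before the sequence) or beyond the newest written
    state read as zeros; the window is deep enough for every delayed read
    the learning rules perform.
    """

    def __init__(self, depth: int, n: int):
        self.depth = depth
        self.buf = np.zeros((depth, n))
        self.newest = 0

    def push(self, idx: int, row: np.ndarray) -> None:
        self.buf[idx % self.depth] = row
        self.newest = idx

    def rows(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        out = self.buf[idx % self.depth].copy()
        out[(idx < 1) | (idx > self.newest)] = 0.0
        return out

    def gather(self, idx: np.ndarray) -> np.ndarray:
        """Per-channel delayed read: vector idx -> vector, matrix -> matrix."""
        idx = np.asarray(idx)
        n = self.buf.shape[1]
        if idx.ndim == 1:
            out = self.buf[idx % self.depth, np.arange(n)].copy()
        else:
            out = self.buf[idx % self.depth, np.arange(n)[None, :]].copy()
        out[(idx < 1) | (idx > self.newest)] = 0.0
        return out


def _shifts(params: NetworkParams, sim: SimParams, rounded: bool):
    """Continuous (default) or rounded delay shifts used inside the kernel."""
    out = {}
    for name, D in (("in", params.D_in), ("rec", params.D_rec)):
        if D is None:
            out[name] = None
        elif rounded:
            out[name] = effective_delay(D, sim.D_max).astype(float)
        else:
            out[name] = delay_shift(D, sim.D_max)
    return out


def train_sequence(
    raster: SpikeRaster,
    label: int,
    params: NetworkParams,
    elig: EligibilityState,
    sim: SimParams,
    kernel: Optional[GaussianKernel] = None,
    surr: Optional[SpikeSurrogateParams] = None,
    learn_w: bool = True,
    learn_d: bool = True,
    use_rounded_shift: bool = False,
) -> float:
    """One online sweep: dynamics, surrogates, learning signal, eligibility
    updates and gradient accumulation, all within a single forward pass.

    Learning state is bounded by the delay range and the kernel window
    (plus a look-ahead of ceil(k/2) steps when recurrent delays are
    learnable, covering the non-causal half of the kernel); nothing scales
    with the sequence length.  Gradients accumulate into ``elig.grads``;
    per-sequence traces are reset on entry.  Returns the sequence loss.
    """
    kernel = kernel or GaussianKernel()
    surr = surr or SpikeSurrogateParams(v_th=sim.v_th)
    p = params
    if not (0 <= label < p.n_out):
        raise ValueError(f"label {label} outside [0, {p.n_out})")
    X = raster.spikes
    T = X.shape[0]
    pi_star = _onehot(label, p.n_out)
    elig.reset_traces()
    elig.n_seq += 1

    learn_d_in = learn_d and p.D_in is not None
    learn_d_rec = learn_d and p.D_rec is not None
    shifts = _shifts(p, sim, use_rounded_shift)
    q_in = K_in = q_rec = K_rec = None
    if learn_d_in:
        q_in, K_in = _kernel_table(shifts["in"], kernel, sim.D_max)
    if learn_d_rec:
        q_rec, K_rec = _kernel_table(shifts["rec"], kernel, sim.D_max)

    eff_in = p.eff_in(sim.D_max)
    eff_rec = p.eff_rec(sim.D_max)
    lag = int(np.ceil(kernel.half_window)) if learn_d_rec else 0

    zwin = None
    if p.recurrent:
        depth = sim.D_max + 2 * int(np.ceil(kernel.half_window)) + 4
        zwin = _SpikeWindow(depth, p.n_hidden)

    # Input-side quantities depend only on the raster; precompute them in
    # fixed-length blocks so the per-step work is a handful of small array
    # ops while learning memory stays bounded regardless of T.
    BLK = 64
    blocks: dict[int, tuple] = {}

    def _input_block(bi: int) -> tuple:
        lo = bi * BLK + 1
        taus = np.arange(lo, min(lo + BLK, T + 1))
        if eff_in is None:
            A = X[taus - 1].astype(float)
        elif eff_in.ndim == 1:
            A = _stacked_rows(X, taus[:, None] - 1 - eff_in[None, :])
        else:
            A = _stacked_gather(X, taus[:, None, None] - 1 - eff_in[None])
        G = _drive_series(X, taus, q_in, K_in) if learn_d_in else None
        return A, G

    from collections import deque

    pending: deque = deque()
    loss = 0.0
    kap, alf = sim.kappa, sim.alpha
    v = np.zeros(p.n_hidden)
    z = np.zeros(p.n_hidden)
    y = np.zeros(p.n_out)
    W_outT = p.W_out.T.copy()

    for s_wall in range(T + lag):
        bi = s_wall // BLK
        if bi not in blocks and s_wall < T:
            blocks[bi] = _input_block(bi)
            blocks.pop(bi - 2, None)
        if s_wall < T:
            a_dyn = blocks[bi][0][s_wall % BLK]
            drive = (
                np.sum(p.W_in * a_dyn, axis=1) if a_dyn.ndim == 2 else p.W_in @ a_dyn
            )
            if p.recurrent:
                sr = s_wall - 1
                if eff_rec is None:
                    z_del = zwin.gather(np.full(p.n_hidden, sr))
                else:
                    z_del = zwin.gather(sr - eff_rec)
                drive = drive + (
                    np.sum(p.W_rec * z_del, axis=1)
                    if z_del.ndim == 2
                    else p.W_rec @ z_del
                )
            v = alf * v + drive - z * sim.v_th
            z = (v > sim.v_th).astype(float)
            if zwin is not None:
                zwin.push(s_wall + 1, z)
            y = kap * y + p.W_out @ z
            m = y.max()
            logz = m + np.log(np.exp(y - m).sum())
            pi = np.exp(y - logz)
            loss += logz - y[label]
            pending.append(
                (spike_surrogate(v, surr), W_outT @ (pi - pi_star), pi, z)
            )
        tau = s_wall + 1 - lag
        if not 1 <= tau <= T:
            continue
        psi, c, pi, z_tau = pending.popleft()
        row = (tau - 1) % BLK
        A_blk, G_blk = blocks[(tau - 1) // BLK]

        # -- readout weights (standard filtered-spike rule)
        if learn_w:
            elig.filtered_z = kap * elig.filtered_z + z_tau
            elig.grads["W_out"] += np.outer(pi - pi_star, elig.filtered_z)

        # -- input projection
        if learn_w:
            a = A_blk[row]
            elig.eps_w_in, e_w = weight_eligibility_update(elig.eps_w_in, psi, a, alf)
            if p.mask_in is not None:
                e_w = e_w * p.mask_in
            elig.filt_w_in = kap * elig.filt_w_in + e_w
            accumulate_gradients(elig.grads["W_in"], c, elig.filt_w_in)
        if learn_d_in:
            g = G_blk[row]
            drive = p.W_in * g if p.flavor_in == "synaptic" else g
            elig.eps_d_in, e_d = delay_eligibility_update(
                elig.eps_d_in, psi, drive, alf, W=p.W_in
            )
            if p.flavor_in == "synaptic" and p.mask_in is not None:
                e_d = e_d * p.mask_in
            elig.filt_d_in = kap * elig.filt_d_in + e_d
            accumulate_gradients(elig.grads["D_in"], c, elig.filt_d_in)

        # -- recurrent projection (sources are hidden spikes, one extra
        #    mandatory step of latency: z[tau-2-D])
        if p.recurrent:
            s_rec = tau - 2
            if learn_w:
                if eff_rec is not None:
                    a_rec = zwin.gather(s_rec - eff_rec)
                else:
                    a_rec = zwin.gather(np.full(p.n_hidden, s_rec))
                elig.eps_w_rec, e_w = weight_eligibility_update(
                    elig.eps_w_rec, psi, a_rec, alf
                )
                if p.mask_rec is not None:
                    e_w = e_w * p.mask_rec
                np.fill_diagonal(e_w, 0.0)
                elig.filt_w_rec = kap * elig.filt_w_rec + e_w
                accumulate_gradients(elig.grads["W_rec"], c, elig.filt_w_rec)
            if learn_d_rec:
                win = zwin.rows(s_rec - q_rec)  # (n_q, n_hidden)
                if K_rec.ndim == 2:
                    g = np.einsum("qi,qi->i", win, K_rec)
                else:
                    g = np.einsum("qi,qji->ji", win, K_rec)
                drive = p.W_rec * g if p.flavor_rec == "synaptic" else g
                elig.eps_d_rec, e_d = delay_eligibility_update(
                    elig.eps_d_rec, psi, drive, alf, W=p.W_rec
                )
                if p.flavor_rec == "synaptic" and p.mask_rec is not None:
                    e_d = e_d * p.mask_rec
                elig.filt_d_rec = kap * elig.filt_d_rec + e_d
                accumulate_gradients(elig.grads["D_rec"], c, elig.filt_d_rec)
    return float(loss)


def offline_sequence_gradients(
    raster: SpikeRaster,
    label: int,
    params: NetworkParams,
    sim: SimParams,
    kernel: Optional[GaussianKernel] = None,
    surr: Optional[SpikeSurrogateParams] = None,
    use_rounded_shift: bool = False,
) -> tuple[dict, float]:
    """Three-factor gradients with the learning signal evaluated literally.

    Stores the full trajectory (test scale) and applies the exact acausal
    learning signal to the alpha-filtered eligibility traces.  Identical to
    :func:`train_sequence` up to floating-point summation order.
    """
    kernel = kernel or GaussianKernel()
    surr = surr or SpikeSurrogateParams(v_th=sim.v_th)
    p = params
    X = raster.spikes
    T = X.shape[0]
    traj = forward_pass(raster, p, sim, label=label)
    psi = spike_surrogate(traj.v, surr)  # (T, n_h)
    err = traj.pi - _onehot(label, p.n_out)[None, :]
    L = offline_learning_signal(traj.pi, label, p.W_out, sim.kappa)
    grads = {}

    # readout: kappa-filtered hidden spikes
    zhat = lfilter([1.0], [1.0, -sim.kappa], traj.z, axis=0)
    grads["W_out"] = np.einsum("tk,tj->kj", err, zhat)

    eff_in = p.eff_in(sim.D_max)
    taus = np.arange(1, T + 1)
    if eff_in is None:
        A = _stacked_rows(X, taus[:, None] - 1 + np.zeros((1, p.n_in), dtype=int))
        A = A  # (T, n_in)
    elif eff_in.ndim == 1:
        A = _stacked_rows(X, taus[:, None] - 1 - eff_in[None, :])
    else:
        A = _stacked_gather(X, taus[:, None, None] - 1 - eff_in[None, :, :])
    eps = lfilter([1.0], [1.0, -sim.alpha], A, axis=0)
    e = psi[:, :, None] * (eps if eps.ndim == 3 else eps[:, None, :])
    if p.mask_in is not None:
        e = e * p.mask_in
    grads["W_in"] = np.einsum("tj,tji->ji", L, e)

    shifts = _shifts(p, sim, use_rounded_shift)
    if p.D_in is not None:
        q, K = _kernel_table(shifts["in"], kernel, sim.D_max)
        G = _drive_series(X, taus, q, K)
        drive = p.W_in[None] * G if p.flavor_in == "synaptic" else G
        eps_d = lfilter([1.0], [1.0, -sim.alpha], drive, axis=0)
        if p.flavor_in == "synaptic":
            e_d = psi[:, :, None] * eps_d
            if p.mask_in is not None:
                e_d = e_d * p.mask_in
            grads["D_in"] = np.einsum("tj,tji->ji", L, e_d)
        else:
            e_d = psi[:, :, None] * p.W_in[None] * eps_d[:, None, :]
            grads["D_in"] = np.einsum("tj,tji->i", L, e_d)

    if p.recurrent:
        Z = np.vstack([np.zeros((1, p.n_hidden)), traj.z])  # Z[m] = z^m, z^0 = 0
        eff_rec = p.eff_rec(sim.D_max)
        if eff_rec is None:
            idx = taus[:, None] - 2 + np.zeros((1, p.n_hidden), dtype=int)
            Ar = _stacked_rows(Z, idx, first_valid=0)
        elif eff_rec.ndim == 1:
            Ar = _stacked_rows(Z, taus[:, None] - 2 - eff_rec[None, :], first_valid=0)
        else:
            Ar = _stacked_gather(Z, taus[:, None, None] - 2 - eff_rec[None], first_valid=0)
        eps_r = lfilter([1.0], [1.0, -sim.alpha], Ar, axis=0)
        e_r = psi[:, :, None] * (eps_r if eps_r.ndim == 3 else eps_r[:, None, :])
        if p.mask_rec is not None:
            e_r = e_r * p.mask_rec
        gW = np.einsum("tj,tji->ji", L, e_r)
        np.fill_diagonal(gW, 0.0)
        grads["W_rec"] = gW
        if p.D_rec is not None:
            q, K = _kernel_table(shifts["rec"], kernel, sim.D_max)
            Gr = _drive_series(Z, taus, q, K, base=-2, first_valid=0)
            drive = p.W_rec[None] * Gr if p.flavor_rec == "synaptic" else Gr
            eps_d = lfilter([1.0], [1.0, -sim.alpha], drive, axis=0)
            if p.flavor_rec == "synaptic":
                e_d = psi[:, :, None] * eps_d
                if p.mask_rec is not None:
                    e_d = e_d * p.mask_rec
                grads["D_rec"] = np.einsum("tj,tji->ji", L, e_d)
            else:
                e_d = psi[:, :, None] * p.W_rec[None] * eps_d[:, None, :]
                grads["D_rec"] = np.einsum("tj,tji->i", L, e_d)
    return grads, traj.loss


def _stacked_rows(X: np.ndarray, idx: np.ndarray, first_valid: int = 0) -> np.ndarray:
    """Per-channel gather X[idx[t, i], i] with out-of-range reads as zero."""
    T = X.shape[0]
    safe = np.clip(idx, 0, T - 1)
    out = X[safe, np.arange(X.shape[1])[None, :]].astype(float)
    out[(idx < first_valid) | (idx >= T)] = 0.0
    return out


def _stacked_gather(X: np.ndarray, idx: np.ndarray, first_valid: int = 0) -> np.ndarray:
    """Per-synapse gather X[idx[t, j, i], i] with out-of-range reads as zero."""
    T = X.shape[0]
    safe = np.clip(idx, 0, T - 1)
    out = X[safe, np.arange(X.shape[1])[None, None, :]].astype(float)
    out[(idx < first_valid) | (idx >= T)] = 0.0
    return out


def _drive_series(
    src: np.ndarray,
    taus: np.ndarray,
    q_grid: np.ndarray,
    K: np.ndarray,
    base: int = -1,
    first_valid: int = 0,
) -> np.ndarray:
    """Kernel-derivative drive for the given steps: row r built from rows
    src[taus[r] + base - q].  ``src`` is the raster (base -1) or the
    zero-prefixed hidden-spike record (base -2)."""
    shape = (len(taus),) + K.shape[1:]
    G = np.zeros(shape)
    for qi, q in enumerate(q_grid):
        rows = _stacked_rows(src, (taus + base - q)[:, None] + np.zeros((1, src.shape[1]), dtype=int), first_valid)
        if K.ndim == 2:
            G += rows * K[qi][None, :]
        else:
            G += rows[:, None, :] * K[qi][None, :, :]
    return G
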