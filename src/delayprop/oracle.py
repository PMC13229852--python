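"""Brute-force unrolled gradient reference.

Reverse-mode differentiation of the full unrolled computation graph, with
the same surrogate substitutions as the online rules: the piecewise-linear
pseudo-derivative at threshold crossings and the Gaussian kernel for delay
paths.  Used to verify the online three-factor rules and to quantify the
eligibility-propagation approximation gap on recurrent networks.

Two credit-assignment modes:

* ``locality_matched`` detaches the reset and recurrent-spike credit paths,
  keeping exactly the derivative terms the online rules factorize; on any
  feedforward configuration it must equal the online gradients to floating
  point.
* ``full`` propagates through everything the surrogates allow (reset and
  recurrent spike consumption included).  On recurrent networks the gap
  between the two modes is the approximation the online rules make; it is
  reported, not asserted.

Two forward variants:

* ``binary`` — the real simulation: binary spikes, delay derivatives from
  the smoothed train substituted only in the backward pass.
* ``relaxed`` — a fully differentiable stand-in (spikes replaced by the C1
  integral of the pseudo-derivative, delayed inputs by the smoothed
  Gaussian train), so central finite differences of the loss converge to
  the ``full``-mode gradient at O(h^2).  Feedforward only.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from scipy.special import log_softmax

from .core import NetworkParams, SimParams, SpikeRaster, delay_shift, effective_delay
from .surrogates import (
    GaussianKernel,
    SpikeSurrogateParams,
    gaussian_delay_derivative,
    gaussian_spike,
    smooth_spike,
    spike_surrogate,
)

__all__ = ["OracleMode", "unrolled_gradient", "relaxed_loss", "compare_gradients"]

OracleMode = Literal["locality_matched", "full"]

_MAX_UNROLL_ELEMS = 5_000_000  # explicit guard: the graph is held in memory


def _onehot(label: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[label] = 1.0
    return v


def _gather(X: np.ndarray, idx: np.ndarray, first_valid: int = 0) -> np.ndarray:
    """Row/elementwise gather with silence outside [first_valid, T)."""
    T = X.shape[0]
    idx = np.asarray(idx)
    safe = np.clip(idx, 0, T - 1)
    if idx.ndim == 1:
        out = X[safe, np.arange(X.shape[1])].astype(float)
    else:
        out = X[safe, np.arange(X.shape[1])[None, :]].astype(float)
    out[(idx < first_valid) | (idx >= T)] = 0.0
    return out


def _tables(shift: np.ndarray, kernel: GaussianKernel, D_max: int):
    """Windowed Gaussian and derivative taps per lag q for every shift."""
    half = kernel.half_window
    ch = int(np.ceil(half))
    q = np.arange(-ch, D_max - 1 + ch + 1)
    u = q.astype(float).reshape((-1,) + (1,) * shift.ndim) - shift[None, ...]
    inwin = np.abs(u) <= half
    Kg = np.where(inwin, gaussian_spike(u, kernel.sigma), 0.0)
    Kd = np.where(inwin, gaussian_delay_derivative(u, kernel.sigma), 0.0)
    return q, Kg, Kd


def _conv_at(src: np.ndarray, s: int, q: np.ndarray, K: np.ndarray, first_valid: int = 0):
    win = _gather(src, (s - q)[:, None] + np.zeros((1, src.shape[1]), dtype=int), first_valid)
    if K.ndim == 2:
        return np.einsum("qi,qi->i", win, K)
    return np.einsum("qi,qji->ji", win, K)


def _check_size(T: int, p: NetworkParams) -> None:
    elems = T * p.n_hidden * max(p.n_in, p.n_hidden if p.recurrent else 1)
    if elems > _MAX_UNROLL_ELEMS:
        raise MemoryError(
            f"unrolled graph of ~{elems} elements exceeds the oracle size guard; "
            "the oracle is meant for test-scale problems"
        )


def unrolled_gradient(
    raster: SpikeRaster,
    label: int,
    params: NetworkParams,
    sim: SimParams,
    kernel: Optional[GaussianKernel] = None,
    surr: Optional[SpikeSurrogateParams] = None,
    mode: OracleMode = "locality_matched",
    forward: Literal["binary", "relaxed"] = "binary",
    use_rounded_shift: bool = False,
) -> tuple[dict, float]:
    """Exact reverse-mode derivatives of the sequence loss.

    Returns ({W_in, W_out[, W_rec][, D_in][, D_rec]}, loss).  See the
    module docstring for the meaning of ``mode`` and ``forward``.
    """
    if mode not in ("locality_matched", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    kernel = kernel or GaussianKernel()
    surr = surr or SpikeSurrogateParams(v_th=sim.v_th)
    p = params
    X = raster.spikes
    T = X.shape[0]
    _check_size(T, p)
    if forward == "relaxed" and p.recurrent:
        raise ValueError("the relaxed forward supports feedforward networks only")
    onehot = _onehot(label, p.n_out)

    eff_in = p.eff_in(sim.D_max)
    eff_rec = p.eff_rec(sim.D_max)
    shift_in = shift_rec = None
    if p.D_in is not None:
        shift_in = (
            effective_delay(p.D_in, sim.D_max).astype(float)
            if use_rounded_shift
            else delay_shift(p.D_in, sim.D_max)
        )
        q_in, Kg_in, Kd_in = _tables(shift_in, kernel, sim.D_max)
    if p.D_rec is not None:
        shift_rec = (
            effective_delay(p.D_rec, sim.D_max).astype(float)
            if use_rounded_shift
            else delay_shift(p.D_rec, sim.D_max)
        )
        q_rec, Kg_rec, Kd_rec = _tables(shift_rec, kernel, sim.D_max)

    nh, ni, no = p.n_hidden, p.n_in, p.n_out
    v = np.zeros((T + 1, nh))
    z = np.zeros((T + 1, nh))
    y = np.zeros((T + 1, no))
    psi = np.zeros((T + 1, nh))
    a_in, g_in, a_rec, g_rec = [None] * (T + 1), [None] * (T + 1), [None] * (T + 1), [None] * (T + 1)
    loss = 0.0
    logpis = np.zeros((T + 1, no))

    # ---- forward
    for t in range(1, T + 1):
        s = t - 1
        if forward == "relaxed" and p.D_in is not None:
            a = _conv_at(X, s, q_in, Kg_in)  # smoothed delayed train values
        elif eff_in is None:
            a = _gather(X, np.full(ni, s))
        else:
            a = _gather(X, s - eff_in)
        a_in[t] = a
        drive = np.sum(p.W_in * a, axis=1) if a.ndim == 2 else p.W_in @ a
        if p.recurrent:
            sr = t - 2
            if eff_rec is None:
                ar = _gather(z, np.full(nh, sr), first_valid=0)
            else:
                ar = _gather(z, sr - eff_rec, first_valid=0)
            a_rec[t] = ar
            drive = drive + (
                np.sum(p.W_rec * ar, axis=1) if ar.ndim == 2 else p.W_rec @ ar
            )
        v[t] = sim.alpha * v[t - 1] + drive - z[t - 1] * sim.v_th
        if forward == "relaxed":
            z[t] = smooth_spike(v[t], surr)
        else:
            z[t] = (v[t] > sim.v_th).astype(float)
        psi[t] = spike_surrogate(v[t], surr)
        y[t] = sim.kappa * y[t - 1] + p.W_out @ z[t]
        logpis[t] = log_softmax(y[t])
        loss += -logpis[t][label]

    # delay-derivative drives (need the complete binary spike record for the
    # recurrent projection, hence a second sweep)
    if p.D_in is not None:
        for t in range(1, T + 1):
            g_in[t] = _conv_at(X, t - 1, q_in, Kd_in)
    if p.D_rec is not None:
        for t in range(1, T + 1):
            g_rec[t] = _conv_at(z, t - 2, q_rec, Kd_rec, first_valid=1)

    # ---- backward
    pis = np.exp(logpis)
    gW_in = np.zeros_like(p.W_in)
    gW_out = np.zeros_like(p.W_out)
    gW_rec = np.zeros_like(p.W_rec) if p.recurrent else None
    gD_in = np.zeros_like(p.D_in) if p.D_in is not None else None
    gD_rec = np.zeros_like(p.D_rec) if p.D_rec is not None else None

    ybar = np.zeros(no)
    vbar = np.zeros((T + 2 + sim.D_max, nh))  # padded so future reads are zero
    for t in range(T, 0, -1):
        ybar = (pis[t] - onehot) + sim.kappa * ybar
        gW_out += np.outer(ybar, z[t])
        zbar = p.W_out.T @ ybar
        if mode == "full":
            zbar = zbar - sim.v_th * vbar[t + 1]
            if p.recurrent:
                # z_i^t is consumed by v_j^{t + 2 + D_rec[j, i]}
                if eff_rec is None:
                    zbar = zbar + p.W_rec.T @ vbar[t + 2]
                elif eff_rec.ndim == 1:
                    # rows[i, j] = vbar_j at the step consuming z_i^t
                    rows = vbar[t + 2 + eff_rec]
                    zbar = zbar + np.einsum("ji,ij->i", p.W_rec, rows)
                else:
                    zbar = zbar + np.einsum(
                        "ji,ji->i", p.W_rec, vbar[t + 2 + eff_rec, np.arange(nh)[:, None]]
                    )
        vbar[t] = psi[t] * zbar + sim.alpha * vbar[t + 1]
        a = a_in[t]
        if a.ndim == 2:
            gW_in += vbar[t][:, None] * a
        else:
            gW_in += np.outer(vbar[t], a)
        if p.D_in is not None:
            g = g_in[t]
            contrib = vbar[t][:, None] * p.W_in * (g if g.ndim == 2 else g[None, :])
            if gD_in.ndim == 2:
                gD_in += contrib
            else:
                gD_in += contrib.sum(axis=0)
        if p.recurrent:
            ar = a_rec[t]
            if ar.ndim == 2:
                gW_rec += vbar[t][:, None] * ar
            else:
                gW_rec += np.outer(vbar[t], ar)
            if p.D_rec is not None:
                g = g_rec[t]
                contrib = vbar[t][:, None] * p.W_rec * (g if g.ndim == 2 else g[None, :])
                if gD_rec.ndim == 2:
                    gD_rec += contrib
                else:
                    gD_rec += contrib.sum(axis=0)

    grads = {"W_in": gW_in, "W_out": gW_out}
    if p.mask_in is not None:
        grads["W_in"] = gW_in * p.mask_in
    if p.recurrent:
        np.fill_diagonal(gW_rec, 0.0)
        grads["W_rec"] = gW_rec * p.mask_rec if p.mask_rec is not None else gW_rec
    if gD_in is not None:
        if p.flavor_in == "synaptic" and p.mask_in is not None:
            gD_in = gD_in * p.mask_in
        grads["D_in"] = gD_in
    if gD_rec is not None:
        if p.flavor_rec == "synaptic" and p.mask_rec is not None:
            gD_rec = gD_rec * p.mask_rec
        grads["D_rec"] = gD_rec
    return grads, float(loss)


def relaxed_loss(
    raster: SpikeRaster,
    label: int,
    params: NetworkParams,
    sim: SimParams,
    kernel: Optional[GaussianKernel] = None,
    surr: Optional[SpikeSurrogateParams] = None,
    use_rounded_shift: bool = False,
) -> float:
    """Loss of the fully differentiable relaxed forward pass (for finite
    differences against the ``full``-mode relaxed gradients)."""
    kernel = kernel or GaussianKernel()
    surr = surr or SpikeSurrogateParams(v_th=sim.v_th)
    p = params
    if p.recurrent:
        raise ValueError("the relaxed forward supports feedforward networks only")
    X = raster.spikes
    T = X.shape[0]
    onehot_idx = label
    if p.D_in is not None:
        shift = (
            effective_delay(p.D_in, sim.D_max).astype(float)
            if use_rounded_shift
            else delay_shift(p.D_in, sim.D_max)
        )
        q, Kg, _ = _tables(shift, kernel, sim.D_max)
    v = np.zeros(p.n_hidden)
    z = np.zeros(p.n_hidden)
    y = np.zeros(p.n_out)
    loss = 0.0
    for t in range(1, T + 1):
        s = t - 1
        if p.D_in is not None:
            a = _conv_at(X, s, q, Kg)
        else:
            a = _gather(X, np.full(p.n_in, s))
        drive = np.sum(p.W_in * a, axis=1) if a.ndim == 2 else p.W_in @ a
        v = sim.alpha * v + drive - z * sim.v_th
        z = smooth_spike(v, surr)
        y = sim.kappa * y + p.W_out @ z
        loss += -log_softmax(y)[onehot_idx]
    return float(loss)


def compare_gradients(a: dict, b: dict) -> dict:
    """Per-parameter-group max absolute and max relative deviation."""
    out = {}
    for key in sorted(set(a) & set(b)):
        da, db = np.asarray(a[key]), np.asarray(b[key])
        diff = np.abs(da - db)
        scale = np.maximum(np.abs(da), np.abs(db))
        denom = np.where(scale > 0, scale, 1.0)
        out[key] = {
            "max_abs": float(diff.max(initial=0.0)),
            "max_rel": float((diff / denom).max(initial=0.0)),
        }
    return out
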