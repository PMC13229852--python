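"""Surrogate functions used only inside learning computations.

Two distinct surrogates live here:

* the piecewise-linear spike derivative that stands in for the Heaviside
  threshold when differentiating the membrane potential, and
* the Gaussian kernel (and its derivative with respect to the delay
  parameter) that stands in for a binary spike train when differentiating
  with respect to synaptic or axonal delays.

Neither surrogate ever enters forward simulation: the inference pass is
purely binary, and the Gaussian pathway is invoked only during parameter
updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpikeSurrogateParams",
    "GaussianKernel",
    "spike_surrogate",
    "smooth_spike",
    "gaussian_spike",
    "gaussian_delay_derivative",
    "smoothed_delayed_train",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class SpikeSurrogateParams:
    """Parameters of the piecewise-linear threshold surrogate.

    gamma_pd dampens the pseudo-derivative; 0.3 is the published value.
    v_th is shared with the simulation parameters.
    """

    gamma_pd: float = 0.3
    v_th: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma_pd > 0:
            raise ValueError("gamma_pd must be positive")
        if not self.v_th > 0:
            raise ValueError("v_th must be positive")


def spike_surrogate(v: np.ndarray | float, p: SpikeSurrogateParams) -> np.ndarray:
    """Pseudo-derivative dz/dv of the spike nonlinearity.

    (gamma_pd / v_th) * max(0, 1 - |v - v_th| / v_th): a triangle of height
    gamma_pd/v_th peaked at the threshold, with support (0, 2*v_th).
    """
    v = np.asarray(v, dtype=float)
    return (p.gamma_pd / p.v_th) * np.maximum(0.0, 1.0 - np.abs((v - p.v_th) / p.v_th))


def smooth_spike(v: np.ndarray | float, p: SpikeSurrogateParams) -> np.ndarray:
    """C1 relaxation of the Heaviside spike whose derivative is spike_surrogate.

    Integral of the triangular pseudo-derivative: 0 below v=0, a piecewise
    quadratic ramp saturating at gamma_pd for v >= 2*v_th.  Used only by the
    relaxed (fully differentiable) forward pass of the gradient oracle, where
    finite differences must agree with reverse-mode derivatives.
    """
    v = np.asarray(v, dtype=float)
    g, vt = p.gamma_pd, p.v_th
    scale = g / (2.0 * vt * vt)
    lo = scale * np.clip(v, 0.0, vt) ** 2
    hi = g - scale * np.clip(2.0 * vt - v, 0.0, vt) ** 2
    return np.where(v <= vt, lo, hi)


@dataclass(frozen=True)
class GaussianKernel:
    """Truncated Gaussian kernel used to smooth delayed spike trains.

    sigma is the kernel width in timesteps; k is the total tap count of the
    truncated window (the look-up-table size of the on-chip memory model).
    The kernel is evaluated only for |u| <= k/2 and is zero outside; no
    renormalization is applied after truncation (plain windowing, so the
    kernel is simply clipped at sequence boundaries).
    """

    sigma: float = 2.0
    k: int = 12

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def half_window(self) -> float:
        return self.k / 2.0

    def taps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Kernel and derivative values on the integer grid -k/2..k/2.

        Exportable as a small table: the hardware analogue is a look-up
        table holding the surrogate gradient.
        """
        half = int(np.floor(self.half_window))
        u = np.arange(-half, half + 1, dtype=float)
        return u, gaussian_spike(u, self.sigma), gaussian_delay_derivative(u, self.sigma)


def gaussian_spike(u: np.ndarray | float, sigma: float) -> np.ndarray:
    """Gaussian density evaluated at time offset u = t - t_k - D."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    u = np.asarray(u, dtype=float)
    return np.exp(-(u * u) / (2.0 * sigma * sigma)) / (_SQRT_2PI * sigma)


def gaussian_delay_derivative(u: np.ndarray | float, sigma: float) -> np.ndarray:
    """Derivative of the smoothed spike with respect to the delay parameter.

    d/dD of gaussian_spike(t - t_k - D) = +u/(sqrt(2*pi)*sigma^3) * exp(-u^2/(2 sigma^2)),
    antisymmetric in u and zero at the center.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    u = np.asarray(u, dtype=float)
    return (u / (_SQRT_2PI * sigma ** 3)) * np.exp(-(u * u) / (2.0 * sigma * sigma))


def _windowed(vals: np.ndarray, u: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    return np.where(np.abs(u) <= kernel.half_window, vals, 0.0)


def smoothed_delayed_train(
    spike_times: np.ndarray,
    shift: float,
    T: int,
    kernel: GaussianKernel,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed, delayed spike train and its delay-derivative on the step grid.

    A binary train with spikes at integer times ``spike_times`` is modelled as
    a superposition of Gaussians centered at ``t_k + shift`` (``shift`` is the
    continuous delay in steps, >= 0).  Returns two length-``T`` traces: the
    smoothed train and its derivative with respect to the delay parameter,
    both truncated to the k-tap window and clipped at the sequence boundary.
    """
    trace = np.zeros(T, dtype=float)
    dtrace = np.zeros(T, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        return trace, dtrace
    t = np.arange(T, dtype=float)
    u = t[:, None] - spike_times[None, :] - shift
    trace += _windowed(gaussian_spike(u, kernel.sigma), u, kernel).sum(axis=1)
    dtrace += _windowed(gaussian_delay_derivative(u, kernel.sigma), u, kernel).sum(axis=1)
    return trace, dtrace
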