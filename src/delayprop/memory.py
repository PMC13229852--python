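"""On-chip memory cost model and parameter counting.

Bit accounting for a neuromorphic implementation of a single-hidden-layer
network with learnable delays: how many bits are needed to store the
parameters, the membrane state, and the extra buffering that delay
*learning* requires (delayed input spike trains, delayed-current ring
buffers, and the surrogate-gradient look-up table).

Conventions (resolved against the published worked example, which they
reproduce bit-exactly):

* the delay buffer length is the addressable delay range 2**B_d (the
  printed "2Bd" read as an exponent; the alternative 2*B_d reading is
  inconsistent with every printed total);
* sparsity at density ``p`` scales the hidden AND readout weight counts
  (and delay parameter counts) by ``p``; membrane state for hidden and
  readout neurons is counted inside the fixed budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "MemorySpec",
    "mem_axonal",
    "mem_synaptic",
    "mem_trace",
    "footprint",
    "min_sparsity",
    "param_count",
    "sparsity_sweep",
]

Flavor = Literal["weights_only", "axonal", "synaptic"]


@dataclass(frozen=True)
class MemorySpec:
    """Layer sizes and bit widths feeding the cost model.

    B_d: delay resolution (bits) — the ring buffer must hold 2**B_d steps;
    B_v: membrane-potential resolution (bits); B_w: weight resolution (bits);
    k: tap count of the surrogate-gradient look-up table.
    """

    n_in: int = 116
    n_hidden: int = 128
    n_out: int = 20
    B_d: int = 5
    B_v: int = 16
    B_w: int = 8
    k: int = 12

    def __post_init__(self) -> None:
        for name in ("n_in", "n_hidden", "n_out", "B_d", "B_v", "B_w", "k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def mem_axonal(spec: MemorySpec) -> int:
    """Bits to buffer the delayed input spike trains (axonal delays).

    n_in * 2**B_d: one bit per buffered timestep of each input train; the
    buffer both realizes the delay and preserves presynaptic spike timing.
    """
    return spec.n_in * 2 ** spec.B_d


def mem_synaptic(spec: MemorySpec) -> int:
    """Bits for per-synapse delay buffering.

    Input-train buffering plus a per-hidden-neuron ring buffer of delayed
    synaptic current at membrane resolution: n_in*2**B_d + n_hidden*2**B_d*B_v.
    """
    return spec.n_in * 2 ** spec.B_d + spec.n_hidden * 2 ** spec.B_d * spec.B_v


def mem_trace(spec: MemorySpec) -> int:
    """Bits for the eligibility/kernel trace: n_hidden * k * B_v (the
    look-up table holding the surrogate gradient, per hidden neuron)."""
    return spec.n_hidden * spec.k * spec.B_v


def _weight_bits(spec: MemorySpec, density: float) -> float:
    return density * (spec.n_in * spec.n_hidden + spec.n_hidden * spec.n_out) * spec.B_w


def _delay_param_bits(spec: MemorySpec, flavor: Flavor, density: float) -> float:
    if flavor == "axonal":
        return spec.n_in * spec.B_d
    if flavor == "synaptic":
        return density * spec.n_in * spec.n_hidden * spec.B_d
    return 0.0


def _state_bits(spec: MemorySpec) -> int:
    return (spec.n_hidden + spec.n_out) * spec.B_v


def footprint(spec: MemorySpec, flavor: Flavor = "weights_only", density: float = 1.0) -> dict:
    """Bit breakdown {parameters, state, learning, total} for one flavor.

    ``parameters``: weights at B_w (scaled by density) plus delay parameters
    at B_d; ``state``: hidden + readout membrane potentials at B_v;
    ``learning``: delay-learning support memory (0 for weights_only).
    """
    if flavor not in ("weights_only", "axonal", "synaptic"):
        raise ValueError(f"invalid flavor {flavor!r}")
    learning = 0
    if flavor == "axonal":
        learning = mem_axonal(spec) + mem_trace(spec)
    elif flavor == "synaptic":
        learning = mem_synaptic(spec) + mem_trace(spec)
    parameters = _weight_bits(spec, density) + _delay_param_bits(spec, flavor, density)
    state = _state_bits(spec)
    return {
        "parameters": parameters,
        "state": state,
        "learning": learning,
        "total": parameters + state + learning,
    }


def min_sparsity(spec: MemorySpec, flavor: Flavor) -> float:
    """Minimum sparsity (1 - density) for the delayed, learning-enabled
    model to fit inside the dense weights-only memory budget.

    Axonal delay parameters (per input neuron) are a fixed cost; synaptic
    delay parameters share the weight mask and scale with density.
    """
    if flavor == "weights_only":
        return 0.0
    budget = footprint(spec, "weights_only")["total"]
    learn = (
        mem_axonal(spec) + mem_trace(spec)
        if flavor == "axonal"
        else mem_synaptic(spec) + mem_trace(spec)
    )
    fixed = _state_bits(spec) + (_delay_param_bits(spec, "axonal", 1.0) if flavor == "axonal" else 0.0)
    per_density = _weight_bits(spec, 1.0) + (
        _delay_param_bits(spec, "synaptic", 1.0) if flavor == "synaptic" else 0.0
    )
    density = (budget - learn - fixed) / per_density
    return float(1.0 - min(max(density, 0.0), 1.0))


def param_count(
    n_in: int,
    n_hidden: int,
    n_out: int,
    recurrent: bool = False,
    flavor_in: Literal["none", "axonal", "synaptic"] = "none",
    flavor_rec: Literal["none", "axonal", "synaptic"] = "none",
    density: float = 1.0,
) -> float:
    """Trainable parameter count (weights plus delay parameters by flavor).

    ``density`` scales every group, matching the published accounting for
    structurally sparse models.
    """
    count = n_in * n_hidden + n_hidden * n_out
    if recurrent:
        count += n_hidden * n_hidden
    if flavor_in == "axonal":
        count += n_in
    elif flavor_in == "synaptic":
        count += n_in * n_hidden
    if recurrent:
        if flavor_rec == "axonal":
            count += n_hidden
        elif flavor_rec == "synaptic":
            count += n_hidden * n_hidden
    return density * count


def sparsity_sweep(spec: MemorySpec, densities) -> list[dict]:
    """Total footprint of each flavor across a density grid (CSV-friendly)."""
    rows = []
    for p in densities:
        row = {"density": float(p)}
        for flavor in ("weights_only", "axonal", "synaptic"):
            row[flavor] = footprint(spec, flavor, density=p)["total"]
        rows.append(row)
    return rows
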