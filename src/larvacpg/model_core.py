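"""Wilson–Cowan population model of the larval crawling CPG.

Each abdominal segment (A1..A8) is one excitatory/inhibitory (EI) unit;
units are chained by nearest-neighbour excitatory and inhibitory
connections.  Optional extensions add stretch-sensitive sensory
populations (one per segment) and a mirrored contralateral chain
(two-sided model).  This module defines the parameter structures and the
time-derivative (right-hand-side) functions used by the integrator.

Conventions
-----------
* Segments are numbered 1..n with A1 = 1 (anterior) and A8 = n = 8
  (posterior).  Internal arrays are 0-based in the same order, so array
  index ``i`` holds segment ``i + 1``.
* All synaptic weights are stored *signed* (inhibitory weights are
  negative) and enter sigmoid arguments with a plus sign:
  ``input = sum(weight * activity)``.
* Chain edge ``k`` (0-based) couples segments ``k+1`` and ``k+2``; edge
  arrays therefore run anterior to posterior, A1–A2 first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SigmoidSpec",
    "PopulationSpec",
    "SegmentCoupling",
    "ChainCoupling",
    "SensorySpec",
    "ContralateralSpec",
    "NetworkSpec",
    "Pulse",
    "DriveProtocol",
    "sigmoid_response",
    "response_ceiling",
    "drive_value",
    "sensory_drive",
    "one_sided_rhs",
    "two_sided_rhs",
    "default_network",
    "REFERENCE_PARAMS",
]

Side = Literal["left", "right", "only"]
ContraKind = Literal["EE", "IE", "EI", "II"]

#: Reference parameter set for wave propagation (dimensionless; time in t.u.).
REFERENCE_PARAMS: dict[str, float] = {
    "a": 16.0, "b": 20.0, "c": -12.0, "d": -20.0, "e": 15.0, "f": -3.0,
    "tau_E": 0.5, "tau_I": 0.5, "tau_S": 0.5, "P_ext": 1.7,
    "b_E": 1.3, "b_I": 2.0, "b_S": 1.3,
    "theta_E": 4.0, "theta_I": 3.7, "theta_S": 2.0,
}


@dataclass(frozen=True)
class SigmoidSpec:
    """Sigmoid response function ``G(x) = 1/(1+e^{-slope(x-threshold)}) - G0``.

    The constant ``G0 = 1/(1+e^{slope*threshold})`` shifts the curve so
    that ``G(0) = 0``: a silent population receives no recurrent drive.
    """

    slope: float
    threshold: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and self.slope > 0):
            raise ValueError(f"sigmoid slope must be finite and > 0, got {self.slope}")
        if not math.isfinite(self.threshold):
            raise ValueError("sigmoid threshold must be finite")


@dataclass(frozen=True)
class PopulationSpec:
    """One neuronal population: decay time constant, response ceiling, sigmoid.

    ``ceiling`` is the saturation factor k in ``(k - x) G(...)``; for the
    reference parameters it equals the supremum of the sigmoid (see
    :func:`response_ceiling`).  Sensory populations carry no ceiling
    factor and use ``ceiling=None``.
    """

    time_constant: float
    sigmoid: SigmoidSpec
    ceiling: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time_constant) and self.time_constant > 0):
            raise ValueError("time_constant must be finite and > 0")
        if self.ceiling is not None and not (0.0 < self.ceiling <= 1.0):
            raise ValueError(f"ceiling must lie in (0, 1], got {self.ceiling}")

    @classmethod
    def with_derived_ceiling(cls, time_constant: float, sigmoid: SigmoidSpec) -> "PopulationSpec":
        """Build a population whose ceiling is the sigmoid's supremum."""
        return cls(time_constant, sigmoid, response_ceiling(sigmoid))


@dataclass(frozen=True)
class SegmentCoupling:
    """Within-segment weights of one EI unit (signed).

    self_excitation (a): E -> E, i_to_e (c): I -> E, e_to_i (e): E -> I,
    i_to_i (f): I -> I.
    """

    self_excitation: float
    i_to_e: float
    e_to_i: float
    i_to_i: float

    def __post_init__(self) -> None:
        for name in ("self_excitation", "i_to_e", "e_to_i", "i_to_i"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ChainCoupling:
    """Nearest-neighbour intersegmental weights (signed).

    ``e_edge_weights[k]`` is the bidirectional E->E weight (b) on the
    undirected pair (segment k+1, segment k+2); ``i_edge_weights[k]`` is
    the weight (d) from each segment's I population onto both
    neighbouring E populations across the same pair.
    """

    e_edge_weights: tuple[float, ...]
    i_edge_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "e_edge_weights", tuple(float(w) for w in self.e_edge_weights))
        object.__setattr__(self, "i_edge_weights", tuple(float(w) for w in self.i_edge_weights))
        if len(self.e_edge_weights) != len(self.i_edge_weights):
            raise ValueError("edge weight arrays must have equal length")
        for w in (*self.e_edge_weights, *self.i_edge_weights):
            if not math.isfinite(w):
                raise ValueError("edge weights must be finite")

    @classmethod
    def uniform(cls, b: float, d: float, n_segments: int = 8) -> "ChainCoupling":
        """All edges share the scalar weights ``b`` (E->E) and ``d`` (I->E)."""
        n_edges = n_segments - 1
        return cls((b,) * n_edges, (d,) * n_edges)

    @property
    def n_edges(self) -> int:
        return len(self.e_edge_weights)


@dataclass(frozen=True)
class SensorySpec:
    """Stretch-sensor feedback loop.

    A sensory population per segment is driven by the rectified activity
    difference to its neighbours, scaled by ``stretch_gain`` (alpha), and
    feeds ``to_excitatory`` (beta) onto E and ``to_inhibitory`` (gamma)
    onto I of its own segment.
    """

    stretch_gain: float
    to_excitatory: float
    to_inhibitory: float
    population: PopulationSpec = field(
        default_factory=lambda: PopulationSpec(
            REFERENCE_PARAMS["tau_S"], SigmoidSpec(REFERENCE_PARAMS["b_S"], REFERENCE_PARAMS["theta_S"])
        )
    )

    def __post_init__(self) -> None:
        if not (math.isfinite(self.stretch_gain) and self.stretch_gain >= 0):
            raise ValueError("stretch_gain must be finite and >= 0")


@dataclass(frozen=True)
class ContralateralSpec:
    """One same-segment commissural connection type in the two-sided model.

    kind EE: E -> contralateral E; IE: I -> contralateral E;
    EI: E -> contralateral I; II: I -> contralateral I.  The weight is
    signed (inhibitory sources normally carry negative weights).
    """

    kind: ContraKind
    weight: float

    def __post_init__(self) -> None:
        if self.kind not in ("EE", "IE", "EI", "II"):
            raise ValueError(f"unknown contralateral kind {self.kind!r}")
        if not math.isfinite(self.weight):
            raise ValueError("contralateral weight must be finite")


@dataclass(frozen=True)
class NetworkSpec:
    """Complete parameterization of a one- or two-sided CPG chain."""

    n_segments: int
    excitatory: PopulationSpec
    inhibitory: PopulationSpec
    segment: SegmentCoupling
    chain: ChainCoupling
    sensory: SensorySpec | None = None
    contralateral: ContralateralSpec | None = None

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be positive")
        if self.chain.n_edges != self.n_segments - 1:
            raise ValueError(
                f"chain has {self.chain.n_edges} edges; "
                f"{self.n_segments} segments require {self.n_segments - 1}"
            )

    @property
    def two_sided(self) -> bool:
        return self.contralateral is not None

    @property
    def has_sensory(self) -> bool:
        return self.sensory is not None

    @property
    def populations_per_side(self) -> int:
        return self.n_segments * (3 if self.has_sensory else 2)

    @property
    def state_size(self) -> int:
        return self.populations_per_side * (2 if self.two_sided else 1)

    def with_chain(self, b: float | None = None, d: float | None = None) -> "NetworkSpec":
        """Copy with uniform intersegmental weights replaced."""
        eb = self.chain.e_edge_weights[0] if b is None else b
        ed = self.chain.i_edge_weights[0] if d is None else d
        return replace(self, chain=ChainCoupling.uniform(eb, ed, self.n_segments))


@dataclass(frozen=True)
class Pulse:
    """One rectangular drive pulse onto an excitatory population."""

    segment_index: int
    strength: float
    onset_time: float = 0.0
    duration: float = 2.0
    side: Side = "only"

    def __post_init__(self) -> None:
        if self.segment_index < 1:
            raise ValueError("segment_index is 1-based (A1=1)")
        if not (math.isfinite(self.strength) and self.strength >= 0):
            raise ValueError("pulse strength must be finite and >= 0")
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def offset_time(self) -> float:
        return self.onset_time + self.duration


@dataclass(frozen=True)
class DriveProtocol:
    """External input: a set of rectangular pulses, E populations only."""

    pulses: tuple[Pulse, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulses", tuple(self.pulses))

    @classmethod
    def single(
        cls,
        segment_index: int = 8,
        strength: float = REFERENCE_PARAMS["P_ext"],
        onset_time: float = 0.0,
        duration: float = 2.0,
        side: Side = "only",
    ) -> "DriveProtocol":
        return cls((Pulse(segment_index, strength, onset_time, duration, side),))

    @property
    def breakpoints(self) -> tuple[float, ...]:
        """Sorted distinct pulse edge times (integration must not straddle them)."""
        times = {p.onset_time for p in self.pulses} | {p.offset_time for p in self.pulses}
        return tuple(sorted(times))

    def end_time(self) -> float:
        return max((p.offset_time for p in self.pulses), default=0.0)


# ---------------------------------------------------------------------------
# Response functions


def sigmoid_response(x, spec: SigmoidSpec):
    """Shifted logistic response ``G(x)``; ``G(0) = 0`` by construction.

    Accepts scalars or arrays; raises on non-finite input.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError("non-finite sigmoid argument")
    lam, theta = spec.slope, spec.threshold
    out = 1.0 / (1.0 + np.exp(-lam * (arr - theta))) - 1.0 / (1.0 + np.exp(lam * theta))
    return out if arr.ndim else float(out)


def response_ceiling(spec: SigmoidSpec) -> float:
    """Supremum of :func:`sigmoid_response`, ``1 - 1/(1+e^{slope*threshold})``."""
    return 1.0 - 1.0 / (1.0 + math.exp(spec.slope * spec.threshold))


def drive_value(
    protocol: DriveProtocol, t: float, segment_index: int, side: Side = "only"
) -> float:
    """Total external drive onto E of ``segment_index`` on ``side`` at time t.

    Pulses tagged ``"only"`` (one-sided runs) match any side; overlapping
    pulses superpose.  The pulse window is half-open: [onset, offset).
    """
    total = 0.0
    for p in protocol.pulses:
        if p.segment_index != segment_index:
            continue
        if p.side != "only" and side != "only" and p.side != side:
            continue
        if p.onset_time <= t < p.offset_time:
            total += p.strength
    return total


def _drive_vector(protocol: DriveProtocol, t: float, n: int, side: Side) -> np.ndarray:
    vec = np.zeros(n)
    for p in protocol.pulses:
        if p.side != "only" and side != "only" and p.side != side:
            continue
        if p.onset_time <= t < p.offset_time:
            vec[p.segment_index - 1] += p.strength
    return vec


def _neighbour_sum(weights: Sequence[float], x: np.ndarray) -> np.ndarray:
    """For each segment, the edge-weighted sum of its neighbours' activity."""
    w = np.asarray(weights)
    out = np.zeros_like(x)
    out[1:] += w * x[:-1]
    out[:-1] += w * x[1:]
    return out


def sensory_drive(E: np.ndarray, spec: SensorySpec) -> np.ndarray:
    """Sigmoid argument of each sensory population: rectified stretch signal.

    Segment i receives ``alpha*[E_{i+1}-E_i]_+ + alpha*[E_{i-1}-E_i]_+``;
    end segments have only their single neighbour's term.
    """
    E = np.asarray(E, dtype=float)
    a = spec.stretch_gain
    out = np.zeros_like(E)
    up = E[1:] - E[:-1]
    out[:-1] += a * np.maximum(up, 0.0)   # stretch from the posterior neighbour
    out[1:] += a * np.maximum(-up, 0.0)   # stretch from the anterior neighbour
    return out


def _side_rhs(
    E: np.ndarray,
    I: np.ndarray,
    S: np.ndarray | None,
    spec: NetworkSpec,
    drive: np.ndarray,
    extra_E: np.ndarray | float = 0.0,
    extra_I: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Derivatives of one side's populations given precomputed external drive."""
    seg, sens = spec.segment, spec.sensory
    arg_E = (
        seg.self_excitation * E
        + seg.i_to_e * I
        + _neighbour_sum(spec.chain.e_edge_weights, E)
        + _neighbour_sum(spec.chain.i_edge_weights, I)
        + drive
        + extra_E
    )
    arg_I = seg.e_to_i * E + seg.i_to_i * I + extra_I
    dS = None
    if S is not None:
        assert sens is not None
        arg_E = arg_E + sens.to_excitatory * S
        arg_I = arg_I + sens.to_inhibitory * S
        pop_S = sens.population
        dS = (-S + sigmoid_response(sensory_drive(E, sens), pop_S.sigmoid)) / pop_S.time_constant
    pe, pi = spec.excitatory, spec.inhibitory
    dE = (-E + (pe.ceiling - E) * sigmoid_response(arg_E, pe.sigmoid)) / pe.time_constant
    dI = (-I + (pi.ceiling - I) * sigmoid_response(arg_I, pi.sigmoid)) / pi.time_constant
    return dE, dI, dS


def _split_side(state: np.ndarray, spec: NetworkSpec):
    n = spec.n_segments
    E, I = state[:n], state[n : 2 * n]
    S = state[2 * n : 3 * n] if spec.has_sensory else None
    return E, I, S


def one_sided_rhs(
    state: np.ndarray, spec: NetworkSpec, protocol: DriveProtocol, t: float
) -> np.ndarray:
    """Time derivative of a one-sided chain state ``[E_1..n, I_1..n, (S_1..n)]``.

    Missing-neighbour terms at the chain ends drop out; external drive
    reaches excitatory populations only.
    """
    if spec.two_sided:
        raise ValueError("spec is two-sided; use two_sided_rhs")
    state = np.asarray(state, dtype=float)
    if state.shape != (spec.state_size,):
        raise ValueError(f"state has shape {state.shape}, expected ({spec.state_size},)")
    E, I, S = _split_side(state, spec)
    drive = _drive_vector(protocol, t, spec.n_segments, "only")
    dE, dI, dS = _side_rhs(E, I, S, spec, drive)
    parts = [dE, dI] if dS is None else [dE, dI, dS]
    return np.concatenate(parts)


def two_sided_rhs(
    state: np.ndarray, spec: NetworkSpec, protocol: DriveProtocol, t: float
) -> np.ndarray:
    """Time derivative of the two-sided model, state = [left block, right block].

    Each side follows the one-sided dynamics plus one same-segment
    commissural term per the contralateral kind.
    """
    contra = spec.contralateral
    if contra is None:
        raise ValueError("spec has no contralateral coupling; use one_sided_rhs")
    state = np.asarray(state, dtype=float)
    if state.shape != (spec.state_size,):
        raise ValueError(f"state has shape {state.shape}, expected ({spec.state_size},)")
    half = spec.populations_per_side
    blocks = []
    for side, block, other in (
        ("left", state[:half], state[half:]),
        ("right", state[half:], state[:half]),
    ):
        E, I, S = _split_side(block, spec)
        oE, oI, _ = _split_side(other, spec)
        src = oE if contra.kind in ("EE", "EI") else oI
        extra = contra.weight * src
        extra_E = extra if contra.kind in ("EE", "IE") else 0.0
        extra_I = extra if contra.kind in ("EI", "II") else 0.0
        drive = _drive_vector(protocol, t, spec.n_segments, side)
        dE, dI, dS = _side_rhs(E, I, S, spec, drive, extra_E, extra_I)
        blocks.extend([dE, dI] if dS is None else [dE, dI, dS])
    return np.concatenate(blocks)


def default_network(
    n_segments: int = 8,
    sensory: SensorySpec | None = None,
    contralateral: ContralateralSpec | None = None,
) -> NetworkSpec:
    """The reference wave-propagation network (REFERENCE_PARAMS values)."""
    p = REFERENCE_PARAMS
    return NetworkSpec(
        n_segments=n_segments,
        excitatory=PopulationSpec.with_derived_ceiling(
            p["tau_E"], SigmoidSpec(p["b_E"], p["theta_E"])
        ),
        inhibitory=PopulationSpec.with_derived_ceiling(
            p["tau_I"], SigmoidSpec(p["b_I"], p["theta_I"])
        ),
        segment=SegmentCoupling(p["a"], p["c"], p["e"], p["f"]),
        chain=ChainCoupling.uniform(p["b"], p["d"], n_segments),
        sensory=sensory,
        contralateral=contralateral,
    )
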