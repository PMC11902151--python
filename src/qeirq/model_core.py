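"""Core definitions of the QEIRQ excitable-cell model.

Each cell in a confluent monolayer is an agent on a triangular lattice that
cycles through four functional states: quiescent (Q), excited (E), inducing
(I) and refractory (R).  A Q cell is activated (Q -> E_1) by a neighbor in
any I substate; every other transition is spontaneous and first order.  The
E, I and R states are split into ``n_E``, ``n_I`` and ``n_R`` exponential
substates so that the total residence times are Erlang distributed with
means ``tau_E``, ``tau_I``, ``tau_R`` and variances ``tau_X**2 / n_X``.

This module holds the parameter/geometry containers, the neighbor relation
of the lattice, and the closed-form quantities that follow directly from
the kinetic scheme (deterministic front speed, full-cycle statistics and
the single-pair activation probability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

__all__ = [
    "ModelParameters",
    "ChannelGeometry",
    "CellState",
    "CycleStatistics",
    "NOMINAL_PARAMETERS",
    "build_geometry",
    "neighbors",
    "cycle_statistics",
    "deterministic_inverse_speed",
    "single_pair_activation_probability",
]

#: Axial-coordinate neighbor offsets (drow, dlayer) of the triangular lattice.
#: Exactly two offsets point into the previous layer, matching the two
#: inducing neighbors of each quiescent cell at a flat front head.
AXIAL_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


class Boundary(str, Enum):
    """Boundary condition along the channel width."""

    PERIODIC = "periodic"
    INERT = "inert"


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic parameters of the QEIRQ model.

    Parameters
    ----------
    tau_act
        Mean time (min) for a single inducing neighbor to activate a
        quiescent cell; the activation propensity of a Q cell is
        ``n_I_neighbors / tau_act``.
    tau_e, tau_i, tau_r
        Mean total residence times (min) in the excited, inducing and
        refractory states.
    n_e, n_i, n_r
        Number of exponential substates of E, I and R.  Larger values make
        the Erlang residence times narrower (variance ``tau**2 / n``).
    """

    tau_act: float = 1.0
    tau_e: float = 4.0
    tau_i: float = 2.0
    tau_r: float = 60.0
    n_e: int = 4
    n_i: int = 2
    n_r: int = 4

    def __post_init__(self) -> None:
        for name in ("tau_act", "tau_e", "tau_i", "tau_r"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_e", "n_i", "n_r"):
            value = getattr(self, name)
            if not (isinstance(value, (int,)) and value >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {value}")

    @property
    def n_states(self) -> int:
        """Total number of distinct cell-state codes (Q plus all substates)."""
        return 1 + self.n_e + self.n_i + self.n_r


#: Nominal parameter set of the model (all times in minutes).
NOMINAL_PARAMETERS = ModelParameters()


@dataclass(frozen=True)
class ChannelGeometry:
    """Triangular-lattice channel of width ``W`` rows and length ``L`` layers.

    Cells are addressed by axial coordinates ``(row, layer)`` with
    ``row in [0, W)`` and ``layer in [0, L)``.  Under periodic boundaries the
    row index wraps modulo ``W``; under inert boundaries edge rows simply
    have fewer neighbors (the bordering cells are biochemically inert).
    """

    width: int
    length: int
    boundary: Boundary = Boundary.PERIODIC

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError(f"width must be >= 1, got {self.width}")
        if self.length < 2:
            raise ValueError(f"length must be >= 2, got {self.length}")
        object.__setattr__(self, "boundary", Boundary(self.boundary))
        if self.width == 1 and self.boundary is Boundary.PERIODIC:
            raise ValueError(
                "W = 1 with periodic boundary makes cells their own neighbors; "
                "use boundary='inert' for single-row channels"
            )

    @property
    def n_cells(self) -> int:
        return self.width * self.length

    def index(self, row: int, layer: int) -> int:
        """Flat cell index; cells are numbered layer-major."""
        return layer * self.width + row

    def coords(self, idx: int) -> tuple[int, int]:
        return idx % self.width, idx // self.width

    def cells(self) -> Iterator[tuple[int, int]]:
        for layer in range(self.length):
            for row in range(self.width):
                yield row, layer


def build_geometry(width: int, length: int, boundary: str | Boundary = "periodic") -> ChannelGeometry:
    """Validate and construct a :class:`ChannelGeometry`."""
    return ChannelGeometry(width=width, length=length, boundary=Boundary(boundary))


def neighbors(geom: ChannelGeometry, cell: tuple[int, int]) -> set[tuple[int, int]]:
    """Neighbors of ``cell = (row, layer)`` on the triangular lattice.

    Every interior cell has six neighbors, exactly two of which lie in the
    previous layer.  Layer indices never wrap; row indices wrap only under
    periodic boundaries.
    """
    row, layer = cell
    if not (0 <= row < geom.width and 0 <= layer < geom.length):
        raise ValueError(f"cell {cell} outside {geom.width}x{geom.length} lattice")
    out: set[tuple[int, int]] = set()
    for drow, dlayer in AXIAL_OFFSETS:
        r, c = row + drow, layer + dlayer
        if not (0 <= c < geom.length):
            continue
        if geom.boundary is Boundary.PERIODIC:
            r %= geom.width
        elif not (0 <= r < geom.width):
            continue
        out.add((r, c))
    return out


@dataclass(frozen=True)
class CycleStatistics:
    """Closed-form statistics of the full Q -> E -> I -> R -> Q cycle."""

    n_neigh_i: float
    t_cycle: float
    sigma_cycle: float

    @property
    def t_refractory(self) -> float:
        """Effective refractory time T_R = T_cycle + sigma_cycle (min)."""
        return self.t_cycle + self.sigma_cycle


def cycle_statistics(p: ModelParameters, n_neigh_i: float = 2.0) -> CycleStatistics:
    """Mean and standard deviation of the full state cycle.

    ``n_neigh_i`` is the assumed mean number of inducing neighbors seen by a
    quiescent cell at the front head (2 for a flat front).  The activation
    stage contributes an exponential waiting time with mean
    ``tau_act / n_neigh_i``; the E, I, R stages contribute their Erlang
    means and variances.
    """
    if n_neigh_i <= 0:
        raise ValueError("n_neigh_i must be positive")
    t_act = p.tau_act / n_neigh_i
    t_cycle = t_act + p.tau_e + p.tau_i + p.tau_r
    var = t_act**2 + p.tau_e**2 / p.n_e + p.tau_i**2 / p.n_i + p.tau_r**2 / p.n_r
    return CycleStatistics(n_neigh_i=n_neigh_i, t_cycle=t_cycle, sigma_cycle=math.sqrt(var))


def deterministic_inverse_speed(p: ModelParameters) -> float:
    """Inverse front speed (min/layer) of the deterministic limit.

    With fixed residence times the front is a straight line and each
    quiescent cell at its head has exactly two inducing neighbors, so one
    forward step takes ``tau_act / 2 + tau_E``.
    """
    return p.tau_act / 2.0 + p.tau_e


def single_pair_activation_probability(p: ModelParameters) -> float:
    """Probability that an I cell activates a given quiescent neighbor.

    The activation channel (rate ``1/tau_act``) races against the ``n_I``
    sequential substate exits (rate ``n_I/tau_I`` each); the cell is
    activated iff activation wins before the inducing cell turns refractory:

    ``P = 1 - (r_I / (r_I + a))**n_I`` with ``r_I = n_I/tau_I``, ``a = 1/tau_act``.
    """
    r_i = p.n_i / p.tau_i
    a = 1.0 / p.tau_act
    return 1.0 - (r_i / (r_i + a)) ** p.n_i


class CellState:
    """Integer encoding of cell-state codes for a given parameter set.

    Codes are ``0`` (Q), ``1..n_E`` (E substates), ``n_E+1..n_E+n_I`` (I
    substates) and ``n_E+n_I+1..n_E+n_I+n_R`` (R substates).  The allowed
    transitions form the single cycle Q -> E_1 -> ... -> R_nR -> Q, where
    only Q -> E_1 requires activation by an inducing neighbor.
    """

    Q = 0

    def __init__(self, p: ModelParameters):
        self.p = p
        self.n_states = p.n_states
        self.first_e = 1
        self.first_i = 1 + p.n_e
        self.first_r = 1 + p.n_e + p.n_i
        self.last_r = p.n_e + p.n_i + p.n_r

    def is_excited(self, code: int) -> bool:
        return self.first_e <= code < self.first_i

    def is_inducing(self, code: int) -> bool:
        return self.first_i <= code < self.first_r

    def is_active(self, code: int) -> bool:
        """Active means E or I: the cells counted in kymographs."""
        return self.first_e <= code < self.first_r

    def is_refractory(self, code: int) -> bool:
        return self.first_r <= code <= self.last_r

    def spontaneous_successor(self, code: int) -> int | None:
        """Successor of a spontaneous transition, or None for Q."""
        if code == self.Q:
            return None
        if not (0 < code <= self.last_r):
            raise ValueError(f"invalid state code {code}")
        return 0 if code == self.last_r else code + 1

    def spontaneous_rate(self, code: int) -> float:
        """Rate (1/min) of the spontaneous exit from a non-Q substate."""
        p = self.p
        if self.is_excited(code):
            return p.n_e / p.tau_e
        if self.is_inducing(code):
            return p.n_i / p.tau_i
        if self.is_refractory(code):
            return p.n_r / p.tau_r
        raise ValueError(f"state {code} has no spontaneous transition")

    def label(self, code: int) -> str:
        if code == self.Q:
            return "Q"
        if self.is_excited(code):
            return f"E{code - self.first_e + 1}"
        if self.is_inducing(code):
            return f"I{code - self.first_i + 1}"
        return f"R{code - self.first_r + 1}"
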