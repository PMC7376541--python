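"""Core model definition for fractional-order Delta-Notch lateral inhibition.

Each cell ``i`` carries three concentrations: Delta ligand ``D_i``, inactive
Notch receptor ``N_i`` and activated (cleaved) Notch ``A_i``.  Delta on a cell
binds Notch on its neighbours ``NG(i)``; activated Notch represses Delta
production in the same cell (lateral inhibition).  The dynamics are posed as a
Caputo fractional system of order ``alpha`` in which every kinetic constant
``k`` enters as ``k**alpha``, so that the integer-order model is recovered
exactly at ``alpha = 1``:

    D^a D_i = lam_i^a / (1 + theta^a A_i) - sum_j f^a D_i N_j - d^a D_i
    D^a N_i = lam_N^a + sum_j f^a D_j N_i - d^a N_i
    D^a A_i = a^a S_i / (b^a + S_i) - d^a A_i,   S_i = (sum_j D_j) N_i

with the neighbour sums running over ``j in NG(i)``.  The activation term is a
saturating (Hill-type) function of the total neighbour-Delta/own-Notch
product ``S_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "EffectiveRates",
    "CellTopology",
    "effective_rates",
    "rhs",
    "total_mass_bound",
]

#: (Delta, inactive Notch, activated Notch) per-cell components.
STATE_COMPONENTS = ("D", "N", "A")


@dataclass(frozen=True)
class ModelParameters:
    """The eight model constants.

    Parameters
    ----------
    lambda_delta
        Delta production rate ``lam`` (concentration/time); may be 0 for a
        non-Delta-expressing cell population.
    lambda_notch
        Inactive-Notch production rate ``lam_N`` (> 0).
    f
        Delta-Notch binding rate (> 0); one rate serves both the ligand- and
        receptor-side binding terms.
    d
        Common degradation rate for all three species (> 0).
    a
        Notch activation (cleavage) rate (> 0).
    b
        Activation saturation constant (> 0).
    theta
        Inhibition coefficient of activated Notch on Delta production (>= 0).
    alpha
        Fractional derivative order, ``0 < alpha <= 1``.
    """

    lambda_delta: float = 1000.0
    lambda_notch: float = 0.07
    f: float = 0.01
    d: float = 0.01
    a: float = 0.01
    b: float = 200.0
    theta: float = 1.0e6
    alpha: float = 0.9

    def __post_init__(self) -> None:
        for name in ("lambda_notch", "f", "d", "a", "b"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        for name in ("lambda_delta", "theta"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must satisfy 0 < alpha <= 1, got {self.alpha!r}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (and re-validated)."""
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class EffectiveRates:
    """Model constants raised to the fractional order ``alpha``.

    These are the coefficients that actually appear in the equations of
    motion; at ``alpha = 1`` they equal the base parameters componentwise.
    """

    lambda_delta: float
    lambda_notch: float
    f: float
    d: float
    a: float
    b: float
    theta: float
    alpha: float


def effective_rates(params: ModelParameters) -> EffectiveRates:
    """Raise every rate constant to the power ``alpha``."""
    q = params.alpha
    return EffectiveRates(
        lambda_delta=params.lambda_delta**q,
        lambda_notch=params.lambda_notch**q,
        f=params.f**q,
        d=params.d**q,
        a=params.a**q,
        b=params.b**q,
        theta=params.theta**q,
        alpha=q,
    )


@dataclass(frozen=True)
class CellTopology:
    """A cell-contact graph: ``n_cells`` cells and neighbour lists ``NG(i)``.

    The adjacency must be symmetric and free of self-loops.  A cell with no
    neighbours is allowed (all its neighbour sums are zero).
    """

    n_cells: int
    neighbors: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        nb = tuple(tuple(int(j) for j in lst) for lst in self.neighbors)
        if len(nb) != self.n_cells:
            raise ValueError(
                f"neighbors has {len(nb)} entries for {self.n_cells} cells"
            )
        for i, lst in enumerate(nb):
            if len(set(lst)) != len(lst):
                raise ValueError(f"duplicate neighbor in NG({i})")
            for j in lst:
                if not (0 <= j < self.n_cells):
                    raise ValueError(f"neighbor index {j} of cell {i} out of range")
                if j == i:
                    raise ValueError(f"self-loop at cell {i}")
                if i not in nb[j]:
                    raise ValueError(
                        f"asymmetric adjacency: {j} in NG({i}) but {i} not in NG({j})"
                    )
        object.__setattr__(self, "neighbors", nb)

    @classmethod
    def pair(cls) -> "CellTopology":
        """The two-cell topology (each cell is the other's only neighbour)."""
        return cls(2, ((1,), (0,)))

    @classmethod
    def grid(
        cls, rows: int, cols: int, horizontal_periodic: bool = False
    ) -> "CellTopology":
        """A rows x cols lattice with von Neumann (4-)neighbourhood.

        ``horizontal_periodic`` wraps the columns into a tube, so every cell
        has exactly two horizontal neighbours (for ``cols >= 3``).
        """
        if rows < 1 or cols < 1:
            raise ValueError("grid dimensions must be positive")
        nb: list[list[int]] = []
        for r in range(rows):
            for c in range(cols):
                lst = []
                if r > 0:
                    lst.append((r - 1) * cols + c)
                if r < rows - 1:
                    lst.append((r + 1) * cols + c)
                for cc in (c - 1, c + 1):
                    if horizontal_periodic:
                        cc %= cols
                    if 0 <= cc < cols and cc != c:
                        lst.append(r * cols + cc)
                nb.append(sorted(set(lst)))
        return cls(rows * cols, tuple(tuple(l) for l in nb))

    def adjacency_matrix(self) -> np.ndarray:
        adj = np.zeros((self.n_cells, self.n_cells))
        for i, lst in enumerate(self.neighbors):
            adj[i, list(lst)] = 1.0
        return adj


def _lambda_vector(
    params: ModelParameters,
    n_cells: int,
    lambda_per_cell: Sequence[float] | None,
) -> np.ndarray:
    if lambda_per_cell is None:
        return np.full(n_cells, float(params.lambda_delta))
    lam = np.asarray(lambda_per_cell, dtype=float)
    if lam.shape != (n_cells,):
        raise ValueError(
            f"lambda_per_cell has shape {lam.shape}, expected ({n_cells},)"
        )
    if np.any(lam < 0) or not np.all(np.isfinite(lam)):
        raise ValueError("per-cell lambda values must be finite and >= 0")
    return lam


def make_rhs(
    params: ModelParameters,
    topology: CellTopology,
    lambda_per_cell: Sequence[float] | None = None,
):
    """Build a vectorised right-hand-side function ``x -> dx`` on (n, 3) states.

    Neighbour sums are evaluated through the adjacency matrix, which keeps a
    single call cheap enough for the time-stepping loop.
    """
    e = effective_rates(params)
    lam_eff = _lambda_vector(params, topology.n_cells, lambda_per_cell) ** params.alpha
    adj = topology.adjacency_matrix()

    def _rhs(state: np.ndarray) -> np.ndarray:
        D, N, A = state[:, 0], state[:, 1], state[:, 2]
        sum_n = adj @ N
        sum_d = adj @ D
        s = sum_d * N
        dD = lam_eff / (1.0 + e.theta * A) - e.f * D * sum_n - e.d * D
        dN = e.lambda_notch + e.f * sum_d * N - e.d * N
        dA = e.a * s / (e.b + s) - e.d * A
        return np.stack([dD, dN, dA], axis=1)

    return _rhs


def rhs(
    state: np.ndarray,
    params: ModelParameters,
    topology: CellTopology,
    lambda_per_cell: Sequence[float] | None = None,
) -> np.ndarray:
    """Evaluate the model right-hand side at ``state`` (shape (n_cells, 3)).

    Returns the per-cell derivative triples ``(dD_i, dN_i, dA_i)``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (topology.n_cells, 3):
        raise ValueError(
            f"state has shape {state.shape}, expected ({topology.n_cells}, 3)"
        )
    return make_rhs(params, topology, lambda_per_cell)(state)


def total_mass_bound(params: ModelParameters) -> float:
    """Asymptotic bound on the total two-cell concentration.

    Summing all six equations of the two-cell system, the cross-cell binding
    terms cancel, the production terms are bounded by ``2 lam^a + 2 lam_N^a +
    2 a^a`` and every species degrades at rate ``d^a``, so the total mass
    ``w(t)`` satisfies ``w(t) <= max(w(0), bound)`` with ``bound`` the value
    returned here.
    """
    e = effective_rates(params)
    return (2.0 * e.lambda_delta + 2.0 * e.lambda_notch + 2.0 * e.a) / e.d
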