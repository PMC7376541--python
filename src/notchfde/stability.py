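"""Local stability analysis of the Delta-Notch fixed points.

For a Caputo system of order ``alpha``, a fixed point is locally
asymptotically stable iff every eigenvalue ``xi`` of the Jacobian satisfies
the sector condition ``|arg(xi)| > alpha * pi / 2`` (the fractional analogue
of "negative real part"; at ``alpha = 1`` the two coincide).  For the
symmetric two-cell equilibrium the analysis reduces to a per-cell 3x3 block
whose characteristic polynomial in ``xi = s**alpha`` is the monic cubic

    xi^3 + a2 xi^2 + a1 xi + a0,

and the Routh-Hurwitz conditions ``a2, a1, a0 > 0`` and ``a2 a1 - a3 a0 > 0``
certify that all roots have negative real part, hence lie outside every
``alpha``-sector.  A closed-form sufficient condition on the rates alone,

    (d^{3a} + f^{2a} d^a) / (4 f^{2a} lam_N^a + 2 f^a d^{2a}) < 1,

implies the Routh-Hurwitz inequalities at the Delta-expressing equilibrium.

The per-cell reduction implicitly uses the exchange symmetry of the two
cells; :func:`full_jacobian` provides the unreduced matrix of the whole
system for a numeric cross-check (and for Newton refinement of equilibria).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import CellTopology, ModelParameters, _lambda_vector, effective_rates

__all__ = [
    "CharPoly",
    "StabilityReport",
    "jacobian",
    "full_jacobian",
    "e0_eigenvalues",
    "characteristic_coefficients",
    "routh_hurwitz",
    "fractional_arg_condition",
    "sufficient_condition_ratio",
    "stability_report",
]

#: |margin| below this is treated as numerically on the sector boundary.
ARG_MARGIN_TOL = 1.0e-10


@dataclass(frozen=True)
class CharPoly:
    """Monic cubic ``xi^3 + a2 xi^2 + a1 xi + a0`` (a3 == 1 by construction)."""

    a3: float
    a2: float
    a1: float
    a0: float

    def __post_init__(self) -> None:
        if self.a3 != 1.0:
            raise ValueError("characteristic polynomial must be monic (a3 = 1)")

    def coefficients(self) -> np.ndarray:
        return np.array([self.a3, self.a2, self.a1, self.a0])

    def roots(self) -> np.ndarray:
        return np.roots(self.coefficients())


@dataclass(frozen=True)
class StabilityReport:
    char: CharPoly | None
    rh_flags: dict
    rh_stable: bool
    sufficient_ratio: float
    sufficient_holds: bool
    eigenvalues: np.ndarray
    arg_margins: np.ndarray
    verdict: str  # "stable" | "unstable" | "inconclusive"

    def to_dict(self) -> dict:
        return {
            "char": None if self.char is None else list(self.char.coefficients()),
            "rh_flags": self.rh_flags,
            "rh_stable": self.rh_stable,
            "sufficient_ratio": self.sufficient_ratio,
            "sufficient_holds": self.sufficient_holds,
            "eigenvalues_real": list(np.real(self.eigenvalues)),
            "eigenvalues_imag": list(np.imag(self.eigenvalues)),
            "arg_margins": list(self.arg_margins),
            "verdict": self.verdict,
        }


def jacobian(params: ModelParameters, point: Sequence[float]) -> np.ndarray:
    """Per-cell 3x3 Jacobian block at a symmetric point ``(D, N, A)``.

    Both cells carry the same values, so the neighbour's Delta and Notch are
    identified with the cell's own; this is the reduction used for the
    two-cell characteristic polynomial.
    """
    D, N, A = (float(v) for v in point)
    e = effective_rates(params)
    hill_den = (e.b + D * N) ** 2
    inh_den = (1.0 + e.theta * A) ** 2
    return np.array(
        [
            [-e.f * N - e.d, -e.f * D, -e.theta * e.lambda_delta / inh_den],
            [e.f * N, e.f * D - e.d, 0.0],
            [e.a * e.b * N / hill_den, e.a * e.b * D / hill_den, -e.d],
        ]
    )


def full_jacobian(
    params: ModelParameters,
    topology: CellTopology,
    state: np.ndarray,
    lambda_per_cell: Sequence[float] | None = None,
) -> np.ndarray:
    """Analytic Jacobian of the full 3n-dimensional system at ``state``."""
    n = topology.n_cells
    state = np.asarray(state, dtype=float).reshape(n, 3)
    e = effective_rates(params)
    lam_eff = _lambda_vector(params, n, lambda_per_cell) ** params.alpha
    D, N, A = state[:, 0], state[:, 1], state[:, 2]
    adj = topology.adjacency_matrix()
    sum_n = adj @ N
    sum_d = adj @ D
    s = sum_d * N
    J = np.zeros((3 * n, 3 * n))
    iD, iN, iA = 3 * np.arange(n), 3 * np.arange(n) + 1, 3 * np.arange(n) + 2
    hill = e.a * e.b / (e.b + s) ** 2
    J[iD, iD] = -e.f * sum_n - e.d
    J[iD, iA] = -lam_eff * e.theta / (1.0 + e.theta * A) ** 2
    J[iN, iN] = e.f * sum_d - e.d
    J[iA, iN] = hill * sum_d
    J[iA, iA] = -e.d
    for i in range(n):
        for j in topology.neighbors[i]:
            J[iD[i], iN[j]] = -e.f * D[i]
            J[iN[i], iD[j]] = e.f * N[i]
            J[iA[i], iD[j]] = hill[i] * N[i]
    return J


def e0_eigenvalues(params: ModelParameters) -> np.ndarray:
    """Eigenvalues of the per-cell block at the no-Delta equilibrium.

    With ``lam = 0`` the block becomes lower-triangular at
    ``(0, lam_N^a/d^a, 0)`` and the eigenvalues are read off the diagonal:
    ``xi_{1,2} = -d^a`` and ``xi_3 = -lam_N^a f^a / d^a - d^a``.  All three
    are negative real, so the equilibrium is locally asymptotically stable
    for every valid parameter set and every order ``alpha``.
    """
    e = effective_rates(params)
    return np.array([-e.d, -e.d, -e.lambda_notch * e.f / e.d - e.d])


def characteristic_coefficients(params: ModelParameters, eq) -> CharPoly:
    """Characteristic cubic in ``xi = s**alpha`` at a Delta-expressing point.

    ``eq`` is an Equilibrium (or any object with per-cell ``values``); the
    coefficients use the symmetric per-cell values ``(D, N, A)`` of cell 0.
    """
    values = np.asarray(getattr(eq, "values", eq), dtype=float).reshape(-1, 3)
    D, N, A = values[0]
    e = effective_rates(params)
    coupling = (
        e.a
        * e.b
        * e.theta
        * e.lambda_delta
        / ((1.0 + e.theta * A) ** 2 * (e.b + D * N) ** 2)
    )
    a2 = e.f * N - e.f * D + 3.0 * e.d
    a1 = 2.0 * e.d * e.f * N - 2.0 * e.d * e.f * D + 3.0 * e.d**2 + coupling * N
    a0 = -(e.d**2) * e.f * D + e.d**2 * e.f * N + e.d**3 + coupling * e.d * N
    return CharPoly(a3=1.0, a2=a2, a1=a1, a0=a0)


def routh_hurwitz(char: CharPoly) -> tuple[bool, dict]:
    """Routh-Hurwitz test for the monic cubic: all roots in the open left
    half-plane iff a3, a2, a1, a0 > 0 and a2*a1 - a3*a0 > 0."""
    h2 = char.a2 * char.a1 - char.a3 * char.a0
    detail = {
        "a3": char.a3,
        "a2": char.a2,
        "a1": char.a1,
        "a0": char.a0,
        "a2a1_minus_a3a0": h2,
    }
    ok = char.a3 > 0 and char.a2 > 0 and char.a1 > 0 and char.a0 > 0 and h2 > 0
    return ok, detail


def fractional_arg_condition(
    eigenvalues: Sequence[complex] | np.ndarray, alpha: float
) -> tuple[str, np.ndarray]:
    """Sector (Matignon) condition: stable iff min |arg(xi)| > alpha*pi/2.

    Returns ``(verdict, margins)`` with ``margins[i] = |arg(xi_i)| -
    alpha*pi/2``; a margin within ``ARG_MARGIN_TOL`` of zero (or an
    eigenvalue at the origin) makes the verdict "inconclusive".
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must satisfy 0 < alpha <= 1, got {alpha!r}")
    xs = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    if not np.all(np.isfinite(xs)):
        raise ValueError("eigenvalues must be finite")
    threshold = alpha * np.pi / 2.0
    margins = np.abs(np.angle(xs)) - threshold
    if np.any(np.abs(xs) == 0.0) or np.any(np.abs(margins) < ARG_MARGIN_TOL):
        return "inconclusive", margins
    return ("stable" if np.all(margins > 0) else "unstable"), margins


def sufficient_condition_ratio(params: ModelParameters) -> tuple[float, bool]:
    """Closed-form stability ratio; ``ratio < 1`` certifies Routh-Hurwitz
    stability of the Delta-expressing equilibrium."""
    e = effective_rates(params)
    ratio = (e.d**3 + e.f**2 * e.d) / (
        4.0 * e.f**2 * e.lambda_notch + 2.0 * e.f * e.d**2
    )
    return float(ratio), bool(ratio < 1.0)


def stability_report(params: ModelParameters, eq) -> StabilityReport:
    """Full per-equilibrium stability summary.

    Uses the characteristic cubic for Delta-expressing points and the closed
    form for the no-Delta equilibrium; the verdict is always taken from the
    fractional sector condition on the eigenvalues.
    """
    kind = getattr(eq, "kind", "E1")
    if kind == "E0":
        char = None
        eigs = e0_eigenvalues(params)
        rh_ok, detail = True, {"closed_form": "triangular block, negative diagonal"}
    else:
        char = characteristic_coefficients(params, eq)
        eigs = char.roots()
        rh_ok, detail = routh_hurwitz(char)
    ratio, holds = sufficient_condition_ratio(params)
    verdict, margins = fractional_arg_condition(eigs, params.alpha)
    return StabilityReport(
        char=char,
        rh_flags=detail,
        rh_stable=rh_ok,
        sufficient_ratio=ratio,
        sufficient_holds=holds,
        eigenvalues=np.asarray(eigs, dtype=complex),
        arg_margins=margins,
        verdict=verdict,
    )
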