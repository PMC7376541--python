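"""Fixed points of the two-cell Delta-Notch system.

Two equilibria exist.  With no Delta production (``lam = 0``) the system has
the closed-form no-Delta equilibrium

    E0 = (0, lam_N^a / d^a, 0)   per cell,

With Delta expressed (``lam > 0``) the symmetric Delta-expressing equilibrium
E1 has equal values in both cells; eliminating D and A through the N- and
A-equations,

    D(N) = (d^a N - lam_N^a) / (f^a N),
    A(N) = (a^a / d^a) * D N / (b^a + D N),

reduces the D-equation to one scalar equation g(N) = 0 on
``N > lam_N^a / d^a``.  A cubic reduction of g (coefficients B1..B4 and the
Cardano / trigonometric root formulas) provides closed-form starting points;
every reported equilibrium is then polished by damped Newton iteration on the
full system and certified by its residual — the fixed-point equations, not
any closed form, are the ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import CellTopology, ModelParameters, effective_rates, rhs
from .stability import full_jacobian

__all__ = [
    "CubicCoefficients",
    "Equilibrium",
    "NoAdmissibleRootError",
    "cubic_coefficients",
    "cardano_roots",
    "equilibrium_no_delta",
    "equilibrium_with_delta",
]

#: residual tolerance certifying a refined fixed point
RESIDUAL_TOL = 1.0e-9


class NoAdmissibleRootError(ValueError):
    """No candidate root yields a positive, residual-certified fixed point."""


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of the cubic reduction ``B1 N^3 + B2 N^2 + B3 N + B4 = 0``
    together with the depressed-cubic parameters p and q."""

    B1: float
    B2: float
    B3: float
    B4: float
    p: float = field(init=False)
    q_card: float = field(init=False)

    def __post_init__(self) -> None:
        if self.B1 == 0.0:
            raise ValueError("degenerate cubic: B1 = 0")
        B1, B2, B3, B4 = self.B1, self.B2, self.B3, self.B4
        object.__setattr__(self, "p", (3 * B1 * B3 - B2**2) / (3 * B1**2))
        object.__setattr__(
            self,
            "q_card",
            (27 * B1**2 * B4 - 9 * B1 * B2 * B3 + 2 * B2**3) / (27 * B1**3),
        )

    def poly(self, x: float) -> float:
        return ((self.B1 * x + self.B2) * x + self.B3) * x + self.B4


def cubic_coefficients(params: ModelParameters) -> CubicCoefficients:
    """The cubic reduction coefficients for the symmetric two-cell case.

    These are the textbook closed forms for this model; note that they carry
    known internal inconsistencies with the fixed-point equations (see the
    methods note), which is why :func:`equilibrium_with_delta` treats their
    roots only as starting points.
    """
    e = effective_rates(params)
    d_, f_, lN, a_, b_, th, lam = (
        e.d,
        e.f,
        e.lambda_notch,
        e.a,
        e.b,
        e.theta,
        e.lambda_delta,
    )
    u = d_**2 + a_ * th * d_
    v = d_ * b_ * f_ - d_ * lN - a_ * th * lN
    B1 = d_ * f_ * u
    B2 = u * (d_**2 + lN * f_) + d_ * f_ * v - lam * d_**2 * f_
    B3 = (d_**2 + lN * f_) * v - d_ * lN * u - lam * d_ * f_ * (b_ * f_ - lN)
    B4 = -d_ * lN * v
    return CubicCoefficients(B1=B1, B2=B2, B3=B3, B4=B4)


def _polish_cubic_root(coeffs: CubicCoefficients, x: float) -> float:
    # a few Newton steps on the cubic tighten Cardano/trig roots to ~1e-15
    B1, B2, B3 = coeffs.B1, coeffs.B2, coeffs.B3
    for _ in range(4):
        fx = coeffs.poly(x)
        dfx = (3 * B1 * x + 2 * B2) * x + B3
        if dfx == 0:
            break
        step = fx / dfx
        x -= step
        if abs(step) < 1e-16 * max(1.0, abs(x)):
            break
    return x


def cardano_roots(coeffs: CubicCoefficients) -> np.ndarray:
    """All real roots of the cubic, ascending.

    Positive Cardano discriminant: the single real root from the depressed
    cubic with real cube roots.  Negative discriminant (three real roots):
    the trigonometric method.  Each root is Newton-polished so that
    ``|poly(N)| / max(1, |B4|) < 1e-10``.
    """
    p, q = coeffs.p, coeffs.q_card
    shift = -coeffs.B2 / (3.0 * coeffs.B1)
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    if disc > 0.0:
        s = np.sqrt(disc)
        roots = [np.cbrt(-q / 2.0 + s) + np.cbrt(-q / 2.0 - s) + shift]
    elif disc == 0.0:
        if p == 0.0:
            roots = [shift]
        else:
            u = np.cbrt(-q / 2.0)
            roots = [2.0 * u + shift, -u + shift]
    else:
        r = np.sqrt(-p / 3.0)
        phi = np.arccos(np.clip(3.0 * q / (2.0 * p * r), -1.0, 1.0))
        roots = [
            2.0 * r * np.cos((phi - 2.0 * np.pi * k) / 3.0) + shift for k in range(3)
        ]
    polished = sorted(_polish_cubic_root(coeffs, x) for x in roots)
    return np.array(polished)


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with residual diagnostics.

    ``values`` has shape (n_cells, 3); ``residual`` is the max-norm of the
    right-hand side at the point.  ``info`` records the cubic roots that were
    considered and any additional admissible points found.
    """

    kind: str  # "E0" | "E1"
    values: np.ndarray
    residual: float
    refined: bool
    info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "values": self.values.tolist(),
            "residual": self.residual,
            "refined": self.refined,
            "info": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.info.items()
            },
        }


def equilibrium_no_delta(
    params: ModelParameters, topology: CellTopology | None = None
) -> Equilibrium:
    """Closed-form no-Delta equilibrium ``(0, lam_N^a/d^a, 0)`` per cell.

    ``lambda_delta`` is treated as zero regardless of its value in
    ``params``.
    """
    topology = topology or CellTopology.pair()
    e = effective_rates(params)
    n_star = e.lambda_notch / e.d
    values = np.zeros((topology.n_cells, 3))
    values[:, 1] = n_star
    p0 = params.replace(lambda_delta=0.0)
    residual = float(np.max(np.abs(rhs(values, p0, topology))))
    return Equilibrium(kind="E0", values=values, residual=residual, refined=False)


def _symmetric_candidates(params: ModelParameters) -> tuple[list[float], np.ndarray]:
    """Candidate symmetric N values: printed-cubic roots plus a bracketed
    root of the exact scalar reduction g(N)."""
    e = effective_rates(params)
    n0 = e.lambda_notch / e.d

    def g(N: float) -> float:
        D = (e.d * N - e.lambda_notch) / (e.f * N)
        s = D * N
        A = (e.a / e.d) * s / (e.b + s)
        return e.lambda_delta / (1.0 + e.theta * A) - e.f * D * N - e.d * D

    cubic = cardano_roots(cubic_coefficients(params))
    candidates = [float(x) for x in cubic if x > n0]
    # geometric scan for a sign change of g above the no-Delta baseline
    lo = n0 * (1.0 + 1e-12) + 1e-300
    g_lo = g(lo)
    hi = max(2.0 * n0, n0 + 1.0)
    for _ in range(200):
        if g_lo * g(hi) <= 0:
            from scipy.optimize import brentq

            candidates.append(float(brentq(g, lo, hi, xtol=1e-13, rtol=1e-14)))
            break
        lo, g_lo = hi, g(hi)
        hi *= 2.0
        if hi > 1e15:
            break
    return candidates, cubic


def _newton_refine(
    params: ModelParameters, topology: CellTopology, x0: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """Damped Newton on the full system; returns (point, residual, converged)."""
    x = x0.ravel().copy()
    n = topology.n_cells

    def res(v: np.ndarray) -> np.ndarray:
        return rhs(v.reshape(n, 3), params, topology).ravel()

    r = res(x)
    norm = np.max(np.abs(r))
    for _ in range(50):
        if norm < 1e-12:
            break
        J = full_jacobian(params, topology, x)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            return x.reshape(n, 3), norm, False
        t = 1.0
        for _ in range(30):
            x_new = x + t * step
            r_new = res(x_new)
            n_new = np.max(np.abs(r_new))
            if n_new < norm:
                x, r, norm = x_new, r_new, n_new
                break
            t /= 2.0
        else:
            break
    return x.reshape(n, 3), norm, norm < RESIDUAL_TOL


def equilibrium_with_delta(
    params: ModelParameters, topology: CellTopology | None = None
) -> Equilibrium:
    """The Delta-expressing equilibrium of the two-cell system.

    Candidate symmetric Notch levels are the admissible real roots of the
    cubic reduction (``N > lam_N^a/d^a`` so that D >= 0) together with a
    bracketed root of the exact scalar reduction; each candidate is completed
    to a full state via the N- and A-equations and polished by damped Newton.
    The admissible (componentwise positive) fixed point with the smallest
    residual is returned; multiple admissible points are flagged in ``info``.
    """
    if params.lambda_delta <= 0:
        raise ValueError("equilibrium_with_delta requires lambda_delta > 0")
    topology = topology or CellTopology.pair()
    e = effective_rates(params)
    candidates, cubic = _symmetric_candidates(params)
    solutions: list[tuple[np.ndarray, float]] = []
    for n_cand in candidates:
        D = (e.d * n_cand - e.lambda_notch) / (e.f * n_cand)
        s = D * n_cand
        A = (e.a / e.d) * s / (e.b + s)
        x0 = np.tile([max(D, 0.0), n_cand, max(A, 0.0)], (topology.n_cells, 1))
        point, residual, ok = _newton_refine(params, topology, x0)
        if ok and np.all(point > 0):
            if not any(
                np.allclose(point, p, rtol=1e-6, atol=1e-9) for p, _ in solutions
            ):
                solutions.append((point, residual))
    if not solutions:
        raise NoAdmissibleRootError(
            "no admissible Delta-expressing equilibrium found; "
            f"real cubic roots were {np.round(cubic, 6).tolist()}"
        )
    solutions.sort(key=lambda pr: pr[1])
    point, residual = solutions[0]
    info = {
        "cubic_roots": cubic,
        "candidates": np.array(candidates),
        "n_admissible": len(solutions),
    }
    if len(solutions) > 1:
        warnings.warn(
            f"{len(solutions)} admissible equilibria found; reporting the one "
            "with the smallest residual",
            stacklevel=2,
        )
        info["alternatives"] = np.array([p for p, _ in solutions[1:]])
    return Equilibrium(
        kind="E1", values=point, residual=residual, refined=True, info=info
    )
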