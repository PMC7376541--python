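"""Packaged scenario presets.

The default constants (the "table-1" set) are lam in {0, 1000}, f = d = 0.01,
lam_N = 0.07, a = 0.01, b = 200, theta = 1e6, alpha = 0.9.  Lattice presets
vary the degradation rate d: 0.018 reproduces the wild-type boundary pattern,
0.012 the mutant, 0.001 the complete mutant, and 0.004 is the operating point
where the fractional and integer-order models classify differently.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lattice import LatticeScenario
from .model import CellTopology, ModelParameters
from .solver import SolverConfig

__all__ = ["ScenarioPreset", "PRESETS", "get_preset"]

TABLE1 = ModelParameters(
    lambda_delta=1000.0,
    lambda_notch=0.07,
    f=0.01,
    d=0.01,
    a=0.01,
    b=200.0,
    theta=1.0e6,
    alpha=0.9,
)


@dataclass(frozen=True)
class ScenarioPreset:
    """A named bundle of parameters, topology/scenario and solver settings."""

    name: str
    params: ModelParameters
    kind: str  # "two-cell" | "lattice"
    solver: SolverConfig
    lattice: LatticeScenario | None = None
    compare_alphas: tuple = ()

    def topology(self) -> CellTopology:
        if self.kind == "two-cell":
            return CellTopology.pair()
        return CellTopology.grid(self.lattice.rows, self.lattice.cols)


def _two_cell(name: str, lam: float) -> ScenarioPreset:
    params = TABLE1.replace(lambda_delta=lam)
    return ScenarioPreset(
        name=name,
        params=params,
        kind="two-cell",
        solver=SolverConfig(h=0.1, t_end=4000.0),
    )


def _lattice(name: str, d: float, compare_alphas: tuple = ()) -> ScenarioPreset:
    params = TABLE1.replace(d=d)
    scenario = LatticeScenario(params=params)
    return ScenarioPreset(
        name=name,
        params=params,
        kind="lattice",
        solver=scenario.solver,
        lattice=scenario,
        compare_alphas=compare_alphas,
    )


PRESETS: dict[str, ScenarioPreset] = {
    p.name: p
    for p in (
        _two_cell("table1-lambda0", 0.0),
        _two_cell("table1-lambda1000", 1000.0),
        _lattice("lattice-wildtype", 0.018),
        _lattice("lattice-mutant", 0.012),
        _lattice("lattice-complete", 0.001),
        _lattice("lattice-order-compare", 0.004, compare_alphas=(0.7, 1.0)),
    )
}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
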