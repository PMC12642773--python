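"""Synthetic test systems with closed-form-verifiable facts.

Three single-cell scenarios cover the qualitatively distinct phase
portraits of a viability region:

* **A** — a linear sink at (0.5, 0.5) inside the box [0, 1]^2; the flow on
  the whole boundary points inward, every interior state is asymptotically
  viable.
* **B** — the same sink moved to (1.5, 0.5), outside the box; every interior
  trajectory exits through the upper x1 facet in finite time (from the
  center at t = ln 2), the whole region is transiently viable.
* **C** — a stable spiral (decay rate lambda = -0.1, rotation omega = 1) at
  the origin in [-1, 1] x [-1, 0.5]; the flow is tangent to the upper x2
  facet where omega*x1 + lambda*x2 = 0, i.e. at x1 = 0.05, splitting the
  region into asymptotically and transiently viable subsets — the mixed
  case that a mortality manifold organizes.

The two-cell system pairs a "blue" and a "purple" cell (one essential
variable each, lower bounds b_min = 0.1 and p_min = 0.05).  Their joint
dynamics is a coupled linear field driving both variables downward, so the
corner (b_min, p_min) is jointly fatal and seeds an ordering manifold.
Each survivor's solo dynamics is the bistable cubic x' = -x(x-a)(x-1) with
unstable point a = 0.4, viable attractor 1 and terminal attractor 0 (below
the threshold) — the reduced system whose unstable equilibrium seeds a
collapse manifold at (a, p_min).

All numerics are chosen so every expected fact is derivable in closed form;
``FixtureSpec.expected_facts`` records them machine-checkably and the test
suite re-verifies each one with the package's own operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Union

import numpy as np

from .dynsys import VectorField, linear_field
from .hybrid import CellSpec, MultiCellSystem
from .intrinsic import CAConfiguration, Grid
from .viability import BoxConstraint, ViabilityRegion, box_region

__all__ = [
    "FixtureSpec",
    "make_single_cell_fixture",
    "make_two_cell_fixture",
    "make_gol_fixture",
    "SINGLE_CELL_SCENARIOS",
    "GOL_FIXTURES",
]

SINGLE_CELL_SCENARIOS = ("A", "B", "C")
GOL_FIXTURES = ("glider", "block", "blinker", "glider_vs_block")


@dataclass(frozen=True)
class FixtureSpec:
    """Name, parameters and machine-checkable expected facts of a fixture."""

    name: str
    parameters: dict[str, Any]
    expected_facts: dict[str, Any]


def _merged(defaults: dict[str, Any], overrides: dict[str, Any]) -> dict[str, Any]:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown override(s): {sorted(unknown)}")
    out = dict(defaults)
    out.update(overrides)
    return out


def make_single_cell_fixture(
    scenario: str, **overrides
) -> tuple[VectorField, ViabilityRegion, FixtureSpec]:
    """Scenario A, B or C (see module docstring).  Overrides are shallow
    parameter replacements; the derived expected facts are recomputed."""
    if scenario == "A":
        p = _merged({"center": (0.5, 0.5), "rate": 1.0, "box": ((0.0, 1.0), (0.0, 1.0))}, overrides)
        A = np.array([[-p["rate"], 0.0], [0.0, -p["rate"]]])
        field = linear_field(A, p["center"])
        region = box_region(p["box"])
        spec = FixtureSpec(
            "single_cell_A",
            p,
            {
                "all_boundary_flow_inward": True,
                "attractor": tuple(p["center"]),
                "attractor_stability": "stable_node",
                "grid_status": "asymptotically_viable",
            },
        )
        return field, region, spec
    if scenario == "B":
        p = _merged({"center": (1.5, 0.5), "rate": 1.0, "box": ((0.0, 1.0), (0.0, 1.0))}, overrides)
        A = np.array([[-p["rate"], 0.0], [0.0, -p["rate"]]])
        field = linear_field(A, p["center"])
        region = box_region(p["box"])
        cx = p["center"][0]
        hi = p["box"][0][1]
        x0 = 0.5 * (p["box"][0][0] + hi)
        # solve c + (x0 - c) e^{-rate t} = hi for the center start
        death_time = math.log((cx - x0) / (cx - hi)) / p["rate"]
        spec = FixtureSpec(
            "single_cell_B",
            p,
            {
                "grid_status": "transiently_viable",
                "exit_constraint": "x1_upper",
                "death_time_from_center": death_time,
            },
        )
        return field, region, spec
    if scenario == "C":
        p = _merged(
            {
                "lam": -0.1,
                "omega": 1.0,
                "center": (0.0, 0.0),
                "box": ((-1.0, 1.0), (-1.0, 0.5)),
            },
            overrides,
        )
        lam, omega = p["lam"], p["omega"]
        A = np.array([[lam, -omega], [omega, lam]])
        field = linear_field(A, p["center"])
        region = box_region(p["box"])
        top = p["box"][1][1]
        # flow tangent to the upper x2 facet: x2' = omega x1 + lam x2 = 0
        tangency_x1 = -lam * top / omega
        spec = FixtureSpec(
            "single_cell_C",
            p,
            {
                "attractor": tuple(p["center"]),
                "attractor_stability": "stable_spiral",
                "tangency_facet": "x2_upper",
                "tangency": (tangency_x1, top),
                "grid_statuses_present": (
                    "asymptotically_viable",
                    "transiently_viable",
                ),
            },
        )
        return field, region, spec
    raise ValueError(f"unknown scenario {scenario!r} (expected A, B or C)")


def _bistable_cubic(a: float, name: str) -> VectorField:
    """x' = -x (x - a)(x - 1): stable at 0 and 1, unstable at a."""

    def rhs(x):
        v = x[0]
        return np.array([-v * (v - a) * (v - 1.0)])

    def jac(x):
        v = x[0]
        return np.array([[-(3.0 * v * v - 2.0 * (1.0 + a) * v + a)]])

    return VectorField(1, rhs, jac, names=(name,))


TwoCellFixture = tuple[MultiCellSystem, FixtureSpec]


def make_two_cell_fixture(**overrides) -> TwoCellFixture:
    """The blue/purple pair of the hybrid examples.

    Joint dynamics (triangular linear field, both variables driven down):

        b' = -alpha (b - c_b) - kappa (p - c_p)
        p' = -gamma (p - c_p)

    Solo dynamics of each survivor: the bistable cubic with unstable point
    ``a``.  Expected facts: the joint-fatal corner at (b_min, p_min) and the
    collapse point (a, p_min) on purple's death facet.
    """
    p = _merged(
        {
            "b_min": 0.1,
            "p_min": 0.05,
            "a": 0.4,
            "alpha": 1.0,
            "gamma": 1.4,
            "kappa": 0.3,
            "c_b": -0.3,
            "c_p": -0.2,
        },
        overrides,
    )
    A = np.array([[-p["alpha"], -p["kappa"]], [0.0, -p["gamma"]]])
    joint = linear_field(A, (p["c_b"], p["c_p"]), names=("b", "p"))

    blue = CellSpec(
        "blue",
        (0,),
        ViabilityRegion(1, (BoxConstraint(0, "lower", p["b_min"], "b_min"),)),
    )
    purple = CellSpec(
        "purple",
        (1,),
        ViabilityRegion(1, (BoxConstraint(0, "lower", p["p_min"], "p_min"),)),
    )
    system = MultiCellSystem(
        cells=(blue, purple),
        dynamics={
            frozenset({"blue", "purple"}): joint,
            frozenset({"blue"}): _bistable_cubic(p["a"], "b"),
            frozenset({"purple"}): _bistable_cubic(p["a"], "p"),
        },
    )
    spec = FixtureSpec(
        "two_cell",
        p,
        {
            "joint_fatal_corner": (p["b_min"], p["p_min"]),
            "collapse_point": (p["a"], p["p_min"]),
            "reduced_blue_equilibria": {
                0.0: "stable_node",
                p["a"]: "unstable",
                1.0: "stable_node",
            },
            "blue_viable_attractor": 1.0,
        },
    )
    return system, spec


_BLOCK = frozenset({(0, 0), (0, 1), (1, 0), (1, 1)})
_BLINKER_H = frozenset({(0, 0), (0, 1), (0, 2)})


def make_gol_fixture(name: str) -> Union[Grid, CAConfiguration]:
    """Canonical Game-of-Life fixtures.

    ``glider`` and ``glider_vs_block`` return :class:`CAConfiguration`
    (phase 0 at the origin; the latter with a 2x2 block placed on the
    glider's southeast path); ``block`` and ``blinker`` return bare grids.
    """
    if name == "glider":
        return CAConfiguration(phase=0, position=(0, 0))
    if name == "block":
        return Grid.from_cells(_BLOCK, margin=3)
    if name == "blinker":
        return Grid.from_cells(_BLINKER_H, margin=3)
    if name == "glider_vs_block":
        block = frozenset({(8, 8), (8, 9), (9, 8), (9, 9)})
        return CAConfiguration(phase=0, position=(0, 0), environment=block)
    raise ValueError(f"unknown GoL fixture {name!r} (expected one of {GOL_FIXTURES})")
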