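"""Multicellular death cascades as a hybrid dynamical system.

A group of cells evolves continuously inside the intersection of the cells'
viability regions; when one or more cells hit their constraints the system
undergoes a discrete death event that removes the dying cells' variables and
hands the survivors to the dynamics registered for the reduced alive subset.
The possible alive subsets and death events form a directed *configuration
graph* (3^k - 2^k possible death edges for k cells), of which any concrete
simulation realizes a path.

Collapse manifolds extend organizing structures of a reduced (post-death)
system backward into the higher-dimensional pre-death space: the facet state
that collapses exactly onto, say, an unstable equilibrium of the survivor's
dynamics is integrated backward in time, and the resulting curve separates
initial conditions by the survivor's post-collapse fate.

Per-alive-subset dynamics are supplied explicitly (a registry): in general,
post-death dynamics need not be a restriction of the full field.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .decomposition import (
    DEFAULT_BACKWARD_HORIZON,
    Manifold,
    _backward_polyline,
)
from .dynsys import Trajectory, VectorField, integrate, stability
from .viability import (
    BoxConstraint,
    Constraint,
    SmoothConstraint,
    ViabilityRegion,
    DEFAULT_TIE_TOL,
)

__all__ = [
    "CellSpec",
    "MultiCellSystem",
    "DeathEvent",
    "HybridTrajectory",
    "CollapsePoint",
    "configuration_graph",
    "simulate_hybrid",
    "reduced_system",
    "collapse_state",
    "find_collapse_points",
    "collapse_manifold",
]

AliveSet = frozenset


@dataclass(frozen=True)
class CellSpec:
    """One cell: a name, the global indices of its variables in the full
    state, and its viability region over those variables (local indices)."""

    name: str
    variables: tuple[int, ...]
    region: ViabilityRegion

    def __post_init__(self):
        if self.region.dimension != len(self.variables):
            raise ValueError(
                f"cell {self.name!r}: region dimension "
                f"{self.region.dimension} != {len(self.variables)} variables"
            )


@dataclass(frozen=True)
class MultiCellSystem:
    """Cells plus a per-alive-subset dynamics registry.

    ``dynamics`` maps each reachable nonempty alive subset (frozenset of
    cell names) to a :class:`VectorField` over the surviving variables,
    ordered by ascending global index.  ``collapse_rule`` maps
    ``(state, alive, dying)`` to the reduced state; the default drops the
    dying cells' coordinates, keeping surviving coordinates bit-identical.
    """

    cells: tuple[CellSpec, ...]
    dynamics: dict
    collapse_rule: Optional[Callable] = None

    def __post_init__(self):
        seen: set[int] = set()
        for c in self.cells:
            if seen & set(c.variables):
                raise ValueError("cells' variable index sets must be disjoint")
            seen |= set(c.variables)
        names = [c.name for c in self.cells]
        if len(set(names)) != len(names):
            raise ValueError("cell names must be unique")
        for size in range(1, len(self.cells) + 1):
            for combo in itertools.combinations(names, size):
                if frozenset(combo) not in self.dynamics:
                    raise ValueError(
                        f"dynamics missing for alive subset {set(combo)}"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.cells)

    @property
    def dimension(self) -> int:
        return sum(len(c.variables) for c in self.cells)

    def cell(self, name: str) -> CellSpec:
        for c in self.cells:
            if c.name == name:
                return c
        raise KeyError(name)

    def alive_variables(self, alive: Iterable[str]) -> tuple[int, ...]:
        """Global variable indices of an alive subset, ascending."""
        idx: list[int] = []
        for name in alive:
            idx.extend(self.cell(name).variables)
        return tuple(sorted(idx))


def _remap_constraint(con: Constraint, offset_map: dict[int, int], prefix: str):
    if isinstance(con, BoxConstraint):
        return BoxConstraint(
            offset_map[con.index], con.side, con.threshold, f"{prefix}{con.id}"
        )
    if isinstance(con, SmoothConstraint):
        idx = sorted(offset_map, key=offset_map.get)  # local order

        def g(x, _c=con, _idx=idx):
            return _c.value(np.asarray(x)[list(_idx)])

        def grad(x, _c=con, _idx=idx, _n=None):
            full = np.zeros(len(x))
            full[list(_idx)] = _c.gradient(np.asarray(x)[list(_idx)])
            return full

        return SmoothConstraint(g, grad, f"{prefix}{con.id}")
    raise TypeError(f"unsupported constraint type {type(con)}")


def _joint_region(system: MultiCellSystem, alive: AliveSet) -> ViabilityRegion:
    """Product of the alive cells' regions over the reduced state."""
    global_idx = system.alive_variables(alive)
    pos = {g: i for i, g in enumerate(global_idx)}
    cons: list[Constraint] = []
    for cell in system.cells:
        if cell.name not in alive:
            continue
        offset_map = {
            local: pos[glob] for local, glob in enumerate(cell.variables)
        }
        for con in cell.region.constraints:
            cons.append(_remap_constraint(con, offset_map, f"{cell.name}:"))
    return ViabilityRegion(len(global_idx), tuple(cons))


def _constraint_owner(cid: str) -> str:
    return cid.split(":", 1)[0]


def configuration_graph(system: MultiCellSystem) -> nx.DiGraph:
    """The directed graph of alive subsets and possible death events.

    Nodes are all 2^k alive subsets (including the empty one); for every
    source subset and every nonempty dying subset of it there is an edge to
    the source minus the dying cells, carrying ``dying`` and a ``realized``
    flag (False until a simulation takes it).
    """
    if len(system.cells) < 1:
        raise ValueError("need at least one cell")
    names = system.names
    G = nx.DiGraph()
    for size in range(len(names) + 1):
        for combo in itertools.combinations(names, size):
            G.add_node(frozenset(combo))
    for source in list(G.nodes):
        for dsize in range(1, len(source) + 1):
            for dying in itertools.combinations(sorted(source), dsize):
                dying = frozenset(dying)
                G.add_edge(source, source - dying, dying=dying, realized=False)
    return G


def reduced_system(
    system: MultiCellSystem, alive: Iterable[str]
) -> tuple[VectorField, ViabilityRegion]:
    """The registered field and product region for an alive subset."""
    alive = frozenset(alive)
    if not alive:
        raise ValueError("alive subset must be nonempty")
    unknown = alive - set(system.names)
    if unknown:
        raise KeyError(f"unknown cells {unknown}")
    return system.dynamics[alive], _joint_region(system, alive)


def collapse_state(
    x: Sequence[float],
    alive: Iterable[str],
    dying: Iterable[str],
    system: MultiCellSystem,
    collapse_rule: Optional[Callable] = None,
) -> np.ndarray:
    """Discrete state map across a death event.

    The default rule projects out the dying cells' coordinates; surviving
    coordinates are carried over bit-identically.  A custom
    ``collapse_rule(state, alive, dying, system)`` may append debris
    variables but must preserve the survivors' coordinates.
    """
    alive, dying = frozenset(alive), frozenset(dying)
    if not dying:
        raise ValueError("dying subset must be nonempty")
    if not dying <= alive:
        raise ValueError("dying subset must be contained in the alive subset")
    x = np.asarray(x, dtype=float)
    rule = collapse_rule if collapse_rule is not None else system.collapse_rule
    if rule is not None:
        return np.asarray(rule(x, alive, dying, system), dtype=float)
    alive_idx = system.alive_variables(alive)
    surv_idx = system.alive_variables(alive - dying)
    pos = {g: i for i, g in enumerate(alive_idx)}
    return x[[pos[g] for g in surv_idx]].copy()


@dataclass(frozen=True)
class DeathEvent:
    """One discrete transition: who died, when, and the state before/after."""

    time: float
    dying: AliveSet
    pre_alive: AliveSet
    pre_state: np.ndarray
    post_state: np.ndarray
    constraint_ids: tuple[str, ...] = ()


@dataclass
class HybridTrajectory:
    """Continuous segments per alive subset, linked by death events."""

    segments: list[tuple[AliveSet, Trajectory]]
    events: list[DeathEvent]
    final_alive: AliveSet = frozenset()

    @property
    def death_order(self) -> list[AliveSet]:
        return [e.dying for e in self.events]


def simulate_hybrid(
    system: MultiCellSystem,
    x0: Sequence[float],
    horizon: float,
    tie_tol: float = DEFAULT_TIE_TOL,
    graph: Optional[nx.DiGraph] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> HybridTrajectory:
    """Run the hybrid system from a full-system state.

    Each alive subset's field is integrated with events on the union of the
    alive cells' constraints; at an event, every cell whose constraint
    crossed within ``tie_tol`` dies at once, the collapse rule is applied
    and integration continues in the reduced space until the empty subset or
    the horizon.  Cells already outside their region at the start die in an
    event at t=0 rather than raising.  When ``graph`` (a configuration
    graph) is supplied, edges taken are flagged ``realized``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    x = np.asarray(x0, dtype=float)
    if x.shape != (system.dimension,):
        raise ValueError(
            f"x0 has shape {x.shape}, expected ({system.dimension},)"
        )

    alive: AliveSet = frozenset(system.names)
    t = 0.0
    segments: list[tuple[AliveSet, Trajectory]] = []
    events: list[DeathEvent] = []

    def mark(source: AliveSet, dying: AliveSet):
        if graph is not None:
            graph.edges[source, source - dying]["realized"] = True

    # immediate deaths at t=0 (cells starting outside their region)
    while alive:
        region = _joint_region(system, alive)
        violated = region.violated_ids(x)
        if not violated:
            break
        dying = frozenset(_constraint_owner(cid) for cid in violated)
        post = collapse_state(x, alive, dying, system)
        events.append(DeathEvent(0.0, dying, alive, x.copy(), post, tuple(violated)))
        mark(alive, dying)
        alive = alive - dying
        x = post

    while alive and t < horizon:
        field, region = reduced_system(system, alive)
        traj = integrate(
            field, x, horizon - t, events=region,
            tie_tol=tie_tol, rtol=rtol, atol=atol,
        )
        segments.append((alive, traj))
        if traj.termination.reason != "event":
            break
        t_event = t + traj.final_time
        pre = traj.final_state
        dying = frozenset(
            _constraint_owner(cid) for cid in traj.termination.constraint_ids
        )
        post = collapse_state(pre, alive, dying, system)
        events.append(
            DeathEvent(
                t_event, dying, alive, pre.copy(), post,
                traj.termination.constraint_ids,
            )
        )
        mark(alive, dying)
        alive = alive - dying
        x = post
        t = t_event
    return HybridTrajectory(segments, events, final_alive=alive)


@dataclass(frozen=True)
class CollapsePoint:
    """A death-facet state whose collapse image is a registered organizing
    structure of the reduced system.

    ``organizing`` is False when the target is a stable attractor of the
    reduced dynamics (a valid preimage, but it organizes nothing).
    """

    location: np.ndarray
    facet_constraint_id: str
    dying_cell: str
    target: np.ndarray
    organizing: bool


def find_collapse_points(
    system: MultiCellSystem,
    source: Iterable[str],
    dying_cell: str,
    target: Sequence[float],
    tol: float = 1e-9,
) -> list[CollapsePoint]:
    """States on the dying cell's death facet(s) that collapse onto
    ``target`` in the reduced system.

    Under the default projection rule this is the facet slice whose
    surviving coordinates equal the target.  The target must lie inside the
    reduced region; each returned point is flagged non-organizing when the
    target is a stable equilibrium of the reduced dynamics.
    """
    source = frozenset(source)
    if dying_cell not in source:
        raise ValueError(f"{dying_cell!r} is not in the source subset")
    survivors = source - {dying_cell}
    if not survivors:
        raise ValueError("collapse needs at least one survivor")
    target = np.asarray(target, dtype=float)
    red_field, red_region = reduced_system(system, survivors)
    if target.shape != (red_region.dimension,):
        raise ValueError("target has the wrong dimension for the reduced system")
    if not red_region.contains(target):
        raise ValueError(f"target {target} lies outside the reduced region")

    organizing = True
    try:
        eq = stability(red_field, target, tol=1e-6)
        organizing = not eq.is_stable
    except Exception:
        pass  # not an equilibrium: a registered separatrix point, organizing

    cell = system.cell(dying_cell)
    src_idx = system.alive_variables(source)
    pos = {g: i for i, g in enumerate(src_idx)}
    surv_idx = system.alive_variables(survivors)

    points: list[CollapsePoint] = []
    for con in cell.region.constraints:
        if not con.finite or not isinstance(con, BoxConstraint):
            continue
        x = np.empty(len(src_idx))
        for i, g in enumerate(surv_idx):
            x[pos[g]] = target[i]
        x[pos[cell.variables[con.index]]] = con.threshold
        # require the facet state to sit on the closure of the source region
        src_region = _joint_region(system, source)
        if not src_region.contains(x):
            continue
        img = collapse_state(x, source, {dying_cell}, system)
        if np.linalg.norm(img - target) > tol:
            continue
        points.append(
            CollapsePoint(
                x, f"{dying_cell}:{con.id}", dying_cell, target.copy(), organizing
            )
        )
    return points


def collapse_manifold(
    system: MultiCellSystem,
    source: Iterable[str],
    point: CollapsePoint,
    backward_horizon: float = DEFAULT_BACKWARD_HORIZON,
    labels_either_side: tuple[str, str] = (
        "asymptotically_viable",
        "transiently_viable",
    ),
) -> Manifold:
    """Collapse manifold: backward trajectory of a collapse point in the
    source subset's (2-D) space.

    Its two sides are labelled by the survivor's post-collapse fate; a probe
    classifier for :func:`~viadeco.decomposition.verify_separation` should
    therefore run :func:`simulate_hybrid` from the probe and report the
    survivor's fate in the reduced space.
    """
    source = frozenset(source)
    field, region = reduced_system(system, source)
    if region.dimension != 2:
        raise ValueError("collapse manifolds are computed in 2-D source spaces")
    if not point.organizing:
        raise ValueError(
            "collapse point targets a stable attractor; it organizes nothing"
        )
    con = region.constraint(point.facet_constraint_id)
    inward = -con.outward_normal(point.location)
    traj, pts, times, halted, degen = _backward_polyline(
        field, region, point.location, inward, backward_horizon
    )
    return Manifold(
        kind="collapse",
        seed=point.location.copy(),
        points=pts,
        times=times,
        labels_either_side=labels_either_side,
        degenerate=degen,
        halted=halted,
        trajectory=traj,
    )
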