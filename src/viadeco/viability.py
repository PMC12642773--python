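"""Viability regions and the brute-force viability classifier.

A viability region is the set of states in which a cell counts as alive,
carved out by per-variable bounds (box constraints) and/or smooth scalar
constraints ``g(x) <= 0``.  States on the boundary are members (closed
convention): death happens at the first transversal crossing, not on contact.

:func:`classify_state` is the simulation oracle for the whole package — it
labels a state *asymptotically viable* (stays inside and converges to a
viable attractor), *transiently viable* (exits in finite time, with the
violated constraint(s) and death time), *nonmember*, or *undecided* at a
finite horizon.  Every manifold computed elsewhere is verified against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .dynsys import Equilibrium, Trajectory, VectorField, integrate

__all__ = [
    "Constraint",
    "BoxConstraint",
    "SmoothConstraint",
    "ViabilityRegion",
    "ViabilityLabel",
    "LabelGrid",
    "box_region",
    "contains",
    "first_violation",
    "classify_state",
    "classify_grid",
    "DEFAULT_HORIZON",
    "DEFAULT_CONV_TOL",
    "DEFAULT_TIE_TOL",
    "BOUNDARY_EXCLUSION",
]

#: default forward-simulation horizon (time units) for classification
DEFAULT_HORIZON = 50.0
#: default distance-to-attractor tolerance for declaring convergence
DEFAULT_CONV_TOL = 1e-2
#: constraints crossing within this time of each other are a joint fatality
DEFAULT_TIE_TOL = 1e-9
#: grid classification skips points this close to the boundary
BOUNDARY_EXCLUSION = 1e-9

#: membership slack: |g| below this counts as "on the boundary", hence inside
_MEMBER_TOL = 1e-12


class Constraint:
    """Base class: a scalar function ``g`` with ``g(x) <= 0`` viable."""

    id: str

    def value(self, x: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def finite(self) -> bool:
        return True

    def outward_normal(self, x: np.ndarray) -> np.ndarray:
        """Unit outward normal (direction of increasing ``g``) at ``x``."""
        grad = self.gradient(x)
        norm = float(np.linalg.norm(grad))
        if norm == 0.0:
            raise ValueError(f"constraint {self.id!r} has zero gradient at {x}")
        return grad / norm


@dataclass(frozen=True)
class BoxConstraint(Constraint):
    """A one-sided bound on a single variable.

    ``side='upper'`` means ``x[index] <= threshold`` is viable,
    ``side='lower'`` means ``x[index] >= threshold``.  Infinite thresholds
    are allowed and render the constraint vacuous (``finite`` is False).
    """

    index: int
    side: str
    threshold: float
    id: str

    def __post_init__(self):
        if self.side not in ("lower", "upper"):
            raise ValueError("side must be 'lower' or 'upper'")

    def value(self, x: np.ndarray) -> float:
        if self.side == "upper":
            return float(x[self.index] - self.threshold)
        return float(self.threshold - x[self.index])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros(len(x))
        g[self.index] = 1.0 if self.side == "upper" else -1.0
        return g

    @property
    def finite(self) -> bool:
        return math.isfinite(self.threshold)


@dataclass(frozen=True)
class SmoothConstraint(Constraint):
    """A smooth scalar constraint ``g(x) <= 0`` with its gradient."""

    g: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray]
    id: str

    def value(self, x: np.ndarray) -> float:
        return float(self.g(np.asarray(x, dtype=float)))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.grad(np.asarray(x, dtype=float)), dtype=float)


@dataclass(frozen=True)
class ViabilityRegion:
    """The closed set ``{x : g_i(x) <= 0 for all i}`` of living states."""

    dimension: int
    constraints: tuple[Constraint, ...]

    def __post_init__(self):
        if not any(c.finite for c in self.constraints):
            raise ValueError("region needs at least one finite constraint")
        ids = [c.id for c in self.constraints]
        if len(set(ids)) != len(ids):
            raise ValueError("constraint ids must be unique")

    def constraint(self, cid: str) -> Constraint:
        for c in self.constraints:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def contains(self, x: Sequence[float]) -> bool:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dimension,):
            raise ValueError(
                f"state has shape {x.shape}, expected ({self.dimension},)"
            )
        return all(c.value(x) <= _MEMBER_TOL for c in self.constraints)

    def violated_ids(self, x: Sequence[float]) -> tuple[str, ...]:
        x = np.asarray(x, dtype=float)
        return tuple(c.id for c in self.constraints if c.value(x) > _MEMBER_TOL)

    def boundary_distance(self, x: Sequence[float]) -> float:
        """Smallest ``|g_i(x)| / ||grad g_i||`` over constraints (first-order
        distance to the nearest facet; exact for box constraints)."""
        x = np.asarray(x, dtype=float)
        dists = []
        for c in self.constraints:
            if not c.finite:
                continue
            gn = float(np.linalg.norm(c.gradient(x)))
            if gn > 0:
                dists.append(abs(c.value(x)) / gn)
        return min(dists)

    def bounding_box(self) -> np.ndarray:
        """Per-variable ``(low, high)`` implied by the box constraints
        (infinite where unbounded)."""
        lo = np.full(self.dimension, -np.inf)
        hi = np.full(self.dimension, np.inf)
        for c in self.constraints:
            if isinstance(c, BoxConstraint) and c.finite:
                if c.side == "lower":
                    lo[c.index] = max(lo[c.index], c.threshold)
                else:
                    hi[c.index] = min(hi[c.index], c.threshold)
        return np.column_stack([lo, hi])

    def diameter(self) -> float:
        box = self.bounding_box()
        span = box[:, 1] - box[:, 0]
        finite = span[np.isfinite(span)]
        if len(finite) == 0:
            return math.inf
        return float(np.linalg.norm(finite))


def box_region(
    bounds: Sequence[tuple[float, float]],
    ids: Optional[Sequence[str]] = None,
    names: Optional[Sequence[str]] = None,
) -> ViabilityRegion:
    """Region from per-variable ``(low, high)`` bounds (``±inf`` to omit).

    Constraint ids default to ``x{i+1}_lower`` / ``x{i+1}_upper`` (or the
    given variable ``names``).
    """
    cons: list[Constraint] = []
    n = len(bounds)
    for i, (lo, hi) in enumerate(bounds):
        base = names[i] if names is not None else f"x{i + 1}"
        if math.isfinite(lo):
            cons.append(BoxConstraint(i, "lower", float(lo), f"{base}_lower"))
        if math.isfinite(hi):
            cons.append(BoxConstraint(i, "upper", float(hi), f"{base}_upper"))
    region = ViabilityRegion(n, tuple(cons))
    if ids is not None:
        if len(ids) != len(cons):
            raise ValueError("ids length must match generated constraint count")
        renamed = []
        for c, cid in zip(cons, ids):
            renamed.append(BoxConstraint(c.index, c.side, c.threshold, cid))
        region = ViabilityRegion(n, tuple(renamed))
    return region


def contains(region: ViabilityRegion, x: Sequence[float]) -> bool:
    """Membership test (closed convention: boundary states are members)."""
    return region.contains(x)


@dataclass(frozen=True)
class ViabilityLabel:
    """Outcome of classifying one initial state.

    ``status`` is ``asymptotically_viable``, ``transiently_viable``,
    ``nonmember`` or ``undecided``.  Transient labels carry the violated
    constraint id(s) and the death time; asymptotic labels carry the
    attractor reached.
    """

    status: str
    violated: tuple[str, ...] = ()
    death_time: Optional[float] = None
    attractor: Optional[Equilibrium] = None

    def __post_init__(self):
        if self.status not in (
            "asymptotically_viable",
            "transiently_viable",
            "nonmember",
            "undecided",
        ):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "transiently_viable":
            if not self.violated or self.death_time is None:
                raise ValueError("transient label needs violated ids and death time")
        if self.status == "asymptotically_viable" and self.attractor is None:
            raise ValueError("asymptotic label needs its attractor")


def first_violation(
    traj: Trajectory,
    region: ViabilityRegion,
    tie_tol: float = DEFAULT_TIE_TOL,
    n_scan: Optional[int] = None,
) -> Optional[tuple[float, tuple[str, ...]]]:
    """Earliest constraint crossing along a trajectory, or ``None``.

    The crossing time of each constraint is bracketed on a scan of the dense
    output (``n_scan`` samples; defaults to 8x the stored samples, at least
    512) and refined by root-finding on ``g(x(t))``.  All constraints whose
    crossing lies within ``tie_tol`` of the earliest are reported together —
    a joint fatality.
    """
    if traj.states.shape[1] != region.dimension:
        raise ValueError("trajectory dimension does not match region")
    if n_scan is None:
        n_scan = max(512, 8 * len(traj.times))
    t0, t1 = float(traj.times[0]), float(traj.times[-1])
    if t0 == t1:
        return None
    ts = np.linspace(t0, t1, n_scan)
    xs = np.array([traj.at(t) for t in ts])

    crossings: list[tuple[float, str]] = []
    for con in region.constraints:
        if not con.finite:
            continue
        g = np.array([con.value(x) for x in xs])
        idx = np.where((g[:-1] <= 0) & (g[1:] > 0))[0]
        if len(idx) == 0:
            continue
        k = int(idx[0])
        if g[k] == 0.0:
            t_star = float(ts[k])
        else:
            t_star = brentq(
                lambda t, _c=con: _c.value(traj.at(t)), ts[k], ts[k + 1],
                xtol=1e-13,
            )
        crossings.append((float(t_star), con.id))
    if not crossings:
        return None
    t_min = min(t for t, _ in crossings)
    ids = tuple(sorted(cid for t, cid in crossings if t - t_min <= tie_tol))
    return t_min, ids


def _viable_attractors(
    region: ViabilityRegion,
    attractors: Sequence[Equilibrium],
    conv_tol: float,
) -> list[Equilibrium]:
    """Stable attractors inside the region, deep enough that a conv_tol ball
    around them stays inside."""
    out = []
    for a in attractors:
        if not a.is_stable:
            continue
        if not region.contains(a.location):
            continue
        if region.boundary_distance(a.location) <= conv_tol:
            continue
        out.append(a)
    return out


def classify_state(
    field: VectorField,
    region: ViabilityRegion,
    x0: Sequence[float],
    horizon: float = DEFAULT_HORIZON,
    attractors: Sequence[Equilibrium] = (),
    conv_tol: float = DEFAULT_CONV_TOL,
    tie_tol: float = DEFAULT_TIE_TOL,
    rtol: float = None,
    atol: float = None,
) -> ViabilityLabel:
    """Label one initial state by forward simulation against the boundary.

    A state is *transiently viable* when its trajectory crosses the boundary
    before ``horizon`` (the event gives the death time and constraint ids),
    *asymptotically viable* when it comes within ``conv_tol`` of a stable
    attractor that sits inside the region with at least ``conv_tol``
    clearance, and *undecided* when the horizon is reached first — a finite
    horizon never silently reports survival.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    x0 = np.asarray(x0, dtype=float)
    if not region.contains(x0):
        return ViabilityLabel("nonmember", violated=region.violated_ids(x0))

    viable = _viable_attractors(region, attractors, conv_tol)
    # already inside an attractor's convergence ball (e.g. the attractor
    # itself): the convergence event would never see a sign change
    for a in viable:
        if np.linalg.norm(x0 - a.location) <= conv_tol:
            return ViabilityLabel("asymptotically_viable", attractor=a)
    kwargs = {}
    if rtol is not None:
        kwargs["rtol"] = rtol
    if atol is not None:
        kwargs["atol"] = atol
    traj = integrate(
        field,
        x0,
        horizon,
        events=region,
        tie_tol=tie_tol,
        converge_to=[a.location for a in viable] or None,
        conv_tol=conv_tol,
        **kwargs,
    )
    term = traj.termination
    if term.reason == "event":
        return ViabilityLabel(
            "transiently_viable",
            violated=term.constraint_ids,
            death_time=traj.final_time,
        )
    if term.reason == "attractor_converged":
        xf = traj.final_state
        nearest = min(viable, key=lambda a: np.linalg.norm(xf - a.location))
        return ViabilityLabel("asymptotically_viable", attractor=nearest)
    return ViabilityLabel("undecided")


@dataclass
class LabelGrid:
    """Labels on a regular interior grid, with summary counts."""

    axes: tuple[np.ndarray, ...]
    points: np.ndarray  # (n_points, dimension)
    labels: list[ViabilityLabel]
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return len(self.labels)

    def fraction(self, status: str) -> float:
        return self.counts.get(status, 0) / self.total if self.total else 0.0


def classify_grid(
    field: VectorField,
    region: ViabilityRegion,
    resolution: Sequence[int],
    horizon: float = DEFAULT_HORIZON,
    attractors: Sequence[Equilibrium] = (),
    conv_tol: float = DEFAULT_CONV_TOL,
) -> LabelGrid:
    """Classify a regular grid of interior points (cell centers).

    The grid spans the region's bounding box with ``resolution[k]`` cell
    centers per axis — centers are strictly interior by construction, and any
    point within :data:`BOUNDARY_EXCLUSION` of the boundary is skipped to
    avoid event-at-start ambiguity.
    """
    resolution = list(resolution)
    if any(r < 2 for r in resolution):
        raise ValueError("resolution must be >= 2 per axis")
    box = region.bounding_box()
    if not np.all(np.isfinite(box)):
        raise ValueError("grid classification needs a bounded region")
    axes = tuple(
        box[k, 0] + (np.arange(r) + 0.5) * (box[k, 1] - box[k, 0]) / r
        for k, r in enumerate(resolution)
    )
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])

    labels: list[ViabilityLabel] = []
    kept: list[np.ndarray] = []
    for p in pts:
        if region.contains(p) and region.boundary_distance(p) <= BOUNDARY_EXCLUSION:
            continue
        kept.append(p)
        labels.append(
            classify_state(
                field, region, p, horizon=horizon,
                attractors=attractors, conv_tol=conv_tol,
            )
        )
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab.status] = counts.get(lab.status, 0) + 1
    return LabelGrid(axes, np.array(kept), labels, counts)
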