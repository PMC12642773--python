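"""Organizing manifolds of the viability region.

Three kinds of global structure organize survival outcomes inside a
viability region:

* **tangency points** — boundary states where the flow is tangent to a facet
  (the normal component of the field vanishes); a tangency whose forward
  fate is asymptotically viable is a *mortality point*;
* **mortality manifolds** — the backward-time trajectory of a mortality
  point, separating the asymptotically viable set from the transiently
  viable one;
* **ordering manifolds** — the backward-time trajectory of a *joint-fatal
  corner* (a corner of the boundary where the flow exits through both facets
  at once), separating regions by which constraint is violated first.

Exact polyline computation is restricted to 2-D state spaces, where the
backward trajectory of a point is itself the codimension-1 object.  For
higher dimensions the module still offers :func:`verify_separation`, the
probe-classification oracle, but no globalization.

Every manifold returned here is checkable: :func:`verify_separation` places
probe pairs across the polyline and classifies them with the brute-force
simulation oracle, reporting the fraction that land on the advertised sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .dynsys import Trajectory, VectorField, integrate
from .viability import (
    BoxConstraint,
    ViabilityLabel,
    ViabilityRegion,
    classify_state,
)

__all__ = [
    "TangencyPoint",
    "Manifold",
    "Corner",
    "CornerScan",
    "SeparationReport",
    "NotAMortalityPoint",
    "NotAJointFatalCorner",
    "PointNotOnFacet",
    "normal_flow",
    "find_tangency_points",
    "mortality_manifold",
    "find_joint_fatal_corners",
    "ordering_manifold",
    "verify_separation",
    "DEFAULT_BACKWARD_HORIZON",
]

#: default backward-integration horizon (time units) for manifolds
DEFAULT_BACKWARD_HORIZON = 100.0

#: tolerance for "this point lies on the facet"
_FACET_TOL = 1e-9

#: inward nudge applied to boundary seeds before backward integration
_SEED_NUDGE = 1e-9

#: ``|normal flow|`` below this counts as marginal at a corner
_MARGINAL_TOL = 1e-12

#: backward runs stop when ``||f||`` drops below this (interior repeller)
_EQUILIBRIUM_STALL_TOL = 1e-12


class NotAMortalityPoint(ValueError):
    """Tangency whose forward fate is not asymptotically viable: it
    organizes nothing and cannot seed a mortality manifold."""


class NotAJointFatalCorner(ValueError):
    """Corner where the flow does not exit through both facets."""


class PointNotOnFacet(ValueError):
    """State handed to a facet operation does not lie on the named facet."""


@dataclass(frozen=True)
class TangencyPoint:
    """A boundary state where the flow is tangent to a facet.

    ``crossing_character`` records how the normal flow changes sign along
    the facet through the tangency (``inward_to_outward`` or
    ``outward_to_inward`` with increasing facet parameter); ``organizing``
    is True exactly when the forward fate is asymptotically viable (a
    mortality point).
    """

    location: np.ndarray
    constraint_id: str
    forward_fate: ViabilityLabel
    crossing_character: str
    normal_residual: float

    @property
    def organizing(self) -> bool:
        return self.forward_fate.status == "asymptotically_viable"


@dataclass
class Manifold:
    """A polyline of states organizing the viability region.

    ``points`` run in backward-time order from ``seed`` (``points[0]`` is the
    seed exactly).  ``labels_either_side`` names the two outcomes the
    manifold separates; ``degenerate`` flags a manifold whose backward
    trajectory left the region immediately.
    """

    kind: str
    seed: np.ndarray
    points: np.ndarray
    times: np.ndarray
    labels_either_side: tuple[str, str]
    degenerate: bool = False
    halted: str = "region_exit"
    trajectory: Optional[Trajectory] = dc_field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in ("mortality", "ordering", "collapse"):
            raise ValueError(f"unknown manifold kind {self.kind!r}")

    def arclength(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def normal_flow(
    field: VectorField,
    region: ViabilityRegion,
    constraint_id: str,
    x: Sequence[float],
    facet_tol: float = _FACET_TOL,
) -> float:
    """Signed normal component of the flow on a facet.

    Dot product of ``f(x)`` with the outward unit normal of the named
    constraint; positive means the flow is immediately fatal there.
    """
    x = np.asarray(x, dtype=float)
    con = region.constraint(constraint_id)
    if abs(con.value(x)) > facet_tol:
        raise PointNotOnFacet(
            f"{x} is not on facet {constraint_id!r} (g = {con.value(x):.3g})"
        )
    return float(np.dot(field(x), con.outward_normal(x)))


def _facet_segment(
    region: ViabilityRegion, constraint_id: str
) -> tuple[Callable[[float], np.ndarray], float, float, int]:
    """Parametrize a 2-D box facet as ``s -> x(s)``; returns the map, the
    parameter range and the free variable index."""
    if region.dimension != 2:
        raise ValueError("exact facet scanning is restricted to 2-D regions")
    con = region.constraint(constraint_id)
    if not isinstance(con, BoxConstraint) or not con.finite:
        raise ValueError("facet scanning needs a finite box constraint")
    i = con.index
    j = 1 - i
    box = region.bounding_box()
    lo, hi = box[j]
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("the transverse variable must be bounded on both sides")

    def point(s: float, _i=i, _j=j, _thr=con.threshold) -> np.ndarray:
        x = np.empty(2)
        x[_i] = _thr
        x[_j] = s
        return x

    return point, float(lo), float(hi), j


def find_tangency_points(
    field: VectorField,
    region: ViabilityRegion,
    constraint_id: str,
    scan_resolution: int = 256,
    horizon: float = 50.0,
    attractors: Sequence = (),
    conv_tol: float = 1e-2,
) -> list[TangencyPoint]:
    """Tangency points on one facet of a 2-D box region.

    The facet is scanned at ``scan_resolution`` points; each sign change of
    the normal flow is bracketed and refined by root-finding to 1e-10 in the
    facet parameter.  Each tangency is annotated with its forward fate
    (classified from a point nudged just inside the boundary) and crossing
    character.  Uniformly one-signed flow yields an empty list.
    """
    if scan_resolution < 2:
        raise ValueError("scan_resolution must be >= 2")
    point, lo, hi, _j = _facet_segment(region, constraint_id)
    con = region.constraint(constraint_id)

    def nf(s: float) -> float:
        return float(np.dot(field(point(s)), con.outward_normal(point(s))))

    ss = np.linspace(lo, hi, scan_resolution)
    vals = np.array([nf(s) for s in ss])

    out: list[TangencyPoint] = []
    for k in range(len(ss) - 1):
        a, b = vals[k], vals[k + 1]
        if a == 0.0 and k > 0:
            continue  # exact hit handled by the bracket ending at it
        if a * b < 0 or (a == 0.0 and k == 0):
            if a == 0.0:
                s_star = float(ss[k])
            else:
                s_star = brentq(nf, ss[k], ss[k + 1], xtol=1e-10)
            x_star = point(s_star)
            character = (
                "inward_to_outward" if a < 0 else "outward_to_inward"
            )
            inward = -con.outward_normal(x_star)
            fate = classify_state(
                field,
                region,
                x_star + _SEED_NUDGE * inward,
                horizon=horizon,
                attractors=attractors,
                conv_tol=conv_tol,
            )
            out.append(
                TangencyPoint(
                    location=x_star,
                    constraint_id=constraint_id,
                    forward_fate=fate,
                    crossing_character=character,
                    normal_residual=abs(nf(s_star)),
                )
            )
    return out


#: in directions where the region is unbounded, backward integration is cut
#: off this far from the seed (an analysis window, not a model constraint)
DEFAULT_WINDOW_MARGIN = 2.0


def _analysis_region(
    region: ViabilityRegion, seed: np.ndarray, margin: float
) -> ViabilityRegion:
    """Region augmented with synthetic bounds at ``seed +/- margin`` in every
    direction the region leaves unbounded, so backward trajectories of
    outward-spiralling/diverging flows terminate at a meaningful extent."""
    box = region.bounding_box()
    extra: list[BoxConstraint] = []
    for i in range(region.dimension):
        if not np.isfinite(box[i, 0]):
            extra.append(
                BoxConstraint(i, "lower", float(seed[i] - margin), f"_window_x{i}_lower")
            )
        if not np.isfinite(box[i, 1]):
            extra.append(
                BoxConstraint(i, "upper", float(seed[i] + margin), f"_window_x{i}_upper")
            )
    if not extra:
        return region
    return ViabilityRegion(region.dimension, region.constraints + tuple(extra))


def _backward_polyline(
    field: VectorField,
    region: ViabilityRegion,
    seed: np.ndarray,
    inward: np.ndarray,
    backward_horizon: float,
    n_dense: int = 2000,
    window_margin: float = DEFAULT_WINDOW_MARGIN,
) -> tuple[Trajectory, np.ndarray, np.ndarray, str, bool]:
    """Backward trajectory from a boundary seed, nudged inward so the exit
    event does not fire at t=0.  Returns the trajectory, points (seed
    prepended exactly), times, halt reason and a degeneracy flag."""
    start = seed + _SEED_NUDGE * inward
    bounded = _analysis_region(region, seed, window_margin)
    traj = integrate(
        field,
        start,
        backward_horizon,
        direction="backward",
        events=bounded,
        stop_at_equilibrium=_EQUILIBRIUM_STALL_TOL,
        n_dense=n_dense,
    )
    pts = np.vstack([seed[None, :], traj.states[1:]])
    times = traj.times.copy()
    if traj.termination.reason == "event":
        if any(c.startswith("_window_") for c in traj.termination.constraint_ids):
            halted = "window_exit"
        else:
            halted = "region_exit"
    elif traj.elapsed >= backward_horizon * (1 - 1e-12):
        halted = "horizon"
    else:
        halted = "equilibrium_stall"
    degenerate = traj.elapsed < 1e-9 or len(pts) < 2
    return traj, pts, times, halted, degenerate


def mortality_manifold(
    field: VectorField,
    region: ViabilityRegion,
    tangency: TangencyPoint,
    backward_horizon: float = DEFAULT_BACKWARD_HORIZON,
) -> Manifold:
    """Mortality manifold seeded at an asymptotically viable tangency.

    The backward-time trajectory from the tangency point, halted at the
    first exit from the viability region (or the backward horizon, or an
    interior equilibrium stall, both flagged in ``halted``).  Raises
    :class:`NotAMortalityPoint` when the tangency's forward fate is not
    asymptotically viable.
    """
    if tangency.forward_fate.status != "asymptotically_viable":
        raise NotAMortalityPoint(
            f"tangency at {tangency.location} has forward fate "
            f"{tangency.forward_fate.status!r}; it does not organize the region"
        )
    con = region.constraint(tangency.constraint_id)
    inward = -con.outward_normal(tangency.location)
    traj, pts, times, halted, degen = _backward_polyline(
        field, region, tangency.location, inward, backward_horizon
    )
    return Manifold(
        kind="mortality",
        seed=tangency.location.copy(),
        points=pts,
        times=times,
        labels_either_side=("asymptotically_viable", "transiently_viable"),
        degenerate=degen,
        halted=halted,
        trajectory=traj,
    )


@dataclass(frozen=True)
class Corner:
    """Intersection of two box facets with the flow's normal components."""

    location: np.ndarray
    constraint_ids: tuple[str, str]
    normal_flows: tuple[float, float]


@dataclass
class CornerScan:
    """Joint-fatal corners plus the marginal ones (a zero normal component)
    and any higher-multiplicity intersections detected but not seeded."""

    fatal: list[Corner]
    marginal: list[Corner]
    triple: list[np.ndarray]

    def __iter__(self):
        return iter(self.fatal)

    def __len__(self):
        return len(self.fatal)


def find_joint_fatal_corners(
    field: VectorField, region: ViabilityRegion
) -> CornerScan:
    """Corners of the boundary where the flow exits through both facets.

    Every pairwise intersection of finite box constraints on distinct
    variables that lies in the closure of the remaining constraints is
    examined; a corner is joint-fatal when both normal flow components are
    strictly positive.  Corners with a component at zero (within tolerance)
    go to the marginal list; intersections where three or more constraints
    are active are recorded in ``triple`` and not seeded.
    """
    boxes = [
        c
        for c in region.constraints
        if isinstance(c, BoxConstraint) and c.finite
    ]
    if len(boxes) < 2:
        raise ValueError("joint-fatal corners need >= 2 finite box constraints")

    fatal: list[Corner] = []
    marginal: list[Corner] = []
    triple: list[np.ndarray] = []
    for a_idx in range(len(boxes)):
        for b_idx in range(a_idx + 1, len(boxes)):
            ca, cb = boxes[a_idx], boxes[b_idx]
            if ca.index == cb.index:
                continue
            if region.dimension != 2:
                # corner states of box pairs are only points in 2-D; in
                # higher dimensions the intersection is a face, out of scope
                continue
            x = np.empty(region.dimension)
            x[ca.index] = ca.threshold
            x[cb.index] = cb.threshold
            others = [
                c for c in region.constraints if c is not ca and c is not cb
            ]
            if any(c.value(x) > _FACET_TOL for c in others):
                continue
            n_active = sum(
                1 for c in region.constraints if abs(c.value(x)) <= _FACET_TOL
            )
            if n_active > 2:
                triple.append(x)
                continue
            f = field(x)
            na = float(np.dot(f, ca.outward_normal(x)))
            nb = float(np.dot(f, cb.outward_normal(x)))
            corner = Corner(x, (ca.id, cb.id), (na, nb))
            if na > _MARGINAL_TOL and nb > _MARGINAL_TOL:
                fatal.append(corner)
            elif na > -_MARGINAL_TOL and nb > -_MARGINAL_TOL:
                marginal.append(corner)
    return CornerScan(fatal, marginal, triple)


def ordering_manifold(
    field: VectorField,
    region: ViabilityRegion,
    corner: Corner,
    backward_horizon: float = DEFAULT_BACKWARD_HORIZON,
) -> Manifold:
    """Ordering manifold seeded at a joint-fatal corner.

    The backward-time trajectory from the corner through the region
    interior; its two sides are labelled with the corner's constraint ids —
    the constraint violated first on each side.  Raises
    :class:`NotAJointFatalCorner` when either normal component fails to be
    strictly positive.  A backward trajectory that exits immediately yields
    a zero-length manifold flagged degenerate.
    """
    if not (
        corner.normal_flows[0] > _MARGINAL_TOL
        and corner.normal_flows[1] > _MARGINAL_TOL
    ):
        raise NotAJointFatalCorner(
            f"corner {corner.location} has normal flows {corner.normal_flows}"
        )
    ca = region.constraint(corner.constraint_ids[0])
    cb = region.constraint(corner.constraint_ids[1])
    inward = -(
        ca.outward_normal(corner.location) + cb.outward_normal(corner.location)
    )
    inward = inward / np.linalg.norm(inward)
    traj, pts, times, halted, degen = _backward_polyline(
        field, region, corner.location, inward, backward_horizon
    )
    return Manifold(
        kind="ordering",
        seed=corner.location.copy(),
        points=pts,
        times=times,
        labels_either_side=corner.constraint_ids,
        degenerate=degen,
        halted=halted,
        trajectory=traj,
    )


@dataclass
class SeparationReport:
    """Result of probing a manifold against a classifier.

    ``fraction`` is the share of evaluated probe pairs whose two labels are
    exactly the manifold's advertised pair (1.0 = perfect separation);
    ``counterexamples`` lists ``(point_plus, point_minus, label_plus,
    label_minus)`` for every inconsistent pair.
    """

    fraction: float
    n_evaluated: int
    n_skipped: int
    counterexamples: list[tuple[np.ndarray, np.ndarray, str, str]]

    @property
    def perfect(self) -> bool:
        return self.n_evaluated > 0 and self.fraction == 1.0


def verify_separation(
    manifold: Manifold,
    classifier: Callable[[np.ndarray], str],
    n_probes: int = 100,
    band: float = 1e-2,
    seed: int = 1234,
    region: Optional[ViabilityRegion] = None,
) -> SeparationReport:
    """Test a manifold's defining property: that it separates two outcomes.

    ``n_probes`` points are drawn uniformly in arclength along the polyline
    (seeded RNG); at each, a probe pair is placed at ``±band`` along the
    local normal and fed to ``classifier``.  A pair is consistent when its
    two labels are distinct and equal, as a set, to ``labels_either_side``.
    Probes outside ``region`` or within ``band`` of its boundary are skipped
    (and counted).
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if band <= 0:
        raise ValueError("band must be positive")
    pts = manifold.points
    if len(pts) < 2:
        raise ValueError("manifold polyline has fewer than 2 points")
    if pts.shape[1] != 2:
        raise ValueError("probe placement along a polyline is 2-D only")

    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    good = seg_len > 0
    seg, seg_len = seg[good], seg_len[good]
    starts = pts[:-1][good]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    rng = np.random.default_rng(seed)
    us = rng.uniform(0.0, total, size=n_probes)

    expected = set(manifold.labels_either_side)
    n_eval = 0
    n_skip = 0
    bad: list[tuple[np.ndarray, np.ndarray, str, str]] = []
    for u in us:
        k = min(int(np.searchsorted(cum, u, side="right")) - 1, len(seg) - 1)
        frac = (u - cum[k]) / seg_len[k]
        x = starts[k] + frac * seg[k]
        tangent = seg[k] / seg_len[k]
        normal = np.array([-tangent[1], tangent[0]])
        p_plus = x + band * normal
        p_minus = x - band * normal
        if region is not None:
            skip = False
            for p in (p_plus, p_minus):
                if not region.contains(p) or region.boundary_distance(p) < band:
                    skip = True
                    break
            if skip:
                n_skip += 1
                continue
        lab_plus = classifier(p_plus)
        lab_minus = classifier(p_minus)
        n_eval += 1
        if lab_plus == lab_minus or {lab_plus, lab_minus} != expected:
            bad.append((p_plus, p_minus, lab_plus, lab_minus))
    frac_ok = (n_eval - len(bad)) / n_eval if n_eval else 0.0
    return SeparationReport(frac_ok, n_eval, n_skip, bad)
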