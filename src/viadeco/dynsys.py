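"""Continuous dynamical-systems substrate.

Vector fields, forward/backward integration with boundary-event detection,
equilibrium finding and linear stability analysis.  Everything downstream
(viability classification, manifold computation, hybrid simulation) is built
on the :func:`integrate` contract defined here.

Conventions
-----------
* Backward integration negates the right-hand side and integrates forward in
  internal time; reported trajectory times are nonpositive and strictly
  decreasing from 0.
* Boundary events use the constraint convention ``g(x) <= 0`` inside; an
  event fires on the first crossing of ``g`` from negative to positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.stats import qmc

__all__ = [
    "VectorField",
    "Trajectory",
    "Termination",
    "Equilibrium",
    "IntegrationFailure",
    "NotAnEquilibrium",
    "integrate",
    "find_equilibria",
    "stability",
    "linear_field",
    "field_from_dict",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

# Defaults chosen for manifold work: backward trajectories amplify local
# error, so both tolerances sit well below the geometric scales of interest.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: step scale for the central finite-difference Jacobian fallback
FD_JACOBIAN_STEP = 1e-6

#: two equilibria closer than this are considered the same root
EQUILIBRIUM_MERGE_RADIUS = 1e-6


class IntegrationFailure(RuntimeError):
    """The right-hand side produced a nonfinite derivative."""

    def __init__(self, state: np.ndarray):
        self.state = np.asarray(state, dtype=float)
        super().__init__(f"nonfinite derivative at state {self.state}")


class NotAnEquilibrium(ValueError):
    """A point handed to :func:`stability` is not a root of the field."""


@dataclass(frozen=True)
class VectorField:
    """An autonomous ODE right-hand side ``x' = f(x)`` on R^n.

    Parameters
    ----------
    dimension
        Number of state variables ``n``.
    rhs
        Map from a length-``n`` state vector to its derivative.
    jacobian
        Optional analytic Jacobian ``x -> n x n`` matrix.  When absent a
        scale-aware central finite difference with step
        ``h = 1e-6 * max(1, ||x||)`` is used.
    names
        Optional per-variable labels (``x1..xn`` when absent).
    """

    dimension: int
    rhs: Callable[[np.ndarray], np.ndarray]
    jacobian: Optional[Callable[[np.ndarray], np.ndarray]] = None
    names: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")
        if self.names is not None and len(self.names) != self.dimension:
            raise ValueError("names length must equal dimension")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        f = np.asarray(self.rhs(np.asarray(x, dtype=float)), dtype=float)
        if f.shape != (self.dimension,):
            raise ValueError(
                f"rhs returned shape {f.shape}, expected ({self.dimension},)"
            )
        return f

    def variable_names(self) -> tuple[str, ...]:
        if self.names is not None:
            return self.names
        return tuple(f"x{i + 1}" for i in range(self.dimension))

    def jacobian_at(self, x: np.ndarray) -> np.ndarray:
        """Jacobian matrix at ``x`` (analytic if provided, else central FD)."""
        x = np.asarray(x, dtype=float)
        if self.jacobian is not None:
            J = np.asarray(self.jacobian(x), dtype=float)
            if J.shape != (self.dimension, self.dimension):
                raise ValueError("jacobian has wrong shape")
            return J
        h = FD_JACOBIAN_STEP * max(1.0, float(np.linalg.norm(x)))
        n = self.dimension
        J = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = h
            J[:, j] = (self(x + e) - self(x - e)) / (2.0 * h)
        return J

    def reversed(self) -> "VectorField":
        """The time-reversed field ``x' = -f(x)``."""
        jac = None
        if self.jacobian is not None:
            orig = self.jacobian
            jac = lambda x: -np.asarray(orig(x), dtype=float)  # noqa: E731
        return VectorField(self.dimension, lambda x: -self(x), jac, self.names)


@dataclass(frozen=True)
class Termination:
    """Why an integration stopped.

    ``reason`` is one of ``horizon_reached``, ``event`` or
    ``attractor_converged``; ``constraint_ids`` names every constraint whose
    crossing time lies within the simultaneity tolerance of the first one.
    """

    reason: str
    constraint_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.reason not in ("horizon_reached", "event", "attractor_converged"):
            raise ValueError(f"unknown termination reason {self.reason!r}")


@dataclass
class Trajectory:
    """A sampled solution of an ODE with its termination record.

    ``times`` are strictly monotone in the stated direction (increasing for
    forward, decreasing for backward, both starting at 0).  ``interpolant``,
    when present, maps any time in the sampled span to a state using the
    integrator's dense output.
    """

    times: np.ndarray
    states: np.ndarray
    direction: str
    termination: Termination
    interpolant: Optional[Callable[[float], np.ndarray]] = dc_field(
        default=None, repr=False
    )

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states) or len(self.times) < 1:
            raise ValueError("times and states must have equal positive length")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if len(self.times) > 1:
            d = np.diff(self.times)
            if self.direction == "forward" and not np.all(d > 0):
                raise ValueError("forward times must be strictly increasing")
            if self.direction == "backward" and not np.all(d < 0):
                raise ValueError("backward times must be strictly decreasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    @property
    def final_time(self) -> float:
        return float(self.times[-1])

    @property
    def elapsed(self) -> float:
        return abs(self.final_time - float(self.times[0]))

    def at(self, t: float) -> np.ndarray:
        """State at time ``t`` (dense output if available, else linear)."""
        if self.interpolant is not None:
            return self.interpolant(t)
        ts = self.times
        if self.direction == "backward":
            ts = ts[::-1]
            xs = self.states[::-1]
        else:
            xs = self.states
        return np.array(
            [np.interp(t, ts, xs[:, j]) for j in range(self.states.shape[1])]
        )


@dataclass(frozen=True)
class Equilibrium:
    """A root of the field with its linearization.

    ``stability`` is one of ``stable_node``, ``stable_spiral``, ``saddle``,
    ``unstable``, ``center`` (the last covers zero-real-part degeneracies,
    which are flagged via ``degenerate``).
    """

    location: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    degenerate: bool = False

    @property
    def is_stable(self) -> bool:
        return self.stability in ("stable_node", "stable_spiral")


def _checked_rhs(field: VectorField):
    def fn(t, y):
        f = field(y)
        if not np.all(np.isfinite(f)):
            raise IntegrationFailure(y)
        return f

    return fn


def integrate(
    field: VectorField,
    x0: Sequence[float],
    duration: float,
    direction: str = "forward",
    events=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    tie_tol: float = 1e-9,
    converge_to: Optional[Sequence[np.ndarray]] = None,
    conv_tol: float = 1e-2,
    stop_at_equilibrium: Optional[float] = None,
    n_dense: Optional[int] = None,
) -> Trajectory:
    """Integrate ``field`` from ``x0`` for ``duration`` time units.

    Parameters
    ----------
    events
        Optional :class:`~viadeco.viability.ViabilityRegion`; integration
        halts at the first constraint crossing, refined by the integrator's
        event root-finding, and every constraint crossing within ``tie_tol``
        of that time is reported together (joint fatality).
    direction
        ``backward`` integrates the time-reversed field; reported times are
        then nonpositive and decreasing.
    converge_to / conv_tol
        Optional attractor locations: integration halts with termination
        ``attractor_converged`` once the state comes within ``conv_tol`` of
        any of them.
    stop_at_equilibrium
        When set, halt once ``||f(x)||`` drops below this value (used by
        backward manifold computations that run into a repeller).
    n_dense
        Resample the solution at this many uniformly spaced times through the
        dense output (the terminal point is kept exactly).
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (field.dimension,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({field.dimension},)")
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if duration == 0:
        return Trajectory(
            np.array([0.0]),
            x0[None, :].copy(),
            direction,
            Termination("horizon_reached"),
        )

    work_field = field if direction == "forward" else field.reversed()

    event_fns = []
    event_kinds: list[tuple[str, str]] = []  # (kind, id)
    if events is not None:
        for con in events.constraints:
            def g(t, y, _c=con):
                return _c.value(y)

            g.terminal = True
            g.direction = 1  # viable (negative) -> violated (positive)
            event_fns.append(g)
            event_kinds.append(("constraint", con.id))
    if converge_to is not None and len(converge_to) > 0:
        targets = [np.asarray(a, dtype=float) for a in converge_to]

        def near(t, y, _ts=targets, _tol=conv_tol):
            return min(np.linalg.norm(y - a) for a in _ts) - _tol

        near.terminal = True
        near.direction = -1
        event_fns.append(near)
        event_kinds.append(("attractor", ""))
    if stop_at_equilibrium is not None:
        def eq_ev(t, y, _tol=stop_at_equilibrium):
            return float(np.linalg.norm(work_field(y))) - _tol

        eq_ev.terminal = True
        eq_ev.direction = -1
        event_fns.append(eq_ev)
        event_kinds.append(("equilibrium", ""))

    sol = solve_ivp(
        _checked_rhs(work_field),
        (0.0, float(duration)),
        x0,
        method="RK45",
        dense_output=True,
        events=event_fns or None,
        rtol=rtol,
        atol=atol,
    )
    if sol.status == -1:
        raise IntegrationFailure(sol.y[:, -1] if sol.y.size else x0)

    termination = Termination("horizon_reached")
    t_end = float(sol.t[-1])
    x_end = sol.y[:, -1].copy()
    if sol.status == 1:  # a terminal event fired
        hits = [
            (float(te[0]), kind, cid)
            for te, (kind, cid) in zip(sol.t_events, event_kinds)
            if len(te) > 0
        ]
        t_first = min(h[0] for h in hits)
        first = [h for h in hits if h[0] - t_first <= tie_tol]
        kinds = {h[1] for h in first}
        if "constraint" in kinds:
            ids = tuple(sorted(h[2] for h in first if h[1] == "constraint"))
            termination = Termination("event", ids)
        elif "attractor" in kinds:
            termination = Termination("attractor_converged")
        else:
            # equilibrium stall during a backward run: treated as a horizon
            termination = Termination("horizon_reached")
        t_end = t_first
        x_end = sol.sol(t_end)

    if n_dense is not None and n_dense >= 2 and t_end > 0:
        ts = np.linspace(0.0, t_end, n_dense)
        xs = sol.sol(ts).T
        xs[-1] = x_end
    else:
        keep = sol.t <= t_end + 1e-15
        ts = sol.t[keep]
        xs = sol.y[:, keep].T
        if len(ts) == 0 or abs(ts[-1] - t_end) > 1e-15:
            ts = np.append(ts, t_end)
            xs = np.vstack([xs, x_end]) if xs.size else x_end[None, :]
        else:
            xs = xs.copy()
            xs[-1] = x_end
    # drop duplicate time stamps the solver may emit at events
    keep_idx = np.concatenate([[True], np.diff(ts) > 0])
    ts, xs = ts[keep_idx], xs[keep_idx]

    dense = sol.sol
    if direction == "backward":
        ts = -ts
        interp = lambda t, _d=dense: np.asarray(_d(-t), dtype=float)  # noqa: E731
    else:
        interp = lambda t, _d=dense: np.asarray(_d(t), dtype=float)  # noqa: E731
    return Trajectory(ts, xs, direction, termination, interp)


# ---------------------------------------------------------------------------
# Equilibria and stability
# ---------------------------------------------------------------------------

#: real parts within this (relative) band of zero are treated as zero
_ZERO_REAL_TOL = 1e-9


def classify_eigenvalues(eigenvalues: np.ndarray) -> tuple[str, bool]:
    """Map Jacobian eigenvalues to a stability label.

    Returns ``(label, degenerate)`` where ``degenerate`` marks a real part
    indistinguishable from zero at tolerance.
    """
    ev = np.asarray(eigenvalues, dtype=complex)
    scale = max(1.0, float(np.max(np.abs(ev))) if ev.size else 1.0)
    re = ev.real
    tol = _ZERO_REAL_TOL * scale
    if np.any(np.abs(re) <= tol):
        return "center", True
    if np.all(re < 0):
        if np.any(np.abs(ev.imag) > tol):
            return "stable_spiral", False
        return "stable_node", False
    if np.all(re > 0):
        return "unstable", False
    return "saddle", False


def stability(field: VectorField, x_eq: Sequence[float], tol: float = 1e-6) -> Equilibrium:
    """Linear stability of an equilibrium candidate.

    Raises :class:`NotAnEquilibrium` when ``||f(x_eq)|| > tol``.
    """
    x_eq = np.asarray(x_eq, dtype=float)
    resid = float(np.linalg.norm(field(x_eq)))
    if resid > tol:
        raise NotAnEquilibrium(
            f"||rhs({x_eq})|| = {resid:.3g} exceeds tolerance {tol:.3g}"
        )
    ev = np.linalg.eigvals(field.jacobian_at(x_eq))
    label, degen = classify_eigenvalues(ev)
    return Equilibrium(x_eq.copy(), np.sort_complex(ev), label, degen)


def find_equilibria(
    field: VectorField,
    search_box: Sequence[tuple[float, float]],
    n_starts: int = 32,
    seed: int = 0,
    tol: float = 1e-9,
) -> list[Equilibrium]:
    """Multistart root search for equilibria inside ``search_box``.

    Start points are drawn from a seeded Sobol sequence, roots are polished
    with a quasi-Newton solver, filtered to the box (with a small margin) and
    merged within :data:`EQUILIBRIUM_MERGE_RADIUS`.  The list may be
    incomplete — multistart search carries no completeness guarantee.
    """
    box = np.asarray(search_box, dtype=float)
    if box.shape != (field.dimension, 2):
        raise ValueError("search_box must give (low, high) per variable")
    if not np.all(np.isfinite(box)):
        raise ValueError("search_box must be finite")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    sampler = qmc.Sobol(d=field.dimension, scramble=True, rng=np.random.default_rng(seed))
    n_draw = 1 << max(0, (n_starts - 1).bit_length())  # Sobol wants powers of 2
    unit = sampler.random(n_draw)[:n_starts]
    starts = box[:, 0] + unit * (box[:, 1] - box[:, 0])

    margin = 1e-9 * np.maximum(1.0, np.abs(box).max(axis=1))
    found: list[np.ndarray] = []
    for s in starts:
        res = root(lambda x: field(x), s, jac=lambda x: field.jacobian_at(x), tol=tol)
        if not res.success:
            continue
        x = res.x
        if float(np.linalg.norm(field(x))) > max(tol, 1e-12):
            continue
        if np.any(x < box[:, 0] - margin) or np.any(x > box[:, 1] + margin):
            continue
        if any(np.linalg.norm(x - y) <= EQUILIBRIUM_MERGE_RADIUS for y in found):
            continue
        found.append(x)
    found.sort(key=lambda x: tuple(x))
    return [stability(field, x, tol=max(1e-6, 10 * tol)) for x in found]


# ---------------------------------------------------------------------------
# Field constructors (also the CLI's plain-text spec loader target)
# ---------------------------------------------------------------------------


def linear_field(
    A: Sequence[Sequence[float]],
    center: Sequence[float],
    names: Optional[tuple[str, ...]] = None,
) -> VectorField:
    """The affine field ``x' = A (x - c)`` with analytic Jacobian."""
    A = np.asarray(A, dtype=float)
    c = np.asarray(center, dtype=float)
    n = len(c)
    if A.shape != (n, n):
        raise ValueError("A must be square and match center length")
    return VectorField(n, lambda x: A @ (x - c), lambda x: A, names)


def field_from_dict(spec: dict) -> VectorField:
    """Build a field from a plain specification mapping.

    Two forms are supported::

        {"type": "linear", "A": [[...]], "center": [...]}
        {"type": "polynomial", "dimension": n,
         "terms": [{"var": i, "coeff": c, "powers": [p1..pn]}, ...]}
    """
    kind = spec.get("type")
    if kind == "linear":
        return linear_field(spec["A"], spec["center"], _names(spec))
    if kind == "polynomial":
        n = int(spec["dimension"])
        terms = [
            (int(t["var"]), float(t["coeff"]), np.asarray(t["powers"], dtype=float))
            for t in spec["terms"]
        ]
        for var, _, powers in terms:
            if not 0 <= var < n or powers.shape != (n,):
                raise ValueError("polynomial term indices/powers inconsistent")

        def rhs(x, _terms=terms, _n=n):
            f = np.zeros(_n)
            for var, coeff, powers in _terms:
                f[var] += coeff * np.prod(np.power(x, powers))
            return f

        return VectorField(n, rhs, None, _names(spec))
    raise ValueError(f"unknown field type {kind!r}")


def _names(spec: dict) -> Optional[tuple[str, ...]]:
    names = spec.get("names")
    return tuple(names) if names else None
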