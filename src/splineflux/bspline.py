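"""Clamped B-spline flux profiles and the structural operations on them.

Each free flux is a spline ``u(t) = sum_i p_i B_{i,k}(t)`` on a clamped knot
vector: ``k+1`` copies of ``t0``, the ``g`` internal knots, ``k+1`` copies of
``t_end``.  The estimator relies on three operations that the incremental
algorithm uses between optimizations:

* ``insert_knot`` — Boehm single-knot insertion; refines the knot vector
  without changing the represented curve, which is what makes the result of
  one subproblem an exact warm start for the next.
* ``prolongate`` — moves the end knot out while keeping the control points;
  the profile shifts slightly but stays close, again a warm start.
* ``constrain_knot`` — records a box window for a knot so that later
  optimizations keep it inside the measurement interval it settled in.

Evaluation and insertion are backed by :mod:`scipy.interpolate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineFunction",
    "FreeFluxSet",
    "clamped_knot_vector",
    "count_basis_functions",
    "evaluate_spline",
    "insert_knot",
    "prolongate",
    "constrain_knot",
]

DEFAULT_DEGREE = 2  # smooth first derivative; fixed in the estimation pipeline


def count_basis_functions(g: int, k: int) -> int:
    """Number of basis functions / control points: q = g + k + 1."""
    if g < 0 or k < 0:
        raise ValueError("g and k must be nonnegative")
    return g + k + 1


@dataclass(frozen=True)
class SplineFunction:
    """One free-flux profile: degree k, horizon [t0, t_end], free internal knots."""

    k: int
    t0: float
    t_end: float
    internal_knots: np.ndarray
    control_points: np.ndarray
    #: per internal knot: (lo, hi) window or None when unconstrained
    knot_windows: tuple = field(default=())

    def __post_init__(self):
        knots = np.atleast_1d(np.asarray(self.internal_knots, dtype=float))
        cp = np.atleast_1d(np.asarray(self.control_points, dtype=float))
        object.__setattr__(self, "internal_knots", knots)
        object.__setattr__(self, "control_points", cp)
        if not self.knot_windows:
            object.__setattr__(self, "knot_windows", (None,) * knots.size)
        if self.t_end <= self.t0:
            raise ValueError("t_end must exceed t0")
        if knots.size and (np.any(np.diff(knots) < 0)
                           or knots[0] <= self.t0 or knots[-1] >= self.t_end):
            raise ValueError("internal knots must be nondecreasing and strictly inside (t0, t_end)")
        if cp.size != count_basis_functions(knots.size, self.k):
            raise ValueError(
                f"{cp.size} control points for g={knots.size}, k={self.k}; "
                f"need q = g+k+1 = {count_basis_functions(knots.size, self.k)}"
            )
        if len(self.knot_windows) != knots.size:
            raise ValueError("one window slot per internal knot required")
        for t, w in zip(knots, self.knot_windows):
            if w is not None and not (w[0] <= t <= w[1]):
                raise ValueError(f"knot {t} outside its window {w}")

    @property
    def g(self) -> int:
        return int(self.internal_knots.size)

    @property
    def q(self) -> int:
        return int(self.control_points.size)

    def as_bspline(self) -> BSpline:
        return BSpline(clamped_knot_vector(self), self.control_points, self.k,
                       extrapolate=False)

    def __call__(self, t):
        return evaluate_spline(self, t)

    def derivative(self, t):
        """First derivative of the profile at t (same domain conventions)."""
        t = np.asarray(t, dtype=float)
        _check_domain(self, t)
        return self.as_bspline().derivative()(np.clip(t, self.t0, _left_of_end(self)))

    def to_dict(self) -> dict:
        return {
            "degree": self.k,
            "t0": float(self.t0),
            "t_end": float(self.t_end),
            "internal_knots": [float(x) for x in self.internal_knots],
            "knot_windows": [None if w is None else [float(w[0]), float(w[1])]
                             for w in self.knot_windows],
            "control_points": [float(x) for x in self.control_points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineFunction":
        return cls(
            k=int(d["degree"]), t0=float(d["t0"]), t_end=float(d["t_end"]),
            internal_knots=np.asarray(d["internal_knots"], dtype=float),
            control_points=np.asarray(d["control_points"], dtype=float),
            knot_windows=tuple(None if w is None else (float(w[0]), float(w[1]))
                               for w in d["knot_windows"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "SplineFunction":
        return cls.from_dict(json.loads(s))


def constant_spline(value: float, t0: float, t_end: float,
                    k: int = DEFAULT_DEGREE) -> SplineFunction:
    return SplineFunction(k=k, t0=t0, t_end=t_end,
                          internal_knots=np.empty(0),
                          control_points=np.full(k + 1, float(value)))


def clamped_knot_vector(s: SplineFunction) -> np.ndarray:
    """Total knot vector: k+1 copies of t0, internal knots, k+1 copies of t_end."""
    return np.concatenate([
        np.full(s.k + 1, s.t0), s.internal_knots, np.full(s.k + 1, s.t_end)
    ])


def _left_of_end(s: SplineFunction) -> float:
    # evaluation is right-continuous except at t_end, which is inclusive
    return np.nextafter(s.t_end, s.t0)


def _check_domain(s: SplineFunction, t: np.ndarray) -> None:
    if np.any(t < s.t0) or np.any(t > s.t_end):
        raise ValueError(
            f"evaluation outside horizon [{s.t0}, {s.t_end}] (no extrapolation)"
        )


def evaluate_spline(s: SplineFunction, t):
    """u(t) = sum_i p_i B_{i,k}(t); right-limit at interior knots, inclusive t_end."""
    t_arr = np.asarray(t, dtype=float)
    _check_domain(s, t_arr)
    # BSpline is right-continuous at interior knots; map t_end to its left limit
    vals = s.as_bspline()(np.clip(t_arr, s.t0, _left_of_end(s)))
    return float(vals) if np.isscalar(t) or t_arr.ndim == 0 else vals


def basis_matrix(s: SplineFunction, t) -> np.ndarray:
    """Matrix B with B[i, j] = B_{j,k}(t_i); u(t) = B @ control_points."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    _check_domain(s, t_arr)
    tc = np.clip(t_arr, s.t0, _left_of_end(s))
    kv = clamped_knot_vector(s)
    return BSpline.design_matrix(tc, kv, s.k, extrapolate=False).toarray()


def insert_knot(s: SplineFunction, t_new: float) -> SplineFunction:
    """Boehm knot insertion: g and q grow by one, the profile is unchanged."""
    if not (s.t0 < t_new < s.t_end):
        raise ValueError(f"t_new={t_new} must lie strictly inside ({s.t0}, {s.t_end})")
    kv = clamped_knot_vector(s)
    if np.sum(np.isclose(kv[s.k + 1:-(s.k + 1)], t_new)) >= s.k:
        raise ValueError(f"knot {t_new} already has multiplicity k={s.k}")
    # convex-combination update of the control points (single knot)
    span = int(np.searchsorted(kv, t_new, side="right") - 1)
    p = s.control_points
    new_p = np.empty(p.size + 1)
    new_p[: span - s.k + 1] = p[: span - s.k + 1]
    for i in range(span - s.k + 1, span + 1):
        denom = kv[i + s.k] - kv[i]
        a = (t_new - kv[i]) / denom if denom > 0 else 0.0
        new_p[i] = (1.0 - a) * p[i - 1] + a * p[i]
    new_p[span + 1:] = p[span:]

    new_knots = np.sort(np.append(s.internal_knots, t_new))
    pos = int(np.searchsorted(new_knots, t_new))
    windows = list(s.knot_windows)
    windows.insert(pos, None)
    return SplineFunction(k=s.k, t0=s.t0, t_end=s.t_end,
                          internal_knots=new_knots, control_points=new_p,
                          knot_windows=tuple(windows))


def prolongate(s: SplineFunction, t_end_new: float) -> SplineFunction:
    """Extend the horizon by moving the end knot; control points are kept."""
    if t_end_new <= s.t_end:
        raise ValueError("t_end_new must exceed the current horizon end")
    if s.g and t_end_new <= s.internal_knots[-1]:
        raise ValueError("t_end_new must exceed the last internal knot")
    return replace(s, t_end=float(t_end_new))


def constrain_knot(s: SplineFunction, knot_index: int, window) -> SplineFunction:
    """Record a box window [lo, hi] for internal knot ``knot_index``."""
    lo, hi = float(window[0]), float(window[1])
    t = s.internal_knots[knot_index]
    if not (lo <= t <= hi):
        raise ValueError(f"knot {t} not inside window [{lo}, {hi}]")
    windows = list(s.knot_windows)
    windows[knot_index] = (lo, hi)
    return replace(s, knot_windows=tuple(windows))


@dataclass(frozen=True)
class FreeFluxSet:
    """The d free-flux splines of one fit; all share the same horizon."""

    splines: tuple

    def __post_init__(self):
        sp = tuple(self.splines)
        object.__setattr__(self, "splines", sp)
        if not sp:
            raise ValueError("need at least one spline")
        t0s = {s.t0 for s in sp}
        tes = {s.t_end for s in sp}
        if len(t0s) > 1 or len(tes) > 1:
            raise ValueError("all splines must share t0 and t_end")

    @property
    def d(self) -> int:
        return len(self.splines)

    @property
    def t0(self) -> float:
        return self.splines[0].t0

    @property
    def t_end(self) -> float:
        return self.splines[0].t_end

    @property
    def g_vec(self) -> np.ndarray:
        return np.array([s.g for s in self.splines], dtype=int)

    @property
    def n_g(self) -> int:
        return int(self.g_vec.sum())

    def evaluate(self, t) -> np.ndarray:
        """Stacked evaluation: shape (d,) for scalar t, (d, len(t)) otherwise."""
        vals = [evaluate_spline(s, t) for s in self.splines]
        return np.asarray(vals)

    def prolongate(self, t_end_new: float) -> "FreeFluxSet":
        return FreeFluxSet(tuple(prolongate(s, t_end_new) for s in self.splines))
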