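"""Direct collocation on finite elements with 3-point Radau (right) points.

Finite-element borders sit at the measurement time points, so a grid with
``n_time`` measurements has ``n_time - 1`` elements.  Within each element the
differential states are cubic Lagrange polynomials through their value at the
element start plus the three Radau collocation points (the right end point is
a Radau root, which is what makes continuity cheap); the algebraic states
(irreversible fluxes) use the same four-coefficient representation.

The collocation block ``h_coll`` enforces the ODE at the interior collocation
points and the algebraic definition z = I_irr K u at the collocation points
plus the global initial time; ``h_cont`` chains the element end states to the
next element's start coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import roots_jacobi

from .bspline import FreeFluxSet
from .dynamics import DynamicModel, irreversible_fluxes, model_rhs
from .network import MetabolicNetwork

__all__ = [
    "CollocationGrid",
    "DiscretizedSystem",
    "radau_grid",
    "radau_points",
    "lagrange_diff_matrix",
    "discretize",
    "dimension_report",
]

N_COLL = 3  # interior Radau points per element; cubic Lagrange states


def radau_points(s: int = N_COLL) -> np.ndarray:
    """Right-Radau abscissae on (0, 1]: s-1 Jacobi(1,0) roots plus the end point."""
    if s < 1:
        raise ValueError("need at least one collocation point")
    if s == 1:
        return np.array([1.0])
    x, _ = roots_jacobi(s - 1, 1.0, 0.0)  # roots in (-1, 1)
    return np.concatenate([(x + 1.0) / 2.0, [1.0]])


def lagrange_diff_matrix(nodes: np.ndarray, eval_at: np.ndarray) -> np.ndarray:
    """D[r, j] = dL_j/dtau at eval_at[r] for the Lagrange basis on ``nodes``."""
    nodes = np.asarray(nodes, dtype=float)
    eval_at = np.asarray(eval_at, dtype=float)
    n = nodes.size
    D = np.empty((eval_at.size, n))
    for j in range(n):
        others = np.delete(nodes, j)
        denom = np.prod(nodes[j] - others)
        for r, x in enumerate(eval_at):
            total = 0.0
            for m_i, m in enumerate(others):
                rest = np.delete(others, m_i)
                total += np.prod(x - rest)
            D[r, j] = total / denom
    return D


@dataclass(frozen=True)
class CollocationGrid:
    """Element borders (measurement times) plus the normalized Radau points."""

    element_borders: np.ndarray
    normalized_points: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "element_borders",
                           np.asarray(self.element_borders, dtype=float))
        object.__setattr__(self, "normalized_points",
                           np.asarray(self.normalized_points, dtype=float))

    @property
    def n_time(self) -> int:
        return int(self.element_borders.size)

    @property
    def n_elements(self) -> int:
        return self.n_time - 1

    def element_times(self, e: int) -> np.ndarray:
        """Absolute times of the 4 coefficients of element e: start + Radau points."""
        a, b = self.element_borders[e], self.element_borders[e + 1]
        return np.concatenate([[a], a + (b - a) * self.normalized_points])

    def all_times(self) -> np.ndarray:
        """Coefficient times of all elements, shape (n_elements, 4)."""
        return np.stack([self.element_times(e) for e in range(self.n_elements)])


def radau_grid(measurement_times) -> CollocationGrid:
    t = np.asarray(measurement_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two measurement times")
    if np.any(np.diff(t) <= 0):
        raise ValueError("measurement times must be sorted and distinct")
    return CollocationGrid(element_borders=t, normalized_points=radau_points())


@dataclass
class DiscretizedSystem:
    """Assembled collocation structure for one model + spline set + grid.

    ``p_x`` has shape (n_elements, 4, n_states): per element the value at the
    element start and at the three Radau points.  ``p_z`` is analogous for the
    n_irr algebraic states.
    """

    model: DynamicModel
    grid: CollocationGrid
    #: differentiation matrix of the cubic Lagrange basis on {0, tau1..tau3},
    #: evaluated at the three Radau points: shape (3, 4)
    D: np.ndarray

    @property
    def n_states(self) -> int:
        return self.model.n_states

    @property
    def n_irr(self) -> int:
        return self.model.net.n_irr

    def h_coll(self, p_x, p_z, flux_set: FreeFluxSet, K=None):
        """Collocation residuals: ODE at interior points, z-definition at all
        coefficient points of each element plus the global initial time."""
        model = self._with_K(K)
        p_x = np.asarray(p_x, dtype=float)
        p_z = np.asarray(p_z, dtype=float)
        res_x, res_z = [], []
        basis = model.basis
        net = model.net
        for e in range(self.grid.n_elements):
            times = self.grid.element_times(e)
            h = self.grid.element_borders[e + 1] - self.grid.element_borders[e]
            u_at = np.column_stack([flux_set.evaluate(t) for t in times])  # (d, 4)
            xdot = self.D @ p_x[e] / h  # (3, n_states)
            for r in range(N_COLL):
                f = model_rhs(model, p_x[e, r + 1], u_at[:, r + 1], times[r + 1])
                res_x.append(xdot[r] - f)
            # algebraic definition at the three Radau points of every element
            for r in range(N_COLL):
                z = irreversible_fluxes(basis, net, u_at[:, r + 1])
                res_z.append(p_z[e, r + 1] - z)
        # the extra algebraic constraint at the global initial point
        u0 = flux_set.evaluate(self.grid.element_borders[0])
        res_z.append(p_z[0, 0] - irreversible_fluxes(basis, net, u0))
        return np.concatenate([np.ravel(res_x), np.ravel(res_z)])

    def h_cont(self, p_x, p_z):
        """Continuity: element end values equal the next element's start coeffs."""
        p_x = np.asarray(p_x, dtype=float)
        p_z = np.asarray(p_z, dtype=float)
        res = []
        for e in range(self.grid.n_elements - 1):
            res.append(p_x[e + 1, 0] - p_x[e, -1])
        for e in range(self.grid.n_elements - 1):
            res.append(p_z[e + 1, 0] - p_z[e, -1])
        return np.concatenate(res) if res else np.empty(0)

    def _with_K(self, K):
        if K is None:
            return self.model
        from dataclasses import replace
        from .network import NullSpaceBasis
        return replace(self.model,
                       basis=NullSpaceBasis(K=K, mode=self.model.basis.mode,
                                            free_flux_ids=self.model.basis.free_flux_ids))

    # ------------------------------------------------------------------
    # exact elimination of the state coefficients
    # ------------------------------------------------------------------
    def solve_states(self, flux_set: FreeFluxSet, x0, K=None):
        """Solve h_coll = h_cont = 0 for (p_x, p_z) given splines and x0.

        The ODE right-hand side is linear in x for fixed u (flux vector times
        the biomass scalar, plus an affine dilution term), so each element's
        collocation equations are a linear solve; elements chain through the
        continuity conditions.  Returns (p_x, p_z).
        """
        model = self._with_K(K)
        n_x = self.n_states
        grid = self.grid
        SeK = model.SeK
        q_bio = model.q_bio
        continuous = model.mode == "continuous"

        t_all = grid.all_times()  # (n_el, 4)
        # evaluate all splines at all coefficient times in one pass
        u_all = np.stack([s.as_bspline()(
            np.clip(t_all.ravel(), flux_set.t0,
                    np.nextafter(flux_set.t_end, flux_set.t0)))
            for s in flux_set.splines])  # (d, n_el*4)
        u_all = u_all.reshape(flux_set.d, grid.n_elements, 4)

        p_x = np.empty((grid.n_elements, 4, n_x))
        D0 = self.D[:, 0]   # (3,)
        D1 = self.D[:, 1:]  # (3, 3)
        x_prev = np.asarray(x0, dtype=float)
        I = np.eye(n_x)
        for e in range(grid.n_elements):
            h = grid.element_borders[e + 1] - grid.element_borders[e]
            p_x[e, 0] = x_prev
            # build A_r = Jacobian of rhs wrt x at collocation point r
            M = np.zeros((3 * n_x, 3 * n_x))
            rhs = np.zeros(3 * n_x)
            for r in range(3):
                a = SeK @ u_all[:, e, r + 1]          # flux direction vector
                A = np.outer(a, q_bio)               # d(rhs)/dx, batch part
                b = np.zeros(n_x)
                if continuous:
                    Dv = float(model.dilution(t_all[e, r + 1]))
                    A = A - Dv * I
                    b = Dv * model.x_in
                for j in range(3):
                    blk = D1[r, j] * I
                    if j == r:
                        blk = blk - h * A
                    M[r * n_x:(r + 1) * n_x, j * n_x:(j + 1) * n_x] = blk
                rhs[r * n_x:(r + 1) * n_x] = h * b - D0[r] * x_prev
            sol = np.linalg.solve(M, rhs).reshape(3, n_x)
            p_x[e, 1:] = sol
            x_prev = sol[-1]

        # algebraic states are explicit
        IK = model.net.I_irr @ model.basis.K  # (n_irr, d)
        p_z = np.einsum("id,dek->eki", IK, u_all)
        return p_x, p_z


def discretize(model: DynamicModel, flux_set: FreeFluxSet,
               grid: CollocationGrid) -> DiscretizedSystem:
    if not (flux_set.t0 <= grid.element_borders[0]
            and flux_set.t_end >= grid.element_borders[-1]):
        raise ValueError("spline horizon does not cover the collocation grid")
    tau = np.concatenate([[0.0], grid.normalized_points])
    D = lagrange_diff_matrix(tau, grid.normalized_points)
    return DiscretizedSystem(model=model, grid=grid, D=D)


def dimension_report(net: MetabolicNetwork, grid: CollocationGrid,
                     flux_set: FreeFluxSet, optimal_K: bool = False,
                     k: int = 2) -> dict:
    """Named variable/constraint counts of the assembled NLP."""
    n_time = grid.n_time
    m1 = net.m_ext + 1
    d = flux_set.d
    n_g = flux_set.n_g
    rep = {
        "differential_state_variables": 4 * (n_time - 1) * m1,
        "algebraic_state_variables": 4 * (n_time - 1) * net.n_irr,
        "spline_parameters": n_g + d * (k + 1),
        "internal_knot_locations": n_g,
        "initial_values": m1,
        "differential_collocation_constraints": 3 * (n_time - 1) * m1,
        "differential_continuity_constraints": (n_time - 2) * m1,
        "algebraic_collocation_constraints": (3 * (n_time - 1) + 1) * net.n_irr,
        "algebraic_continuity_constraints": (n_time - 2) * net.n_irr,
        "initial_value_constraints": m1,
    }
    if optimal_K:
        rep["K_matrix_values"] = net.n * d
        rep["K_nullspace_constraints"] = net.m_int * d
        rep["K_orthogonality_constraints"] = d * (d + 1) // 2
    return rep
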