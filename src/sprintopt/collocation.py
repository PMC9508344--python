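"""Flipped Legendre-Gauss-Radau direct collocation and NLP solution.

Transcribes an implicit-dynamics optimal control problem onto a uniform mesh:
states are interpolated with Lagrange polynomials through the interval start
plus ``d`` flipped-LGR nodes (Radau IIA family, right endpoint included),
controls are piecewise constant and parameterised at interval starts,
first-order dynamics are enforced at the LGR nodes, algebraic path
constraints at interval starts, and state continuity between intervals.
The resulting NLP is scaled to [-1, 1] and solved, by default, with the
in-package feasible-path reduced-gradient SQP (SciPy's ``trust-constr``
interior-point method is available as an alternative).

The dynamics here are *implicit chains of integrators* (the state derivative
is a fixed linear map of states and controls; all model nonlinearity enters
through algebraic path constraints), which keeps every collocation equation
linear and the constraint Jacobian mostly constant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from numpy.polynomial import legendre, polynomial as P
from scipy.optimize import Bounds, LinearConstraint, NonlinearConstraint, minimize

from ._smooth import cs_jacobian

import logging

logger = logging.getLogger(__name__)

__all__ = [
    "lgr_nodes",
    "lagrange_differentiation",
    "lagrange_basis_at",
    "Mesh",
    "OCPDefinition",
    "OCPSolution",
    "transcribe",
    "solve",
]


def lgr_nodes(d: int) -> tuple[np.ndarray, np.ndarray]:
    """Flipped LGR collocation nodes and quadrature weights on (0, 1].

    The ``d`` nodes include the right endpoint 1 (Radau IIA). The weights
    integrate polynomials exactly up to degree ``2d - 2`` and sum to 1.
    """
    if d < 1:
        raise ValueError("collocation order must be >= 1")
    if d == 1:
        return np.array([1.0]), np.array([1.0])
    # Left-Radau abscissae on [-1, 1] are -1 together with the roots of
    # (P_{d-1} + P_d)/(1 + x); flipping x -> -x moves the fixed point to +1.
    c = np.zeros(d + 1)
    c[d - 1] = 1.0
    c[d] = 1.0
    roots = legendre.legroots(c)
    interior = np.sort(-roots[np.abs(roots + 1.0) > 1e-9])
    x = np.concatenate([interior, [1.0]])
    nodes = 0.5 * (x + 1.0)
    # Weights: exact integral of each Lagrange basis polynomial over [0, 1].
    weights = np.empty(d)
    for j in range(d):
        others = np.delete(nodes, j)
        coef = P.polyfromroots(others)
        coef = coef / P.polyval(nodes[j], coef)
        weights[j] = P.polyval(1.0, P.polyint(coef)) - P.polyval(0.0, P.polyint(coef))
    return nodes, weights


def lagrange_basis_at(points: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Values of the Lagrange basis through ``points`` evaluated at ``t``.

    Returns an array of shape ``(len(t), len(points))``.
    """
    points = np.asarray(points, dtype=float)
    if len(np.unique(points)) != len(points):
        raise ValueError("interpolation points must be distinct")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty((t.size, points.size))
    for j in range(points.size):
        others = np.delete(points, j)
        num = np.prod(t[:, None] - others[None, :], axis=1)
        den = np.prod(points[j] - others)
        out[:, j] = num / den
    return out


def lagrange_differentiation(points: np.ndarray, at: np.ndarray | None = None) -> np.ndarray:
    """Differentiation matrix of the Lagrange basis through ``points``.

    Row ``k`` maps values at ``points`` to the interpolant's derivative at
    ``at[k]`` (default: at every point of ``points``). Exact for polynomials
    up to degree ``len(points) - 1``.
    """
    points = np.asarray(points, dtype=float)
    if len(np.unique(points)) != len(points):
        raise ValueError("interpolation points must be distinct")
    if at is None:
        at = points
    at = np.atleast_1d(np.asarray(at, dtype=float))
    n = points.size
    D = np.empty((at.size, n))
    for j in range(n):
        others = np.delete(points, j)
        coef = P.polyfromroots(others)
        coef = coef / P.polyval(points[j], coef)
        D[:, j] = P.polyval(at, P.polyder(coef))
    return D


@dataclass
class Mesh:
    """Uniform collocation mesh with ``n_intervals`` intervals of order ``d``.

    ``t_final`` is either a fixed duration or a ``(lower, upper)`` pair, in
    which case the horizon is a decision variable and the problem is posed
    on normalized time [0, 1] scaled by ``t_final``.
    """

    n_intervals: int
    d: int = 3
    t_final: float | tuple[float, float] = 1.0

    def __post_init__(self):
        if self.n_intervals < 1:
            raise ValueError("mesh needs at least one interval")
        self.nodes, self.weights = lgr_nodes(self.d)
        self.points = np.concatenate([[0.0], self.nodes])  # interpolation points
        self.D = lagrange_differentiation(self.points, at=self.nodes)
        self.h = 1.0 / self.n_intervals

    @property
    def free_time(self) -> bool:
        return isinstance(self.t_final, (tuple, list))

    @property
    def tf_bounds(self) -> tuple[float, float]:
        if self.free_time:
            lo, hi = self.t_final
            if lo > hi:
                raise ValueError("t_final bounds are out of order")
            return float(lo), float(hi)
        return float(self.t_final), float(self.t_final)

    def normalized_times(self) -> tuple[np.ndarray, np.ndarray]:
        """(interval starts, collocation times) on the normalized horizon."""
        starts = np.arange(self.n_intervals) * self.h
        coll = starts[:, None] + self.h * self.nodes[None, :]
        return starts, coll


@dataclass
class OCPDefinition:
    """Implicit-chain optimal control problem.

    Dynamics: ``dx/dt = A_x @ x + A_u @ u`` (constant matrices). Model
    nonlinearity is expressed through ``path`` constraints evaluated at
    interval starts and through quadrature cost residuals.

    path(x, u, sigma, tf) -> vector, bounded by (path_lb, path_ub)
    boundary(x0, xf, tf) -> vector, bounded by (boundary_lb, boundary_ub)
    quad_residuals(x, u, sigma, tf) -> residual vector; the Lagrange cost is
        sum over collocation nodes of quadrature weight * h * tf * |r|^2.
    mayer(x0, xf, tf) -> scalar added to the objective.
    ``term_slices`` names slices of the quadrature residual vector for the
    per-term objective breakdown.
    """

    nx: int
    nu: int
    A_x: np.ndarray
    A_u: np.ndarray
    x_lb: np.ndarray
    x_ub: np.ndarray
    u_lb: np.ndarray
    u_ub: np.ndarray
    path: Callable | None = None
    path_batch: Callable | None = None  # vectorized twin: (X, U, sigma, tf) -> (B, n)
    path_lb: np.ndarray | None = None
    path_ub: np.ndarray | None = None
    path_scale: np.ndarray | None = None
    boundary: Callable | None = None
    boundary_lb: np.ndarray | None = None
    boundary_ub: np.ndarray | None = None
    quad_residuals: Callable | None = None
    quad_batch: Callable | None = None  # vectorized twin of quad_residuals
    n_quad: int = 0
    mayer: Callable | None = None
    term_slices: dict[str, slice] = field(default_factory=dict)
    mayer_terms: Callable | None = None

    def __post_init__(self):
        for name in ("x_lb", "x_ub", "u_lb", "u_ub"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.x_lb > self.x_ub) or np.any(self.u_lb > self.u_ub):
            raise ValueError("infeasible bounds: lower > upper")


@dataclass
class OCPSolution:
    """Discretized solution trajectories in physical units."""

    mesh: Mesh
    states: np.ndarray  # (N, d+1, nx): interval start + d collocation nodes
    controls: np.ndarray  # (N, nu)
    t_final: float
    objective: float
    breakdown: dict
    status: int
    message: str
    n_iter: int
    constr_violation: float
    success: bool

    @property
    def times(self) -> np.ndarray:
        """Physical times of all state points, flattened in mesh order."""
        starts, coll = self.mesh.normalized_times()
        pts = np.concatenate(
            [np.concatenate([[s], c]) for s, c in zip(starts, coll)]
        )
        return pts * self.t_final

    def state_knots(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, states) at every mesh point, flattened."""
        return self.times, self.states.reshape(-1, self.states.shape[-1])

    def interpolate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the piecewise Lagrange state interpolant at times ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        N, h, tf = self.mesh.n_intervals, self.mesh.h, self.t_final
        sigma = np.clip(t / tf, 0.0, 1.0 - 1e-12)
        idx = np.minimum((sigma / h).astype(int), N - 1)
        out = np.empty((t.size, self.states.shape[-1]))
        for i in np.unique(idx):
            m = idx == i
            local = (sigma[m] - i * h) / h
            B = lagrange_basis_at(self.mesh.points, local)
            out[m] = B @ self.states[i]
        return out

    def control_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-constant control evaluated at times ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        sigma = np.clip(t / self.t_final, 0.0, 1.0 - 1e-12)
        idx = np.minimum((sigma / self.mesh.h).astype(int), self.mesh.n_intervals - 1)
        return self.controls[idx]


class _Transcription:
    """Assembled NLP: scaled variables, constraints, objective callbacks."""

    def __init__(self, ocp: OCPDefinition, mesh: Mesh):
        self.ocp = ocp
        self.mesh = mesh
        N, d, nx, nu = mesh.n_intervals, mesh.d, ocp.nx, ocp.nu
        self.N, self.d, self.nx, self.nu = N, d, nx, nu
        self.n_state_pts = N * (d + 1)
        self.nz = self.n_state_pts * nx + N * nu + (1 if mesh.free_time else 0)
        self.iu0 = self.n_state_pts * nx
        self.itf = self.nz - 1 if mesh.free_time else None

        # --- scaling: z_phys = mid + half * z_scaled -------------------
        tf_lo, tf_hi = mesh.tf_bounds
        x_mid, x_half = 0.5 * (ocp.x_lb + ocp.x_ub), 0.5 * (ocp.x_ub - ocp.x_lb)
        u_mid, u_half = 0.5 * (ocp.u_lb + ocp.u_ub), 0.5 * (ocp.u_ub - ocp.u_lb)
        x_half = np.maximum(x_half, 1e-9)
        u_half = np.maximum(u_half, 1e-9)
        mid = np.concatenate(
            [np.tile(x_mid, self.n_state_pts), np.tile(u_mid, N)]
        )
        half = np.concatenate(
            [np.tile(x_half, self.n_state_pts), np.tile(u_half, N)]
        )
        if mesh.free_time:
            mid = np.append(mid, 0.5 * (tf_lo + tf_hi))
            half = np.append(half, max(0.5 * (tf_hi - tf_lo), 1e-9))
        self.mid, self.half = mid, half
        self.x_half = x_half

        starts, coll = mesh.normalized_times()
        self.sigma_starts, self.sigma_coll = starts, coll

        self._build_linear_blocks()
        self._build_path_sparsity()

    # ------------------------------------------------------------------
    def x_index(self, i: int, k: int) -> int:
        """Start of state point ``k`` (0=interval start) of interval ``i``."""
        return (i * (self.d + 1) + k) * self.nx

    def u_index(self, i: int) -> int:
        return self.iu0 + i * self.nu

    def unpack(self, z):
        states = z[: self.iu0].reshape(self.N, self.d + 1, self.nx)
        controls = z[self.iu0 : self.iu0 + self.N * self.nu].reshape(self.N, self.nu)
        tf = z[self.itf] if self.itf is not None else self.mesh.tf_bounds[0]
        return states, controls, tf

    def phys(self, zs):
        return self.mid + self.half * zs

    # ------------------------------------------------------------------
    def _build_linear_blocks(self):
        """Collocation-derivative and continuity matrices (constant)."""
        N, d, nx, nu = self.N, self.d, self.nx, self.nu
        D = self.mesh.D
        rows, cols, vals = [], [], []
        # derivative part: for interval i, node k, state s:
        # sum_j D[k, j] * x_i(j, s)
        for i in range(N):
            for k in range(d):
                r0 = (i * d + k) * nx
                for j in range(d + 1):
                    base = self.x_index(i, j)
                    for s in range(nx):
                        rows.append(r0 + s)
                        cols.append(base + s)
                        vals.append(D[k, j])
        self.Dmat = sp.csr_matrix(
            (vals, (rows, cols)), shape=(N * d * nx, self.nz)
        )
        # dynamics RHS selector: rhs_{i,k} = A_x @ x_ik + A_u @ u_i
        rows, cols, vals = [], [], []
        A_x, A_u = np.asarray(self.ocp.A_x), np.asarray(self.ocp.A_u)
        for i in range(N):
            for k in range(d):
                r0 = (i * d + k) * nx
                basex = self.x_index(i, k + 1)
                baseu = self.u_index(i)
                for s in range(nx):
                    for s2 in range(nx):
                        if A_x[s, s2] != 0.0:
                            rows.append(r0 + s)
                            cols.append(basex + s2)
                            vals.append(A_x[s, s2])
                    for m in range(nu):
                        if A_u[s, m] != 0.0:
                            rows.append(r0 + s)
                            cols.append(baseu + m)
                            vals.append(A_u[s, m])
        self.Rmat = sp.csr_matrix(
            (vals, (rows, cols)), shape=(N * d * nx, self.nz)
        )
        # continuity: x_i(end) - x_{i+1}(0) = 0
        rows, cols, vals = [], [], []
        for i in range(N - 1):
            r0 = i * nx
            for s in range(nx):
                rows.append(r0 + s)
                cols.append(self.x_index(i, d) + s)
                vals.append(1.0)
                rows.append(r0 + s)
                cols.append(self.x_index(i + 1, 0) + s)
                vals.append(-1.0)
        self.Cmat = sp.csr_matrix(
            (vals, (rows, cols)), shape=((N - 1) * nx, self.nz)
        )
        # row scaling for dynamics rows: per-state variable scale
        self.dyn_row_scale = np.tile(1.0 / self.x_half, N * self.d)
        self.cont_row_scale = np.tile(1.0 / self.x_half, N - 1)

    def _build_path_sparsity(self):
        ocp = self.ocp
        if ocp.path is None:
            self.n_path = 0
            return
        self.n_path = len(np.atleast_1d(ocp.path_lb))
        if ocp.path_scale is None:
            self.path_scale = np.ones(self.n_path)
        else:
            self.path_scale = np.asarray(ocp.path_scale, dtype=float)
        # local variables per interval: state at start + control (+ tf)
        loc = []
        rows_all, cols_all = [], []
        for i in range(self.N):
            cols = list(range(self.x_index(i, 0), self.x_index(i, 0) + self.nx))
            cols += list(range(self.u_index(i), self.u_index(i) + self.nu))
            if self.itf is not None:
                cols.append(self.itf)
            loc.append(np.array(cols))
            rows_all.append(np.repeat(np.arange(self.n_path) + i * self.n_path, len(cols)))
            cols_all.append(np.tile(np.array(cols), self.n_path))
        self.path_cols = loc
        self._path_rc = (np.concatenate(rows_all), np.concatenate(cols_all))

    # ------------------------------------------------------------------
    # constraints (scaled space)
    def dynamics_fun(self, zs):
        z = self.phys(zs)
        _, _, tf = self.unpack(z)
        lin = self.Dmat @ z - (self.mesh.h * tf) * (self.Rmat @ z)
        return lin * self.dyn_row_scale

    def dynamics_jac(self, zs):
        z = self.phys(zs)
        _, _, tf = self.unpack(z)
        J = self.Dmat - (self.mesh.h * tf) * self.Rmat
        J = (sp.diags(self.dyn_row_scale) @ J @ sp.diags(self.half)).tocsr()
        if self.itf is not None:
            extra = (
                -(self.mesh.h) * (self.Rmat @ z) * self.dyn_row_scale
                * self.half[self.itf]
            )
            m = J.shape[0]
            rows = np.nonzero(extra)[0]
            col = sp.csr_matrix(
                (extra[rows], (rows, np.full(rows.size, self.itf))),
                shape=(m, self.nz),
            )
            J = J + col
        return J

    def path_fun(self, zs):
        z = self.phys(zs)
        states, controls, tf = self.unpack(z)
        if self.ocp.path_batch is not None:
            G = self.ocp.path_batch(
                states[:, 0, :], controls, self.sigma_starts, np.full(self.N, tf)
            )
            return (G / self.path_scale).ravel()
        out = np.empty(self.N * self.n_path)
        for i in range(self.N):
            g = self.ocp.path(states[i, 0], controls[i], self.sigma_starts[i], tf)
            out[i * self.n_path : (i + 1) * self.n_path] = g / self.path_scale
        return out

    def _path_jac_batched(self, zs):
        """Path Jacobian by one vectorized complex-step sweep."""
        z = self.phys(zs)
        states, controls, tf = self.unpack(z)
        N, nx, nu = self.N, self.nx, self.nu
        ntf = 1 if self.itf is not None else 0
        nloc = nx + nu + ntf
        h = 1e-100
        X = np.repeat(states[:, 0, :], nloc, axis=0).astype(complex)
        U = np.repeat(controls, nloc, axis=0).astype(complex)
        TF = np.full(N * nloc, tf, dtype=complex)
        sig = np.repeat(self.sigma_starts, nloc)
        rows_base = np.arange(N)[:, None] * nloc
        for j in range(nx):
            X[(rows_base + j).ravel(), j] += 1j * h
        for j in range(nu):
            U[(rows_base + nx + j).ravel(), j] += 1j * h
        if ntf:
            TF[(rows_base + nx + nu).ravel()] += 1j * h
        G = self.ocp.path_batch(X, U, sig, TF)  # (N*nloc, n_path)
        J = G.imag / h  # sensitivity per perturbed direction
        data = np.empty(N * self.n_path * nloc)
        pos = 0
        rows, cols = self._path_rc
        for i in range(N):
            block = J[i * nloc : (i + 1) * nloc].T / self.path_scale[:, None]
            data[pos : pos + block.size] = block.ravel()
            pos += block.size
        Js = sp.csr_matrix(
            (data, (rows, cols)), shape=(self.N * self.n_path, self.nz)
        )
        return Js @ sp.diags(self.half)

    def path_jac(self, zs):
        if self.ocp.path_batch is not None:
            return self._path_jac_batched(zs)
        z = self.phys(zs)
        states, controls, tf = self.unpack(z)
        rows, cols, vals = [], [], []
        ntf = 1 if self.itf is not None else 0
        for i in range(self.N):
            loc = np.concatenate([states[i, 0], controls[i], [tf]][: 2 + ntf])

            def g_local(v, i=i):
                x = v[: self.nx]
                u = v[self.nx : self.nx + self.nu]
                tfl = v[-1] if ntf else tf
                return self.ocp.path(x, u, self.sigma_starts[i], tfl) / self.path_scale

            J = cs_jacobian(g_local, loc)
            r0 = i * self.n_path
            cidx = self.path_cols[i]
            for a in range(self.n_path):
                for b in range(cidx.size):
                    rows.append(r0 + a)
                    cols.append(cidx[b])
                    vals.append(J[a, b])
        Js = sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.N * self.n_path, self.nz)
        )
        return Js @ sp.diags(self.half)

    def boundary_fun(self, zs):
        z = self.phys(zs)
        states, _, tf = self.unpack(z)
        return np.atleast_1d(self.ocp.boundary(states[0, 0], states[-1, -1], tf))

    def boundary_jac(self, zs):
        z = self.phys(zs)
        states, _, tf = self.unpack(z)
        nb = len(np.atleast_1d(self.ocp.boundary_lb))
        ntf = 1 if self.itf is not None else 0
        loc = np.concatenate([states[0, 0], states[-1, -1], [tf]][: 2 + ntf])

        def b_local(v):
            x0 = v[: self.nx]
            xf = v[self.nx : 2 * self.nx]
            tfl = v[-1] if ntf else tf
            return np.atleast_1d(self.ocp.boundary(x0, xf, tfl))

        J = cs_jacobian(b_local, loc)
        cols = np.concatenate(
            [
                np.arange(self.x_index(0, 0), self.x_index(0, 0) + self.nx),
                np.arange(
                    self.x_index(self.N - 1, self.d),
                    self.x_index(self.N - 1, self.d) + self.nx,
                ),
                [self.itf] if ntf else [],
            ]
        ).astype(int)
        Js = sp.lil_matrix((nb, self.nz))
        Js[:, cols] = J
        return (Js.tocsr()) @ sp.diags(self.half)

    # ------------------------------------------------------------------
    # objective (scaled space): Gauss-Newton structure
    def _quad_cols(self):
        if not hasattr(self, "_quad_cols_cache"):
            cols = []
            for i in range(self.N):
                for k in range(self.d):
                    c = list(range(self.x_index(i, k + 1), self.x_index(i, k + 1) + self.nx))
                    c += list(range(self.u_index(i), self.u_index(i) + self.nu))
                    if self.itf is not None:
                        c.append(self.itf)
                    cols.append(np.array(c))
            self._quad_cols_cache = cols
        return self._quad_cols_cache

    def _quad_terms_batched(self, z, with_jac=False):
        states, controls, tf = self.unpack(z)
        N, d, nx, nu = self.N, self.d, self.nx, self.nu
        M = N * d
        h_w = self.mesh.h
        w = self.mesh.weights
        fac = (h_w * tf) * np.tile(w, N)  # per node
        X = states[:, 1:, :].reshape(M, nx)
        U = np.repeat(controls, d, axis=0)
        sig = self.sigma_coll.ravel()
        r = np.asarray(self.ocp.quad_batch(X, U, sig, np.full(M, tf)))
        sq = np.einsum("mr,mr->m", r, r)
        total = float(fac @ sq)
        term_sums = {
            k: float(fac @ np.einsum("mr,mr->m", r[:, sl], r[:, sl]))
            for k, sl in self.ocp.term_slices.items()
        }
        if not with_jac:
            return total, None, None, term_sums
        ntf = 1 if self.itf is not None else 0
        nloc = nx + nu + ntf
        hstep = 1e-100
        Xp = np.repeat(X, nloc, axis=0).astype(complex)
        Up = np.repeat(U, nloc, axis=0).astype(complex)
        TFp = np.full(M * nloc, tf, dtype=complex)
        sigp = np.repeat(sig, nloc)
        rows_base = np.arange(M)[:, None] * nloc
        for j in range(nx):
            Xp[(rows_base + j).ravel(), j] += 1j * hstep
        for j in range(nu):
            Up[(rows_base + nx + j).ravel(), j] += 1j * hstep
        if ntf:
            TFp[(rows_base + nx + nu).ravel()] += 1j * hstep
        Gp = np.asarray(self.ocp.quad_batch(Xp, Up, sigp, TFp))
        Jall = (Gp.imag / hstep).reshape(M, nloc, -1)  # (M, nloc, nres)
        grad = np.zeros(self.nz)
        cols = self._quad_cols()
        tri_r, tri_c, tri_v = [], [], []
        for m in range(M):
            Jm = Jall[m].T  # (nres, nloc)
            gloc = 2.0 * fac[m] * (Jm.T @ r[m])
            if ntf:
                gloc[-1] += h_w * np.tile(w, N)[m] * sq[m]
            np.add.at(grad, cols[m], gloc)
            Hloc = 2.0 * fac[m] * (Jm.T @ Jm)
            rr, cc = np.meshgrid(cols[m], cols[m], indexing="ij")
            tri_r.append(rr.ravel())
            tri_c.append(cc.ravel())
            tri_v.append(Hloc.ravel())
        tri = (np.concatenate(tri_r), np.concatenate(tri_c), np.concatenate(tri_v))
        return total, grad, tri, term_sums

    def _quad_terms(self, z, with_jac=False):
        if self.ocp.quad_batch is not None:
            return self._quad_terms_batched(z, with_jac)
        """Quadrature cost, gradient and GN Hessian in physical space."""
        states, controls, tf = self.unpack(z)
        h = self.mesh.h
        w = self.mesh.weights
        total = 0.0
        grad = np.zeros(self.nz) if with_jac else None
        tri = ([], [], []) if with_jac else None
        term_sums: dict[str, float] = {
            k: 0.0 for k in self.ocp.term_slices
        }
        ntf = 1 if self.itf is not None else 0
        for i in range(self.N):
            for k in range(self.d):
                x = states[i, k + 1]
                u = controls[i]
                sig = self.sigma_coll[i, k]
                r = np.asarray(self.ocp.quad_residuals(x, u, sig, tf))
                fac = h * tf * w[k]
                total += fac * float(r @ r)
                for name, sl in self.ocp.term_slices.items():
                    term_sums[name] += fac * float(r[sl] @ r[sl])
                if not with_jac:
                    continue
                loc = np.concatenate([x, u, [tf]][: 2 + ntf])

                def r_local(v, i=i, sig=sig):
                    xx = v[: self.nx]
                    uu = v[self.nx : self.nx + self.nu]
                    tfl = v[-1] if ntf else tf
                    return np.asarray(
                        self.ocp.quad_residuals(xx, uu, sig, tfl)
                    )

                J = cs_jacobian(r_local, loc)
                cidx = np.concatenate(
                    [
                        np.arange(self.x_index(i, k + 1), self.x_index(i, k + 1) + self.nx),
                        np.arange(self.u_index(i), self.u_index(i) + self.nu),
                        [self.itf] if ntf else [],
                    ]
                ).astype(int)
                gloc = 2.0 * fac * (J.T @ r)
                if ntf:
                    gloc[-1] += h * w[k] * float(r @ r)  # d(fac)/dtf
                np.add.at(grad, cidx, gloc)
                Hloc = 2.0 * fac * (J.T @ J)
                rr, cc = np.meshgrid(cidx, cidx, indexing="ij")
                tri[0].extend(rr.ravel())
                tri[1].extend(cc.ravel())
                tri[2].extend(Hloc.ravel())
        return total, grad, tri, term_sums

    def objective(self, zs):
        return self._objective_full(zs)[0]

    def objective_grad(self, zs):
        return self._objective_full(zs, with_grad=True)[1]

    def _objective_full(self, zs, with_grad=False, with_hess=False):
        z = self.phys(zs)
        states, _, tf = self.unpack(z)
        need_jac = with_grad or with_hess
        total, grad, tri, terms = 0.0, None, None, {}
        if self.ocp.quad_residuals is not None:
            total, grad, tri, terms = self._quad_terms(z, with_jac=need_jac)
        elif need_jac:
            grad = np.zeros(self.nz)
            tri = ([], [], [])
        if self.ocp.mayer is not None:
            x0, xf = states[0, 0], states[-1, -1]
            total += float(self.ocp.mayer(x0, xf, tf))
            if need_jac:
                ntf = 1 if self.itf is not None else 0
                loc = np.concatenate([x0, xf, [tf]][: 2 + ntf])

                def m_local(v):
                    a = v[: self.nx]
                    b = v[self.nx : 2 * self.nx]
                    tfl = v[-1] if ntf else tf
                    return self.ocp.mayer(a, b, tfl)

                from ._smooth import cs_gradient

                gm = cs_gradient(m_local, loc)
                cidx = np.concatenate(
                    [
                        np.arange(self.x_index(0, 0), self.x_index(0, 0) + self.nx),
                        np.arange(
                            self.x_index(self.N - 1, self.d),
                            self.x_index(self.N - 1, self.d) + self.nx,
                        ),
                        [self.itf] if ntf else [],
                    ]
                ).astype(int)
                np.add.at(grad, cidx, gm)
        if with_grad and not with_hess:
            return total, grad * self.half, None, terms
        if with_hess:
            H = sp.csr_matrix(
                (tri[2], (tri[0], tri[1])), shape=(self.nz, self.nz)
            )
            H = sp.diags(self.half) @ H @ sp.diags(self.half)
            return total, grad * self.half, H, terms
        return total, None, None, terms

    def breakdown(self, zs):
        z = self.phys(zs)
        states, _, tf = self.unpack(z)
        terms = {}
        if self.ocp.quad_residuals is not None:
            _, _, _, terms = self._quad_terms(z, with_jac=False)
        if self.ocp.mayer is not None:
            if self.ocp.mayer_terms is not None:
                terms.update(self.ocp.mayer_terms(states[0, 0], states[-1, -1], tf))
            else:
                terms["mayer"] = float(self.ocp.mayer(states[0, 0], states[-1, -1], tf))
        return terms


def transcribe(ocp: OCPDefinition, mesh: Mesh) -> _Transcription:
    """Assemble the scaled NLP for ``ocp`` on ``mesh``."""
    return _Transcription(ocp, mesh)


def _initial_guess_vector(tr: _Transcription, guess) -> np.ndarray:
    """Scaled decision vector from a (states, controls, tf) guess triple."""
    states, controls, tf = guess
    z = np.empty(tr.nz)
    z[: tr.iu0] = np.asarray(states, dtype=float).reshape(-1)
    z[tr.iu0 : tr.iu0 + tr.N * tr.nu] = np.asarray(controls, dtype=float).reshape(-1)
    if tr.itf is not None:
        z[tr.itf] = tf
    zs = (z - tr.mid) / tr.half
    return np.clip(zs, -1.0, 1.0)


def _project_feasible(tr: _Transcription, zs0, iters: int = 10, target: float = 1e-4):
    """Minimum-norm Gauss-Newton projection of a guess onto the equality
    constraint manifold (dynamics, continuity, equality path rows).

    Keeps the start point close to the supplied trajectories while making
    it dynamically consistent, which prevents the interior-point solver
    from taking a long feasibility-restoration excursion through poorly
    tracking regions.
    """
    import scipy.sparse.linalg as spla

    eq_path = None
    if tr.ocp.path is not None or tr.ocp.path_batch is not None:
        lb = np.atleast_1d(tr.ocp.path_lb)
        ub = np.atleast_1d(tr.ocp.path_ub)
        eq_rows = np.where((lb == ub))[0]
        if eq_rows.size:
            mask = np.tile(np.isin(np.arange(lb.size), eq_rows), tr.N)
            eq_path = (mask, np.tile(lb / tr.path_scale, tr.N)[mask])
    zs = zs0.copy()
    for it in range(iters):
        parts = [tr.dynamics_fun(zs)]
        jacs = [tr.dynamics_jac(zs)]
        if tr.N > 1:
            parts.append((tr.Cmat @ tr.phys(zs)) * tr.cont_row_scale)
            jacs.append(sp.diags(tr.cont_row_scale) @ tr.Cmat @ sp.diags(tr.half))
        if eq_path is not None:
            mask, rhs = eq_path
            parts.append(tr.path_fun(zs)[mask] - rhs)
            jacs.append(tr.path_jac(zs)[np.where(mask)[0]])
        c = np.concatenate(parts)
        worst = np.abs(c).max()
        if worst < target:
            break
        J = sp.vstack(jacs).tocsr()
        # damped minimum-norm step: delta = -J^T (J J^T + lam I)^-1 c
        JJt = (J @ J.T).tocsc()
        lam = 1e-8 * max(JJt.diagonal().max(), 1.0)
        y = spla.spsolve(JJt + lam * sp.eye(JJt.shape[0]), c)
        delta = -(J.T @ y)
        step = min(1.0, 0.5 / max(np.abs(delta).max(), 1e-12)) \
            if np.abs(delta).max() > 0.5 else 1.0
        zs = np.clip(zs + step * delta, -1.0, 1.0)
    return zs


class _EqualitySystem:
    """Equality constraints of the NLP: dynamics, continuity, equality
    path rows, equality boundary rows, plus any *pinned* inequality rows
    (active-set treatment of path/boundary inequalities)."""

    def __init__(self, tr: _Transcription):
        self.tr = tr
        self.path_eq_rows = np.array([], dtype=int)
        self.path_ineq_rows = np.array([], dtype=int)
        self.bnd_eq_rows = np.array([], dtype=int)
        self.bnd_ineq_rows = np.array([], dtype=int)
        if tr.ocp.path is not None or tr.ocp.path_batch is not None:
            lb = np.atleast_1d(tr.ocp.path_lb)
            ub = np.atleast_1d(tr.ocp.path_ub)
            eq = lb == ub
            base = np.arange(lb.size)
            self.path_eq_rows = np.concatenate(
                [base[eq] + i * lb.size for i in range(tr.N)]
            )
            self.path_ineq_rows = np.concatenate(
                [base[~eq] + i * lb.size for i in range(tr.N)]
            )
            self.path_lb_full = np.tile(lb / tr.path_scale, tr.N)
            self.path_ub_full = np.tile(ub / tr.path_scale, tr.N)
        if tr.ocp.boundary is not None:
            lb = np.atleast_1d(tr.ocp.boundary_lb)
            ub = np.atleast_1d(tr.ocp.boundary_ub)
            self.bnd_eq_rows = np.where(lb == ub)[0]
            self.bnd_ineq_rows = np.where(lb != ub)[0]
            self.bnd_lb, self.bnd_ub = lb, ub
        self.pinned_path: dict[int, float] = {}
        self.pinned_bnd: dict[int, float] = {}

    def update_active(self, zs, margin=1e-9):
        """Pin inequality rows that are violated at ``zs``."""
        self.pinned_path.clear()
        self.pinned_bnd.clear()
        if self.path_ineq_rows.size:
            p = self.tr.path_fun(zs)
            for r in self.path_ineq_rows:
                if p[r] < self.path_lb_full[r] - margin:
                    self.pinned_path[r] = self.path_lb_full[r]
                elif p[r] > self.path_ub_full[r] + margin:
                    self.pinned_path[r] = self.path_ub_full[r]
        if self.bnd_ineq_rows.size:
            bvals = self.tr.boundary_fun(zs)
            for r in self.bnd_ineq_rows:
                if bvals[r] < self.bnd_lb[r] - margin:
                    self.pinned_bnd[r] = self.bnd_lb[r]
                elif bvals[r] > self.bnd_ub[r] + margin:
                    self.pinned_bnd[r] = self.bnd_ub[r]

    def residual_and_jac(self, zs, with_jac=True):
        tr = self.tr
        parts, jacs = [], []
        parts.append(tr.dynamics_fun(zs))
        if with_jac:
            jacs.append(tr.dynamics_jac(zs))
        if tr.N > 1:
            parts.append((tr.Cmat @ tr.phys(zs)) * tr.cont_row_scale)
            if with_jac:
                jacs.append(sp.diags(tr.cont_row_scale) @ tr.Cmat @ sp.diags(tr.half))
        need_path = self.path_eq_rows.size or self.pinned_path
        if need_path:
            p = tr.path_fun(zs)
            rows = np.concatenate([
                self.path_eq_rows, np.array(sorted(self.pinned_path), dtype=int)
            ]).astype(int)
            tgt = np.concatenate([
                self.path_lb_full[self.path_eq_rows],
                np.array([self.pinned_path[r] for r in sorted(self.pinned_path)]),
            ])
            parts.append(p[rows] - tgt)
            if with_jac:
                Jp = tr.path_jac(zs).tocsr()
                jacs.append(Jp[rows])
        need_bnd = self.bnd_eq_rows.size or self.pinned_bnd
        if need_bnd:
            bvals = self.tr.boundary_fun(zs)
            rows = np.concatenate([
                self.bnd_eq_rows, np.array(sorted(self.pinned_bnd), dtype=int)
            ]).astype(int)
            tgt = np.concatenate([
                self.bnd_lb[self.bnd_eq_rows],
                np.array([self.pinned_bnd[r] for r in sorted(self.pinned_bnd)]),
            ])
            parts.append(bvals[rows] - tgt)
            if with_jac:
                Jb = self.tr.boundary_jac(zs).tocsr()
                jacs.append(Jb[rows])
        c = np.concatenate(parts)
        if not with_jac:
            return c, None
        return c, sp.vstack(jacs).tocsr()

    def ineq_violation(self, zs):
        worst = 0.0
        if self.path_ineq_rows.size:
            p = self.tr.path_fun(zs)
            worst = max(
                worst,
                float(np.max(np.maximum(self.path_lb_full - p, 0.0)[self.path_ineq_rows], initial=0.0)),
                float(np.max(np.maximum(p - self.path_ub_full, 0.0)[self.path_ineq_rows], initial=0.0)),
            )
        if self.bnd_ineq_rows.size:
            b = self.tr.boundary_fun(zs)
            worst = max(
                worst,
                float(np.max(np.maximum(self.bnd_lb - b, 0.0)[self.bnd_ineq_rows], initial=0.0)),
                float(np.max(np.maximum(b - self.bnd_ub, 0.0)[self.bnd_ineq_rows], initial=0.0)),
            )
        return worst


def _project_eq(tr, eq: _EqualitySystem, zs, iters=15, target=1e-6, refresh=1,
                frozen=None):
    """Gauss-Newton projection onto the (active) equality manifold.

    The constraint Jacobian (and its normal-equations factorization) is
    refreshed every ``refresh`` iterations and reused in between (chord
    Gauss-Newton); near-feasible starts converge in a few cheap sweeps.
    """
    import scipy.sparse.linalg as spla

    zs = zs.copy()
    worst = np.inf
    if frozen is not None:
        J, lu = frozen
    else:
        lu = None
        J = None
    for k in range(iters):
        if frozen is not None:
            c, _ = eq.residual_and_jac(zs, with_jac=False)
        elif lu is None or k % refresh == 0:
            eq.update_active(zs)  # active set frozen between refreshes
            c, J = eq.residual_and_jac(zs)
            JJt = (J @ J.T).tocsc()
            lam = 1e-10 * max(JJt.diagonal().max(), 1.0)
            lu = spla.splu(JJt + lam * sp.eye(JJt.shape[0], format="csc"))
        else:
            c, _ = eq.residual_and_jac(zs, with_jac=False)
        worst = np.abs(c).max() if c.size else 0.0
        if worst < target:
            break
        delta = -(J.T @ lu.solve(c))
        mx = np.abs(delta).max()
        if mx > 0.5:
            delta *= 0.5 / mx
        zs = np.clip(zs + delta, -1.0, 1.0)
    return zs, worst


def _solve_reduced(tr: _Transcription, zs0, tol=1e-3, maxiter=150, cg_iters=200,
                   verbose=False):
    """Feasible-path reduced-gradient SQP.

    Alternates Gauss-Newton projection onto the constraint manifold with
    Gauss-Newton descent steps restricted to its tangent space (projected
    conjugate gradients), and a line search that re-projects each trial
    point. Stiff foot-ground contact makes long linearized excursions
    catastrophically infeasible; keeping every iterate feasible sidesteps
    the problem entirely.
    """
    import scipy.sparse.linalg as spla

    eq = _EqualitySystem(tr)
    proj_target = max(1e-11, 0.01 * tol)
    zs, feas = _project_eq(tr, eq, zs0, target=proj_target)
    f, g, H, _ = tr._objective_full(zs, with_grad=True, with_hess=True)
    n_small = 0
    delta = 0.5  # infinity-norm trust radius in scaled variables
    for it in range(maxiter):
        # restore any inequality rows the previous (frozen-Jacobian) line
        # search pushed out of bounds, then refresh the active set
        if eq.ineq_violation(zs) > tol:
            zs, feas = _project_eq(tr, eq, zs, iters=8, target=proj_target)
            f, g, H, _ = tr._objective_full(zs, with_grad=True, with_hess=True)
        c, J = eq.residual_and_jac(zs)
        lu = spla.splu((J @ J.T + 1e-10 * sp.eye(J.shape[0])).tocsc())
        pins = (dict(eq.pinned_path), dict(eq.pinned_bnd))

        active_lo = (zs <= -1.0 + 1e-9)
        active_hi = (zs >= 1.0 - 1e-9)

        def mask_bounds(vec):
            out = vec.copy()
            out[active_lo & (out > 0)] = 0.0  # direction = -out; keep inward
            out[active_hi & (out < 0)] = 0.0
            return out

        def proj(vec):
            return vec - J.T @ lu.solve(J @ vec)

        # projected CG on the Gauss-Newton model
        r = mask_bounds(proj(g))
        gnorm = np.abs(r).max()
        if gnorm < tol:
            break
        def cg_direction(delta_tr):
            """Steihaug projected CG on the Gauss-Newton model, truncated
            at the infinity-norm trust boundary."""
            d = np.zeros_like(zs)
            rcg = r.copy()
            p = -rcg
            rr = rcg @ rcg
            for _ in range(cg_iters):
                Hp = mask_bounds(proj(H @ p + 1e-8 * p))
                pHp = p @ Hp
                if pHp <= 1e-12 * (p @ p):
                    edge = (delta_tr - np.abs(d).max()) / max(np.abs(p).max(), 1e-12)
                    d = d + max(edge, 0.0) * p
                    if not d.any():
                        d = -rcg * (delta_tr / max(np.abs(rcg).max(), 1e-12))
                    break
                alpha = rr / pHp
                d_new = d + alpha * p
                if np.abs(d_new).max() > delta_tr:
                    edge = (delta_tr - np.abs(d).max()) / max(np.abs(p).max(), 1e-12)
                    d = d + max(edge, 0.0) * p
                    break
                d = d_new
                rcg = rcg + alpha * Hp
                rr_new = rcg @ rcg
                if np.sqrt(rr_new) < 1e-3 * np.sqrt(g @ g) + 1e-12:
                    break
                p = -rcg + (rr_new / rr) * p
                rr = rr_new
            return d

        # trust-region loop: shrink the radius (re-running CG, so the
        # direction re-bends toward the well-conditioned subspace) until a
        # projected step is accepted
        accepted = False
        while delta >= 1e-4:
            d = cg_direction(delta)
            slope = g @ d
            if slope > 0:
                d = -mask_bounds(proj(g)) * (delta / max(np.abs(r).max(), 1e-12))
                slope = g @ d
            for a in (1.0, 0.3):
                zt = np.clip(zs + a * d, -1.0, 1.0)
                # frozen projection requires the active set that J was
                # assembled with (a fallback below may have changed it)
                eq.pinned_path, eq.pinned_bnd = dict(pins[0]), dict(pins[1])
                zt, feas_t = _project_eq(tr, eq, zt, iters=12, frozen=(J, lu),
                                         target=proj_target)
                if feas_t >= 10 * tol:
                    # chord projection too weak for this step: refresh the
                    # Jacobian a couple of times (factorizations dominate
                    # the runtime, so keep the budget small)
                    zt, feas_t = _project_eq(tr, eq, np.clip(zs + a * d, -1.0, 1.0),
                                             iters=8, target=proj_target, refresh=3)
                ft = tr.objective(zt)
                if feas_t < 10 * tol and ft < f + 1e-4 * a * slope:
                    rel = (f - ft) / max(abs(f), 1e-12)
                    zs, f, feas = zt, ft, feas_t
                    accepted = True
                    break
                logger.debug(
                    "reduced-SQP reject: delta=%.3g a=%.3g f=%.6g->%.6g feas=%.2e",
                    delta, a, f, ft, feas_t,
                )
            if accepted:
                delta = min(2.0 * delta, 2.0)
                break
            delta *= 0.25
        if not accepted:
            logger.debug("reduced-SQP: no acceptable step at iteration %d", it)
            break
        if verbose:
            print(f"reduced-SQP it {it}: f={f:.6g} feas={feas:.2e} |g_red|={gnorm:.3g} alpha={alpha}")
        f, g, H, _ = tr._objective_full(zs, with_grad=True, with_hess=True)
        n_small = n_small + 1 if rel < 1e-8 else 0
        if n_small >= 3:
            break
    eq.update_active(zs)
    c, _ = eq.residual_and_jac(zs, with_jac=False)
    viol = max(np.abs(c).max() if c.size else 0.0, eq.ineq_violation(zs))
    status = 1 if viol < 10 * tol else 4
    return zs, f, viol, it + 1, status


def solve(
    tr: _Transcription,
    guess,
    tol: float = 1e-3,
    maxiter: int = 1000,
    verbose: int = 0,
    project_guess: bool = True,
    method: str = "reduced",
) -> OCPSolution:
    """Solve the transcribed NLP with the trust-constr interior-point method.

    ``guess`` is a ``(states, controls, tf)`` triple in physical units with
    shapes ``(N, d+1, nx)`` and ``(N, nu)``. Non-convergence is reported via
    the solution status, not an exception.
    """
    zs0 = _initial_guess_vector(tr, guess)
    if method == "reduced":
        zs, f, viol, nit, status = _solve_reduced(
            tr, zs0, tol=tol, maxiter=maxiter, verbose=bool(verbose)
        )
        z = tr.phys(zs)
        states, controls, tf = tr.unpack(z)
        return OCPSolution(
            mesh=tr.mesh,
            states=states.copy(),
            controls=controls.copy(),
            t_final=float(tf),
            objective=float(f),
            breakdown=tr.breakdown(zs),
            status=status,
            message="reduced-gradient SQP converged" if status == 1
            else "reduced-gradient SQP stopped with residual infeasibility",
            n_iter=int(nit),
            constr_violation=float(viol),
            success=status == 1,
        )
    if project_guess:
        zs0 = _project_feasible(tr, zs0)
    constraints = []
    if tr.mesh.free_time:
        constraints.append(
            NonlinearConstraint(
                tr.dynamics_fun, 0.0, 0.0, jac=tr.dynamics_jac,
                hess=lambda x, v: sp.csr_matrix((tr.nz, tr.nz)),
            )
        )
    else:
        tf = tr.mesh.tf_bounds[0]
        A = sp.diags(tr.dyn_row_scale) @ (tr.Dmat - tr.mesh.h * tf * tr.Rmat) @ sp.diags(tr.half)
        b = -(sp.diags(tr.dyn_row_scale) @ (tr.Dmat - tr.mesh.h * tf * tr.Rmat)) @ tr.mid
        constraints.append(LinearConstraint(A, -b, -b))
    if tr.N > 1:
        Ac = sp.diags(tr.cont_row_scale) @ tr.Cmat @ sp.diags(tr.half)
        bc = -(sp.diags(tr.cont_row_scale) @ tr.Cmat) @ tr.mid
        constraints.append(LinearConstraint(Ac, -bc, -bc))
    if tr.ocp.path is not None:
        lb = np.tile(np.atleast_1d(tr.ocp.path_lb) / tr.path_scale, tr.N)
        ub = np.tile(np.atleast_1d(tr.ocp.path_ub) / tr.path_scale, tr.N)
        constraints.append(
            NonlinearConstraint(
                tr.path_fun, lb, ub, jac=tr.path_jac,
                hess=lambda x, v: sp.csr_matrix((tr.nz, tr.nz)),
            )
        )
    if tr.ocp.boundary is not None:
        constraints.append(
            NonlinearConstraint(
                tr.boundary_fun,
                np.atleast_1d(tr.ocp.boundary_lb),
                np.atleast_1d(tr.ocp.boundary_ub),
                jac=tr.boundary_jac,
                hess=lambda x, v: sp.csr_matrix((tr.nz, tr.nz)),
            )
        )
    bounds = Bounds(-np.ones(tr.nz), np.ones(tr.nz))

    def fun(zs):
        return tr.objective(zs)

    def grad(zs):
        return tr._objective_full(zs, with_grad=True)[1]

    def hess(zs):
        return tr._objective_full(zs, with_grad=True, with_hess=True)[2]

    res = minimize(
        fun,
        zs0,
        jac=grad,
        hess=hess,
        bounds=bounds,
        constraints=constraints,
        method="trust-constr",
        options={
            "xtol": tol * 1e-3,
            "gtol": tol,
            "maxiter": maxiter,
            "verbose": verbose,
            "initial_tr_radius": 0.1,
        },
    )
    z = tr.phys(res.x)
    states, controls, tf = tr.unpack(z)
    return OCPSolution(
        mesh=tr.mesh,
        states=states.copy(),
        controls=controls.copy(),
        t_final=float(tf),
        objective=float(res.fun),
        breakdown=tr.breakdown(res.x),
        status=int(res.status),
        message=str(res.message),
        n_iter=int(res.nit),
        constr_violation=float(res.constr_violation),
        success=bool(res.status in (1, 2)),
    )
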