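"""Steady interstitial flow in the porous arterial wall.

The wall is treated as a Brinkman porous medium: momentum balance

    rho_t (dw/dt + (w.grad) w) = -grad P + mu_t lap(w) - (mu_t / K) w
    div w = 0

on the tissue domain, with a prescribed transmural filtration speed V
entering through the lumen-tissue interface and a zero normal velocity
gradient at the adventitial boundary.  The discretisation is a Marker-and-
Cell (MAC) staggered grid: u on vertical cell faces, v on horizontal cell
faces, pressure at cell centers, each pixel of the label grid being one
control volume.  Irregular interfaces are handled by direct forcing at the
boundary faces (immersed-boundary treatment on the pixel grid).

The steady state is reached by a pseudo-transient march.  The Darcy drag
is taken pointwise-implicitly (with Table-level permeabilities its
relaxation time is ~1e-13 s, far below any usable explicit step); the
viscous, convective and pressure terms are explicit.  Each pseudo-step is
followed by a pressure-velocity projection: an SOR solve (omega = 1.2 by
default) of the pressure-correction Poisson system, polished by SOLA
cell-wise corrections until the maximum absolute cell divergence is below
1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import splu

from .geometry import GeometryError, TissueLabelGrid
from .parameters import ModelParameters

__all__ = [
    "FlowField", "NumericsSettings", "StaggeredDomain", "FlowSolverError",
    "solve_interstitial_flow", "sor_poisson", "sor_pressure_solve",
    "sola_correct", "apply_flow_bcs",
]

# face type codes
INACTIVE, INTERIOR, INNER, OUTER = 0, 1, 2, 3


class FlowSolverError(RuntimeError):
    """The flow solver failed to converge."""


@dataclass
class NumericsSettings:
    """Solver knobs for the flow and transport marches."""

    omega: float = 1.2            # SOR over-relaxation factor
    div_tol: float = 1e-12        # certified max |divergence|, 1/s
    steady_tol: float = 1e-10     # relative velocity change per pseudo-step
    max_iters: int = 100_000      # pseudo-transient step budget
    max_sweeps: int = 200_000     # SOR/SOLA sweep budget per projection
    safety: float = 0.8           # time-step safety factor
    direct_init: bool = True      # sparse direct warm start of the first solve

    def __post_init__(self) -> None:
        if not (1.0 <= self.omega < 2.0):
            raise ValueError(f"omega must lie in [1, 2), got {self.omega}")
        if not (0 < self.safety <= 1):
            raise ValueError("safety must lie in (0, 1]")


@dataclass
class FlowField:
    """MAC velocity/pressure field on a label grid.

    ``u`` lives on vertical faces (ny, nx+1), ``v`` on horizontal faces
    (ny+1, nx), ``P`` at cell centers (ny, nx); units mm/s and g/(mm s^2).
    ``div_max`` is the certified maximum absolute discrete divergence over
    tissue cells after the last projection.
    """

    u: np.ndarray
    v: np.ndarray
    P: np.ndarray
    pixel_size: float
    div_max: float = np.inf

    @classmethod
    def zeros(cls, grid: TissueLabelGrid) -> "FlowField":
        ny, nx = grid.shape
        return cls(np.zeros((ny, nx + 1)), np.zeros((ny + 1, nx)),
                   np.zeros((ny, nx)), grid.pixel_size, div_max=0.0)

    def divergence(self, tissue_mask: np.ndarray) -> np.ndarray:
        h = self.pixel_size
        div = (np.diff(self.u, axis=1) + np.diff(self.v, axis=0)) / h
        return np.where(tissue_mask, div, 0.0)

    def speed_at_cells(self) -> np.ndarray:
        uc = 0.5 * (self.u[:, :-1] + self.u[:, 1:])
        vc = 0.5 * (self.v[:-1, :] + self.v[1:, :])
        return np.hypot(uc, vc)


class StaggeredDomain:
    """Face classification and boundary data for a label grid.

    Each face is INACTIVE, INTERIOR (tissue|tissue), INNER (tissue|lumen,
    i.e. on the lumen-tissue interface) or OUTER (tissue|exterior, the
    adventitial boundary).  Inner faces carry the local interface normal
    estimated from a smoothed lumen indicator so that direct forcing can
    impose the filtration velocity in the true normal direction on the
    staircase boundary.
    """

    #: physical length scale (mm) over which interface normals are
    #: estimated; fixed in physical units so the normal field converges
    #: under grid refinement, with a two-pixel floor for coarse grids
    NORMAL_SMOOTHING_MM = 0.16

    def __init__(self, grid: TissueLabelGrid,
                 smoothing_sigma: float | None = None):
        self.grid = grid
        self.h = grid.pixel_size
        if smoothing_sigma is None:
            smoothing_sigma = max(2.0, self.NORMAL_SMOOTHING_MM / self.h)
        labels = grid.labels
        ny, nx = labels.shape
        from .parameters import DC, EXTERIOR, HT, LUMEN

        pad = np.pad(labels, 1, constant_values=EXTERIOR)
        tis = (pad >= HT) & (pad <= DC)
        lum = pad == LUMEN

        def classify(tL, lL, tR, lR):
            t = np.full(tL.shape, INACTIVE, dtype=np.int8)
            t[tL & tR] = INTERIOR
            t[(tL & lR) | (lL & tR)] = INNER
            t[(tL & ~tR & ~lR) | (tR & ~tL & ~lL)] = OUTER
            return t

        # u faces: (ny, nx+1); face i sits between cells i-1 and i
        self.u_type = classify(tis[1:-1, :-1], lum[1:-1, :-1],
                               tis[1:-1, 1:], lum[1:-1, 1:])
        # v faces: (ny+1, nx); face j sits between cells j-1 and j
        self.v_type = classify(tis[:-1, 1:-1], lum[:-1, 1:-1],
                               tis[1:, 1:-1], lum[1:, 1:-1])

        self.tissue = grid.tissue_mask
        # interior-face connectivity per cell (E, W, N, S) and open count
        self.cE = self.u_type[:, 1:] == INTERIOR
        self.cW = self.u_type[:, :-1] == INTERIOR
        self.cS = self.v_type[1:, :] == INTERIOR
        self.cN = self.v_type[:-1, :] == INTERIOR
        self.n_open = (self.cE.astype(np.int8) + self.cW + self.cN
                       + self.cS).astype(np.float64)
        if np.any(self.tissue & (self.n_open == 0)):
            raise GeometryError("tissue cells with no interior faces: the "
                                "wall is unresolved at this pixel size")
        # adventitial (outer) faces per cell direction: these participate
        # in the projection as free outflow degrees of freedom
        self.oE = self.u_type[:, 1:] == OUTER
        self.oW = self.u_type[:, :-1] == OUTER
        self.oS = self.v_type[1:, :] == OUTER
        self.oN = self.v_type[:-1, :] == OUTER
        self.n_out = (self.oE.astype(np.int8) + self.oW + self.oN
                      + self.oS).astype(np.float64)
        self.n_corr = self.n_open + self.n_out

        # smoothed lumen indicator -> interface normal pointing into the
        # lumen (out of the tissue), sampled at the staggered faces
        phi = ndimage.gaussian_filter(lum[1:-1, 1:-1].astype(float),
                                      smoothing_sigma, mode="nearest")
        phip = np.pad(phi, 1, mode="edge")
        h = self.h
        gx_u = (phip[1:-1, 1:] - phip[1:-1, :-1]) / h        # (ny, nx+1)
        gy_c = np.gradient(phip, h, axis=0)[1:-1, :]
        gy_u = 0.5 * (gy_c[:, 1:] + gy_c[:, :-1])
        gy_v = (phip[1:, 1:-1] - phip[:-1, 1:-1]) / h        # (ny+1, nx)
        gx_c = np.gradient(phip, h, axis=1)[:, 1:-1]
        gx_v = 0.5 * (gx_c[1:, :] + gx_c[:-1, :])

        def unit(gx, gy):
            mag = np.hypot(gx, gy)
            mag[mag == 0] = 1.0
            return gx / mag, gy / mag

        self.nx_u, self.ny_u = unit(gx_u, gy_u)   # lumen normal at u faces
        self.nx_v, self.ny_v = unit(gx_v, gy_v)   # lumen normal at v faces

        # outward sign of boundary faces: +1 when tissue is on the low-index
        # side (so positive u/v leaves the tissue), else -1
        self.u_out_sign = np.where(tis[1:-1, :-1], 1.0, -1.0)
        self.v_out_sign = np.where(tis[:-1, 1:-1], 1.0, -1.0)
        self.u_inner = self.u_type == INNER
        self.v_inner = self.v_type == INNER
        self.u_outer = self.u_type == OUTER
        self.v_outer = self.v_type == OUTER
        self.u_interior = self.u_type == INTERIOR
        self.v_interior = self.v_type == INTERIOR

        # donors for the adventitial zero-normal-gradient copy: the next
        # face towards the tissue side
        self._check_outer_donors()

    def _check_outer_donors(self) -> None:
        uj, ui = np.nonzero(self.u_outer)
        tis_left = self.u_out_sign[uj, ui] > 0
        donor_i = np.where(tis_left, ui - 1, ui + 1)
        ok = (donor_i >= 0) & (donor_i < self.u_type.shape[1])
        if not ok.all() or np.any(
                self.u_type[uj[ok], donor_i[ok]] == INACTIVE):
            raise GeometryError("adventitial face without an interior "
                                "neighbor along its normal")
        self._u_donor = (uj, ui, donor_i)
        vj, vi = np.nonzero(self.v_outer)
        tis_up = self.v_out_sign[vj, vi] > 0
        donor_j = np.where(tis_up, vj - 1, vj + 1)
        ok = (donor_j >= 0) & (donor_j < self.v_type.shape[0])
        if not ok.all() or np.any(
                self.v_type[donor_j[ok], vi[ok]] == INACTIVE):
            raise GeometryError("adventitial face without an interior "
                                "neighbor along its normal")
        self._v_donor = (vj, vi, donor_j)

    # -- boundary data ---------------------------------------------------
    def forced_inner_values(self, V: float) -> Tuple[np.ndarray, np.ndarray]:
        """Face velocities imposing w = V along the inward interface
        normal on the lumen-tissue faces."""
        fu = np.where(self.u_inner, -V * self.nx_u, 0.0)
        fv = np.where(self.v_inner, -V * self.ny_v, 0.0)
        return fu, fv

    def inner_inflow(self, u: np.ndarray, v: np.ndarray) -> float:
        """Net volumetric inflow through the lumen-tissue interface
        (positive into the tissue), mm^2/s per unit depth."""
        qu = -(u * self.u_out_sign)[self.u_inner].sum()
        qv = -(v * self.v_out_sign)[self.v_inner].sum()
        return float((qu + qv) * self.h)

    def outer_outflow(self, u: np.ndarray, v: np.ndarray) -> float:
        """Net volumetric outflow through the adventitial boundary."""
        qu = (u * self.u_out_sign)[self.u_outer].sum()
        qv = (v * self.v_out_sign)[self.v_outer].sum()
        return float((qu + qv) * self.h)


def apply_flow_bcs(field: FlowField, grid: TissueLabelGrid,
                   params: ModelParameters,
                   domain: StaggeredDomain | None = None) -> FlowField:
    """Impose the interface conditions on the staggered velocities.

    Lumen-tissue faces are direct-forced so the velocity along the local
    interface normal equals the filtration speed V (into the tissue);
    adventitial faces copy their interior neighbor, the discrete form of a
    zero normal velocity gradient.
    """
    dom = domain or StaggeredDomain(grid)
    fu, fv = dom.forced_inner_values(params.V)
    u, v = field.u, field.v
    u[dom.u_inner] = fu[dom.u_inner]
    v[dom.v_inner] = fv[dom.v_inner]
    uj, ui, udon = dom._u_donor
    u[uj, ui] = u[uj, udon]
    vj, vi, vdon = dom._v_donor
    v[vj, vi] = v[vdon, vi]
    return field


# ---------------------------------------------------------------------------
# Pressure solvers
# ---------------------------------------------------------------------------

def sor_poisson(rhs: np.ndarray, conn: Dict[str, np.ndarray],
                active: np.ndarray, omega: float = 1.2,
                x0: np.ndarray | None = None,
                fixed: np.ndarray | None = None,
                fixed_values: np.ndarray | None = None,
                extra_diag: np.ndarray | None = None,
                tol: float = 1e-12, max_sweeps: int = 200_000
                ) -> Tuple[np.ndarray, int]:
    """Red-black SOR for the 5-point graph Laplacian ``n_c x_c - sum
    x_nb = rhs`` on the active cells.

    ``conn`` holds the per-cell connection masks ``cE, cW, cN, cS``;
    ``fixed`` marks Dirichlet cells held at ``fixed_values``;
    ``extra_diag`` adds uncoupled (ghost Dirichlet-0) degrees to the cell
    diagonal.  Returns the solution and the number of sweeps used.  The
    residual decreases monotonically in the energy norm for omega in
    [1, 2).
    """
    if not (1.0 <= omega < 2.0):
        raise ValueError(f"omega must lie in [1, 2), got {omega}")
    cE, cW, cN, cS = conn["cE"], conn["cW"], conn["cN"], conn["cS"]
    degree = (cE.astype(float) + cW + cN + cS)
    if extra_diag is not None:
        degree = degree + extra_diag
    x = np.zeros_like(rhs) if x0 is None else x0.copy()
    if fixed is not None:
        x[fixed] = fixed_values[fixed]
        solve_mask = active & ~fixed
    else:
        solve_mask = active
    deg_safe = np.where(degree > 0, degree, 1.0)
    jj, ii = np.mgrid[0:rhs.shape[0], 0:rhs.shape[1]]
    colors = [(solve_mask & ((jj + ii) % 2 == p)) for p in (0, 1)]

    def nb_sum(x):
        s = np.zeros_like(x)
        s[:, :-1] += np.where(cE[:, :-1], x[:, 1:], 0.0)
        s[:, 1:] += np.where(cW[:, 1:], x[:, :-1], 0.0)
        s[:-1, :] += np.where(cS[:-1, :], x[1:, :], 0.0)
        s[1:, :] += np.where(cN[1:, :], x[:-1, :], 0.0)
        return s

    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        for mask in colors:
            gs = (nb_sum(x) + rhs) / deg_safe
            x[mask] = (1 - omega) * x[mask] + omega * gs[mask]
        res = np.abs(degree * x - nb_sum(x) - rhs)[solve_mask]
        if res.size == 0 or res.max() <= tol:
            break
    return x, sweeps


def _projection_rhs_scale(dom: StaggeredDomain, beta: float):
    """Connection masks and scaling for the pressure-correction system."""
    conn = {"cE": dom.cE, "cW": dom.cW, "cN": dom.cN, "cS": dom.cS}
    return conn


def sor_pressure_solve(field: FlowField, grid: TissueLabelGrid,
                       omega: float = 1.2, beta: float = 1.0,
                       domain: StaggeredDomain | None = None,
                       tol: float = 1e-14, max_sweeps: int = 200_000,
                       x0: np.ndarray | None = None) -> np.ndarray:
    """Solve the pressure-correction Poisson system for the current
    divergence of ``field`` and return the correction dP.

    Applying ``u -= beta * grad(dP)`` across interior faces then removes
    the divergence.  ``beta`` is the projection mobility (time step over
    inertial-plus-drag mass, mm^3 s / g).
    """
    dom = domain or StaggeredDomain(grid)
    div = field.divergence(dom.tissue)
    rhs = -div * dom.h ** 2 / beta
    conn = _projection_rhs_scale(dom, beta)
    rhs_tol = tol * dom.h ** 2 / beta
    dP, _ = sor_poisson(rhs, conn, dom.tissue, omega=omega,
                        extra_diag=dom.n_out, tol=rhs_tol,
                        max_sweeps=max_sweeps, x0=x0)
    return dP


def _apply_pressure_correction(u, v, P, dP, dom: StaggeredDomain,
                               beta: float) -> None:
    h = dom.h
    gx = np.zeros_like(u)
    gx[:, 1:-1] = (dP[:, 1:] - dP[:, :-1]) / h
    u[dom.u_interior] -= beta * gx[dom.u_interior]
    gy = np.zeros_like(v)
    gy[1:-1, :] = (dP[1:, :] - dP[:-1, :]) / h
    v[dom.v_interior] -= beta * gy[dom.v_interior]
    # adventitial faces: Dirichlet-0 ghost pressure, outward flux adjusts
    k = beta / h
    u[:, 1:][dom.oE] += k * dP[dom.oE]
    u[:, :-1][dom.oW] -= k * dP[dom.oW]
    v[1:, :][dom.oS] += k * dP[dom.oS]
    v[:-1, :][dom.oN] -= k * dP[dom.oN]
    P += dP


def sola_correct(field: FlowField, grid: TissueLabelGrid,
                 omega: float = 1.2, beta: float = 1.0,
                 domain: StaggeredDomain | None = None,
                 tol: float = 1e-12, max_sweeps: int = 200_000,
                 stall_window: int = 50) -> FlowField:
    """Cell-by-cell SOLA pressure-velocity correction.

    Sweeps the tissue cells (red-black), nudging each cell's open face
    velocities to cancel its divergence, with over-relaxation ``omega``,
    until the maximum absolute divergence is at most ``tol``.  Raises
    FlowSolverError if the divergence stops decreasing.
    """
    dom = domain or StaggeredDomain(grid)
    h = dom.h
    u, v, P = field.u, field.v, field.P
    n_corr = np.where(dom.n_corr > 0, dom.n_corr, 1.0)
    jj, ii = np.mgrid[0:dom.tissue.shape[0], 0:dom.tissue.shape[1]]
    colors = [(dom.tissue & ((jj + ii) % 2 == p)) for p in (0, 1)]
    history = []
    for sweep in range(max_sweeps):
        for mask in colors:
            div = (np.diff(u, axis=1) + np.diff(v, axis=0)) / h
            delta = np.where(mask, omega * div * h / n_corr, 0.0)
            u[:, 1:][dom.cE] -= delta[dom.cE]
            u[:, :-1][dom.cW] += delta[dom.cW]
            v[1:, :][dom.cS] -= delta[dom.cS]
            v[:-1, :][dom.cN] += delta[dom.cN]
            u[:, 1:][dom.oE] -= delta[dom.oE]
            u[:, :-1][dom.oW] += delta[dom.oW]
            v[1:, :][dom.oS] -= delta[dom.oS]
            v[:-1, :][dom.oN] += delta[dom.oN]
            P[mask] -= delta[mask] * h / beta
        dmax = np.abs(field.divergence(dom.tissue)).max()
        if dmax <= tol:
            field.div_max = float(dmax)
            return field
        history.append(dmax)
        if len(history) > stall_window and \
                history[-1] >= history[-stall_window] * (1 - 1e-12):
            raise FlowSolverError(
                f"SOLA stagnated at max divergence {dmax:.3e} "
                f"(tolerance {tol:.1e}) after {sweep + 1} sweeps")
    raise FlowSolverError(f"SOLA did not reach divergence {tol:.1e} in "
                          f"{max_sweeps} sweeps (last {history[-1]:.3e})")


def _direct_pressure_init(dom: StaggeredDomain):
    """LU factorisation of the (pinned) cell Laplacian for warm starts."""
    tissue = dom.tissue
    idx = -np.ones(tissue.shape, dtype=np.int64)
    cells = np.nonzero(tissue)
    n = len(cells[0])
    idx[cells] = np.arange(n)
    rows, cols, vals = [], [], []

    def add_edges(conn_mask, dj, di):
        cj, ci = np.nonzero(conn_mask & tissue)
        a = idx[cj, ci]
        b = idx[cj + dj, ci + di]
        rows.extend(a)
        cols.extend(b)
        vals.extend(np.full(len(a), -1.0))

    add_edges(dom.cE, 0, 1)
    add_edges(dom.cW, 0, -1)
    add_edges(dom.cS, 1, 0)
    add_edges(dom.cN, -1, 0)
    # the adventitial ghost-Dirichlet faces make the system non-singular
    diag = dom.n_corr[cells]
    rows.extend(np.arange(n))
    cols.extend(np.arange(n))
    vals.extend(diag)
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    lu = splu(A.tocsc())
    return lu, idx, cells


# ---------------------------------------------------------------------------
# Momentum terms
# ---------------------------------------------------------------------------

def _laplacian(a: np.ndarray, h: float) -> np.ndarray:
    ap = np.pad(a, 1, mode="edge")
    return (ap[1:-1, 2:] + ap[1:-1, :-2] + ap[2:, 1:-1] + ap[:-2, 1:-1]
            - 4 * a) / h ** 2


def _hybrid_deriv(a: np.ndarray, vel: np.ndarray, h: float, axis: int,
                  pe_switch: np.ndarray) -> np.ndarray:
    """Hybrid central / second-order-upwind first derivative of ``a``.

    Central differencing where the cell Peclet number is at most 2,
    second-order upwind (falling back to first-order at the array edge)
    where it exceeds 2.
    """
    ap = np.pad(a, 2, mode="edge")
    sl = [slice(2, -2)] * 2

    def shift(k):
        s = list(sl)
        s[axis] = slice(2 + k, ap.shape[axis] - 2 + k)
        return ap[tuple(s)]

    central = (shift(1) - shift(-1)) / (2 * h)
    up_pos = (3 * a - 4 * shift(-1) + shift(-2)) / (2 * h)
    up_neg = (-3 * a + 4 * shift(1) - shift(2)) / (2 * h)
    upwind = np.where(vel >= 0, up_pos, up_neg)
    return np.where(pe_switch, upwind, central)


def _convective_u(u, v, h, rho, mu):
    v_at_u = np.zeros_like(u)
    v_at_u[:, 1:-1] = 0.25 * (v[:-1, :-1] + v[:-1, 1:]
                              + v[1:, :-1] + v[1:, 1:])
    pe = rho * np.hypot(u, v_at_u) * h / mu > 2.0
    return (u * _hybrid_deriv(u, u, h, 1, pe)
            + v_at_u * _hybrid_deriv(u, v_at_u, h, 0, pe))


def _convective_v(u, v, h, rho, mu):
    u_at_v = np.zeros_like(v)
    u_at_v[1:-1, :] = 0.25 * (u[:-1, :-1] + u[:-1, 1:]
                              + u[1:, :-1] + u[1:, 1:])
    pe = rho * np.hypot(u_at_v, v) * h / mu > 2.0
    return (u_at_v * _hybrid_deriv(v, u_at_v, h, 1, pe)
            + v * _hybrid_deriv(v, v, h, 0, pe))


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def solve_interstitial_flow(grid: TissueLabelGrid, params: ModelParameters,
                            numerics: NumericsSettings | None = None,
                            domain: StaggeredDomain | None = None
                            ) -> FlowField:
    """March the Brinkman system to its steady state on the label grid.

    Returns the steady MAC field with ``div_max`` certified at or below
    the numerics divergence tolerance (1e-12 by default) at every tissue
    cell.  Raises FlowSolverError on non-convergence, with the residual
    history in the message.
    """
    num = numerics or NumericsSettings()
    dom = domain or StaggeredDomain(grid)
    h, rho, mu, K = dom.h, params.rho_t, params.mu_t, params.K
    field = FlowField.zeros(grid)
    u, v, P = field.u, field.v, field.P

    dt = num.safety * rho * h ** 2 / (4.0 * mu)   # viscous pseudo-step bound
    drag = 1.0 + dt * mu / (rho * K)
    beta = dt / (rho + dt * mu / K)
    conn = {"cE": dom.cE, "cW": dom.cW, "cN": dom.cN, "cS": dom.cS}
    lu_ctx = _direct_pressure_init(dom) if num.direct_init else None

    history = []
    umax_prev = 0.0
    for it in range(num.max_iters):
        apply_flow_bcs(field, grid, params, dom)
        # momentum (explicit pressure/viscous/convective, implicit drag)
        gx = np.zeros_like(u)
        gx[:, 1:-1] = (P[:, 1:] - P[:, :-1]) / h
        gy = np.zeros_like(v)
        gy[1:-1, :] = (P[1:, :] - P[:-1, :]) / h
        du = dt * (-gx / rho + (mu / rho) * _laplacian(u, h)
                   - _convective_u(u, v, h, rho, mu))
        dv = dt * (-gy / rho + (mu / rho) * _laplacian(v, h)
                   - _convective_v(u, v, h, rho, mu))
        u_old = u.copy()
        v_old = v.copy()
        u[dom.u_interior] = ((u + du)[dom.u_interior]) / drag
        v[dom.v_interior] = ((v + dv)[dom.v_interior]) / drag

        # re-slave the adventitial faces (discrete zero normal gradient);
        # the projection below re-balances mass through them
        apply_flow_bcs(field, grid, params, dom)

        # projection: SOR (warm-started) then SOLA polish to the certificate
        div = field.divergence(dom.tissue)
        if np.abs(div).max() > num.div_tol:
            rhs = -div * h ** 2 / beta
            if lu_ctx is not None:
                lu, idx, cells = lu_ctx
                x0 = np.zeros_like(rhs)
                x0[cells] = lu.solve(rhs[cells])
            else:
                x0 = None
            dP, _ = sor_poisson(rhs, conn, dom.tissue, omega=num.omega,
                                x0=x0, extra_diag=dom.n_out,
                                tol=num.div_tol * h ** 2 / beta,
                                max_sweeps=num.max_sweeps)
            _apply_pressure_correction(u, v, P, dP, dom, beta)
            sola_correct(field, grid, omega=num.omega, beta=beta,
                         domain=dom, tol=num.div_tol,
                         max_sweeps=num.max_sweeps)

        umax = max(np.abs(u).max(), np.abs(v).max())
        change = max(np.abs(u - u_old).max(), np.abs(v - v_old).max())
        rel = change / max(umax, umax_prev, 1e-300)
        history.append(rel)
        umax_prev = umax
        if it > 0 and rel <= num.steady_tol:
            P -= P[dom.tissue].mean()          # pin the pressure level
            field.div_max = float(np.abs(
                field.divergence(dom.tissue)).max())
            return field
        if umax == 0.0 and it > 0:             # zero-forcing fixed point
            field.div_max = 0.0
            return field
    raise FlowSolverError(
        "flow solver did not reach steady state in "
        f"{num.max_iters} pseudo-steps; last relative changes "
        f"{['%.2e' % r for r in history[-5:]]}")
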