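"""Tissue potential energy, vertex forces and overdamped dynamics.

The energy of cell *i* with reference area ``A0``, edge length ``l0`` and
turning angle ``alpha0 = pi/3`` is

    E_i = eta_i (A_i - A0)^2 + mu_i P_i^2
          + sigma_i sum_j (l_ij - l0)^2 + phi_i sum_j (alpha_ij - alpha0)^2

where ``alpha_ij`` is the signed turning (exterior) angle at vertex *j*.
The tissue energy is the sum over cells; the force on a vertex is the
negative gradient of that sum with respect to its position.  Motion is
first-order (overdamped): ``V = k F H(|F| - F0)`` — a vertex moves with
velocity proportional to the force on it, and not at all while the force
magnitude stays at or below the yield threshold ``F0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidCellError, StructuralInstabilityError
from .mesh import Geometry, TissueMesh, hexagon_area

__all__ = [
    "ElasticCoeffs",
    "DynamicsParams",
    "ReferenceState",
    "cell_energy",
    "cell_energies",
    "tissue_energy",
    "vertex_forces",
    "finite_difference_forces",
    "step_mechanics",
    "vertex_velocities",
    "cell_velocity",
]


@dataclass
class ReferenceState:
    """Reference (undeformed regular hexagon) geometry of the energy."""

    l0: float = 1.0
    alpha0: float = math.pi / 3.0
    A0: float | None = None

    def __post_init__(self):
        if self.A0 is None:
            self.A0 = hexagon_area(self.l0)


@dataclass
class DynamicsParams:
    """Mobility ``k``, force threshold ``F0`` and Euler time step ``dt``."""

    k: float = 0.5
    F0: float = 0.1
    dt: float = 0.005

    def __post_init__(self):
        if self.k <= 0 or self.dt <= 0 or self.F0 < 0:
            raise ValueError("require k > 0, dt > 0, F0 >= 0")


class ElasticCoeffs:
    """Per-cell elastic coefficients (eta, mu, sigma, phi).

    Stored as one array per coefficient so that chemo-mechanical coupling
    can retarget individual cells; uniform tissues simply replicate values.
    ``phi`` is restricted to [0, 1]; ``eta`` and ``sigma`` must be >= 0
    (``mu`` may be negative: negative contractility expands boundaries).
    """

    __slots__ = ("eta", "mu", "sigma", "phi")

    def __init__(self, eta, mu, sigma, phi):
        self.eta = np.atleast_1d(np.asarray(eta, dtype=float))
        self.mu = np.atleast_1d(np.asarray(mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        self.phi = np.atleast_1d(np.asarray(phi, dtype=float))
        if np.any(self.eta < 0) or np.any(self.sigma < 0):
            raise ValueError("eta and sigma must be non-negative")
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise ValueError("phi must lie in [0, 1]")

    @classmethod
    def uniform(cls, n: int, eta: float, mu: float, sigma: float, phi: float):
        return cls(
            np.full(n, float(eta)),
            np.full(n, float(mu)),
            np.full(n, float(sigma)),
            np.full(n, float(phi)),
        )

    def append_copy(self, source_cell: int) -> None:
        """Append a new cell inheriting the coefficients of ``source_cell``."""
        self.eta = np.append(self.eta, self.eta[source_cell])
        self.mu = np.append(self.mu, self.mu[source_cell])
        self.sigma = np.append(self.sigma, self.sigma[source_cell])
        self.phi = np.append(self.phi, self.phi[source_cell])

    def __len__(self):
        return len(self.eta)

    def copy(self) -> "ElasticCoeffs":
        return ElasticCoeffs(
            self.eta.copy(), self.mu.copy(), self.sigma.copy(), self.phi.copy()
        )


# ---------------------------------------------------------------------------
# energy


def cell_energies(
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
    geom: Geometry | None = None,
) -> np.ndarray:
    """Vector of per-cell energies."""
    if mesh.n_cells == 0:
        raise InvalidCellError("empty mesh has no energy")
    g = geom if geom is not None else mesh.compute_geometry()
    c = mesh.cache
    starts = c.offsets[:-1]
    dl2 = np.add.reduceat((g.edge_len - ref.l0) ** 2, starts)
    da2 = np.add.reduceat((g.angles - ref.alpha0) ** 2, starts)
    return (
        coeffs.eta * (g.area - ref.A0) ** 2
        + coeffs.mu * g.perimeter ** 2
        + coeffs.sigma * dl2
        + coeffs.phi * da2
    )


def cell_energy(
    cell_id: int,
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
) -> float:
    """Energy of a single cell."""
    return float(cell_energies(mesh, coeffs, ref)[cell_id])


def tissue_energy(
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
    geom: Geometry | None = None,
) -> float:
    """Total potential energy U(t), summed over all cells."""
    return float(cell_energies(mesh, coeffs, ref, geom).sum())


# ---------------------------------------------------------------------------
# forces


def vertex_forces(
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
    geom: Geometry | None = None,
) -> np.ndarray:
    """Analytic force on every vertex: ``F = -dU/dR``.

    A vertex shared by *m* cells accumulates contributions from all *m*
    cell energies: the shoelace-area gradient, the perimeter and edge-length
    gradients through its two incident edges in each cell, and the gradients
    of the three turning angles of each cell that depend on its position.
    """
    g = geom if geom is not None else mesh.compute_geometry()
    c = mesh.cache
    V = mesh.n_vertices
    p = mesh.positions

    eta_s = coeffs.eta[c.cell_of]
    mu_s = coeffs.mu[c.cell_of]
    sig_s = coeffs.sigma[c.cell_of]
    phi_s = coeffs.phi[c.cell_of]

    # --- area term: dA/dr_j = 0.5 * (y_{j+1} - y_{j-1}, x_{j-1} - x_{j+1})
    wA = (2.0 * coeffs.eta * (g.area - ref.A0))[c.cell_of]
    rn = p[c.next_v]
    rp = p[c.prev_v]
    gx_area = wA * 0.5 * (rn[:, 1] - rp[:, 1])
    gy_area = wA * 0.5 * (rp[:, 0] - rn[:, 0])

    # --- perimeter + edge terms share the unit edge vector u_j = ev/el
    el = g.edge_len
    if np.any(el <= 0):
        raise StructuralInstabilityError("zero-length edge in force evaluation")
    ux = g.edge_vec[:, 0] / el
    uy = g.edge_vec[:, 1] / el
    w_edge = 2.0 * mu_s * g.perimeter[c.cell_of] + 2.0 * sig_s * (el - ref.l0)
    # d l_j / d r_tail = -u_j ; d l_j / d r_head = +u_j

    # --- angle term: alpha_j = angle(c) - angle(b), b = r_j - r_{j-1},
    # c = r_{j+1} - r_j.  d angle(v)/dv = (-v_y, v_x)/|v|^2.
    bx = p[c.flat_v][:, 0] - rp[:, 0]
    by = p[c.flat_v][:, 1] - rp[:, 1]
    lb2 = bx * bx + by * by
    lc2 = el * el
    wT = 2.0 * phi_s * (g.angles - ref.alpha0)
    # d alpha_j / d r_{j-1} = (-b_y, b_x)/|b|^2 * (-1) applied via b-chain:
    #   d alpha/d b = (b_y, -b_x)/|b|^2 ; d b/d r_{j-1} = -I
    dbx = by / lb2
    dby = -bx / lb2
    dcx = -uy / el  # (-c_y, c_x)/|c|^2 with c = edge_vec
    dcy = ux / el

    # scatter-add: for x and y separately, concatenate all contributions
    idx = np.concatenate((
        c.flat_v,              # area
        c.flat_v, c.next_v,    # perimeter+edge tail/head
        c.prev_v, c.flat_v, c.next_v,  # angle b-tail, center, c-head
    ))
    valx = np.concatenate((
        gx_area,
        -w_edge * ux, w_edge * ux,
        -wT * dbx, wT * (dbx - dcx), wT * dcx,
    ))
    valy = np.concatenate((
        gy_area,
        -w_edge * uy, w_edge * uy,
        -wT * dby, wT * (dby - dcy), wT * dcy,
    ))
    grad = np.stack(
        (
            np.bincount(idx, weights=valx, minlength=V),
            np.bincount(idx, weights=valy, minlength=V),
        ),
        axis=1,
    )
    return -grad


def finite_difference_forces(
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
    h: float = 1e-6,
) -> np.ndarray:
    """Central-difference force oracle: ``-(U(R+h e) - U(R-h e)) / (2h)``.

    Independent of the analytic gradient path; O(V) energy evaluations, so
    intended for validation on small meshes, or as a slow fallback.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    F = np.zeros_like(mesh.positions)
    pos = mesh.positions
    for v in range(mesh.n_vertices):
        for d in range(2):
            orig = pos[v, d]
            pos[v, d] = orig + h
            up = tissue_energy(mesh, coeffs, ref)
            pos[v, d] = orig - h
            um = tissue_energy(mesh, coeffs, ref)
            pos[v, d] = orig
            F[v, d] = -(up - um) / (2.0 * h)
    return F


# ---------------------------------------------------------------------------
# dynamics


def vertex_velocities(
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
    dyn: DynamicsParams,
    geom: Geometry | None = None,
    forces: np.ndarray | None = None,
) -> np.ndarray:
    """Thresholded overdamped velocities ``V = k F H(|F| - F0)``.

    ``H`` is the Heaviside step with ``H(x) = 0`` for ``x <= 0``: a vertex
    whose force magnitude is exactly ``F0`` stays put.  Gating is on the
    vector norm, applied identically to interior and boundary vertices.
    """
    F = forces if forces is not None else vertex_forces(mesh, coeffs, ref, geom)
    if not np.all(np.isfinite(F)):
        raise StructuralInstabilityError("non-finite vertex force")
    mag = np.hypot(F[:, 0], F[:, 1])
    gate = mag > dyn.F0
    return dyn.k * F * gate[:, None]


def min_incident_edge_length(mesh: TissueMesh, geom: Geometry) -> np.ndarray:
    """Shortest edge incident to each vertex (inf for unused vertex slots)."""
    c = mesh.cache
    both = np.concatenate((geom.edge_len, geom.edge_len))
    out = np.minimum.reduceat(both[c.incident_order], c.incident_offsets)
    if np.any(c.incident_empty):
        out[c.incident_empty] = np.inf
    return out


def step_mechanics(
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
    dyn: DynamicsParams,
    geom: Geometry | None = None,
    max_step_frac: float | None = 0.25,
) -> np.ndarray:
    """Advance all vertex positions by one explicit Euler step (in place).

    All forces are evaluated from the state at the start of the step, then
    every position is updated at once (synchronous / Jacobi update), so the
    result does not depend on vertex ordering.  Returns the velocities used.

    ``max_step_frac`` is a numerical safeguard for strongly contracted
    tissues: no vertex may move further in one step than this fraction of
    its shortest incident edge, which prevents a single Euler step from
    inverting a polygon when the angle-elasticity stiffness (which scales
    like 1/l**2) outruns the fixed time step.  The cap only engages for
    displacements that would already violate the explicit-stability limit;
    set it to ``None`` for the raw update.
    """
    g = geom if geom is not None else mesh.compute_geometry()
    vel = vertex_velocities(mesh, coeffs, ref, dyn, g)
    disp = vel * dyn.dt
    if max_step_frac is not None:
        mag = np.hypot(disp[:, 0], disp[:, 1])
        allowed = max_step_frac * min_incident_edge_length(mesh, g)
        over = mag > allowed
        if np.any(over):
            disp[over] *= (allowed[over] / mag[over])[:, None]
    mesh.positions += disp
    return vel


def cell_velocity(cell_id: int, mesh: TissueMesh, velocities: np.ndarray) -> np.ndarray:
    """Cell speed observable: arithmetic mean of its vertex velocities."""
    return velocities[mesh.cells[cell_id]].mean(axis=0)
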