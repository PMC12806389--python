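"""Intercellular chemical transport and chemo-mechanical coupling.

Each cell carries a concentration vector ``C_i`` of one or more signaling
species.  Neighboring cells exchange signal through their shared edge with
a flux proportional to the edge length and the concentration difference,
and every cell degrades signal at rate ``beta``:

    dC_i/dt = sum_j delta * l_ij * (C_j - C_i) - beta * C_i

so a cell richer than all of its neighbors loses mass.  Optional source
cells (a band at the left boundary of the tissue) are clamped to a fixed
concentration after each update.

Coupling maps concentration onto per-cell elastic coefficients through the
linear law ``coeff_i = clamp(-k1 * |C_i| + b1)``; with the defaults the
angle-elasticity ``phi`` falls to 0 (shape-flexible, mesenchymal-like
cells) near the source and stays at 1 (stiff epithelial phenotype) far
from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, StructuralInstabilityError
from .mechanics import ElasticCoeffs
from .mesh import TissueMesh

__all__ = [
    "SourceSpec",
    "ChemParams",
    "CouplingSpec",
    "init_concentrations",
    "diffusion_fluxes",
    "step_chemistry",
    "apply_coupling",
]

#: admissible targets of a coupling and the clamp range that keeps each
#: coefficient inside its physical domain
_COUPLING_RANGES = {
    "phi": (0.0, 1.0),
    "eta": (0.0, math.inf),
    "sigma": (0.0, math.inf),
    "mu": (-math.inf, math.inf),
}


@dataclass
class SourceSpec:
    """Constant-concentration source cells at the left tissue boundary.

    Cells whose centroid x-coordinate lies within ``band`` (in units of the
    reference edge length) of the leftmost centroid are clamped to
    ``value`` after every chemistry step.
    """

    value: float = 1.0
    band: float = 1.0

    def select(self, mesh: TissueMesh) -> np.ndarray:
        cx = mesh.cell_centroids()[:, 0]
        return cx <= cx.min() + self.band


@dataclass
class ChemParams:
    """Diffusion ``delta``, degradation ``beta`` and optional source."""

    delta: float = 1.0
    beta: float = 0.04
    source: SourceSpec | None = None

    def __post_init__(self):
        if self.delta < 0 or self.beta < 0:
            raise ValueError("delta and beta must be non-negative")


def init_concentrations(n_cells: int, n_species: int = 1) -> np.ndarray:
    """Zero-initialized ``(N, S)`` concentration array."""
    return np.zeros((n_cells, n_species))


def diffusion_fluxes(mesh: TissueMesh, conc: np.ndarray, delta: float) -> np.ndarray:
    """Per-interior-edge flux ``J_ij = delta * l_ij * (C_i - C_j)``.

    ``i`` is the first incident cell of each interior edge in cache order;
    swapping the two cells flips the sign (antisymmetry).
    """
    c = mesh.cache
    geom = mesh.compute_geometry()
    mask = c.interior
    le = geom.edge_len[c.edge_first_slot][mask]
    ci = c.edge_cell_a[mask]
    cj = c.edge_cell_b[mask]
    conc = np.atleast_2d(conc.T).T
    return delta * le[:, None] * (conc[ci] - conc[cj])


def step_chemistry(
    mesh: TissueMesh,
    conc: np.ndarray,
    params: ChemParams,
    dt: float,
    source_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One explicit Euler step of transport + degradation.

    Returns the updated ``(N, S)`` array; source cells (if any) are
    re-clamped to the source value after the update.
    """
    conc = np.atleast_2d(np.asarray(conc, dtype=float).T).T
    c = mesh.cache
    geom = mesh.compute_geometry()
    mask = c.interior
    le = geom.edge_len[c.edge_first_slot][mask]
    ci = c.edge_cell_a[mask]
    cj = c.edge_cell_b[mask]
    n = mesh.n_cells
    dC = np.zeros_like(conc)
    flux = params.delta * le[:, None] * (conc[ci] - conc[cj])
    for s in range(conc.shape[1]):
        out = np.bincount(ci, weights=flux[:, s], minlength=n)
        dC[:, s] = np.bincount(cj, weights=flux[:, s], minlength=n) - out
    new = conc + dt * (dC - params.beta * conc)
    if not np.all(np.isfinite(new)):
        raise StructuralInstabilityError("non-finite concentration update")
    if params.source is not None:
        if source_mask is None:
            source_mask = params.source.select(mesh)
        new[source_mask] = params.source.value
    return new


@dataclass
class CouplingSpec:
    """Linear chemo-mechanical coupling ``coeff = clamp(-k1 |C| + b1)``."""

    target: str = "phi"
    k1: float = 1.0
    b1: float = 1.0
    clamp: tuple[float, float] | None = None

    def __post_init__(self):
        if self.target not in _COUPLING_RANGES:
            raise ConfigError(
                f"unknown coupling target {self.target!r}; "
                f"expected one of {sorted(_COUPLING_RANGES)}"
            )
        lo, hi = _COUPLING_RANGES[self.target]
        if self.clamp is None:
            self.clamp = (lo, hi)
        elif self.clamp[0] < lo or self.clamp[1] > hi:
            raise ConfigError(
                f"clamp range {self.clamp} outside the valid domain of "
                f"{self.target!r} ({lo}, {hi})"
            )


def apply_coupling(
    conc: np.ndarray,
    couplings: list[CouplingSpec],
    coeffs: ElasticCoeffs,
) -> ElasticCoeffs:
    """Update per-cell coefficients from concentrations (in place).

    ``|C_i|`` is the Euclidean norm over species; uncoupled coefficients
    are untouched.  Applying the same state twice is a no-op.
    """
    conc = np.atleast_2d(np.asarray(conc, dtype=float).T).T
    mag = np.sqrt((conc * conc).sum(axis=1))
    for spec in couplings:
        val = -spec.k1 * mag + spec.b1
        lo, hi = spec.clamp
        setattr(coeffs, spec.target, np.clip(val, lo, hi))
    return coeffs
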