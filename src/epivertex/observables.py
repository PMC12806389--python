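"""Tissue-level statistics: polygon-class distributions, energies,
regime classification and parameter sweeps.

Cells are binned by polygon class ``n0`` into {4, 5, 6, 7, 8+}; the pooled
8+ class collects everything with eight or more sides.  Completed runs are
classified into one of four regimes — ``uniform`` (cells of comparable
size), ``bubble`` (a few abnormally large many-sided cells among small
contracted ones), ``thread`` (collapse into filamentous chains of tiny
quadrilaterals) or ``unstable`` (the tessellation broke down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidCellError
from .mechanics import ElasticCoeffs, ReferenceState, cell_energies, tissue_energy
from .mesh import Geometry, TissueMesh

__all__ = [
    "POLYGON_CLASSES",
    "TimeSeriesRecord",
    "RegimeThresholds",
    "RegimeLabel",
    "polygon_class_fractions",
    "mean_area_by_class",
    "mean_sides",
    "energy_per_cell",
    "mean_edge_length",
    "classify_regime",
    "phase_sweep",
    "fields_dataframe",
]

#: reported polygon classes; 8 pools all side counts >= 8
POLYGON_CLASSES = (4, 5, 6, 7, 8)


def _pooled_classes(mesh: TissueMesh) -> np.ndarray:
    return np.minimum(mesh.side_counts(), 8)


def polygon_class_fractions(mesh: TissueMesh) -> dict[int, float]:
    """Fraction of cells per polygon class {4, 5, 6, 7, 8+}; sums to 1."""
    if mesh.n_cells == 0:
        raise InvalidCellError("empty mesh")
    n = _pooled_classes(mesh)
    return {
        k: float(np.count_nonzero(n == k)) / mesh.n_cells
        for k in POLYGON_CLASSES
    }


def mean_area_by_class(
    mesh: TissueMesh, A0: float, geom: Geometry | None = None
) -> dict[int, float]:
    """Class-wise mean cell area normalized by ``A0``.

    Classes with no cells in the mesh are omitted (missing, not zero).
    """
    if mesh.n_cells == 0:
        raise InvalidCellError("empty mesh")
    g = geom if geom is not None else mesh.compute_geometry()
    n = _pooled_classes(mesh)
    out = {}
    for k in POLYGON_CLASSES:
        sel = n == k
        if np.any(sel):
            out[k] = float(g.area[sel].mean() / A0)
    return out


def mean_sides(
    mesh: TissueMesh,
    interior_only: bool = False,
    weighting: str = "cells",
) -> float:
    """Mean polygon side count ``<n>``.

    ``interior_only`` restricts to cells with no boundary edge (for the
    Euler-characteristic check: this tends to 6 as the patch grows); the
    default includes boundary cells, matching how the grown-tissue values
    are reported.  ``weighting="neighbors"`` samples each cell once per
    interior adjacency (the mean side count of a randomly chosen
    *neighbor*), which is biased above the plain mean whenever side
    counts vary.
    """
    counts = mesh.side_counts()
    if weighting == "neighbors":
        c = mesh.cache
        ci = c.edge_cell_a[c.interior]
        cj = c.edge_cell_b[c.interior]
        if not len(ci):
            raise InvalidCellError("no interior adjacencies")
        return float((counts[ci].sum() + counts[cj].sum()) / (2 * len(ci)))
    if weighting != "cells":
        raise ValueError("weighting must be 'cells' or 'neighbors'")
    if interior_only:
        sel = ~mesh.cache.boundary_cell
        if not np.any(sel):
            raise InvalidCellError("no interior cells")
        counts = counts[sel]
    return float(counts.mean())


def energy_per_cell(
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
    geom: Geometry | None = None,
) -> tuple[float, float]:
    """``(U/N, mu * (6 l0)^2)``: energy per cell and the analytic value for
    an undeformed hexagonal lattice (the reference line of the energy
    plots).  The reference uses the mean ``mu`` over cells."""
    u = tissue_energy(mesh, coeffs, ref, geom) / mesh.n_cells
    refline = float(np.mean(coeffs.mu)) * (6.0 * ref.l0) ** 2
    return u, refline


def mean_edge_length(mesh: TissueMesh, geom: Geometry | None = None) -> float:
    """Mean length over unique edges (shared edges counted once)."""
    g = geom if geom is not None else mesh.compute_geometry()
    return float(g.edge_len[mesh.cache.edge_first_slot].mean())


# ---------------------------------------------------------------------------
# time series


@dataclass
class TimeSeriesRecord:
    """One observable sample of a running simulation."""

    t: float
    N: int
    U_per_N: float
    P: dict[int, float]
    R: dict[int, float]          # class-wise <A_n>/A0; absent classes missing
    mean_sides: float
    mean_edge_length: float
    R5to8: float = float("nan")  # pooled <A_{n>=5}>/A0

    def as_row(self) -> dict:
        row = {"t": self.t, "N": self.N, "U_per_N": self.U_per_N}
        for k in POLYGON_CLASSES:
            name = f"{k}plus" if k == 8 else str(k)
            row[f"P{name}"] = self.P.get(k, 0.0)
            row[f"R{name}"] = self.R.get(k, float("nan"))
        row["R5to8"] = self.R5to8
        row["mean_sides"] = self.mean_sides
        row["mean_edge_length"] = self.mean_edge_length
        return row


def sample_record(
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
    t: float,
    geom: Geometry | None = None,
) -> TimeSeriesRecord:
    """Compute a full observable record for the current state."""
    g = geom if geom is not None else mesh.compute_geometry()
    u, _ = energy_per_cell(mesh, coeffs, ref, g)
    n = _pooled_classes(mesh)
    big = n >= 5
    pooled = float(g.area[big].mean() / ref.A0) if np.any(big) else float("nan")
    return TimeSeriesRecord(
        t=t,
        N=mesh.n_cells,
        U_per_N=u,
        P=polygon_class_fractions(mesh),
        R=mean_area_by_class(mesh, ref.A0, g),
        mean_sides=mean_sides(mesh),
        mean_edge_length=mean_edge_length(mesh, g),
        R5to8=pooled,
    )


def records_to_frame(records: list[TimeSeriesRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])


# ---------------------------------------------------------------------------
# regime classification


@dataclass
class RegimeThresholds:
    """Heuristic cutoffs operationalizing the by-eye regime regions."""

    thread_edge_frac: float = 0.35    # <l> below this multiple of l0 ...
    thread_area_frac: float = 0.15    # ... and <A> below this multiple of A0
    bubble_area_ratio: float = 3.0    # largest cell area / median area
    bubble_min_sides: int = 7         # bubbles are many-sided cells
    bubble_top_fraction: float = 0.1
    bubble_class_disparity: float = 3.0  # <A_{n>=7}> / <A_4>


@dataclass
class RegimeLabel:
    """Classification of a completed run plus its diagnostic scores."""

    label: str
    scores: dict = field(default_factory=dict)


def classify_regime(
    mesh: TissueMesh,
    ref: ReferenceState,
    integrity_ok: bool = True,
    thresholds: RegimeThresholds | None = None,
    u_per_n: float | None = None,
    reference_line: float | None = None,
) -> RegimeLabel:
    """Label a final state as uniform / bubble / thread / unstable.

    The primary split is the mean geometric scale: a tissue whose mean
    edge length and mean area have both collapsed far below the reference
    hexagon is in one of the two collapsed states; there, the class-area
    disparity ``<A_{n>=7}>/<A_4>`` separates the bubble state (large
    many-sided cells among contracted quadrilaterals: class-area ratios
    near 4, against roughly 2.3 for uniform tissue) from the thread
    state.  An uncollapsed tissue is uniform unless a single
    many-sided cell dominates the area distribution (several times the
    median), the hallmark bubble configuration at mild contraction.
    Steady energy per cell and the undeformed-lattice line are recorded
    as diagnostics when supplied (the uniform state holds U/N above the
    line at mild contractility).
    """
    th = thresholds or RegimeThresholds()
    if not integrity_ok:
        return RegimeLabel("unstable", {})
    g = mesh.compute_geometry()
    ml = mean_edge_length(mesh, g)
    mean_area = float(g.area.mean())
    scores = {"mean_edge_length": ml, "mean_area": mean_area}

    sides = mesh.side_counts()
    quads = sides == 4
    many = sides >= th.bubble_min_sides
    disparity = float("nan")
    if np.any(quads) and np.any(many):
        r4 = float(g.area[quads].mean())
        disparity = float(g.area[many].mean()) / r4 if r4 > 0 else float("inf")
    imax = int(np.argmax(g.area))
    med = float(np.median(g.area))
    max_ratio = float(g.area[imax]) / med if med > 0 else float("inf")
    scores.update(
        {
            "class_disparity": disparity,
            "max_area_ratio": max_ratio,
            "max_cell_sides": int(sides[imax]),
        }
    )
    if u_per_n is not None:
        scores["u_per_n"] = float(u_per_n)
    if reference_line is not None:
        scores["reference_line"] = float(reference_line)

    collapsed = (
        ml < th.thread_edge_frac * ref.l0
        and mean_area < th.thread_area_frac * ref.A0
    )
    if collapsed:
        if np.isfinite(disparity) and disparity > th.bubble_class_disparity:
            return RegimeLabel("bubble", scores)
        return RegimeLabel("thread", scores)
    if max_ratio > th.bubble_area_ratio and sides[imax] >= th.bubble_min_sides:
        return RegimeLabel("bubble", scores)
    return RegimeLabel("uniform", scores)


# ---------------------------------------------------------------------------
# sweeps and field exports


def phase_sweep(mu_grid, eta_grid, base_config, seeds) -> pd.DataFrame:
    """Run the simulator over a mu x eta grid for each seed.

    Returns one row per (mu, eta, seed) in grid order with the regime label
    and its diagnostic scores, plus a ``majority`` column holding the modal
    label of each grid point.  Failed runs are labeled ``unstable``.
    """
    from .driver import run_simulation  # local import: avoids a cycle

    rows = []
    for mu in mu_grid:
        for eta in eta_grid:
            labels = []
            for seed in seeds:
                cfg = base_config.replace(mu=float(mu), eta=float(eta), seed=int(seed))
                try:
                    res = run_simulation(cfg)
                    label, scores = res.regime.label, res.regime.scores
                except Exception:
                    label, scores = "unstable", {}
                labels.append(label)
                rows.append(
                    {
                        "mu": float(mu),
                        "eta": float(eta),
                        "seed": int(seed),
                        "label": label,
                        **{f"score_{k}": v for k, v in scores.items()},
                    }
                )
            vals, cnt = np.unique(labels, return_counts=True)
            majority = str(vals[np.argmax(cnt)])
            for r in rows[-len(seeds):]:
                r["majority"] = majority
    return pd.DataFrame(rows)


def fields_dataframe(
    mesh: TissueMesh,
    coeffs: ElasticCoeffs,
    ref: ReferenceState,
    conc: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cell scalar fields (for concentration / perimeter / energy maps)."""
    g = mesh.compute_geometry()
    cent = mesh.cell_centroids()
    d = {
        "cell": np.arange(mesh.n_cells),
        "x": cent[:, 0],
        "y": cent[:, 1],
        "n0": mesh.side_counts(),
        "area": g.area,
        "perimeter": g.perimeter,
        "energy": cell_energies(mesh, coeffs, ref, g),
        "phi": coeffs.phi,
    }
    if conc is not None:
        conc = np.atleast_2d(np.asarray(conc).T).T
        for s in range(conc.shape[1]):
            d[f"C{s}" if conc.shape[1] > 1 else "C"] = conc[:, s]
    return pd.DataFrame(d)
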