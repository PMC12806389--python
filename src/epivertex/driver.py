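"""Simulation configuration, main loop and canned experiment presets.

One time step advances the tissue in a fixed order: mechanics (forces and
the thresholded Euler position update), chemistry (intercellular transport
plus source clamping), chemo-mechanical coupling, cell divisions, and
intercalations; observables are sampled periodically.  The loop runs at
``dt = 0.005`` by default and stops when the cell count reaches a target,
the step budget is exhausted, or the mesh becomes structurally unstable
(which is itself a reported outcome, not an exception).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mesh as mmod
from .errors import ConfigError, StructuralInstabilityError
from .mechanics import (
    DynamicsParams,
    ElasticCoeffs,
    ReferenceState,
    step_mechanics,
)
from .mesh import TissueMesh, hexagon_area, make_hex_patch, make_regular_hexagon
from .observables import (
    RegimeLabel,
    classify_regime,
    records_to_frame,
    sample_record,
)
from .signaling import (
    ChemParams,
    CouplingSpec,
    SourceSpec,
    apply_coupling,
    init_concentrations,
    step_chemistry,
)
from .topology import (
    DivisionParams,
    IntercalationParams,
    attempt_divisions,
    attempt_intercalations,
    repair_short_edges,
)

log = logging.getLogger("epivertex")

__all__ = [
    "SimulationConfig",
    "RunResult",
    "PRESETS",
    "preset_config",
    "load_config",
    "save_config",
    "run_simulation",
]


@dataclass
class SimulationConfig:
    """Complete, serializable description of one simulation run."""

    # elastic coefficients (uniform initial values)
    mu: float = 0.1
    eta: float = 0.9
    sigma: float = 1.0
    phi: float = 1.0
    # reference state
    l0: float = 1.0
    alpha0: float = math.pi / 3.0
    A0: float | None = None  # defaults to the regular-hexagon area
    # dynamics
    k: float = 0.5
    F0: float = 0.1
    dt: float = 0.005
    # division
    p0: float = 5e-5
    q: float = 1.4
    # intercalation
    d_int: float = 0.15
    post_length_factor: float = 1.5
    # chemistry
    delta: float = 1.0
    beta: float = 0.04
    n_species: int = 1
    source_enabled: bool = False
    source_value: float = 1.0
    source_band: float = 1.0
    # couplings: list of dicts {target, k1, b1, clamp}
    couplings: list = field(default_factory=list)
    # initial condition: "patch" (n_cells hexagons) or "hexagon"
    initial: str = "patch"
    n_cells: int = 32
    # stop criteria
    max_cells: int = 500
    max_steps: int = 200_000
    steady_pn_tol: float | None = None  # optional trailing P_n stationarity gate
    steady_window: int = 10
    # numerical safeguards: per-step displacement cap as a fraction of the
    # shortest incident edge (None disables), and the mesh-repair length
    # below which degenerate edges are collapsed (0 disables)
    max_step_frac: float | None = 0.25
    repair_min_edge: float = 0.02
    # sampling / reproducibility
    sample_every: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.A0 is None:
            self.A0 = hexagon_area(self.l0)
        self.validate()

    def validate(self) -> None:
        positive = {
            "l0": self.l0, "k": self.k, "dt": self.dt, "q": self.q,
            "d_int": self.d_int, "post_length_factor": self.post_length_factor,
            "sample_every": self.sample_every, "n_cells": self.n_cells,
            "max_cells": self.max_cells, "max_steps": self.max_steps,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive (got {v})")
        if not 0.0 <= self.p0 <= 1.0:
            raise ConfigError(f"p0 must lie in [0, 1] (got {self.p0})")
        if self.F0 < 0 or self.delta < 0 or self.beta < 0:
            raise ConfigError("F0, delta and beta must be non-negative")
        if not 0.0 <= self.phi <= 1.0:
            raise ConfigError(f"phi must lie in [0, 1] (got {self.phi})")
        if self.eta < 0 or self.sigma < 0:
            raise ConfigError("eta and sigma must be non-negative")
        if self.initial not in ("patch", "hexagon"):
            raise ConfigError(f"initial must be 'patch' or 'hexagon' (got {self.initial!r})")
        if self.d_int >= self.l0:
            raise ConfigError("d_int must be smaller than l0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def params_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- component views ---------------------------------------------------
    def reference(self) -> ReferenceState:
        return ReferenceState(l0=self.l0, alpha0=self.alpha0, A0=self.A0)

    def dynamics(self) -> DynamicsParams:
        return DynamicsParams(k=self.k, F0=self.F0, dt=self.dt)

    def division(self) -> DivisionParams:
        return DivisionParams(p0=self.p0, q=self.q)

    def intercalation(self) -> IntercalationParams:
        return IntercalationParams(
            d_int=self.d_int, post_length_factor=self.post_length_factor
        )

    def chemistry(self) -> ChemParams:
        src = (
            SourceSpec(value=self.source_value, band=self.source_band)
            if self.source_enabled
            else None
        )
        return ChemParams(delta=self.delta, beta=self.beta, source=src)

    def coupling_specs(self) -> list[CouplingSpec]:
        return [CouplingSpec(**c) if isinstance(c, dict) else c for c in self.couplings]

    def initial_mesh(self) -> TissueMesh:
        if self.initial == "hexagon":
            return make_regular_hexagon(self.l0)
        return make_hex_patch(self.n_cells, self.l0)


def load_config(path) -> SimulationConfig:
    """Read a config file (JSON, or TOML if the suffix is .toml)."""
    text = open(path).read()
    if str(path).endswith(".toml"):
        import tomllib

        d = tomllib.loads(text)
    else:
        d = json.loads(text)
    return SimulationConfig.from_dict(d)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# presets

#: Case 1 varies contractility/area-elasticity at sigma=1 (stiff edges);
#: Case 2 removes the edge penalty (sigma=0); Case 3 frees the angles
#: (phi=0, spindle/mesenchymal shapes); Case 4 couples phi to a chemical
#: gradient from a left-boundary source.  Case 3/4 background coefficients
#: are this package's choices for otherwise-unspecified settings.
PRESETS: dict[str, dict] = {
    "case1-uniform": dict(mu=0.1, eta=0.9, sigma=1.0, phi=1.0),
    "case1-bubble": dict(mu=0.5, eta=0.2, sigma=1.0, phi=1.0),
    "case1-thread": dict(mu=0.4, eta=0.0, sigma=1.0, phi=1.0),
    "case2-uniform": dict(mu=0.0, eta=1.0, sigma=0.0, phi=1.0),
    "case2-bubble": dict(mu=1.0, eta=0.1, sigma=0.0, phi=1.0),
    "case3-spindle": dict(mu=0.1, eta=0.9, sigma=1.0, phi=0.0),
    "case4-coupled": dict(
        mu=0.0,
        eta=1.0,
        sigma=0.0,
        phi=1.0,
        source_enabled=True,
        source_value=1.0,
        source_band=1.5,
        couplings=[{"target": "phi", "k1": 1.0, "b1": 1.0}],
    ),
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a named preset."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    d = dict(PRESETS[name])
    d.update(overrides)
    return SimulationConfig(**d)


# ---------------------------------------------------------------------------
# main loop


@dataclass
class RunResult:
    """Artifacts of one simulation run."""

    config: SimulationConfig
    initial_mesh: TissueMesh
    mesh: TissueMesh
    timeseries: pd.DataFrame
    events: list
    regime: RegimeLabel
    termination: str  # reached_target | step_limit | unstable
    concentrations: np.ndarray | None = None
    coeffs: ElasticCoeffs | None = None


def _pn_stationary(records, tol: float, window: int) -> bool:
    if len(records) < window:
        return False
    tail = records[-window:]
    for k in (4, 5, 6, 7, 8):
        vals = [r.P.get(k, 0.0) for r in tail]
        if max(vals) - min(vals) >= tol:
            return False
    return True


def run_simulation(config: SimulationConfig) -> RunResult:
    """Run the coupled chemo-mechanical loop until a stop criterion fires.

    Fully reproducible from ``(config, seed)``: a single RNG stream is
    consumed only by the division round (one uniform per cell per step, in
    cell-id order).
    """
    rng = np.random.default_rng(config.seed)
    mesh = config.initial_mesh()
    initial_mesh = mesh.copy()
    ref = config.reference()
    dyn = config.dynamics()
    div = config.division()
    intc = config.intercalation()
    chem = config.chemistry()
    specs = config.coupling_specs()

    n = mesh.n_cells
    coeffs = ElasticCoeffs.uniform(n, config.eta, config.mu, config.sigma, config.phi)
    conc = init_concentrations(n, config.n_species)
    # chemistry is inert while every concentration is zero and no source runs
    chem_active = chem.source is not None

    events: list[dict] = []
    records = [sample_record(mesh, coeffs, ref, 0.0)]
    termination = "step_limit"
    unstable = False

    for step in range(1, config.max_steps + 1):
        t = step * config.dt
        try:
            geom = mesh.compute_geometry()
            step_mechanics(
                mesh, coeffs, ref, dyn, geom, max_step_frac=config.max_step_frac
            )

            if chem_active:
                conc = step_chemistry(mesh, conc, chem, dyn.dt)
                if specs:
                    apply_coupling(conc, specs, coeffs)

            if div.p0 > 0:
                new_events = attempt_divisions(mesh, div, rng, time=t)
                for ev in new_events:
                    conc = np.vstack([conc, conc[ev["cell"]][None, :]])
                    coeffs.append_copy(ev["cell"])
                events.extend(new_events)

            t1_events = attempt_intercalations(mesh, intc, time=t)
            events.extend(t1_events)

            if config.repair_min_edge > 0:
                events.extend(
                    repair_short_edges(
                        mesh, config.repair_min_edge * config.l0, time=t
                    )
                )
        except StructuralInstabilityError as exc:
            log.warning("run went unstable at step %d: %s", step, exc)
            unstable = True
            termination = "unstable"
            break

        if step % config.sample_every == 0:
            g = mesh.compute_geometry()
            if not np.all(np.isfinite(g.area)) or np.any(g.area <= 0):
                log.warning("degenerate cell areas at step %d", step)
                unstable = True
                termination = "unstable"
                break
            records.append(sample_record(mesh, coeffs, ref, t, g))
            log.debug(
                "t=%.2f N=%d U/N=%.4f", t, records[-1].N, records[-1].U_per_N
            )
            if mesh.n_cells >= config.max_cells and (
                config.steady_pn_tol is None
                or _pn_stationary(records, config.steady_pn_tol, config.steady_window)
            ):
                termination = "reached_target"
                break

    if not unstable:
        report = mmod.mesh_integrity(mesh)
        if not report.valid:
            unstable = True
            termination = "unstable"
    records.append(sample_record(mesh, coeffs, ref, (step if records else 0) * config.dt))
    tail = records[max(0, int(len(records) * 0.8)):]
    u_tail = float(np.mean([r.U_per_N for r in tail]))
    refline = float(np.mean(coeffs.mu)) * (6.0 * ref.l0) ** 2
    regime = classify_regime(
        mesh,
        ref,
        integrity_ok=not unstable,
        u_per_n=u_tail,
        reference_line=refline,
    )
    return RunResult(
        config=config,
        initial_mesh=initial_mesh,
        mesh=mesh,
        timeseries=records_to_frame(records),
        events=events,
        regime=regime,
        termination=termination,
        concentrations=conc,
        coeffs=coeffs,
    )


# ---------------------------------------------------------------------------
# artifact output


def write_run_artifacts(result: RunResult, outdir) -> None:
    """Write timeseries.csv, events.jsonl, final/initial snapshots and
    fields.csv into ``outdir``."""
    import os

    from .observables import fields_dataframe

    os.makedirs(outdir, exist_ok=True)
    result.timeseries.to_csv(os.path.join(outdir, "timeseries.csv"), index=False)
    with open(os.path.join(outdir, "events.jsonl"), "w") as fh:
        for ev in result.events:
            fh.write(json.dumps(ev) + "\n")
    phash = result.config.params_hash()
    mmod.save_snapshot(
        os.path.join(outdir, "initial.json"),
        result.initial_mesh,
        time=0.0,
        params_hash=phash,
    )
    per_cell = None
    if result.coeffs is not None:
        per_cell = {
            "eta": result.coeffs.eta,
            "mu": result.coeffs.mu,
            "sigma": result.coeffs.sigma,
            "phi": result.coeffs.phi,
        }
    t_final = float(result.timeseries["t"].iloc[-1])
    mmod.save_snapshot(
        os.path.join(outdir, "final.json"),
        result.mesh,
        time=t_final,
        params_hash=phash,
        concentrations=result.concentrations,
        per_cell_coeffs=per_cell,
    )
    fields_dataframe(
        result.mesh, result.coeffs, result.config.reference(), result.concentrations
    ).to_csv(os.path.join(outdir, "fields.csv"), index=False)
    save_config(result.config, os.path.join(outdir, "config.json"))
    with open(os.path.join(outdir, "run.json"), "w") as fh:
        json.dump(
            {
                "regime": result.regime.label,
                "scores": result.regime.scores,
                "termination": result.termination,
                "n_cells": result.mesh.n_cells,
                "n_events": len(result.events),
            },
            fh,
            indent=2,
        )
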