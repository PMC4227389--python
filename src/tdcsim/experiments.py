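"""Packaged, config-driven experiments on the 2D five-tissue phantom.

Two experiment families ship with the package:

* ``ap-conduction`` — no electrodes; an action potential is initiated in a
  2.5 mm radius disc at (0, -25) mm by an applied current during the first
  10 ms, and propagates through the brain for 100 ms.  Used to measure
  conduction velocity and the (small) electric potential an AP projects to
  the scalp.
* ``tdcs-1`` / ``tdcs-2`` — 10 mm electrodes carrying 1.0 mA for 100 ms,
  no applied current; a matching stationary volume-conductor (Laplace)
  solve is run automatically and compared against the coupled model.

Electrode configuration 1 places the anode at (-100, 0) mm and the cathode
at (70.7, 70.7) mm; configuration 2 the anode at (-70.7, 70.7) mm and the
cathode at (0, -100) mm.

Every spec is fully serializable (YAML) and constructible offline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .assembly import DEFAULT_EXTRACELLULAR, DEFAULT_INTRACELLULAR, build_conductivity
from .cell_model import FHNParams
from .laplace_ref import compare_fields, solve_laplace
from .mesh import ElectrodeKind, Tissue, build_annulus_phantom, place_electrode
from .postprocess import (
    ap_sensitivity,
    conduction_velocity,
    current_density,
    electric_field,
    export_probes_csv,
    export_vtk,
)
from .solver import ProbeSpec, SolverConfig, StimulusDisc, run_simulation

__all__ = [
    "ExperimentSpec",
    "experiment_ap_conduction",
    "experiment_tdcs",
    "run_experiment",
    "builtin_experiments",
    "DEFAULT_STIMULUS_AMPLITUDE",
]

#: Applied-current amplitude (V/s) used to initiate an action potential.
#: This package's own calibration: the smallest round (1-2-5 series) value
#: that reliably ignites the tissue surrounding the stimulus disc, so that
#: both default conduction-velocity probes register threshold crossings, at
#: both the default and the quarter-scale mesh resolution.
DEFAULT_STIMULUS_AMPLITUDE = 100.0


@dataclass(frozen=True)
class ElectrodeSpec:
    kind: str                 # 'anode' | 'cathode'
    center_angle_deg: float   # position on the outer circle
    arc_length: float = 0.010  # m
    total_current: float = 0.0  # A (per meter depth)


@dataclass(frozen=True)
class StimulusSpec:
    center: tuple[float, float] = (0.0, -0.025)  # m
    radius: float = 0.0025                       # m
    t_on: float = 0.0                            # s
    t_off: float = 0.010                         # s
    amplitude: float = DEFAULT_STIMULUS_AMPLITUDE  # V/s


@dataclass(frozen=True)
class ExperimentSpec:
    """A complete, serializable description of one phantom experiment."""

    name: str
    radii: tuple[float, ...] = (0.040, 0.050, 0.070, 0.090, 0.100)
    csf_strip_width: float = 0.010
    target_elements: int = 10_000
    conductivities: dict = field(
        default_factory=lambda: {t.name: v for t, v in DEFAULT_EXTRACELLULAR.items()}
    )
    intra_sigma: float = DEFAULT_INTRACELLULAR
    electrodes: tuple[ElectrodeSpec, ...] = ()
    stimulus: StimulusSpec | None = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    probes: tuple[ProbeSpec, ...] = ()
    snapshot_times: tuple[float, ...] = ()
    compare_laplace: bool = False

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["solver"] = asdict(self.solver)
        d["electrodes"] = [asdict(e) for e in self.electrodes]
        d["stimulus"] = asdict(self.stimulus) if self.stimulus else None
        d["probes"] = [asdict(p) for p in self.probes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        d = dict(d)
        missing = {"name", "radii"} - set(d)
        if missing:
            raise ValueError(f"experiment spec missing fields: {sorted(missing)}")
        d["radii"] = tuple(d["radii"])
        d["solver"] = SolverConfig(**d.get("solver", {}))
        d["electrodes"] = tuple(
            ElectrodeSpec(**e) for e in d.get("electrodes", []) or []
        )
        stim = d.get("stimulus")
        if stim is not None:
            stim = dict(stim)
            stim["center"] = tuple(stim["center"])
            stim = StimulusSpec(**stim)
        d["stimulus"] = stim
        d["probes"] = tuple(
            ProbeSpec(name=p["name"], location=tuple(p["location"]),
                      quantity=p.get("quantity", "v"))
            for p in d.get("probes", []) or []
        )
        d["snapshot_times"] = tuple(d.get("snapshot_times", ()))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def experiment_ap_conduction() -> ExperimentSpec:
    """AP-conduction experiment: stimulus disc, no electrodes, 100 ms.

    Probes: two membrane-voltage probes on the vertical axis 5 and 10 mm
    below the stimulus center (along the propagation direction, inside the
    brain, away from the CSF strip and outside the stimulated disc), used
    for the conduction-velocity measurement; plus electric-potential probes
    at the domain center and the four boundary points on the Cartesian
    axes.  Note the CSF strip severs the intracellular domain, so the wave
    cannot cross from the lower to the upper brain half; velocity probes
    must sit on the stimulated side.
    """
    probes = (
        ProbeSpec("cv-a", (0.0, -0.030), "v"),
        ProbeSpec("cv-b", (0.0, -0.035), "v"),
        ProbeSpec("phi-center", (0.0, 0.0), "phi"),
        ProbeSpec("phi-east", (0.100, 0.0), "phi"),
        ProbeSpec("phi-west", (-0.100, 0.0), "phi"),
        ProbeSpec("phi-north", (0.0, 0.100), "phi"),
        ProbeSpec("phi-south", (0.0, -0.100), "phi"),
    )
    return ExperimentSpec(
        name="ap-conduction",
        stimulus=StimulusSpec(),
        probes=probes,
        snapshot_times=(0.001, 0.010, 0.046, 0.100),
    )


def experiment_tdcs(config_id: int) -> ExperimentSpec:
    """tDCS experiment with 10 mm, 1.0 mA electrodes; no applied current.

    ``config_id`` 1: anode at angle 180 deg, cathode at 45 deg.
    ``config_id`` 2: anode at 135 deg, cathode at -90 deg.
    """
    if config_id == 1:
        anode_deg, cathode_deg = 180.0, 45.0
    elif config_id == 2:
        anode_deg, cathode_deg = 135.0, -90.0
    else:
        raise ValueError(f"unknown tDCS configuration {config_id!r} (use 1 or 2)")
    electrodes = (
        ElectrodeSpec("anode", anode_deg, 0.010, 1.0e-3),
        ElectrodeSpec("cathode", cathode_deg, 0.010, 0.0),
    )
    probes = (
        ProbeSpec("phi-center", (0.0, 0.0), "phi"),
        ProbeSpec("v-center", (0.0, -0.020), "v"),
    )
    return ExperimentSpec(
        name=f"tdcs-{config_id}",
        electrodes=electrodes,
        probes=probes,
        snapshot_times=(0.001, 0.025, 0.100),
        compare_laplace=True,
    )


def builtin_experiments() -> dict[str, ExperimentSpec]:
    return {
        "ap-conduction": experiment_ap_conduction(),
        "tdcs-1": experiment_tdcs(1),
        "tdcs-2": experiment_tdcs(2),
    }


def run_experiment(
    spec: ExperimentSpec,
    outdir: str | Path | None = None,
    scale: float = 1.0,
    t_end: float | None = None,
):
    """Run one experiment and return (result, summary dict).

    ``scale`` scales the mesh target element count (e.g. 0.25 for a quick
    check); ``t_end`` optionally overrides the simulated duration.  With
    ``outdir`` set, the spec copy, VTK snapshots, probe CSV and summary
    JSON are written there.
    """
    target = int(round(spec.target_elements * scale))
    mesh = build_annulus_phantom(
        radii=spec.radii,
        csf_strip_width=spec.csf_strip_width,
        target_element_count=target,
    )
    table = {Tissue[k]: float(v) for k, v in spec.conductivities.items()}
    cond = build_conductivity(mesh, table, spec.intra_sigma)
    electrodes = [
        place_electrode(
            mesh,
            ElectrodeKind(e.kind),
            np.deg2rad(e.center_angle_deg),
            e.arc_length,
            e.total_current,
        )
        for e in spec.electrodes
    ]
    stim = None
    if spec.stimulus is not None:
        s = spec.stimulus
        stim = StimulusDisc(s.center, s.radius, s.t_on, s.t_off, s.amplitude)
    solver_cfg = spec.solver if t_end is None else replace(spec.solver, t_end=t_end)
    params = FHNParams()

    result = run_simulation(
        mesh,
        electrodes or None,
        cell_params=params,
        config=solver_cfg,
        probes=list(spec.probes),
        stimulus=stim,
        conductivity=cond,
        snapshot_times=spec.snapshot_times,
    )

    summary: dict = {
        "name": spec.name,
        "n_elements": mesh.n_elements,
        "n_nodes": mesh.n_nodes,
        "t_end": solver_cfg.t_end,
        "cg_iterations_mean": float(np.mean(result.cg_iterations))
        if result.cg_iterations else 0.0,
    }

    if "cv-a" in result.traces and "cv-b" in result.traces:
        try:
            summary["conduction_velocity_m_per_s"] = conduction_velocity(
                result.traces["cv-a"], result.traces["cv-b"], params
            )
        except ValueError as exc:
            summary["conduction_velocity_m_per_s"] = None
            summary["conduction_velocity_error"] = str(exc)

    phi = result.state.phi
    summary["phi_max_V"] = float(phi.max())
    summary["phi_min_V"] = float(phi.min())
    sens = ap_sensitivity(result.state.cell.v, params)
    summary["ap_sensitivity_max_pct"] = float(sens.max())

    if spec.compare_laplace and electrodes:
        anode = next(e for e in electrodes if e.kind is ElectrodeKind.ANODE)
        cathode = next(e for e in electrodes if e.kind is ElectrodeKind.CATHODE)
        phi_lap = solve_laplace(mesh, cond, anode, cathode,
                                rel_tol=solver_cfg.cg_rel_tol,
                                omega=solver_cfg.ilu_relaxation)
        summary["laplace_rel_l2_final"] = compare_fields(mesh, phi, phi_lap)
        for ts, snap in result.snapshots.items():
            summary[f"laplace_rel_l2_t{ts * 1e3:g}ms"] = compare_fields(
                mesh, snap["phi"], phi_lap
            )
    else:
        phi_lap = None

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spec.to_yaml(outdir / "config.yaml")
        export_probes_csv(result.traces.values(), outdir / "probes.csv")
        E = electric_field(mesh, phi)
        J = current_density(E, cond.sigma_e)
        fields = {
            "phi": phi,
            "E": E,
            "J_magnitude": np.linalg.norm(J, axis=1),
            "v": result.state.cell.v,
            "sensitivity": sens,
        }
        if phi_lap is not None:
            fields["phi_laplace"] = phi_lap
        export_vtk(mesh, fields, outdir / f"{spec.name}_final.vtk")
        for ts, snap in result.snapshots.items():
            export_vtk(
                mesh,
                {"phi": snap["phi"], "v": snap["v"]},
                outdir / f"{spec.name}_t{ts * 1e3:g}ms.vtk",
            )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)

    return result, summary
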