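"""End-to-end runs: mesh -> electrodynamics -> flow -> cupula -> SPV.

A :class:`RunConfig` captures every knob of a run; :func:`run_pipeline`
executes the chain for both labyrinths and returns the stimulus set, SPV
record and plateau times together with a :class:`RunManifest` describing the
stages, wall times, seeds and (when an output directory is given) the hashes
of every file written.

The absolute scale of the electrical drive is the model's one free constant
(the underlying boundary-condition data are not published).  With
``drive="auto"`` the total dark-cell current is calibrated once so that the
supine 7 T run reaches a peak utricular endolymph speed of
``calibration_speed_m_s`` (default 134 um/s, the headline utricular vortex
speed); normalized outputs do not depend on this choice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .cupula import (
    ConvergenceCriterion,
    CristaStimulusSet,
    CupulaParams,
    assemble_stimuli,
    plateau_time,
    steady_strain,
)
from .electrodynamics import (
    BoundaryConditionSet,
    ConductivityMap,
    FieldSolution,
    current_and_force,
    solve_potential,
)
from .flow import FluidParams, FlowSolution, solve_flow, regional_speed_summary
from .geometry import (
    CANALS,
    REGION_ID,
    HeadOrientation,
    LabyrinthConfig,
    LabyrinthGeometry,
    build_labyrinth,
    mirror_labyrinth,
    orient,
)
from .vor import SPVRecord, spv_from_cristae

__all__ = [
    "RunConfig",
    "RunManifest",
    "PipelineResult",
    "run_pipeline",
    "validate_config",
    "config_to_dict",
    "config_from_dict",
    "calibrate_drive",
    "b_field_series_physics",
    "sweep_orientation_physics",
]


@dataclass(frozen=True)
class RunConfig:
    geometry: LabyrinthConfig = field(default_factory=LabyrinthConfig)
    conductivity: ConductivityMap = field(default_factory=ConductivityMap)
    hair_potential_v: float = 0.01
    drive_mode: str = "neumann_current"
    drive_total_current_a: float | str = "auto"
    calibration_speed_m_s: float = 1.34e-4
    fluid: FluidParams = field(default_factory=FluidParams)
    cupula: CupulaParams = field(default_factory=CupulaParams)
    criterion: ConvergenceCriterion = field(default_factory=ConvergenceCriterion)
    orientation: HeadOrientation = field(default_factory=HeadOrientation)
    B_magnitude: float = 7.0
    B_axis_sign: str = "head_to_feet"
    seed: int = 0

    def cupula_params(self) -> CupulaParams:
        """Cupula plate dimensions follow the geometry unless overridden."""
        return dataclasses.replace(
            self.cupula,
            radius_m=self.geometry.ampulla_radius_mm * 1e-3,
            thickness_m=self.geometry.cupula_thickness_mm * 1e-3,
        )


# -- config (de)serialization -------------------------------------------------

_TUPLE_FIELDS = {
    "utricle_semiaxes_mm",
    "ampulla_arc_rad",
    "common_crus_arc_rad",
    "macula_x_frac",
    "spv_deg_s",
    "baseline_drift_deg_s",
}


def config_to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)


def _retuple(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = _retuple(v)
        elif k in _TUPLE_FIELDS and isinstance(v, list):
            out[k] = tuple(v)
        else:
            out[k] = v
    return out


def config_from_dict(d: dict) -> RunConfig:
    d = _retuple(dict(d))
    return RunConfig(
        geometry=LabyrinthConfig(**d.get("geometry", {})),
        conductivity=ConductivityMap(**d.get("conductivity", {})),
        hair_potential_v=d.get("hair_potential_v", 0.01),
        drive_mode=d.get("drive_mode", "neumann_current"),
        drive_total_current_a=d.get("drive_total_current_a", "auto"),
        calibration_speed_m_s=d.get("calibration_speed_m_s", 1.34e-4),
        fluid=FluidParams(**d.get("fluid", {})),
        cupula=CupulaParams(**d.get("cupula", {})),
        criterion=ConvergenceCriterion(**d.get("criterion", {})),
        orientation=HeadOrientation(**d.get("orientation", {})),
        B_magnitude=d.get("B_magnitude", 7.0),
        B_axis_sign=d.get("B_axis_sign", "head_to_feet"),
        seed=d.get("seed", 0),
    )


def validate_config(source) -> list:
    """Schema/sanity diagnostics for a config file or dict.

    Returns a list of (level, field, message); level "error" marks values a
    run would reject, "warning" marks unknown keys (kept for forward
    compatibility).
    """
    from .io import load_yaml

    if isinstance(source, dict):
        d = source
    else:
        d = load_yaml(source)
        if d is None:
            return [("error", "", "config file is empty or unreadable")]
    diags = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in d:
        if key not in known:
            diags.append(("warning", key, "unknown configuration key (ignored)"))
    clean = {k: v for k, v in d.items() if k in known}
    try:
        cfg = config_from_dict(clean)
    except (TypeError, ValueError) as exc:
        return diags + [("error", "", f"config does not parse: {exc}")]
    checks = [
        (cfg.geometry.validate, "geometry"),
        (cfg.conductivity.validate, "conductivity"),
        (cfg.fluid.validate, "fluid"),
        (cfg.cupula_params().validate, "cupula"),
        (cfg.criterion.validate, "criterion"),
    ]
    for fn, name in checks:
        try:
            fn()
        except ValueError as exc:
            diags.append(("error", name, str(exc)))
    if cfg.B_magnitude < 0:
        diags.append(("error", "B_magnitude", "field magnitude must be >= 0 tesla"))
    if not (0 < cfg.B_magnitude <= 20) and cfg.B_magnitude != 0:
        diags.append(("warning", "B_magnitude", f"{cfg.B_magnitude} T is outside clinical range"))
    if cfg.B_axis_sign not in ("head_to_feet", "feet_to_head"):
        diags.append(("error", "B_axis_sign", f"unknown value {cfg.B_axis_sign!r}"))
    if cfg.drive_total_current_a != "auto" and not (
        isinstance(cfg.drive_total_current_a, (int, float))
        and np.isfinite(cfg.drive_total_current_a)
    ):
        diags.append(("error", "drive_total_current_a", "must be 'auto' or a finite number"))
    return diags


# -- manifest -----------------------------------------------------------------

@dataclass
class StageRecord:
    name: str
    wall_time_s: float
    outputs: dict = field(default_factory=dict)   # filename -> sha256
    status: str = "completed"
    message: str = ""


@dataclass
class RunManifest:
    stages: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "stages": [asdict(s) for s in self.stages],
            "seeds": self.seeds,
        }


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    config: RunConfig
    drive_current_a: float
    geometries: dict                 # side -> LabyrinthGeometry (oriented)
    fields: dict                     # side -> FieldSolution
    flows: dict                      # side -> FlowSolution
    strains: dict                    # side -> {canal: signed utriculopetal strain}
    stimuli: CristaStimulusSet
    spv: SPVRecord
    plateau_s: float                 # plateau time of the largest crista response
    plateau_per_crista: dict
    speed_summary: dict
    manifest: RunManifest = None


# -- calibration ---------------------------------------------------------------

def _solve_side(geom0, cfg: RunConfig, B_magnitude, B_axis_sign, orientation, drive):
    geom, B = orient(geom0, orientation, B_magnitude, B_axis_sign)
    bc = BoundaryConditionSet(
        hair_potential_v=cfg.hair_potential_v,
        drive_mode=cfg.drive_mode,
        total_current_a=drive,
    )
    sol = solve_potential(geom, cfg.conductivity, bc)
    sol = current_and_force(sol, B)
    flow = solve_flow(geom, sol.f_l, cfg.fluid)
    return geom, sol, flow


def calibrate_drive(cfg: RunConfig, _reuse=None) -> float:
    """Total dark-cell current (A) that attains the calibration speed in the
    supine 7 T reference run (unit-drive solve, exact linear rescale)."""
    if _reuse is not None:
        flow = _reuse
    else:
        geom0 = build_labyrinth(cfg.geometry)
        _, _, flow = _solve_side(
            geom0, cfg, 7.0, "head_to_feet", HeadOrientation(), drive=1.0
        )
    peak = regional_speed_summary(flow)["utricle"]
    if peak <= 0:
        raise ValueError("calibration run produced no flow; check the drive configuration")
    return cfg.calibration_speed_m_s / peak


# -- main chain -----------------------------------------------------------------

def _effective_dp(flow: FlowSolution, sol: FieldSolution, canal: str, cfg: RunConfig) -> float:
    """Transcupular pressure plus the direct Lorentz load on the cupula volume."""
    geom = flow.geom
    dp = flow.transcupular_dp[canal]
    cells = geom.region_cells(f"cupula_{canal}")
    if len(cells):
        vols = np.abs(geom.mesh.volumes()[cells])
        f_mean = (sol.f_l[cells] * vols[:, None]).sum(axis=0) / vols.sum()
        u = geom.crista_frames[canal]["utriculopetal"]
        dp = dp + float(f_mean @ u) * cfg.geometry.cupula_thickness_mm * 1e-3
    return dp


def run_pipeline(cfg: RunConfig = RunConfig(), outdir=None) -> PipelineResult:
    """Run the full chain for both labyrinths under one head orientation."""
    manifest = RunManifest(seeds={"run": cfg.seed})
    outputs_dir = None
    if outdir is not None:
        import pathlib

        outputs_dir = pathlib.Path(outdir)
        outputs_dir.mkdir(parents=True, exist_ok=True)

    def record(name, t0, files=(), status="completed", message=""):
        outputs = {}
        for f in files:
            outputs[str(f.name)] = _hash_file(f)
        manifest.stages.append(
            StageRecord(name, time.perf_counter() - t0, outputs, status, message)
        )

    # stage 1: mesh
    t0 = time.perf_counter()
    left0 = build_labyrinth(cfg.geometry)
    right0 = mirror_labyrinth(left0)
    files = []
    if outputs_dir is not None:
        from .io import write_vtk_unstructured, write_vtk_surface, save_yaml

        save_yaml(config_to_dict(cfg), outputs_dir / "config.yaml")
        f = outputs_dir / "labyrinth_left.vtk"
        write_vtk_unstructured(
            f,
            left0.mesh.vertices,
            left0.mesh.cells,
            cell_data={"region": left0.cell_region, "zone": left0.cell_zone},
        )
        fs = outputs_dir / "labyrinth_left_surface.vtk"
        write_vtk_surface(fs, left0.mesh.vertices, left0.boundary_faces, {"patch": left0.face_patch})
        files = [outputs_dir / "config.yaml", f, fs]
    record("mesh", t0, files)

    # stage 2: electrodynamics (unit drive, then exact rescale)
    t0 = time.perf_counter()
    geoms, sols, flows = {}, {}, {}
    geoms["left"], sols["left"], flows["left"] = _solve_side(
        left0, cfg, cfg.B_magnitude, cfg.B_axis_sign, cfg.orientation, drive=1.0
    )
    supine_reference = (
        cfg.B_magnitude == 7.0
        and cfg.B_axis_sign == "head_to_feet"
        and cfg.orientation == HeadOrientation()
    )
    if cfg.drive_total_current_a == "auto":
        if supine_reference and cfg.B_magnitude > 0:
            drive = calibrate_drive(cfg, _reuse=flows["left"])
        else:
            drive = calibrate_drive(cfg)
    else:
        drive = float(cfg.drive_total_current_a)
    record("electrodynamics", t0)

    # stage 3: flow (rescale the left unit solve; solve the right side)
    t0 = time.perf_counter()
    sols["left"].scale_drive(drive)
    fl = flows["left"]
    fl.v = fl.v * drive
    fl.p = fl.p * drive
    fl.canal_fluxes = {k: [x * drive for x in v] for k, v in fl.canal_fluxes.items()}
    fl.transcupular_dp = {k: v * drive for k, v in fl.transcupular_dp.items()}
    geoms["right"], sols["right"], flows["right"] = _solve_side(
        right0, cfg, cfg.B_magnitude, cfg.B_axis_sign, cfg.orientation, drive=drive
    )
    speed_summary = regional_speed_summary(flows["left"])
    record("flow", t0)

    # stage 4: cupula strains
    t0 = time.perf_counter()
    params = cfg.cupula_params()
    strains = {}
    for side in ("left", "right"):
        strains[side] = {
            c: steady_strain(_effective_dp(flows[side], sols[side], c, cfg), params)
            for c in CANALS
        }
    stimuli = assemble_stimuli(strains["left"], strains["right"])
    plateau_per = {
        f"{side[0].upper()}{c}": plateau_time(strains[side][c], params, cfg.criterion)
        for side in ("left", "right")
        for c in CANALS
    }
    plateau = max(plateau_per.values())
    record("cupula", t0)

    # stage 5: SPV
    t0 = time.perf_counter()
    spv = spv_from_cristae(stimuli)
    spv.B_magnitude = cfg.B_magnitude
    spv.B_axis_sign = cfg.B_axis_sign
    files = []
    if outputs_dir is not None:
        from .io import save_json

        summary = {
            "drive_current_a": drive,
            "strains": strains,
            "stimuli": stimuli.as_dict(),
            "spv": {"hor": spv.spv_hor, "ver": spv.spv_ver, "tor": spv.spv_tor},
            "plateau_s": plateau,
            "plateau_per_crista": plateau_per,
            "transcupular_dp_pa": {s: flows[s].transcupular_dp for s in flows},
            "speed_summary_m_s": speed_summary,
        }
        f = outputs_dir / "summary.json"
        save_json(summary, f)
        files = [f]
    record("spv", t0, files)

    if outputs_dir is not None:
        from .io import save_json

        save_json(manifest.as_dict(), outputs_dir / "manifest.json")

    return PipelineResult(
        config=cfg,
        drive_current_a=drive,
        geometries=geoms,
        fields=sols,
        flows=flows,
        strains=strains,
        stimuli=stimuli,
        spv=spv,
        plateau_s=plateau,
        plateau_per_crista=plateau_per,
        speed_summary=speed_summary,
        manifest=manifest,
    )


# -- series and sweeps -----------------------------------------------------------

def b_field_series_physics(B_list, cfg: RunConfig = RunConfig()) -> list[SPVRecord]:
    """One full-physics SPV record per field strength (shared factorization).

    The current density is independent of B, so both labyrinths are solved
    once per field value with the force field J x B; by Stokes linearity the
    records scale exactly with B.
    """
    B_list = list(B_list)
    if any(b <= 0 for b in B_list):
        raise ValueError("B values must be positive")
    left0 = build_labyrinth(cfg.geometry)
    right0 = mirror_labyrinth(left0)
    drive = (
        calibrate_drive(cfg) if cfg.drive_total_current_a == "auto"
        else float(cfg.drive_total_current_a)
    )
    params = cfg.cupula_params()
    per_side = {}
    for side, g0 in (("left", left0), ("right", right0)):
        geom, Bvec = orient(g0, cfg.orientation, 1.0, cfg.B_axis_sign)
        bc = BoundaryConditionSet(
            hair_potential_v=cfg.hair_potential_v,
            drive_mode=cfg.drive_mode,
            total_current_a=drive,
        )
        sol = current_and_force(solve_potential(geom, cfg.conductivity, bc), Bvec)
        forces = [sol.f_l * (b / 1.0) for b in B_list]
        flows = solve_flow(geom, forces, cfg.fluid)
        per_side[side] = [
            {c: steady_strain(_effective_dp(flow, sol, c, cfg), params) for c in CANALS}
            for flow in flows
        ]
        # note: _effective_dp uses sol.f_l at 1 T for the direct load; rescale
        for k, b in enumerate(B_list):
            base = {
                c: steady_strain(flows[k].transcupular_dp[c], params) for c in CANALS
            }
            extra = {c: per_side[side][k][c] - base[c] for c in CANALS}
            per_side[side][k] = {c: base[c] + extra[c] * b for c in CANALS}
    records = []
    for k, b in enumerate(B_list):
        stim = assemble_stimuli(per_side["left"][k], per_side["right"][k])
        rec = spv_from_cristae(stim)
        rec.B_magnitude = b
        rec.B_axis_sign = cfg.B_axis_sign
        records.append(rec)
    return records


def sweep_orientation_physics(axis: str, angles_deg, cfg: RunConfig = RunConfig()):
    """Full-physics orientation sweep (expensive: one run per angle)."""
    records = []
    for th in angles_deg:
        if axis.upper() == "ETS":
            head = dataclasses.replace(cfg.orientation, ets_deg=float(th))
        elif axis.upper() == "FE":
            head = dataclasses.replace(cfg.orientation, fe_deg=float(th))
        else:
            raise ValueError(f"unknown sweep axis {axis!r}")
        res = run_pipeline(dataclasses.replace(cfg, orientation=head))
        rec = res.spv
        rec.angle_deg = float(th)
        rec.axis = axis.upper()
        records.append(rec)
    return records
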