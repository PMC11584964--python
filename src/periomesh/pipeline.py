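"""End-to-end orchestration: simulate, align, section, measure, summarize.

The pipeline is declarative: a :class:`PipelineConfig` lists the per-tooth
case records (scan paths, label sidecars, sectioning azimuth, optional crop)
plus ICP parameters and a seed; :func:`run_pipeline` processes each tooth
independently — a failing tooth is recorded as unmeasurable and does not
affect the rest — and writes per-tooth audit records plus cohort tables.

:func:`measure_pair` is the in-memory core used by both the file-based
pipeline and the test/acceptance suites:

1. crown-restricted best fit of the re-evaluation mesh onto baseline,
2. one tooth frame estimated on baseline and shared by both sections,
3. plane sections of both meshes,
4. the P1/P2/P3 margin construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import CohortSummary, summarize_cohort
from .cross_section import SectionPolyline, estimate_tooth_frame, section_mesh
from .errors import ConfigError, PeriomeshError
from .margin_metrics import MarginMeasurement, measure_tooth
from .mesh_model import LabeledMesh, crop_region, load_labeled, write_stl
from .superimpose import AlignmentReport, icp_crown
from .synthetic_scan import (
    PhantomSpec,
    generate_cohort_chart,
    generate_phantom_pair,
    read_chart_csv,
    write_chart_csv,
)
from .superimpose import RigidTransform

MEASUREMENT_COLUMNS = [
    "patient_id", "tooth_id", "height_loss", "width_loss",
    "height_loss_axial", "width_loss_signed", "status",
    "rms_residual", "n_iterations", "converged",
]


# ---------------------------------------------------------------------------
# in-memory core
# ---------------------------------------------------------------------------

def measure_pair(
    mesh0: LabeledMesh,
    mesh1: LabeledMesh,
    azimuth_hint=None,
    max_iter: int = 100,
    tol: float = 1e-6,
    trim_fraction: float = 0.10,
    side: str = "positive",
    tooth_id: str = "",
    patient_id: str = "",
) -> tuple[MarginMeasurement, AlignmentReport, SectionPolyline, SectionPolyline]:
    """Align mesh1 onto mesh0, cut both with one plane, measure the margin."""
    report = icp_crown(mesh1, mesh0, max_iter=max_iter, tol=tol,
                       trim_fraction=trim_fraction)
    aligned = mesh1.transformed(report.transform.rotation,
                                report.transform.translation)
    frame = estimate_tooth_frame(mesh0, azimuth_hint=azimuth_hint)
    s0 = section_mesh(mesh0, frame)
    s1 = section_mesh(aligned, frame)
    measurement = measure_tooth(s0, s1, tooth_id=tooth_id,
                                patient_id=patient_id, side=side)
    return measurement, report, s0, s1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CaseSpec:
    """One tooth's inputs: scan pair, sidecars, sectioning azimuth, crop."""

    patient_id: str
    tooth_id: str
    stl0: str
    stl1: str
    labels0: str | None = None
    labels1: str | None = None
    azimuth: tuple = (1.0, 0.0, 0.0)
    crop_seed: tuple | None = None
    crop_radius: float | None = None


@dataclass
class PipelineConfig:
    """Declarative pipeline run description (one file, not flags per tooth)."""

    cases: list = field(default_factory=list)
    chart: str | None = None
    icp_max_iter: int = 100
    icp_tol: float = 1e-6
    trim_fraction: float = 0.10
    side: str = "positive"
    seed: int = 0
    strict: bool = False
    out_dir: str | None = None

    def validate(self) -> None:
        for case in self.cases:
            for attr in ("stl0", "stl1"):
                p = Path(getattr(case, attr))
                if not p.exists():
                    raise ConfigError(f"case {case.patient_id}/{case.tooth_id}: "
                                      f"missing file {p}")
            if case.crop_radius is not None and case.crop_radius <= 0:
                raise ConfigError("crop radius must be > 0")
        if self.chart is not None and not Path(self.chart).exists():
            raise ConfigError(f"missing chart file {self.chart}")
        if not 0 <= self.trim_fraction < 0.5:
            raise ConfigError("trim_fraction must be in [0, 0.5)")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cases = []
        for c in d.get("cases", []):
            c = dict(c)
            c["azimuth"] = tuple(c.get("azimuth", (1.0, 0.0, 0.0)))
            if c.get("crop_seed") is not None:
                c["crop_seed"] = tuple(c["crop_seed"])
            cases.append(CaseSpec(**c))
        d["cases"] = cases
        return cls(**d)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    measurements: pd.DataFrame
    summary: CohortSummary
    audits: list = field(default_factory=list)
    n_failed: int = 0


def _measure_case(case: CaseSpec, config: PipelineConfig) -> tuple[dict, dict]:
    mesh0 = load_labeled(case.stl0, case.labels0, frame_id="STL0")
    mesh1 = load_labeled(case.stl1, case.labels1, frame_id="STL1")
    if case.crop_seed is not None and case.crop_radius is not None:
        mesh0 = crop_region(mesh0, case.crop_seed, case.crop_radius)
        mesh1 = crop_region(mesh1, case.crop_seed, case.crop_radius)
    m, rep, s0, s1 = measure_pair(
        mesh0, mesh1,
        azimuth_hint=np.asarray(case.azimuth, dtype=np.float64),
        max_iter=config.icp_max_iter,
        tol=config.icp_tol,
        trim_fraction=config.trim_fraction,
        side=config.side,
        tooth_id=case.tooth_id,
        patient_id=case.patient_id,
    )
    row = {
        "patient_id": case.patient_id,
        "tooth_id": case.tooth_id,
        "height_loss": m.height_loss,
        "width_loss": m.width_loss,
        "height_loss_axial": m.height_loss_axial,
        "width_loss_signed": m.width_loss_signed,
        "status": "ok",
        "rms_residual": rep.rms_residual,
        "n_iterations": rep.n_iterations,
        "converged": rep.converged,
    }
    audit = {"patient_id": case.patient_id, "tooth_id": case.tooth_id,
             "measurement": m.to_dict(), "alignment": rep.to_dict(),
             "plane": {"origin": s0.plane_origin.tolist(),
                       "normal": s0.plane_normal.tolist(),
                       "axis": s0.axis.tolist()}}
    return row, audit


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Process every case; failures are isolated as unmeasurable teeth.

    With ``config.out_dir`` set, writes measurements.csv, summary tables and a
    run manifest (version, config hash, seed) for provenance.
    """
    config.validate()
    rows: list[dict] = []
    audits: list[dict] = []
    n_failed = 0
    for case in config.cases:
        try:
            row, audit = _measure_case(case, config)
        except PeriomeshError as exc:
            n_failed += 1
            row = {
                "patient_id": case.patient_id, "tooth_id": case.tooth_id,
                "height_loss": np.nan, "width_loss": np.nan,
                "height_loss_axial": np.nan, "width_loss_signed": np.nan,
                "status": f"unmeasurable: {type(exc).__name__}",
                "rms_residual": np.nan, "n_iterations": 0, "converged": False,
            }
            audit = {"patient_id": case.patient_id, "tooth_id": case.tooth_id,
                     "error": str(exc)}
            if config.strict:
                rows.append(row)
                audits.append(audit)
                _write_outputs(config, rows, audits, None)
                raise
        rows.append(row)
        audits.append(audit)

    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    chart = read_chart_csv(config.chart) if config.chart else None
    summary = summarize_cohort(chart, measurements)
    _write_outputs(config, rows, audits, summary)
    return PipelineResult(measurements=measurements, summary=summary,
                          audits=audits, n_failed=n_failed)


def _write_outputs(config: PipelineConfig, rows, audits, summary) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(
        out / "measurements.csv", index=False
    )
    (out / "audit.json").write_text(json.dumps(audits, indent=1))
    if summary is not None and summary.rows:
        summary.to_frame().to_csv(out / "summary.csv", index=False)
    (out / "run_manifest.json").write_text(json.dumps({
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_cases": len(config.cases),
    }, indent=1))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Synthetic cohort description: who, how many teeth, and the phantom."""

    n_patients: int = 12
    teeth_per_patient: int = 11
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    pose_max_angle_deg: float = 10.0
    pose_max_translation: float = 2.0
    seed: int = 0
    chart_kwargs: dict = field(default_factory=dict)

    def tooth_seed(self, i: int, j: int) -> int:
        ss = np.random.SeedSequence([self.seed, i, j])
        return int(ss.generate_state(1)[0] % (2**31))


def simulated_pair(sim: SimulationSpec, i: int, j: int):
    """Phantom pair for patient i, tooth j, with a per-tooth random pose."""
    seed = sim.tooth_seed(i, j)
    rng = np.random.default_rng(seed)
    pose = RigidTransform.random(rng, sim.pose_max_angle_deg,
                                 sim.pose_max_translation)
    spec = PhantomSpec(**{**sim.phantom.to_dict(), "pose": pose, "seed": seed})
    return generate_phantom_pair(spec)


def simulate_cohort(sim: SimulationSpec, out_dir) -> PipelineConfig:
    """Write a synthetic cohort to disk: STL pairs, sidecars, chart, manifest.

    Returns a ready-to-run :class:`PipelineConfig` (also serialized as
    cases.json) whose truth manifest allows end-to-end parameter recovery.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases: list[CaseSpec] = []
    manifest: dict = {"sim": {
        "n_patients": sim.n_patients,
        "teeth_per_patient": sim.teeth_per_patient,
        "phantom": sim.phantom.to_dict(),
        "pose_max_angle_deg": sim.pose_max_angle_deg,
        "pose_max_translation": sim.pose_max_translation,
        "seed": sim.seed,
    }, "teeth": []}

    for i in range(sim.n_patients):
        for j in range(sim.teeth_per_patient):
            mesh0, mesh1, truth = simulated_pair(sim, i, j)
            pid = f"P{i + 1:02d}"
            tid = f"T{j + 1:02d}"
            stem = out / f"{pid}_{tid}"
            write_stl(mesh0, stem.with_suffix(".stl0.stl"), dialect="binary")
            write_stl(mesh1, stem.with_suffix(".stl1.stl"), dialect="binary")
            cases.append(CaseSpec(
                patient_id=pid, tooth_id=tid,
                stl0=str(stem.with_suffix(".stl0.stl")),
                stl1=str(stem.with_suffix(".stl1.stl")),
                azimuth=(1.0, 0.0, 0.0),
            ))
            entry = truth.to_dict()
            entry.update({"patient_id": pid, "tooth_id": tid})
            manifest["teeth"].append(entry)

    chart = generate_cohort_chart(
        sim.n_patients, sim.teeth_per_patient,
        seed=sim.tooth_seed(10**6, 0), **sim.chart_kwargs,
    )
    write_chart_csv(chart, out / "chart.csv")
    (out / "truth_manifest.json").write_text(json.dumps(manifest, indent=1))
    config = PipelineConfig(cases=cases, chart=str(out / "chart.csv"),
                            seed=sim.seed, out_dir=str(out / "derived"))
    config.to_json(out / "cases.json")
    return config


def simulate_and_measure(sim: SimulationSpec):
    """In-memory cohort run (no STL round trip): measurement rows + truths.

    Used by the statistics drivers and the acceptance suite where disk I/O
    would only add time; the file-based path is exercised separately.
    """
    rows = []
    truths = []
    for i in range(sim.n_patients):
        for j in range(sim.teeth_per_patient):
            mesh0, mesh1, truth = simulated_pair(sim, i, j)
            pid, tid = f"P{i + 1:02d}", f"T{j + 1:02d}"
            try:
                m, rep, _, _ = measure_pair(
                    mesh0, mesh1, azimuth_hint=truth.frame.section_normal,
                    tooth_id=tid, patient_id=pid,
                )
                rows.append({
                    "patient_id": pid, "tooth_id": tid,
                    "height_loss": m.height_loss, "width_loss": m.width_loss,
                    "height_loss_axial": m.height_loss_axial,
                    "width_loss_signed": m.width_loss_signed,
                    "status": "ok", "rms_residual": rep.rms_residual,
                    "n_iterations": rep.n_iterations,
                    "converged": rep.converged,
                })
            except PeriomeshError as exc:
                rows.append({
                    "patient_id": pid, "tooth_id": tid,
                    "height_loss": np.nan, "width_loss": np.nan,
                    "height_loss_axial": np.nan, "width_loss_signed": np.nan,
                    "status": f"unmeasurable: {type(exc).__name__}",
                    "rms_residual": np.nan, "n_iterations": 0,
                    "converged": False,
                })
            truths.append(truth)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS), truths
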