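"""Synthetic labelled scan pairs with known ground truth, plus clinical charts.

No patient scans are distributed with the study this package models, so every
downstream stage is exercised on phantoms: surfaces of revolution consisting of
a tapered crown on a root cylinder, wrapped by a gingival collar.  The phantom
is built so the margin landmarks are closed form:

* the baseline margin rim sits at axial height 0 with radius
  ``crown_radius + collar_thickness`` (point P1);
* at re-evaluation the rim has moved apically by ``delta_h`` while keeping its
  radius, so P2 sits directly below P1 and |P1 P2| = delta_h;
* the baseline collar bulges outward below the rim so that its radius at the
  new rim level exceeds the rim radius by exactly ``delta_w`` — the horizontal
  P2-P3 distance — and the re-evaluation wall is inset relative to baseline,
  the loss tapering to zero at the collar base.

The crown (and the tooth surface generally) is identical between the two time
points up to the rigid ``pose`` and per-vertex scanner noise; recession exposes
a small strip of root in the re-evaluation scan, as in real scans.  The sulcus
floor connecting rim and tooth is labelled OTHER (it is neither the alignment
surface nor the free gingival surface).

Clinical charts are simulated with patient-level clustering: the probing-depth
change of tooth j in patient i is mean_change + b_i + e_ij with normal patient
and tooth effects, and bleeding follows a Bernoulli transition model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mesh_model import CROWN, GINGIVA, OTHER, LabeledMesh, ToothFrame
from .superimpose import RigidTransform


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry, deformation and noise parameters of one phantom pair (mm).

    Defaults reproduce the cohort-mean soft-tissue changes this package's
    source study reports (height loss 0.196 mm, width loss 0.344 mm) with
    scanner noise of intraoral-scanner order (20 µm).
    """

    crown_height: float = 8.0
    crown_radius: float = 3.5
    root_length: float = 4.0
    collar_height: float = 3.0
    collar_thickness: float = 1.0
    delta_h: float = 0.196
    delta_w: float = 0.344
    noise_sd: float = 0.02
    pose: RigidTransform | None = None
    mesh_resolution: float = 0.08
    seed: int = 0
    # secondary shape/meshing knobs
    base_thickness: float = 1.2
    sulcus_depth: float = 0.1
    crown_taper: float = 0.35
    cap_rise: float = 0.8
    azimuth_step: float = 0.3
    crown_step: float | None = None
    noise_mode: str = "normal"  # "normal" (along vertex normals) or "isotropic"
    # scanner error is smooth waviness, not independent vertex jitter: the
    # noise field is low-pass filtered over this many neighbour-averaging
    # passes (0 = white noise) and rescaled to noise_sd afterwards
    noise_smooth_iters: int = 3
    # azimuthal crown lobes: real crowns are not bodies of revolution, and a
    # rotationally symmetric crown would leave the about-axis rotation
    # unconstrained for the best-fit step.  The modulation ramps in well above
    # the margin so the collar and margin zone stay exactly axisymmetric and
    # the P-point ground truth stays closed form.
    lobe_amp2: float = 0.15
    lobe_amp3: float = 0.09
    lobe_ramp_start: float = 0.1
    lobe_ramp_end: float = 0.6

    def validate(self) -> None:
        if min(self.crown_height, self.crown_radius, self.collar_height,
               self.collar_thickness, self.base_thickness,
               self.mesh_resolution, self.azimuth_step) <= 0:
            raise ConfigError("phantom dimensions and resolutions must be positive")
        if self.delta_h < 0 or self.delta_w < 0 or self.noise_sd < 0:
            raise ConfigError("delta_h, delta_w and noise_sd must be >= 0")
        if self.collar_thickness <= self.delta_w:
            raise ConfigError(
                f"collar_thickness ({self.collar_thickness}) must exceed delta_w "
                f"({self.delta_w}): the gingiva must not invert"
            )
        if self.delta_h >= self.collar_height:
            raise ConfigError(
                f"delta_h ({self.delta_h}) must be smaller than collar_height "
                f"({self.collar_height}): the margin must stay on the collar"
            )
        if self.collar_height > self.root_length:
            raise ConfigError("collar_height cannot exceed root_length")
        if self.delta_h > 0 and self.mesh_resolution > self.delta_h / 2:
            raise ConfigError(
                f"mesh_resolution {self.mesh_resolution} mm is too coarse to "
                f"represent delta_h = {self.delta_h} mm (needs <= delta_h/2)"
            )
        if self.noise_mode not in ("normal", "isotropic"):
            raise ConfigError("noise_mode must be 'normal' or 'isotropic'")

    @property
    def rim_radius(self) -> float:
        return self.crown_radius + self.collar_thickness

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pose"] = None if self.pose is None else self.pose.as_matrix().tolist()
        return d


@dataclass
class PhantomTruth:
    """Ground truth of one phantom pair, in the generative (STL0) frame."""

    frame: ToothFrame
    p1: tuple
    p2: tuple
    p3: tuple
    height_loss: float
    width_loss: float
    height_loss_axial: float
    z_margin0: float
    z_margin1: float
    spec: PhantomSpec

    def to_dict(self) -> dict:
        return {
            "frame": {
                "origin": self.frame.origin.tolist(),
                "axis": self.frame.axis.tolist(),
                "section_normal": self.frame.section_normal.tolist(),
            },
            "p1": list(self.p1),
            "p2": list(self.p2),
            "p3": list(self.p3),
            "height_loss": self.height_loss,
            "width_loss": self.width_loss,
            "height_loss_axial": self.height_loss_axial,
            "z_margin0": self.z_margin0,
            "z_margin1": self.z_margin1,
            "spec": self.spec.to_dict(),
        }


# ---------------------------------------------------------------------------
# profile construction (r, z) -> revolved mesh
# ---------------------------------------------------------------------------

def _subdivide(p0, p1, step: float) -> list:
    """Points from p0 (exclusive) to p1 (inclusive) at arc spacing <= step."""
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    n = max(1, int(np.ceil(np.linalg.norm(p1 - p0) / step)))
    return [tuple(p0 + (p1 - p0) * k / n) for k in range(1, n + 1)]


def _profile(spec: PhantomSpec, timepoint: int) -> tuple[list, list]:
    """Ordered (r, z) profile polyline and per-point labels for STL0 or STL1."""
    r_t = spec.crown_radius
    rim_r = spec.rim_radius
    res = spec.mesh_resolution
    crown_step = spec.crown_step or max(res, 0.25)
    dh, dw = spec.delta_h, spec.delta_w

    if timepoint == 0:
        z_rim = 0.0
        # Below the rim the baseline collar bulges outward by delta_w and then
        # runs VERTICALLY through the future margin level (a cylindrical band
        # around v = -delta_h), so the P3 abscissa is insensitive to small
        # errors in the P2 level; a short near-vertical prominence right under
        # the rim keeps the rim itself the unambiguous most-coronal point.
        wall_controls = [(r_t + spec.base_thickness, -spec.collar_height)]
        if dh > 0 and dw > 0:
            band_top = -dh + min(0.06, 0.4 * dh)
            band_bottom = max(-dh - 0.15, -spec.collar_height + 0.3)
            # steep mini-lip just below the rim: the free margin crest stands
            # slightly proud of the bulge, so noisy ledge points do not rival
            # the rim as the most coronal gingival point
            lip = min(0.02, 0.2 * dh, 0.3 * dw)
            wall_controls += [(rim_r + dw, band_bottom), (rim_r + dw, band_top),
                              (rim_r + lip, -lip)]
        wall_controls.append((rim_r, z_rim))
    else:
        if dh > 0:
            z_rim = -dh
            rim1_r = rim_r  # P2 sits directly below P1
        else:
            z_rim = 0.0
            rim1_r = rim_r - dw  # pure horizontal inset
        wall_controls = [(r_t + spec.base_thickness, -spec.collar_height),
                         (rim1_r, z_rim)]

    pts: list[tuple] = [wall_controls[0]]
    labels: list[str] = [GINGIVA]
    for a, b in zip(wall_controls[:-1], wall_controls[1:]):
        seg = _subdivide(a, b, res)
        pts.extend(seg)
        labels.extend([GINGIVA] * len(seg))

    # sulcus floor: from the rim inward/down to the tooth surface
    rim_pt = pts[-1]
    shelf_end = (r_t, z_rim - spec.sulcus_depth)
    seg = _subdivide(rim_pt, shelf_end, res)
    pts.extend(seg)
    labels.extend([OTHER] * (len(seg) - 1) + [CROWN])  # junction point is tooth

    # tooth wall: cylinder sampled on a fixed absolute grid so both time
    # points share vertex rings exactly on their common surface
    z_low = shelf_end[1]
    k_max = int(np.floor(-z_low / res + 1e-9))
    grid = [-k * res for k in range(k_max, -1, -1) if -k * res > z_low + 1e-12]
    if not grid or grid[-1] != 0.0:
        grid.append(0.0)
    pts.extend((r_t, z) for z in grid)
    labels.extend([CROWN] * len(grid))

    # tapered crown cone and cap to the axis (fixed subdivision counts)
    r_top = r_t * (1.0 - spec.crown_taper)
    seg = _subdivide((r_t, 0.0), (r_top, spec.crown_height), crown_step)
    pts.extend(seg)
    labels.extend([CROWN] * len(seg))
    seg = _subdivide((r_top, spec.crown_height),
                     (0.0, spec.crown_height + spec.cap_rise), crown_step)
    pts.extend(seg)
    labels.extend([CROWN] * len(seg))
    return pts, labels


def _lobe_weights(profile: list, labels: list, spec: PhantomSpec) -> np.ndarray:
    """Per-profile-point weight of the azimuthal crown modulation."""
    z = np.asarray(profile, dtype=np.float64)[:, 1]
    span = max(spec.lobe_ramp_end - spec.lobe_ramp_start, 1e-9)
    w = np.clip((z - spec.lobe_ramp_start) / span, 0.0, 1.0)
    w[np.asarray(labels, dtype="U8") != CROWN] = 0.0
    return w


def _revolve(profile: list, labels: list, n_theta: int, theta_offset: float,
             lobe_weights: np.ndarray | None = None,
             lobe_amp2: float = 0.0, lobe_amp3: float = 0.0) -> LabeledMesh:
    """Revolve an (r, z) profile about the z axis into a triangle mesh.

    The last profile point may lie on the axis (r = 0) and becomes a single
    apex vertex with a triangle fan; all other radii must be positive.
    With ``lobe_weights`` the ring radii are modulated azimuthally:
    ``r * (1 + w * (a2 cos 2θ + a3 cos 3θ))``.  Triangles wind so normals
    point outward/upward.
    """
    prof = np.asarray(profile, dtype=np.float64)
    lab = np.asarray(labels, dtype="U8")
    has_apex = prof[-1, 0] == 0.0
    rings = prof[:-1] if has_apex else prof
    ring_lab = lab[:-1] if has_apex else lab
    if np.any(rings[:, 0] <= 0):
        raise ConfigError("profile radii must be positive except at the apex")

    n_rings = len(rings)
    theta = theta_offset + 2 * np.pi * np.arange(n_theta) / n_theta
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    radii = np.repeat(rings[:, 0], n_theta).reshape(n_rings, n_theta)
    if lobe_weights is not None and (lobe_amp2 or lobe_amp3):
        w = np.asarray(lobe_weights, dtype=np.float64)
        w = (w[:-1] if has_apex else w)[:, None]
        radii = radii * (1.0 + w * (lobe_amp2 * np.cos(2 * theta)
                                    + lobe_amp3 * np.cos(3 * theta)))
    verts = np.empty((n_rings * n_theta + (1 if has_apex else 0), 3))
    verts[: n_rings * n_theta, 0] = (radii * cos_t).ravel()
    verts[: n_rings * n_theta, 1] = (radii * sin_t).ravel()
    verts[: n_rings * n_theta, 2] = np.repeat(rings[:, 1], n_theta)
    vlab = np.repeat(ring_lab, n_theta)
    if has_apex:
        apex = n_rings * n_theta
        verts[apex] = (0.0, 0.0, prof[-1, 1])
        vlab = np.append(vlab, lab[-1])

    j = np.arange(n_theta)
    jn = (j + 1) % n_theta
    quads = []
    for i in range(n_rings - 1):
        a = i * n_theta + j
        b = i * n_theta + jn
        c = (i + 1) * n_theta + jn
        d = (i + 1) * n_theta + j
        quads.append(np.column_stack([a, b, d]))
        quads.append(np.column_stack([b, c, d]))
    faces = np.concatenate(quads)
    if has_apex:
        a = (n_rings - 1) * n_theta + j
        b = (n_rings - 1) * n_theta + jn
        fan = np.column_stack([a, b, np.full(n_theta, apex)])
        faces = np.concatenate([faces, fan])
    return LabeledMesh(verts, faces, vlab)


def _smooth_field(field: np.ndarray, faces: np.ndarray, n_vertices: int,
                  iters: int) -> np.ndarray:
    """Neighbour-average a per-vertex field and rescale it to unit variance."""
    if iters <= 0:
        return field
    from scipy import sparse

    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_vertices, n_vertices)
    )
    adj.data[:] = 1.0  # collapse duplicate edges
    deg = np.maximum(np.asarray(adj.sum(axis=1)).ravel(), 1.0)
    out = field
    for _ in range(iters):
        out = 0.5 * (out + (adj @ out) / (deg[:, None] if out.ndim == 2 else deg))
    sd = out.std()
    return out / sd if sd > 0 else out


def _apply_noise(mesh: LabeledMesh, sd: float, rng: np.random.Generator,
                 mode: str, smooth_iters: int) -> None:
    """Perturb vertices in place; draws are consumed even when sd == 0 so the
    random stream layout is independent of the noise level."""
    if mode == "isotropic":
        delta = rng.normal(0.0, 1.0, size=mesh.vertices.shape)
        if sd > 0:
            delta = _smooth_field(delta, mesh.faces, mesh.n_vertices, smooth_iters)
            mesh.vertices += sd * delta
    else:
        amp = rng.normal(0.0, 1.0, size=mesh.n_vertices)
        if sd > 0:
            amp = _smooth_field(amp, mesh.faces, mesh.n_vertices, smooth_iters)
            mesh.vertices += sd * amp[:, None] * mesh.vertex_normals()


def generate_phantom_pair(
    spec: PhantomSpec,
) -> tuple[LabeledMesh, LabeledMesh, PhantomTruth]:
    """Generate (STL0, STL1, truth) for one phantom tooth.

    STL1 carries the rigid ``spec.pose`` (identity if None) and both scans are
    perturbed with independent Gaussian scanner noise from ``spec.seed``.
    The returned truth holds the generative tooth frame and the closed-form
    P1/P2/P3 landmarks in the STL0 frame.
    """
    spec.validate()
    max_r = spec.crown_radius + spec.base_thickness
    n_theta = max(8, int(np.ceil(2 * np.pi * max_r / spec.azimuth_step)))
    theta_offset = np.pi / n_theta  # keep vertices off the axial planes

    prof0, lab0 = _profile(spec, 0)
    prof1, lab1 = _profile(spec, 1)
    mesh0 = _revolve(prof0, lab0, n_theta, theta_offset,
                     _lobe_weights(prof0, lab0, spec),
                     spec.lobe_amp2, spec.lobe_amp3)
    mesh1 = _revolve(prof1, lab1, n_theta, theta_offset,
                     _lobe_weights(prof1, lab1, spec),
                     spec.lobe_amp2, spec.lobe_amp3)
    mesh0.frame_id = "STL0"
    mesh1.frame_id = "STL1"

    pose = spec.pose or RigidTransform.identity()
    mesh1.vertices = pose.apply(mesh1.vertices)

    rng = np.random.default_rng(spec.seed)
    _apply_noise(mesh0, spec.noise_sd, rng, spec.noise_mode,
                 spec.noise_smooth_iters)
    _apply_noise(mesh1, spec.noise_sd, rng, spec.noise_mode,
                 spec.noise_smooth_iters)

    rim_r = spec.rim_radius
    if spec.delta_h > 0:
        p1 = (rim_r, 0.0)
        p2 = (rim_r, -spec.delta_h)
        p3 = (rim_r + spec.delta_w, -spec.delta_h)
    else:
        p1 = (rim_r, 0.0)
        p2 = (rim_r - spec.delta_w, 0.0)
        p3 = (rim_r, 0.0)
    truth = PhantomTruth(
        frame=ToothFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                         np.array([1.0, 0.0, 0.0])),
        p1=p1,
        p2=p2,
        p3=p3,
        height_loss=float(np.hypot(p1[0] - p2[0], p1[1] - p2[1])),
        width_loss=float(abs(p3[0] - p2[0])),
        height_loss_axial=float(p1[1] - p2[1]),
        z_margin0=0.0,
        z_margin1=-spec.delta_h,
        spec=spec,
    )
    return mesh0, mesh1, truth


# ---------------------------------------------------------------------------
# clinical chart simulation
# ---------------------------------------------------------------------------

@dataclass
class ClinicalRecord:
    """Per-tooth chart entry at baseline (0) and re-evaluation (1)."""

    patient_id: str
    tooth_id: str
    pst0: float
    pst1: float
    recession0: float
    recession1: float
    bleeding0: bool
    bleeding1: bool


CHART_COLUMNS = ["patient_id", "tooth_id", "pst0", "pst1",
                 "recession0", "recession1", "bleeding0", "bleeding1"]


def _round_sites(true_depth: float, rng: np.random.Generator, sites: int,
                 site_sd: float, step: float) -> float:
    """Average of per-site probe readings recorded in ``step``-mm increments."""
    raw = true_depth + rng.normal(0.0, site_sd, size=sites)
    probed = np.maximum(step, np.round(raw / step) * step)
    return float(np.mean(probed))


def generate_cohort_chart(
    n_patients: int,
    teeth_per_patient: int,
    mean_change: float = -0.34,
    sd_within: float = 0.4,
    sd_between: float = 0.3,
    p_bleed0: float = 0.74,
    p_resolve: float = 52 / 97,
    p_new: float = 1 / 34,
    seed: int = 0,
    base_mean: float = 2.74,
    base_sd_between: float = 0.4,
    base_sd_within: float = 0.5,
    sites: int = 3,
    site_sd: float = 0.3,
    probe_step: float = 0.5,
    p_recession: float = 4 / 131,
) -> list[ClinicalRecord]:
    """Simulate a clustered clinical chart.

    The probing-depth change of tooth j in patient i is
    ``mean_change + b_i + e_ij`` with b_i ~ N(0, sd_between^2) and
    e_ij ~ N(0, sd_within^2).  Recorded depths are averages of ``sites``
    per-tooth probe readings in ``probe_step``-mm increments, which yields
    values like 2.67.  Bleeding at baseline is Bernoulli(p_bleed0) and
    transitions resolve with probability p_resolve (appear with p_new).
    Default rates are the source cohort's observed values.
    """
    if n_patients < 1 or teeth_per_patient < 1:
        raise ConfigError("counts must be >= 1")
    for name, p in (("p_bleed0", p_bleed0), ("p_resolve", p_resolve),
                    ("p_new", p_new), ("p_recession", p_recession)):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    records: list[ClinicalRecord] = []
    for i in range(n_patients):
        b_i = rng.normal(0.0, sd_between)
        a_i = rng.normal(0.0, base_sd_between)
        pid = f"P{i + 1:02d}"
        for t in range(teeth_per_patient):
            true0 = max(1.0, base_mean + a_i + rng.normal(0.0, base_sd_within))
            change = mean_change + b_i + rng.normal(0.0, sd_within)
            true1 = max(0.5, true0 + change)
            pst0 = _round_sites(true0, rng, sites, site_sd, probe_step)
            pst1 = _round_sites(true1, rng, sites, site_sd, probe_step)
            bleeding0 = bool(rng.random() < p_bleed0)
            if bleeding0:
                bleeding1 = not (rng.random() < p_resolve)
            else:
                bleeding1 = bool(rng.random() < p_new)
            recession1 = 1.0 if rng.random() < p_recession else 0.0
            records.append(
                ClinicalRecord(
                    patient_id=pid,
                    tooth_id=f"T{t + 1:02d}",
                    pst0=pst0,
                    pst1=pst1,
                    recession0=0.0,
                    recession1=recession1,
                    bleeding0=bleeding0,
                    bleeding1=bleeding1,
                )
            )
    return records


def chart_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=CHART_COLUMNS)


def write_chart_csv(records, path) -> Path:
    path = Path(path)
    chart_to_frame(records).to_csv(path, index=False)
    return path


def read_chart_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CHART_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: chart is missing columns {sorted(missing)}")
    return df
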