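"""The P1/P2/P3 margin construction on a pair of section polylines.

On the shared cutting plane, P1 is the most coronal gingival point of the
baseline section and P2 the most coronal gingival point of the re-evaluation
section.  A horizontal line L (perpendicular to the tooth axis, v = v(P2))
drawn from P2 meets the baseline section at P3.  Then

* vertical (height) soft-tissue change = |P1 P2| (planar Euclidean distance),
* horizontal (width) soft-tissue change = |P2 P3|.

Both are reported as nonnegative distances to 3 decimals mm; the signed axial
component v(P1) - v(P2) and the signed width u(P3) - u(P2) are kept as
diagnostics (positive = apical / inward movement, i.e. tissue loss).

The profile is measured on one radial side of the tooth only (positive u,
the azimuth chosen by the cutting-plane configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cross_section import SectionPolyline
from .errors import MissingGingivaError, NoIntersectionError
from .mesh_model import GINGIVA

#: tolerance for "same v" ties and duplicate-crossing deduplication (mm)
_TIE = 1e-12
_DEDUP = 1e-9


@dataclass
class MarginMeasurement:
    """Per-tooth soft-tissue change between baseline and re-evaluation."""

    p1: tuple
    p2: tuple
    p3: tuple
    line_l_v: float
    height_loss: float
    width_loss: float
    height_loss_axial: float
    width_loss_signed: float
    tooth_id: str = ""
    patient_id: str = ""
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "tooth_id": self.tooth_id,
            "p1": list(self.p1),
            "p2": list(self.p2),
            "p3": list(self.p3),
            "line_l_v": self.line_l_v,
            "height_loss": self.height_loss,
            "width_loss": self.width_loss,
            "height_loss_axial": self.height_loss_axial,
            "width_loss_signed": self.width_loss_signed,
            "status": self.status,
        }


def find_sulcus_point(section: SectionPolyline, min_u: float | None = None) -> tuple:
    """Most coronal (max v) GINGIVA-labelled point; v-ties -> smaller u.

    ``min_u`` restricts the search to one radial side of the profile (the
    measured azimuth); the tie-break toward smaller u selects the point
    closest to the axis, i.e. deepest in the sulcus.
    """
    mask = section.labels == GINGIVA
    if min_u is not None:
        mask &= section.points2d[:, 0] >= min_u
    if not mask.any():
        raise MissingGingivaError(
            f"section of {section.source_frame!r} has no GINGIVA points"
            + (f" with u >= {min_u}" if min_u is not None else "")
        )
    pts = section.points2d[mask]
    vmax = pts[:, 1].max()
    top = pts[pts[:, 1] >= vmax - _TIE]
    i = int(np.argmin(top[:, 0]))
    return (float(top[i, 0]), float(top[i, 1]))


def horizontal_crossings(
    section: SectionPolyline, v_level: float, min_u: float | None = None
) -> np.ndarray:
    """All u values where the polyline crosses v = v_level (deduplicated).

    Points exactly on the level count once; interior crossings are linearly
    interpolated along their segment.  With ``min_u`` set, segments with an
    endpoint on the excluded side are skipped.
    """
    p = section.points2d
    if min_u is None:
        keep_pt = np.ones(len(p), dtype=bool)
    else:
        keep_pt = p[:, 0] >= min_u

    us = []
    on_level = np.abs(p[:, 1] - v_level) <= _TIE
    us.extend(p[on_level & keep_pt, 0].tolist())

    va = p[:-1, 1] - v_level
    vb = p[1:, 1] - v_level
    seg = (va * vb < 0) & keep_pt[:-1] & keep_pt[1:]
    if seg.any():
        t = va[seg] / (va[seg] - vb[seg])
        ua = p[:-1, 0][seg]
        ub = p[1:, 0][seg]
        us.extend((ua + t * (ub - ua)).tolist())

    if not us:
        return np.empty(0)
    us = np.sort(np.asarray(us, dtype=np.float64))
    dedup = [us[0]]
    for u in us[1:]:
        if u - dedup[-1] > _DEDUP:
            dedup.append(u)
    return np.asarray(dedup)


def intersect_horizontal(
    section: SectionPolyline, v_level: float, u_ref: float,
    min_u: float | None = None,
) -> tuple:
    """Intersection of line L (v = v_level) with the section, nearest ``u_ref``.

    Among all crossings the one with u closest to the P2 abscissa ``u_ref`` is
    returned (distance ties -> smaller u).
    """
    us = horizontal_crossings(section, v_level, min_u=min_u)
    if len(us) == 0:
        raise NoIntersectionError(
            f"section of {section.source_frame!r} does not cross v = {v_level:.6f}"
        )
    dist = np.abs(us - u_ref)
    # stable argmin on sorted u realises the smaller-u tie-break
    i = int(np.argmin(dist))
    return (float(us[i]), float(v_level))


def measure_tooth(
    section0: SectionPolyline,
    section1: SectionPolyline,
    tooth_id: str = "",
    patient_id: str = "",
    side: str = "positive",
    decimals: int = 3,
) -> MarginMeasurement:
    """Apply the P1/P2/P3 construction to a baseline/re-evaluation section pair.

    Both sections must share the same cutting plane (the pipeline estimates
    one frame on the baseline scan and reuses it for the aligned re-evaluation
    scan).  ``side="positive"`` measures the positive-u half of the profile;
    ``side="both"`` uses the whole polyline.
    """
    if not np.allclose(section0.plane_origin, section1.plane_origin, atol=1e-9) or \
       not np.allclose(section0.plane_normal, section1.plane_normal, atol=1e-9):
        raise ValueError("sections do not share a cutting plane")
    min_u = 0.0 if side == "positive" else None

    p1 = find_sulcus_point(section0, min_u=min_u)
    p2 = find_sulcus_point(section1, min_u=min_u)
    p3 = intersect_horizontal(section0, v_level=p2[1], u_ref=p2[0], min_u=min_u)

    height = float(np.hypot(p1[0] - p2[0], p1[1] - p2[1]))
    width = float(abs(p3[0] - p2[0]))
    return MarginMeasurement(
        p1=p1,
        p2=p2,
        p3=p3,
        line_l_v=p2[1],
        height_loss=round(height, decimals),
        width_loss=round(width, decimals),
        height_loss_axial=round(p1[1] - p2[1], decimals),
        width_loss_signed=round(p3[0] - p2[0], decimals),
        tooth_id=tooth_id,
        patient_id=patient_id,
    )
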