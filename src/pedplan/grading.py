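"""Quantitative and qualitative screw-plan evaluation.

Quantitative: per-screw deviations of length, diameter, and pedicle
transverse/sagittal angles between an automatic and a reference plan, plus
the Dice overlap of the voxelized screw cylinders.

Qualitative: Gertzbein-Robbins grading of cortical breach depth — grade A
(no breach), B (< 2 mm), C (< 4 mm), D (< 6 mm), E (>= 6 mm), intervals
half-open at the printed bounds so a 2.0 mm breach grades C — with the
perforation direction (medial/lateral/superior/inferior) of every non-A
screw; and Badu grading of superior-facet violation (0 clear, 1 abutting
the joint surface, 2 invading <= 1 mm, 3 crossing the joint).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from pedplan.errors import ValidationError
from pedplan.geometry import voxelize_cylinder
from pedplan.imaging import LabelMap, Volume
from pedplan.planner import ScrewPlan
from pedplan.segnet import dice_coefficient

__all__ = [
    "GradeReport",
    "DeviationReport",
    "voxelize_screw",
    "screw_dice",
    "deviations",
    "gr_grade",
    "badu_grade",
    "cohort_report",
]

GR_THRESHOLDS = ((2.0, "B"), (4.0, "C"), (6.0, "D"))  # breach < t → grade


@dataclasses.dataclass(frozen=True)
class GradeReport:
    gr_class: str                  # A..E
    breach_mm: float               # max cortical breach depth
    breach_direction: str          # none | medial | lateral | superior | inferior
    badu: int                      # 0..3
    facet_penetration_mm: float

    def __post_init__(self) -> None:
        if (self.gr_class == "A") != (self.breach_mm == 0.0):
            raise ValidationError("grade A iff breach depth 0")
        if (self.gr_class == "A") != (self.breach_direction == "none"):
            raise ValidationError("direction 'none' iff grade A")
        if self.badu >= 2 and self.facet_penetration_mm <= 0:
            raise ValidationError("Badu >= 2 requires positive facet penetration")


@dataclasses.dataclass(frozen=True)
class DeviationReport:
    d_pta: float       # degrees, unsigned
    d_psa: float       # degrees, unsigned
    d_length: float    # mm, signed (auto - reference)
    d_diameter: float  # mm, signed (auto - reference)
    screw_dice: float


# ---------------------------------------------------------------------------
# voxelization and overlap
# ---------------------------------------------------------------------------

def voxelize_screw(p: ScrewPlan, geometry: Volume) -> np.ndarray:
    """Binary mask of the screw cylinder (voxel centers inside the capped
    cylinder); wholly off-grid screws give an empty mask with a warning."""
    mask = voxelize_cylinder(p.entry, p.direction, p.length, p.diameter, geometry)
    if not mask.any():
        import warnings

        warnings.warn(f"screw {p.level}/{p.side} lies wholly outside the grid")
    return mask


def screw_dice(a: ScrewPlan, b: ScrewPlan, geometry: Volume) -> float:
    """Dice overlap of two voxelized screws on the same grid."""
    return dice_coefficient(voxelize_screw(a, geometry), voxelize_screw(b, geometry))


def deviations(auto: ScrewPlan, ref: ScrewPlan, geometry: Volume) -> DeviationReport:
    """Per-screw deviation of angles (unsigned), size (signed), and overlap."""
    if (auto.level, auto.side) != (ref.level, ref.side):
        raise ValidationError(
            f"level/side mismatch: {(auto.level, auto.side)} vs {(ref.level, ref.side)}"
        )
    return DeviationReport(
        d_pta=abs(auto.pta - ref.pta),
        d_psa=abs(auto.psa - ref.psa),
        d_length=auto.length - ref.length,
        d_diameter=auto.diameter - ref.diameter,
        screw_dice=screw_dice(auto, ref, geometry),
    )


# ---------------------------------------------------------------------------
# Gertzbein-Robbins
# ---------------------------------------------------------------------------

def _gr_class(breach_mm: float) -> str:
    if breach_mm == 0.0:
        return "A"
    for t, grade in GR_THRESHOLDS:
        if breach_mm < t:
            return grade
    return "E"


def gr_grade(
    screw_mask: np.ndarray,
    bone: LabelMap | np.ndarray,
    pedicle_axis,
    side: str | None = None,
    spacing=None,
) -> tuple[str, float, str]:
    """(grade, breach depth mm, perforation direction) for one screw.

    Breach depth is the largest distance from a screw voxel outside the bone
    mask to the nearest bone voxel (distance transform of the bone
    complement).  The perforation direction is the dominant transverse
    component (x → medial/lateral given ``side``, z → superior/inferior) of
    the offset from the screw axis to the breach centroid.  ``side``
    defaults to the sign of the screw centroid's x coordinate (x < 0 →
    left-side screw, medial = +x).
    """
    screw_mask = np.asarray(screw_mask, dtype=bool)
    if not screw_mask.any():
        raise ValidationError("empty screw mask")
    if isinstance(bone, LabelMap):
        bone_mask = bone.data > 0
        spacing = bone.spacing if spacing is None else spacing
    else:
        bone_mask = np.asarray(bone, dtype=bool)
        spacing = (1.0, 1.0, 1.0) if spacing is None else spacing
    if bone_mask.shape != screw_mask.shape:
        raise ValidationError("screw and bone masks must share a grid")

    outside = screw_mask & ~bone_mask
    if not outside.any():
        return "A", 0.0, "none"

    dist_to_bone = ndimage.distance_transform_edt(~bone_mask, sampling=spacing)
    breach = float(dist_to_bone[outside].max())
    breach = max(breach, float(np.finfo(float).tiny))

    sp = np.asarray(spacing)
    c_breach = np.asarray(np.nonzero(outside)).mean(axis=1) * sp
    c_screw = np.asarray(np.nonzero(screw_mask)).mean(axis=1) * sp
    d = np.asarray(pedicle_axis, dtype=float)
    d = d / np.linalg.norm(d)
    w = c_breach - c_screw
    w_perp = w - np.dot(w, d) * d
    if side is None:
        side = "left" if c_screw[0] <= bone_mask.shape[0] * sp[0] / 2 else "right"
    medial_sign = 1.0 if side == "left" else -1.0
    if abs(w_perp[0]) >= abs(w_perp[2]):
        direction = "medial" if w_perp[0] * medial_sign > 0 else "lateral"
    else:
        direction = "superior" if w_perp[2] > 0 else "inferior"
    return _gr_class(breach), breach, direction


# ---------------------------------------------------------------------------
# Badu facet violation
# ---------------------------------------------------------------------------

def badu_grade(
    screw_mask: np.ndarray,
    facet: LabelMap | np.ndarray,
    contact_eps: float = 0.5,
    axis=None,
    spacing=None,
) -> tuple[int, float]:
    """(Badu grade, facet penetration depth mm) for one screw.

    Grade 0: the screw is clear of the facet joint; 1: it abuts the joint
    surface (surface gap <= ``contact_eps``) without entering it; 2: it
    invades the joint by at most 1 mm; 3: it crosses the joint surface
    (transfixes the facet region, or invades deeper than 1 mm).

    The surface gap is approximated as the center-to-center distance to the
    nearest facet voxel minus one mean voxel size.  Transfixion is detected
    by the screw extending past the facet's far extent along its own axis
    (``axis`` defaults to the principal axis of the screw mask).
    """
    screw_mask = np.asarray(screw_mask, dtype=bool)
    if isinstance(facet, LabelMap):
        facet_mask = facet.data > 0
        spacing = facet.spacing if spacing is None else spacing
    else:
        facet_mask = np.asarray(facet, dtype=bool)
        spacing = (1.0, 1.0, 1.0) if spacing is None else spacing
    if not facet_mask.any():
        raise ValidationError("empty facet label")
    if facet_mask.shape != screw_mask.shape:
        raise ValidationError("screw and facet masks must share a grid")
    if not screw_mask.any():
        raise ValidationError("empty screw mask")
    sp = np.asarray(spacing)

    overlap = screw_mask & facet_mask
    if not overlap.any():
        dist_to_facet = ndimage.distance_transform_edt(~facet_mask, sampling=spacing)
        gap = float(dist_to_facet[screw_mask].min()) - float(sp.mean())
        return (1, 0.0) if gap <= contact_eps else (0, 0.0)

    depth_in_facet = ndimage.distance_transform_edt(facet_mask, sampling=spacing)
    penetration = float(depth_in_facet[overlap].max())

    if axis is None:
        pts = np.asarray(np.nonzero(screw_mask)).T * sp
        pts = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        axis = vt[0]
    d = np.asarray(axis, dtype=float)
    d = d / np.linalg.norm(d)
    t_screw = (np.asarray(np.nonzero(screw_mask)).T * sp) @ d
    t_facet = (np.asarray(np.nonzero(facet_mask)).T * sp) @ d
    step = float(sp.max())
    transfixes = t_screw.max() > t_facet.max() + step / 2 and t_screw.min() < t_facet.min() - step / 2

    if transfixes or penetration > 1.0:
        return 3, penetration
    return 2, penetration


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------

def grade_plan(
    plan: ScrewPlan, labels: LabelMap, level_label: int
) -> GradeReport:
    """Full GradeReport of one screw against its vertebra's bone and facet."""
    geometry = labels.geometry()
    screw = voxelize_screw(plan, geometry)
    bone = labels.mask([level_label, 10 * level_label + 1, 10 * level_label + 2])
    bone_lm = LabelMap(
        bone.astype(np.int16), labels.spacing, labels.origin, {1: "bone"}
    )
    gr, breach, direction = gr_grade(screw, bone_lm, plan.direction, plan.side)
    facet = labels.mask([10 * level_label + 3, 10 * level_label + 4])
    if facet.any():
        facet_lm = LabelMap(
            facet.astype(np.int16), labels.spacing, labels.origin, {1: "facet"}
        )
        badu, pen = badu_grade(screw, facet_lm, axis=plan.direction)
    else:
        badu, pen = 0, 0.0
    return GradeReport(gr, breach, direction, badu, pen)


def cohort_report(
    auto_plans: list[list[ScrewPlan]],
    ref_plans: list[list[ScrewPlan]],
    labelmaps: list[LabelMap],
) -> tuple[pd.DataFrame, dict]:
    """Per-screw deviation + grade rows and cohort aggregates.

    ``auto_plans[i]``/``ref_plans[i]`` are matched by (level, side) within
    case ``i`` on the grid of ``labelmaps[i]``.  Unmatched screws are
    reported as rows with null deviations, never silently dropped.  Returns
    (rows, summary): the rows as a DataFrame ready for CSV, and aggregate
    mean ± SD per metric plus GR/Badu class counts and percentages.
    """
    from pedplan.keypoints import LEVEL_LABELS

    if not (len(auto_plans) == len(ref_plans) == len(labelmaps)):
        raise ValidationError("auto_plans, ref_plans and labelmaps must align per case")
    rows = []
    for case, (autos, refs, labels) in enumerate(zip(auto_plans, ref_plans, labelmaps)):
        geometry = labels.geometry()
        ref_by_key = {(r.level, r.side): r for r in refs}
        seen = set()
        for a in autos:
            key = (a.level, a.side)
            seen.add(key)
            row = {"case": case, "level": a.level, "side": a.side, "matched": key in ref_by_key}
            g = grade_plan(a, labels, LEVEL_LABELS[a.level])
            row.update(
                gr=g.gr_class, breach_mm=g.breach_mm, direction=g.breach_direction,
                badu=g.badu, facet_penetration_mm=g.facet_penetration_mm,
            )
            if key in ref_by_key:
                dev = deviations(a, ref_by_key[key], geometry)
                row.update(
                    d_pta=dev.d_pta, d_psa=dev.d_psa, d_length=dev.d_length,
                    d_diameter=dev.d_diameter, dice=dev.screw_dice,
                )
            rows.append(row)
        for key, r in ref_by_key.items():
            if key not in seen:
                rows.append(
                    {"case": case, "level": r.level, "side": r.side, "matched": False}
                )
    df = pd.DataFrame(rows)

    summary: dict = {"n_screws": int(len(df))}
    for col in ("d_pta", "d_psa", "d_length", "d_diameter", "dice", "breach_mm"):
        if col in df and df[col].notna().any():
            summary[f"{col}_mean"] = float(df[col].mean())
            summary[f"{col}_sd"] = float(df[col].std(ddof=1)) if df[col].notna().sum() > 1 else 0.0
    graded = df[df.get("gr").notna()] if "gr" in df else df.iloc[0:0]
    n = len(graded)
    if n:
        summary["gr_counts"] = {g: int((graded["gr"] == g).sum()) for g in "ABCDE"}
        summary["gr_percent"] = {g: 100.0 * c / n for g, c in summary["gr_counts"].items()}
        summary["badu_counts"] = {b: int((graded["badu"] == b).sum()) for b in range(4)}
        summary["badu_percent"] = {b: 100.0 * c / n for b, c in summary["badu_counts"].items()}
    return df, summary
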