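"""Geometric pedicle-screw planning from a bone label map and keypoints.

Each screw is modeled as a capped cylinder along the straight segment from
the posterior entry point toward the anterior exit point.  The planner

1. traces the contiguous in-bone segment of that ray (the bone-screw
   channel) and its isthmus clearance,
2. sets the insertion depth to 80 % of the channel length,
3. maximizes the screw diameter subject to not penetrating the pedicle
   cortex (Euclidean distance transform of the bone mask, with an optional
   safety margin), and
4. reports the pedicle transverse and sagittal angles of the trajectory.

Clearance along the axis is read from the distance transform; samples within
one screw radius of the channel mouth (where the nearest background is the
entry cortex the screw legitimately crosses, not the pedicle wall) are
excluded, which makes the distance-based diameter agree with a brute-force
containment search.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from pedplan.errors import PlanningError, ValidationError
from pedplan.geometry import compute_angles, voxelize_cylinder
from pedplan.imaging import LabelMap, Volume, continuous_index
from pedplan.keypoints import LEVEL_LABELS, KeypointSet

__all__ = [
    "Channel",
    "ScrewPlan",
    "PlannerConfig",
    "PlanFailure",
    "trace_channel",
    "select_length",
    "select_diameter",
    "plan_screws",
    "compute_angles",
    "save_plans",
    "load_plans",
]

SHORT_CHANNEL_MM = 10.0


@dataclasses.dataclass(frozen=True)
class Channel:
    """The in-bone segment of an entry-to-exit ray."""

    entry: np.ndarray
    exit: np.ndarray
    axis: np.ndarray
    length: float
    isthmus_radius: float
    short: bool = False  # warning flag: in-bone segment < 10 mm

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"channel length must be > 0, got {self.length}")
        if self.isthmus_radius <= 0:
            raise ValidationError(f"isthmus radius must be > 0, got {self.isthmus_radius}")


@dataclasses.dataclass(frozen=True)
class ScrewPlan:
    """One cylindrical pedicle screw."""

    level: str
    side: str
    entry: np.ndarray
    direction: np.ndarray
    length: float
    diameter: float
    pta: float
    psa: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-6:
            raise ValidationError(f"direction must be unit length, |d| = {n:.6g}")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "entry", np.asarray(self.entry, dtype=float))
        if self.length <= 0 or self.diameter <= 0:
            raise ValidationError("length and diameter must be positive")
        if not (np.isnan(self.pta) or 0.0 <= self.pta <= 90.0):
            raise ValidationError(f"PTA out of range: {self.pta}")
        if not -90.0 <= self.psa <= 90.0:
            raise ValidationError(f"PSA out of range: {self.psa}")

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "side": self.side,
            "entry_mm": [float(v) for v in self.entry],
            "direction": [float(v) for v in self.direction],
            "length_mm": float(self.length),
            "diameter_mm": float(self.diameter),
            "pta_deg": float(self.pta),
            "psa_deg": float(self.psa),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScrewPlan":
        return cls(
            level=d["level"],
            side=d["side"],
            entry=np.asarray(d["entry_mm"], float),
            direction=np.asarray(d["direction"], float),
            length=d["length_mm"],
            diameter=d["diameter_mm"],
            pta=d["pta_deg"],
            psa=d["psa_deg"],
        )


@dataclasses.dataclass(frozen=True)
class PlannerConfig:
    fraction: float = 0.8          # insertion depth as fraction of channel length
    margin: float = 0.0            # radial safety margin to cortex, mm
    min_diameter: float = 4.0      # below this the pedicle is "too narrow", mm
    catalog_step: float | None = None  # snap length down to multiples, mm
    diameter_step: float = 0.1     # search resolution, mm


@dataclasses.dataclass(frozen=True)
class PlanFailure:
    """Structured record of a screw that could not be planned."""

    level: str
    side: str
    stage: str
    reason: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# channel tracing
# ---------------------------------------------------------------------------

def _bone_distance_field(bone_mask: np.ndarray, spacing) -> np.ndarray:
    """Distance (mm) from each bone voxel to the nearest background voxel."""
    return ndimage.distance_transform_edt(bone_mask, sampling=spacing)


def _sample_field(field: np.ndarray, points_mm: np.ndarray, geometry: Volume) -> np.ndarray:
    coords = np.stack([continuous_index(p, geometry) for p in points_mm], axis=1)
    return ndimage.map_coordinates(field, coords, order=1, mode="constant", cval=0.0)


def _max_inscribed_radius(ts, edt_vals, lo: float, hi: float, *, cap_lo=True, cap_hi=True):
    """Largest r with EDT(t) >= r for all samples t in [r·cap_lo, hi - r·cap_hi].

    End caps of depth r are excluded where the screw/channel legitimately
    meets the cortex surface (mouth and tip), since there the distance
    transform measures the axial distance to that surface rather than the
    radial clearance.
    """
    r_grid = np.arange(0.0, max(edt_vals.max(), 0.0) + 0.05, 0.05)
    best = 0.0
    for r in r_grid:
        t_lo = lo + (r if cap_lo else 0.0)
        t_hi = hi - (r if cap_hi else 0.0)
        sel = (ts >= t_lo) & (ts <= t_hi)
        if not np.any(sel):
            continue
        if edt_vals[sel].min() >= r:
            best = r
    return float(best)


def trace_channel(entry, exit, bone: LabelMap) -> Channel:
    """Trace the contiguous in-bone segment of the ray entry → exit.

    The ray is sampled at quarter-voxel steps; the longest contiguous run of
    samples inside the bone mask is the channel.  ``isthmus_radius`` is the
    largest radius a cylinder around the axis could have without leaving
    bone, read from the distance transform with end caps excluded.
    """
    entry = np.asarray(entry, dtype=float)
    exit = np.asarray(exit, dtype=float)
    seg = exit - entry
    seg_len = float(np.linalg.norm(seg))
    if seg_len < 1e-9:
        raise ValidationError("entry and exit coincide")
    axis = seg / seg_len
    geometry = bone.geometry()
    bone_mask = bone.data > 0

    step = min(bone.spacing) / 4.0
    n = int(np.ceil(seg_len / step)) + 1
    ts = np.linspace(0.0, seg_len, n)
    pts = entry[None, :] + ts[:, None] * axis[None, :]
    # nearest-voxel bone membership along the ray
    coords = np.stack([continuous_index(p, geometry) for p in pts], axis=1)
    idx = np.rint(coords).astype(int)
    inside_grid = np.all((idx >= 0) & (idx < np.asarray(bone.shape)[:, None]), axis=0)
    in_bone = np.zeros(n, dtype=bool)
    ig = np.where(inside_grid)[0]
    in_bone[ig] = bone_mask[idx[0, ig], idx[1, ig], idx[2, ig]]

    if not np.any(in_bone):
        raise PlanningError("no channel: segment never enters bone")

    # longest contiguous run of in-bone samples
    runs = []
    start = None
    for i, b in enumerate(in_bone):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, n - 1))
    s, e = max(runs, key=lambda r: r[1] - r[0])
    t0, t1 = ts[s], ts[e]
    length = float(t1 - t0)
    if length <= 0:
        raise PlanningError("no channel: in-bone segment has zero length")

    edt = _bone_distance_field(bone_mask, bone.spacing)
    sel = slice(s, e + 1)
    edt_vals = _sample_field(edt, pts[sel], geometry)
    isthmus = _max_inscribed_radius(ts[sel] - t0, edt_vals, 0.0, length)
    if isthmus <= 0:
        isthmus = float(max(edt_vals.max(), min(bone.spacing) / 2))

    return Channel(
        entry=entry + t0 * axis,
        exit=entry + t1 * axis,
        axis=axis,
        length=length,
        isthmus_radius=isthmus,
        short=length < SHORT_CHANNEL_MM,
    )


# ---------------------------------------------------------------------------
# screw sizing
# ---------------------------------------------------------------------------

def select_length(c: Channel, fraction: float = 0.8, catalog_step: float | None = None) -> float:
    """Insertion depth: ``fraction`` (default 80 %) of the channel length,
    optionally snapped *down* to a hardware catalog step."""
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if c.length <= 0:
        raise ValidationError("channel has non-positive length")
    length = fraction * c.length
    if catalog_step is not None:
        if catalog_step <= 0:
            raise ValidationError("catalog_step must be positive")
        length = np.floor(length / catalog_step) * catalog_step
    return float(length)


def select_diameter(
    c: Channel,
    bone: LabelMap,
    length: float,
    margin: float = 0.0,
    min_diameter: float = 4.0,
    step: float = 0.1,
) -> float:
    """Largest screw diameter that keeps the inserted cylinder inside bone.

    The distance transform gives a warm start: the largest ``r`` such that
    the distance-to-cortex along the inserted segment (excluding the entry
    cap of depth ``r``, where the screw legitimately meets the mouth
    cortex) stays at least ``r + margin``.  Because the interpolated
    distance field under-reads by up to half a voxel near the axis, the
    estimate is then refined in ``step`` increments against the actual
    voxelized-cylinder containment test, which is the defining criterion:
    the screw plus its radial safety shell (diameter + 2 margin) must lie
    inside the bone mask.  Falls below ``min_diameter`` → planning error.
    """
    if length > c.length + 1e-9:
        raise ValidationError(f"inserted length {length} exceeds channel {c.length}")
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    geometry = bone.geometry()
    bone_mask = bone.data > 0
    edt = _bone_distance_field(bone_mask, bone.spacing)

    n = int(np.ceil(length / (min(bone.spacing) / 4.0))) + 1
    ts = np.linspace(0.0, length, n)
    pts = c.entry[None, :] + ts[:, None] * c.axis[None, :]
    edt_vals = np.maximum(_sample_field(edt, pts, geometry) - margin, 0.0)

    r = _max_inscribed_radius(ts, edt_vals, 0.0, length, cap_lo=True, cap_hi=False)
    r = np.floor(r / step) * step  # report on the search grid
    diameter = 2.0 * r

    # refine against voxelized containment: the screw plus its radial
    # safety shell (diameter + 2*margin) must lie inside the bone mask
    def contained(d: float) -> bool:
        mask = voxelize_cylinder(c.entry, c.axis, length, d + 2 * margin, geometry)
        return not np.any(mask & ~bone_mask)

    cap = 2.0 * float(edt_vals.max()) + 2.0
    while diameter >= min_diameter and not contained(diameter):
        diameter -= 2 * step
    if diameter >= min_diameter:
        while diameter + 2 * step <= cap and contained(diameter + 2 * step):
            diameter += 2 * step
    if diameter < min_diameter:
        raise PlanningError(
            f"pedicle too narrow: achievable diameter {diameter:.1f} mm "
            f"< minimum {min_diameter:.1f} mm"
        )
    return float(diameter)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _vertebra_bone(labels: LabelMap, level: str) -> LabelMap:
    """Bone of one vertebra: body + posterior elements + both pedicles
    (facet-joint regions are kept separate for grading)."""
    v = LEVEL_LABELS[level]
    wanted = [v, 10 * v + 1, 10 * v + 2]
    data = np.where(np.isin(labels.data, wanted), labels.data, 0).astype(labels.data.dtype)
    scheme = {k: labels.label_scheme.get(k, f"label_{k}") for k in wanted}
    return LabelMap(data, labels.spacing, labels.origin, scheme)


def plan_screws(
    bone: LabelMap, kps: KeypointSet, cfg: PlannerConfig = PlannerConfig()
) -> tuple[list[ScrewPlan], list[PlanFailure]]:
    """One ScrewPlan per (level, side) keypoint pair.

    Pipeline per screw: trace_channel → select_length → select_diameter →
    compute_angles.  Stage errors become structured :class:`PlanFailure`
    records carrying the (level, side) context; remaining screws still plan.
    """
    plans: list[ScrewPlan] = []
    failures: list[PlanFailure] = []
    for (level, side), pair in kps.items():
        if LEVEL_LABELS[level] not in np.unique(bone.data) and not np.any(
            np.isin(bone.data, [10 * LEVEL_LABELS[level] + 1, 10 * LEVEL_LABELS[level] + 2])
        ):
            failures.append(PlanFailure(level, side, "trace", f"no {level} label in bone map"))
            continue
        vb = _vertebra_bone(bone, level)
        try:
            channel = trace_channel(pair.entry, pair.exit, vb)
            length = select_length(channel, cfg.fraction, cfg.catalog_step)
            diameter = select_diameter(
                channel, vb, length, cfg.margin, cfg.min_diameter, cfg.diameter_step
            )
            pta, psa = compute_angles(channel.axis)
            plans.append(
                ScrewPlan(
                    level=level,
                    side=side,
                    entry=channel.entry,
                    direction=channel.axis,
                    length=length,
                    diameter=diameter,
                    pta=pta,
                    psa=psa,
                )
            )
        except (PlanningError, ValidationError) as e:
            failures.append(PlanFailure(level, side, type(e).__name__, str(e)))
    return plans, failures


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def save_plans(plans, path, failures=()) -> None:
    doc = {
        "plans": [p.to_dict() for p in plans],
        "failures": [f.to_dict() for f in failures],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_plans(path) -> tuple[list[ScrewPlan], list[PlanFailure]]:
    doc = json.loads(Path(path).read_text())
    plans = [ScrewPlan.from_dict(d) for d in doc["plans"]]
    failures = [PlanFailure(**d) for d in doc.get("failures", [])]
    return plans, failures
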