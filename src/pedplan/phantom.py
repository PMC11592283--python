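"""Procedural lumbosacral vertebra phantoms with analytic ground truth.

Each phantom is constructive solid geometry on a voxel grid: the vertebral
body is an elliptic cylinder, the posterior elements a rectangular slab, and
each pedicle an oblique circular cylinder connecting the two along the
bone-screw channel axis (tilted by the pedicle transverse/sagittal angles).
Left/right superior facet regions are thin slabs adjacent to the pedicle
entry zones, labeled separately so facet-violation grading is decidable
without anatomical inference.

Intensities emulate CT: bone voxels draw HU ~ N(700, noise_sd), surrounding
soft tissue ~ N(40, noise_sd), and air is exactly -1000 HU, so the standard
bone window (center 150, width 1500) separates the structures.

Ground truth is analytic: the channel axis, entry point (posterior cortex
mouth), exit point (anterior body cortex along the axis), channel length,
isthmus radius, the per-structure label map, and a reference screw plan per
pedicle (80 % insertion depth, 0.5 mm radial clearance) that grades
Gertzbein-Robbins A and Badu 0 by construction.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from pedplan.errors import ValidationError
from pedplan.geometry import compute_angles, direction_from_angles
from pedplan.imaging import LabelMap, Volume
from pedplan.keypoints import LEVEL_LABELS, LEVELS, KeypointPair, KeypointSet
from pedplan.planner import Channel, ScrewPlan

__all__ = ["LevelGeometry", "PhantomSpec", "GroundTruth", "generate", "make_dataset"]

HU_BONE = 700.0
HU_SOFT = 40.0
HU_AIR = -1000.0
SOFT_TISSUE_RIM_MM = 5.0
REFERENCE_CLEARANCE_MM = 0.5  # radial clearance of reference screws to cortex
LEVEL_PITCH_MM = 34.0  # craniocaudal center-to-center distance of stacked levels


@dataclasses.dataclass(frozen=True)
class LevelGeometry:
    """Geometry of one vertebral level (all lengths in mm, angles in deg)."""

    body_rx: float = 16.0        # lateral semi-axis of the body ellipse
    body_ry: float = 12.0        # anteroposterior semi-axis
    body_height: float = 26.0    # craniocaudal extent of the body
    pedicle_radius: float = 4.0  # isthmus radius of each pedicle
    pedicle_x: float = 12.0      # lateral offset of the pedicle axis at its center
    pta_deg: float = 10.0        # medial (transverse) channel angle
    psa_deg: float = 5.0         # cranial (sagittal) channel angle
    facet_gap: float = 2.0       # clearance between facet slab and channel cylinder
    slab_width: float = 36.0     # posterior-element slab, lateral extent
    slab_depth: float = 10.0     # posterior-element slab, AP extent
    slab_height: float = 22.0    # posterior-element slab, craniocaudal extent
    pedicle_span: float = 15.0   # AP gap bridged by the pedicle (slab front → body back)
    facet_size: tuple[float, float, float] = (8.0, 6.0, 3.0)  # facet slab (x, y, z)

    def validate(self) -> None:
        if self.pedicle_radius < 2.0:
            raise ValidationError(
                f"pedicle isthmus radius must be >= 2 mm (plannable), got {self.pedicle_radius}"
            )
        if min(self.body_rx, self.body_ry) <= self.pedicle_radius:
            raise ValidationError("body radius must exceed pedicle radius")
        if self.pedicle_x <= self.pedicle_radius:
            raise ValidationError("pedicles self-intersect across the midline")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full phantom recipe; identical spec + seed → bit-identical output."""

    levels: Mapping[str, LevelGeometry] = dataclasses.field(
        default_factory=lambda: {"L4": LevelGeometry()}
    )
    shape: tuple[int, int, int] = (48, 60, 36)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 30.0  # HU
    seed: int = 0

    def validate(self) -> None:
        for level, geom in self.levels.items():
            if level not in LEVELS:
                raise ValidationError(f"unknown level {level!r}; expected one of {LEVELS}")
            geom.validate()
        if any(s <= 0 for s in self.spacing) or any(n < 1 for n in self.shape):
            raise ValidationError("shape/spacing must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Analytic ground truth paired with a phantom volume."""

    labelmap: LabelMap
    keypoints: KeypointSet
    channels: dict[tuple[str, str], Channel]
    reference_plans: list[ScrewPlan]


# ---------------------------------------------------------------------------
# analytic channel geometry
# ---------------------------------------------------------------------------

def _channel_geometry(geom: LevelGeometry, side: str, z_center: float):
    """Entry/exit/axis of one channel, from the analytic solids.

    The axis passes through the pedicle center, tilted by (PTA, PSA).  Entry
    is its intersection with the posterior face of the posterior-element
    slab; exit is its intersection with the elliptic body cortex, anterior
    crossing.
    """
    d = direction_from_angles(geom.pta_deg, geom.psa_deg, side)
    sx = -1.0 if side == "left" else 1.0

    body_cy = geom.pedicle_span + geom.body_ry          # body center y
    slab_back = -geom.slab_depth                        # posterior face of the slab
    p_center = np.array([sx * geom.pedicle_x, geom.pedicle_span / 2.0, z_center])
    p_center[1] = geom.pedicle_span / 2.0               # mid-bridge

    t_entry = (slab_back - p_center[1]) / d[1]
    entry = p_center + t_entry * d

    # anterior intersection with ((x)/rx)^2 + ((y - cy)/ry)^2 = 1
    rx, ry = geom.body_rx, geom.body_ry
    ox, oy = p_center[0], p_center[1] - body_cy
    a = (d[0] / rx) ** 2 + (d[1] / ry) ** 2
    b = 2 * (ox * d[0] / rx**2 + oy * d[1] / ry**2)
    c = (ox / rx) ** 2 + (oy / ry) ** 2 - 1.0
    disc = b * b - 4 * a * c
    if disc <= 0:
        raise ValidationError(f"channel on side {side!r} misses the vertebral body")
    t_exit = (-b + math.sqrt(disc)) / (2 * a)
    exit = p_center + t_exit * d
    if abs(exit[2] - z_center) > geom.body_height / 2.0:
        raise ValidationError(f"channel on side {side!r} exits through an endplate")

    length = float(t_exit - t_entry)
    return entry, exit, d, length, p_center


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _grid_axes(spec: PhantomSpec):
    """Voxel-center coordinate axes; x and z centered on 0, y spanning the
    vertebra from behind the posterior slab to past the anterior cortex."""
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    ox = -(nx - 1) / 2.0 * sx
    geoms = list(spec.levels.values())
    max_depth = max(g.slab_depth for g in geoms)
    oy = -(max_depth + 4.0)
    n_levels = len(spec.levels)
    z_extent = (nz - 1) * sz
    oz = -z_extent / 2.0
    origin = (ox, oy, oz)
    xs = ox + sx * np.arange(nx)
    ys = oy + sy * np.arange(ny)
    zs = oz + sz * np.arange(nz)
    return origin, xs, ys, zs


def _level_z_centers(levels: Sequence[str]) -> dict[str, float]:
    n = len(levels)
    # stack cranial→caudal along z (higher level = more superior = larger z)
    order = sorted(levels, key=lambda lv: LEVEL_LABELS[lv])
    zs = {}
    for i, lv in enumerate(order):
        zs[lv] = (n - 1) / 2.0 * LEVEL_PITCH_MM - i * LEVEL_PITCH_MM
    return zs


def generate(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Build one phantom volume (HU) and its analytic ground truth."""
    spec.validate()
    origin, xs, ys, zs = _grid_axes(spec)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    labels = np.zeros(spec.shape, dtype=np.int16)
    scheme: dict[int, str] = {}
    keypairs: dict[tuple[str, str], KeypointPair] = {}
    channels: dict[tuple[str, str], Channel] = {}
    plans: list[ScrewPlan] = []

    z_centers = _level_z_centers(list(spec.levels))
    for level, geom in spec.levels.items():
        v = LEVEL_LABELS[level]
        zc = z_centers[level]
        body_cy = geom.pedicle_span + geom.body_ry

        body = (
            ((X / geom.body_rx) ** 2 + ((Y - body_cy) / geom.body_ry) ** 2 <= 1.0)
            & (np.abs(Z - zc) <= geom.body_height / 2.0)
        )
        slab = (
            (np.abs(X) <= geom.slab_width / 2.0)
            & (Y >= -geom.slab_depth)
            & (Y <= 0.0)
            & (np.abs(Z - zc) <= geom.slab_height / 2.0)
        )
        main = body | slab
        scheme[v] = level

        for si, side in enumerate(("left", "right")):
            entry, exit, d, length, _ = _channel_geometry(geom, side, zc)
            VX, VY, VZ = X - entry[0], Y - entry[1], Z - entry[2]
            t = VX * d[0] + VY * d[1] + VZ * d[2]
            r2 = VX**2 + VY**2 + VZ**2 - t**2
            ped_cyl = (r2 <= geom.pedicle_radius**2) & (t >= 0.0) & (t <= length)
            bridge = ped_cyl & ~main
            sub = 10 * v + 1 + si
            labels[bridge & (labels == 0)] = sub
            scheme[sub] = f"{level}_{side}_pedicle"
            main |= ped_cyl

            # superior facet region: thin slab riding above the channel mouth
            fx, fy, fz = geom.facet_size
            f_cz = entry[2] + geom.pedicle_radius + geom.facet_gap + fz / 2.0
            facet = (
                (np.abs(X - entry[0]) <= fx / 2.0)
                & (Y >= -geom.slab_depth)
                & (Y <= -geom.slab_depth + fy)
                & (np.abs(Z - f_cz) <= fz / 2.0)
            )
            fsub = 10 * v + 3 + si
            labels[facet & (labels == 0)] = fsub
            scheme[fsub] = f"{level}_{side}_superior_facet"

            pta, psa = compute_angles(d)
            keypairs[(level, side)] = KeypointPair(entry, exit)
            channels[(level, side)] = Channel(
                entry=entry,
                exit=exit,
                axis=d,
                length=length,
                isthmus_radius=geom.pedicle_radius,
            )
            plans.append(
                ScrewPlan(
                    level=level,
                    side=side,
                    entry=entry,
                    direction=d,
                    length=0.8 * length,
                    diameter=2.0 * (geom.pedicle_radius - REFERENCE_CLEARANCE_MM),
                    pta=pta,
                    psa=psa,
                )
            )

        labels[main & (labels == 0)] = v

    bone = labels > 0
    rng = np.random.default_rng(spec.seed)
    hu = np.full(spec.shape, HU_AIR, dtype=np.float32)
    # soft-tissue rim: everything within a few mm of bone
    dist_to_bone = ndimage.distance_transform_edt(~bone, sampling=spec.spacing)
    soft = (~bone) & (dist_to_bone <= SOFT_TISSUE_RIM_MM)
    hu[soft] = HU_SOFT + spec.noise_sd * rng.standard_normal(int(soft.sum())).astype(np.float32)
    hu[bone] = HU_BONE + spec.noise_sd * rng.standard_normal(int(bone.sum())).astype(np.float32)

    volume = Volume(hu, spec.spacing, origin)
    labelmap = LabelMap(labels, spec.spacing, origin, scheme)
    truth = GroundTruth(
        labelmap=labelmap,
        keypoints=KeypointSet(keypairs),
        channels=channels,
        reference_plans=plans,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# randomized datasets
# ---------------------------------------------------------------------------

#: parameter intervals accepted by make_dataset, with realistic defaults
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "body_rx": (14.0, 18.0),
    "body_ry": (10.5, 13.5),
    "body_height": (24.0, 28.0),
    "pedicle_radius": (3.0, 5.0),
    "pedicle_x": (10.0, 13.0),
    "pta_deg": (5.0, 15.0),
    "psa_deg": (-5.0, 8.0),
    "facet_gap": (1.5, 3.0),
}


def make_dataset(
    n: int,
    spec_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    levels: Sequence[str] = ("L4",),
    shape: tuple[int, int, int] = (48, 60, 36),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sd: float = 30.0,
) -> list[tuple[Volume, GroundTruth]]:
    """``n`` phantoms with geometry drawn uniformly from ``spec_ranges``.

    Reproducible: the same arguments and seed give element-wise identical
    datasets.
    """
    if n < 1:
        raise ValidationError(f"dataset size must be >= 1, got {n}")
    ranges = dict(DEFAULT_RANGES)
    if spec_ranges:
        unknown = set(spec_ranges) - set(DEFAULT_RANGES)
        if unknown:
            raise ValidationError(f"unknown spec_ranges keys: {sorted(unknown)}")
        ranges.update({k: tuple(v) for k, v in spec_ranges.items()})
    for k, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValidationError(f"empty range for {k!r}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        params = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        geom = LevelGeometry(**params)
        spec = PhantomSpec(
            levels={lv: geom for lv in levels},
            shape=shape,
            spacing=spacing,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate(spec))
    return out
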