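"""Shared geometric primitives: screw-axis angles and cylinder voxelization.

Angle conventions (surgical standard, RAS+ axes):

* PTA (pedicle transverse angle): unsigned angle, in degrees, between the
  axial-plane (x-y) projection of the screw axis and the anteroposterior
  (+y) axis.  A perfectly anteroposterior screw has PTA 0.
* PSA (pedicle sagittal angle): signed angle between the screw axis and the
  axial plane; positive = cranial (toward +z).
"""

from __future__ import annotations

import math

import numpy as np

from pedplan.errors import ValidationError
from pedplan.imaging import Volume

__all__ = ["compute_angles", "direction_from_angles", "voxelize_cylinder"]


def compute_angles(direction) -> tuple[float, float]:
    """(PTA, PSA) in degrees for a unit screw-axis ``direction``.

    If the axis is perpendicular to the axial plane the transverse angle is
    undefined; it is flagged by returning ``nan`` for PTA.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if not math.isclose(n, 1.0, abs_tol=1e-6):
        raise ValidationError(f"direction must be a unit vector, |d| = {n:.6g}")
    dx, dy, dz = d
    psa = math.degrees(math.asin(max(-1.0, min(1.0, dz))))
    proj = math.hypot(dx, dy)
    if proj < 1e-9:
        return float("nan"), psa  # PTA undefined: axis ⟂ axial plane
    pta = math.degrees(math.atan2(abs(dx), dy))
    return pta, psa


def direction_from_angles(pta_deg: float, psa_deg: float, side: str) -> np.ndarray:
    """Unit screw axis with the given angles, pointing anteriorly (+y).

    ``side`` ("left"/"right") fixes the medial tilt: a left-side screw
    (entry at x < 0) converges toward +x, a right-side screw toward -x.
    """
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    th = math.radians(pta_deg)
    ps = math.radians(psa_deg)
    sx = 1.0 if side == "left" else -1.0
    d = np.array(
        [sx * math.sin(th) * math.cos(ps), math.cos(th) * math.cos(ps), math.sin(ps)]
    )
    return d / np.linalg.norm(d)


def voxelize_cylinder(
    entry, direction, length: float, diameter: float, geometry: Volume
) -> np.ndarray:
    """Binary mask of a capped cylinder on the grid of ``geometry``.

    A voxel is included iff its *center* lies inside the cylinder whose axis
    runs from ``entry`` (mm) a distance ``length`` along the unit vector
    ``direction``, with radius ``diameter / 2``.
    """
    if length <= 0 or diameter <= 0:
        raise ValidationError(f"need positive length/diameter, got {length}/{diameter}")
    entry = np.asarray(entry, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    spacing = np.asarray(geometry.spacing)
    origin = np.asarray(geometry.origin)
    shape = np.asarray(geometry.shape)

    # bounding box of the cylinder, padded by its radius
    ends = np.stack([entry, entry + length * d])
    lo = ends.min(axis=0) - diameter / 2
    hi = ends.max(axis=0) + diameter / 2
    i_lo = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    i_hi = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, shape)
    mask = np.zeros(geometry.shape, dtype=bool)
    if np.any(i_lo >= i_hi):
        return mask  # wholly outside the grid

    ax = [origin[k] + spacing[k] * np.arange(i_lo[k], i_hi[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    vx, vy, vz = X - entry[0], Y - entry[1], Z - entry[2]
    t = vx * d[0] + vy * d[1] + vz * d[2]
    r2 = vx * vx + vy * vy + vz * vz - t * t
    inside = (t >= 0) & (t <= length) & (r2 <= (diameter / 2) ** 2 + 1e-12)
    mask[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]] = inside

    if diameter < float(np.linalg.norm(spacing)):
        # degenerate thin screw: guarantee a 1-voxel chain along the axis
        # (voxel centers may all miss a sub-voxel-diameter cylinder)
        n_steps = max(2, int(np.ceil(length / (spacing.min() / 4))))
        ts = np.linspace(0.0, length, n_steps)
        pts = entry[None, :] + ts[:, None] * d[None, :]
        idx = np.rint((pts - origin) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask
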