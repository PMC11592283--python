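"""Screw voxelization, overlap Dice, deviations, GR and Badu grading."""

import numpy as np
import pytest

from pedplan.errors import ValidationError
from pedplan.geometry import voxelize_cylinder
from pedplan.grading import (
    badu_grade,
    cohort_report,
    deviations,
    gr_grade,
    screw_dice,
    voxelize_screw,
)
from pedplan.imaging import LabelMap, Volume
from pedplan.planner import ScrewPlan


def grid(n=60, spacing=1.0, origin=None):
    if origin is None:
        origin = (-(n - 1) / 2 * spacing,) * 3
    return Volume(np.zeros((n, n, n), dtype=np.float32), (spacing,) * 3, origin)


def plan(entry=(0, -20, 0), direction=(0, 1, 0), length=40.0, diameter=8.0,
         level="L4", side="left"):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    from pedplan.geometry import compute_angles

    pta, psa = compute_angles(d)
    return ScrewPlan(level, side, np.asarray(entry, float), d, length, diameter, pta, psa)


class TestVoxelizeScrew:
    def test_cylinder_volume_matches_analytic(self):
        g = grid()
        mask = voxelize_screw(plan(), g)
        analytic = np.pi * 4.0**2 * 40.0
        assert mask.sum() == pytest.approx(analytic, rel=0.05)

    def test_subvoxel_diameter_gives_axis_chain(self):
        g = grid()
        mask = voxelize_screw(plan(diameter=0.5), g)
        assert mask.sum() >= 40  # a contiguous 1-voxel chain along the axis
        xs, ys, zs = np.nonzero(mask)
        assert len(np.unique(xs)) <= 2 and len(np.unique(zs)) <= 2

    def test_identical_plans_identical_masks(self):
        g = grid()
        np.testing.assert_array_equal(voxelize_screw(plan(), g), voxelize_screw(plan(), g))

    def test_offgrid_screw_warns_and_is_empty(self):
        g = grid(n=10, origin=(0, 0, 0))
        with pytest.warns(UserWarning):
            mask = voxelize_screw(plan(entry=(500, 500, 500)), g)
        assert not mask.any()


class TestScrewDice:
    def test_identical_plans_dice_one(self):
        assert screw_dice(plan(), plan(), grid()) == 1.0

    def test_displaced_beyond_length_dice_zero(self):
        a = plan()
        b = plan(entry=(20, -20, 0))
        assert screw_dice(a, b, grid()) == 0.0

    def test_coaxial_half_length_matches_closed_form(self):
        # coaxial screws, equal diameter, lengths L and L/2 sharing the entry:
        # Dice = 2*(L/2) / (L + L/2) = 2/3
        a = plan(length=40.0)
        b = plan(length=20.0)
        assert screw_dice(a, b, grid()) == pytest.approx(2 / 3, rel=0.03)


class TestDeviations:
    def test_identical_plans_zero_deviation(self):
        d = deviations(plan(), plan(), grid())
        assert (d.d_pta, d.d_psa, d.d_length, d.d_diameter) == (0, 0, 0, 0)
        assert d.screw_dice == 1.0

    def test_angle_and_length_deltas(self):
        a = plan(direction=(np.sin(np.radians(10)), np.cos(np.radians(10)), 0), length=46.0)
        r = plan(direction=(np.sin(np.radians(11.5)), np.cos(np.radians(11.5)), 0), length=50.0)
        d = deviations(a, r, grid())
        assert d.d_pta == pytest.approx(1.5, abs=1e-6)
        assert d.d_length == pytest.approx(-4.0)

    def test_level_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            deviations(plan(level="L4"), plan(level="L5"), grid())


def slab_bone(n=61, spacing=1.0):
    """Bone occupying the half-space y <= 0 on a voxel-center-aligned grid.

    With odd n the voxel centers sit on integer coordinates, so constructed
    breach depths land exactly on voxel centers and the center-to-center
    distance transform reproduces them.
    """
    g = grid(n, spacing)
    ys = np.asarray(g.origin)[1] + spacing * np.arange(n)
    bone = np.zeros((n, n, n), dtype=bool)
    bone[:, ys <= 0, :] = True
    return g, bone


class TestGRGrade:
    def test_fully_contained_screw_is_grade_a(self):
        g, bone = slab_bone()
        screw = voxelize_cylinder((0, -30, 0), (0, 1, 0), 25.0, 6.0, g)
        assert gr_grade(screw, bone, (0, 1, 0), side="left") == ("A", 0.0, "none")

    @pytest.mark.parametrize(
        "depth,expected", [(1.5, "B"), (3.0, "C"), (5.0, "D"), (6.0, "E"), (2.0, "C")]
    )
    def test_constructed_breach_depths(self, depth, expected):
        # screw along y crossing the planar cortex at y=0 by `depth` mm:
        # analytic max breach depth equals the overshoot past the surface
        g, bone = slab_bone()
        screw = voxelize_cylinder((0, -30, 0), (0, 1, 0), 30.0 + depth, 6.0, g)
        grade, breach, direction = gr_grade(screw, bone, (0, 1, 0), side="left")
        assert grade == expected
        assert breach == pytest.approx(depth, abs=0.8)

    def test_deeper_breach_never_lowers_grade(self):
        g, bone = slab_bone()
        order = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4}
        grades = []
        for depth in (0.0, 1.0, 2.5, 4.5, 7.0):
            screw = voxelize_cylinder((0, -30, 0), (0, 1, 0), 30.0 + depth, 6.0, g)
            grades.append(order[gr_grade(screw, bone, (0, 1, 0), side="left")[0]])
        assert grades == sorted(grades)

    def test_medial_breach_direction(self):
        # left-side screw (medial = +x) inside a bone tube whose medial wall
        # is shaved off: the breach centroid lies medial to the axis
        g = grid(61)
        bone = voxelize_cylinder((0, -30, 0), (0, 1, 0), 60.0, 20.0, g)
        xs = np.arange(61) * 1.0 + g.origin[0]
        bone[xs > 2.0, :, :] = False
        screw = voxelize_cylinder((0, -30, 0), (0, 1, 0), 50.0, 8.0, g)
        grade, breach, direction = gr_grade(screw, bone, (0, 1, 0), side="left")
        assert grade != "A"
        assert direction == "medial"

    def test_empty_screw_rejected(self):
        g, bone = slab_bone()
        with pytest.raises(ValidationError):
            gr_grade(np.zeros_like(bone), bone, (0, 1, 0))


def facet_slab(g, y0=0.0, y1=3.0, half=6.0):
    """Facet region: slab y in [y0, y1], |x|,|z| <= half."""
    n = g.shape[0]
    ax = np.asarray(g.origin)[0] + np.arange(n) * g.spacing[0]
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (Y >= y0) & (Y <= y1) & (np.abs(X) <= half) & (np.abs(Z) <= half)


class TestBaduGrade:
    def test_clear_screw_grade_zero(self):
        g = grid(61)
        facet = facet_slab(g, y0=1.0, y1=4.0)
        screw = voxelize_cylinder((0, -30, 0), (0, 1, 0), 25.0, 6.0, g)  # ends 5 mm short
        badu, pen = badu_grade(screw, facet, axis=(0, 1, 0))
        assert (badu, pen) == (0, 0.0)

    def test_abutting_screw_grade_one(self):
        g = grid(61)
        facet = facet_slab(g, y0=1.0, y1=4.0)
        # screw tip in the voxel row adjacent to the facet face: contact
        screw = voxelize_cylinder((0, -30, 0), (0, 1, 0), 30.5, 6.0, g)
        badu, pen = badu_grade(screw, facet, axis=(0, 1, 0))
        assert (badu, pen) == (1, 0.0)

    def test_shallow_invasion_grade_two(self):
        g = grid(spacing=0.5, n=101)
        facet = facet_slab(g, y0=0.5, y1=3.5)
        screw = voxelize_cylinder((0, -20, 0), (0, 1, 0), 21.3, 6.0, g)  # 0.8 mm in
        badu, pen = badu_grade(screw, facet, axis=(0, 1, 0), spacing=(0.5,) * 3)
        assert badu == 2
        assert 0 < pen <= 1.0

    def test_transfixion_grade_three(self):
        g = grid(61)
        facet = facet_slab(g, y0=1.0, y1=4.0)
        screw = voxelize_cylinder((0, -30, 0), (0, 1, 0), 45.0, 6.0, g)  # through and past
        badu, pen = badu_grade(screw, facet, axis=(0, 1, 0))
        assert badu == 3

    def test_empty_facet_rejected(self):
        g = grid()
        screw = voxelize_cylinder((0, -30, 0), (0, 1, 0), 20.0, 6.0, g)
        with pytest.raises(ValidationError):
            badu_grade(screw, np.zeros_like(screw))

    def test_irrelevant_relabeling_invariance(self):
        # grading depends only on the facet/bone masks, not other labels
        g = grid()
        facet = facet_slab(g)
        screw = voxelize_cylinder((0, -30, 0), (0, 1, 0), 20.0, 6.0, g)
        lm1 = LabelMap(facet.astype(np.int16) * 43, g.spacing, g.origin, {43: "f"})
        lm2 = LabelMap(facet.astype(np.int16) * 53, g.spacing, g.origin, {53: "f"})
        assert badu_grade(screw, lm1.mask([43]).astype(bool)) == badu_grade(
            screw, lm2.mask([53]).astype(bool)
        )


class TestCohortReport:
    def test_identical_cohort_all_grade_a_zero_deviation(self, default_phantom):
        _, gt = default_phantom
        refs = gt.reference_plans
        df, summary = cohort_report([refs], [refs], [gt.labelmap])
        assert summary["gr_percent"]["A"] == 100.0
        assert summary["badu_percent"][0] == 100.0
        assert summary["d_pta_mean"] == 0.0
        assert (df["dice"] == 1.0).all()

    def test_percentages_sum_to_100(self, default_phantom):
        _, gt = default_phantom
        refs = gt.reference_plans
        df, summary = cohort_report([refs], [refs], [gt.labelmap])
        assert sum(summary["gr_percent"].values()) == pytest.approx(100.0)
        assert sum(summary["badu_percent"].values()) == pytest.approx(100.0)

    def test_mean_matches_rows(self, default_phantom):
        _, gt = default_phantom
        refs = gt.reference_plans
        shifted = [
            ScrewPlan(p.level, p.side, p.entry, p.direction, p.length - 2.0,
                      p.diameter, p.pta, p.psa)
            for p in refs
        ]
        df, summary = cohort_report([shifted], [refs], [gt.labelmap])
        assert summary["d_length_mean"] == pytest.approx(df["d_length"].mean())

    def test_unmatched_screws_reported(self, default_phantom):
        _, gt = default_phantom
        refs = gt.reference_plans
        df, _ = cohort_report([refs[:1]], [refs], [gt.labelmap])
        assert (~df["matched"]).sum() == len(refs) - 1
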