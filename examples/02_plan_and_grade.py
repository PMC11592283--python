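"""Plan screws geometrically from ground-truth keypoints and grade them.

Runs the planner (channel tracing, 80 % insertion depth, cortex-constrained
maximal diameter, trajectory angles) on a phantom's true entry/exit points,
then grades the plans against the phantom's reference screws: size/angle
deviations, screw-overlap Dice, Gertzbein-Robbins breach class, and Badu
facet-violation class.  On clean keypoints every screw should grade A / 0.
"""

from pedplan import PhantomSpec, generate, plan_screws
from pedplan.grading import cohort_report

_, truth = generate(PhantomSpec(seed=7))
plans, failures = plan_screws(truth.labelmap, truth.keypoints)
print(f"planned {len(plans)} screws, {len(failures)} failures")
for p in plans:
    print(f"  {p.level} {p.side:5s}: length {p.length:.1f} mm, "
          f"diameter {p.diameter:.1f} mm, PTA {p.pta:.1f}, PSA {p.psa:.1f}")

rows, summary = cohort_report([plans], [truth.reference_plans], [truth.labelmap])
print(rows[["level", "side", "d_length", "d_diameter", "dice", "gr", "badu"]])
print(f"GR-A: {summary['gr_percent']['A']:.1f}%  Badu-0: {summary['badu_percent'][0]:.1f}%")
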