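"""Generate a lumbosacral vertebra phantom and inspect its ground truth.

Builds one L4 phantom on a 1 mm grid, prints the analytic bone-screw
channels (entry/exit points, length, isthmus radius) and the reference
screw plans derived from them.  Channel length times 0.8 is the reference
insertion depth; the isthmus radius bounds the achievable screw radius.
"""

import numpy as np

from pedplan import PhantomSpec, generate, window_hu

volume, truth = generate(PhantomSpec(seed=42))
print(f"volume: shape {volume.shape}, spacing {volume.spacing} mm")

windowed = window_hu(volume)  # center 150 HU, width 1500 HU
bone = truth.labelmap.data > 0
print(f"windowed intensity: bone mean {windowed.data[bone].mean():.2f}, "
      f"background mean {windowed.data[~bone].mean():.2f}")

for (level, side), ch in sorted(truth.channels.items()):
    print(f"{level} {side:5s}: entry {np.round(ch.entry, 1)} mm -> "
          f"exit {np.round(ch.exit, 1)} mm, length {ch.length:.1f} mm, "
          f"isthmus radius {ch.isthmus_radius:.1f} mm")

for plan in truth.reference_plans:
    print(f"reference screw {plan.level} {plan.side:5s}: "
          f"length {plan.length:.1f} mm, diameter {plan.diameter:.1f} mm, "
          f"PTA {plan.pta:.1f} deg, PSA {plan.psa:.1f} deg")
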