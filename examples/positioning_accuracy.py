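"""Positioning repeatability from repeated photographs of the printed target.

Renders 40 images of the 1 mm red disc with Gaussian positioning jitter
(σ = 4 µm), detects the disc's centre of mass in each, and summarises the
deviations from the series mean against the 8 µm optical-resolution
criterion.
"""

import numpy as np

from octbiofilm import accuracy_report, com_deviations, detect_target, synth_target_image

rng = np.random.default_rng(0)
records = []
for i in range(40):
    jitter = tuple(rng.normal(0.0, 4.0, size=2))
    img, _ = synth_target_image(jitter, dust=3, seed=100 + i)
    records.append(detect_target(img, image_id=f"img{i:03d}"))

dev = com_deviations(records)
rep = accuracy_report(dev, tolerance=8.0)

for axis in ("x", "y"):
    s = dev.summary[axis]
    print(
        f"Δ{axis}: sd={s['sd']:.2f} µm  median={s['median']:.2f}  "
        f"range=[{s['min']:.1f}, {s['max']:.1f}]  outliers(1.5·IQR)={s['n_outliers']}"
    )
print(
    f"within ±{rep.tolerance_um:g} µm: x={rep.fraction_within_x:.0%} "
    f"y={rep.fraction_within_y:.0%}  -> {'PASS' if rep.passed else 'FAIL'}"
)
print(
    "\nThe SD per axis estimates the true positioning jitter; the run passes\n"
    "when at least 75% of movements stay within the optical resolution."
)
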