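"""Run a single AIZE test on one synthetic glaucomatous field.

Generates a moderately damaged field, simulates a complete threshold test
with a 9% FP / 9% FN observer, and prints the speed and accuracy of the
result: total stimulus presentations (test length) and RMSE between the
estimated and true sensitivities (accuracy, dB).
"""

import numpy as np

from aize import (
    NormativeModel,
    ObserverConfig,
    ScotomaSpec,
    build_24_2,
    generate_glaucoma_field,
    preset,
    run_trial,
    trial_rmse,
)

grid = build_24_2("right")
rng = np.random.default_rng(7)
field = generate_glaucoma_field(NormativeModel(), ScotomaSpec(), target_md=-8.0, rng=rng)
print(f"true field: MD {field.md:.2f} dB, "
      f"range {field.sensitivity.min():.0f}..{field.sensitivity.max():.0f} dB")

cfg = preset("aize")
observer = ObserverConfig(fp=0.09, fn=0.09)
result = run_trial(field, grid, cfg, observer, seed=42)

print(f"total presentations: {result.total_presentations} "
      f"(of which {result.verification_presentations.sum()} verification retests)")
print(f"presentations per location: min {result.presentations.min()}, "
      f"max {result.presentations.max()}")
print(f"RMSE vs truth: {trial_rmse(result.estimates, field, grid):.2f} dB")

# a few locations in detail: estimate vs truth
print("\n  x    y   true  estimate")
for loc in list(grid)[::9]:
    print(f"{loc.x:4.0f} {loc.y:4.0f} {field.sensitivity[loc.index]:6.1f} "
          f"{result.estimates[loc.index]:8.1f}")
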