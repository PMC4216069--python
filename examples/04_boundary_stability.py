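"""Boundary stability across monthly repartitions.

Re-clusters each month of a scene independently at fixed k and maps how
often every grid cell sits on a boundary between provinces.  Stable
borders score near 100%; open-ocean interiors score near 0%.
"""

import numpy as np

from bioregion import (build_stack, log_depth, log_transform,
                       make_planted_scene, make_province_scene, stability)

spec = make_planted_scene(3, seed=7, n_months=24)
fields, truth = make_province_scene(spec)

monthly_stacks = []
for t in fields["sst"].times:
    features = {
        "sst": fields["sst"],
        "chl": log_transform(fields["chl"]),
        "bathymetry": log_depth(fields["bathymetry"]),
    }
    monthly_stacks.append(
        build_stack(features, "classical", "single_month", month=t))

stab = stability(monthly_stacks, k=3, seed=0)
pct = stab.percentage
finite = pct[np.isfinite(pct)]
print(f"stability over {stab.n_months} monthly repartitions:")
print(f"  never a boundary: {np.mean(finite == 0) * 100:.0f}% of cells")
print(f"  boundary in every month: {np.mean(finite == 100) * 100:.0f}% "
      f"of cells")
print(f"  mean stability on boundary cells: "
      f"{finite[finite > 0].mean():.0f}%")
print("With time-invariant province means and moderate noise the same "
      "borders reappear every month, so the boundary network is sharp; "
      "noisier features would smear it.")
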