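"""Segment one disc from landmarks and quantify its enhancement.

Six operator points (A, B, C on each endplate border) define the disc:
five stacked layer ROIs (endplate zones, peripheral bands, central disc,
each fifth of the local thickness) plus a 6-pixel subchondral bone band
above and below, separated by a 1-pixel gap.
"""

import numpy as np

from discdiff import (LandmarkSet, build_disc_rois, estimate_disc_height,
                      compute_enhancement, PhantomConfig, DiscSpec,
                      solve_disc_diffusion, render_series)
from dataclasses import replace

# a gently tilted disc, landmarks in (row, col) pixel coordinates
lms = LandmarkSet(
    disc_id="L4L5",
    upper=np.array([[40.0, 10.0], [39.2, 30.0], [41.0, 52.0]]),
    lower=np.array([[52.0, 10.0], [52.6, 30.0], [53.0, 52.0]]),
    pixel_spacing=0.83,
)
print(f"disc height: {estimate_disc_height(lms):.2f} mm")

rois = build_disc_rois(lms, (96, 96))
for name, mask in rois.masks.items():
    print(f"  {name:<17} {int(mask.sum()):4d} px")

# quantify a rendered noise-free phantom disc via the same route
cfg = replace(PhantomConfig(), noise_sd=0.0)
spec = DiscSpec(height_mm=10.0)
field = solve_disc_diffusion(spec, cfg.kinetics, cfg.time_points)
series, truth = render_series(replace(cfg, discs=(spec,)),
                              {"d0": field}, cfg.kinetics)
table = compute_enhancement(series["d0"],
                            build_disc_rois(truth["d0"].landmarks,
                                            cfg.grid_shape))
print("\nenhancement (signal units, post minus pre) per ROI:")
wide = table.pivot(index="roi", columns="time", values="enhancement")
order = ["POST_5MIN", "POST_10MIN", "POST_2H", "POST_4H", "POST_6H"]
print(wide[order].round(1))
# Subchondral bone peaks at 5 min and decays with the blood pool; the
# endplate zone peaks at 2 h; the central disc fills last, peaking at 6 h.
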