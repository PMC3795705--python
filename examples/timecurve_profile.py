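"""The enhancement-over-time profile of the default noise-free disc.

Contrast agent appears in the vertebral blood pool within minutes, is
handed across the endplates, and diffuses toward the disc centre over
hours — the central region stays essentially empty for the first ten
minutes and peaks six hours after injection.
"""

from discdiff.validation import timecurve_shape_summary

s = timecurve_shape_summary()
labels = ("5 min", "10 min", "2 h", "4 h", "6 h")
print(f"{'time':>8} {'SCB':>8} {'EPZ':>8} {'Central':>8}")
for i, lab in enumerate(labels):
    print(f"{lab:>8} {s['scb'][i]:8.1f} {s['epz'][i]:8.1f} "
          f"{s['central'][i]:8.1f}")
print()
print("SCB strictly decreasing:", s["scb_strictly_decreasing"])
print("EPZ peak:", s["epz_peak"], "| central peak:", s["central_peak"])
print(f"central early/late fraction: {s['central_early_fraction']:.2e} "
      "(the centre is effectively agent-free at 5-10 min)")
print(f"central enhancement at 6 h: {s['central_6h']:.1f} signal units")
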