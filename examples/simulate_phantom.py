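"""Generate a small synthetic cohort and look at what it contains.

Each synthetic subject carries one lumbar disc imaged at six time points
(PRE plus 5 min, 10 min, 2 h, 4 h, 6 h post-injection) and one T2 slice,
with known degeneration grade, Modic status, geometry and kinetics.
"""

from discdiff import PhantomConfig, generate_cohort

cohort = generate_cohort(PhantomConfig(), n_discs=12, seed=42)

meta = cohort.metadata
print("cohort metadata (first rows):")
print(meta[["disc_id", "pfirrmann", "height_mm", "hydration",
            "mc_upper", "mc_lower", "irregular"]].head(8).round(2))
print()
print("grade counts:", meta["pfirrmann"].value_counts().sort_index().to_dict())
print("discs with Modic changes:",
      int(((meta["mc_upper"] != "0") | (meta["mc_lower"] != "0")).sum()))

d0 = cohort.disc_ids[0]
series = cohort.series[d0]
print(f"\n{d0}: images {sorted(series.images)} "
      f"shape {series.images['PRE'].shape}, "
      f"pixel spacing {series.pixel_spacing} mm")
print("Mean PRE intensity inside the true central ROI:",
      round(float(series.images['PRE'][
          cohort.ground_truth[d0].masks['Central']].mean()), 1),
      "(baseline 99 plus noise)")
# Higher Pfirrmann grades get thinner, drier discs; Modic-change discs
# carry a perfusion source, which the cohort statistics should recover.
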