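"""Run the full statistical battery on a 120-disc synthetic cohort.

The generator plants two effects: central enhancement decreases with
disc height (longer diffusion path), and Modic-change discs carry a
perfusion source (vascularization) that shows up from the 10-minute scan
onward.  The battery should recover both and nothing else.
"""

import pandas as pd

from discdiff import PhantomConfig, generate_cohort, run_paper_analyses
from discdiff.validation import cohort_enhancement_table

cohort = generate_cohort(PhantomConfig(), n_discs=120, seed=7,
                         height_distribution="uniform")
table, quant = cohort_enhancement_table(cohort)
report = run_paper_analyses(table, quant, cohort.metadata)

t = report.tests
height = t[(t["name"] == "enhancement vs height_mm (all discs)")]
print("Spearman height vs central enhancement:")
print(height[["time", "statistic", "p", "significant"]]
      .rename(columns={"statistic": "rho"}).round(4).to_string(index=False))

print("\nModic-change discs vs rest (rank-sum):")
mc = t[t["family"] == "mc_any"]
print(mc[["time", "p", "significant"]].round(4).to_string(index=False))

print("\nANOVA (height/defect/MC/grade model):")
an = report.anova
print(an[an["model"] == "grade"][["time", "variable", "F", "p"]]
      .round(3).to_string(index=False))
# Disc height should dominate every model; the Modic effect is absent at
# 5 min and strong afterwards; age never reaches significance.
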