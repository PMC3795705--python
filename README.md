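# discdiff

Quantitative analysis of gadolinium transport into lumbar intervertebral
discs from serial post-contrast MRI — plus a synthetic phantom that makes
the whole pipeline testable without patient data.

The intervertebral disc is the largest avascular structure in the body:
its cells live on nutrients that cross the vertebral endplates and then
diffuse toward the disc centre. Serial T1-weighted imaging after
injection of a gadolinium contrast agent turns this transport into a
measurable signal: the agent peaks in vertebral blood within minutes,
crosses the endplates over the first hours, and reaches the disc centre
only around six hours after injection. `discdiff` implements the full
measurement chain for researchers studying disc nutrition and
degeneration:

* **phantom** — synthetic sagittal spine slices with known geometry,
  contrast kinetics (blood pool C_b(t) = A(e^(−t/τe) − e^(−t/τa)),
  1-D Robin-boundary diffusion ∂c/∂t = D∂²c/∂x² + v(C_b − c) through
  the disc), per-disc degeneration/Modic/defect status, and Gaussian
  image noise — with full ground truth.
* **segmentation** — landmark-based layered ROIs: from three operator
  points per endplate border, five stacked disc layers (endplate zones,
  peripheral bands, central disc; each boundary band 1/5 of the local
  thickness) plus 6-pixel subchondral bone bands; disc height
  estimation; exclusion rules (height ≤ 3 mm, spondylolisthesis).
* **quantification** — per-ROI enhancement E = mean(post) − mean(pre)
  at each time point, and the CSF-adjusted T2 signal intensity
  (disc mean / CSF reference mean) as a hydration index.
* **stats** — the cohort battery: Wilcoxon rank-sum (exact permutation
  p for small samples), Kruskal–Wallis with Dunn's multiple
  comparisons, Spearman correlations, Type-III univariate ANOVA
  models, Shapiro–Wilk gate, one-sample t noise analysis.
* **pipeline / CLI** — `discdiff simulate|segment|quantify|analyze|run|
  fixtures` tying the stages into one seeded, manifest-tracked run.

## A worked example

```python
from discdiff import PhantomConfig, generate_cohort, run_paper_analyses
from discdiff.validation import cohort_enhancement_table

cohort = generate_cohort(PhantomConfig(), n_discs=120, seed=7,
                         height_distribution="uniform")
table, quant = cohort_enhancement_table(cohort)
report = run_paper_analyses(table, quant, cohort.metadata)

t = report.tests
print(t[t["name"] == "enhancement vs height_mm (all discs)"]
      [["time", "statistic", "p"]].round(4))
```

prints the Spearman correlation of disc height with central-disc
enhancement at each post-contrast time point:

```
      time  statistic      p
 POST_5MIN     0.1042 0.2573
POST_10MIN     0.1224 0.1829
   POST_2H    -0.4177 0.0000
   POST_4H    -0.6317 0.0000
   POST_6H    -0.5958 0.0000
```

No correlation exists at 5–10 minutes (the agent has not reached the
disc centre yet; the values are noise), and from 2 h on taller discs
enhance systematically less — the diffusion path from endplate to
centre is longer. The same report contains the Modic-change group
tests (significant from the 10-minute scan onward, a vascularization
signature), the per-grade Kruskal–Wallis/Dunn comparisons, and the
multivariable ANOVA models in `report.anova`, where disc height is the
dominant determinant of central enhancement at every late time point.

The `examples/` directory holds short narrative scripts, one per
capability: `simulate_phantom.py`, `segment_and_measure.py`,
`timecurve_profile.py`, `cohort_statistics.py`.

## Command line

```bash
discdiff run --n-discs 24 --seed 3 --out runs/demo
discdiff fixtures --seed 0 --out runs/fix   # tiny 6-disc cohort
```

A run directory holds NIfTI images per disc and time point, the
landmark JSON, label-map masks, tidy CSV tables (geometry, enhancement,
CSF-adjusted T2), the statistical report, and a manifest with the seed
and SHA-256 checksums of every result table.

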