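# Methods

## The measurement being modelled

After intravenous injection of a gadolinium-based contrast agent, serial
T1-weighted sagittal MRI of the lumbar spine shows the agent arriving in
the vascularized vertebral bone within minutes and then slowly
penetrating the avascular intervertebral disc through the two cartilage
endplates. The analysis quantifies this transport as *enhancement*: the
difference in mean ROI signal intensity between a post-contrast image
and the pre-contrast image, with no normalization by the pre-contrast
value (normalizing would add variability unrelated to agent
concentration). Disc hydration is summarized separately from one
T2-weighted image as the CSF-adjusted T2 signal intensity: mean disc
(central + peripheral) T2 signal divided by the mean of a 3x5-pixel
cerebrospinal-fluid reference rectangle, a continuous degeneration
index that is invariant to global intensity scaling.

## Phantom model

No public image data exist for this protocol, so the package ships a
synthetic phantom that emulates the statistical structure the analysis
assumes, with full ground truth. Three coupled pieces:

**Blood pool.** C_b(t) = A (exp(-t/tau_e) - exp(-t/tau_a)) with
tau_a = 1 min (uptake) and tau_e = 120 min (renal clearance). The curve
is zero at injection, peaks at t* = tau_a tau_e / (tau_e - tau_a)
ln(tau_e/tau_a) ≈ 4.8 min — before the first post-contrast acquisition
at 5 min, so the subchondral bone ROI is strictly decreasing over the
five sampled time points — and decays to ~5% of peak at 6 h.

**Disc transport.** One spatial dimension along the disc axis x ∈ [0, h]:

    dc/dt = D d²c/dx² + v (C_b(t) − c),   c(x, 0) = 0,
    −D dc/dx|₀ = P (C_b − c(0)),   +D dc/dx|ₕ = −P (C_b − c(h)).

The Robin boundaries model finite endplate permeability P; the exchange
term v (C_b − c) models perfusion by capillaries inside vascularized
disc tissue (v = 0 for a healthy avascular disc). The solution is
symmetric about the mid-plane, obeys the maximum principle
0 ≤ c ≤ max C_b, and reproduces the qualitative transport sequence:
endplate zone enhancing within minutes and peaking near 2 h, central
disc essentially empty during the first 10 minutes and peaking near
6 h.

**Signal.** T1 intensity = baseline + alpha·c + N(0, sigma²) per pixel,
i.e. enhancement is linear in concentration. T1 relaxivity
nonlinearity, Rician noise statistics, sequence physics, partial-volume
and motion effects are deliberately out of scope: the measurand of the
analysis is a signal difference, and a linear-signal phantom exercises
every pipeline stage without committing to a scanner model.

### Default parameters

| parameter | symbol | default | unit | rationale |
|---|---|---|---|---|
| blood amplitude | A | 1 | conc. | concentration unit definition |
| uptake time | tau_a | 1 | min | peak before 5-min scan |
| clearance time | tau_e | 120 | min | near-zero blood signal at 6 h |
| diffusivity | D | 0.012 | mm²/min | central peak at 6 h for a 10 mm disc |
| endplate permeability | P | 0.04 | mm/min | endplate zone peak at 2 h |
| signal gain | alpha | 260 | signal/conc. | central 6-h enhancement ≈ 19 for the default disc |
| pixel noise | sigma | 60 | signal | ROI-mean enhancement SD ≈ 8 for a ~110-px central ROI |
| pixel spacing | — | 0.83 | mm/px | acquisition geometry |
| time points | — | 0, 5, 10, 120, 240, 360 | min | acquisition schedule |

alpha and sigma are anchored to the reference cohort's printed scale:
mean central enhancement of 19 signal units at 6 h against a per-disc
measurement SD of ~8 (PRE baseline 99). The noise is i.i.d. Gaussian
per pixel; because an ROI mean over N pixels is differenced against the
PRE mean, the per-measurement SD is sigma·sqrt(2/N) ≈ 8.1 at the
phantom's typical central-ROI size (≈ 110 px for a 10 mm × 38 mm disc).

### Cohort effect structure

Per-disc specs are drawn to mirror the reference cohort: Pfirrmann
grades at frequencies 50/43/58/48/15 per 214, Modic changes on ~26% of
discs (type mix I : II : I/II ≈ 27 : 56 : 8, two-endplate involvement
more common than one), endplate defects on ~37%, irregular endplates
only on grade ≥ 4 discs and always with Modic changes, rare
spondylolisthesis. Degeneration couples monotonically to morphology
(higher grade ⇒ thinner, drier disc) and to transport (endplate
permeability × (1 + 0.3·(grade−1))). Vascularization is planted as
perfusion: v = 0.0022 min⁻¹ for Modic-change discs (plus a 1.2×
permeability factor), doubled for irregular endplates.

The perfusion rate is an a-priori power choice: at the cohort size used
for validation (120 discs) the Modic group difference in central
enhancement is rarely detectable at 5 min (the delivered dose,
v·∫₀⁵C_b ≈ 0.009 concentration units ≈ 2.3 signal units, sits well
below the measurement SD) but is detected in the large majority of
cohorts from 10 min onward, and essentially always at 2–6 h where the
accumulated dose is an order of magnitude larger. Because the blood
curve fixes the 10-min/5-min dose ratio at ≈ 2.2, no choice of v makes
the 5-min test *never* significant while keeping the 10-min test
*always* significant; the validation checks therefore assert the
majority pattern, which is also how the underpowered early comparison
behaves in real cohorts.

With the default grade-coupled heights the degeneration effect on
enhancement flows mostly through disc height, plus the permeability
factor; with `height_distribution="uniform"` (used for planted-effect
recovery) height is decoupled from grade so the height–enhancement
correlation can be tested in isolation.

What the phantom does **not** emulate: multi-disc spines with shared
subject effects (each disc is an independent "subject", matching the
analysis, which treats discs as independent), registration error
(series are aligned by construction; real data must be pre-registered),
3-D partial-volume effects, spatially correlated noise, and any
concentration–relaxivity nonlinearity. Passing tests therefore validate
the pipeline's arithmetic and statistical behaviour, not scanner
fidelity.

## Segmentation geometry

Endplate borders are piecewise-linear polylines through the three
operator points (A anterior, B middle, C posterior; sub-pixel allowed;
coordinates are 0-based (row, col) with row increasing downward). Disc
height is pixel_spacing × mean(|A₁A₂|, |C₁C₂|). For every image column
between the landmark columns, a normalized depth u runs from the upper
border (0) to the lower border (1); a pixel joins the band containing
its centre, with layer bands EPZ [0, 0.2), peripheral [0.2, 0.4),
central [0.4, 0.6], peripheral (0.6, 0.8], EPZ (0.8, 1]. A u value
exactly on an interior edge goes to the band nearer the disc centre —
a deterministic tie rule. The subchondral bone band spans the same
columns, 6 pixels (4.98 mm at 0.83 mm/px) measured along the image
column direction beyond each border, after a 1-pixel gap (the grey
bone–disc interface). Between the landmark columns the bands follow
per-column linear interpolation of the borders, which reproduces exact
fifths for parallel borders and degrades gracefully for tilted discs.

Exclusions: disc height ≤ 3 mm (inclusive), severe spondylolisthesis,
or no measurable height. The time-curve profile is computed only on
discs with defect-free, non-irregular, Modic-free endplates.

## Statistics

Two-sided tests at alpha = 0.05 throughout; a Shapiro–Wilk gate is
recorded and the battery stays nonparametric regardless (matching the
study design). Rank-sum: exact permutation p (midranks, full
enumeration) when min(n) ≤ 8 and the enumeration is ≤ 5·10⁵ labelings,
otherwise the normal approximation with tie correction and no
continuity correction. Kruskal–Wallis uses the tie-corrected chi-square
approximation; Dunn's pairwise z-tests on mean ranks use the pooled
tie-corrected variance and a Bonferroni-style adjustment over all
pairs, and the pipeline never declares a pair significant unless the
omnibus test is. Spearman uses midranks and the t approximation.
Quantiles for the time-curve summaries use linear interpolation.

The multivariable models are SPSS-style univariate analyses of
variance: ordinary least squares with per-variable partial (Type-III)
F tests, sum-to-zero contrasts for categorical terms; degeneration
grade enters as a single continuous covariate, binary flags as 0/1,
disc height and CSF-adjusted T2 as continuous. Three covariate sets are
fitted at 2 h, 4 h and 6 h: {height, defect, MC, grade}, {height,
defect, MC, CSF-adj T2}, {height, irregular, MC, grade}. Muscle-based
signal normalization is intentionally not implemented.

## Numerical choices

Time stepping is Crank–Nicolson with dt = 0.5 min (unconditionally
stable; second-order); an explicit forward-Euler path exists for
cross-checking and rejects steps with D·dt/dx² > 0.5. The Robin
condition is imposed through ghost-node elimination, keeping the scheme
second-order and exactly symmetric under x → h−x. The spatial grid has
61 nodes by default; halving the step changes the solution by < 10⁻³
relative. Against the analytic Fourier-series slab solution (boundary
clamped, 201 nodes, dt = 0.05 min) the maximum error is below
10⁻³·C0. A disc with D = 0 degenerates to the uniform perfusion ODE.
Degenerate statistical inputs have documented conventions: two
identical constant samples give p = 1; a constant sample at mu0 gives
t = 0, p = 1; zero rank variance raises.

## Validation problem sizes

Planted-effect recovery uses 20 independent cohorts of 120 discs with
heights uniform on 5–14 mm; type-I calibration uses 1000 null
replicates per test family (rank-sum at n = 20+20, Kruskal–Wallis at
3×15, ANOVA at n = 60 with four covariates) and 500 noise-only phantom
replicates of 8 discs for the early-central-enhancement t-test. These
sizes give binomial standard errors well inside the asserted bands
while keeping the whole validation suite to a few minutes.

## Known limitations

- The kinetic parameter values are tuned to qualitative curve shape
  and the printed signal scale only; the study measured no kinetic
  constants, so the defaults are not a physiological claim.
- Within-subject correlation between discs of one spine is not
  modelled (nor used by the statistics, which treat discs as
  independent — a limitation inherited deliberately).
- The exchange form of the perfusion term pulls vascularized discs
  back toward the decaying blood concentration at late times, so the
  planted Modic effect at 6 h rides mostly on the slow washout of the
  accumulated dose; mechanisms like extravascular binding are not
  modelled.
- MC type III is accepted in user data but grouped separately and
  excluded from the Modic comparison with a warning; the generator
  never emits it.
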