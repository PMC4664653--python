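# Methods

This note documents the models, defaults and numerical choices behind
`gm1quant`, and what the synthetic studies do and do not establish.

## Mass and isotope model (`gm1quant.chem`)

Monoisotopic masses are sums of lowest-isotope atomic masses from a bundled
static IUPAC table (H, C, N, O, S, P, Na). The [M−H]− *m/z* is the neutral
monoisotopic mass minus one proton (1.007276 Da); the electron mass
(~0.00055 Da) is deliberately ignored — the error is two orders of
magnitude below the 0.01 Da precision at which the anchors 1544.87 and
1572.90 are stated. The GM1 formulas assume the stearoyl (18:0) fatty acid
for both species — the assignment that reproduces those two anchors; other
fatty-acyl compositions would shift both masses.

Isotope envelopes are aggregated by nucleon number (unit-mass envelope,
peaks ~1.0034 Da apart). Reflectron-TOF data at *m/z* ≈ 1500 cannot resolve
isotope fine structure, so a finer model would add nothing the instrument
can see. Abundances come from exact per-element convolution
(exponentiation-by-squaring of the single-atom distribution), truncated to
`max_peaks` (default 8, >99.99% of either GM1 envelope) and validated in
the tests against exhaustive isotopologue enumeration for small formulas.
For both GM1 species the monoisotopic peak is the largest envelope peak,
which is what justifies quantifying "the highest peak" at the predicted
*m/z* and treating its area as proportional to total species signal.

## Baseline removal (`gm1quant.preprocessing`)

Around each species a correction window of predicted *m/z* ±
(search + integration halfwidths) = ±0.9 Da is flanked by two 1.0 Da
sub-windows. A straight line through one anchor point per flank is
subtracted; negative residuals are clipped at zero. Any order statistic of
a linear segment lies on the line, so constant and linear baselines are
removed exactly on noise-free data for every anchor choice. The anchor
statistic is configurable:

* **median** (default). Unbiased under symmetric noise. The species' own
  +1/+2 isotope peaks fall inside the high-*m/z* flank and raise its median
  in proportion to the peak amplitude; because that error is multiplicative
  in amplitude it is common-mode between the two species and cancels in the
  AUC ratio to < 1% (measured on realistic envelopes).
* **min** — the minimum-intensity point of each flank, the way interactive
  baseline tools behave, and exactly idempotent. Under noise, however, the
  minimum of a ~50-bin flank sits ≈ 2.3 noise-SD below the true baseline,
  which inflates both AUCs and compresses ratios: ≈ −2% at gray-matter and
  ≈ −8% at white-matter signal levels at the default noise. It is kept for
  noise-free or strongly averaged data and for sensitivity analysis.
* **tophat** — morphological opening, for sensitivity analysis.

## Peak quantification (`gm1quant.quantify`)

The apex is the maximum-intensity local maximum within predicted *m/z* ±
0.5 Da (half an isotope spacing — only the monoisotopic peak can be
selected); ties break toward the predicted *m/z*, then toward lower *m/z*.
Detection requires the apex to exceed 3 robust noise SDs (1.4826 × MAD) of
the *unclipped* residuals of the low-*m/z* flank — the peak-free side; the
high-*m/z* flank contains the +1 isotope and would corrupt a noise
estimate. The AUC is the trapezoidal integral over apex ± 0.4 Da (within
one isotope spacing; integration bounds carry a 1e-9 Da tolerance so
grid-coincident endpoints are included deterministically). A missing peak
or zero denominator yields a flagged invalid record, never an infinite
ratio. Ratios are exactly invariant under any global intensity gain.

## Averaging and statistics (`gm1quant.roi_analysis`, `gm1quant.stats`)

Per-ROI ratios are grouped by (animal, region); groups with fewer than two
valid measurements are excluded (logged, not an error; the threshold is
configurable). Region summaries report mean ± SEM over per-animal means
with the sample (n−1) SD — the animal, not the ROI, is the unit of
analysis. Sums are taken over sorted values so results are exactly
permutation-invariant.

Comparisons are gated on normality at α = 0.05 per group:
D'Agostino–Pearson by default (Shapiro–Wilk selectable, and used
automatically with a warning for 3 ≤ n < 8 where the D'Agostino statistic
is undefined; n < 3 or constant samples fail closed to the nonparametric
path). Two groups: unpaired two-sided t-test, or Mann–Whitney U (exact null
distribution for pooled n ≤ 20 — without tie correction, which is
conservative — normal approximation with tie correction above). Three or
more: one-way ANOVA with Tukey's HSD, or Kruskal–Wallis with Dunn's
pairwise test under Holm adjustment. The nonparametric post hoc is a
declared convention: pairwise p-values after a Kruskal–Wallis omnibus are
reported by convention in this field without naming the procedure, and
Dunn + Holm is the interpretation implemented here.

## The synthetic study generator (`gm1quant.synthetic`)

Per-pixel spectra on a shared (continuous-mode) axis:

```
intensity = gain × Σ_species ab_s Σ_k frac_{s,k} N(m/z; μ_{s,k}, σ) + baseline + ε,  clipped at 0
```

* **Peak model**: Gaussian, σ = 0.15 Da — baseline-resolved isotope peaks,
  as reflectron-TOF spectra of these species show. Axis: uniform 0.02 Da
  bins, default range 1000–2000 Da.
* **Abundance split**: the generating parameter is the *highest-peak AUC
  ratio* r — the pipeline's measurand — not the total-envelope ratio. With
  ρ = r·f2/f1 (f = monoisotopic envelope fraction of each species),
  ab1 = total·ρ/(1+ρ) and ab2 = total/(1+ρ), so the expected recovered
  ratio equals r exactly. `total` defaults to 100 intensity units
  (15 for white-matter presets, whose per-pixel peaks sit near the noise —
  images are uninformative there but ROI-averaged spectra remain
  quantifiable, reproducing the white-matter situation).
* **Baseline**: constant 2 + slope −0.002/Da + broad Gaussian bump
  (amplitude 5, center 1500 Da, width 120 Da) — the simplest background
  that exercises local baseline removal.
* **Gain**: lognormal per pixel (σ = 0.3), mean-centred; cancels exactly in
  ratios and is why the pipeline reports ratios at all.
* **Noise**: additive Gaussian, σ = 1 intensity unit, then clipping at 0.
* **Biological variability**: real cohorts do not share one exact ratio —
  published regional SEMs in this kind of study imply between-animal
  relative SDs of roughly 4–26%. The generator draws mean-centred lognormal
  effects on the local true ratio per animal-region (CV 0.08) and per ROI
  (CV 0.08). Without such a term the only variance source would be pixel
  noise, whose effect on the recovered SEM and on the baseline-anchor bias
  both scale linearly with noise σ — making "group mean within a few SEM of
  truth" unattainable at any noise level, which is a property of the model,
  not of the pipeline. Set both CVs to 0 for purely technical simulations.
* **Seeding**: one master seed; children are derived per animal and section
  through `SeedSequence` spawn keys, so any subset of a study is
  reproducible on its own and whole runs are byte-identical (the imzML
  writer's file UUID is derived from content for the same reason).

Peak width and noise levels are plausibility choices, not fits to an
instrument: no published peak-width or noise figures exist for the original
acquisitions. What passing tests establish is therefore that the *pipeline*
recovers known ratios under a realistic noise/gain/baseline model — not
that the simulator reproduces any particular spectrometer. Real data add
mass-calibration drift, matrix crystal heterogeneity, detector saturation
and chemical interferences that are out of scope here.

## Study presets and problem sizes (`gm1quant.studies`)

Ten presets carry the published regional generating ratios and cohort
sizes (e.g. amygdala 8.15, n = 19; corpus callosum 5.506, n = 19 at
low signal with 8 ROIs/animal; DG molecular layer 1.90, n = 21 with small
~30-pixel ROIs). The three-band cortex phantom uses 2.55 / 3.5 / 4.43; the
intermediate value is not published and 3.5 was chosen between the two
quantified bands, matching their qualitative description. Desk-scale runs
use ~200 pixels per ROI and an *m/z* axis restricted to 1520–1600 Da (both
species' envelopes, windows and flanks, with margin); replicate-heavy
significance checks run at 50 pixels per ROI. These are problem-size
choices — smaller ROIs only add noise and are conservative for every test.

## Known limitations

* Only [M−H]− and the two GM1 species are modelled; no deisotoping, no
  untargeted peak picking, no absolute quantification (that would need
  concentration standards).
* Processed-mode imzML files with per-pixel axes are linearly resampled
  onto the first pixel's axis on read.
* The exclusion rule implements only the ≥ 2-measurements criterion; any
  further "insufficient resolution" judgement in the original workflow was
  manual and is not reproducible.
* Whether baseline removal was originally applied per pixel or per
  ROI-average spectrum is unstated; this pipeline corrects the ROI-average
  spectrum (and, for ion images, each pixel independently).
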