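# Methods

## The measurement model

The pipeline treats one TMA core per patient (2 mm punch of lymphoma
microenvironment) plus two normal-tonsil reference cores on the same array.
Analysis proceeds in the order the stages run:

1. **Segmentation and measurement** (`imaging`). Cells are segmented on the
   nuclear channel (Gaussian smoothing → automatic Otsu threshold computed
   shift-invariantly → optional distance-transform watershed → small-object
   removal) and each cell's intensity per marker is the raw pixel sum under
   its label divided by its area in µm² (and by the detector gain recorded
   in the image sidecar). Intensities are *not* background-subtracted by
   default; subtraction is an explicit flag because recorded fluorescence
   concentrations are treated as raw arbitrary units. Region restriction is
   by cell centroid, boundary-inclusive, so cells straddling a manually
   drawn analysis boundary are assigned unambiguously.

2. **Cutoff calibration** (`calibration`). For each marker, the cutoff is
   the maximum intensity among `n_sample` (default 200, recommended range
   50–200) cells sampled uniformly without replacement from a lineage with
   known lack of expression. Positivity is *strict* exceedance, so every
   calibration cell is itself called negative. A consequence worth knowing:
   for a fresh cell drawn from the same negative distribution, the
   probability of exceeding the max of n i.i.d. draws is exactly
   1/(n+1) regardless of the distribution (a rank statistic), so the
   per-marker false-positive rate is ≈0.5% at n=200 and cannot be reduced
   by increasing the expressor/background separation — only by enlarging
   the calibration sample.

3. **Reference normalization** (`calibration`). Relative expression
   RE = 100 · x / x̄_ref, where x̄_ref is the unweighted arithmetic mean over
   all reference cells of both tonsil cores pooled (≈500 each; with roughly
   balanced cores, core-weighted pooling would differ negligibly). Group RE
   is computed as 100 · (group mean)/x̄_ref, which by linearity equals the
   mean of per-cell REs. RE is invariant under rescaling all intensities by
   a common factor and linear in its argument; both properties are tested.
   CD3 RE per patient serves as an immunoreactivity control: patients
   deviating more than a configurable factor (default 3×) from the cohort
   median are flagged.

4. **Phenotyping** (`phenotyping`). Gating precedence: CD20⁺ → B cell
   (before CD3, resolving B/T double-positives); else CD3⁺ with subset
   markers resolved FOXP3 > CD8 > CD4 (rarest first); CD3⁺ without a subset
   marker → T_OTHER; otherwise OTHER. CD3-lineage cells are partitioned
   into the four checkpoint quadrants. Cohort-level quadrant fractions are
   the *unweighted mean of per-patient fractions* (each patient counts
   equally); pooled-cell fractions are reported alongside. The top-decile
   summary sorts the RE of *positive* cells descending and averages the top
   ceil(f·n) (default f = 0.10), with ties at the boundary broken
   deterministically by (value, cell_id).

5. **Cohort statistics** (`stats`). Medians, ranges and the fraction of
   patients below a configurable RE threshold (default 50%); one-way
   fixed-effects ANOVA computed from the sums-of-squares definition with
   the p-value from the F(k−1, n−k) distribution. The grouping factor is
   configurable (T-cell subset, HL subtype, lineage); Tukey HSD is
   available behind a flag but off by default. Because no published F or p
   values exist to compare against, the ANOVA is validated by a worked
   sums-of-squares example, an independent-library cross-check, and a
   type-I-error calibration (10,000 null simulations, rejection rate at
   α = 0.05 within ±0.01).

## The synthetic cohort generator

`synthetic` emulates the statistical structure the analysis assumes, not
the optics of the microscope:

* **Populations.** Each patient core is a mixture of B cells (CD20⁺) and
  CD4/CD8/FOXP3 T subsets (CD3⁺). Default weights 0.20/0.45/0.25/0.10
  represent a classical-HL lymphocytic background dominated by helper
  T cells.
* **Intensities.** Log-normal (right-skewed, as fluorescence intensities
  are), parameterized by arithmetic mean m and coefficient of variation cv
  (σ² = ln(1+cv²), µ = ln m − σ²/2), so the closed-form mean is m and
  cv = 0 degenerates to exactly m. Expressing cells draw around their
  population mean (default 50 a.u./µm²), non-expressing cells around the
  background mean (default 1 a.u./µm²); default measurement noise
  cv = 0.3. No published distributional form exists for these choices;
  they are generator defaults, not claims about any dataset.
* **Inter-patient variability** is one multiplicative `expression_scale`
  per patient per checkpoint marker. In the quadrant-recovery
  configuration scales are drawn in [0.5, 1.2], keeping the weakest
  expressor ≥ 25× background so that positivity calling is governed by the
  cutoff rule rather than distributional overlap; the 40-patient
  `full_study_cohort` uses a much wider range ([0.05, 1.0], with the
  NLPHL case above 1) to emulate the observed 1–122% RE spread.
* **Checkpoint co-expression.** TIGIT/PD-1 expressor states are drawn
  jointly per cell from explicit four-class quadrant probabilities —
  the most direct way to realize a target quadrant structure — or from
  marginals plus an odds ratio (Plackett construction). The classical-HL
  T-cell default is (0.68, 0.14, 0.05, 0.13).
* **Reference cores.** Two tonsil cores of ≈500 germinal-center-periphery
  cells each (±25 jitter), whose configured checkpoint mean anchors
  RE = 100%.
* **Images.** Cells are hard discs (radius from a log-normal area,
  mean 45 µm² — lymphocyte-sized) placed by rejection sampling with no
  overlap inside the core disc; each disc paints a uniform pixel value
  `round(intensity · pixel_area · gain)` in every channel (16-bit, default
  0.5 µm/px, gain 100 DN per a.u./µm² recorded in the sidecar YAML), so
  masked pixel averaging recovers the table intensity up to quantization.

**What the generator does not emulate** — and hence what passing tests do
not show about real tissue: touching/overlapping nuclei, point-spread and
spectral crosstalk, autofluorescence gradients, HRS cells and the rosette
architecture around them, exposure-time adjustment between fluorochromes,
and batch/slide effects. Segmentation recall on the synthetic cores is
therefore an upper bound; on real mfIHC the segmentation stage, not the
statistics, is the accuracy bottleneck.

## Numerical and design choices

* Determinism: every stochastic step takes a seed; identical config + seed
  reproduces tables bit-for-bit. Calibration sampling uses an independent
  sub-seed per marker.
* Degenerate inputs are defined, not errors, where a value exists: blank
  image → empty mask; all-identical ANOVA values → F = 0, p = 1; zero
  cutoff with zero negatives → any positive intensity is called positive.
  Genuinely undefined quantities (RE with zero reference mean, quadrants
  with no T cells, conditional co-expression with empty denominator) raise
  or return None.
* Masks use 0 = background with labels 1..K; pixel indices are 0-based and
  the physical coordinate of pixel i is (i + 0.5)·pixel_size from the
  top-left pixel center.
* One cutoff per marker per run (not per core): cores share one staining
  batch on a TMA, and per-core recalibration at n ≤ 200 would add
  order-statistic noise without modeling any real drift.
* Reference-cell selection is a generator flag (or a user-supplied region
  on real data); the germinal-center-periphery geometry itself is not
  modeled.

## Problem sizes used in validation

Quadrant and positive-fraction recovery run at 30 patients × 20,000 cells
(≈600k cells, seconds on one CPU), matching the reported per-core analysis
scale of 18,000–30,000 cells. Segmentation validation uses a 300 µm field
with 200 non-overlapping nuclei — density and size chosen so hard-disc
placement succeeds while keeping the rendered image small. The cutoff-law
check uses 1,000 replicate calibrations against the closed-form
max-of-200 distribution; ANOVA calibration uses 10,000 null simulations.

## Known limitations

* The per-marker false-positive floor of 1/(n_sample+1) biases quadrant
  fractions by a few tenths of a percentage point (cells leak from
  "neither" into the positive quadrants); at n = 200 this is an order of
  magnitude below the ±2 pp recovery tolerance but would matter for rare
  populations.
* Lineage gating accuracy is bounded by the same floor: a cell is
  misassigned when any of its truly-negative lineage markers exceeds its
  cutoff, so expected accuracy depends on the population mix (≈99% for
  typical mixes) and cannot approach 100% however well separated the
  intensity distributions are.
* The image path assumes one intensity per cell per channel (no
  compartmentalization into membrane/cytoplasm/nucleus) and 2-D fields.
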