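# mfiquant

Quantification of immune-checkpoint receptor expression (TIGIT, PD-1) on
T-cell subsets in multiplex fluorescence immunohistochemistry (mfIHC) of
lymphoma tissue microarrays — for pathology and tumor-immunology groups who
measure per-cell marker intensities on TMA cores and need reproducible
positivity calling, cross-run normalization, and cohort statistics.

## What it computes

Given per-cell mean fluorescence intensities (a.u./µm²) for a marker panel
(DAPI, CD20, CD3, CD4/CD8/FOXP3, TIGIT, PD-1), either measured from
multichannel TIFFs or supplied as a CSV table:

* **Positivity cutoffs** from negative controls: the intensity of a marker is
  sampled in 50–200 cells of a lineage with known lack of expression (e.g.
  CD20⁺ B cells for TIGIT) and the cutoff is the maximum "false positive"
  value; a cell is positive iff its intensity strictly exceeds it.
* **Relative expression (RE)**: the mean intensity of ≈1000 tonsil
  germinal-center-periphery lymphocytes (500 from each of two reference
  cores) defines RE = 100%; every cell or group mean is reported as
  RE = 100 · x / x̄_ref. RE is invariant to rescaling all intensities,
  making values comparable across staining runs.
* **Phenotypes**: lineage gating (CD20 → B cell; CD3 plus subset markers →
  CD4/CD8/FOXP3 T subsets), checkpoint quadrants of CD3⁺ T cells
  (both⁺ / TIGIT-only / PD-1-only / neither), per-case positive fractions,
  conditional co-expression, and top-decile RE of positive cells.
* **Cohort statistics**: per-patient RE summaries, medians and ranges,
  CD3 immunoreactivity control, and one-way ANOVA
  (F = [SS_between/(k−1)] / [SS_within/(n−k)]) for group differences.

A seeded synthetic TMA generator (`mfiquant.synthetic`) produces cohorts with
this exact statistical structure — lineage mixtures, log-normal intensities,
patient-variable checkpoint scaling, jointly drawn TIGIT/PD-1 expressor
states, two tonsil reference cores — both as ground-truthed cell tables and
as renderable multichannel images, so the whole pipeline is testable without
any external data.

## Worked example

```python
import mfiquant as mq

# 30-patient NSCHL-style cohort, 20,000 cells per core, joint T-cell
# checkpoint quadrant probabilities (both, TIGIT-only, PD-1-only, neither)
config = mq.nschl_quadrant_cohort(
    n_patients=30, n_cells=20000, seed=20180,
    quadrant_probs=(0.68, 0.14, 0.05, 0.13),
)
result = mq.analyze_cohort(config)          # calibrate -> phenotype -> summarize

study = result.phenotypes[~result.cells["is_reference"].to_numpy()]
mean_qf, pooled_qf, per_patient = mq.cohort_quadrant_fractions(study)
print({q: round(100 * v, 1) for q, v in mean_qf.as_dict().items()})
print(mq.conditional_coexpression(mean_qf))
```

prints

```
{'both': 68.2, 'tigit_only': 14.1, 'pd1_only': 4.9, 'neither': 12.7}
{'pd1_given_tigit': 0.8285530225327742, 'tigit_given_pd1': 0.932358510035888}
```

i.e. the pipeline recovers the configured quadrant structure from raw
intensities — 68.2% of CD3⁺ T cells co-express both receptors (averaged
across patients) — and 82.9% of TIGIT⁺ T cells are also PD-1⁺.

A command-line interface mirrors the library
(`mfiquant simulate|segment|calibrate|phenotype|report|run-all`); see
`mfiquant --help`.

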