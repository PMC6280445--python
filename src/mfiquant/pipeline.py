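"""End-to-end table analysis: calibrate, normalize, phenotype, summarize.

Glue over the stage modules so that a cohort — synthetic or measured from
images — runs through the full analysis with one call.  The default
negative-population plan assigns each marker a lineage known not to express
it (B cells for the checkpoints, since TIGIT is essentially undetectable on
CD20+ B lymphocytes; the reciprocal T/B subsets for the lineage markers);
real studies can override the plan marker by marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .calibration import (
    ReferenceStats,
    ThresholdSet,
    calibrate_threshold,
    compute_reference,
    immunoreactivity_control,
)
from .phenotyping import call_phenotypes
from .stats import CohortSummary, summarize_cohort, summarize_patients
from .synthetic import (
    B_CELL,
    CD3,
    CD4,
    CD8,
    CD20,
    FOXP3,
    PD1,
    T_CD4,
    T_CD8,
    TIGIT,
    CohortConfig,
    generate_cell_table,
)

#: marker -> lineage with known lack of expression (calibration population)
DEFAULT_NEGATIVE_PLAN = {
    TIGIT: B_CELL,
    PD1: B_CELL,
    CD20: T_CD4,
    CD3: B_CELL,
    CD4: T_CD8,
    CD8: T_CD4,
    FOXP3: T_CD4,
}


def calibrate_thresholds(
    cells: pd.DataFrame,
    lineages: pd.Series,
    negative_plan: dict[str, str] | None = None,
    n_sample: int = 200,
    seed: int = 0,
) -> ThresholdSet:
    """Calibrate one cutoff per marker from its known-negative lineage.

    ``lineages`` aligns with ``cells`` (ground truth for synthetic runs, a
    prior lineage call otherwise).  Each marker gets an independent
    sub-seed so sampling one marker does not perturb another.
    """
    plan = negative_plan or DEFAULT_NEGATIVE_PLAN
    tab = cells.copy()
    tab["lineage"] = lineages.to_numpy()
    thresholds = ThresholdSet()
    for i, marker in enumerate(sorted(plan)):
        entry = calibrate_threshold(
            tab, plan[marker], marker, n_sample=n_sample, seed=seed + i
        )
        thresholds.set(entry)
    return thresholds


def compute_reference_stats(
    cells: pd.DataFrame, markers: tuple[str, ...] = (TIGIT, PD1, CD3)
) -> ReferenceStats:
    """Reference (RE = 100%) means from the flagged tonsil reference cells."""
    ref_cells = cells[cells["is_reference"]]
    stats = ReferenceStats()
    for marker in markers:
        stats.set(compute_reference(ref_cells, marker))
    return stats


@dataclass
class AnalysisResult:
    """Everything one cohort run produces, ready for reporting."""

    cells: pd.DataFrame
    truth: pd.DataFrame | None
    thresholds: ThresholdSet
    reference: ReferenceStats
    phenotypes: pd.DataFrame
    per_patient: pd.DataFrame
    summary: CohortSummary
    control: object = field(default=None)


def analyze_cell_table(
    cells: pd.DataFrame,
    calibration_lineages: pd.Series,
    truth: pd.DataFrame | None = None,
    negative_plan: dict[str, str] | None = None,
    n_sample: int = 200,
    seed: int = 0,
) -> AnalysisResult:
    """Run calibration, phenotyping and summaries on a measured cell table."""
    thresholds = calibrate_thresholds(
        cells, calibration_lineages, negative_plan, n_sample, seed
    )
    reference = compute_reference_stats(cells)
    phenotypes = call_phenotypes(cells, thresholds)
    per_patient = summarize_patients(cells, phenotypes, thresholds, reference)
    summary = summarize_cohort(per_patient)
    control = None
    cd3_col = f"{CD3}_mean_re_t_cells"
    if cd3_col in per_patient.columns and len(per_patient) >= 2:
        control = immunoreactivity_control(per_patient[cd3_col])
    return AnalysisResult(
        cells=cells,
        truth=truth,
        thresholds=thresholds,
        reference=reference,
        phenotypes=phenotypes,
        per_patient=per_patient,
        summary=summary,
        control=control,
    )


def analyze_cohort(
    config: CohortConfig, n_sample: int = 200, calibration_seed: int = 0
) -> AnalysisResult:
    """Generate a synthetic cohort and analyze it end to end.

    Thresholds are calibrated on the generator's ground-truth lineages,
    mirroring the study's use of populations with known lack of expression.
    """
    cells, truth = generate_cell_table(config)
    return analyze_cell_table(
        cells,
        calibration_lineages=truth["lineage"],
        truth=truth,
        n_sample=n_sample,
        seed=calibration_seed,
    )
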