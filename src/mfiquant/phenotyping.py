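"""Lineage assignment, checkpoint positivity calls and co-expression summaries.

Gating is threshold-based on the calibrated cutoffs, with a fixed precedence
order resolving multi-positive cells: CD20 positivity wins over CD3 (B cell
before T cell), and among the T-subset markers FOXP3 > CD8 > CD4 (rarest
first).  A CD3+ cell positive for none of the subset markers is T_OTHER;
a cell positive for neither CD20 nor CD3 is OTHER.

CD3-lineage cells are partitioned into the four checkpoint quadrants
(both+, TIGIT-only, PD-1-only, neither); cohort-level fractions are the
unweighted mean of per-patient fractions, with pooled-cell fractions
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ReferenceStats, ThresholdSet, relative_expression
from .synthetic import CD3, CD4, CD8, CD20, FOXP3, PD1, QUADRANTS, TIGIT

T_OTHER = "T_OTHER"
OTHER = "OTHER"
T_LINEAGES = ("T_CD4", "T_CD8", "T_FOXP3", T_OTHER)

#: precedence among T-subset markers when a cell is multi-positive
_SUBSET_PRECEDENCE = ((FOXP3, "T_FOXP3"), (CD8, "T_CD8"), (CD4, "T_CD4"))


class PhenotypingError(ValueError):
    pass


def assign_lineages(
    cells: pd.DataFrame, thresholds: ThresholdSet
) -> pd.Series:
    """Vectorized lineage call for every cell.

    Requires calibrated cutoffs for CD20, CD3, CD4, CD8 and FOXP3; raises
    naming the first missing marker.
    """
    for marker in (CD20, CD3, CD4, CD8, FOXP3):
        if marker not in cells.columns:
            raise PhenotypingError(
                f"cells table lacks lineage channel {marker!r}"
            )
        if marker not in thresholds:
            raise PhenotypingError(
                f"no cutoff calibrated for lineage marker {marker!r}"
            )
    pos = {
        m: thresholds.is_positive(cells[m].to_numpy(), m)
        for m in (CD20, CD3, CD4, CD8, FOXP3)
    }
    lineage = np.full(len(cells), OTHER, dtype=object)
    cd3 = ~pos[CD20] & pos[CD3]
    lineage[cd3] = T_OTHER
    for marker, label in reversed(_SUBSET_PRECEDENCE):
        # applied lowest-precedence first so higher precedence overwrites
        lineage[cd3 & pos[marker]] = label
    lineage[pos[CD20]] = "B_CELL"
    return pd.Series(lineage, index=cells.index, name="lineage")


def call_phenotypes(
    cells: pd.DataFrame, thresholds: ThresholdSet
) -> pd.DataFrame:
    """Full per-cell phenotype table: lineage, positivity bits, quadrant.

    The quadrant is defined for CD3-lineage cells (T_* labels) and empty
    otherwise.
    """
    lineage = assign_lineages(cells, thresholds)
    tigit_pos = thresholds.is_positive(cells[TIGIT].to_numpy(), TIGIT)
    pd1_pos = thresholds.is_positive(cells[PD1].to_numpy(), PD1)
    quadrant = np.where(
        tigit_pos & pd1_pos, "both",
        np.where(tigit_pos, "tigit_only",
                 np.where(pd1_pos, "pd1_only", "neither")),
    )
    quadrant = np.where(lineage.isin(T_LINEAGES), quadrant, "")
    return pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "patient_id": cells["patient_id"].to_numpy(),
            "lineage": lineage.to_numpy(),
            "tigit_positive": tigit_pos,
            "pd1_positive": pd1_pos,
            "quadrant": quadrant,
        },
        index=cells.index,
    )


@dataclass
class QuadrantFractions:
    """Four-way partition of CD3+ T cells by TIGIT/PD-1 positivity."""

    both: float
    tigit_only: float
    pd1_only: float
    neither: float
    n_cells: int
    scope: str = "per_patient"

    def as_dict(self) -> dict[str, float]:
        return {q: getattr(self, q) for q in QUADRANTS}

    def __post_init__(self) -> None:
        total = self.both + self.tigit_only + self.pd1_only + self.neither
        if self.n_cells and abs(total - 1.0) > 1e-9:
            raise PhenotypingError(
                f"quadrant fractions sum to {total!r}, expected 1"
            )


def call_quadrants(
    phenotypes: pd.DataFrame, scope: str = "per_patient"
) -> QuadrantFractions:
    """Quadrant fractions over the CD3-lineage cells of one patient/group."""
    t_cells = phenotypes[phenotypes["lineage"].isin(T_LINEAGES)]
    n = len(t_cells)
    if n == 0:
        raise PhenotypingError("no CD3-lineage cells; quadrants undefined")
    counts = t_cells["quadrant"].value_counts()
    frac = {q: float(counts.get(q, 0)) / n for q in QUADRANTS}
    return QuadrantFractions(**frac, n_cells=n, scope=scope)


def cohort_quadrant_fractions(
    phenotypes: pd.DataFrame,
) -> tuple[QuadrantFractions, QuadrantFractions, pd.DataFrame]:
    """Cohort quadrant summary.

    Returns ``(mean_of_patients, pooled, per_patient)`` where
    ``mean_of_patients`` is the unweighted average of per-patient fractions
    (the headline "average across all patients" quantity), ``pooled`` counts
    all CD3-lineage cells as one pool, and ``per_patient`` is a DataFrame of
    the individual patients' fractions.
    """
    rows = []
    for patient_id, group in phenotypes.groupby("patient_id", sort=True):
        qf = call_quadrants(group)
        rows.append({"patient_id": patient_id, "n_cells": qf.n_cells,
                     **qf.as_dict()})
    per_patient = pd.DataFrame(rows).set_index("patient_id")
    mean = per_patient[list(QUADRANTS)].mean()
    mean_of_patients = QuadrantFractions(
        **{q: float(mean[q]) for q in QUADRANTS},
        n_cells=int(per_patient["n_cells"].sum()),
        scope="cohort_mean_of_patients",
    )
    pooled = call_quadrants(phenotypes, scope="cohort_pooled")
    return mean_of_patients, pooled, per_patient


def per_case_positive_fraction(
    cells: pd.DataFrame, marker: str, thresholds: ThresholdSet
) -> float:
    """Fraction of all analyzed cells of one case with intensity > cutoff."""
    if cells.empty:
        raise PhenotypingError("no cells for positive-fraction computation")
    return float(thresholds.is_positive(cells[marker].to_numpy(), marker).mean())


@dataclass
class TopDecileSummary:
    marker: str
    fraction: float
    mean_re: float
    n_cells: int


def top_decile_mean(
    re_values,
    marker: str = "",
    fraction: float = 0.10,
    cell_ids=None,
) -> TopDecileSummary:
    """Mean RE of the top ``fraction`` of values (default the top decile).

    Values are sorted descending and the top ``ceil(fraction * n)`` are
    averaged.  Ties at the boundary are resolved deterministically by a
    stable sort on (value, cell_id) when cell ids are supplied, plain value
    order otherwise.
    """
    values = np.asarray(re_values, dtype=float)
    if values.size == 0:
        raise PhenotypingError("top-decile mean of an empty set is undefined")
    if not (0.0 < fraction < 1.0):
        raise PhenotypingError(f"fraction {fraction} outside (0, 1)")
    if values.size < 10:
        import warnings

        warnings.warn(
            f"only {values.size} values; top-{fraction:.0%} mean is unstable",
            stacklevel=2,
        )
    k = math.ceil(fraction * values.size)
    if cell_ids is not None:
        order = np.lexsort((np.asarray(cell_ids), -values))
    else:
        order = np.argsort(-values, kind="stable")
    top = values[order[:k]]
    return TopDecileSummary(
        marker=marker,
        fraction=fraction,
        mean_re=float(top.mean()),
        n_cells=int(k),
    )


def positive_cell_re(
    cells: pd.DataFrame,
    phenotypes: pd.DataFrame,
    marker: str,
    thresholds: ThresholdSet,
    reference: ReferenceStats,
    lineages: tuple[str, ...] = T_LINEAGES,
) -> pd.Series:
    """Per-cell RE of marker-positive cells of the given lineages."""
    pos_col = "tigit_positive" if marker == TIGIT else "pd1_positive"
    sel = phenotypes["lineage"].isin(lineages) & phenotypes[pos_col]
    vals = cells.loc[sel.to_numpy(), marker]
    return pd.Series(
        relative_expression(vals.to_numpy(), reference, marker),
        index=vals.index,
        name=f"{marker}_re",
    )


def conditional_coexpression(qf: QuadrantFractions) -> dict[str, float | None]:
    """Fraction of single-marker-positive cells also positive for the other.

    ``pd1_given_tigit`` = both / (both + tigit_only);
    ``tigit_given_pd1`` = both / (both + pd1_only).
    A zero denominator yields ``None`` (undefined).
    """
    out: dict[str, float | None] = {}
    denom_t = qf.both + qf.tigit_only
    denom_p = qf.both + qf.pd1_only
    out["pd1_given_tigit"] = qf.both / denom_t if denom_t > 0 else None
    out["tigit_given_pd1"] = qf.both / denom_p if denom_p > 0 else None
    return out
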