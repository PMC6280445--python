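"""Cohort-level summaries, one-way ANOVA and report generation.

The headline cohort quantities are per-patient mean relative expression (RE)
of the checkpoint markers on CD3+ T cells, their median and range across
patients, the fraction of patients under an RE threshold (default 50%), and
a one-way fixed-effects ANOVA testing expression differences between groups
(T-cell subset by default; HL subtype or lineage configurable).

The F statistic is computed from its sums-of-squares definition::

    SS_between = sum_i n_i (mean_i - grand_mean)^2
    SS_within  = sum_i sum_j (x_ij - mean_i)^2
    F = [SS_between / (k - 1)] / [SS_within / (n - k)]

with the p-value taken from the F distribution on (k-1, n-k) degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .calibration import ImmunoreactivityReport, ReferenceStats, ThresholdSet
from .phenotyping import (
    QUADRANTS,
    T_LINEAGES,
    cohort_quadrant_fractions,
    per_case_positive_fraction,
)
from .synthetic import CD3, PD1, TIGIT


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# One-way ANOVA from the definition
# --------------------------------------------------------------------------


@dataclass
class AnovaResult:
    grouping: str
    k: int
    n: int
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    f_statistic: float
    p_value: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def one_way_anova(
    values, groups, grouping: str = "group"
) -> AnovaResult:
    """One-way fixed-effects ANOVA of ``values`` grouped by ``groups``.

    Needs at least two groups and at least one residual degree of freedom.
    With identical values everywhere the test degenerates to F=0, p=1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise StatsError(
            f"values ({values.shape}) and groups ({groups.shape}) differ"
        )
    labels = pd.unique(groups)
    k = len(labels)
    n = len(values)
    if k < 2:
        raise StatsError("ANOVA needs at least 2 groups")
    if n - k < 1:
        raise StatsError("ANOVA needs at least one within-group df")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lab in labels:
        x = values[groups == lab]
        m = x.mean()
        ss_between += len(x) * (m - grand) ** 2
        ss_within += float(((x - m) ** 2).sum())
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            f, p = 0.0, 1.0
        else:
            f, p = float("inf"), 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        grouping=grouping,
        k=k,
        n=n,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        df_between=df_b,
        df_within=df_w,
        f_statistic=float(f),
        p_value=p,
    )


def tukey_hsd(values, groups) -> pd.DataFrame:
    """Optional post-hoc pairwise comparison (Tukey HSD) behind a flag."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    samples = [values[groups == lab] for lab in labels]
    res = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(
                        samples[i].mean() - samples[j].mean()
                    ),
                    "p_value": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cohort summaries
# --------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Per-patient and cohort-level aggregates of one analysis run."""

    per_patient: pd.DataFrame
    cohort: dict[str, float] = field(default_factory=dict)
    per_subtype: pd.DataFrame | None = None


def summarize_patients(
    cells: pd.DataFrame,
    phenotypes: pd.DataFrame,
    thresholds: ThresholdSet,
    reference: ReferenceStats,
    markers: tuple[str, ...] = (TIGIT, PD1, CD3),
) -> pd.DataFrame:
    """Per-patient table: mean RE on CD3+ T cells per marker, positive
    fractions and quadrant fractions.

    Reference cells are excluded from patient summaries.
    """
    study = cells[~cells["is_reference"]]
    pheno = phenotypes.loc[study.index]
    rows = []
    for patient_id, pcells in study.groupby("patient_id", sort=True):
        ppheno = pheno.loc[pcells.index]
        t_mask = ppheno["lineage"].isin(T_LINEAGES).to_numpy()
        row: dict[str, object] = {
            "patient_id": patient_id,
            "subtype": pcells["subtype"].iloc[0]
            if "subtype" in pcells.columns
            else "",
            "n_cells": len(pcells),
            "n_t_cells": int(t_mask.sum()),
        }
        for marker in markers:
            t_vals = pcells.loc[t_mask, marker]
            mean_int = float(t_vals.mean()) if len(t_vals) else float("nan")
            row[f"{marker}_mean_re_t_cells"] = (
                100.0 * mean_int / reference.mean(marker)
                if marker in reference.entries
                else float("nan")
            )
            if marker in thresholds:
                row[f"{marker}_positive_fraction"] = (
                    per_case_positive_fraction(pcells, marker, thresholds)
                )
        if t_mask.any():
            qcounts = ppheno.loc[t_mask, "quadrant"].value_counts()
            for q in QUADRANTS:
                row[f"quadrant_{q}"] = float(qcounts.get(q, 0)) / int(
                    t_mask.sum()
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def summarize_cohort(
    per_patient: pd.DataFrame,
    re_column: str = f"{TIGIT}_mean_re_t_cells",
    low_re_threshold: float = 50.0,
) -> CohortSummary:
    """Cohort medians/ranges of per-patient values.

    Reports, for the chosen RE column, the min/median/max across patients
    and the fraction of patients below ``low_re_threshold`` (%).
    """
    if per_patient.empty:
        raise StatsError("no patients to summarize")
    cohort: dict[str, float] = {}
    for col in per_patient.columns:
        if not pd.api.types.is_numeric_dtype(per_patient[col]):
            continue
        vals = per_patient[col].dropna()
        if vals.empty:
            continue
        cohort[f"{col}_min"] = float(vals.min())
        cohort[f"{col}_median"] = float(vals.median())
        cohort[f"{col}_max"] = float(vals.max())
    if re_column in per_patient.columns:
        vals = per_patient[re_column].dropna()
        cohort["fraction_below_re_threshold"] = float(
            (vals < low_re_threshold).mean()
        )
        cohort["low_re_threshold"] = low_re_threshold
    per_subtype = None
    if "subtype" in per_patient.columns:
        num = per_patient.select_dtypes("number")
        per_subtype = num.groupby(per_patient["subtype"]).agg(
            ["mean", "min", "max"]
        )
    return CohortSummary(
        per_patient=per_patient, cohort=cohort, per_subtype=per_subtype
    )


# --------------------------------------------------------------------------
# Report rendering
# --------------------------------------------------------------------------


def render_report(
    summary: CohortSummary,
    out_dir: str,
    anova: AnovaResult | None = None,
    control: ImmunoreactivityReport | None = None,
    phenotypes: pd.DataFrame | None = None,
    make_figures: bool = True,
) -> dict[str, str]:
    """Write machine-readable summaries (CSV/YAML) and the two study figures.

    Figures: per-subtype RE distributions with CD3 immunoreactivity bars,
    and the cohort quadrant pie.  Returns a name->path map of the files
    written.  Output is deterministic for fixed inputs (no timestamps).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    per_patient_csv = os.path.join(out_dir, "per_patient_summary.csv")
    summary.per_patient.to_csv(per_patient_csv)
    paths["per_patient_csv"] = per_patient_csv

    doc: dict = {"cohort": {k: _plain(v) for k, v in summary.cohort.items()}}
    if anova is not None:
        doc["anova"] = {
            "grouping": anova.grouping,
            "k": anova.k,
            "n": anova.n,
            "f_statistic": _plain(anova.f_statistic),
            "p_value": _plain(anova.p_value),
            "df": [anova.df_between, anova.df_within],
        }
    if control is not None:
        doc["immunoreactivity_control"] = {
            "cv": _plain(control.cv),
            "flagged_patients": control.flagged,
            "factor": control.factor,
        }
    quad_mean = None
    if phenotypes is not None:
        quad_mean, quad_pooled, _ = cohort_quadrant_fractions(phenotypes)
        doc["quadrant_fractions"] = {
            "mean_of_patients": {
                q: _plain(v) for q, v in quad_mean.as_dict().items()
            },
            "pooled": {
                q: _plain(v) for q, v in quad_pooled.as_dict().items()
            },
        }
    summary_yaml = os.path.join(out_dir, "cohort_summary.yaml")
    with open(summary_yaml, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    paths["summary_yaml"] = summary_yaml

    if make_figures:
        paths.update(
            _render_figures(summary, quad_mean, out_dir)
        )
    return paths


def _plain(v):
    if v is None:
        return None
    f = float(v)
    return f if np.isfinite(f) else str(f)


def _render_figures(summary, quad_mean, out_dir):
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    pp = summary.per_patient
    re_cols = [c for c in pp.columns if c.endswith("_mean_re_t_cells")]
    if "subtype" in pp.columns and re_cols:
        fig, axes = plt.subplots(
            1, len(re_cols), figsize=(4 * len(re_cols), 4), squeeze=False
        )
        subtypes = sorted(s for s in pp["subtype"].unique() if s)
        kept = [s for s in subtypes if (pp["subtype"] == s).any()]
        for ax, col in zip(axes[0], re_cols):
            data = [
                pp.loc[pp["subtype"] == s, col].dropna().to_numpy()
                for s in kept
            ]
            nonempty = [(s, d) for s, d in zip(kept, data) if len(d)]
            if not nonempty:
                continue
            ax.boxplot(
                [d for _, d in nonempty],
                tick_labels=[s for s, _ in nonempty],
            )
            ax.axhline(100.0, ls="--", lw=0.8, color="gray")
            ax.set_ylabel("relative expression (%)")
            ax.set_title(col.replace("_mean_re_t_cells", " RE in CD3+ T cells"))
        fig.tight_layout()
        p = os.path.join(out_dir, "re_by_subtype.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["re_by_subtype"] = p
    if quad_mean is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        fracs = quad_mean.as_dict()
        ax.pie(
            [fracs[q] for q in QUADRANTS],
            labels=[q.replace("_", " ") for q in QUADRANTS],
            colors=["gold", "green", "red", "steelblue"],
            autopct="%.0f%%",
        )
        ax.set_title("CD3+ T-cell checkpoint quadrants")
        p = os.path.join(out_dir, "quadrant_pie.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["quadrant_pie"] = p
    return paths
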