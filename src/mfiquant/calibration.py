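"""Positivity-cutoff calibration and tonsil-reference normalization.

Two calibration constructs drive the whole analysis:

* **Negative-population cutoff** — the fluorescence of a marker is measured
  in 50-200 cells of a lineage known not to express it (e.g. CD20+ B cells
  for TIGIT) and the highest such "false positive" value becomes the
  positivity cutoff.  A cell is called positive iff its intensity strictly
  exceeds the cutoff, so every calibration cell is itself negative.

* **Relative expression (RE)** — the mean intensity of ~1000 tonsil
  germinal-center-periphery lymphocytes (500 from each of the two reference
  cores, pooled unweighted) defines 100%; any cell or group mean is
  expressed as a percentage of it.  RE is invariant to rescaling all
  intensities by a common factor, which is what makes measurements
  comparable across staining runs.

CD3, expressed by every T cell, doubles as an immunoreactivity control:
a patient whose CD3 RE deviates grossly from the cohort flags a fixation or
processing artefact rather than biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml


class CalibrationError(ValueError):
    pass


@dataclass
class ThresholdEntry:
    marker: str
    cutoff: float
    n_negative_cells: int
    negative_lineage: str
    seed: int | None = None


@dataclass
class ThresholdSet:
    """Per-marker positivity cutoffs derived from known-negative populations."""

    entries: dict[str, ThresholdEntry] = field(default_factory=dict)

    def cutoff(self, marker: str) -> float:
        try:
            return self.entries[marker].cutoff
        except KeyError:
            raise CalibrationError(
                f"no cutoff calibrated for marker {marker!r}"
            ) from None

    def __contains__(self, marker: str) -> bool:
        return marker in self.entries

    def set(self, entry: ThresholdEntry) -> None:
        self.entries[entry.marker] = entry

    def is_positive(self, intensities, marker: str) -> np.ndarray:
        """Strict exceedance: intensity > cutoff."""
        return np.asarray(intensities) > self.cutoff(marker)

    def to_yaml(self, path: str) -> None:
        doc = {
            m: {
                "cutoff": float(e.cutoff),
                "n_negative_cells": int(e.n_negative_cells),
                "negative_lineage": e.negative_lineage,
                "seed": e.seed,
            }
            for m, e in self.entries.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ThresholdSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        ts = cls()
        for marker, d in doc.items():
            ts.set(
                ThresholdEntry(
                    marker=marker,
                    cutoff=float(d["cutoff"]),
                    n_negative_cells=int(d["n_negative_cells"]),
                    negative_lineage=d.get("negative_lineage", ""),
                    seed=d.get("seed"),
                )
            )
        return ts


@dataclass
class ReferenceEntry:
    marker: str
    mean: float
    n_reference_cells: int
    per_core_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ReferenceStats:
    """Per-marker mean intensity of the tonsil reference population (RE=100%)."""

    entries: dict[str, ReferenceEntry] = field(default_factory=dict)

    def mean(self, marker: str) -> float:
        try:
            return self.entries[marker].mean
        except KeyError:
            raise CalibrationError(
                f"no reference mean computed for marker {marker!r}"
            ) from None

    def set(self, entry: ReferenceEntry) -> None:
        self.entries[entry.marker] = entry

    def to_yaml(self, path: str) -> None:
        doc = {
            m: {
                "mean": float(e.mean),
                "n_reference_cells": int(e.n_reference_cells),
                "per_core_counts": {
                    k: int(v) for k, v in e.per_core_counts.items()
                },
            }
            for m, e in self.entries.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ReferenceStats":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rs = cls()
        for marker, d in doc.items():
            rs.set(
                ReferenceEntry(
                    marker=marker,
                    mean=float(d["mean"]),
                    n_reference_cells=int(d["n_reference_cells"]),
                    per_core_counts=d.get("per_core_counts", {}),
                )
            )
        return rs


def calibrate_threshold(
    cells: pd.DataFrame,
    negative_lineage: str,
    marker: str,
    n_sample: int = 200,
    seed: int | None = None,
    lineage_column: str = "lineage",
) -> ThresholdEntry:
    """Cutoff = maximum marker intensity among sampled known-negative cells.

    ``cells`` must carry a lineage assignment (ground truth or a prior call)
    in ``lineage_column`` and the marker intensity column.  ``n_sample``
    cells of ``negative_lineage`` are drawn uniformly without replacement
    (seeded); 50-200 is the recommended range, values outside it warn but
    proceed.
    """
    if marker not in cells.columns:
        raise CalibrationError(f"cells table has no column {marker!r}")
    neg = cells.loc[cells[lineage_column] == negative_lineage, marker]
    if neg.empty:
        raise CalibrationError(
            f"no cells of negative lineage {negative_lineage!r} available "
            f"to calibrate {marker}"
        )
    if not (50 <= n_sample <= 200):
        warnings.warn(
            f"n_sample={n_sample} outside the recommended 50-200 range",
            stacklevel=2,
        )
    if len(neg) < n_sample:
        raise CalibrationError(
            f"only {len(neg)} {negative_lineage} cells available, "
            f"need n_sample={n_sample}"
        )
    rng = np.random.default_rng(seed)
    sampled = rng.choice(neg.to_numpy(), size=n_sample, replace=False)
    return ThresholdEntry(
        marker=marker,
        cutoff=float(sampled.max()),
        n_negative_cells=n_sample,
        negative_lineage=negative_lineage,
        seed=seed,
    )


def compute_reference(
    reference_cells: pd.DataFrame,
    marker: str,
    core_column: str = "core_id",
) -> ReferenceEntry:
    """Arithmetic mean marker intensity over all reference cells, cores pooled.

    Warns (and records a single-core count map) if only one reference core
    contributed cells.
    """
    if reference_cells.empty:
        raise CalibrationError("no reference cells provided")
    if marker not in reference_cells.columns:
        raise CalibrationError(f"reference cells have no column {marker!r}")
    counts = reference_cells[core_column].value_counts().to_dict()
    if len(counts) < 2:
        warnings.warn(
            "only one reference core represented; reference mean may be "
            "unstable",
            stacklevel=2,
        )
    return ReferenceEntry(
        marker=marker,
        mean=float(reference_cells[marker].mean()),
        n_reference_cells=int(len(reference_cells)),
        per_core_counts={str(k): int(v) for k, v in counts.items()},
    )


def relative_expression(value, reference: ReferenceStats, marker: str):
    """RE (%) = 100 * value / reference mean; accepts scalars or arrays."""
    ref_mean = reference.mean(marker)
    if ref_mean <= 0:
        raise CalibrationError(
            f"reference mean for {marker} is {ref_mean}; RE undefined"
        )
    return 100.0 * np.asarray(value, dtype=float) / ref_mean if np.ndim(
        value
    ) else 100.0 * float(value) / ref_mean


@dataclass
class ImmunoreactivityReport:
    per_patient_re: pd.Series
    cv: float
    flagged: list[str]
    factor: float


def immunoreactivity_control(
    per_patient_cd3_re: pd.Series, factor: float = 3.0
) -> ImmunoreactivityReport:
    """Flag patients whose CD3 RE deviates >``factor``x from the cohort median.

    ``per_patient_cd3_re`` is indexed by patient id.  The coefficient of
    variation across patients summarizes overall immunoreactivity stability.
    """
    if len(per_patient_cd3_re) < 2:
        raise CalibrationError(
            "immunoreactivity control needs at least 2 patients"
        )
    vals = per_patient_cd3_re.astype(float)
    med = float(vals.median())
    mean = float(vals.mean())
    cv = float(vals.std(ddof=1) / mean) if mean > 0 else float("nan")
    flagged = vals.index[(vals > factor * med) | (vals < med / factor)]
    return ImmunoreactivityReport(
        per_patient_re=vals,
        cv=cv,
        flagged=[str(p) for p in flagged],
        factor=factor,
    )
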