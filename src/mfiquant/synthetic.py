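"""Seeded synthetic tissue-microarray (TMA) cohorts for checkpoint-receptor analysis.

Generates ground-truth cell tables — and optionally renderable multichannel
core images — with the statistical structure of a Hodgkin-lymphoma
microenvironment TMA: a lymphocytic background of B cells (CD20+) and T-cell
subsets (CD3+ split into CD4/CD8/FOXP3), two checkpoint markers (TIGIT, PD-1)
whose expression varies between patients, and two normal-tonsil reference
cores carrying a high-expressing germinal-center-periphery population that
anchors relative-expression (RE) normalization at 100%.

Per-cell intensities are log-normal: an expressing cell draws around its
population's mean (a.u./um^2) scaled by the patient's expression multiplier;
a non-expressing cell draws around the background mean.  The log-normal is
parameterized by its arithmetic mean m and coefficient of variation cv
(sigma^2 = ln(1+cv^2), mu = ln m - sigma^2/2), so the closed-form mean is m
exactly and cv = 0 degenerates to the noiseless value m.

TIGIT and PD-1 expressor states are drawn jointly per cell from explicit
four-class quadrant probabilities (both / TIGIT-only / PD-1-only / neither),
either given directly or derived from marginal probabilities plus an odds
ratio coupling the two markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

# --------------------------------------------------------------------------
# Marker panel and lineage vocabulary
# --------------------------------------------------------------------------

NUCLEAR = "DAPI"
CD20 = "CD20"
CD3 = "CD3"
CD4 = "CD4"
CD8 = "CD8"
FOXP3 = "FOXP3"
TIGIT = "TIGIT"
PD1 = "PD1"

DEFAULT_PANEL = (NUCLEAR, CD20, CD3, CD4, CD8, FOXP3, TIGIT, PD1)
CHECKPOINT_MARKERS = (TIGIT, PD1)
LINEAGE_MARKERS = (CD20, CD3, CD4, CD8, FOXP3)

B_CELL = "B_CELL"
T_CD4 = "T_CD4"
T_CD8 = "T_CD8"
T_FOXP3 = "T_FOXP3"
REFERENCE = "REFERENCE"

LINEAGES = (B_CELL, T_CD4, T_CD8, T_FOXP3)

#: which lineage markers each generated lineage truly expresses
_LINEAGE_EXPRESSION = {
    B_CELL: (CD20,),
    T_CD4: (CD3, CD4),
    T_CD8: (CD3, CD8),
    T_FOXP3: (CD3, FOXP3),
    REFERENCE: (CD3, CD4),  # follicular helper T cells at the GC periphery
}

QUADRANTS = ("both", "tigit_only", "pd1_only", "neither")

#: schema of the cell table shared with the image-measurement path
CELL_META_COLUMNS = (
    "cell_id",
    "patient_id",
    "core_id",
    "x_um",
    "y_um",
    "area_um2",
    "is_reference",
    "subtype",
)


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


# --------------------------------------------------------------------------
# Configuration dataclasses
# --------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """One mixture component (cell population) of a patient core.

    ``marker_means`` holds the arithmetic mean intensity (a.u./um^2) an
    expressing cell of this population draws around, per marker;
    ``background_mean`` is the mean for markers the cell does not express.
    Checkpoint expressor states come from ``quadrant_probs`` when given
    (both, tigit_only, pd1_only, neither), otherwise from
    ``checkpoint_pos_prob`` marginals coupled by ``coexpr_odds`` (odds
    ratio; 1.0 = independent).
    """

    lineage_label: str
    mixture_weight: float
    marker_means: dict[str, float] = field(default_factory=dict)
    background_mean: float = 1.0
    checkpoint_pos_prob: dict[str, float] = field(default_factory=dict)
    coexpr_odds: float = 1.0
    quadrant_probs: tuple[float, float, float, float] | None = None

    def validate(self) -> None:
        if self.lineage_label not in LINEAGES:
            raise ConfigurationError(
                f"unknown lineage_label {self.lineage_label!r}; "
                f"expected one of {LINEAGES}"
            )
        if not (0.0 <= self.mixture_weight <= 1.0):
            raise ConfigurationError(
                f"population {self.lineage_label}: mixture_weight "
                f"{self.mixture_weight} outside [0, 1]"
            )
        if self.background_mean <= 0:
            raise ConfigurationError(
                f"population {self.lineage_label}: background_mean must be > 0"
            )
        for marker, m in self.marker_means.items():
            if m <= 0:
                raise ConfigurationError(
                    f"population {self.lineage_label}: marker_means[{marker}] "
                    "must be > 0"
                )
        for marker, p in self.checkpoint_pos_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"population {self.lineage_label}: "
                    f"checkpoint_pos_prob[{marker}]={p} outside [0, 1]"
                )
        if self.coexpr_odds <= 0:
            raise ConfigurationError(
                f"population {self.lineage_label}: coexpr_odds must be > 0"
            )
        if self.quadrant_probs is not None:
            q = np.asarray(self.quadrant_probs, dtype=float)
            if q.shape != (4,) or (q < 0).any() or abs(q.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"population {self.lineage_label}: quadrant_probs must be "
                    "4 non-negative values summing to 1"
                )

    def joint_quadrant_probs(self) -> np.ndarray:
        """Joint (both, tigit_only, pd1_only, neither) probabilities."""
        if self.quadrant_probs is not None:
            return np.asarray(self.quadrant_probs, dtype=float)
        p_t = self.checkpoint_pos_prob.get(TIGIT, 0.0)
        p_p = self.checkpoint_pos_prob.get(PD1, 0.0)
        p11 = _joint_from_margins_and_odds(p_t, p_p, self.coexpr_odds)
        return np.array([p11, p_t - p11, p_p - p11, 1.0 - p_t - p_p + p11])


def _joint_from_margins_and_odds(p_t: float, p_p: float, odds: float) -> float:
    """P(both+) for a 2x2 table with given margins and odds ratio (Plackett)."""
    if p_t in (0.0, 1.0) or p_p in (0.0, 1.0) or odds == 1.0:
        return p_t * p_p
    a = odds - 1.0
    s = 1.0 + (p_t + p_p) * a
    disc = s * s - 4.0 * odds * a * p_t * p_p
    p11 = (s - math.sqrt(disc)) / (2.0 * a)
    return float(min(max(p11, max(0.0, p_t + p_p - 1.0)), min(p_t, p_p)))


@dataclass
class PatientSpec:
    """One patient core: subtype, cell count and checkpoint expression scale.

    ``expression_scale`` multiplies the checkpoint-marker means of every
    expressing cell of this patient, realizing inter-patient relative-
    expression variability; a mapping gives per-marker scales, a float
    applies to both checkpoints.  ``n_cells=None`` draws the analyzed cell
    count uniformly from [18000, 30000] at generation time.
    """

    patient_id: str
    subtype: str = "NSCHL"
    n_cells: int | None = None
    expression_scale: float | dict[str, float] = 1.0
    populations: list[PopulationSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_cells is not None and self.n_cells <= 0:
            raise ConfigurationError(
                f"patient {self.patient_id}: n_cells must be > 0"
            )
        for s in self.scale_map().values():
            if s <= 0:
                raise ConfigurationError(
                    f"patient {self.patient_id}: expression_scale must be > 0"
                )
        if not self.populations:
            raise ConfigurationError(
                f"patient {self.patient_id}: no populations configured"
            )
        total = 0.0
        for pop in self.populations:
            pop.validate()
            total += pop.mixture_weight
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"patient {self.patient_id}: mixture weights sum to {total!r}, "
                "expected 1"
            )

    def scale_map(self) -> dict[str, float]:
        if isinstance(self.expression_scale, dict):
            return {m: float(self.expression_scale.get(m, 1.0))
                    for m in CHECKPOINT_MARKERS}
        return {m: float(self.expression_scale) for m in CHECKPOINT_MARKERS}


@dataclass
class ReferenceCoreSpec:
    """One tonsil reference core: ~500 germinal-center-periphery cells."""

    core_id: str
    n_reference_cells: int = 500
    n_jitter: int = 25
    marker_means: dict[str, float] = field(default_factory=dict)
    background_mean: float = 1.0

    def validate(self) -> None:
        if self.n_reference_cells <= 0:
            raise ConfigurationError(
                f"reference core {self.core_id}: n_reference_cells must be > 0"
            )
        if self.n_reference_cells < 50:
            warnings.warn(
                f"reference core {self.core_id}: only "
                f"{self.n_reference_cells} cells configured; the reference "
                "mean will be unstable",
                stacklevel=2,
            )


@dataclass
class CohortConfig:
    """Full cohort: patients, two tonsil reference cores, panel, noise, seed."""

    patients: list[PatientSpec]
    reference_cores: list[ReferenceCoreSpec]
    markers: tuple[str, ...] = DEFAULT_PANEL
    noise_cv: float = 0.3
    nuclear_mean: float = 20.0
    cell_area_mean_um2: float = 45.0
    cell_area_cv: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if len(self.reference_cores) != 2:
            raise ConfigurationError(
                f"exactly 2 tonsil reference cores required, got "
                f"{len(self.reference_cores)}"
            )
        if NUCLEAR not in self.markers:
            raise ConfigurationError("marker panel lacks a nuclear channel")
        if not any(m in self.markers for m in LINEAGE_MARKERS):
            raise ConfigurationError("marker panel lacks a lineage marker")
        if not any(m in self.markers for m in CHECKPOINT_MARKERS):
            raise ConfigurationError("marker panel lacks a checkpoint marker")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        for p in self.patients:
            p.validate()
        for r in self.reference_cores:
            r.validate()


# --------------------------------------------------------------------------
# Log-normal sampling parameterized by arithmetic mean and CV
# --------------------------------------------------------------------------


def lognormal_mean_cv(
    rng: np.random.Generator, mean: np.ndarray, cv: float, size: int
) -> np.ndarray:
    """Draw log-normal values with given arithmetic mean(s) and CV.

    ``cv=0`` returns the means exactly (noiseless limit).
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if cv == 0:
        return mean.copy()
    sigma2 = math.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2))


# --------------------------------------------------------------------------
# Cell-table generation
# --------------------------------------------------------------------------


def generate_cell_table(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the per-cell intensity table and its ground-truth table.

    Returns ``(cells, truth)``: ``cells`` has one row per cell with metadata
    columns plus one noisy intensity column per panel marker; ``truth``
    carries the generated lineage, checkpoint expressor states and the
    noiseless intensity per marker.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cell_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    next_cell_id = 1

    for patient in config.patients:
        n = patient.n_cells
        if n is None:
            n = int(rng.integers(18000, 30001))
        cells, truth = _generate_patient_cells(
            config, patient, n, rng, next_cell_id
        )
        next_cell_id += n
        cell_frames.append(cells)
        truth_frames.append(truth)

    ref_cells, ref_truth = _generate_reference_frames(config, rng, next_cell_id)
    cell_frames.append(ref_cells)
    truth_frames.append(ref_truth)

    cells = pd.concat(cell_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return cells, truth


def _generate_patient_cells(
    config: CohortConfig,
    patient: PatientSpec,
    n: int,
    rng: np.random.Generator,
    id_start: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    pops = patient.populations
    weights = np.array([p.mixture_weight for p in pops], dtype=float)
    pop_idx = rng.choice(len(pops), size=n, p=weights / weights.sum())
    lineage = np.array([pops[i].lineage_label for i in pop_idx])

    scale = patient.scale_map()

    # joint checkpoint expressor quadrant per cell, drawn per population
    quadrant = np.empty(n, dtype=np.int64)  # index into QUADRANTS
    for i, pop in enumerate(pops):
        sel = pop_idx == i
        k = int(sel.sum())
        if k:
            quadrant[sel] = rng.choice(4, size=k, p=pop.joint_quadrant_probs())
    tigit_on = (quadrant == 0) | (quadrant == 1)
    pd1_on = (quadrant == 0) | (quadrant == 2)

    noiseless: dict[str, np.ndarray] = {}
    for marker in config.markers:
        if marker == NUCLEAR:
            mean = np.full(n, config.nuclear_mean)
        else:
            mean = np.empty(n)
            for i, pop in enumerate(pops):
                sel = pop_idx == i
                if not sel.any():
                    continue
                if marker in CHECKPOINT_MARKERS:
                    on = tigit_on if marker == TIGIT else pd1_on
                    expr_mean = (
                        pop.marker_means.get(marker, pop.background_mean)
                        * scale[marker]
                    )
                    mean[sel] = np.where(
                        on[sel], expr_mean, pop.background_mean
                    )
                elif marker in _LINEAGE_EXPRESSION[pop.lineage_label]:
                    mean[sel] = pop.marker_means.get(
                        marker, pop.background_mean
                    )
                else:
                    mean[sel] = pop.background_mean
        noiseless[marker] = mean

    cells, truth = _assemble_frames(
        config, rng, id_start, n,
        patient_id=patient.patient_id, core_id=patient.patient_id,
        is_reference=False, subtype=patient.subtype, lineage=lineage,
        tigit_on=tigit_on, pd1_on=pd1_on, noiseless=noiseless,
    )
    return cells, truth


def _generate_reference_frames(
    config: CohortConfig, rng: np.random.Generator, id_start: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    frames = []
    truths = []
    for core in config.reference_cores:
        n = core.n_reference_cells
        if core.n_jitter:
            n = int(n + rng.integers(-core.n_jitter, core.n_jitter + 1))
        n = max(n, 1)
        noiseless = {}
        for marker in config.markers:
            if marker == NUCLEAR:
                mean = np.full(n, config.nuclear_mean)
            elif marker in core.marker_means:
                mean = np.full(n, core.marker_means[marker])
            elif marker in _LINEAGE_EXPRESSION[REFERENCE]:
                # CD3/CD4 default to the checkpoint level if not configured
                mean = np.full(n, core.background_mean)
            else:
                mean = np.full(n, core.background_mean)
            noiseless[marker] = mean
        cells, truth = _assemble_frames(
            config, rng, id_start, n,
            patient_id=core.core_id, core_id=core.core_id,
            is_reference=True,
            lineage=np.full(n, REFERENCE),
            tigit_on=np.ones(n, dtype=bool),
            pd1_on=np.ones(n, dtype=bool),
            noiseless=noiseless,
        )
        id_start += n
        frames.append(cells)
        truths.append(truth)
    return pd.concat(frames, ignore_index=True), pd.concat(
        truths, ignore_index=True
    )


def _assemble_frames(
    config: CohortConfig,
    rng: np.random.Generator,
    id_start: int,
    n: int,
    *,
    patient_id: str,
    core_id: str,
    is_reference: bool,
    subtype: str = "TONSIL",
    lineage: np.ndarray,
    tigit_on: np.ndarray,
    pd1_on: np.ndarray,
    noiseless: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    area = lognormal_mean_cv(
        rng, config.cell_area_mean_um2, config.cell_area_cv, n
    )
    meta = {
        "cell_id": np.arange(id_start, id_start + n, dtype=np.int64),
        "patient_id": patient_id,
        "core_id": core_id,
        "x_um": np.full(n, np.nan),
        "y_um": np.full(n, np.nan),
        "area_um2": area,
        "is_reference": is_reference,
        "subtype": subtype,
    }
    cells = pd.DataFrame(meta)
    truth = pd.DataFrame(
        {
            "cell_id": meta["cell_id"],
            "patient_id": patient_id,
            "lineage": lineage,
            "tigit_expressor": tigit_on,
            "pd1_expressor": pd1_on,
        }
    )
    for marker in config.markers:
        cells[marker] = lognormal_mean_cv(
            rng, noiseless[marker], config.noise_cv, n
        )
        truth[f"true_{marker}"] = noiseless[marker]
    return cells, truth


def generate_reference_cells(config: CohortConfig) -> pd.DataFrame:
    """Generate only the tonsil reference cells (both cores).

    Their configured checkpoint mean intensities anchor RE = 100%.  Uses the
    same stream layout as :func:`generate_cell_table` restricted to the
    reference cores.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells, _ = _generate_reference_frames(config, rng, 1)
    return cells


# --------------------------------------------------------------------------
# Core image rendering
# --------------------------------------------------------------------------


@dataclass
class ImageSpec:
    """Geometry and digitization of a rendered core image.

    ``intensity_gain`` converts intensity (a.u./um^2) to detector counts:
    pixel value = round(intensity * pixel_area_um2 * gain), so that
    sum(pixels) / (gain * area_um2) recovers the intensity.  The gain and
    channel order belong in the sidecar YAML next to the TIFF.
    """

    core_diameter_um: float = 2000.0
    pixel_size_um: float = 0.5
    intensity_gain: float = 100.0
    placement_margin_um: float = 1.0
    max_placement_tries: int = 200

    @property
    def shape(self) -> tuple[int, int]:
        n = int(round(self.core_diameter_um / self.pixel_size_um))
        return (n, n)


def place_cells(
    cells: pd.DataFrame, spec: ImageSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign non-overlapping (x, y) positions inside the core disc.

    Hard-disc rejection sampling: each cell is a disc of radius
    sqrt(area/pi); candidate centers are drawn uniformly in the core and
    rejected on overlap (separation < r_i + r_j + margin).  Raises if a cell
    cannot be placed within the retry budget, reporting how many fit.
    """
    cells = cells.copy()
    radius = np.sqrt(cells["area_um2"].to_numpy() / math.pi)
    R = spec.core_diameter_um / 2.0
    centers = np.empty((len(cells), 2))
    placed_r = np.empty(len(cells))
    for i, r in enumerate(radius):
        ok = False
        for _ in range(spec.max_placement_tries):
            # uniform in the disc, keeping the whole cell inside
            rho = (R - r) * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            x = R + rho * math.cos(theta)
            y = R + rho * math.sin(theta)
            if i:
                d2 = ((centers[:i] - (x, y)) ** 2).sum(axis=1)
                min_sep = placed_r[:i] + r + spec.placement_margin_um
                if (d2 < min_sep**2).any():
                    continue
            centers[i] = (x, y)
            placed_r[i] = r
            ok = True
            break
        if not ok:
            raise ValueError(
                f"could not place cell {i + 1} of {len(cells)} without "
                f"overlap after {spec.max_placement_tries} tries; "
                f"{i} cells fit at this density"
            )
    cells["x_um"] = centers[:, 0]
    cells["y_um"] = centers[:, 1]
    return cells


def render_core_image(
    cells: pd.DataFrame,
    markers: tuple[str, ...] = DEFAULT_PANEL,
    spec: ImageSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one core as a (C, H, W) uint16 stack plus a truth label mask.

    Cells without positions are placed first (see :func:`place_cells`).
    Every cell paints a uniform disc in each marker channel whose measured
    mean intensity (per the sidecar gain) equals its table intensity up to
    16-bit quantization; the mask holds one positive label per cell
    (the cell_id order, starting at 1), 0 = background.

    Returns ``(stack, mask, placed_cells)``.
    """
    spec = spec or ImageSpec()
    h, w = spec.shape
    stack = np.zeros((len(markers), h, w), dtype=np.uint16)
    mask = np.zeros((h, w), dtype=np.uint16)
    if len(cells) == 0:
        return stack, mask, cells.copy()
    if len(cells) > np.iinfo(np.uint16).max:
        raise ValueError("too many cells for a 16-bit label mask")

    if cells[["x_um", "y_um"]].isna().any().any():
        rng = rng if rng is not None else np.random.default_rng(0)
        cells = place_cells(cells, spec, rng)
    else:
        cells = cells.copy()

    px = spec.pixel_size_um
    px_area = px * px
    yy, xx = np.mgrid[0:h, 0:w]
    # physical coordinate of each pixel center
    xc = (xx + 0.5) * px
    yc = (yy + 0.5) * px

    radius = np.sqrt(cells["area_um2"].to_numpy() / math.pi)
    xs = cells["x_um"].to_numpy()
    ys = cells["y_um"].to_numpy()
    intens = cells[list(markers)].to_numpy()

    for i in range(len(cells)):
        r = radius[i]
        # bounding box in pixels
        x0 = max(int((xs[i] - r) / px) - 1, 0)
        x1 = min(int((xs[i] + r) / px) + 2, w)
        y0 = max(int((ys[i] - r) / px) - 1, 0)
        y1 = min(int((ys[i] + r) / px) + 2, h)
        sub = (
            (xc[y0:y1, x0:x1] - xs[i]) ** 2 + (yc[y0:y1, x0:x1] - ys[i]) ** 2
            <= r * r
        )
        mask[y0:y1, x0:x1][sub] = i + 1
        for c in range(len(markers)):
            dn = int(round(intens[i, c] * px_area * spec.intensity_gain))
            stack[c, y0:y1, x0:x1][sub] = min(dn, np.iinfo(np.uint16).max)
    return stack, mask, cells


def write_core_image(
    path_tiff: str,
    path_yaml: str,
    stack: np.ndarray,
    markers: tuple[str, ...],
    spec: ImageSpec,
    mask: np.ndarray | None = None,
    mask_path: str | None = None,
) -> None:
    """Write a multi-page 16-bit TIFF plus its channel-order sidecar YAML."""
    import tifffile

    tifffile.imwrite(path_tiff, stack.astype(np.uint16))
    sidecar = {
        "channels": list(markers),
        "pixel_size_um": spec.pixel_size_um,
        "intensity_gain": spec.intensity_gain,
    }
    with open(path_yaml, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    if mask is not None and mask_path is not None:
        tifffile.imwrite(mask_path, mask.astype(np.uint16))


# --------------------------------------------------------------------------
# Ready-made cohort configurations (the study conditions)
# --------------------------------------------------------------------------

#: lymphocytic-background mixture of a classical-HL core
DEFAULT_WEIGHTS = {B_CELL: 0.20, T_CD4: 0.45, T_CD8: 0.25, T_FOXP3: 0.10}

#: expressor mean intensity for lineage and checkpoint markers (a.u./um^2)
DEFAULT_EXPRESSOR_MEAN = 50.0
DEFAULT_BACKGROUND_MEAN = 1.0
#: tonsil germinal-center-periphery cells: the highest physiological level
DEFAULT_REFERENCE_MEAN = 50.0

#: four-class joint checkpoint probabilities of a classical-HL T cell
#: (both, TIGIT only, PD-1 only, neither)
HL_T_CELL_QUADRANT_PROBS = (0.68, 0.14, 0.05, 0.13)


def make_population(
    lineage: str,
    weight: float,
    quadrant_probs: tuple[float, float, float, float] | None = None,
    checkpoint_pos_prob: dict[str, float] | None = None,
    coexpr_odds: float = 1.0,
    expressor_mean: float = DEFAULT_EXPRESSOR_MEAN,
    background_mean: float = DEFAULT_BACKGROUND_MEAN,
) -> PopulationSpec:
    """Population with the default well-separated intensity structure."""
    markers = dict.fromkeys(
        _LINEAGE_EXPRESSION[lineage] + CHECKPOINT_MARKERS, expressor_mean
    )
    return PopulationSpec(
        lineage_label=lineage,
        mixture_weight=weight,
        marker_means=markers,
        background_mean=background_mean,
        checkpoint_pos_prob=checkpoint_pos_prob or {},
        coexpr_odds=coexpr_odds,
        quadrant_probs=quadrant_probs,
    )


def default_reference_cores(
    reference_mean: float = DEFAULT_REFERENCE_MEAN,
) -> list[ReferenceCoreSpec]:
    means = {
        CD3: DEFAULT_EXPRESSOR_MEAN,
        CD4: DEFAULT_EXPRESSOR_MEAN,
        TIGIT: reference_mean,
        PD1: reference_mean,
    }
    return [
        ReferenceCoreSpec(core_id=f"TONSIL_{i + 1}", marker_means=dict(means))
        for i in range(2)
    ]


def nschl_quadrant_cohort(
    n_patients: int = 30,
    n_cells: int = 20000,
    seed: int = 0,
    quadrant_probs: tuple[float, float, float, float] = (
        HL_T_CELL_QUADRANT_PROBS
    ),
    weights: dict[str, float] | None = None,
    noise_cv: float = 0.3,
) -> CohortConfig:
    """NSCHL-style cohort configured to a target T-cell quadrant structure.

    T-cell populations share the given joint quadrant probabilities; B cells
    are checkpoint-negative (the TIGIT-negative calibration population).
    Expressor means sit 50x above background so positivity calling is
    governed by the cutoff rule, not by overlap.  Patient expression scales
    are drawn in [0.5, 1.2] (kept >= 10x background over noise so the
    configured quadrants remain recoverable).
    """
    weights = weights or DEFAULT_WEIGHTS
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n_patients):
        pops = [
            make_population(B_CELL, weights[B_CELL]),
            make_population(T_CD4, weights[T_CD4], quadrant_probs),
            make_population(T_CD8, weights[T_CD8], quadrant_probs),
            make_population(T_FOXP3, weights[T_FOXP3], quadrant_probs),
        ]
        patients.append(
            PatientSpec(
                patient_id=f"NSCHL_{i + 1:02d}",
                subtype="NSCHL",
                n_cells=n_cells,
                expression_scale=float(rng.uniform(0.5, 1.2)),
                populations=pops,
            )
        )
    return CohortConfig(
        patients=patients,
        reference_cores=default_reference_cores(),
        noise_cv=noise_cv,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def tigit_positivity_cohort(
    marginal_tigit: float = 0.70,
    marginal_pd1: float = 0.73,
    coexpr_odds: float = 25.0,
    n_patients: int = 30,
    n_cells: int = 20000,
    seed: int = 0,
) -> CohortConfig:
    """Cohort whose CD3 populations have a set marginal TIGIT positivity.

    The default marginals reproduce the observed overall scenario: 70% of
    CD3+ T cells TIGIT-positive, with strong within-cell TIGIT/PD-1
    coupling.
    """
    rng = np.random.default_rng(seed)
    marg = {TIGIT: marginal_tigit, PD1: marginal_pd1}
    weights = DEFAULT_WEIGHTS
    patients = []
    for i in range(n_patients):
        pops = [
            make_population(B_CELL, weights[B_CELL]),
            make_population(T_CD4, weights[T_CD4], None, marg, coexpr_odds),
            make_population(T_CD8, weights[T_CD8], None, marg, coexpr_odds),
            make_population(
                T_FOXP3, weights[T_FOXP3], None, marg, coexpr_odds
            ),
        ]
        patients.append(
            PatientSpec(
                patient_id=f"HL_{i + 1:02d}",
                subtype="NSCHL",
                n_cells=n_cells,
                expression_scale=float(rng.uniform(0.5, 1.2)),
                populations=pops,
            )
        )
    return CohortConfig(
        patients=patients,
        reference_cores=default_reference_cores(),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def full_study_cohort(seed: int = 0, n_cells: int | None = None) -> CohortConfig:
    """A 40-patient cohort mirroring the study's subtype composition.

    30 NSCHL, 7 MCCHL, 1 LRCHL, 1 NLPHL and 1 of undetermined subtype;
    2 mm cores with 18,000-30,000 analyzed cells each unless ``n_cells``
    pins the count.  Patient expression scales span a wide range so
    per-patient relative expression is highly variable, with the NLPHL case
    configured above the tonsil reference level.
    """
    rng = np.random.default_rng(seed)
    subtype_counts = [("NSCHL", 30), ("MCCHL", 7), ("LRCHL", 1),
                      ("NLPHL", 1), ("UNDETERMINED", 1)]
    patients = []
    i = 0
    for subtype, count in subtype_counts:
        for _ in range(count):
            i += 1
            if subtype == "NLPHL":
                scale = float(rng.uniform(1.0, 1.25))
            else:
                scale = float(rng.uniform(0.05, 1.0))
            pops = [
                make_population(B_CELL, DEFAULT_WEIGHTS[B_CELL]),
                make_population(
                    T_CD4, DEFAULT_WEIGHTS[T_CD4], HL_T_CELL_QUADRANT_PROBS
                ),
                make_population(
                    T_CD8, DEFAULT_WEIGHTS[T_CD8], HL_T_CELL_QUADRANT_PROBS
                ),
                make_population(
                    T_FOXP3, DEFAULT_WEIGHTS[T_FOXP3],
                    HL_T_CELL_QUADRANT_PROBS,
                ),
            ]
            patients.append(
                PatientSpec(
                    patient_id=f"HL_{i:02d}",
                    subtype=subtype,
                    n_cells=n_cells,
                    expression_scale=scale,
                    populations=pops,
                )
            )
    return CohortConfig(
        patients=patients,
        reference_cores=default_reference_cores(),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# --------------------------------------------------------------------------
# YAML config I/O (CLI surface)
# --------------------------------------------------------------------------


def cohort_config_to_yaml(config: CohortConfig, path: str) -> None:
    def pop_dict(p: PopulationSpec) -> dict:
        d = {
            "lineage_label": p.lineage_label,
            "mixture_weight": p.mixture_weight,
            "marker_means": p.marker_means,
            "background_mean": p.background_mean,
            "checkpoint_pos_prob": p.checkpoint_pos_prob,
            "coexpr_odds": p.coexpr_odds,
        }
        if p.quadrant_probs is not None:
            d["quadrant_probs"] = list(p.quadrant_probs)
        return d

    doc = {
        "seed": config.seed,
        "noise_cv": config.noise_cv,
        "nuclear_mean": config.nuclear_mean,
        "cell_area_mean_um2": config.cell_area_mean_um2,
        "cell_area_cv": config.cell_area_cv,
        "markers": list(config.markers),
        "patients": [
            {
                "patient_id": p.patient_id,
                "subtype": p.subtype,
                "n_cells": p.n_cells,
                "expression_scale": p.expression_scale,
                "populations": [pop_dict(q) for q in p.populations],
            }
            for p in config.patients
        ],
        "reference_cores": [
            {
                "core_id": r.core_id,
                "n_reference_cells": r.n_reference_cells,
                "n_jitter": r.n_jitter,
                "marker_means": r.marker_means,
                "background_mean": r.background_mean,
            }
            for r in config.reference_cores
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def cohort_config_from_yaml(path: str) -> CohortConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    patients = [
        PatientSpec(
            patient_id=p["patient_id"],
            subtype=p.get("subtype", "NSCHL"),
            n_cells=p.get("n_cells"),
            expression_scale=p.get("expression_scale", 1.0),
            populations=[
                PopulationSpec(
                    lineage_label=q["lineage_label"],
                    mixture_weight=q["mixture_weight"],
                    marker_means=q.get("marker_means", {}),
                    background_mean=q.get("background_mean", 1.0),
                    checkpoint_pos_prob=q.get("checkpoint_pos_prob", {}),
                    coexpr_odds=q.get("coexpr_odds", 1.0),
                    quadrant_probs=(
                        tuple(q["quadrant_probs"])
                        if q.get("quadrant_probs") is not None
                        else None
                    ),
                )
                for q in p["populations"]
            ],
        )
        for p in doc["patients"]
    ]
    cores = [
        ReferenceCoreSpec(
            core_id=r["core_id"],
            n_reference_cells=r.get("n_reference_cells", 500),
            n_jitter=r.get("n_jitter", 25),
            marker_means=r.get("marker_means", {}),
            background_mean=r.get("background_mean", 1.0),
        )
        for r in doc["reference_cores"]
    ]
    return CohortConfig(
        patients=patients,
        reference_cores=cores,
        markers=tuple(doc.get("markers", DEFAULT_PANEL)),
        noise_cv=doc.get("noise_cv", 0.3),
        nuclear_mean=doc.get("nuclear_mean", 20.0),
        cell_area_mean_um2=doc.get("cell_area_mean_um2", 45.0),
        cell_area_cv=doc.get("cell_area_cv", 0.2),
        seed=doc.get("seed", 0),
    )
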