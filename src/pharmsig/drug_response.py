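"""IC50 panel summarization: thresholding, quantiles, drug categories,
outliers, and six-bin sensitivity discretization.

A drug is *effective* when the panel median IC50 is at or below a low-dose
cut (default 1 µM), *ineffective* when the median sits at the assay ceiling
(default 8 µM), and *selective* when the interquartile spread is wide (the
q75/q25 fold exceeds a configured ratio) — the long-boxplot pattern of drugs
that act on only a subset of lines. Everything else is *intermediate*.

Two outlier reports are produced: the conventional Tukey 1.5·IQR whisker
rule, and a "sensitive outlier" report listing lines with IC50 below 4 µM
for drugs whose median equals the ceiling — the cells worth a second look
under an otherwise inert drug.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AxisSemantics, DrugResponseMatrix, LabeledMatrix

__all__ = [
    "DrugCategory",
    "DrugSummary",
    "SensitivityBins",
    "threshold_ic50",
    "summarize_drug",
    "categorize_drug",
    "find_outliers",
    "sensitive_outliers",
    "summarize_panel",
    "bin_sensitivity",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_CEILING = 8.0  # µM, assay censoring concentration
DEFAULT_EFFECTIVE_CUT = 1.0  # µM, low-dose median for an "effective" call
DEFAULT_SELECTIVE_FOLD = 20.0  # q75/q25 ratio marking a long boxplot
SENSITIVE_OUTLIER_CUT = 4.0  # µM, reported for drugs whose median is at ceiling
DEFAULT_BIN_EDGES = (0.1, 0.5, 1.0, 2.0, 4.0)  # µM, six-bin color scale


class DrugCategory(str, enum.Enum):
    effective = "effective"
    ineffective = "ineffective"
    selective = "selective"
    intermediate = "intermediate"


@dataclass
class DrugSummary:
    """Per-drug panel summary: type-7 quantiles, category, outliers."""

    drug_id: str
    q25: float
    q50: float
    q75: float
    n: int
    category: DrugCategory | None = None
    outliers: list[tuple[str, float]] = field(default_factory=list)
    sensitive_outliers: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValueError(
                f"{self.drug_id}: quantiles must be ordered, got "
                f"({self.q25}, {self.q50}, {self.q75})"
            )


@dataclass
class SensitivityBins:
    """Cell × drug ordinal discretization into 6 bins (higher = more resistant)."""

    bin_edges: tuple[float, ...]
    binned: LabeledMatrix  # cell_by_drug, values in {1..6} or NaN

    def __post_init__(self) -> None:
        if len(self.bin_edges) != 5:
            raise ValueError("exactly 5 edges define 6 bins")


def threshold_ic50(
    drm: DrugResponseMatrix, ceiling: float = DEFAULT_CEILING
) -> DrugResponseMatrix:
    """Censor IC50 values above the assay ceiling at the ceiling.

    Returns a new panel whose ``censored`` mask records which entries were
    thresholded (strictly above the ceiling; values already at the ceiling
    keep an unset flag unless previously censored). Idempotent.
    """
    values = drm.matrix.values
    if np.any(values[~np.isnan(values)] <= 0):
        bad = np.argwhere(np.nan_to_num(values, nan=1.0) <= 0)[0]
        raise ValueError(
            f"non-positive IC50 at cell {drm.cell_ids[bad[0]]!r}, "
            f"drug {drm.drug_ids[bad[1]]!r}"
        )
    over = values > ceiling
    new_values = np.where(over, ceiling, values)
    return DrugResponseMatrix(
        matrix=LabeledMatrix(
            list(drm.cell_ids),
            list(drm.drug_ids),
            new_values,
            AxisSemantics.cell_by_drug,
            drm.matrix.units or "µM",
        ),
        ceiling=ceiling,
        censored=over | drm.censored,
    )


def summarize_drug(values: pd.Series | np.ndarray) -> tuple[float, float, float]:
    """Return the (25%, 50%, 75%) quantiles of one drug's IC50 vector.

    Uses linear interpolation with plotting position h = (n−1)p — the
    "type 7" convention, the default of common statistical environments, so
    summaries are comparable with published quantile tables. Missing values
    are dropped; fewer than 2 observations is an error.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError(f"need at least 2 non-missing IC50 values, got {v.size}")
    q25, q50, q75 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return float(q25), float(q50), float(q75)


def categorize_drug(
    summary: DrugSummary,
    effective_cut: float = DEFAULT_EFFECTIVE_CUT,
    ceiling: float = DEFAULT_CEILING,
    selective_fold: float = DEFAULT_SELECTIVE_FOLD,
) -> DrugCategory:
    """Classify a drug from its quantile summary.

    effective ⇔ q50 ≤ effective_cut; ineffective ⇔ q50 ≥ ceiling; otherwise
    selective ⇔ q75/q25 ≥ selective_fold; else intermediate.
    """
    if summary.q50 <= effective_cut:
        return DrugCategory.effective
    if summary.q50 >= ceiling:
        return DrugCategory.ineffective
    if summary.q25 > 0 and summary.q75 / summary.q25 >= selective_fold:
        return DrugCategory.selective
    return DrugCategory.intermediate


def find_outliers(
    values: pd.Series, summary: DrugSummary
) -> list[tuple[str, float]]:
    """Cells outside the Tukey fences q25 − 1.5·IQR, q75 + 1.5·IQR."""
    iqr = summary.q75 - summary.q25
    lo, hi = summary.q25 - 1.5 * iqr, summary.q75 + 1.5 * iqr
    out = [
        (str(cell), float(v))
        for cell, v in values.items()
        if not np.isnan(v) and (v < lo or v > hi)
    ]
    return sorted(out, key=lambda t: t[0])


def sensitive_outliers(
    values: pd.Series,
    summary: DrugSummary,
    ceiling: float = DEFAULT_CEILING,
    cut: float = SENSITIVE_OUTLIER_CUT,
) -> list[tuple[str, float]]:
    """Lines with IC50 < 4 µM under a drug whose median sits at the ceiling."""
    if summary.q50 < ceiling:
        return []
    out = [
        (str(cell), float(v))
        for cell, v in values.items()
        if not np.isnan(v) and v < cut
    ]
    return sorted(out, key=lambda t: t[0])


def summarize_panel(
    drm: DrugResponseMatrix,
    effective_cut: float = DEFAULT_EFFECTIVE_CUT,
    selective_fold: float = DEFAULT_SELECTIVE_FOLD,
) -> list[DrugSummary]:
    """Full per-drug report for a panel, ordered by drug id."""
    summaries = []
    for drug in sorted(drm.drug_ids):
        vals = drm.drug_values(drug)
        q25, q50, q75 = summarize_drug(vals)
        s = DrugSummary(drug_id=drug, q25=q25, q50=q50, q75=q75,
                        n=int(vals.notna().sum()))
        s.category = categorize_drug(s, effective_cut, drm.ceiling, selective_fold)
        s.outliers = find_outliers(vals, s)
        s.sensitive_outliers = sensitive_outliers(vals, s, drm.ceiling)
        summaries.append(s)
    return summaries


def bin_sensitivity(
    drm: DrugResponseMatrix, bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
) -> SensitivityBins:
    """Discretize IC50s into 6 ordinal bins for mosaic-plot export.

    Bin k collects values in (edge_{k−1}, edge_k] with edge_0 = 0 and
    edge_6 = the ceiling (right-closed convention); missing stays missing.
    """
    edges = tuple(float(e) for e in bin_edges)
    if len(edges) != 5 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"need 5 strictly increasing edges, got {edges}")
    if edges[0] <= 0 or edges[-1] >= drm.ceiling:
        raise ValueError("edges must lie strictly inside (0, ceiling)")
    v = drm.matrix.values
    binned = np.where(
        np.isnan(v), np.nan, np.searchsorted(edges, v, side="left") + 1.0
    )
    return SensitivityBins(
        bin_edges=edges,
        binned=LabeledMatrix(
            list(drm.cell_ids), list(drm.drug_ids), binned,
            AxisSemantics.cell_by_drug, "bin",
        ),
    )
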