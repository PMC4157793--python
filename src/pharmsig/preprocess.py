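"""Expression and copy-number preprocessing.

Expression matrices arrive already array-normalized (e.g. RMA at the probe
level); this module handles the remaining steps: dropping unannotated
probes, averaging probes within a gene, averaging duplicate samples, and
per-gene standard (z-score) normalization. Copy-number tables are recoded
onto a five-level ordinal scale, and RNA-seq counts are z-scored per gene
for cross-platform signature projection.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .datamodel import AxisSemantics, CNVCategory, LabeledMatrix

__all__ = [
    "collapse_probes",
    "average_duplicates",
    "standard_normalize",
    "recode_cnv",
    "recode_cnv_matrix",
    "normalize_counts",
]

log = logging.getLogger(__name__)


def collapse_probes(
    probe_matrix: LabeledMatrix, probe_gene_map: dict[str, str]
) -> LabeledMatrix:
    """Collapse a probe × sample matrix to gene level by averaging probes.

    Probes mapping to an empty gene symbol (or absent from the map) are
    dropped. Each gene row is the unweighted arithmetic mean of its probes'
    rows; output genes are sorted lexicographically.
    """
    groups: dict[str, list[int]] = {}
    for i, probe in enumerate(probe_matrix.row_ids):
        gene = probe_gene_map.get(probe, "")
        if gene:
            groups.setdefault(gene, []).append(i)
    if not groups:
        raise ValueError("no probe maps to any gene symbol")
    genes = sorted(groups)
    values = np.vstack(
        [np.nanmean(probe_matrix.values[groups[g]], axis=0) for g in genes]
    )
    return LabeledMatrix(
        genes, list(probe_matrix.col_ids), values,
        AxisSemantics.gene_by_sample, probe_matrix.units,
    )


def average_duplicates(
    matrix: LabeledMatrix, groups: dict[str, str]
) -> LabeledMatrix:
    """Average columns sharing a canonical sample id.

    ``groups`` maps every column id to its canonical id; columns with the
    same canonical id are replaced by their mean, in order of first
    appearance.
    """
    missing = [c for c in matrix.col_ids if c not in groups]
    if missing:
        raise ValueError(f"samples missing from groups map: {', '.join(missing)}")
    canon_order: list[str] = []
    members: dict[str, list[int]] = {}
    for j, col in enumerate(matrix.col_ids):
        canon = groups[col]
        if canon not in members:
            members[canon] = []
            canon_order.append(canon)
        members[canon].append(j)
    values = np.column_stack(
        [matrix.values[:, members[c]].mean(axis=1) for c in canon_order]
    )
    return LabeledMatrix(
        list(matrix.row_ids), canon_order, values,
        matrix.axis_semantics, matrix.units,
    )


def standard_normalize(matrix: LabeledMatrix, ddof: int = 1) -> LabeledMatrix:
    """Z-score each feature row: (x − mean) / sd, with sample sd (n−1).

    Constant rows become all zeros with a logged warning rather than being
    dropped, so gene sets stay aligned across datasets. Idempotent on
    already-z-scored input to numerical precision.
    """
    if len(matrix.col_ids) < 2:
        raise ValueError("standard normalization needs at least 2 columns")
    v = matrix.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(v, axis=1, keepdims=True)
        sd = np.nanstd(v, axis=1, ddof=ddof, keepdims=True)
    degenerate = (sd == 0) | np.isnan(sd)
    if degenerate.any():
        names = [matrix.row_ids[i] for i in np.flatnonzero(degenerate.ravel())]
        log.warning(
            "%d constant feature(s) mapped to all-zero z-rows: %s%s",
            len(names), ", ".join(names[:5]), "..." if len(names) > 5 else "",
        )
    z = np.where(degenerate, 0.0, (v - mean) / np.where(degenerate, 1.0, sd))
    z = np.where(np.isnan(v), np.nan, z)
    return LabeledMatrix(
        list(matrix.row_ids), list(matrix.col_ids), z,
        matrix.axis_semantics, "z-score",
    )


_CNV_BOUNDS = (
    (0, 0, CNVCategory.complete_loss),
    (1, 1, CNVCategory.partial_loss),
    (2, 2, CNVCategory.no_change),
    (3, 7, CNVCategory.partial_gain),
)


def recode_cnv(copies: int) -> CNVCategory:
    """Map an integer copy number onto the five-level ordinal scale.

    0 → complete loss; 1 → partial loss; 2 → no change; 3–7 → partial gain;
    ≥8 → complete gain.
    """
    if isinstance(copies, float) and not float(copies).is_integer():
        raise ValueError(f"copy number must be an integer, got {copies}")
    c = int(copies)
    if c < 0:
        raise ValueError(f"copy number must be non-negative, got {c}")
    for lo, hi, cat in _CNV_BOUNDS:
        if lo <= c <= hi:
            return cat
    return CNVCategory.complete_gain


def recode_cnv_matrix(cnv: LabeledMatrix) -> dict[str, dict[str, CNVCategory]]:
    """Recode a gene × sample integer copy-number matrix.

    Returns ``{gene: {sample: category}}``; missing entries are omitted.
    """
    out: dict[str, dict[str, CNVCategory]] = {}
    for i, gene in enumerate(cnv.row_ids):
        row = {}
        for j, sample in enumerate(cnv.col_ids):
            v = cnv.values[i, j]
            if not np.isnan(v):
                row[sample] = recode_cnv(v)
        out[gene] = row
    return out


def normalize_counts(counts: LabeledMatrix, log1p: bool = False) -> LabeledMatrix:
    """Per-gene z-score RNA-seq counts for signature projection.

    By default raw counts are z-scored directly. ``log1p=True`` applies a
    log(1+x) variance-stabilizing transform first; this is an optional extra
    beyond the default protocol and is off unless requested. All-zero genes
    become all-zero z-rows with a warning.
    """
    v = counts.values
    if np.nanmin(v) < 0:
        raise ValueError("counts must be non-negative")
    if log1p:
        counts = LabeledMatrix(
            list(counts.row_ids), list(counts.col_ids), np.log1p(v),
            counts.axis_semantics, "log1p-counts",
        )
    return standard_normalize(counts)
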