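"""Shared matrix and table containers used by every pipeline stage.

All matrices are stored features-in-rows (genes/probes × samples, or cells ×
drugs for the drug-response panel, where cells play the row role). Readers
transpose on ingest when told the file is laid out the other way, so
downstream code only ever sees one canonical layout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AxisSemantics",
    "MutationType",
    "Zygosity",
    "CNVCategory",
    "LabeledMatrix",
    "MutationRecord",
    "MutationTable",
    "GeneCoordinates",
    "DrugResponseMatrix",
]


class AxisSemantics(str, enum.Enum):
    """What the rows/columns of a LabeledMatrix mean."""

    probe_by_sample = "probe_by_sample"
    gene_by_sample = "gene_by_sample"
    cell_by_drug = "cell_by_drug"


class MutationType(str, enum.Enum):
    intronic = "intronic"
    missense = "missense"
    nonsense = "nonsense"
    frameshift_insertion = "frameshift_insertion"
    frameshift_deletion = "frameshift_deletion"


#: Mutation types presumed to abolish protein function.
TRUNCATING_TYPES = frozenset(
    {
        MutationType.nonsense,
        MutationType.frameshift_insertion,
        MutationType.frameshift_deletion,
    }
)


class Zygosity(str, enum.Enum):
    homozygous = "homozygous"
    heterozygous = "heterozygous"


class CNVCategory(str, enum.Enum):
    """Five-level ordinal recoding of integer copy number."""

    complete_loss = "complete_loss"
    partial_loss = "partial_loss"
    no_change = "no_change"
    partial_gain = "partial_gain"
    complete_gain = "complete_gain"


def _check_unique(ids, kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: dict[str, int] = {}
    dupes = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dupes.append(i)
    if dupes:
        raise ValueError(f"duplicate {kind} ids: {', '.join(sorted(dupes))}")
    return ids


@dataclass
class LabeledMatrix:
    """A labeled real matrix with declared axis semantics and units.

    Parameters
    ----------
    row_ids, col_ids
        Ordered, unique identifiers. Rows are features (genes, probes) or
        cell lines; columns are samples or drugs.
    values
        float array of shape ``(len(row_ids), len(col_ids))``; NaN marks
        missing entries.
    axis_semantics
        One of :class:`AxisSemantics`.
    units
        Free text (``"µM"``, ``"z-score"``, ``"copies"``, ``"counts"``).
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    axis_semantics: AxisSemantics
    units: str = ""

    def __post_init__(self) -> None:
        self.row_ids = _check_unique(self.row_ids, "row")
        self.col_ids = _check_unique(self.col_ids, "column")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.row_ids)}, {len(self.col_ids)}) ids"
            )
        self.axis_semantics = AxisSemantics(self.axis_semantics)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, axis_semantics: AxisSemantics, units: str = ""
    ) -> "LabeledMatrix":
        return cls(
            row_ids=[str(i) for i in df.index],
            col_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            axis_semantics=axis_semantics,
            units=units,
        )

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]

    def col(self, col_id: str) -> np.ndarray:
        return self.values[:, self.col_ids.index(col_id)]

    def subset_rows(self, ids: list[str]) -> "LabeledMatrix":
        idx = [self.row_ids.index(i) for i in ids]
        return LabeledMatrix(
            list(ids), list(self.col_ids), self.values[idx], self.axis_semantics, self.units
        )

    def subset_cols(self, ids: list[str]) -> "LabeledMatrix":
        idx = [self.col_ids.index(i) for i in ids]
        return LabeledMatrix(
            list(self.row_ids), list(ids), self.values[:, idx], self.axis_semantics, self.units
        )

    def equals(self, other: "LabeledMatrix", tol: float = 1e-12) -> bool:
        return (
            self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and self.axis_semantics == other.axis_semantics
            and np.allclose(self.values, other.values, atol=tol, rtol=0.0, equal_nan=True)
        )


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene: str
    mutation_type: MutationType
    zygosity: Zygosity


@dataclass
class MutationTable:
    """Validated list of mutation calls (sample, gene, type, zygosity)."""

    records: list[MutationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def for_sample(self, sample_id: str) -> list[MutationRecord]:
        return [r for r in self.records if r.sample_id == sample_id]

    def for_gene(self, sample_id: str, gene: str) -> list[MutationRecord]:
        return [r for r in self.records if r.sample_id == sample_id and r.gene == gene]

    def samples(self) -> list[str]:
        return sorted({r.sample_id for r in self.records})


@dataclass
class GeneCoordinates:
    """Gene positions on a declared ordered karyotype.

    Coordinates follow the BED convention: 0-based, half-open. The karyotype
    is an ordered list of chromosome names; gene chromosomes must be drawn
    from it.
    """

    karyotype: list[str]
    genes: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end)
    arms: dict[str, str] = field(default_factory=dict)  # gene -> arm label
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.karyotype, "karyotype chromosome")
        order = set(self.karyotype)
        for gene, (chrom, start, end) in self.genes.items():
            if chrom not in order:
                raise ValueError(f"gene {gene} on undeclared chromosome {chrom}")
            if not start < end:
                raise ValueError(f"gene {gene}: start {start} must be < end {end}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def chromosome(self, gene: str) -> str:
        return self.genes[gene][0]

    def genes_on(self, chrom: str) -> list[str]:
        return sorted(
            (g for g, (c, _, _) in self.genes.items() if c == chrom),
            key=lambda g: self.genes[g][1],
        )


@dataclass
class DrugResponseMatrix:
    """Cell-line × drug IC50 panel (µM) with an explicit assay ceiling.

    ``censored`` marks entries that were thresholded at the ceiling; it is
    all-False until :func:`pharmsig.drug_response.threshold_ic50` runs.
    """

    matrix: LabeledMatrix  # cell_by_drug, µM
    ceiling: float = 8.0
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.matrix.axis_semantics != AxisSemantics.cell_by_drug:
            raise ValueError("DrugResponseMatrix requires cell_by_drug semantics")
        if self.ceiling <= 0:
            raise ValueError("ceiling must be positive")
        if self.censored is None:
            self.censored = np.zeros(self.matrix.shape, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
            if self.censored.shape != self.matrix.shape:
                raise ValueError("censored mask shape mismatch")

    @property
    def cell_ids(self) -> list[str]:
        return self.matrix.row_ids

    @property
    def drug_ids(self) -> list[str]:
        return self.matrix.col_ids

    def drug_values(self, drug_id: str) -> pd.Series:
        return pd.Series(self.matrix.col(drug_id), index=self.cell_ids, name=drug_id)
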