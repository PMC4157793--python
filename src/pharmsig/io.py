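"""Readers and writers for the tabular formats the pipeline touches.

Matrices arrive as delimited text (TSV or CSV, decided by file extension)
with one header row and one leading ID column. Mutation calls arrive as a
MAF-like TSV with columns ``sample, gene, type, zygosity``. Gene coordinates
arrive as a BED-like TSV (``chrom, start, end, gene[, arm]``, 0-based
half-open). Pipeline results are serialized as JSON with a schema-version
field.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import (
    AxisSemantics,
    GeneCoordinates,
    LabeledMatrix,
    MutationRecord,
    MutationTable,
    MutationType,
    Zygosity,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_mutations",
    "write_mutations",
    "read_gene_coordinates",
    "write_gene_coordinates",
    "write_result",
    "read_result",
]

MISSING_TOKEN = "NA"  # case-sensitive, matches common exports of the source databases
SCHEMA_VERSION = 1


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    axis_semantics: AxisSemantics | str,
    orientation_hint: str = "rows_are_features",
    units: str = "",
) -> LabeledMatrix:
    """Read a delimited numeric matrix into a :class:`LabeledMatrix`.

    Parameters
    ----------
    path
        TSV or CSV file; the delimiter is chosen from the extension.
    axis_semantics
        Declared meaning of the canonical (features-in-rows) layout.
    orientation_hint
        ``"rows_are_features"`` (default) or ``"rows_are_samples"``; in the
        latter case the parsed table is transposed so the returned matrix is
        always features-in-rows.

    Raises
    ------
    ValueError
        On duplicate IDs (naming them), ragged rows (with the line number),
        or non-numeric cells other than the ``NA`` missing token.
    """
    path = Path(path)
    if orientation_hint not in ("rows_are_features", "rows_are_samples"):
        raise ValueError(f"unknown orientation_hint: {orientation_hint!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split(sep)
    ncol = len(header) - 1
    col_ids = header[1:]
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split(sep)
        if len(fields) != ncol + 1:
            raise ValueError(
                f"{path}: ragged row at line {lineno}: expected {ncol + 1} "
                f"fields, found {len(fields)}"
            )
        row_ids.append(fields[0])
        parsed = []
        for j, tok in enumerate(fields[1:]):
            if tok == MISSING_TOKEN or tok == "":
                parsed.append(math.nan)
                continue
            try:
                parsed.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {tok!r} at line {lineno}, "
                    f"column {col_ids[j]!r}"
                ) from None
        rows.append(parsed)
    mat = LabeledMatrix(
        row_ids=row_ids,
        col_ids=col_ids,
        values=np.array(rows, dtype=float).reshape(len(row_ids), ncol),
        axis_semantics=AxisSemantics(axis_semantics),
        units=units,
    )
    if orientation_hint == "rows_are_samples":
        mat = LabeledMatrix(
            row_ids=mat.col_ids,
            col_ids=mat.row_ids,
            values=mat.values.T,
            axis_semantics=mat.axis_semantics,
            units=units,
        )
    return mat


def write_matrix(matrix: LabeledMatrix, path: str | Path) -> None:
    """Write a LabeledMatrix as delimited text with NA for missing."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["id"] + matrix.col_ids) + "\n")
        for i, rid in enumerate(matrix.row_ids):
            cells = [
                MISSING_TOKEN if math.isnan(v) else format(v, ".12g")
                for v in matrix.values[i]
            ]
            fh.write(sep.join([rid] + cells) + "\n")


def read_mutations(path: str | Path) -> MutationTable:
    """Read a MAF-like TSV (sample, gene, type, zygosity) into a MutationTable.

    Unknown mutation types or zygosities are rejected with the offending
    value and row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = ["sample", "gene", "type", "zygosity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            mtype = MutationType(row.type)
        except ValueError:
            raise ValueError(
                f"{path}: unknown mutation type {row.type!r} at row {i}"
            ) from None
        try:
            zyg = Zygosity(row.zygosity)
        except ValueError:
            raise ValueError(
                f"{path}: unknown zygosity {row.zygosity!r} at row {i}"
            ) from None
        records.append(MutationRecord(row.sample, row.gene, mtype, zyg))
    return MutationTable(records)


def write_mutations(table: MutationTable, path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["sample", "gene", "type", "zygosity"]) + "\n")
        for r in table.records:
            fh.write(
                sep.join([r.sample_id, r.gene, r.mutation_type.value, r.zygosity.value])
                + "\n"
            )


def read_gene_coordinates(
    path: str | Path, karyotype: list[str] | None = None
) -> GeneCoordinates:
    """Read a BED-like gene map: chrom, start, end, gene[, arm].

    If ``karyotype`` is not given, chromosomes are ordered by first
    appearance in the file.
    """
    path = Path(path)
    genes: dict[str, tuple[str, int, int]] = {}
    arms: dict[str, str] = {}
    seen_chroms: list[str] = []
    with open(path) as fh:
        first = True
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if first and fields[0] in ("chrom", "#chrom", "chr"):
                first = False
                continue
            first = False
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected ≥4 fields")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if gene in genes:
                raise ValueError(f"{path}: duplicate gene {gene!r} at line {lineno}")
            genes[gene] = (chrom, start, end)
            if len(fields) >= 5 and fields[4]:
                arms[gene] = fields[4]
            if chrom not in seen_chroms:
                seen_chroms.append(chrom)
    return GeneCoordinates(karyotype=karyotype or seen_chroms, genes=genes, arms=arms)


def write_gene_coordinates(coords: GeneCoordinates, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgene\tarm\n")
        for chrom in coords.karyotype:
            for gene in coords.genes_on(chrom):
                _, start, end = coords.genes[gene]
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{gene}\t{coords.arms.get(gene, '')}\n"
                )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"__type__": type(obj).__name__}
        for f in dataclasses.fields(obj):
            d[f.name] = _jsonable(getattr(obj, f.name))
        return d
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float):
        # 17 significant digits round-trips IEEE doubles exactly
        return obj
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if hasattr(obj, "value") and isinstance(obj, object) and hasattr(type(obj), "__members__"):
        return obj.value  # Enum
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def write_result(result: Any, path: str | Path) -> None:
    """Serialize any pipeline result (dataclass, dict, or list) as JSON.

    The payload carries a ``schema_version`` field; integers and strings
    round-trip bit-identically and reals to at least 12 significant digits.
    Lists of summaries keep their order.
    """
    payload = {"schema_version": SCHEMA_VERSION, "result": _jsonable(result)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, allow_nan=True)
        fh.write("\n")


def read_result(path: str | Path) -> Any:
    """Read back a JSON result written by :func:`write_result`.

    Dataclass payloads come back as plain dicts (with their ``__type__``
    tag); numeric arrays come back as nested lists under ``__ndarray__``.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema version")
    return payload["result"]
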