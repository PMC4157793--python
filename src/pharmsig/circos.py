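"""Per-sample integrated genomic tracks and circos-format export.

For one cell line, three concentric data layers are assembled on a declared
karyotype: signature-gene expression (z-scores), recoded copy number, and
mutation glyphs at gene positions. Derived resistance flags capture the
qualitative genotype of drug-resistant lines — homozygous truncating TP53 or
RB1 mutations, chromosome-X copy loss — against the amplification of
MYC-family genes seen in sensitive lines.

Export is the plain-text circos data-file convention: one whitespace-
delimited file per ring (``chrom start end value``) plus a karyotype file;
a minimal polar-plot adapter is available for quick looks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    CNVCategory,
    GeneCoordinates,
    LabeledMatrix,
    MutationRecord,
    MutationTable,
    MutationType,
    TRUNCATING_TYPES,
    Zygosity,
)

__all__ = [
    "GLYPH_BY_TYPE",
    "TYPE_BY_GLYPH",
    "CircosTrackBundle",
    "ResistanceFlags",
    "classify_mutation",
    "call_amplification",
    "resistance_flags",
    "build_tracks",
    "arm_summary",
    "export_tracks",
    "parse_tracks",
    "plot_tracks",
    "MYC_FAMILY",
]

#: Fixed glyph bijection for mutation types.
GLYPH_BY_TYPE = {
    MutationType.intronic: "open_triangle",
    MutationType.missense: "black_circle",
    MutationType.nonsense: "black_square",
    MutationType.frameshift_insertion: "red_triangle",
    MutationType.frameshift_deletion: "green_triangle",
}
TYPE_BY_GLYPH = {g: t for t, g in GLYPH_BY_TYPE.items()}

MYC_FAMILY = ("MYC", "MYCN", "MYCL")
DEFAULT_CHRX_LOSS_FRACTION = 0.25
LOSS_CATEGORIES = {CNVCategory.complete_loss, CNVCategory.partial_loss}

_CNV_ORDINAL = {
    CNVCategory.complete_loss: 0,
    CNVCategory.partial_loss: 1,
    CNVCategory.no_change: 2,
    CNVCategory.partial_gain: 3,
    CNVCategory.complete_gain: 4,
}
_CNV_FROM_ORDINAL = {v: k for k, v in _CNV_ORDINAL.items()}


@dataclass
class CircosTrackBundle:
    """Ordered per-sample track data ready for circos-file export."""

    sample_id: str
    karyotype: list[str]
    expression: list[tuple[str, int, int, str, float]]  # chrom, start, end, gene, z
    cnv: list[tuple[str, int, int, str, CNVCategory]]
    mutations: list[tuple[str, str, str]]  # gene, glyph, zygosity
    skipped_genes: list[str] = field(default_factory=list)


@dataclass
class ResistanceFlags:
    """Deterministic genotype flags for one sample."""

    sample_id: str
    tp53_truncating: bool
    rb1_truncating: bool
    myc_family_amplified: bool
    chrx_loss: bool


def classify_mutation(record: MutationRecord) -> tuple[str, str]:
    """Map a mutation record to its plot glyph and severity class.

    Nonsense and frameshift variants are *truncating* (presumed loss of
    protein function); intronic and missense variants are of unknown
    significance.
    """
    glyph = GLYPH_BY_TYPE[record.mutation_type]
    severity = (
        "truncating"
        if record.mutation_type in TRUNCATING_TYPES
        else "unknown_significance"
    )
    return glyph, severity


def call_amplification(
    recoded: dict[str, dict[str, CNVCategory]],
    gene_set: tuple[str, ...],
    sample: str,
) -> bool:
    """True iff any gene in the set is at complete gain (≥8 copies) in the sample."""
    for gene in gene_set:
        if gene not in recoded:
            raise ValueError(f"gene {gene!r} absent from CNV matrix")
    return any(
        recoded[g].get(sample) == CNVCategory.complete_gain for g in gene_set
    )


def resistance_flags(
    sample: str,
    mutations: MutationTable,
    recoded: dict[str, dict[str, CNVCategory]],
    coords: GeneCoordinates,
    myc_genes: tuple[str, ...] = MYC_FAMILY,
    chrx: str = "chrX",
    chrx_loss_fraction: float = DEFAULT_CHRX_LOSS_FRACTION,
    require_homozygous: bool = True,
) -> ResistanceFlags:
    """Derive the resistance-genotype flags for one sample.

    TP53/RB1 flags require a truncating mutation, homozygous by default
    (relaxable); chrX loss fires when the fraction of chromosome-X genes in
    a loss category exceeds the threshold; MYC-family amplification is any
    complete gain among the configured gene set (genes missing from the CNV
    table are ignored here, unlike :func:`call_amplification`).
    """

    def truncating(gene: str) -> bool:
        for r in mutations.for_gene(sample, gene):
            if r.mutation_type in TRUNCATING_TYPES and (
                not require_homozygous or r.zygosity == Zygosity.homozygous
            ):
                return True
        return False

    chrx_genes = [g for g in coords.genes_on(chrx) if g in recoded]
    lost = sum(
        1 for g in chrx_genes if recoded[g].get(sample) in LOSS_CATEGORIES
    )
    frac = lost / len(chrx_genes) if chrx_genes else 0.0
    amplified = any(
        recoded.get(g, {}).get(sample) == CNVCategory.complete_gain
        for g in myc_genes
    )
    return ResistanceFlags(
        sample_id=sample,
        tp53_truncating=truncating("TP53"),
        rb1_truncating=truncating("RB1"),
        myc_family_amplified=amplified,
        chrx_loss=frac > chrx_loss_fraction,
    )


def build_tracks(
    sample: str,
    signature_expr: LabeledMatrix,
    recoded: dict[str, dict[str, CNVCategory]],
    mutations: MutationTable,
    coords: GeneCoordinates,
    karyotype: list[str] | None = None,
) -> CircosTrackBundle:
    """Assemble the per-sample expression/CNV/mutation tracks.

    ``signature_expr`` is the z-scored signature-gene submatrix; genes with
    no coordinates are skipped and listed in the bundle's skip report.
    Entries are sorted by karyotype order then start position, so output is
    deterministic.
    """
    karyotype = list(coords.karyotype if karyotype is None else karyotype)
    if not karyotype:
        raise ValueError("karyotype must not be empty")
    order = {c: i for i, c in enumerate(karyotype)}
    skipped = []

    def sort_key(entry):
        return (order[entry[0]], entry[1], entry[3])

    expr_track = []
    if sample in signature_expr.col_ids:
        col = signature_expr.col(sample)
        for gene, z in zip(signature_expr.row_ids, col):
            if gene not in coords or np.isnan(z):
                skipped.append(gene)
                continue
            chrom, start, end = coords.genes[gene]
            expr_track.append((chrom, start, end, gene, float(z)))
    cnv_track = []
    for gene, per_sample in recoded.items():
        if sample not in per_sample:
            continue
        if gene not in coords:
            if gene not in skipped:
                skipped.append(gene)
            continue
        chrom, start, end = coords.genes[gene]
        cnv_track.append((chrom, start, end, gene, per_sample[sample]))
    glyphs = [
        (r.gene, GLYPH_BY_TYPE[r.mutation_type], r.zygosity.value)
        for r in mutations.for_sample(sample)
    ]
    return CircosTrackBundle(
        sample_id=sample,
        karyotype=karyotype,
        expression=sorted(expr_track, key=sort_key),
        cnv=sorted(cnv_track, key=sort_key),
        mutations=sorted(glyphs),
        skipped_genes=sorted(set(skipped)),
    )


def arm_summary(bundle: CircosTrackBundle) -> dict[str, float]:
    """Mean signature z-score per chromosome; empty chromosomes omitted."""
    sums: dict[str, list[float]] = {}
    for chrom, _, _, _, z in bundle.expression:
        sums.setdefault(chrom, []).append(z)
    return {c: float(np.mean(v)) for c, v in sums.items() if v}


def export_tracks(bundle: CircosTrackBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text circos data files.

    Files: ``karyotype.txt``, ``expression.txt`` (chrom start end value with
    a trailing gene comment column), ``cnv.txt`` (ordinal 0–4 value), and
    ``mutations.txt``. Text round-trips bit-exactly through
    :func:`parse_tracks`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = out / "karyotype.txt"
    p.write_text("".join(f"{c}\n" for c in bundle.karyotype))
    paths["karyotype"] = p
    p = out / "expression.txt"
    with open(p, "w") as fh:
        for chrom, start, end, gene, z in bundle.expression:
            fh.write(f"{chrom} {start} {end} {z:.12g} gene={gene}\n")
    paths["expression"] = p
    p = out / "cnv.txt"
    with open(p, "w") as fh:
        for chrom, start, end, gene, cat in bundle.cnv:
            fh.write(f"{chrom} {start} {end} {_CNV_ORDINAL[cat]} gene={gene}\n")
    paths["cnv"] = p
    p = out / "mutations.txt"
    with open(p, "w") as fh:
        for gene, glyph, zyg in bundle.mutations:
            fh.write(f"{gene} {glyph} {zyg}\n")
    paths["mutations"] = p
    p = out / "sample.txt"
    p.write_text(bundle.sample_id + "\n")
    paths["sample"] = p
    if bundle.skipped_genes:
        p = out / "skipped.txt"
        p.write_text("".join(f"{g}\n" for g in bundle.skipped_genes))
        paths["skipped"] = p
    return paths


def parse_tracks(in_dir: str | Path) -> CircosTrackBundle:
    """Read back a bundle exported by :func:`export_tracks`."""
    d = Path(in_dir)
    karyotype = d.joinpath("karyotype.txt").read_text().split()
    sample = d.joinpath("sample.txt").read_text().strip()
    expression = []
    for ln in d.joinpath("expression.txt").read_text().splitlines():
        chrom, start, end, z, genecol = ln.split()
        expression.append(
            (chrom, int(start), int(end), genecol.removeprefix("gene="), float(z))
        )
    cnv = []
    for ln in d.joinpath("cnv.txt").read_text().splitlines():
        chrom, start, end, v, genecol = ln.split()
        cnv.append(
            (chrom, int(start), int(end), genecol.removeprefix("gene="),
             _CNV_FROM_ORDINAL[int(v)])
        )
    muts = []
    for ln in d.joinpath("mutations.txt").read_text().splitlines():
        gene, glyph, zyg = ln.split()
        muts.append((gene, glyph, zyg))
    skipped_path = d / "skipped.txt"
    skipped = skipped_path.read_text().split() if skipped_path.exists() else []
    return CircosTrackBundle(
        sample_id=sample,
        karyotype=karyotype,
        expression=expression,
        cnv=cnv,
        mutations=muts,
        skipped_genes=skipped,
    )


def plot_tracks(bundle: CircosTrackBundle, path: str | Path) -> None:
    """Minimal polar rendering of the three rings (quick-look only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chrom_span = {c: i for i, c in enumerate(bundle.karyotype)}
    n = len(bundle.karyotype)

    def theta(chrom: str, pos: int, span: int = 250_000_000) -> float:
        return 2 * np.pi * (chrom_span[chrom] + min(pos / span, 0.999)) / n

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for chrom, start, _, _, z in bundle.expression:
        ax.plot([theta(chrom, start)], [2.0 + 0.15 * z], "o", ms=2, color="tab:blue")
    for chrom, start, _, _, cat in bundle.cnv:
        ax.plot([theta(chrom, start)], [1.0 + 0.15 * _CNV_ORDINAL[cat]], "s",
                ms=2, color="tab:red")
    ax.set_yticks([])
    ax.set_xticks([2 * np.pi * i / n for i in range(n)])
    ax.set_xticklabels(bundle.karyotype, fontsize=6)
    ax.set_title(bundle.sample_id)
    fig.savefig(path, dpi=100)
    plt.close(fig)
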