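"""Synthetic pharmacogenomic cohort with planted ground truth.

The generator emulates a small-cell-lung-cancer cell-line panel and a
companion tumor RNA-seq cohort so every pipeline stage can be exercised and
scored against known truth:

* a latent drug-response phenotype (sensitive / intermediate / resistant)
  drives log-normal IC50s for a PLK-inhibitor-like anchor drug, censored at
  an 8 µM assay ceiling; further drugs are planted broadly effective,
  inert, bimodal-selective and intermediate so every drug category occurs;
* gene expression carries a 3-subtype block structure plus a signature of
  genes differentially expressed between the phenotype extremes, including
  a chromosome-13-up / chromosome-19-down component in sensitive lines
  (reversed in resistant lines);
* copy number is diploid baseline with MYC-family amplification planted in
  sensitive lines and chromosome-X loss in resistant lines;
* every resistant line carries a homozygous truncating TP53 and/or RB1
  mutation, sensitive lines carry only variants of unknown significance;
* tumor counts are negative-binomial, with a subgroup whose mean profile
  follows the sensitive-line signature.

Phenotype extremes are stratified across subtypes (the sensitive and
resistant groups get identical subtype composition), so subtype-marker
genes are exactly null with respect to the phenotype contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datamodel import (
    AxisSemantics,
    DrugResponseMatrix,
    GeneCoordinates,
    LabeledMatrix,
    MutationRecord,
    MutationTable,
    MutationType,
    Zygosity,
)

__all__ = ["CohortConfig", "GroundTruth", "SyntheticCohort", "generate_cohort",
           "truth_metrics", "write_cohort"]

# Relative gene density per chromosome of the synthetic karyotype
# (proportions loosely shaped like the human protein-coding distribution).
_CHROM_WEIGHTS = {
    "chr1": 2000, "chr2": 1300, "chr3": 1100, "chr4": 800, "chr5": 900,
    "chr6": 1000, "chr7": 900, "chr8": 700, "chr9": 800, "chr10": 700,
    "chr11": 1300, "chr12": 1000, "chr13": 350, "chr14": 600, "chr15": 600,
    "chr16": 800, "chr17": 1200, "chr18": 300, "chr19": 1400, "chr20": 500,
    "chr21": 200, "chr22": 400, "chrX": 800,
}
KARYOTYPE = list(_CHROM_WEIGHTS)

ANCHOR_DRUG = "PLKi-A"
DRUG_EFFECTIVE = "BROAD-1"
DRUG_INERT = "INERT-1"
DRUG_SELECTIVE = "SEL-1"
DRUG_INTERMEDIATE = "MOD-1"

_NAMED_GENES = {  # real loci the integration stage keys on
    "MYCL": ("chr1", 0),
    "MYCN": ("chr2", 0),
    "MYC": ("chr8", 0),
    "RB1": ("chr13", 0),
    "TP53": ("chr17", 0),
}


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults define the study conditions."""

    n_cells: int = 30
    n_tumors: int = 30
    n_genes: int = 2000
    subtype_proportions: tuple[float, float, float] = (0.6, 0.25, 0.15)
    n_subtype_genes: int = 200  # per subtype
    subtype_effect: float = 2.0  # z-units
    n_signature_genes: int = 150
    signature_effect: float = 2.0  # z-units; extreme groups shifted ±δ
    n_chr13_signature: int = 20
    n_chr19_signature: int = 20
    ic50_log10_mean: dict = field(default_factory=lambda: {
        "sensitive": -1.3, "intermediate": -0.3, "resistant": 0.9})
    ic50_log10_sd: float = 0.3
    ceiling: float = 8.0
    n_sensitive: int = 5
    n_resistant: int = 5
    probe_noise_sd: float = 0.1
    n_unmapped_probes: int = 10
    nb_dispersion: float = 0.2  # variance = µ + dispersion·µ²
    tumor_subgroup_fraction: float = 0.25
    chrx_loss_fraction: float = 0.4  # fraction of chrX genes lost per resistant line
    n_cnv_background: int = 100  # random diploid autosomal genes in the CNV table
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if self.signature_effect < 0:
            raise ValueError("signature effect must be ≥ 0")
        if min(self.n_cells, self.n_tumors, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        if self.n_cells < 2 * (self.n_sensitive + self.n_resistant):
            raise ValueError("too few cells for the extreme groups")
        need = 3 * self.n_subtype_genes + self.n_signature_genes
        if need > self.n_genes:
            raise ValueError("not enough genes for subtype and signature blocks")


@dataclass
class GroundTruth:
    """What was planted, keyed by the emitted sample/gene ids."""

    phenotype: dict[str, str]  # cell -> sensitive|intermediate|resistant
    subtype: dict[str, int]  # cell -> 1..3
    signature_genes: dict[str, str]  # gene -> up_in_sensitive|up_in_resistant
    subtype_marker_genes: list[str]
    flags: dict[str, dict[str, bool]]  # cell -> planted resistance flags
    tumor_subgroup: dict[str, bool]  # tumor -> shares sensitive profile
    anchor_drug: str = ANCHOR_DRUG
    drug_categories: dict[str, str] = field(default_factory=dict)

    def sensitive_cells(self) -> list[str]:
        return sorted(c for c, p in self.phenotype.items() if p == "sensitive")

    def resistant_cells(self) -> list[str]:
        return sorted(c for c, p in self.phenotype.items() if p == "resistant")


@dataclass
class SyntheticCohort:
    config: CohortConfig
    drug_response: DrugResponseMatrix  # raw, pre-thresholding
    probe_matrix: LabeledMatrix
    probe_gene_map: dict[str, str]
    gene_expression: LabeledMatrix  # probe-collapsed convenience view
    cnv: LabeledMatrix  # gene × cell integer copies
    mutations: MutationTable
    coords: GeneCoordinates
    tumor_counts: LabeledMatrix
    truth: GroundTruth


def _largest_remainder(total: int, proportions) -> list[int]:
    raw = [p * total for p in proportions]
    counts = [math.floor(r) for r in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _build_coords(gene_chrom: dict[str, str]) -> GeneCoordinates:
    per_chrom: dict[str, list[str]] = {c: [] for c in KARYOTYPE}
    for g, c in gene_chrom.items():
        per_chrom[c].append(g)
    genes = {}
    lengths = {}
    for chrom in KARYOTYPE:
        names = sorted(per_chrom[chrom])
        for i, g in enumerate(names):
            start = i * 1_000_000
            genes[g] = (chrom, start, start + 500_000)
        lengths[chrom] = (len(names) + 1) * 1_000_000
    return GeneCoordinates(karyotype=KARYOTYPE, genes=genes, chrom_lengths=lengths)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full cohort; fully deterministic given ``config.seed``."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cells = [f"CELL{i:03d}" for i in range(1, cfg.n_cells + 1)]
    tumors = [f"TUMOR{i:03d}" for i in range(1, cfg.n_tumors + 1)]
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]

    # --- karyotype placement ------------------------------------------------
    weights = np.array([_CHROM_WEIGHTS[c] for c in KARYOTYPE], dtype=float)
    counts = _largest_remainder(cfg.n_genes, weights / weights.sum())
    gene_chrom: dict[str, str] = {}
    pos = 0
    for chrom, cnt in zip(KARYOTYPE, counts):
        for g in genes[pos:pos + cnt]:
            gene_chrom[g] = chrom
        pos += cnt
    for name, (chrom, _) in _NAMED_GENES.items():
        gene_chrom[name] = chrom
    coords = _build_coords(gene_chrom)

    # --- subtype and phenotype labels --------------------------------------
    sub_counts = _largest_remainder(cfg.n_cells, cfg.subtype_proportions)
    subtype_arr = np.repeat(np.arange(1, 4), sub_counts)
    rng.shuffle(subtype_arr)
    subtype = {c: int(s) for c, s in zip(cells, subtype_arr)}

    phenotype = {c: "intermediate" for c in cells}
    # identical composition for both extreme groups, stratified by subtype
    sens_per_sub = _largest_remainder(cfg.n_sensitive, [n / cfg.n_cells for n in sub_counts])
    for s in (1, 2, 3):
        members = rng.permutation([c for c in cells if subtype[c] == s])
        k = sens_per_sub[s - 1]
        for c in members[:k]:
            phenotype[c] = "sensitive"
        for c in members[k:2 * k]:
            phenotype[c] = "resistant"
    sens_cells = [c for c in cells if phenotype[c] == "sensitive"]
    res_cells = [c for c in cells if phenotype[c] == "resistant"]

    # --- expression ---------------------------------------------------------
    X = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_cells))
    gene_index = {g: i for i, g in enumerate(genes)}
    sub_marker_genes: list[str] = []
    cursor = 0
    for s in (1, 2, 3):
        block = genes[cursor:cursor + cfg.n_subtype_genes]
        sub_marker_genes.extend(block)
        cols = [j for j, c in enumerate(cells) if subtype[c] == s]
        rows = [gene_index[g] for g in block]
        X[np.ix_(rows, cols)] += cfg.subtype_effect
        cursor += cfg.n_subtype_genes

    pool13 = [g for g in genes[cursor:] if gene_chrom[g] == "chr13"]
    pool19 = [g for g in genes[cursor:] if gene_chrom[g] == "chr19"]
    sig13 = list(rng.choice(pool13, size=cfg.n_chr13_signature, replace=False))
    sig19 = list(rng.choice(pool19, size=cfg.n_chr19_signature, replace=False))
    rest_pool = [g for g in genes[cursor:] if g not in set(sig13) | set(sig19)]
    n_rest = cfg.n_signature_genes - len(sig13) - len(sig19)
    sig_rest = list(rng.choice(rest_pool, size=n_rest, replace=False))
    signature_genes: dict[str, str] = {}
    for g in sig13:
        signature_genes[g] = "up_in_sensitive"
    for g in sig19:
        signature_genes[g] = "up_in_resistant"
    for g in sig_rest:
        signature_genes[g] = str(rng.choice(["up_in_sensitive", "up_in_resistant"]))
    pheno_sign = np.array(
        [1 if phenotype[c] == "sensitive" else -1 if phenotype[c] == "resistant" else 0
         for c in cells]
    )
    for g, direction in signature_genes.items():
        d = 1.0 if direction == "up_in_sensitive" else -1.0
        X[gene_index[g]] += d * cfg.signature_effect * pheno_sign

    gene_expression = LabeledMatrix(genes, cells, X, AxisSemantics.gene_by_sample)

    # --- probes -------------------------------------------------------------
    probe_rows = []
    probe_ids = []
    probe_gene_map: dict[str, str] = {}
    pc = 0
    for g in genes:
        for _ in range(int(rng.integers(1, 3))):
            pc += 1
            pid = f"P{pc:05d}"
            probe_ids.append(pid)
            probe_gene_map[pid] = g
            probe_rows.append(X[gene_index[g]] + rng.normal(0, cfg.probe_noise_sd, cfg.n_cells))
    for _ in range(cfg.n_unmapped_probes):
        pc += 1
        pid = f"P{pc:05d}"
        probe_ids.append(pid)
        probe_gene_map[pid] = ""
        probe_rows.append(rng.normal(0, 1, cfg.n_cells))
    probe_matrix = LabeledMatrix(probe_ids, cells, np.vstack(probe_rows),
                                 AxisSemantics.probe_by_sample)

    # --- drug panel ---------------------------------------------------------
    mu = {c: cfg.ic50_log10_mean[phenotype[c]] for c in cells}
    anchor = 10.0 ** np.array([rng.normal(mu[c], cfg.ic50_log10_sd) for c in cells])
    broad = 10.0 ** rng.normal(-1.0, cfg.ic50_log10_sd, cfg.n_cells)
    inert = np.full(cfg.n_cells, 10.0)  # all censored to the ceiling
    responder = pheno_sign.copy()
    # bimodal drug: sensitive lines plus half the intermediates respond
    inter_idx = [j for j, c in enumerate(cells) if phenotype[c] == "intermediate"]
    responders = set(np.flatnonzero(pheno_sign == 1)) | set(inter_idx[: len(inter_idx) // 2])
    selective = np.where(
        [j in responders for j in range(cfg.n_cells)],
        10.0 ** rng.normal(-1.3, cfg.ic50_log10_sd, cfg.n_cells),
        10.0 ** rng.normal(0.95, cfg.ic50_log10_sd, cfg.n_cells),
    )
    moderate = 10.0 ** rng.normal(0.45, 0.2, cfg.n_cells)
    moderate[int(rng.integers(cfg.n_cells))] = np.nan  # exercise missing handling
    panel = np.column_stack([anchor, broad, inert, selective, moderate])
    drug_ids = [ANCHOR_DRUG, DRUG_EFFECTIVE, DRUG_INERT, DRUG_SELECTIVE, DRUG_INTERMEDIATE]
    drug_response = DrugResponseMatrix(
        matrix=LabeledMatrix(cells, drug_ids, panel, AxisSemantics.cell_by_drug, "µM"),
        ceiling=cfg.ceiling,
    )

    # --- copy number --------------------------------------------------------
    chrx_genes = [g for g in genes if gene_chrom[g] == "chrX"]
    autosomal = [g for g in genes if gene_chrom[g] not in ("chrX",)]
    background = list(rng.choice(autosomal, size=cfg.n_cnv_background, replace=False))
    cnv_genes = sorted(set(background) | set(chrx_genes)
                       | set(_NAMED_GENES))
    cnv = np.full((len(cnv_genes), cfg.n_cells), 2, dtype=float)
    cnv_index = {g: i for i, g in enumerate(cnv_genes)}
    myc_cycle = ["MYC", "MYC", "MYCN", "MYCN", "MYCL"]
    flags: dict[str, dict[str, bool]] = {}
    for c in cells:
        flags[c] = {"tp53_truncating": False, "rb1_truncating": False,
                    "myc_family_amplified": False, "chrx_loss": False}
    for i, c in enumerate(sens_cells):
        gene = myc_cycle[i % len(myc_cycle)]
        cnv[cnv_index[gene], cells.index(c)] = float(rng.integers(8, 13))
        flags[c]["myc_family_amplified"] = True
    for c in res_cells:
        j = cells.index(c)
        lost = rng.choice(len(chrx_genes),
                          size=int(round(cfg.chrx_loss_fraction * len(chrx_genes))),
                          replace=False)
        for li in lost:
            cnv[cnv_index[chrx_genes[li]], j] = float(rng.integers(0, 2))
        flags[c]["chrx_loss"] = True
    # mild diploid noise on background autosomal genes of intermediate lines
    for g in background:
        if g in _NAMED_GENES:
            continue
        j = rng.integers(cfg.n_cells)
        if phenotype[cells[j]] == "intermediate" and rng.random() < 0.3:
            cnv[cnv_index[g], j] = float(rng.choice([1, 3]))
    cnv_matrix = LabeledMatrix(cnv_genes, cells, cnv,
                               AxisSemantics.gene_by_sample, "copies")

    # --- mutations ----------------------------------------------------------
    truncating = [MutationType.nonsense, MutationType.frameshift_insertion,
                  MutationType.frameshift_deletion]
    benign = [MutationType.intronic, MutationType.missense]
    records: list[MutationRecord] = []
    for c in res_cells:
        hit = str(rng.choice(["TP53", "RB1", "both"]))
        targets = ["TP53", "RB1"] if hit == "both" else [hit]
        for gene in targets:
            records.append(MutationRecord(
                c, gene, truncating[int(rng.integers(len(truncating)))],
                Zygosity.homozygous))
            flags[c][f"{gene.lower()}_truncating"] = True
    for c in sens_cells:
        gene = str(rng.choice(["TP53", "RB1"]))
        records.append(MutationRecord(
            c, gene, benign[int(rng.integers(len(benign)))],
            Zygosity(rng.choice(["homozygous", "heterozygous"]))))
    for c in cells:
        if phenotype[c] == "intermediate" and rng.random() < 0.3:
            records.append(MutationRecord(
                c, str(rng.choice(["TP53", "RB1"])), MutationType.missense,
                Zygosity.heterozygous))
    mutations = MutationTable(sorted(records, key=lambda r: (r.sample_id, r.gene)))

    # --- tumor counts -------------------------------------------------------
    base_mean = np.exp(rng.normal(3.5, 1.0, cfg.n_genes))
    n_sub = int(round(cfg.tumor_subgroup_fraction * cfg.n_tumors))
    sub_idx = set(rng.choice(cfg.n_tumors, size=n_sub, replace=False))
    tumor_subgroup = {t: (j in sub_idx) for j, t in enumerate(tumors)}
    fold = 2.0 ** cfg.signature_effect
    mean_mat = np.tile(base_mean[:, None], (1, cfg.n_tumors))
    for g, direction in signature_genes.items():
        f = fold if direction == "up_in_sensitive" else 1.0 / fold
        for j in sub_idx:
            mean_mat[gene_index[g], j] *= f
    r = 1.0 / cfg.nb_dispersion  # NB size parameter; variance = µ + µ²/r
    p = r / (r + mean_mat)
    counts_mat = rng.negative_binomial(r, p).astype(float)
    tumor_counts = LabeledMatrix(genes, tumors, counts_mat,
                                 AxisSemantics.gene_by_sample, "counts")

    truth = GroundTruth(
        phenotype=phenotype,
        subtype=subtype,
        signature_genes=signature_genes,
        subtype_marker_genes=sub_marker_genes,
        flags=flags,
        tumor_subgroup=tumor_subgroup,
        drug_categories={
            ANCHOR_DRUG: "selective", DRUG_EFFECTIVE: "effective",
            DRUG_INERT: "ineffective", DRUG_SELECTIVE: "selective",
            DRUG_INTERMEDIATE: "intermediate",
        },
    )
    return SyntheticCohort(
        config=cfg,
        drug_response=drug_response,
        probe_matrix=probe_matrix,
        probe_gene_map=probe_gene_map,
        gene_expression=gene_expression,
        cnv=cnv_matrix,
        mutations=mutations,
        coords=coords,
        tumor_counts=tumor_counts,
        truth=truth,
    )


def truth_metrics(
    truth: GroundTruth,
    signature_result=None,
    cluster_labels: dict[str, int] | None = None,
    chosen_k: int | None = None,
    flags=None,
) -> dict:
    """Score pipeline outputs against the planted truth.

    Reports signature precision/recall, adjusted Rand index of subtype
    labels, the K-recovery indicator, and the resistance-flag confusion
    (count of cells whose four derived flags all match the planted ones).
    """
    report: dict = {}
    if signature_result is not None:
        unknown = [c for c in signature_result.sensitive_set
                   if c not in truth.phenotype]
        if unknown:
            raise ValueError(f"cells not in cohort: {unknown}")
        selected = set(signature_result.signature_genes)
        planted = set(truth.signature_genes)
        tp = len(selected & planted)
        report["signature_precision"] = tp / len(selected) if selected else 0.0
        report["signature_recall"] = tp / len(planted) if planted else 0.0
        null_genes = [g for g in signature_result.gene_ids if g not in planted]
        null_selected = sum(1 for g in null_genes if g in selected)
        report["null_selection_rate"] = (
            null_selected / len(null_genes) if null_genes else 0.0)
    if cluster_labels is not None:
        from sklearn.metrics import adjusted_rand_score

        common = [c for c in cluster_labels if c in truth.subtype]
        if not common:
            raise ValueError("cluster labels share no ids with the cohort")
        report["subtype_ari"] = float(adjusted_rand_score(
            [truth.subtype[c] for c in common],
            [cluster_labels[c] for c in common]))
    if chosen_k is not None:
        report["k_recovered"] = bool(chosen_k == 3)
    if flags is not None:
        agree = 0
        for f in flags:
            planted_f = truth.flags.get(f.sample_id)
            if planted_f is None:
                raise ValueError(f"sample {f.sample_id} not in cohort")
            agree += (
                f.tp53_truncating == planted_f["tp53_truncating"]
                and f.rb1_truncating == planted_f["rb1_truncating"]
                and f.myc_family_amplified == planted_f["myc_family_amplified"]
                and f.chrx_loss == planted_f["chrx_loss"]
            )
        report["flag_agreement"] = agree / len(list(flags))
    return report


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write every input table the pipeline reads, as TSV/JSON text."""
    from . import io as psio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    psio.write_matrix(cohort.drug_response.matrix, out / "ic50.tsv")
    paths["ic50"] = out / "ic50.tsv"
    psio.write_matrix(cohort.probe_matrix, out / "probes.tsv")
    paths["probes"] = out / "probes.tsv"
    with open(out / "probe_map.tsv", "w") as fh:
        fh.write("probe\tgene\n")
        for p, g in cohort.probe_gene_map.items():
            fh.write(f"{p}\t{g}\n")
    paths["probe_map"] = out / "probe_map.tsv"
    psio.write_matrix(cohort.cnv, out / "cnv.tsv")
    paths["cnv"] = out / "cnv.tsv"
    psio.write_mutations(cohort.mutations, out / "mutations.tsv")
    paths["mutations"] = out / "mutations.tsv"
    psio.write_gene_coordinates(cohort.coords, out / "genes.bed.tsv")
    paths["genes"] = out / "genes.bed.tsv"
    psio.write_matrix(cohort.tumor_counts, out / "tumor_counts.tsv")
    paths["tumor_counts"] = out / "tumor_counts.tsv"
    psio.write_result(
        {"phenotype": cohort.truth.phenotype, "subtype": cohort.truth.subtype,
         "signature_genes": cohort.truth.signature_genes,
         "tumor_subgroup": cohort.truth.tumor_subgroup,
         "flags": cohort.truth.flags,
         "config": asdict(cohort.config)},
        out / "truth.json",
    )
    paths["truth"] = out / "truth.json"
    return paths
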