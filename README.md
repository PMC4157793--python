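# pharmsig

Pharmacogenomic drug-sensitivity analysis for cancer cell-line panels, built
around the workflow used to mine public drug-screening resources (CCLE/GDSC
style) for new therapeutic leads in small-cell lung cancer: summarize IC50
panels into drug-efficacy categories, discover expression/copy-number
subtypes by resampling consensus clustering, derive a drug-sensitivity gene
signature from extreme responders, validate it by leave-one-out
reclustering, project it onto external tumor RNA-seq counts, and export
integrated per-sample circos tracks. It is aimed at computational biologists
who want each of those steps as a tested, seedable library function rather
than a one-off script.

## Methods at a glance

**Drug efficacy.** IC50 values (µM) are censored at the assay ceiling
(default 8 µM). Per drug the panel quantiles (q25, q50, q75) use the type-7
convention (linear interpolation, h = (n−1)p). A drug is *effective* when
q50 ≤ 1 µM, *ineffective* when q50 ≥ ceiling, *selective* when
q75/q25 ≥ 20, else *intermediate*. Outliers follow the Tukey 1.5·IQR rule,
with a separate "sensitive outlier" report (IC50 < 4 µM under a drug whose
median sits at the ceiling). A six-bin ordinal discretization
(edges 0.1/0.5/1/2/4 µM) supports mosaic-plot exports.

**Consensus clustering.** For each K = 2..maxK, draw ⌈0.8·n⌉ samples
without replacement, cluster by average-linkage agglomeration on
d(i,j) = 1 − r(i,j) (Pearson), and tally co-clusterings; the consensus is

    M_K(i,j) = #(i,j co-clustered) / #(i,j co-sampled).

K is selected from the consensus CDFs: the area A(K) under the empirical
CDF of off-diagonal entries, the relative delta-area
(A(K) − A(K−1))/A(K−1), and the proportion of ambiguous entries
(M ∈ (0.1, 0.9)). The chosen K is the largest one reachable from K = 2
through steps that stay crisp (ambiguous proportion ≤ 0.1) and add relative
delta-area above 0.1 (see `docs/methods.md` for why crispness is required).
Subtype markers are screened per gene with the Kruskal-Wallis test
(uncorrected, p < 0.05; exact permutation null for very small panels).

**Signature derivation.** The k most and k least sensitive lines for one
drug (default k = 5) anchor a per-gene exact two-sided Wilcoxon rank-sum
screen; genes with p < α (default 0.05) form the signature, with direction
from the group medians. Validation: 2-group cut of the labeled extremes on
the signature (clean iff each group is pure), leave-one-out reclustering
(fixed-signature or re-derive mode), and projection — per-dataset per-gene
z-scoring of tumor counts and reference expression, merge, hierarchical
clustering, and a report of which tumors co-cluster with each reference
line.

**Integration.** Copy numbers recode as 0 → complete loss, 1 → partial
loss, 2 → no change, 3–7 → partial gain, ≥8 → complete gain. Resistance
flags: homozygous truncating (nonsense/frameshift) TP53 or RB1, MYC-family
(MYC/MYCN/MYCL) complete gain, and chromosome-X loss (> 25% of chrX genes
in a loss category). Per-sample circos tracks (expression ring, CNV ring,
mutation glyphs) export as plain-text data files that round-trip exactly.

**Synthetic cohorts.** `pharmsig.simulate` generates a full cohort with
planted truth — phenotype-driven log-normal IC50s, 3 expression subtypes,
150 signature genes with a chr13-up/chr19-down asymmetry in sensitive
lines, MYC-family amplification, chrX loss, truncating TP53/RB1 mutations,
and negative-binomial tumor counts with a subgroup sharing the sensitive
profile — so every stage can be scored against known truth.

## Worked example

`examples/03_drug_sensitivity_signature.py` derives and validates a
signature on a synthetic cohort (seed 7):

```
sensitive extremes: CELL023, CELL017, CELL003, CELL004, CELL019
resistant extremes: CELL007, CELL015, CELL016, CELL021, CELL025
189 signature genes at p < 0.05 (150 of 150 planted recovered)
extremes separate cleanly: True
leave-one-out: 0 of 30 heatmaps misclassified
```

The 189 selected genes contain all 150 planted differential genes plus the
expected ~3% false positives from the 1850 null genes (the exact 5-vs-5
test's achievable level at α = 0.05 is 8/252 ≈ 3.2%). Clean separation
means the 10 labeled extremes split into a pure sensitive and a pure
resistant group when clustered on the signature; zero misclassified
heatmaps means that holding out any single line never breaks that split.
The other examples cover panel summaries, subtype discovery, tumor
projection, circos tracks, and the file-driven pipeline; the same steps are
available from the shell via `pharmsig simulate / drugs / cluster /
signature / circos / run`.

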