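# Methods

This note records the models and procedures pharmsig implements, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic cohorts do and do not establish about real data.

## Drug-response summarization

IC50 values are µM concentrations producing 50% growth inhibition; lower
means more sensitive. Screening assays only test up to a maximum
concentration, so values above the ceiling (default 8 µM) are censored at
the ceiling; a boolean mask records which entries were censored, and
thresholding is idempotent.

Panel quantiles use the type-7 (linear interpolation, h = (n−1)p)
convention — the default of the common statistical environments — so
summaries are directly comparable with published quantile tables. Missing
values are dropped, never imputed; a summary needs at least two
observations.

Categories are rule-based on the quantile summary: *effective* if
q50 ≤ effective_cut (default 1 µM, a "most lines respond at low dose"
call), *ineffective* if q50 ≥ ceiling (the median line never responds),
otherwise *selective* if q75/q25 ≥ selective_fold (default 20; a long box
spanning responders and non-responders), else *intermediate*. All three
cuts are configuration values.

Two outlier reports are produced deliberately. A literal "outside the
25–75% box" rule would flag half of every panel, so the default report uses
the conventional Tukey fences (beyond q25 − 1.5·IQR or q75 + 1.5·IQR). A
second, separately labeled report lists *sensitive outliers*: lines with
IC50 < 4 µM under a drug whose median sits at the ceiling — the unusual
responders worth follow-up under an otherwise inert drug.

The six-bin discretization for mosaic exports uses right-closed bins on
five strictly increasing edges; the defaults (0.1, 0.5, 1, 2, 4 µM) spread
the observed IC50 dynamic range roughly log-uniformly and are
configuration values, since no canonical breakpoints exist.

## Preprocessing

Expression input is assumed already array-normalized (e.g. RMA) at probe
level. Probes without a gene symbol are dropped; gene level is the
unweighted mean of a gene's probes; duplicate samples are averaged into
canonical columns. Standard normalization z-scores each gene with the
sample standard deviation (n−1), matching the default `scale` behavior of
statistical environments. Constant genes map to all-zero rows with a
warning instead of being dropped — dropping them would desynchronize gene
sets between datasets during signature projection.

RNA-seq counts are z-scored per gene on the raw counts by default; a
log1p pre-transform is available but off by default, so the default path
matches the plain standard-normalization protocol. Copy numbers recode
onto the five-level ordinal scale 0 / 1 / 2 / 3–7 / ≥8 →
complete loss / partial loss / no change / partial gain / complete gain.

## Consensus clustering

The engine re-implements Monti-style resampling consensus from scratch.
Samples are columns; the sample–sample dissimilarity is 1 − Pearson
correlation across features (constant samples get maximal distance 1);
inner clustering is average-linkage agglomeration. Defaults: maxK = 10,
1000 resamples (raised from typical reference defaults for stability;
acceptance-scale runs use 250), subsample fraction 0.8, no feature
subsampling. One subsample draw is made per resample from a single seeded
generator and reused across every K — the distance matrix is computed once
and the per-resample work is a submatrix linkage, which keeps a full
K-sweep on a 30-sample panel under a second. Pairs never co-sampled score
consensus 0 with a warning rather than an undefined division. Results are
bit-reproducible given the seed.

### Choosing K

For each K we compute the empirical CDF of off-diagonal consensus values,
its area A(K) (computed exactly as 1 − mean since the support is [0, 1]),
the relative delta-area (A(K) − A(K−1))/A(K−1), and the proportion of
*ambiguous* entries, PAC(K) = P(0.1 < M < 0.9).

The textbook elbow rule — largest K whose relative delta-area exceeds a
threshold — fails on clean block structure: forcing K one past the true
cluster number fragments crisp blocks differently in every subsample,
which floods the consensus with mid-values and *inflates* the delta-area
(on a planted 3-subtype panel the relative delta-area at K = 4 is
~0.25–0.30, larger than the genuine gain at K = 3). The selector therefore
grows a run from K = 2 and accepts the step to K+1 only while the K+1
consensus stays crisp (PAC ≤ 0.1) *and* adds relative delta-area above the
elbow threshold (0.1); the second condition stops tie-degenerate
refinements that change nothing (duplicate samples cannot be split below a
zero merge height, so the "K+1" consensus can be identical to K's). If not
even K = 2 is crisp, the plain delta-area elbow is the fallback. A panel
of identical samples returns K = 2 with a degeneracy warning. Both
thresholds are configuration values; areas, delta-areas and PAC are all
reported so a user can audit the choice.

Labels come from average-linkage clustering of 1 − M at the chosen K,
renumbered by decreasing cluster size with ties broken by the smallest
member id. Marker screening is per-gene Kruskal-Wallis across cluster
labels with mid-rank ties, uncorrected, selected at p < 0.05. For total
N ≤ 10 the p-value is the exact permutation tail (every assignment of the
observed values to the group sizes is enumerated); the chi-square
approximation is used above that and can be forced. At N = 9 the
chi-square tail is off by ~0.02 at the top of the statistic's range, which
is why the exact route exists.

CNV subtyping runs this same engine on the raw integer copy-number matrix;
the ordinal recoding is used only for display and export.

## Signature derivation and validation

Extreme responders are the k lowest- and k highest-IC50 lines (default
k = 5), ties broken by lexicographic cell id. The per-gene test is the
exact two-sided Wilcoxon rank-sum: for tie-free data the exact null
distribution of U is computed once per group-size pair by the classic
partition-counting recurrence and applied to all genes (vectorized);
tied genes are handled by full enumeration of splits up to pooled n = 14,
and by the mid-rank normal approximation beyond. Welch's t is available as
a configuration alternative. Selection is p < α (default 0.05),
uncorrected, matching the marker screen; direction compares group medians.
Note the discreteness floor: with 5 vs 5 the smallest achievable two-sided
p is 2/252 ≈ 0.0079 and the achievable level at α = 0.05 is
8/252 ≈ 3.2%, not 5% — visible in every false-positive-rate measurement.

*Separation* clusters the 2k labeled extremes on the signature genes
(average linkage, 1 − Pearson), cuts at 2, assigns each group the label
minimizing total misclassification, and is *clean* iff no labeled cell
sits in the opposite group. This operationalizes the qualitative
"extremes cluster at opposite ends of the heatmap". Restricting a
full-cohort dendrogram to a subset is not a well-defined scipy operation,
so the restricted tree is built directly from the labeled cells' own
distances.

*Leave-one-out* removes each cell in turn and re-runs the separation
check on the remainder. Default mode reuses the full-data signature
(`fixed_signature`); `rederive` mode re-derives the signature per fold
from the shrunken extreme sets (k−1 when the held-out cell was an
extreme). Both are shipped because either protocol is defensible; neither
is privileged by the package. One "heatmap" per held-out cell; the
summary counts heatmaps with any misclassified member.

*Projection* intersects the signature with the external gene set
(reporting the shortfall), z-scores tumors and reference expression per
gene within their own dataset — cross-platform levels are not comparable,
ranks of standardized profiles are — merges columns, clusters
hierarchically (default 2 groups; the consensus engine can be swapped in
by configuration), and reports each reference line's co-clustered tumors.

## Integrated tracks and resistance flags

Mutation glyphs are a fixed bijection (intronic → open triangle,
missense → black circle, nonsense → black square, frameshift insertion →
red triangle, frameshift deletion → green triangle); nonsense and
frameshift variants count as truncating, intronic/missense as unknown
significance. Flags per sample: truncating TP53 (or RB1) requires a
truncating, homozygous record (homozygosity relaxable by configuration —
a heterozygous truncating hit leaves one functional allele);
MYC-family amplification is complete gain (≥8 copies) at MYC, MYCN or
MYCL, reusing the recoding rule rather than a separate threshold; chrX
loss fires when more than 25% of chromosome-X genes are in a loss
category — the source observation is qualitative, so this threshold is an
artifact convention, documented and configurable. Tracks are sorted by
karyotype order then start coordinate (BED convention, 0-based half-open)
and export as whitespace-delimited `chrom start end value` files plus a
karyotype file; exports re-parse bit-exactly. A minimal matplotlib polar
adapter renders quick-look plots; publication-grade circos rendering is
out of scope.

## Synthetic cohorts

The generator emulates the structure of a small-cell lung cancer cell-line
panel plus a tumor RNA-seq cohort, with every planted effect recorded as
ground truth. Defaults (all configurable): 30 cell lines, 30 tumors,
2000 genes on a 23-chromosome synthetic karyotype with gene counts
proportional to a fixed density table; subtype proportions 0.6/0.25/0.15;
IC50 log10 means −1.3 / −0.3 / 0.9 (sensitive / intermediate / resistant)
with sd 0.3 and an 8 µM ceiling; one planted broadly-effective drug
(log10 mean −1), one inert drug (all values above the ceiling), one
phenotype-bimodal selective drug and one intermediate drug, so every
category occurs; 5 sensitive and 5 resistant extreme lines.

Expression is N(0, 1) background plus two planted components. Subtype
structure: 200 marker genes per subtype shifted +2 z-units — sized so the
subtype component dominates the phenotype component in sample–sample
correlations, which is what lets full-transcriptome clustering recover the
three subtypes on the same cohort that carries a strong signature.
Signature: 150 genes whose sensitive and resistant group means sit at ±δ
(default δ = 2, i.e. 4 z-units of separation between extremes — the level
at which a 5-vs-5 exact rank test has near-complete power, since its
selection region demands U ≤ 2 of 25); 20 signature genes are placed on
chr13 (up in sensitive) and 20 on chr19 (down in sensitive) so the
chromosome-level asymmetry is expressible without making non-signature
genes differential. Extreme phenotypes are assigned *stratified* by
subtype — the sensitive and resistant groups get identical subtype
composition — so subtype markers are exactly null with respect to the
phenotype contrast while phenotype and subtype remain unassociated.

CNV is diploid baseline with 8–12 copies of one MYC-family gene per
sensitive line (cycling MYC/MYC/MYCN/MYCN/MYCL), 0–1 copies at a planted
40% of chrX genes per resistant line (above the 25% flag threshold), and
sparse ±1 noise on background autosomal genes of intermediate lines.
Every resistant line gets at least one homozygous truncating TP53 or RB1
mutation (sometimes both); sensitive lines get only intronic/missense
variants. Tumor counts are negative binomial with
variance = µ + 0.2µ² on log-normal base means; a 25% subgroup multiplies
signature-gene means by 2^±δ following the sensitive-line directions.

What passing tests on these cohorts do *not* show: the generator has
independent genes given its block structure, Gaussian noise, no
batch/platform effects, no probe-level artifacts beyond iid N(0, 0.1)
probe noise, and planted effects that are homogeneous within groups. Real
panels have correlated pathways, heavier tails and heterogeneous effect
sizes; recovery rates measured here are upper bounds on what the same
pipeline would achieve on real data, and the published headline figures
from real panels (marker counts, signature sizes, specific co-clustering
cell counts) are not reproducible without the original downloads.

## Numerical and engineering choices

- One seeded `numpy` Generator per run; subsample draws are consumed in a
  documented fixed order, so all results are platform-reproducible.
- JSON result files carry a schema version; reals round-trip to at least
  12 significant digits, integers and strings exactly.
- The "NA" token (case-sensitive) marks missing values in delimited text;
  readers reject duplicate ids (naming them) and ragged rows (with line
  numbers) rather than guessing.
- Matrices are stored features-in-rows internally; readers transpose on
  request so downstream code sees one canonical layout.
- Degenerate inputs have declared behavior everywhere: constant genes
  (zero rows + warning), all-identical panels (K = 2 + warning),
  never-co-sampled pairs (consensus 0 + warning), genes without
  coordinates (skipped + listed).
- Pipeline stages are pure functions of (inputs, config, seed); the run
  manifest records seed, a canonical-config hash and per-stage status, and
  a failed stage halts the run while keeping earlier outputs.

## Known limitations

- No dose-response curve fitting: IC50 matrices are the input.
- No multiple-testing correction anywhere, by protocol; signature sizes
  therefore include the expected false-positive mass at the chosen α.
- The K selector assumes block-like consensus structure; gradient or
  nested structures fall back to the plain elbow and deserve manual
  inspection of the reported diagnostics.
- Projection assumes the external dataset shares gene symbols; no ortholog
  or probe mapping is attempted beyond the provided probe map.
- The circos adapter is a data exporter first; the bundled plot is a
  quick look, not a figure generator.
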