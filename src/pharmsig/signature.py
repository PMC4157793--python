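"""Drug-sensitivity gene signatures from extreme responders.

The workflow anchors a signature on the k most and k least sensitive lines
for one drug (by IC50), screens every gene with an exact two-sided Wilcoxon
rank-sum test between the two groups, and keeps genes with p below alpha.
The signature is validated by checking that the labeled extremes separate
cleanly under hierarchical clustering on the signature genes, by
leave-one-out reclustering, and by projection onto external RNA-seq tumor
counts (per-dataset z-scoring, merge, cluster) to find tumor subgroups that
share the sensitive-line profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, ttest_ind

from .consensus import correlation_distance
from .datamodel import AxisSemantics, LabeledMatrix
from .preprocess import normalize_counts, standard_normalize

__all__ = [
    "SignatureResult",
    "LOOResult",
    "ProjectionResult",
    "select_extremes",
    "derive_signature",
    "evaluate_separation",
    "loo_validate",
    "project_signature",
]


@dataclass
class SignatureResult:
    """Extreme-responder sets plus per-gene test results and selected genes."""

    drug_id: str
    sensitive_set: list[str]
    resistant_set: list[str]
    gene_ids: list[str]
    statistic: np.ndarray
    p_value: np.ndarray
    direction: list[str]  # per gene: up_in_sensitive | up_in_resistant
    alpha: float

    def __post_init__(self) -> None:
        if set(self.sensitive_set) & set(self.resistant_set):
            raise ValueError("sensitive and resistant sets overlap")

    @property
    def selected(self) -> np.ndarray:
        return self.p_value < self.alpha

    @property
    def signature_genes(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"statistic": self.statistic, "p_value": self.p_value,
             "direction": self.direction, "selected": self.selected},
            index=self.gene_ids,
        )


@dataclass
class LOOResult:
    """Per-held-out-cell separation outcomes from leave-one-out reclustering."""

    mode: str
    outcomes: dict[str, list[str]]  # held-out cell -> misclassified members
    total_heatmaps: int = 0

    def __post_init__(self) -> None:
        self.total_heatmaps = len(self.outcomes)

    @property
    def misclassified_heatmap_count(self) -> int:
        return sum(1 for mis in self.outcomes.values() if mis)


@dataclass
class ProjectionResult:
    """Signature projection of external tumors plus reference cell lines."""

    genes_used: int
    genes_missing: list[str]
    labels: dict[str, int]  # merged sample -> cluster
    reference_ids: list[str]
    co_clustered: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.co_clustered:
            for ref in self.reference_ids:
                c = self.labels[ref]
                self.co_clustered[ref] = sorted(
                    s for s, lab in self.labels.items()
                    if lab == c and s != ref and s not in self.reference_ids
                )


def select_extremes(ic50: pd.Series, k: int = 5) -> tuple[list[str], list[str]]:
    """The k lowest-IC50 (sensitive) and k highest-IC50 (resistant) lines.

    Missing values are dropped; ties at the k-th value are broken by the
    lexicographically smaller cell id.
    """
    v = ic50.dropna()
    if len(v) < 2 * k:
        raise ValueError(f"need at least {2 * k} cells with IC50, got {len(v)}")
    by_value = sorted(v.items(), key=lambda t: (t[1], t[0]))
    sensitive = [cell for cell, _ in by_value[:k]]
    by_value_desc = sorted(v.items(), key=lambda t: (-t[1], t[0]))
    resistant = [cell for cell, _ in by_value_desc[:k]]
    return sensitive, resistant


EXACT_TIED_MAX_N = 14


def _tied_exact_rank_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p for tied data by enumerating all
    C(n1+n2, n1) splits of the observed values (mid-ranks throughout);
    two-sided p is twice the smaller tail, capped at 1."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([
        ranks[list(c)].sum() - n1 * (n1 + 1) / 2
        for c in combinations(range(n), n1)
    ])
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return float(u_obs), float(min(1.0, 2.0 * min(lo, hi)))


def _exact_rank_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; exact null whenever feasible.

    Tie-free data uses the standard exact distribution; tied data is
    handled by full enumeration of splits while the pooled size permits,
    falling back to the mid-rank normal approximation above that.
    """
    if len(np.unique(np.concatenate([x, y]))) == len(x) + len(y):
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if len(x) + len(y) <= EXACT_TIED_MAX_N:
        return _tied_exact_rank_p(x, y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _exact_u_pvalues(n1: int, n2: int) -> np.ndarray:
    """Two-sided p-value for every U = 0..n1·n2 under the tie-free exact
    null, by the classic partition-counting recurrence."""
    # counts[k][u] = number of k-subsets of ranks seen so far with U = u
    counts = np.zeros((n1 + 1, n1 * n2 + 1))
    counts[0, 0] = 1.0
    for rank in range(1, n1 + n2 + 1):
        for k in range(min(rank, n1), 0, -1):
            # picking this rank as the k-th group-1 member adds rank - k
            # to the U statistic
            u_add = rank - k
            if u_add <= n1 * n2:
                counts[k, u_add:] += counts[k - 1, : n1 * n2 + 1 - u_add]
    dist = counts[n1] / counts[n1].sum()
    cdf = np.cumsum(dist)
    sf = np.cumsum(dist[::-1])[::-1]
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def derive_signature(
    expr: LabeledMatrix,
    sensitive_set: list[str],
    resistant_set: list[str],
    alpha: float = 0.05,
    drug_id: str = "",
    test: str = "wilcoxon",
) -> SignatureResult:
    """Screen every gene for differential expression between extremes.

    Default test is the exact two-sided Wilcoxon rank-sum (asymptotic with
    mid-ranks when ties prevent the exact null); ``test="welch"`` switches
    to Welch's t. No multiple-testing correction is applied; selection is
    p < alpha. Direction is the sign of (sensitive median − resistant
    median).
    """
    for cell in list(sensitive_set) + list(resistant_set):
        if cell not in expr.col_ids:
            raise ValueError(f"cell {cell!r} not in expression matrix")
    if len(sensitive_set) < 2 or len(resistant_set) < 2:
        raise ValueError("each extreme group needs at least 2 members")
    s_idx = [expr.col_ids.index(c) for c in sensitive_set]
    r_idx = [expr.col_ids.index(c) for c in resistant_set]
    n1, n2 = len(s_idx), len(r_idx)
    n_genes = len(expr.row_ids)
    stat = np.zeros(n_genes)
    pval = np.ones(n_genes)

    sub = expr.values[:, s_idx + r_idx]
    if test == "wilcoxon":
        # tie-free genes share one exact null: vectorize U and look p up
        from scipy.stats import rankdata

        tied = np.array([
            len(np.unique(sub[i])) < n1 + n2 for i in range(n_genes)
        ])
        if (~tied).any():
            p_table = _exact_u_pvalues(n1, n2)
            ranks = rankdata(sub[~tied], axis=1)
            u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2
            stat[~tied] = u
            pval[~tied] = p_table[u.astype(int)]
        for i in np.flatnonzero(tied):
            x, y = sub[i, :n1], sub[i, n1:]
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                stat[i], pval[i] = 0.0, 1.0
            else:
                stat[i], pval[i] = _exact_rank_p(x, y)
    else:
        for i in range(n_genes):
            x, y = sub[i, :n1], sub[i, n1:]
            res = ttest_ind(x, y, equal_var=False)
            stat[i], pval[i] = float(res.statistic), float(res.pvalue)

    med_s = np.median(sub[:, :n1], axis=1)
    med_r = np.median(sub[:, n1:], axis=1)
    direction = ["up_in_sensitive" if ms >= mr else "up_in_resistant"
                 for ms, mr in zip(med_s, med_r)]
    return SignatureResult(
        drug_id=drug_id,
        sensitive_set=list(sensitive_set),
        resistant_set=list(resistant_set),
        gene_ids=list(expr.row_ids),
        statistic=stat,
        p_value=pval,
        direction=direction,
        alpha=alpha,
    )


def _two_cut_misclassified(
    expr: LabeledMatrix,
    signature_genes: list[str],
    sensitive: list[str],
    resistant: list[str],
) -> list[str]:
    """Cut the labeled cells into 2 groups on signature genes; return the
    members falling in the group dominated by the opposite label."""
    labeled = list(sensitive) + list(resistant)
    genes = [g for g in signature_genes if g in expr.row_ids]
    if not genes:
        raise ValueError("signature is empty on this expression matrix")
    sub = expr.subset_rows(genes).subset_cols(labeled)
    d = correlation_distance(sub.values)
    link = linkage(squareform(d, checks=False), method="average")
    cut = fcluster(link, t=2, criterion="maxclust")
    truth = np.array([c in set(sensitive) for c in labeled])
    # assign each of the 2 groups the label minimizing total misclassification
    in1 = cut == cut[0]
    err_a = int(np.sum(truth[in1] == False)) + int(np.sum(truth[~in1] == True))  # noqa: E712
    err_b = int(np.sum(truth[in1] == True)) + int(np.sum(truth[~in1] == False))  # noqa: E712
    sens_is_group1 = err_a <= err_b
    mis = []
    for i, cell in enumerate(labeled):
        in_group1 = bool(in1[i])
        predicted_sensitive = in_group1 == sens_is_group1
        if predicted_sensitive != truth[i]:
            mis.append(cell)
    return sorted(mis)


def evaluate_separation(
    expr: LabeledMatrix,
    signature_genes: list[str],
    sensitive_set: list[str],
    resistant_set: list[str],
) -> tuple[bool, list[str]]:
    """Do the labeled extremes separate on the signature?

    Average-linkage clustering (1 − Pearson on signature rows) of the
    labeled cells, cut at 2 groups; misclassified members are those in the
    group dominated by the opposite label. Returns (clean, misclassified).
    """
    mis = _two_cut_misclassified(expr, signature_genes, sensitive_set, resistant_set)
    return (len(mis) == 0), mis


def loo_validate(
    expr: LabeledMatrix,
    ic50: pd.Series,
    k: int = 5,
    alpha: float = 0.05,
    mode: str = "fixed_signature",
    drug_id: str = "",
) -> LOOResult:
    """Leave-one-out robustness check of the signature.

    For each cell with expression data the cell is removed and the
    remaining labeled extremes are re-clustered on signature genes. In
    ``fixed_signature`` mode the signature derived from the full data is
    reused; in ``rederive`` mode the signature is re-derived from the
    remaining extreme members (a held-out extreme member shrinks its group
    to k−1). One "heatmap" per held-out cell; a heatmap is misclassified
    when any labeled member lands with the opposite group.
    """
    if mode not in ("fixed_signature", "rederive"):
        raise ValueError(f"unknown mode {mode!r}")
    ic50 = ic50[[c for c in ic50.index if c in expr.col_ids]]
    sensitive, resistant = select_extremes(ic50, k)
    full = derive_signature(expr, sensitive, resistant, alpha, drug_id)
    outcomes: dict[str, list[str]] = {}
    for cell in expr.col_ids:
        keep = [c for c in expr.col_ids if c != cell]
        sub_expr = expr.subset_cols(keep)
        sens = [c for c in sensitive if c != cell]
        resi = [c for c in resistant if c != cell]
        if mode == "rederive":
            if len(sens) < 2 or len(resi) < 2:
                raise ValueError(
                    f"holding out {cell} shrinks an extreme group below 2"
                )
            sig = derive_signature(sub_expr, sens, resi, alpha, drug_id)
            genes = sig.signature_genes
        else:
            genes = full.signature_genes
        outcomes[cell] = _two_cut_misclassified(sub_expr, genes, sens, resi)
    return LOOResult(mode=mode, outcomes=outcomes)


def project_signature(
    signature: SignatureResult,
    external_counts: LabeledMatrix,
    reference_expr: LabeledMatrix,
    n_clusters: int = 2,
    log1p: bool = False,
) -> ProjectionResult:
    """Project the signature onto an external tumor count matrix.

    Signature genes are intersected with the external gene set (the shortfall
    is reported), each dataset is z-scored per gene separately, the columns
    are merged, and the merged panel is clustered hierarchically
    (average linkage, 1 − Pearson) into ``n_clusters``. Each reference
    column's co-clustered tumor ids are reported.
    """
    sig_genes = signature.signature_genes
    ext_genes = set(external_counts.row_ids)
    ref_genes = set(reference_expr.row_ids)
    genes = [g for g in sig_genes if g in ext_genes and g in ref_genes]
    missing = [g for g in sig_genes if g not in ext_genes or g not in ref_genes]
    if not genes:
        raise ValueError("no signature gene present in the external data")

    ext_z = normalize_counts(external_counts, log1p=log1p).subset_rows(genes)
    if reference_expr.units == "z-score":
        ref_z = reference_expr.subset_rows(genes)
    else:
        ref_z = standard_normalize(reference_expr).subset_rows(genes)

    merged_ids = list(ext_z.col_ids) + list(ref_z.col_ids)
    merged = np.column_stack([ext_z.values, ref_z.values])
    d = correlation_distance(merged)
    link = linkage(squareform(d, checks=False), method="average")
    cut = fcluster(link, t=n_clusters, criterion="maxclust")
    labels = {s: int(c) for s, c in zip(merged_ids, cut)}
    return ProjectionResult(
        genes_used=len(genes),
        genes_missing=missing,
        labels=labels,
        reference_ids=list(ref_z.col_ids),
    )
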