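"""Extreme-responder signatures: derivation, separation, LOO, projection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from pharmsig.datamodel import AxisSemantics, LabeledMatrix
from pharmsig.signature import (
    derive_signature,
    evaluate_separation,
    loo_validate,
    project_signature,
    select_extremes,
)

from conftest import labeled


def rank_sum_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating all C(n1+n2, n1) splits
    of the observed pooled values (mid-ranks; doubled smaller tail)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    offset = n1 * (n1 + 1) / 2
    u_obs = ranks[:n1].sum() - offset
    us = [ranks[list(c)].sum() - offset
          for c in itertools.combinations(range(n), n1)]
    us = np.array(us)
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


def two_group_expr(sens_block, res_block, n_genes=4, sens=5, res=5):
    """Signature-gene matrix with mixed directions: even genes carry the
    block value, odd genes its negation (a flat profile is invisible to
    the correlation distance, as it is in real data)."""
    dirs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n_genes)])
    values = np.concatenate([
        np.tile(dirs[:, None] * float(sens_block), (1, sens)),
        np.tile(dirs[:, None] * float(res_block), (1, res)),
    ], axis=1)
    ids = [f"SC{i}" for i in range(sens)] + [f"RC{i}" for i in range(res)]
    m = LabeledMatrix([f"g{i}" for i in range(n_genes)], ids, values,
                      AxisSemantics.gene_by_sample, "z-score")
    return m, ids[:sens], ids[sens:]


class TestSelectExtremes:
    def test_distinct_values(self):
        ic50 = pd.Series([5.0, 1.0, 3.0, 0.2, 9.0, 7.0],
                         index=list("abcdef"))
        sens, res = select_extremes(ic50, 2)
        assert sens == ["d", "b"] and res == ["e", "f"]

    def test_tie_broken_lexicographically(self):
        ic50 = pd.Series([1.0, 1.0, 2.0, 3.0], index=["b", "a", "c", "d"])
        sens, _ = select_extremes(ic50, 1)
        assert sens == ["a"]

    def test_k5_partitions_ten_cells(self):
        ic50 = pd.Series(np.arange(10.0), index=[f"c{i}" for i in range(10)])
        sens, res = select_extremes(ic50, 5)
        assert sorted(sens + res) == sorted(ic50.index)
        assert not set(sens) & set(res)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            select_extremes(pd.Series([1.0, 2.0, 3.0], index=list("abc")), 2)


class TestDeriveSignature:
    def test_complete_separation_exact_p(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.uniform(1, 2, (1, 5)),
                                 rng.uniform(3, 4, (1, 5))], axis=1)
        ids = [f"c{i}" for i in range(10)]
        m = LabeledMatrix(["g0"], ids, values, AxisSemantics.gene_by_sample)
        sig = derive_signature(m, ids[:5], ids[5:])
        assert sig.p_value[0] == pytest.approx(2 / 252)
        assert sig.signature_genes == ["g0"]
        assert sig.direction[0] == "up_in_resistant"

    def test_identical_groups_not_selected(self):
        m, sens, res = two_group_expr(1.0, 1.0, n_genes=1)
        sig = derive_signature(m, sens, res)
        assert sig.p_value[0] == 1.0 and sig.signature_genes == []

    @pytest.mark.parametrize("n1, n2", [(3, 3), (4, 5), (6, 6)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(42)
        for trial in range(6):
            x = rng.normal(size=n1)
            y = rng.normal(loc=0.8, size=n2)
            if trial % 2:  # exercise tied data too
                x = np.round(x)
                y = np.round(y)
            ids = [f"c{i}" for i in range(n1 + n2)]
            m = LabeledMatrix(["g0"], ids,
                              np.concatenate([x, y])[None, :],
                              AxisSemantics.gene_by_sample)
            sig = derive_signature(m, ids[:n1], ids[n1:])
            assert sig.p_value[0] == pytest.approx(rank_sum_oracle(x, y),
                                                   abs=1e-9)

    def test_welch_alternative(self):
        m, sens, res = two_group_expr(2.0, -2.0, n_genes=1)
        # perturb so variances exist
        rng = np.random.default_rng(1)
        m.values[0] += rng.normal(0, 0.1, 10)
        sig = derive_signature(m, sens, res, test="welch")
        assert sig.p_value[0] < 0.001
        assert sig.direction[0] == "up_in_sensitive"

    def test_overlap_rejected(self):
        m, sens, res = two_group_expr(1, -1)
        with pytest.raises(ValueError, match="overlap"):
            derive_signature(m, sens, sens)

    def test_planted_recovery_and_type_I(self, cohort, expr_z):
        sig = derive_signature(expr_z, cohort.truth.sensitive_cells(),
                               cohort.truth.resistant_cells())
        planted = set(cohort.truth.signature_genes)
        selected = set(sig.signature_genes)
        recall = len(selected & planted) / len(planted)
        null_rate = len(selected - planted) / (len(sig.gene_ids) - len(planted))
        assert recall >= 0.9
        assert 0.01 <= null_rate <= 0.07

    def test_recall_monotone_in_effect_size(self):
        from pharmsig.simulate import CohortConfig, generate_cohort

        recalls = []
        for delta in (0.5, 1.0, 2.0):
            co = generate_cohort(CohortConfig(seed=5, signature_effect=delta))
            sig = derive_signature(
                co.gene_expression, co.truth.sensitive_cells(),
                co.truth.resistant_cells())
            planted = set(co.truth.signature_genes)
            recalls.append(len(set(sig.signature_genes) & planted) / len(planted))
        assert recalls == sorted(recalls)


class TestSeparation:
    def test_perfect_blocks_clean(self):
        m, sens, res = two_group_expr(1.0, -1.0)
        rng = np.random.default_rng(2)
        m.values[:] += rng.normal(0, 0.05, m.values.shape)
        clean, mis = evaluate_separation(m, m.row_ids, sens, res)
        assert clean and mis == []

    def test_swapped_profile_detected(self):
        m, sens, res = two_group_expr(1.0, -1.0)
        rng = np.random.default_rng(3)
        m.values[:] += rng.normal(0, 0.05, m.values.shape)
        m.values[:, 0] = -m.values[:, 0]  # SC0 given the resistant profile
        clean, mis = evaluate_separation(m, m.row_ids, sens, res)
        assert not clean and mis == ["SC0"]

    def test_synthetic_cohort_clean(self, cohort, expr_z):
        sig = derive_signature(expr_z, cohort.truth.sensitive_cells(),
                               cohort.truth.resistant_cells())
        clean, mis = evaluate_separation(
            expr_z, sig.signature_genes,
            cohort.truth.sensitive_cells(), cohort.truth.resistant_cells())
        assert clean, mis


class TestLeaveOneOut:
    def loo_fixture(self, flip_cell=None):
        m, sens, res = two_group_expr(1.0, -1.0, n_genes=6)
        extra = np.zeros((6, 3))
        ids = m.col_ids + [f"I{i}" for i in range(3)]
        values = np.concatenate([m.values, extra], axis=1)
        rng = np.random.default_rng(4)
        values = values + rng.normal(0, 0.05, values.shape)
        if flip_cell is not None:
            values[:, flip_cell] = -values[:, flip_cell]
        expr = LabeledMatrix(m.row_ids, ids, values,
                             AxisSemantics.gene_by_sample, "z-score")
        ic50 = pd.Series([0.1] * 5 + [8.0] * 5 + [1.0] * 3, index=ids)
        return expr, ic50

    @pytest.mark.parametrize("mode", ["fixed_signature", "rederive"])
    def test_perfect_cohort_zero_misclassified(self, mode):
        expr, ic50 = self.loo_fixture()
        result = loo_validate(expr, ic50, k=5, mode=mode)
        assert result.total_heatmaps == 13
        assert result.misclassified_heatmap_count == 0

    def test_ambiguous_cell_localized(self):
        # SC0 carries the resistant profile: every heatmap retaining SC0 is
        # dirty, the single heatmap holding SC0 out is clean
        expr, ic50 = self.loo_fixture(flip_cell=0)
        result = loo_validate(expr, ic50, k=5, mode="fixed_signature")
        dirty = {cell for cell, mis in result.outcomes.items() if mis}
        assert "SC0" not in dirty
        assert dirty == set(expr.col_ids) - {"SC0"}

    def test_synthetic_cohort_mostly_clean(self, cohort, expr_z, panel):
        result = loo_validate(expr_z, panel.drug_values(cohort.truth.anchor_drug),
                              k=5, mode="fixed_signature")
        frac = result.misclassified_heatmap_count / result.total_heatmaps
        assert frac <= 0.15

    def test_unknown_mode_rejected(self):
        expr, ic50 = self.loo_fixture()
        with pytest.raises(ValueError, match="mode"):
            loo_validate(expr, ic50, k=5, mode="bootstrap")


class TestProjection:
    def test_gene_intersection_bookkeeping(self, cohort, expr_z):
        sig = derive_signature(expr_z, cohort.truth.sensitive_cells(),
                               cohort.truth.resistant_cells())
        # drop 4 signature genes from the external data: 173-gene style
        # bookkeeping, reported count must match exactly
        drop = sig.signature_genes[:4]
        keep = [g for g in cohort.tumor_counts.row_ids if g not in drop]
        external = cohort.tumor_counts.subset_rows(keep)
        ref = expr_z.subset_cols(cohort.truth.sensitive_cells()[:1])
        result = project_signature(sig, external, ref)
        assert result.genes_used == len(sig.signature_genes) - 4
        assert set(drop) <= set(result.genes_missing)

    def test_reference_joins_planted_subgroup(self, cohort, expr_z):
        sig = derive_signature(expr_z, cohort.truth.sensitive_cells(),
                               cohort.truth.resistant_cells())
        ref_cell = cohort.truth.sensitive_cells()[0]
        result = project_signature(sig, cohort.tumor_counts,
                                   expr_z.subset_cols([ref_cell]))
        subgroup = {t for t, v in cohort.truth.tumor_subgroup.items() if v}
        mates = set(result.co_clustered[ref_cell])
        assert mates == subgroup

    def test_column_order_invariance(self, cohort, expr_z):
        sig = derive_signature(expr_z, cohort.truth.sensitive_cells(),
                               cohort.truth.resistant_cells())
        ref = expr_z.subset_cols(cohort.truth.sensitive_cells()[:1])
        a = project_signature(sig, cohort.tumor_counts, ref)
        shuffled = cohort.tumor_counts.subset_cols(
            list(reversed(cohort.tumor_counts.col_ids)))
        b = project_signature(sig, shuffled, ref)
        assert a.co_clustered == b.co_clustered

    def test_disjoint_genes_rejected(self, cohort, expr_z):
        sig = derive_signature(expr_z, cohort.truth.sensitive_cells(),
                               cohort.truth.resistant_cells())
        renamed = LabeledMatrix(
            [f"X{g}" for g in cohort.tumor_counts.row_ids],
            cohort.tumor_counts.col_ids, cohort.tumor_counts.values,
            AxisSemantics.gene_by_sample, "counts")
        with pytest.raises(ValueError, match="no signature gene"):
            project_signature(sig, renamed,
                              expr_z.subset_cols(cohort.truth.sensitive_cells()[:1]))
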