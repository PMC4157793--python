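"""Consensus clustering engine, K selection, labels and marker screening."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from pharmsig.consensus import (
    assign_labels,
    consensus_cluster,
    select_k,
    subtype_markers,
)
from pharmsig.datamodel import AxisSemantics, LabeledMatrix

from conftest import labeled


def block_matrix(block_vectors, block_sizes, noise=0.0, seed=0):
    """Columns = samples; each block repeats its prototype vector."""
    rng = np.random.default_rng(seed)
    cols = []
    for vec, size in zip(block_vectors, block_sizes):
        for _ in range(size):
            cols.append(np.asarray(vec, float) + rng.normal(0, noise, len(vec)))
    values = np.column_stack(cols)
    return LabeledMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j:02d}" for j in range(values.shape[1])],
        values, AxisSemantics.gene_by_sample)


class TestConsensusMatrix:
    def test_two_point_masses_give_binary_consensus(self):
        m = block_matrix([[1, 2, 3, 4], [4, 3, 2, 1]], [5, 5])
        res = consensus_cluster(m, maxk=3, resamples=60, seed=0)
        c2 = res.consensus[2]
        within = np.array([[c2[i, j] for i in range(5) for j in range(5) if i != j],
                           [c2[i, j] for i in range(5, 10) for j in range(5, 10) if i != j]])
        between = c2[:5, 5:]
        assert np.all(within == 1.0)
        assert np.all(between == 0.0)
        assert res.chosen_k == 2

    def test_duplicate_pair_always_coclusters(self):
        # 4 distinct prototypes plus an exact duplicate of the first
        protos = [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]]
        m = block_matrix(protos + [protos[0]], [1, 1, 1, 1, 1])
        res = consensus_cluster(m, maxk=3, resamples=80, subsample_fraction=0.9,
                                seed=1)
        for k in (2, 3):
            assert res.consensus[k][0, 4] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, expr_z):
        res = consensus_cluster(expr_z, maxk=4, resamples=40, seed=2)
        for k, ck in res.consensus.items():
            assert np.allclose(ck, ck.T)
            assert np.all(np.diag(ck) == 1.0)
            assert ck.min() >= 0.0 and ck.max() <= 1.0

    def test_same_seed_bit_identical(self):
        m = block_matrix([[1, 2, 3, 4], [4, 3, 2, 1]], [5, 5], noise=0.3)
        a = consensus_cluster(m, maxk=4, resamples=50, seed=11)
        b = consensus_cluster(m, maxk=4, resamples=50, seed=11)
        assert a.labels == b.labels and a.chosen_k == b.chosen_k
        for k in a.consensus:
            assert np.array_equal(a.consensus[k], b.consensus[k])

    def test_monte_carlo_convergence(self):
        # deviation from the crisp 2-block truth shrinks as resamples grow
        m = block_matrix([[2, 0, 0, 2], [0, 2, 2, 0]], [6, 6], noise=0.4)
        truth = np.kron(np.eye(2), np.ones((6, 6)))
        errs = []
        for resamples in (30, 300):
            res = consensus_cluster(m, maxk=2, resamples=resamples, seed=3)
            errs.append(np.abs(res.consensus[2] - truth).mean())
        assert errs[1] <= errs[0]

    def test_too_few_samples_rejected(self):
        m = block_matrix([[1, 2, 3]], [4])
        with pytest.raises(ValueError, match="samples"):
            consensus_cluster(m, maxk=5, resamples=10, seed=0)


class TestSelectK:
    def test_planted_three_subtypes_recovered(self, cohort, expr_z):
        from sklearn.metrics import adjusted_rand_score

        res = consensus_cluster(expr_z, maxk=10, resamples=150,
                                seed=cohort.config.seed)
        assert res.chosen_k == 3
        truth = [cohort.truth.subtype[c] for c in expr_z.col_ids]
        got = [res.labels[c] for c in expr_z.col_ids]
        assert adjusted_rand_score(truth, got) >= 0.9

    def test_degraded_beyond_two_blocks_picks_two(self):
        m = block_matrix([[1, 2, 3, 4], [4, 3, 2, 1]], [5, 5], noise=0.05)
        res = consensus_cluster(m, maxk=5, resamples=80, seed=5)
        assert res.chosen_k == 2

    def test_all_identical_degenerate_picks_two(self, caplog):
        m = block_matrix([[1, 2, 3, 4]], [8])
        res = consensus_cluster(m, maxk=4, resamples=40, seed=0)
        assert res.chosen_k == 2 and res.degenerate

    def test_delta_area_nonnegative_at_two(self, expr_z):
        res = consensus_cluster(expr_z, maxk=4, resamples=40, seed=7)
        assert res.delta_areas[2] >= 0.0

    def test_select_k_updates_result(self, expr_z):
        res = consensus_cluster(expr_z, maxk=4, resamples=40, seed=8)
        k = select_k(res)
        assert k == res.chosen_k and set(res.pac) == {2, 3, 4}


class TestAssignLabels:
    def perfect_consensus(self, sizes):
        n = sum(sizes)
        c = np.zeros((n, n))
        pos = 0
        for s in sizes:
            c[pos:pos + s, pos:pos + s] = 1.0
            pos += s
        return c

    def test_two_blocks_forced(self):
        ids = [f"s{i}" for i in range(8)]
        labels = assign_labels(self.perfect_consensus([4, 4]), 2, ids)
        assert len(set(labels.values())) == 2
        assert len({labels[f"s{i}"] for i in range(4)}) == 1

    def test_larger_block_labeled_first(self):
        ids = [f"s{i}" for i in range(10)]
        labels = assign_labels(self.perfect_consensus([6, 4]), 2, ids)
        assert all(labels[f"s{i}"] == 1 for i in range(6))
        assert all(labels[f"s{i}"] == 2 for i in range(6, 10))


def kruskal_oracle(groups):
    """Exact permutation p for the Kruskal-Wallis statistic by enumerating
    every distinct ordering of the pooled sample (independent of the
    implementation's combination-based enumeration)."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)

    def h_of(order):
        ranks = rankdata(pooled)[list(order)]
        h, pos = 0.0, 0
        for s in sizes:
            h += ranks[pos:pos + s].sum() ** 2 / s
            pos += s
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
        return h / tie if tie else 0.0

    h_obs = h_of(range(n))
    count = total = 0
    seen = set()
    for perm in itertools.permutations(range(n)):
        key = tuple(tuple(sorted(perm[sum(sizes[:i]):sum(sizes[:i + 1])]))
                    for i in range(len(sizes)))
        if key in seen:
            continue
        seen.add(key)
        total += 1
        if h_of(perm) >= h_obs - 1e-12:
            count += 1
    return h_obs, count / total


class TestSubtypeMarkers:
    def marker_input(self, rows, n_per_group=3):
        values = np.asarray(rows, float)
        m = labeled(values)
        labels = {f"s{j}": j // n_per_group + 1 for j in range(values.shape[1])}
        return m, labels

    def test_textbook_example_statistic(self):
        m, labels = self.marker_input([[1, 2, 3, 4, 5, 6, 7, 8, 9]])
        mk = subtype_markers(m, labels, method="chi2")
        assert mk.statistic[0] == pytest.approx(7.2)
        assert mk.p_value[0] == pytest.approx(0.0273, abs=1e-3)
        assert mk.selected[0]

    def test_exact_small_sample_matches_permutation_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            rows = rng.integers(0, 5, size=(1, 8)).astype(float)
            m, labels = self.marker_input(rows, n_per_group=2)
            mk = subtype_markers(m, labels)  # auto -> exact at N=8
            h, p = kruskal_oracle([rows[0, i:i + 2] for i in range(0, 8, 2)])
            assert mk.statistic[0] == pytest.approx(h, abs=1e-9)
            assert mk.p_value[0] == pytest.approx(p, abs=1e-9)

    def test_constant_gene_not_selected(self):
        m, labels = self.marker_input([[2, 2, 2, 2, 2, 2, 2, 2, 2]])
        mk = subtype_markers(m, labels)
        assert not mk.selected[0] and mk.p_value[0] == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(4, 12))
        m = labeled(values)
        labels = {f"s{j}": j % 3 + 1 for j in range(12)}
        mk = subtype_markers(m, labels)
        order = rng.permutation(12)
        m2 = LabeledMatrix(m.row_ids, [m.col_ids[j] for j in order],
                           values[:, order], AxisSemantics.gene_by_sample)
        mk2 = subtype_markers(m2, labels)
        assert np.allclose(mk.p_value, mk2.p_value)

    def test_small_cluster_rejected(self):
        m = labeled(np.ones((1, 5)))
        labels = {"s0": 1, "s1": 1, "s2": 2, "s3": 2, "s4": 3}
        with pytest.raises(ValueError, match="fewer than 2"):
            subtype_markers(m, labels)

    def test_planted_subtype_markers_found(self, cohort, expr_z):
        labels = {c: cohort.truth.subtype[c] for c in expr_z.col_ids}
        mk = subtype_markers(expr_z, labels)
        selected = set(mk.selected_genes)
        planted = set(cohort.truth.subtype_marker_genes)
        # KW power at the smallest group (5 samples) caps recall below 1
        assert len(selected & planted) / len(planted) >= 0.85
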