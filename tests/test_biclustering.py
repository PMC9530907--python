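import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geiblock import (
    Partition,
    best_of,
    bicluster,
    exhaustive_bicluster,
    sse_bc,
)
from geiblock.biclustering import _partitions_into_k, _stirling2

from conftest import make_table, random_masked_table


def brute_force_sse(table, partition):
    """Independent plain-loop implementation of the within-cell SSE."""
    total = 0.0
    for p in range(partition.n_row_clusters):
        for l in range(partition.n_col_clusters):
            cell = []
            for i in range(table.n_genotypes):
                if partition.row_assignment[i] != p:
                    continue
                for j in range(table.n_environments):
                    if partition.col_assignment[j] == l and table.observed[i, j]:
                        cell.append(table.values[i, j])
            if cell:
                mean = sum(cell) / len(cell)
                total += sum((v - mean) ** 2 for v in cell)
    return total


class TestPartition:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            Partition([0, 2], [0, 0], 2, 1)

    def test_more_clusters_than_items_rejected(self):
        with pytest.raises(ValueError):
            Partition([0], [0], 2, 1)


class TestSseBc:
    def test_single_cell_complete(self, table_2x2):
        part = Partition([0, 0], [0, 0], 1, 1)
        assert sse_bc(table_2x2, part) == pytest.approx(8.75)

    def test_singleton_cells_zero(self, table_2x2):
        part = Partition([0, 1], [0, 1], 2, 2)
        assert sse_bc(table_2x2, part) == 0.0

    def test_single_cell_masked(self):
        t = make_table([[1.0, np.nan], [3.0, 5.0]])
        part = Partition([0, 0], [0, 0], 1, 1)
        assert sse_bc(t, part) == pytest.approx(8.0)

    def test_dimension_mismatch(self, table_2x2):
        with pytest.raises(ValueError):
            sse_bc(table_2x2, Partition([0, 0, 0], [0, 0], 1, 1))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 4), st.integers(1, 3))
    def test_matches_brute_force(self, seed, n, m):
        rng = np.random.default_rng(seed)
        t = random_masked_table(rng, 4, 3, 0.25)
        part = Partition(rng.integers(0, n, 4), rng.integers(0, m, 3), n, m)
        assert sse_bc(t, part) == pytest.approx(brute_force_sse(t, part), abs=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t = random_masked_table(rng, 5, 4, 0.2)
        part = Partition(rng.integers(0, 2, 5), rng.integers(0, 2, 4), 2, 2)
        flipped = Partition(1 - part.row_assignment, part.col_assignment, 2, 2)
        assert sse_bc(t, part) == pytest.approx(sse_bc(t, flipped))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_missing_cell_neutrality(self, seed):
        # values stored at unobserved positions never influence the objective
        rng = np.random.default_rng(seed)
        t = random_masked_table(rng, 4, 4, 0.3)
        junk = np.where(t.observed, t.values, rng.normal(0, 100, (4, 4)))
        from geiblock import PhenotypeTable
        t_junk = PhenotypeTable(t.genotype_ids, t.environment_ids, junk, t.observed)
        part = Partition(rng.integers(0, 2, 4), rng.integers(0, 2, 4), 2, 2)
        assert sse_bc(t_junk, part) == pytest.approx(sse_bc(t, part))


class TestBicluster:
    def test_zero_noise_planted_recovery(self):
        vals = np.array([[1.0, 1, 5, 5], [1, 1, 5, 5], [5, 5, 1, 1], [5, 5, 1, 1]])
        t = make_table(vals)
        res = best_of(t, 2, 2, trials=10, base_seed=0)
        assert res.sse_bc == pytest.approx(0.0, abs=1e-12)
        ra = res.partition.row_assignment
        assert ra[0] == ra[1] and ra[2] == ra[3] and ra[0] != ra[2]

    def test_n1_m1_seed_independent(self, table_2x2):
        for seed in (0, 1, 99):
            res = bicluster(table_2x2, 1, 1, seed=seed)
            assert res.sse_bc == pytest.approx(8.75)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        t = random_masked_table(rng, 8, 5, 0.2)
        a = bicluster(t, 3, 2, seed=42)
        b = bicluster(t, 3, 2, seed=42)
        assert np.array_equal(a.partition.row_assignment, b.partition.row_assignment)
        assert np.array_equal(a.partition.col_assignment, b.partition.col_assignment)
        assert a.sse_bc == b.sse_bc and a.iterations == b.iterations

    def test_out_of_range_counts(self, table_2x2):
        with pytest.raises(ValueError):
            bicluster(table_2x2, 3, 1)
        with pytest.raises(ValueError):
            bicluster(table_2x2, 1, 0)

    def test_result_objective_consistent(self):
        rng = np.random.default_rng(11)
        t = random_masked_table(rng, 10, 6, 0.3)
        res = bicluster(t, 3, 2, seed=5)
        assert res.sse_bc == pytest.approx(sse_bc(t, res.partition))
        assert res.iterations >= 1
        # fitted clusters all nonempty
        assert len(np.unique(res.partition.row_assignment)) == 3
        assert len(np.unique(res.partition.col_assignment)) == 2

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_objective_monotone_over_sweeps(self, seed):
        rng = np.random.default_rng(seed)
        t = random_masked_table(rng, 7, 5, 0.3)
        res = bicluster(t, 3, 2, seed=seed)
        h = res.objective_history
        for a, b in zip(h, h[1:]):
            assert b <= a * (1 + 1e-9) + 1e-12


class TestBestOf:
    def test_trials_one_equals_single_run(self):
        rng = np.random.default_rng(2)
        t = random_masked_table(rng, 6, 4, 0.2)
        single = bicluster(t, 2, 2, seed=17)
        best = best_of(t, 2, 2, trials=1, base_seed=17)
        assert best.sse_bc == single.sse_bc
        assert np.array_equal(best.partition.row_assignment,
                              single.partition.row_assignment)

    def test_not_worse_than_any_seed(self):
        rng = np.random.default_rng(4)
        t = random_masked_table(rng, 8, 5, 0.25)
        best = best_of(t, 3, 2, trials=10, base_seed=100)
        singles = [bicluster(t, 3, 2, seed=100 + s).sse_bc for s in range(10)]
        assert best.sse_bc == pytest.approx(min(singles))
        # ties broken by lowest seed (best_of keeps the first strict minimum)
        assert best.seed == 100 + int(np.argmin(singles))


class TestExhaustive:
    def test_planted_3x4(self):
        t = make_table([[1.0, 1, 5, 5], [1, 1, 5, 5], [5, 5, 1, 1]])
        res = exhaustive_bicluster(t, 2, 2)
        assert res.sse_bc == pytest.approx(0.0, abs=1e-12)
        ra, ca = res.partition.row_assignment, res.partition.col_assignment
        assert ra[0] == ra[1] != ra[2]
        assert ca[0] == ca[1] != ca[2] and ca[2] == ca[3]

    def test_full_singletons_zero(self, table_2x2):
        assert exhaustive_bicluster(table_2x2, 2, 2).sse_bc == 0.0

    def test_constant_table_zero(self):
        t = make_table([[3.0, 3.0], [3.0, 3.0]])
        for n, m in [(1, 1), (1, 2), (2, 2)]:
            assert exhaustive_bicluster(t, n, m).sse_bc == pytest.approx(0.0)

    def test_guard_on_large_instance(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.normal(size=(40, 12)))
        with pytest.raises(ValueError, match="too large"):
            exhaustive_bicluster(t, 10, 5)

    def test_partition_enumeration_counts(self):
        # number of set partitions into exactly k blocks = Stirling numbers
        assert _stirling2(4, 2) == 7
        assert len(list(_partitions_into_k(4, 2))) == 7
        assert len(list(_partitions_into_k(5, 3))) == _stirling2(5, 3) == 25

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_heuristic_attains_optimum_small(self, seed):
        rng = np.random.default_rng(seed)
        t = random_masked_table(rng, 4, 3, 0.2)
        opt = exhaustive_bicluster(t, 2, 2).sse_bc
        heur = best_of(t, 2, 2, trials=60, base_seed=seed).sse_bc
        assert heur <= opt * (1 + 1e-9) + 1e-9
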