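"""Expression statistics: normalization, rank tests against enumeration and
permutation oracles, subgenome balance, bias/specificity calls and fates."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ohnofate as of
from ohnofate.errors import ValidationError


def matrix_from(counts, cell_type=None):
    counts = np.asarray(counts)
    return of.CellMatrix(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(counts.shape[0])],
        gene_ids=[f"g{j}" for j in range(counts.shape[1])],
        cell_type=cell_type,
    )


# --------------------------------------------------------------------------
# normalization and scaling
# --------------------------------------------------------------------------


class TestNormalize:
    def test_hand_evaluated_formula(self):
        m = of.normalize_counts(matrix_from([[1, 3]]))
        assert m.norm[0, 0] == pytest.approx(math.log(2501), abs=1e-10)
        assert m.norm[0, 1] == pytest.approx(math.log(1 + 10000 * 3 / 4), abs=1e-10)

    def test_single_expressed_gene_saturates(self):
        for c in (1, 7, 500):
            m = of.normalize_counts(matrix_from([[c, 0]]))
            assert m.norm[0, 0] == pytest.approx(math.log(10001), abs=1e-10)

    def test_all_zero_gene_stays_zero(self):
        m = of.normalize_counts(matrix_from([[5, 0], [3, 0]]))
        assert np.all(m.norm[:, 1] == 0)

    def test_zero_total_cells_reported(self):
        m = of.normalize_counts(matrix_from([[0, 0], [1, 1]]))
        assert m.zero_total_cells == ["c0"] and np.all(m.norm[0] == 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            matrix_from([[-1, 2]])

    def test_delogged_row_sums_equal_scale_factor(self, small_sim):
        _, _, matrix, _ = small_sim
        sums = np.expm1(matrix.norm).sum(axis=1)
        nz = matrix.counts.sum(axis=1) > 0
        assert np.allclose(sums[nz], 10_000.0, rtol=1e-6)


class TestScale:
    def test_two_cell_example(self):
        m = of.scale_genes(of.normalize_counts(matrix_from([[0, 1], [2, 1]])))
        # gene 0 norm values are symmetric around their mean; sample sd (n-1)
        assert m.scaled[0, 0] == pytest.approx(-1 / np.sqrt(2), abs=1e-12)
        assert m.scaled[1, 0] == pytest.approx(+1 / np.sqrt(2), abs=1e-12)

    def test_constant_gene_and_clip(self):
        n = 300
        m = matrix_from([[1, 1]] * n)
        of.normalize_counts(m)
        m.norm[:, 1] = 0.0
        m.norm[-1, 1] = 1.0  # engineered outlier: z ~ sqrt(n) >> 10
        of.scale_genes(m)
        assert np.all(m.scaled[:, 0] == 0)  # zero variance -> zeros
        assert m.scaled[-1, 1] == 10.0  # clipped at scale_clip

    def test_single_cell_error(self):
        with pytest.raises(ValidationError):
            of.scale_genes(of.normalize_counts(matrix_from([[1, 2]])))


# --------------------------------------------------------------------------
# Wilcoxon rank-sum: enumeration + permutation oracles
# --------------------------------------------------------------------------


def enumeration_p(x, y):
    """Independent oracle: exact two-sided p by enumerating every assignment
    of the pooled values into the two groups."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n1)
    ]
    le = sum(s <= w_obs + 1e-9 for s in sums)
    ge = sum(s >= w_obs - 1e-9 for s in sums)
    return min(1.0, 2.0 * min(le, ge) / len(sums))


class TestRankSum:
    def test_textbook_extreme_case(self):
        assert of.rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_vectors_give_p_one(self):
        assert of.rank_sum_test([2, 2, 2], [2, 2, 2]) == 1.0

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=5),
        st.lists(st.integers(0, 5), min_size=2, max_size=5),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_exact_path_matches_enumeration_oracle(self, x, y):
        assert of.rank_sum_test(x, y) == pytest.approx(enumeration_p(x, y), abs=1e-9)

    def test_asymptotic_path_matches_permutation_null(self, rng):
        x = rng.poisson(3.0, size=20).astype(float)
        y = rng.poisson(4.5, size=22).astype(float)
        p_impl = of.rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:20].sum()
        n_perm = 10_000
        w_null = np.array([
            ranks[rng.permutation(len(pooled))[:20]].sum() for _ in range(n_perm)
        ])
        le = np.mean(w_null <= w_obs + 1e-9)
        ge = np.mean(w_null >= w_obs - 1e-9)
        p_mc = min(1.0, 2.0 * min(le, ge))
        assert p_impl == pytest.approx(p_mc, abs=0.02)

    def test_batch_agrees_with_scalar(self, rng):
        X = rng.poisson(2.0, size=(30, 6)).astype(float)
        Y = rng.poisson(2.5, size=(28, 6)).astype(float)
        batch = of.rank_sum_batch(X, Y)
        for g in range(6):
            assert batch[g] == pytest.approx(of.rank_sum_test(X[:, g], Y[:, g]), rel=1e-9)


# --------------------------------------------------------------------------
# binomial asymmetry test
# --------------------------------------------------------------------------


class TestBinomialAsymmetry:
    def test_symmetric_counts(self):
        assert of.binomial_asymmetry_test(5, 5) == 1.0

    def test_five_zero(self):
        assert of.binomial_asymmetry_test(5, 0) == pytest.approx(0.0625, abs=1e-12)

    def test_matches_direct_tail_summation(self):
        # independent oracle: sum the binomial pmf tail term by term
        n_l, n_s = 40, 22
        n, k = n_l + n_s, max(n_l, n_s)
        tail = sum(math.comb(n, i) for i in range(k, n + 1)) / 2**n
        assert of.binomial_asymmetry_test(n_l, n_s) == pytest.approx(2 * tail, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            of.binomial_asymmetry_test(-1, 3)


# --------------------------------------------------------------------------
# per-cell subgenome balance
# --------------------------------------------------------------------------


def two_gene_pairs(n):
    return [of.OhnologPair(f"g{2*i}", f"g{2*i+1}", f"z{i}") for i in range(n)]


class TestSubgenomeBalance:
    def test_identical_members_give_zero_ratio(self):
        m = of.normalize_counts(matrix_from([[3, 3, 1, 1], [2, 2, 5, 5]]))
        per_cell, _ = of.per_cell_subgenome_balance(m, two_gene_pairs(2))
        assert np.allclose(per_cell["log2_ratio"], 0.0)
        assert (per_cell["l_sum"] > per_cell["s_sum"]).sum() == 0

    def test_exact_doubling_gives_ratio_one(self):
        m = of.normalize_counts(matrix_from([[4, 2, 8, 4], [6, 3, 2, 1]]))
        per_cell, _ = of.per_cell_subgenome_balance(m, two_gene_pairs(2))
        assert np.allclose(per_cell["log2_ratio"], 1.0, atol=1e-9)

    def test_both_zero_cell_flagged(self):
        m = of.normalize_counts(matrix_from([[0, 0, 1, 1], [1, 1, 0, 0]]))
        per_cell, _ = of.per_cell_subgenome_balance(m, two_gene_pairs(1))
        assert bool(per_cell["both_zero"][0]) and per_cell["log2_ratio"][0] == 0.0

    def test_no_pairs_error(self, small_sim):
        _, _, matrix, _ = small_sim
        with pytest.raises(ValidationError):
            of.per_cell_subgenome_balance(matrix, [])

    def test_planted_global_ratio_recovered(self):
        # every pair L-biased at fold change 1.2 -> mean per-cell ratio ~1.2
        cfg = of.SimConfig(
            n_chrom_pairs=1, genes_per_chrom=200, n_cell_types=2, cells_per_type=250,
            fates={"l_biased": 1.0}, bias_fc=1.2,
            frac_evalue_violators=0, frac_nonreciprocal=0,
            frac_c1_violators=0, frac_c2_violators=0, seed=77,
        )
        genome = of.simulate_genomes(cfg)
        m, _ = of.simulate_counts(cfg, genome.true_pairs)
        of.normalize_counts(m)
        per_cell, _ = of.per_cell_subgenome_balance(m, genome.true_pairs)
        mean_ratio = ((per_cell.l_sum + 1e-9) / (per_cell.s_sum + 1e-9)).mean()
        assert 1.15 <= mean_ratio <= 1.25


# --------------------------------------------------------------------------
# pair bias table
# --------------------------------------------------------------------------


class TestPairBias:
    def test_identical_members_unbiased(self):
        counts = np.tile([5, 5, 2, 2], (6, 1))
        m = of.normalize_counts(matrix_from(counts))
        tab = of.pair_bias_table(m, two_gene_pairs(2))
        assert np.all(tab["p"] == 1.0)
        assert np.allclose(tab["log2fc"], 0.0) and all(tab["biased"] == "none")

    def test_strong_bias_called_with_direction(self, rng):
        n = 60
        counts = np.column_stack([
            rng.poisson(12.0, n), rng.poisson(1.0, n),  # pair 0: L-biased
            rng.poisson(1.0, n), rng.poisson(12.0, n),  # pair 1: S-biased
            rng.poisson(4.0, n), rng.poisson(4.0, n),   # pair 2: balanced
        ])
        m = of.normalize_counts(matrix_from(counts))
        tab = of.pair_bias_table(m, two_gene_pairs(3))
        assert list(tab["biased"]) == ["L", "S", "none"]
        assert tab["p_adj"].iloc[0] == pytest.approx(min(1.0, tab["p"].iloc[0] * 3))

    def test_unknown_group_error(self, small_sim):
        _, genome, matrix, _ = small_sim
        with pytest.raises(ValidationError, match="nope"):
            of.pair_bias_table(matrix, genome.true_pairs, group="nope")

    def test_bias_flag_respects_fold_change_gate(self, rng):
        # significant rank difference but fold change below 2 -> "none"
        n = 400
        counts = np.column_stack([rng.poisson(10.0, n), rng.poisson(13.0, n)])
        m = of.normalize_counts(matrix_from(counts))
        tab = of.pair_bias_table(m, two_gene_pairs(1))
        assert tab["p_adj"].iloc[0] < 0.05
        assert abs(tab["log2fc"].iloc[0]) < 1
        assert tab["biased"].iloc[0] == "none"


# --------------------------------------------------------------------------
# cell-type specificity
# --------------------------------------------------------------------------


class TestSpecificity:
    @staticmethod
    def _typed_matrix(rng, mu_by_type, n_per_type=100):
        types = sorted(mu_by_type[0].keys())
        counts, labels = [], []
        for t in types:
            block = np.column_stack([
                rng.poisson(mu[t], n_per_type) for mu in mu_by_type
            ])
            counts.append(block)
            labels += [t] * n_per_type
        m = matrix_from(np.vstack(counts), cell_type=np.array(labels, dtype=object))
        return of.normalize_counts(m)

    def test_exclusive_gene_recovered(self, rng):
        m = self._typed_matrix(rng, [{"A": 5.0, "B": 0.0, "C": 0.0}])
        assert of.celltype_specificity(m, genes=["g0"])["g0"] == {"A"}

    def test_uniform_gene_empty(self, rng):
        m = self._typed_matrix(rng, [{"A": 3.0, "B": 3.0, "C": 3.0}])
        assert of.celltype_specificity(m, genes=["g0"])["g0"] == set()

    def test_eightfold_two_types_recovered(self, rng):
        # gene 0 planted 8-fold high in A and B; gene 1 is a constant
        # housekeeping background so library normalization stays stable
        m = self._typed_matrix(
            rng,
            [{"A": 4.0, "B": 4.0, "C": 0.5, "D": 0.5},
             {"A": 20.0, "B": 20.0, "C": 20.0, "D": 20.0}],
        )
        assert of.celltype_specificity(m, genes=["g0"])["g0"] == {"A", "B"}

    def test_min_pct_detection_filter(self, rng):
        # highly expressed in very few in-type cells: detection below min_pct
        counts = np.zeros((200, 1), dtype=int)
        counts[:5, 0] = 50  # 5% of type A cells
        labels = np.array(["A"] * 100 + ["B"] * 100, dtype=object)
        m = of.normalize_counts(matrix_from(counts, cell_type=labels))
        assert of.celltype_specificity(m, genes=["g0"])["g0"] == set()

    def test_small_celltype_skipped_with_warning(self, rng, caplog):
        counts = rng.poisson(3.0, size=(53, 1))
        labels = np.array(["A"] * 50 + ["tiny"] * 3 + [], dtype=object)
        labels[-2:] = "B"  # tiny has 1 cell
        m = of.normalize_counts(matrix_from(counts, cell_type=labels))
        with caplog.at_level("WARNING"):
            of.celltype_specificity(m, genes=["g0"])
        assert any("tiny" in r.message for r in caplog.records)


# --------------------------------------------------------------------------
# fate classification
# --------------------------------------------------------------------------


def _bias_tables(universe, biased_map):
    """biased_map: {group: {pair_id: 'L'|'S'}}; everything else 'none'."""
    out = {}
    for group, flags in biased_map.items():
        out[group] = pd.DataFrame(
            {
                "pair_id": universe,
                "cell_type": group,
                "biased": [flags.get(p, "none") for p in universe],
            }
        )
    return out


class TestClassifyFates:
    PAIRS = [of.OhnologPair(f"l{i}", f"s{i}", f"z{i}") for i in range(4)]
    IDS = [p.pair_id for p in PAIRS]

    def _tables(self):
        return _bias_tables(
            self.IDS,
            {
                "ALL": {self.IDS[1]: "L"},
                "rod": {self.IDS[1]: "L", self.IDS[2]: "S"},
                "cone": {self.IDS[1]: "L"},
                "RPE": {},
            },
        )

    def test_fate_partition_and_dominance(self):
        calls = of.classify_fates(self._tables(), {}, {}, {}, self.PAIRS)
        by = {c.pair_id: c for c in calls}
        assert by[self.IDS[0]].fate == "balanced_all"
        assert by[self.IDS[1]].fate == "biased_multi"
        assert by[self.IDS[1]].dominance == "L"
        assert by[self.IDS[2]].fate == "biased_one"
        assert by[self.IDS[2]].dominance == "comparable"
        # partition property: categories sum to the universe
        counts = pd.Series([c.fate for c in calls]).value_counts()
        assert counts.sum() == len(self.PAIRS)

    def test_divergence_rules(self):
        spec_l = {"l0": {"cone"}, "l1": {"rod", "cone", "RPE"}, "l2": set(), "l3": {"rod"}}
        spec_s = {"s0": {"cone"}, "s1": {"cone"}, "s2": {"rod"}, "s3": set()}
        calls = of.classify_fates(self._tables(), spec_l, spec_s, {}, self.PAIRS)
        by = {c.pair_id: c.divergence for c in calls}
        assert by[self.IDS[0]] == "similar"
        assert by[self.IDS[1]] == "divergent"
        assert by[self.IDS[2]] == "not_applicable"  # one side empty
        assert by[self.IDS[3]] == "not_applicable"

    def test_inconsistent_universe_error(self):
        tables = self._tables()
        tables["rod"] = tables["rod"].iloc[:2]
        with pytest.raises(ValidationError):
            of.classify_fates(tables, {}, {}, {}, self.PAIRS)


# --------------------------------------------------------------------------
# subpopulation divergence
# --------------------------------------------------------------------------


class TestSubpopulationDivergence:
    @staticmethod
    def _matrix(l_counts, s_counts):
        counts = np.column_stack([l_counts, s_counts])
        m = of.CellMatrix(
            counts=counts,
            cell_ids=[f"c{i}" for i in range(len(l_counts))],
            gene_ids=["gl", "gs"],
        )
        return of.normalize_counts(m)

    PAIR = of.OhnologPair("gl", "gs", "z")

    def test_identical_fraction_gives_h_zero(self):
        m = self._matrix([2] * 20, [2] * 20)
        h, p = of.subpopulation_divergence(m, self.PAIR, ["a"] * 10 + ["b"] * 10)
        assert h == 0.0 and p == 1.0

    def test_opposite_subclusters_highly_significant(self):
        l = [5] * 20 + [0] * 20
        s = [0] * 20 + [5] * 20
        m = self._matrix(l, s)
        h, p = of.subpopulation_divergence(m, self.PAIR, ["a"] * 20 + ["b"] * 20)
        assert p < 0.001

    def test_single_subcluster_error(self):
        m = self._matrix([1] * 10, [1] * 10)
        with pytest.raises(ValidationError):
            of.subpopulation_divergence(m, self.PAIR, ["a"] * 10)

    def test_type_one_error_calibrated_under_permutation(self, rng):
        l = rng.poisson(3.0, 60)
        s = rng.poisson(3.0, 60)
        m = self._matrix(l + 1, s + 1)  # keep every cell expressing
        base = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        rejections = 0
        n_perm = 1000
        for _ in range(n_perm):
            _, p = of.subpopulation_divergence(m, self.PAIR, rng.permutation(base))
            rejections += p < 0.05
        assert rejections / n_perm == pytest.approx(0.05, abs=0.02)
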