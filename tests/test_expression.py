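import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rankwin as rw
from rankwin.expression import binomial_de_pvalues

from conftest import TOY_DESIGN


def frame(values, index, columns):
    return pd.DataFrame(values, index=index, columns=columns)


class TestComputeFPKM:
    def test_unit_case(self):
        counts = frame([[100]], ["e1"], ["s1"])
        fpkm = rw.compute_fpkm(counts, pd.Series([1000], index=["e1"]),
                               pd.Series([1e6], index=["s1"]))
        assert fpkm.loc["e1", "s1"] == pytest.approx(100.0)

    def test_zero_count_gives_zero(self):
        counts = frame([[0]], ["e1"], ["s1"])
        fpkm = rw.compute_fpkm(counts, pd.Series([500], index=["e1"]),
                               pd.Series([1e6], index=["s1"]))
        assert fpkm.loc["e1", "s1"] == 0.0

    def test_median_scale_case(self):
        # a median-length EST with a median-scale count in a 27-million-read library
        counts = frame([[174]], ["e1"], ["s1"])
        fpkm = rw.compute_fpkm(counts, pd.Series([663], index=["e1"]),
                               pd.Series([27e6], index=["s1"]))
        assert fpkm.loc["e1", "s1"] == pytest.approx(174 / (0.663 * 27), rel=1e-12)
        assert fpkm.loc["e1", "s1"] == pytest.approx(9.72, abs=5e-3)

    def test_zero_library_size_is_error(self):
        counts = frame([[1]], ["e1"], ["s1"])
        with pytest.raises(ValueError):
            rw.compute_fpkm(counts, pd.Series([500], index=["e1"]),
                            pd.Series([0.0], index=["s1"]))

    @settings(deadline=None, max_examples=40)
    @given(
        count=st.integers(1, 10_000),
        length=st.integers(1, 9_000),
        lib=st.floats(1e4, 1e8),
        scale=st.integers(2, 7),
    )
    def test_linear_in_counts_inverse_in_length_and_depth(self, count, length, lib, scale):
        def one(c, l, s):
            return rw.compute_fpkm(
                frame([[c]], ["e"], ["x"]),
                pd.Series([l], index=["e"]),
                pd.Series([s], index=["x"]),
            ).iloc[0, 0]

        base = one(count, length, lib)
        assert one(count * scale, length, lib) == pytest.approx(base * scale, rel=1e-9)
        assert one(count, length * scale, lib) == pytest.approx(base / scale, rel=1e-9)
        assert one(count, length, lib * scale) == pytest.approx(base / scale, rel=1e-9)


class TestAveragingAndRatio:
    def test_replicate_pair_mean(self):
        fpkm = frame([[10.0, 14.0]], ["e1"], ["NR_1", "NR_2"])
        means = rw.average_replicates(fpkm, {"NR_1": (rw.N_REPLETE, 1), "NR_2": (rw.N_REPLETE, 2)})
        assert means.loc["e1", rw.N_REPLETE] == 12.0

    def test_single_replicate_is_identity(self):
        fpkm = frame([[7.5]], ["e1"], ["NR_1"])
        means = rw.average_replicates(fpkm, {"NR_1": (rw.N_REPLETE, 1)})
        assert means.loc["e1", rw.N_REPLETE] == 7.5

    def test_top_abundance_pair_mean(self):
        # the printed level of a top-ranked EST is the mean of its two replicates
        fpkm = frame([[12000.89, 12942.0]], ["e1"], ["NR_1", "NR_2"])
        means = rw.average_replicates(fpkm, {"NR_1": (rw.N_REPLETE, 1), "NR_2": (rw.N_REPLETE, 2)})
        assert means.loc["e1", rw.N_REPLETE] == pytest.approx(12471.445)

    def test_ratio_and_logfc(self):
        means = frame([[4.0, 8.0], [3.0, 3.0]], ["a", "b"], [rw.N_REPLETE, rw.N_DEPLETED])
        ratio, lfc = rw.compute_ratio(means)
        assert ratio["a"] == 2.0 and lfc["a"] == 1.0
        assert ratio["b"] == 1.0 and lfc["b"] == 0.0

    def test_large_logfc_round_trip(self):
        means = frame([[1.0, 2.0 ** 12.06]], ["a"], [rw.N_REPLETE, rw.N_DEPLETED])
        _, lfc = rw.compute_ratio(means)
        assert lfc["a"] == pytest.approx(12.06)

    def test_zero_mean_is_invariant_error(self):
        means = frame([[0.0, 5.0]], ["a"], [rw.N_REPLETE, rw.N_DEPLETED])
        with pytest.raises(ValueError):
            rw.compute_ratio(means)

    def test_ratio_commutes_with_replicate_relabeling(self, toy_table):
        matrix = rw.expression_matrix(toy_table)
        swapped = dict(toy_table.sample_design)
        swapped["NR_1"], swapped["NR_2"] = swapped["NR_2"], swapped["NR_1"]
        table2 = rw.AnnotatedESTTable(toy_table.records, swapped, toy_table.annotations)
        matrix2 = rw.expression_matrix(table2)
        pd.testing.assert_series_equal(matrix.ratio, matrix2.ratio)


class TestRanking:
    def make_matrix(self, keys):
        ids = [f"e{i}" for i in range(len(keys))]
        means = frame(
            [[k, k] for k in keys], ids, [rw.N_REPLETE, rw.N_DEPLETED]
        )
        return rw.ExpressionMatrix(fpkm=means.copy(), condition_means=means,
                                   ratio=means[rw.N_DEPLETED] / means[rw.N_REPLETE],
                                   log_fc=None)

    def test_descending_order(self):
        ranking = rw.rank_ests(self.make_matrix([5.0, 9.0, 1.0]), "by_level")
        assert ranking.est_ids == ("e1", "e0", "e2")

    def test_tie_break_is_lexicographic(self):
        ranking = rw.rank_ests(self.make_matrix([3.0, 3.0, 3.0]), "by_level")
        assert ranking.est_ids == ("e0", "e1", "e2")

    def test_output_is_permutation_and_keys_non_increasing(self, default_matrix):
        ranking = rw.rank_ests(default_matrix, "by_level")
        assert sorted(ranking.est_ids) == sorted(default_matrix.est_ids)
        assert all(a >= b for a, b in zip(ranking.keys, ranking.keys[1:]))

    def test_by_ratio_uses_response_not_level(self, toy_table):
        matrix = rw.expression_matrix(toy_table)
        by_ratio = rw.rank_ests(matrix, "by_ratio")
        # e5/e6 doubled upon depletion: they top the ratio ranking
        assert set(by_ratio.est_ids[:2]) == {"e5", "e6"}

    def test_planted_term_members_reach_top_ranks(self, default_table):
        table, truth = default_table
        matrix = rw.expression_matrix(table)
        ranking = rw.rank_ests(matrix, "by_level")
        top_window = set(ranking.est_ids[:1024])
        members = table.annotations.members("GO:7999999")
        # 3x density in window 1 => 15 of the 60 members inside it
        assert len(members & top_window) == 15


class TestDEThresholds:
    def test_fold_and_p_gates(self):
        lfc = pd.Series({"up": 12.06, "down": -4.55, "weak": 0.5, "insig": 3.0})
        p = pd.Series({"up": 1.2e-13, "down": 6.4e-3, "weak": 1e-9, "insig": 0.2})
        flags = rw.apply_de_thresholds(lfc, p)
        assert flags.up == {"up"} and flags.down == {"down"}

    def test_missing_p_excludes_est(self):
        lfc = pd.Series({"a": 5.0, "b": 5.0})
        p = pd.Series({"a": 0.001})
        flags = rw.apply_de_thresholds(lfc, p)
        assert flags.up == {"a"}

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            rw.apply_de_thresholds(pd.Series({"a": 1.0}), pd.Series({"a": 1.5}))

    def test_type_i_error_controlled_under_sampling_noise_null(self):
        """The pooled binomial count test is calibrated when replicate counts
        carry only sequencing sampling noise (Poisson limit, equal means)."""
        config = rw.GeneratorConfig(
            n_ests=1000, seed=11, de_structure=None, nb_dispersion=1e9,
            planted_terms=(), n_go_bp_terms=0, n_kegg_terms=0,
        )
        table, _ = rw.generate_table(config)
        p = binomial_de_pvalues(table.counts_frame(), table.sample_design)
        assert (p < 0.05).mean() <= 0.07
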