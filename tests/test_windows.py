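import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rankwin as rw
from rankwin.windows import _window_counts, binomial_upper_tail


def brute_force_windows(N, w, s):
    """Independent enumeration: slide start by s while a full window fits."""
    out = []
    start = 1
    while start + w - 1 <= N:
        out.append((start, start + w - 1))
        start += s
    return out


def exact_binomial_upper_tail(x, n, p):
    """Direct summation of the binomial pmf, independent of scipy tails."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(x, n + 1))


def simple_ranking(ids):
    return rw.Ranking(mode=rw.RankMode.by_level, est_ids=tuple(ids),
                      keys=tuple(float(len(ids) - i) for i in range(len(ids))))


class TestMakeWindows:
    def test_default_geometry_full_transcriptome(self):
        assert len(rw.make_windows(12292)) == 23

    def test_single_window_when_universe_equals_size(self):
        assert rw.make_windows(1024) == [(1, 1024)]

    def test_three_overlapping_windows(self):
        assert rw.make_windows(2048) == [(1, 1024), (513, 1536), (1025, 2048)]

    def test_universe_smaller_than_window_is_error(self):
        with pytest.raises(ValueError):
            rw.make_windows(1023)

    @pytest.mark.parametrize("w,s", [(1024, 512), (100, 50), (64, 64), (10, 3)])
    def test_matches_enumeration_oracle(self, w, s):
        for N in range(w, 5001, 37):
            assert rw.make_windows(N, rw.WindowSpec(w, s)) == brute_force_windows(N, w, s)

    def test_covered_rank_multiplicity(self):
        """Every covered rank lies in exactly ceil(w/s) windows, except the
        ramp-up/ramp-down edges of the sliding scheme."""
        w, s, N = 1024, 512, 12292
        windows = rw.make_windows(N, rw.WindowSpec(w, s))
        mult = np.zeros(N + 1, dtype=int)
        for a, b in windows:
            mult[a : b + 1] += 1
        covered = mult[1 : windows[-1][1] + 1]
        interior = covered[s : len(covered) - s]
        assert (interior == math.ceil(w / s)).all()
        assert (covered[:s] == 1).all() and (covered[-s:] == 1).all()

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            rw.WindowSpec(10, 11)


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert rw.bonferroni_adjust(0.001, 23) == pytest.approx(0.023)
        assert rw.bonferroni_adjust(0.01, 2369) == 1.0
        assert rw.bonferroni_adjust(0.4, 1) == 0.4

    @settings(deadline=None, max_examples=50)
    @given(p=st.floats(0, 1), m=st.integers(1, 10_000))
    def test_bounded_and_monotone_in_m(self, p, m):
        adj = rw.bonferroni_adjust(p, m)
        assert 0 <= adj <= 1
        assert adj >= rw.bonferroni_adjust(p, max(1, m - 1)) or adj == 1.0


class TestWindowTermEnrichment:
    def test_toy_exact_binomial(self):
        """N=10, K=5, first window of 4 all members: p0=0.5, fold 2, p=0.5^4."""
        ids = [f"e{i}" for i in range(10)]
        ranking = simple_ranking(ids)
        tm = rw.TermMap.from_pairs([(e, "T") for e in ids[:4] + [ids[7]]], "GO_BP")
        results = rw.window_term_enrichment(
            ranking, tm, rw.WindowSpec(4, 2), rw.EligibilityPolicy(min_term_size_exclusive=0)
        )
        first = next(r for r in results if r.window_index == 1)
        assert (first.x, first.K, first.N) == (4, 5, 10)
        assert first.fold == pytest.approx(2.0)
        assert first.p_raw == pytest.approx(0.5**4)

    def test_background_density_not_flagged(self):
        rng = np.random.default_rng(3)
        N, K = 400, 100
        ids = [f"e{i}" for i in range(N)]
        members = rng.choice(ids, size=K, replace=False)
        tm = rw.TermMap.from_pairs([(e, "T") for e in members], "GO_BP")
        results = rw.window_term_enrichment(simple_ranking(ids), tm, rw.WindowSpec(40, 20))
        assert not any(r.flagged for r in results)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_and_tails_match_brute_force(self, seed):
        """Exhaustive oracle on small universes: window member counts by direct
        scan and the binomial tail by pmf summation."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(50, 201))
        w = int(rng.integers(8, 30))
        s = int(rng.integers(1, w + 1))
        K = int(rng.integers(5, N // 2))
        ids = [f"e{i:03d}" for i in range(N)]
        members = set(rng.choice(ids, size=K, replace=False))
        tm = rw.TermMap.from_pairs([(e, "T") for e in members], "KEGG_pathway")
        ranking = simple_ranking(ids)
        results = rw.window_term_enrichment(
            ranking, tm, rw.WindowSpec(w, s), rw.EligibilityPolicy(min_term_size_exclusive=0)
        )
        windows = brute_force_windows(N, w, s)
        assert len(results) == len(windows)
        for r, (a, b) in zip(sorted(results, key=lambda r: r.window_index), windows):
            x_oracle = sum(1 for rank in range(a, b + 1) if ids[rank - 1] in members)
            assert r.x == x_oracle
            assert r.p_raw == pytest.approx(exact_binomial_upper_tail(x_oracle, w, K / N), rel=1e-9)

    def test_small_terms_excluded_by_eligibility(self):
        ids = [f"e{i}" for i in range(2000)]
        tm = rw.TermMap.from_pairs([(e, "small") for e in ids[:30]], "GO_BP")
        tm = tm.merged(rw.TermMap.from_pairs([(e, "big") for e in ids[:31]], "GO_BP"))
        results = rw.window_term_enrichment(simple_ranking(ids), tm)
        assert {r.term_id for r in results} == {"big"}

    def test_bonferroni_family_modes(self):
        ids = [f"e{i}" for i in range(2048)]
        tm = rw.TermMap.from_pairs(
            [(e, "A") for e in ids[:40]] + [(e, "B") for e in ids[40:80]], "GO_BP"
        )
        ranking = simple_ranking(ids)
        both = rw.window_term_enrichment(ranking, tm, family="terms_x_windows")
        per_term = rw.window_term_enrichment(ranking, tm, family="windows")
        n_windows = len(rw.make_windows(2048))
        for rb, rp in zip(both, per_term):
            assert rb.p_adj == pytest.approx(min(1.0, 2 * n_windows * rb.p_raw))
            assert rp.p_adj == pytest.approx(min(1.0, n_windows * rp.p_raw))

    def test_monotone_tail_in_x(self):
        tails = [binomial_upper_tail(x, 50, 0.2) for x in range(0, 51)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestTopK:
    def test_strong_photosynthesis_like_enrichment(self):
        """21 of the top 30 from a 36-member term in a 12,292 universe: ~239-fold."""
        N, K, k, x = 12292, 36, 30, 21
        ids = [f"e{i:05d}" for i in range(N)]
        members = set(ids[:x]) | set(ids[k : k + (K - x)])
        xx, fold, p = rw.top_k_term_enrichment(simple_ranking(ids), members, k)
        assert xx == x
        assert fold == pytest.approx((x / k) / (K / N))
        assert round(fold) == 239
        assert p < 1e-26

    def test_absent_term_closed_form(self):
        ids = [f"e{i}" for i in range(100)]
        members = set(ids[-10:])
        k = 20
        x, fold, p = rw.top_k_term_enrichment(simple_ranking(ids), members, k)
        assert x == 0 and fold == 0.0
        assert p == pytest.approx(1.0)  # P[X >= 0]

    def test_whole_universe_fold_is_one(self):
        ids = [f"e{i}" for i in range(50)]
        members = set(ids[::5])
        _, fold, _ = rw.top_k_term_enrichment(simple_ranking(ids), members, 50)
        assert fold == pytest.approx(1.0)


class TestSubsetEnrichment:
    def test_exact_membership_is_extreme(self):
        ids = [f"e{i}" for i in range(40)]
        tm = rw.TermMap.from_pairs([(e, "T") for e in ids[:8]], "KEGG_pathway")
        df = rw.subset_pathway_enrichment(set(ids[:8]), tm, set(ids))
        row = df.iloc[0]
        assert row["fold"] == pytest.approx(40 / 8)
        assert row["p_raw"] == pytest.approx(1 / math.comb(40, 8), rel=1e-9)

    def test_null_subsets_rarely_flagged(self):
        """Monte-Carlo calibration: random subsets on random annotations are
        flagged (Bonferroni, alpha 0.05) in at most ~5 % of simulations."""
        rng = np.random.default_rng(5)
        N = 600
        ids = [f"e{i}" for i in range(N)]
        n_flagged_sims = 0
        n_sims = 200
        policy = rw.EligibilityPolicy()
        for _ in range(n_sims):
            tm = rw.TermMap()
            for t in range(10):
                for e in rng.choice(ids, size=60, replace=False):
                    tm.add(f"T{t}", e, "KEGG_pathway")
            subset = set(rng.choice(ids, size=50, replace=False))
            df = rw.subset_pathway_enrichment(subset, tm, set(ids), policy=policy)
            n_flagged_sims += int(df["flagged"].any())
        assert n_flagged_sims / n_sims <= 0.05 + 0.02

    def test_keyword_subset_equals_manual_grep(self):
        desc = pd.Series(
            {
                "a": "alcohol dehydrogenase",
                "b": "Dehydrogenase, unspecific",
                "c": "kinase",
                "d": None,
            }
        )
        subset = rw.keyword_subset(desc, "dehydrogenase")
        assert subset == {"a", "b"}

    def test_empty_subset_is_error(self):
        tm = rw.TermMap.from_pairs([("a", "T")], "EC")
        with pytest.raises(ValueError):
            rw.subset_pathway_enrichment(set(), tm, {"a"})


class TestFlaggedSetDistribution:
    def test_empty_flags_all_zero(self):
        ids = [f"e{i}" for i in range(2048)]
        flags = rw.DEFlagSet(up=frozenset(), down=frozenset())
        df = rw.flagged_set_window_distribution(flags, simple_ranking(ids))
        assert (df["up_count"] == 0).all() and (df["down_count"] == 0).all()

    def test_whole_universe_density_one(self):
        ids = [f"e{i}" for i in range(2048)]
        flags = rw.DEFlagSet(up=frozenset(ids), down=frozenset())
        df = rw.flagged_set_window_distribution(flags, simple_ranking(ids))
        assert np.allclose(df["up_density_ratio"], 1.0)

    def test_bottom_planted_flags_concentrate_in_bottom_windows(self):
        ids = [f"e{i:04d}" for i in range(4096)]
        flags = rw.DEFlagSet(up=frozenset(ids[-300:]), down=frozenset())
        df = rw.flagged_set_window_distribution(flags, simple_ranking(ids))
        assert df["up_density_ratio"].iloc[-1] > 2
        assert df["up_density_ratio"].iloc[0] == 0.0
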