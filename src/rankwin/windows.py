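"""Sliding-window enrichment of term-annotated ESTs along a ranking.

The statistic: slide a window of ``w`` consecutive ranks (default 1,024) in
steps of ``s`` ranks (default 512) along the ordered EST universe. For each
annotated term with more than 30 members in the universe, count its members
``x`` inside each window and test the upper tail of Binomial(n=w, p=K/N),
where K is the term's universe membership and N the universe size — the term
members are "successes" and the window's ranks the "trials". A (term,
window) pair is flagged when the density fold (x/w)/(K/N) exceeds 2 and the
Bonferroni-adjusted p-value stays below 0.05.

The binomial (sampling with replacement) null is intentional, matching the
published analysis, and is slightly conservative relative to the
hypergeometric for enrichment at these K/N.

Also here: top-k enrichment of a single term among the highest ranks,
membership enrichment of an arbitrary EST subset across all terms
(hypergeometric), and the per-window distribution of differential-expression
flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DEFlagSet, Ranking
from .io import TermMap


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry in rank units: size ``w`` and step ``s``, with s <= w."""

    window_size: int = 1024
    step: int = 512

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.step < 1:
            raise ValueError("window_size and step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size (windows would skip ranks)")


@dataclass(frozen=True)
class EligibilityPolicy:
    """Which terms are tested and when a (term, window) pair is flagged."""

    min_term_size_exclusive: int = 30
    fold_min: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_term_size_exclusive < 0 or self.fold_min <= 0 or not 0 < self.alpha <= 1:
            raise ValueError("invalid eligibility policy")


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one term in one window of the ranking."""

    term_id: str
    window_index: int          # 1-based
    window_start_rank: int     # 1-based, inclusive
    x: int                     # term members inside the window
    n: int                     # window size (trials)
    K: int                     # term members in the universe
    N: int                     # universe size
    fold: float                # (x/n) / (K/N)
    p_raw: float
    p_adj: float
    flagged: bool


def make_windows(N: int, spec: WindowSpec = WindowSpec()) -> list[tuple[int, int]]:
    """Closed 1-based rank intervals [start, start + w - 1].

    Windows start at ranks 1, 1+s, 1+2s, ... and only full-size windows are
    produced: floor((N - w)/s) + 1 of them, leaving any trailing remainder of
    fewer than w ranks uncovered.
    """
    w, s = spec.window_size, spec.step
    if N < w:
        raise ValueError(f"universe size {N} smaller than window size {w}")
    n_windows = (N - w) // s + 1
    return [(1 + i * s, i * s + w) for i in range(n_windows)]


def bonferroni_adjust(p_raw: float | np.ndarray, m: int) -> float | np.ndarray:
    """Family-wise error control: p_adj = min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return np.minimum(1.0, m * np.asarray(p_raw, dtype=float)) if np.ndim(p_raw) else min(
        1.0, m * float(p_raw)
    )


def binomial_upper_tail(x: int, n: int, p0: float) -> float:
    """P[X >= x] for X ~ Binomial(n, p0)."""
    return float(stats.binom.sf(x - 1, n, p0))


def _window_counts(member_ranks: np.ndarray, windows: list[tuple[int, int]]) -> np.ndarray:
    """Members per window from sorted 1-based member ranks."""
    starts = np.array([w[0] for w in windows])
    ends = np.array([w[1] for w in windows])
    lo = np.searchsorted(member_ranks, starts, side="left")
    hi = np.searchsorted(member_ranks, ends, side="right")
    return hi - lo


def window_term_enrichment(
    ranking: Ranking,
    terms: TermMap,
    spec: WindowSpec = WindowSpec(),
    policy: EligibilityPolicy = EligibilityPolicy(),
    family: str = "terms_x_windows",
) -> list[EnrichmentResult]:
    """Binomial enrichment of every eligible term in every window.

    Terms are restricted to the ranked universe; only terms with more than
    ``min_term_size_exclusive`` members there are tested. The Bonferroni
    family is ``terms_x_windows`` (default: eligible terms times windows) or
    ``windows`` (per-term correction over windows only).
    """
    if family not in ("terms_x_windows", "windows"):
        raise ValueError("family must be 'terms_x_windows' or 'windows'")
    N = len(ranking)
    windows = make_windows(N, spec)
    restricted = terms.restricted(ranking.est_ids)
    eligible = [
        t for t in restricted if len(restricted.members(t)) > policy.min_term_size_exclusive
    ]
    m = len(eligible) * len(windows) if family == "terms_x_windows" else len(windows)
    rank_of = ranking.rank_of()
    results: list[EnrichmentResult] = []
    for term in eligible:
        members = restricted.members(term)
        K = len(members)
        p0 = K / N
        member_ranks = np.sort([rank_of[e] for e in members])
        xs = _window_counts(member_ranks, windows)
        for wi, ((start, _end), x) in enumerate(zip(windows, xs), start=1):
            x = int(x)
            p_raw = binomial_upper_tail(x, spec.window_size, p0)
            p_adj = float(bonferroni_adjust(p_raw, m))
            fold = (x / spec.window_size) / p0
            results.append(
                EnrichmentResult(
                    term_id=term,
                    window_index=wi,
                    window_start_rank=start,
                    x=x,
                    n=spec.window_size,
                    K=K,
                    N=N,
                    fold=fold,
                    p_raw=p_raw,
                    p_adj=p_adj,
                    flagged=(fold > policy.fold_min) and (p_adj < policy.alpha),
                )
            )
    return results


def enrichment_frame(results: list[EnrichmentResult], terms: TermMap | None = None) -> pd.DataFrame:
    """Long-form table of enrichment results, one row per (term, window)."""
    df = pd.DataFrame([r.__dict__ for r in results])
    if terms is not None and len(df):
        df.insert(1, "namespace", [terms.namespace(t) for t in df["term_id"]])
    return df


def density_matrix(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Terms x windows matrix of density folds (heatmap-shaped output)."""
    df = pd.DataFrame([(r.term_id, r.window_index, r.fold) for r in results],
                      columns=["term_id", "window_index", "fold"])
    return df.pivot(index="term_id", columns="window_index", values="fold")


def top_k_term_enrichment(
    ranking: Ranking, members: frozenset[str] | set[str], k: int
) -> tuple[int, float, float]:
    """Enrichment of one term among the top-k ranks: (x, fold, p_raw).

    fold = (x/k)/(K/N) with K the term's membership in the ranked universe;
    p_raw is the Binomial(k, K/N) upper tail at x.
    """
    N = len(ranking)
    if not 1 <= k <= N:
        raise ValueError(f"k must be in [1, {N}]")
    universe = set(ranking.est_ids)
    members = set(members) & universe
    if not members:
        raise ValueError("term has no members in the ranked universe")
    K = len(members)
    x = sum(1 for e in ranking.est_ids[:k] if e in members)
    p0 = K / N
    fold = (x / k) / p0
    return x, fold, binomial_upper_tail(x, k, p0)


def subset_pathway_enrichment(
    subset: set[str] | frozenset[str],
    terms: TermMap,
    universe: set[str] | frozenset[str],
    policy: EligibilityPolicy | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of *subset* within each term.

    For every term (restricted to *universe*) the 2x2 overlap of subset
    membership against term membership is tested one-sided: with N the
    universe size, K the term size, n the subset size and k the overlap,
    p = P[X >= k], X ~ Hypergeometric(N, K, n). fold = observed/expected
    = (k/n)/(K/N). Bonferroni over the number of terms tested.
    """
    subset = set(subset)
    universe = set(universe)
    if not subset:
        raise ValueError("empty subset")
    if not subset <= universe:
        raise ValueError("subset must be contained in the universe")
    restricted = terms.restricted(universe)
    N, n = len(universe), len(subset)
    rows = []
    m = len(restricted)
    for term in restricted:
        members = restricted.members(term)
        K = len(members)
        k = len(subset & members)
        expected = n * K / N
        fold = (k / expected) if expected > 0 else np.nan
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "namespace": restricted.namespace(term),
                "overlap": k,
                "term_size": K,
                "subset_size": n,
                "universe_size": N,
                "fold": fold,
                "p_raw": p_raw,
                "p_adj": float(bonferroni_adjust(p_raw, max(m, 1))),
            }
        )
    df = pd.DataFrame(rows)
    if policy is not None and len(df):
        df["flagged"] = (df["fold"] > policy.fold_min) & (df["p_adj"] < policy.alpha)
    return df


def keyword_subset(descriptions: pd.Series, keyword: str) -> frozenset[str]:
    """EST ids whose free-text description contains *keyword* (case-insensitive)."""
    mask = descriptions.fillna("").str.contains(keyword, case=False, regex=False)
    return frozenset(descriptions.index[mask])


def flagged_set_window_distribution(
    flags: DEFlagSet, ranking: Ranking, spec: WindowSpec = WindowSpec()
) -> pd.DataFrame:
    """Per-window counts and density ratios of up- and down-regulated ESTs.

    The density ratio for a set is (count in window / window size) divided by
    (set size / universe size); it answers where along the ranking the
    differentially expressed ESTs sit (e.g. whether up-regulated ESTs were
    low-abundance before the treatment).
    """
    N = len(ranking)
    windows = make_windows(N, spec)
    rank_of = ranking.rank_of()
    universe = set(ranking.est_ids)
    out: dict[str, np.ndarray] = {}
    for name, ids in (("up", flags.up), ("down", flags.down)):
        ids = set(ids) & universe
        ranks = np.sort([rank_of[e] for e in ids]) if ids else np.array([], dtype=int)
        counts = _window_counts(ranks, windows)
        out[f"{name}_count"] = counts
        if ids:
            background = len(ids) / N
            out[f"{name}_density_ratio"] = (counts / spec.window_size) / background
        else:
            out[f"{name}_density_ratio"] = np.zeros(len(windows))
    df = pd.DataFrame(out)
    df.insert(0, "window_index", np.arange(1, len(windows) + 1))
    df.insert(1, "window_start_rank", [w[0] for w in windows])
    return df
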