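"""FPKM normalisation, replicate averaging, expression ratios and rankings.

Expression values are carried as an :class:`ExpressionMatrix`: an EST x
sample FPKM table plus per-condition means, the nitrogen-depleted /
nitrogen-replete ratio and its log2 (the ``logFC`` of differential-expression
tables). Rankings order ESTs either by absolute level in nitrogen-replete
(log-phase) cells or by the depletion/control ratio; both orderings feed the
sliding-window enrichment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import N_DEPLETED, N_REPLETE, AnnotatedESTTable


class RankMode(str, Enum):
    """How ESTs are ordered: by expression level or by depletion/control ratio."""

    by_level = "by_level"
    by_ratio = "by_ratio"


@dataclass
class ExpressionMatrix:
    """FPKM per sample plus condition means and the -N/+N ratio per EST."""

    fpkm: pd.DataFrame                      # EST x sample
    condition_means: pd.DataFrame           # EST x condition
    ratio: pd.Series | None = None          # N_depleted mean / N_replete mean
    log_fc: pd.Series | None = None         # log2(ratio)

    @property
    def est_ids(self) -> list[str]:
        return list(self.fpkm.index)


@dataclass(frozen=True)
class Ranking:
    """Descending ordering of ESTs; rank 1 is the highest key."""

    mode: RankMode
    est_ids: tuple[str, ...]
    keys: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.est_ids) != len(self.keys):
            raise ValueError("est_ids and keys length mismatch")

    def rank_of(self) -> dict[str, int]:
        """Map est_id -> 1-based rank."""
        return {e: i + 1 for i, e in enumerate(self.est_ids)}

    def __len__(self) -> int:
        return len(self.est_ids)


@dataclass
class DEFlagSet:
    """Up/down differential-expression calls under fold-change and p cutoffs."""

    up: frozenset[str]
    down: frozenset[str]
    fold_change_min: float = 2.0
    p_max: float = 0.05
    p_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("an EST cannot be both up- and down-regulated")


def compute_fpkm(
    counts: pd.DataFrame, lengths_bp: pd.Series, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """FPKM[i, s] = counts[i, s] / (length_i / 1e3) / (library_size_s / 1e6).

    ``library_sizes`` defaults to the per-sample column sums of *counts*
    (total mapped fragments).
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        bad = list(library_sizes.index[library_sizes <= 0])
        raise ValueError(f"non-positive library size for samples {bad}")
    lengths_bp = lengths_bp.reindex(counts.index)
    if (lengths_bp < 1).any():
        raise ValueError("all lengths must be >= 1 bp")
    kb = lengths_bp.to_numpy(dtype=float) / 1e3
    millions = library_sizes.to_numpy(dtype=float) / 1e6
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / kb[:, None] / millions[None, :],
        index=counts.index,
        columns=counts.columns,
    )


def average_replicates(
    fpkm: pd.DataFrame, sample_design: Mapping[str, tuple[str, int]]
) -> pd.DataFrame:
    """Arithmetic mean of replicate columns, one output column per condition."""
    by_cond: dict[str, list[str]] = {}
    for sid, (cond, _rep) in sample_design.items():
        if sid in fpkm.columns:
            by_cond.setdefault(cond, []).append(sid)
    if not by_cond:
        raise ValueError("no sample in the design matches the matrix columns")
    return pd.DataFrame({c: fpkm[cols].mean(axis=1) for c, cols in by_cond.items()})


def compute_ratio(condition_means: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Depleted/replete ratio and its log2 per EST.

    Both condition means must be strictly positive: ESTs with a zero FPKM are
    expected to have been removed by the upstream filter.
    """
    for cond in (N_REPLETE, N_DEPLETED):
        if cond not in condition_means.columns:
            raise ValueError(f"condition_means lacks {cond!r} column")
        if (condition_means[cond] <= 0).any():
            raise ValueError(
                f"non-positive {cond} mean encountered; zero-FPKM ESTs must be filtered first"
            )
    ratio = condition_means[N_DEPLETED] / condition_means[N_REPLETE]
    return ratio.rename("ratio"), np.log2(ratio).rename("log_fc")


def expression_matrix(table: AnnotatedESTTable, fpkm: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Assemble the full expression view of a filtered table.

    Uses the table's stored FPKM values when present, otherwise computes FPKM
    from counts with library sizes equal to the per-sample count totals.
    """
    if fpkm is None:
        stored = table.fpkm_frame()
        if stored.notna().all().all() and any(r.fpkm for r in table.records):
            fpkm = stored
        else:
            fpkm = compute_fpkm(table.counts_frame(), table.lengths())
    cond_means = average_replicates(fpkm, table.sample_design)
    ratio, log_fc = compute_ratio(cond_means)
    return ExpressionMatrix(fpkm=fpkm, condition_means=cond_means, ratio=ratio, log_fc=log_fc)


def rank_ests(matrix: ExpressionMatrix, mode: RankMode | str = RankMode.by_level) -> Ranking:
    """Order ESTs descending by the mode's key; ties break lexicographically.

    ``by_level`` keys on the nitrogen-replete condition mean (log-phase
    abundance); ``by_ratio`` keys on the depleted/replete ratio.
    """
    mode = RankMode(mode)
    if mode is RankMode.by_level:
        key = matrix.condition_means[N_REPLETE]
    else:
        if matrix.ratio is None:
            raise ValueError("matrix has no ratio; build it via expression_matrix()")
        key = matrix.ratio
    # mergesort is stable; pre-sorting the index lexicographically makes the
    # tie-break deterministic by est_id
    df = pd.DataFrame({"key": key.loc[sorted(key.index)]}).sort_values(
        by="key", ascending=False, kind="mergesort"
    )
    return Ranking(
        mode=mode,
        est_ids=tuple(df.index),
        keys=tuple(float(v) for v in df["key"]),
    )


def binomial_de_pvalues(
    counts: pd.DataFrame, sample_design: Mapping[str, tuple[str, int]]
) -> pd.Series:
    """Per-EST two-sided binomial test of the depleted count proportion.

    Pools counts across replicates within each condition and tests whether
    the depleted share of each EST's total deviates from the library-size
    share, i.e. X ~ Binomial(n_i, p0) with n_i the EST's pooled total and
    p0 the depleted fraction of all mapped fragments. A simple sequencing-
    noise null: no replicate-level dispersion is modelled.
    """
    dep = [s for s, (c, _) in sample_design.items() if c == N_DEPLETED and s in counts.columns]
    rep = [s for s, (c, _) in sample_design.items() if c == N_REPLETE and s in counts.columns]
    if not dep or not rep:
        raise ValueError("need samples in both conditions")
    x_dep = counts[dep].sum(axis=1).to_numpy(dtype=np.int64)
    x_rep = counts[rep].sum(axis=1).to_numpy(dtype=np.int64)
    total = x_dep + x_rep
    p0 = counts[dep].to_numpy().sum() / counts.to_numpy().sum()
    pvals = np.ones(len(counts), dtype=float)
    for i in range(len(counts)):
        if total[i] > 0:
            pvals[i] = stats.binomtest(int(x_dep[i]), int(total[i]), p0).pvalue
    return pd.Series(pvals, index=counts.index, name="p_value")


def apply_de_thresholds(
    log_fc: pd.Series,
    p_values: pd.Series,
    fold_change_min: float = 2.0,
    p_max: float = 0.05,
) -> DEFlagSet:
    """Call up/down ESTs with |fold change| > threshold and p below cutoff.

    ESTs missing a p-value are excluded from both sets.
    """
    if ((p_values < 0) | (p_values > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    lf_thresh = np.log2(fold_change_min)
    joined = pd.DataFrame({"log_fc": log_fc, "p": p_values}).dropna()
    up = joined.index[(joined["log_fc"] > lf_thresh) & (joined["p"] < p_max)]
    down = joined.index[(joined["log_fc"] < -lf_thresh) & (joined["p"] < p_max)]
    return DEFlagSet(
        up=frozenset(up),
        down=frozenset(down),
        fold_change_min=fold_change_min,
        p_max=p_max,
        p_values=dict(joined["p"]),
    )
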