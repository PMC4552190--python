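"""Synthetic annotated EST tables with known ground truth.

The generator emulates the statistical shape of a two-condition (nitrogen
replete / depleted), two-replicate annotated de novo transcriptome survey:

* ~12,292 annotated ESTs with log-normal lengths (median ~663 bp, truncated
  to 301-8,268 bp) and heavy-tailed negative-binomial read counts (median
  total ~174, floored at 42, no zero in any sample so the standard filter
  keeps every generated EST);
* library sizes of ~27 million mapped fragments per sample, so FPKM is
  computed from counts exactly as for real data;
* a catalog of GO/KEGG-like terms assigned uniformly at random, except for
  *planted* terms whose members are concentrated at a chosen density
  multiplier inside chosen rank windows of the realised ranking;
* differentially expressed ESTs with chosen log2 fold changes, up-regulated
  ones placed among low-abundance ESTs and down-regulated ones among
  high-abundance ESTs.

Everything is deterministic given the seed, and the ground truth (planted
windows, achieved densities, true DE labels) is returned alongside the
table so detectors can be validated without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import RankMode, expression_matrix, rank_ests
from .io import (
    N_DEPLETED,
    N_REPLETE,
    AnnotatedESTTable,
    ESTRecord,
    TermMap,
    read_est_table,
    write_est_table,
    write_term_map,
)
from .phenotype import GrowthSeries
from .windows import WindowSpec, make_windows

DEFAULT_SAMPLE_DESIGN: dict[str, tuple[str, int]] = {
    "NR_1": (N_REPLETE, 1),
    "NR_2": (N_REPLETE, 2),
    "ND_1": (N_DEPLETED, 1),
    "ND_2": (N_DEPLETED, 2),
}


@dataclass(frozen=True)
class PlantedTerm:
    """A term whose members are concentrated in target windows of a ranking."""

    term_id: str
    size: int = 60
    namespace: str = "GO_BP"
    mode: RankMode = RankMode.by_level
    windows: tuple[int, ...] = (1,)
    density_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.density_multiplier < 1:
            raise ValueError("density multiplier must be >= 1")
        if self.size < 1:
            raise ValueError("term size must be positive")


@dataclass(frozen=True)
class DEStructure:
    """Fractions, effect sizes and rank placement of true DE ESTs.

    Up-regulated ESTs are drawn from the low-abundance portion of the
    baseline level distribution and down-regulated ones from the
    high-abundance portion, mirroring where DE calls concentrate in ranked
    transcriptomes of nitrogen-starved cells. Default fractions reproduce a
    ~593-up / ~116-down split at the default universe size.
    """

    frac_up: float = 593 / 12292
    frac_down: float = 116 / 12292
    lfc_min: float = 1.5
    lfc_mean_excess: float = 1.5      # |logFC| ~ lfc_min + Exponential(mean)
    up_quantile_range: tuple[float, float] = (0.45, 1.0)    # low-abundance ranks
    down_quantile_range: tuple[float, float] = (0.0, 0.2)   # high-abundance ranks


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults mirror the surveyed transcriptome's printed summary statistics."""

    n_ests: int = 12292
    length_median_bp: float = 663.0
    length_sigma: float = 0.55
    length_range_bp: tuple[int, int] = (301, 8268)
    count_total_median: float = 174.0
    count_total_floor: int = 42
    count_sigma: float = 1.6          # lognormal spread of per-EST baseline means
    nb_dispersion: float = 20.0       # NB size parameter; larger = closer to Poisson
    library_size: float = 27e6
    sample_design: tuple[tuple[str, tuple[str, int]], ...] = tuple(DEFAULT_SAMPLE_DESIGN.items())
    n_go_bp_terms: int = 44
    n_kegg_terms: int = 59
    term_size_range: tuple[int, int] = (31, 400)
    window_spec: WindowSpec = WindowSpec()
    planted_terms: tuple[PlantedTerm, ...] = ()
    de_structure: DEStructure | None = DEStructure()
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Ground truth of one generated table."""

    planted: dict[str, dict]                 # term_id -> {windows, multiplier, achieved}
    de_up: frozenset[str]
    de_down: frozenset[str]
    true_log_fc: dict[str, float]
    seed: int

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "planted": self.planted,
            "de_up": sorted(self.de_up),
            "de_down": sorted(self.de_down),
            "true_log_fc": self.true_log_fc,
        }


def _truncated_lognormal(
    rng: np.random.Generator, n: int, median: float, sigma: float, lo: float, hi: float
) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = median * np.exp(sigma * rng.standard_normal(n - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    return out


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate_table(config: GeneratorConfig = GeneratorConfig()) -> tuple[AnnotatedESTTable, SyntheticTruth]:
    """Generate an annotated expression table plus its ground truth.

    Raises before sampling if a planted term cannot fit its target windows
    at the requested density (multiplier x window share exceeding either the
    window capacity or the term size).
    """
    rng = np.random.default_rng(config.seed)
    design = dict(config.sample_design)
    samples = list(design)
    n = config.n_ests
    w = config.window_spec.window_size
    windows = make_windows(n, config.window_spec) if config.planted_terms else []

    # feasibility of planting, checked before any sampling
    for pt in config.planted_terms:
        per_window = _planted_per_window(pt, n, w)
        if per_window * len(pt.windows) > pt.size:
            raise ValueError(
                f"planted term {pt.term_id}: {per_window} members x {len(pt.windows)} windows "
                f"exceeds term size {pt.size}"
            )
        if per_window > w:
            raise ValueError(f"planted term {pt.term_id}: density exceeds window capacity")
        for wi in pt.windows:
            if not 1 <= wi <= len(windows):
                raise ValueError(f"planted term {pt.term_id}: window {wi} out of range")

    est_ids = [f"est{i:06d}" for i in range(n)]
    lengths = np.round(
        _truncated_lognormal(
            rng, n, config.length_median_bp, config.length_sigma, *config.length_range_bp
        )
    ).astype(int)

    # baseline per-sample mean counts; median chosen so the 4-sample total
    # count matches the configured median
    base_mean = (config.count_total_median / len(samples)) * np.exp(
        config.count_sigma * rng.standard_normal(n)
    )

    # true DE effects applied to the depleted condition's means
    de = config.de_structure
    up_ids: set[str] = set()
    down_ids: set[str] = set()
    lfc = np.zeros(n)
    if de is not None:
        order = np.argsort(-base_mean, kind="stable")  # high abundance first
        n_up = int(round(de.frac_up * n))
        n_down = int(round(de.frac_down * n))
        lo_u, hi_u = (int(q * n) for q in de.up_quantile_range)
        lo_d, hi_d = (int(q * n) for q in de.down_quantile_range)
        up_pool = order[lo_u:hi_u]
        down_pool = order[lo_d:hi_d]
        up_idx = rng.choice(up_pool, size=min(n_up, len(up_pool)), replace=False)
        remaining = np.setdiff1d(down_pool, up_idx, assume_unique=False)
        down_idx = rng.choice(remaining, size=min(n_down, len(remaining)), replace=False)
        lfc[up_idx] = de.lfc_min + rng.exponential(de.lfc_mean_excess, size=len(up_idx))
        lfc[down_idx] = -(de.lfc_min + rng.exponential(de.lfc_mean_excess, size=len(down_idx)))
        up_ids = {est_ids[i] for i in up_idx}
        down_ids = {est_ids[i] for i in down_idx}

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        cond = design[sid][0]
        mu = base_mean * (2.0 ** lfc) if cond == N_DEPLETED else base_mean
        counts[:, j] = _nb_sample(rng, mu, config.nb_dispersion)

    # enforce the total-count floor (resample low ESTs at doubled mean) and
    # strictly positive per-sample counts so the standard filter keeps all
    for _ in range(60):
        low = counts.sum(axis=1) < config.count_total_floor
        if not low.any():
            break
        base_mean[low] *= 2.0
        for j, sid in enumerate(samples):
            cond = design[sid][0]
            mu = base_mean[low] * (2.0 ** lfc[low]) if cond == N_DEPLETED else base_mean[low]
            counts[low, j] = _nb_sample(rng, mu, config.nb_dispersion)
    counts = np.maximum(counts, 1)

    records = [
        ESTRecord(
            est_id=est_ids[i],
            length_bp=int(lengths[i]),
            counts={s: int(counts[i, j]) for j, s in enumerate(samples)},
        )
        for i in range(n)
    ]
    table = AnnotatedESTTable(records, design)

    # FPKM from counts against the configured library sizes, stored on records
    from .expression import compute_fpkm  # local import to avoid cycle at module load

    lib = pd.Series(config.library_size, index=samples, dtype=float)
    fpkm = compute_fpkm(table.counts_frame(), table.lengths(), lib)
    records = [
        ESTRecord(
            est_id=r.est_id,
            length_bp=r.length_bp,
            counts=r.counts,
            fpkm={s: float(fpkm.iloc[i][s]) for s in samples},
        )
        for i, r in enumerate(records)
    ]
    table = AnnotatedESTTable(records, design)

    # realised rankings, then term planting in rank space
    matrix = expression_matrix(table)
    rankings = {
        RankMode.by_level: rank_ests(matrix, RankMode.by_level),
        RankMode.by_ratio: rank_ests(matrix, RankMode.by_ratio),
    }

    tm = TermMap()
    planted_info: dict[str, dict] = {}
    for pt in config.planted_terms:
        ranking = rankings[pt.mode]
        per_window = _planted_per_window(pt, n, w)
        member_ranks: list[int] = []
        covered: set[int] = set()
        for wi in pt.windows:
            start, end = windows[wi - 1]
            in_window = rng.choice(np.arange(start, end + 1), size=per_window, replace=False)
            member_ranks.extend(int(r) for r in in_window)
            covered.update(range(start, end + 1))
        outside = np.array(sorted(set(range(1, n + 1)) - covered - set(member_ranks)))
        n_rest = pt.size - len(member_ranks)
        if n_rest > 0:
            member_ranks.extend(int(r) for r in rng.choice(outside, size=n_rest, replace=False))
        for r in member_ranks:
            tm.add(pt.term_id, ranking.est_ids[r - 1], pt.namespace)
        achieved = {
            str(wi): (per_window / w) / (pt.size / n) for wi in pt.windows
        }
        planted_info[pt.term_id] = {
            "mode": pt.mode.value,
            "windows": list(pt.windows),
            "target_multiplier": pt.density_multiplier,
            "achieved_multiplier": achieved,
            "size": pt.size,
        }

    # background terms: uniform random membership
    catalog = [("GO_BP", f"GO:{7000000 + i}", i) for i in range(config.n_go_bp_terms)]
    catalog += [("KEGG_pathway", f"ko{10000 + i}", i) for i in range(config.n_kegg_terms)]
    lo_t, hi_t = config.term_size_range
    for ns, term_id, _ in catalog:
        size = int(rng.integers(lo_t, hi_t + 1))
        for i in rng.choice(n, size=size, replace=False):
            tm.add(term_id, est_ids[i], ns)

    table = table.with_annotations(tm)
    truth = SyntheticTruth(
        planted=planted_info,
        de_up=frozenset(up_ids),
        de_down=frozenset(down_ids),
        true_log_fc={est_ids[i]: float(lfc[i]) for i in range(n) if lfc[i] != 0.0},
        seed=config.seed,
    )
    return table, truth


def _planted_per_window(pt: PlantedTerm, n: int, w: int) -> int:
    """Members to place in each target window: multiplier x the uniform share."""
    return int(round(pt.density_multiplier * pt.size * w / n))


def generate_growth_series(
    template_days: np.ndarray,
    template_cdw: np.ndarray,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrowthSeries:
    """Replicate CDW trajectories around a template curve.

    Multiplicative log-normal measurement noise with the given relative SD;
    ``noise_sd = 0`` reproduces the template exactly in every replicate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    template_cdw = np.asarray(template_cdw, dtype=float)
    reps = np.tile(template_cdw, (n_replicates, 1))
    if noise_sd > 0:
        reps = reps * np.exp(noise_sd * rng.standard_normal(reps.shape))
    return GrowthSeries(timepoints_days=np.asarray(template_days, dtype=float), cdw=reps)


def export_fixture(table: AnnotatedESTTable, truth: SyntheticTruth, directory) -> dict[str, Path]:
    """Write the table, term maps, sample design and truth JSON to *directory*.

    Files use the TSV dialects of :mod:`rankwin.io`; re-reading reproduces
    the table exactly. Returns the written paths keyed by role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    est_path = directory / "est_table.tsv"
    write_est_table(table, est_path)
    paths["est_table"] = est_path

    by_ns: dict[str, TermMap] = {}
    for term in table.annotations:
        ns = table.annotations.namespace(term)
        sub = by_ns.setdefault(ns, TermMap())
        for est in table.annotations.members(term):
            sub.add(term, est, ns)
    for ns, sub in sorted(by_ns.items()):
        p = directory / f"terms_{ns}.tsv"
        write_term_map(sub, p)
        paths[f"terms_{ns}"] = p

    design_path = directory / "sample_design.json"
    design_path.write_text(
        json.dumps({s: list(v) for s, v in table.sample_design.items()}, indent=1)
    )
    paths["sample_design"] = design_path

    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(truth.as_dict(), indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths


def load_fixture(directory) -> AnnotatedESTTable:
    """Re-read a fixture written by :func:`export_fixture`."""
    directory = Path(directory)
    design_raw = json.loads((directory / "sample_design.json").read_text())
    design = {s: (c, int(r)) for s, (c, r) in design_raw.items()}
    table = read_est_table(directory / "est_table.tsv", design)
    tm = TermMap()
    for p in sorted(directory.glob("terms_*.tsv")):
        ns = p.stem[len("terms_"):]
        from .io import read_term_map

        tm = tm.merged(read_term_map(p, ns))
    return table.with_annotations(tm)
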