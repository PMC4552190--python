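"""Domain types and tab-separated file I/O for annotated EST expression tables.

The central object is :class:`AnnotatedESTTable`: one row per assembled
non-redundant transcript contig (EST), with its length in base pairs,
per-sample read counts and/or FPKM values, optional best-hit annotation, and
a :class:`TermMap` tying ESTs to GO functions, KEGG pathways, EC numbers or
free-text keywords.

Filtering follows the quality rules used for de novo transcriptome surveys of
*Botryococcus braunii*: an EST is kept only if it is longer than 300 bp, has
more than 40 reads summed over all samples, and (optionally) has no sample
with an FPKM of exactly zero.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_REPLETE = "N_replete"
N_DEPLETED = "N_depleted"
CONDITIONS = (N_REPLETE, N_DEPLETED)

TERM_NAMESPACES = ("GO_BP", "GO_CC", "GO_MF", "KEGG_pathway", "EC", "keyword")


class FormatError(ValueError):
    """A mandatory column is missing or a row cannot be parsed."""


@dataclass(frozen=True)
class ESTRecord:
    """One assembled transcript contig with expression and annotation."""

    est_id: str
    length_bp: int
    counts: Mapping[str, int] = field(default_factory=dict)
    fpkm: Mapping[str, float] = field(default_factory=dict)
    best_hit_id: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"EST {self.est_id}: length_bp must be >= 1, got {self.length_bp}")
        if self.counts and self.fpkm and set(self.counts) != set(self.fpkm):
            raise ValueError(f"EST {self.est_id}: counts and fpkm sample ids differ")
        for s, v in self.counts.items():
            if v < 0:
                raise ValueError(f"EST {self.est_id}: negative count in sample {s}")
        for s, v in self.fpkm.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"EST {self.est_id}: non-finite or negative FPKM in sample {s}")

    @property
    def total_count(self) -> int:
        return int(sum(self.counts.values()))


class TermMap:
    """Many-to-many mapping from term ids to sets of EST ids.

    Each term carries a namespace tag: GO_BP / GO_CC / GO_MF / KEGG_pathway /
    EC / keyword. Empty member sets are not stored.
    """

    def __init__(self) -> None:
        self._members: dict[str, set[str]] = {}
        self._namespace: dict[str, str] = {}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], namespace: str) -> "TermMap":
        tm = cls()
        for est_id, term_id in pairs:
            tm.add(term_id, est_id, namespace)
        return tm

    def add(self, term_id: str, est_id: str, namespace: str) -> None:
        if namespace not in TERM_NAMESPACES:
            raise ValueError(f"unknown term namespace {namespace!r}")
        prev = self._namespace.get(term_id)
        if prev is not None and prev != namespace:
            raise ValueError(f"term {term_id} already registered under namespace {prev}")
        self._members.setdefault(term_id, set()).add(est_id)
        self._namespace[term_id] = namespace

    def members(self, term_id: str) -> frozenset[str]:
        return frozenset(self._members[term_id])

    def namespace(self, term_id: str) -> str:
        return self._namespace[term_id]

    def terms(self, namespace: str | None = None) -> list[str]:
        if namespace is None:
            return sorted(self._members)
        return sorted(t for t in self._members if self._namespace[t] == namespace)

    def est_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self._members.values():
            out |= s
        return frozenset(out)

    def restricted(self, universe: Iterable[str]) -> "TermMap":
        """Return a copy with memberships intersected with *universe*; empty terms dropped."""
        uni = set(universe)
        tm = TermMap()
        for term, members in self._members.items():
            kept = members & uni
            if kept:
                tm._members[term] = kept
                tm._namespace[term] = self._namespace[term]
        return tm

    def merged(self, other: "TermMap") -> "TermMap":
        tm = TermMap()
        for src in (self, other):
            for term, members in src._members.items():
                for est in members:
                    tm.add(term, est, src._namespace[term])
        return tm

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._members

    def __iter__(self):
        return iter(sorted(self._members))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermMap):
            return NotImplemented
        return self._members == other._members and self._namespace == other._namespace


@dataclass(frozen=True)
class BlastHitRow:
    """One row of 12-column tabular sequence-similarity output."""

    query_id: str
    subject_id: str
    identity_pct: float = 100.0
    evalue: float = 0.0
    alignment_length: int = 0
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class FilterPolicy:
    """Inclusion rules for ESTs; thresholds are strict (> not >=)."""

    min_length_exclusive_bp: int = 300
    min_count_exclusive: int = 40
    drop_any_zero_fpkm: bool = True

    def __post_init__(self) -> None:
        if self.min_length_exclusive_bp < 0 or self.min_count_exclusive < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_short: int
    removed_low_count: int
    removed_zero_fpkm: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


class AnnotatedESTTable:
    """Ordered collection of ESTRecords plus sample design and term annotations.

    ``sample_design`` maps sample id -> (condition, replicate index), with
    condition one of ``N_replete`` / ``N_depleted``.
    """

    def __init__(
        self,
        records: Sequence[ESTRecord],
        sample_design: Mapping[str, tuple[str, int]],
        annotations: TermMap | None = None,
    ) -> None:
        ids = [r.est_id for r in records]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(f"duplicate est_ids: {list(dup[dup > 1].index[:5])}")
        for sid, (cond, _rep) in sample_design.items():
            if cond not in CONDITIONS:
                raise ValueError(f"sample {sid}: unknown condition {cond!r}")
        present = {c for c, _ in sample_design.values()}
        if sample_design and len(present) < 1:
            raise ValueError("at least one condition required")
        self.records: list[ESTRecord] = list(records)
        self.sample_design: dict[str, tuple[str, int]] = dict(sample_design)
        annotations = annotations if annotations is not None else TermMap()
        unknown = annotations.est_ids() - set(ids)
        if unknown:
            raise ValueError(f"annotations reference unknown est_ids, e.g. {sorted(unknown)[:5]}")
        self.annotations = annotations

    # -- container basics -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def est_ids(self) -> list[str]:
        return [r.est_id for r in self.records]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_design)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, (c, _) in self.sample_design.items() if c == condition]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedESTTable):
            return NotImplemented
        return (
            self.records == other.records
            and self.sample_design == other.sample_design
            and self.annotations == other.annotations
        )

    # -- matrix views ------------------------------------------------------
    def counts_frame(self) -> pd.DataFrame:
        data = {s: [r.counts.get(s, 0) for r in self.records] for s in self.sample_ids}
        return pd.DataFrame(data, index=self.est_ids, dtype=np.int64)

    def fpkm_frame(self) -> pd.DataFrame:
        data = {s: [r.fpkm.get(s, np.nan) for r in self.records] for s in self.sample_ids}
        return pd.DataFrame(data, index=self.est_ids, dtype=float)

    def lengths(self) -> pd.Series:
        return pd.Series([r.length_bp for r in self.records], index=self.est_ids, name="length_bp")

    def with_records(self, records: Sequence[ESTRecord]) -> "AnnotatedESTTable":
        kept = {r.est_id for r in records}
        return AnnotatedESTTable(
            records, self.sample_design, self.annotations.restricted(kept)
        )

    def with_annotations(self, annotations: TermMap) -> "AnnotatedESTTable":
        return AnnotatedESTTable(
            self.records, self.sample_design, annotations.restricted(self.est_ids)
        )


@dataclass
class OverlapSummary:
    n_queries: int
    n_homologous: int
    pct_homologous: float
    n_annotated_of_homologous: int
    pct_annotated_of_homologous: float
    warning: str | None = None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_est_table(path, sample_design: Mapping[str, tuple[str, int]]) -> AnnotatedESTTable:
    """Read a TSV expression table into an :class:`AnnotatedESTTable`.

    Expected columns: ``est_id``, ``length_bp``, ``count_<sample>`` for each
    sample, optional ``fpkm_<sample>``, ``best_hit_id``, ``description``.
    Lines starting with ``#`` are comments. Row order is preserved.
    """
    df = _read_tsv(path)
    for col in ("est_id", "length_bp"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    count_cols = {c[len("count_"):]: c for c in df.columns if c.startswith("count_")}
    fpkm_cols = {c[len("fpkm_"):]: c for c in df.columns if c.startswith("fpkm_")}
    if not count_cols and not fpkm_cols:
        raise FormatError("no count_<sample> or fpkm_<sample> columns found")
    for sid in sample_design:
        if sid not in count_cols and sid not in fpkm_cols:
            raise FormatError(f"no expression column for sample {sid!r}")

    records: list[ESTRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        row = row._asdict()
        try:
            length = int(row["length_bp"])
            counts = {s: int(row[c]) for s, c in count_cols.items()}
            fpkm = {s: float(row[c]) for s, c in fpkm_cols.items()}
        except (TypeError, ValueError) as exc:
            raise FormatError(f"line {i}: non-numeric value ({exc})") from exc
        try:
            records.append(
                ESTRecord(
                    est_id=row["est_id"],
                    length_bp=length,
                    counts=counts,
                    fpkm=fpkm,
                    best_hit_id=row.get("best_hit_id") or None,
                    description=row.get("description") or None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {i}: {exc}") from exc
    return AnnotatedESTTable(records, sample_design)


def write_est_table(table: AnnotatedESTTable, path) -> None:
    """Write the TSV dialect read by :func:`read_est_table` (lossless round-trip)."""
    samples = table.sample_ids
    cols: dict[str, list] = {
        "est_id": table.est_ids,
        "length_bp": [r.length_bp for r in table.records],
    }
    if any(r.counts for r in table.records):
        for s in samples:
            cols[f"count_{s}"] = [r.counts.get(s, 0) for r in table.records]
    if any(r.fpkm for r in table.records):
        for s in samples:
            cols[f"fpkm_{s}"] = [repr(float(r.fpkm.get(s, 0.0))) for r in table.records]
    cols["best_hit_id"] = [r.best_hit_id or "" for r in table.records]
    cols["description"] = [r.description or "" for r in table.records]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_term_map(path, namespace: str) -> TermMap:
    """Read a two-column (est_id, term_id) TSV into a TermMap; duplicates collapse."""
    df = _read_tsv(path)
    need = ("est_id", "term_id")
    for col in need:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    return TermMap.from_pairs(zip(df["est_id"], df["term_id"]), namespace)


def write_term_map(tm: TermMap, path) -> None:
    rows = [
        {"est_id": est, "term_id": term}
        for term in tm
        for est in sorted(tm.members(term))
    ]
    pd.DataFrame(rows, columns=["est_id", "term_id"]).to_csv(path, sep="\t", index=False)


def read_blast_hits(path) -> list[BlastHitRow]:
    """Parse 12-column tabular hit files (outfmt-6-like); extra columns kept opaque."""
    rows: list[BlastHitRow] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"line {i}: expected tab-separated hit row")
            ident = float(parts[2]) if len(parts) > 2 else 100.0
            aln = int(parts[3]) if len(parts) > 3 else 0
            evalue = float(parts[10]) if len(parts) > 10 else 0.0
            rows.append(
                BlastHitRow(
                    query_id=parts[0],
                    subject_id=parts[1],
                    identity_pct=ident,
                    evalue=evalue,
                    alignment_length=aln,
                    extra=tuple(parts[12:]),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_filter(
    table: AnnotatedESTTable, policy: FilterPolicy = FilterPolicy()
) -> tuple[AnnotatedESTTable, FilterReport]:
    """Apply the EST inclusion rules and report removals per rule.

    Retains ESTs with length strictly above the length threshold AND total
    read count (summed over samples) strictly above the count threshold AND,
    when ``drop_any_zero_fpkm``, no zero FPKM in any sample. Rules are
    evaluated in that order for reporting; an EST is charged to the first
    rule that rejects it.
    """
    removed_short = removed_low = removed_zero = 0
    kept: list[ESTRecord] = []
    for r in table.records:
        if r.length_bp <= policy.min_length_exclusive_bp:
            removed_short += 1
            continue
        if r.counts and r.total_count <= policy.min_count_exclusive:
            removed_low += 1
            continue
        if policy.drop_any_zero_fpkm and r.fpkm and any(v == 0.0 for v in r.fpkm.values()):
            removed_zero += 1
            continue
        kept.append(r)
    report = FilterReport(
        n_input=len(table),
        n_retained=len(kept),
        removed_short=removed_short,
        removed_low_count=removed_low,
        removed_zero_fpkm=removed_zero,
    )
    return table.with_records(kept), report


def homology_overlap_summary(
    hits: Iterable[BlastHitRow],
    query_ids: Iterable[str],
    evalue_cutoff: float,
    annotated_ids: Iterable[str],
) -> OverlapSummary:
    """Fraction of queries with at least one hit below the e-value cutoff,
    and the annotated fraction among those.

    A single qualifying hit makes a query "homologous". Percentages are on a
    0–100 scale. With zero homologous queries, the annotated fraction is 0
    by convention and a warning is set.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    queries = set(query_ids)
    if not queries:
        raise ValueError("empty query set: percentages undefined")
    annotated = set(annotated_ids)
    homologous = {h.query_id for h in hits if h.evalue < evalue_cutoff and h.query_id in queries}
    n_hom = len(homologous)
    n_ann = len(homologous & annotated)
    warning = None
    if n_hom == 0:
        pct_ann = 0.0
        warning = "no query has a hit below the cutoff; annotated fraction set to 0"
    else:
        pct_ann = 100.0 * n_ann / n_hom
    return OverlapSummary(
        n_queries=len(queries),
        n_homologous=n_hom,
        pct_homologous=100.0 * n_hom / len(queries),
        n_annotated_of_homologous=n_ann,
        pct_annotated_of_homologous=pct_ann,
        warning=warning,
    )
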