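"""Enzyme-level (EC-grouped) expression panels and panel-overlap significance.

Many enzymes are encoded by several non-redundant ESTs; summing the
condition-mean FPKM of every EST mapped to the same EC number gives an
enzyme-level ("summative") expression value that is robust to how the
assembler split transcripts. A panel is a curated EC list (e.g. the proposed
very-long-chain fatty-acid biosynthesis enzymes); the overlap between the
enzymes detected in two transcriptomes drawn from the same proposed list is
tested with the one-sided hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DEFlagSet, ExpressionMatrix
from .io import N_DEPLETED, N_REPLETE, AnnotatedESTTable, TermMap


@dataclass
class EnzymePanel:
    """EC-number -> member EST ids, restricted to a curated panel list."""

    panel_name: str
    enzymes: dict[str, frozenset[str]]
    panel_ec_list: frozenset[str] = field(default_factory=frozenset)

    @property
    def detected_ecs(self) -> frozenset[str]:
        return frozenset(self.enzymes)

    @property
    def n_detected(self) -> int:
        return len(self.enzymes)

    def copy_numbers(self) -> dict[str, int]:
        """Number of distinct ESTs encoding each detected enzyme."""
        return {ec: len(m) for ec, m in self.enzymes.items()}


@dataclass(frozen=True)
class PanelOverlap:
    """Overlap of two detected enzyme sets from a fixed proposed universe."""

    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_value: float


def group_by_enzyme(
    table: AnnotatedESTTable, ec_map: TermMap, panel_ec_list: set[str], panel_name: str = "panel"
) -> EnzymePanel:
    """Group the table's ESTs by EC number, restricted to the panel list.

    An EST mapped to several EC numbers contributes to each of them. Panel
    ECs with no mapped EST in the table are absent from the result (not
    detected).
    """
    if not panel_ec_list:
        raise ValueError("empty panel EC list")
    for ec in panel_ec_list:
        if ec in ec_map and ec_map.namespace(ec) != "EC":
            raise ValueError(f"term {ec} is not in the EC namespace")
    universe = set(table.est_ids)
    enzymes: dict[str, frozenset[str]] = {}
    for ec in sorted(panel_ec_list):
        if ec in ec_map:
            members = ec_map.members(ec) & universe
            if members:
                enzymes[ec] = frozenset(members)
    return EnzymePanel(panel_name=panel_name, enzymes=enzymes, panel_ec_list=frozenset(panel_ec_list))


def summative_levels_and_flags(
    panel: EnzymePanel, matrix: ExpressionMatrix, fold_min: float = 2.0
) -> pd.DataFrame:
    """Per-enzyme summed condition means, fold change, and >fold_min flags.

    The summative level is the sum of member ESTs' condition-mean FPKM. An
    enzyme is flagged when the larger of the two direction ratios exceeds
    ``fold_min``; direction is 'up' when the depleted sum is the larger one.
    Enzymes with a zero sum in either condition get an undefined ratio and
    are never flagged.
    """
    rows = []
    for ec in sorted(panel.enzymes):
        members = sorted(panel.enzymes[ec])
        missing = [m for m in members if m not in matrix.condition_means.index]
        if missing:
            raise ValueError(f"enzyme {ec}: member ESTs absent from matrix, e.g. {missing[:3]}")
        sums = matrix.condition_means.loc[members].sum(axis=0)
        s_rep, s_dep = float(sums[N_REPLETE]), float(sums[N_DEPLETED])
        if s_rep > 0 and s_dep > 0:
            ratio = s_dep / s_rep
            flag = max(ratio, 1.0 / ratio) > fold_min
            direction = "up" if (flag and ratio > 1) else ("down" if flag else "")
        else:
            ratio, flag, direction = np.nan, False, ""
        rows.append(
            {
                "ec_number": ec,
                "n_ests": len(members),
                "sum_fpkm_n_replete": s_rep,
                "sum_fpkm_n_depleted": s_dep,
                "ratio": ratio,
                "flagged": flag,
                "direction": direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ec_number", "n_ests", "sum_fpkm_n_replete", "sum_fpkm_n_depleted",
            "ratio", "flagged", "direction",
        ],
    )


def panel_overlap_test(universe_size: int, a: int, b: int, k: int) -> PanelOverlap:
    """P[X >= k] for X ~ Hypergeometric(universe_size, b, a), by exact summation.

    Models drawing the ``a`` enzymes detected in one transcriptome from the
    proposed universe and asking how many land in the ``b`` detected in the
    other.
    """
    if a > universe_size or b > universe_size:
        raise ValueError("set sizes cannot exceed the universe")
    if k > min(a, b):
        raise ValueError(f"overlap {k} impossible for sets of {a} and {b}")
    if k < max(0, a + b - universe_size):
        raise ValueError("overlap below the forced minimum is impossible")
    p = float(stats.hypergeom.sf(k - 1, universe_size, b, a))
    return PanelOverlap(universe_size=universe_size, set_a_size=a, set_b_size=b, overlap=k, p_value=p)


def per_est_panel_report(
    panel: EnzymePanel, matrix: ExpressionMatrix, flags: DEFlagSet | None = None
) -> pd.DataFrame:
    """Long-form table: one row per (enzyme, member EST) with levels and DE marks."""
    rows = []
    for ec in sorted(panel.enzymes):
        for est in sorted(panel.enzymes[ec]):
            fr = float(matrix.condition_means.loc[est, N_REPLETE])
            fd = float(matrix.condition_means.loc[est, N_DEPLETED])
            de = ""
            if flags is not None:
                de = "up" if est in flags.up else ("down" if est in flags.down else "")
            rows.append(
                {
                    "ec_number": ec,
                    "est_id": est,
                    "fpkm_n_replete": fr,
                    "fpkm_n_depleted": fd,
                    "ratio": fd / fr if fr > 0 else np.nan,
                    "de_flag": de,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["ec_number", "est_id", "fpkm_n_replete", "fpkm_n_depleted", "ratio", "de_flag"],
    )
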