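"""Culture phenotype arithmetic: growth rate, lipid content, pigments, PAM yield.

Growth is summarised from replicate cell-dry-weight (CDW, g/L) time courses
with the discrete exponential rate r = (x_t2/x_t1)^(1/(t2-t1)) - 1 per
2-day interval. Lipid and hydrocarbon contents are expressed as percent of
CDW; chlorophyll from two-wavelength ethanol-extract absorbance; PSII
quantum yield from PAM fluorometry as Y(II) = (Fm' - F)/Fm'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GrowthSeries:
    """Replicate CDW trajectories: ``cdw`` is replicate x timepoint (g/L)."""

    timepoints_days: np.ndarray
    cdw: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints_days = np.asarray(self.timepoints_days, dtype=float)
        self.cdw = np.atleast_2d(np.asarray(self.cdw, dtype=float))
        if np.any(np.diff(self.timepoints_days) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.cdw.shape[1] != len(self.timepoints_days):
            raise ValueError("cdw must have one column per timepoint")
        if np.any(self.cdw <= 0):
            raise ValueError("CDW values must be positive")

    @property
    def n_replicates(self) -> int:
        return self.cdw.shape[0]


@dataclass
class GrowthSummary:
    """Per-period rates and the Table-style average / maximum growth rate."""

    periods: list[tuple[float, float]]
    replicate_rates: np.ndarray        # replicate x period
    period_means: np.ndarray
    period_sds: np.ndarray             # sample SD (ddof=1); nan for 1 replicate
    average_rate: float                # mean of the period means
    maximum_rate: float                # max of the period means


@dataclass
class LipidMeasurement:
    """Gravimetric replicate measurements for one nitrogen condition (g/L)."""

    condition: str
    cdw_g_per_l: np.ndarray
    total_lipid_g_per_l: np.ndarray
    hydrocarbon_g_per_l: np.ndarray

    def __post_init__(self) -> None:
        for name in ("cdw_g_per_l", "total_lipid_g_per_l", "hydrocarbon_g_per_l"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be positive")
            setattr(self, name, arr)

    def summary(self) -> dict[str, float]:
        """Replicate means and percent-of-CDW values computed from the means."""
        cdw = float(self.cdw_g_per_l.mean())
        tl = float(self.total_lipid_g_per_l.mean())
        hc = float(self.hydrocarbon_g_per_l.mean())
        return {
            "cdw_g_per_l": cdw,
            "total_lipid_g_per_l": tl,
            "hydrocarbon_g_per_l": hc,
            "total_lipid_pct_cdw": percent_cdw(tl, cdw),
            "hydrocarbon_pct_cdw": percent_cdw(hc, cdw),
        }


def growth_rate(x_t1: float, x_t2: float, t1: float, t2: float) -> float:
    """Discrete exponential growth rate r = (x_t2/x_t1)^(1/(t2-t1)) - 1 per day."""
    if x_t1 <= 0 or x_t2 <= 0:
        raise ValueError("biomass must be positive")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return (x_t2 / x_t1) ** (1.0 / (t2 - t1)) - 1.0


def summarize_growth(
    series: GrowthSeries, interval_days: float = 2.0, last_day: float = 8.0
) -> GrowthSummary:
    """Per-period replicate rates over [0, last_day] and their summary.

    The average growth rate is the unweighted mean of the period mean rates;
    the maximum growth rate is the largest period mean. SDs are sample
    standard deviations over replicates.
    """
    edges = np.arange(0.0, last_day + interval_days / 2, interval_days)
    t = series.timepoints_days
    idx = []
    for e in edges:
        hits = np.flatnonzero(np.isclose(t, e))
        if len(hits) == 0:
            raise ValueError(f"series lacks a timepoint at day {e}")
        idx.append(int(hits[0]))
    periods = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    rates = np.empty((series.n_replicates, len(periods)))
    for j, ((ta, tb), ia, ib) in enumerate(zip(periods, idx[:-1], idx[1:])):
        for r in range(series.n_replicates):
            rates[r, j] = growth_rate(series.cdw[r, ia], series.cdw[r, ib], ta, tb)
    means = rates.mean(axis=0)
    sds = rates.std(axis=0, ddof=1) if series.n_replicates > 1 else np.full(len(periods), np.nan)
    return GrowthSummary(
        periods=periods,
        replicate_rates=rates,
        period_means=means,
        period_sds=sds,
        average_rate=float(means.mean()),
        maximum_rate=float(means.max()),
    )


def chlorophyll_content(
    od645: float, od663: float, cdw_g_per_l: float | None = None
) -> tuple[float, float | None]:
    """Total chlorophyll (a+b) from 96 % ethanol-extract absorbance.

    C (mg/L) = 20.2 * OD645 + 8.05 * OD663; optionally also returned as
    percent of CDW (C in mg/L over CDW in g/L): C / (1000 * cdw) * 100.
    """
    if od645 < 0 or od663 < 0:
        raise ValueError("absorbances must be non-negative")
    c = 20.2 * od645 + 8.05 * od663
    pct = None
    if cdw_g_per_l is not None:
        if cdw_g_per_l <= 0:
            raise ValueError("CDW must be positive")
        pct = c / (1000.0 * cdw_g_per_l) * 100.0
    return c, pct


def quantum_yield(fm_prime: float, f: float) -> float:
    """Effective PSII quantum yield Y(II) = (Fm' - F)/Fm', in [0, 1]."""
    if fm_prime <= 0:
        raise ValueError("Fm' must be positive")
    if f < 0 or f > fm_prime:
        raise ValueError("invalid measurement: need 0 <= F <= Fm'")
    return (fm_prime - f) / fm_prime


def percent_cdw(component_g_per_l: float, cdw_g_per_l: float) -> float:
    """Component mass as percent of cell dry weight."""
    if cdw_g_per_l <= 0:
        raise ValueError("CDW must be positive")
    return 100.0 * component_g_per_l / cdw_g_per_l


def fold_change(before: float, after: float) -> float:
    """after / before; display convention rounds to one decimal."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return after / before


def growth_series_from_frame(df: pd.DataFrame) -> GrowthSeries:
    """Build a GrowthSeries from a TSV-style frame: 'day' column + one column per replicate."""
    if "day" not in df.columns:
        raise ValueError("frame must have a 'day' column")
    reps = [c for c in df.columns if c != "day"]
    if not reps:
        raise ValueError("frame must have at least one replicate column")
    return GrowthSeries(
        timepoints_days=df["day"].to_numpy(dtype=float),
        cdw=df[reps].to_numpy(dtype=float).T,
    )
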