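"""Published culture measurements for the *B. braunii* 779 subisolate.

Replicate cell-dry-weight time courses in standard (1x) and double-strength
(2x) BB medium, and gravimetric lipid/hydrocarbon measurements before and
after nitrogen deprivation. These small printed tables are inputs to the
phenotype calculators and to the worked examples; they let growth and lipid
summaries be recomputed without any external download.
"""

from __future__ import annotations

import numpy as np

from .io import N_DEPLETED, N_REPLETE
from .phenotype import GrowthSeries, LipidMeasurement

# CDW (g/L), three replicate cultures sampled every 2 days, days 0-12.
GROWTH_BB_DAYS = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
GROWTH_BB_CDW = np.array(
    [
        [0.140, 0.215, 0.600, 0.920, 1.150, 1.500, 1.900],
        [0.155, 0.245, 0.640, 0.960, 1.350, 1.700, 2.200],
        [0.155, 0.235, 0.630, 0.970, 1.300, 1.650, 1.900],
    ]
)

GROWTH_2XBB_DAYS = GROWTH_BB_DAYS.copy()
GROWTH_2XBB_CDW = np.array(
    [
        [0.140, 0.730, 1.610, 2.250, 3.000, 3.500, 3.800],
        [0.155, 0.755, 1.580, 2.500, 3.000, 3.850, 4.300],
        [0.155, 0.750, 1.630, 2.550, 3.300, 3.850, 4.050],
    ]
)

# Gravimetric triplicates (g/L): CDW, total lipid (methanol/chloroform
# extract), hydrocarbon (hexane extract), before (+N) and 3 days after (-N)
# nitrogen deprivation.
LIPID_N_REPLETE = {
    "cdw": (1.61, 1.58, 1.63),
    "total_lipid": (0.59, 0.60, 0.56),
    "hydrocarbon": (0.30, 0.36, 0.28),
}
LIPID_N_DEPLETED = {
    "cdw": (1.67, 1.67, 1.70),
    "total_lipid": (1.25, 1.29, 1.23),
    "hydrocarbon": (0.87, 0.84, 0.92),
}

# Rounded replicate-mean masses (g/L) as printed alongside the raw
# triplicates; the percent-of-CDW and fold-change summaries are quoted from
# these rounded means.
LIPID_MEANS_G_PER_L = {
    N_REPLETE: {"cdw": 1.61, "total_lipid": 0.58, "hydrocarbon": 0.31},
    N_DEPLETED: {"cdw": 1.68, "total_lipid": 1.25, "hydrocarbon": 0.87},
}

# Scale of the sequenced annotated transcriptome, used as generator defaults
# and in the reporting arithmetic: counts of ESTs with a best-hit among all
# non-redundant ESTs, and annotated among the ESTs homologous to the A-race
# Bot-88 transcriptome.
TRANSCRIPTOME_COUNTS = {
    "n_nonredundant_ests": 61_220,
    "n_annotated_ests": 12_292,
    "n_bot88_homologous": 5_860,
    "n_bot88_homologous_annotated": 715,
}


def growth_series_bb() -> GrowthSeries:
    """Replicate CDW time course in standard BB medium."""
    return GrowthSeries(timepoints_days=GROWTH_BB_DAYS, cdw=GROWTH_BB_CDW)


def growth_series_2xbb() -> GrowthSeries:
    """Replicate CDW time course in double-strength BB medium."""
    return GrowthSeries(timepoints_days=GROWTH_2XBB_DAYS, cdw=GROWTH_2XBB_CDW)


def lipid_measurements() -> dict[str, LipidMeasurement]:
    """Gravimetric lipid/hydrocarbon triplicates keyed by nitrogen condition."""
    return {
        N_REPLETE: LipidMeasurement(
            condition=N_REPLETE,
            cdw_g_per_l=np.array(LIPID_N_REPLETE["cdw"]),
            total_lipid_g_per_l=np.array(LIPID_N_REPLETE["total_lipid"]),
            hydrocarbon_g_per_l=np.array(LIPID_N_REPLETE["hydrocarbon"]),
        ),
        N_DEPLETED: LipidMeasurement(
            condition=N_DEPLETED,
            cdw_g_per_l=np.array(LIPID_N_DEPLETED["cdw"]),
            total_lipid_g_per_l=np.array(LIPID_N_DEPLETED["total_lipid"]),
            hydrocarbon_g_per_l=np.array(LIPID_N_DEPLETED["hydrocarbon"]),
        ),
    }
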