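"""Growth-rate and lipid-content summaries from replicate culture measurements.

Recomputes, from the embedded replicate cell-dry-weight (CDW) tables of the
*B. braunii* 779 subisolate, the 2-day-period growth rates in standard and
double-strength BB medium, and the lipid/hydrocarbon contents before and
after nitrogen deprivation.
"""

import numpy as np

import rankwin as rw
from rankwin import reference

for label, series in [
    ("1x BB medium", reference.growth_series_bb()),
    ("2x BB medium", reference.growth_series_2xbb()),
]:
    s = rw.summarize_growth(series)
    print(f"{label}:")
    for (t1, t2), mean, sd in zip(s.periods, s.period_means, s.period_sds):
        print(f"  days {t1:.0f}-{t2:.0f}: rate {mean:.3f} +/- {sd:.3f} per day")
    print(f"  average rate {s.average_rate:.3f}, maximum {s.maximum_rate:.3f} per day")

print()
means = reference.LIPID_MEANS_G_PER_L
rep, dep = means[rw.N_REPLETE], means[rw.N_DEPLETED]
tl_fold = rw.fold_change(rep["total_lipid"], dep["total_lipid"])
hc_fold = rw.fold_change(rep["hydrocarbon"], dep["hydrocarbon"])
print("lipid response to nitrogen deprivation (from replicate-mean g/L):")
print(f"  total lipid: {rw.percent_cdw(rep['total_lipid'], rep['cdw']):.1f} % "
      f"-> {rw.percent_cdw(dep['total_lipid'], dep['cdw']):.1f} % of CDW "
      f"({tl_fold:.1f}-fold)")
print(f"  hydrocarbon: {rw.percent_cdw(rep['hydrocarbon'], rep['cdw']):.1f} % "
      f"-> {rw.percent_cdw(dep['hydrocarbon'], dep['cdw']):.1f} % of CDW "
      f"({hc_fold:.1f}-fold)")
print()
print("The rates are r = (CDW_t2/CDW_t1)^(1/2) - 1 per 2-day period, averaged")
print("over 3 replicate cultures; the maximum period mean is the strain's peak")
print("relative growth rate, and lipid percentages are component mass over CDW.")
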