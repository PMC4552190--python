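"""Sliding-window term enrichment on a synthetic table with a planted signal.

Generates a 12,292-EST two-condition expression table in which one GO-like
term of 60 ESTs is concentrated at 3x its background density inside the
highest-expression window, then runs the rank-by-level sliding-window
binomial scan (window 1,024, step 512, Bonferroni) and prints the windows
the detector flags.
"""

import rankwin as rw

config = rw.GeneratorConfig(
    seed=1,
    n_go_bp_terms=10,
    n_kegg_terms=0,
    planted_terms=(
        rw.PlantedTerm("GO:planted", size=60, windows=(1,), density_multiplier=3.0),
    ),
)
table, truth = rw.generate_table(config)
matrix = rw.expression_matrix(table)
ranking = rw.rank_ests(matrix, "by_level")
results = rw.window_term_enrichment(
    ranking, table.annotations, family="windows"
)

print(f"universe: {len(ranking)} ESTs, {len(rw.make_windows(len(ranking)))} windows")
print(f"planted: {truth.planted['GO:planted']}")
print("\nflagged (term, window) pairs  [fold > 2 and Bonferroni p < 0.05]:")
for r in results:
    if r.flagged:
        print(f"  {r.term_id}  window {r.window_index:2d}  x={r.x:3d}/{r.n}  "
              f"K={r.K}  fold={r.fold:.2f}  p_adj={r.p_adj:.2e}")
print("\nThe planted term should be flagged in window 1 (ranks 1-1024) and the")
print("ten uniformly annotated background terms nowhere: members of a")
print("co-regulated pathway cluster in a narrow band of the expression ranking.")
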