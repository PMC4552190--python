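# Methods

## Scope and data model

The package analyses annotated de novo transcriptome expression tables of a
two-condition, two-replicate design: nitrogen-replete (log-phase) versus
nitrogen-depleted cells of an oleaginous microalga. The unit of analysis is
the EST — an assembled non-redundant transcript contig — carrying a length
in base pairs, per-sample read counts and/or FPKM values, and term
annotations (GO biological process / cellular component / molecular
function, KEGG pathway, EC number, or free-text keyword). All tables are
plain TSV; hit files follow the 12-column tabular similarity-search layout.

## Filtering

An EST enters the analysis universe only if (a) its length strictly exceeds
300 bp, (b) its read count summed over all samples strictly exceeds 40, and
(c) no sample has an FPKM of exactly zero (rule (c) is optional). The
strict inequalities follow the convention under which the retained length
range starts at 301 bp. "Read count per EST" is the pooled total across
samples because the cutoff belongs to the pooled assembly, not to any one
library. The filter is idempotent, and the windows/eligibility machinery
always re-restricts term memberships to the post-filter universe.

## Expression and ranking

FPKM is computed as counts / (length/10³) / (library size/10⁶); library
sizes are the total mapped fragments per sample (defaulting to column sums
when not given). Condition means are arithmetic means over replicates. The
response ratio is depleted mean / replete mean, and logFC is its base-2
logarithm, consistent with a "fold change > 2" gate at |logFC| > 1.

Rankings are descending and 1-based. `by_level` keys on the nitrogen-replete
condition mean — the log-phase abundance — and `by_ratio` on the response
ratio. Ties break lexicographically by EST id so that reruns and platform
changes cannot permute ranks.

## Sliding-window enrichment

Window geometry: full-size windows of w ranks starting at 1, 1+s, 1+2s, …,
i.e. ⌊(N−w)/s⌋+1 windows, with any trailing remainder left uncovered. This
is the only reading that yields 23 windows at the reference universe size
N = 12,292 with the default w = 1,024, s = 512. With s ≤ w every covered
rank falls in exactly ⌈w/s⌉ windows away from the edges (2 at the default),
which the tests assert explicitly.

For each term with K > 30 members in the ranked universe, the count x of
members in a window is tested against Binomial(n = w, p₀ = K/N), upper
tail. The binomial "sampling with replacement" null is deliberate — the
term members are treated as successes arriving among the window's trials —
and is slightly conservative for enrichment relative to the hypergeometric
at small K/N. The density fold is (x/w)/p₀. Flagging requires fold > 2 and
Bonferroni-adjusted p < 0.05.

The Bonferroni family defaults to (eligible terms × windows) per ranking
mode; a per-term family (windows only, m = 23 at the default geometry) is
available and appropriate when a single designated term is being validated.
The conservative product family is the default because the correction is
meant to cover every test actually performed in a scan. At genome scale
this matters: a 60-member term concentrated at 3× density in one window has
a raw tail probability ≈ 2×10⁻⁴, which survives the per-term family
(p_adj ≈ 5×10⁻³) but not a 103-term product family (p_adj ≈ 0.16) —
Bonferroni trades power for family-wise control, and the recovery tests are
formulated as single-term detector validations for that reason.

Related statistics:

- **top-k enrichment**: x members of one term among the top k ranks; fold
  (x/k)/(K/N) and Binomial(k, K/N) upper tail. At x = 0 the upper tail is
  1 by definition (no evidence of enrichment), not (1−p₀)^k.
- **subset over-representation**: for an arbitrary EST subset (e.g. a
  keyword match on descriptions), each term's 2×2 overlap is tested with
  the one-sided hypergeometric upper tail — the standard exact test for
  membership overlap from a fixed universe — Bonferroni over terms.
- **DE placement**: per-window counts and density ratios of up/down
  differential-expression flags along either ranking, which shows, e.g.,
  that up-regulated ESTs were low-abundance before the treatment.

## Differential expression

The package consumes an input p-value column when one is provided (the
preferred route; dispersion-modelling count tools are out of scope). As a
self-contained stand-in it offers a per-EST two-sided binomial test of the
depleted share of the EST's pooled count against the depleted share of all
mapped fragments. This models sequencing sampling noise only: it is
calibrated in the Poisson limit (measured type-I ≈ 0.05 at nominal 0.05 on
null data) but anticonservative when replicate counts are overdispersed —
at the generator's default negative-binomial dispersion of 20 the empirical
type-I rate is ≈ 0.3, which is precisely why dedicated DE tools model
dispersion. Fold-change and p gates are logFC > 1 (or < −1) and p < 0.05;
ESTs without a p-value are excluded from both flag sets.

## Enzyme panels

ESTs are grouped by EC number, restricted to a curated panel list; an EST
mapped to several ECs contributes to each. The enzyme-level ("summative")
expression is the sum of member ESTs' condition means — summing before
ratioing, so the value is invariant to how the assembler split a transcript
into contigs (asserted as a splitting-linearity property test). An enzyme
is flagged when the larger direction ratio exceeds 2; zero sums give an
undefined ratio and no flag. Overlap between two detected enzyme sets from
a proposed universe of size 55 is tested with the exact hypergeometric
upper tail: for sets of 20 and 19 sharing 11, p = 0.0176 (verified against
brute-force enumeration on small universes). A published value of 0.0137
for this configuration is not reproduced by the exact one-sided
hypergeometric (nor by a binomial approximation we examined); since the
test behind that printed number is unstated, the package reports the exact
summation value.

## Phenotype calculators

- Growth: r = (x_t2/x_t1)^(1/(t2−t1)) − 1 per 2-day period over days 0–8;
  the **average growth rate** is the unweighted mean of the four period
  mean rates and the **maximum** the largest period mean — the definition
  that reproduces the reference tables' 0.318/0.641 (1× BB) and
  0.515/1.230 (2× BB) exactly at 3-decimal display rounding. No regression
  fit is involved. SDs are sample standard deviations over replicates.
- Lipids: percent of CDW = 100 × component (g/L) / CDW (g/L), and fold
  change = after/before, displayed to one decimal. The reference tables'
  nitrogen-replete hydrocarbon row is internally inconsistent (0.31/1.61 =
  19.3 %, printed as 18.3 %); the package computes from the formula and
  does not special-case that cell. Percentages computed from unrounded
  replicate means differ in the first decimal from those computed from the
  printed rounded means (74.8 vs 74.4 % for depleted total lipid); the
  summary helpers use unrounded means, while the quoted headline values
  come from the rounded means they were published with.
- Chlorophyll: C (mg/L) = 20.2·OD645 + 8.05·OD663 from 96 % ethanol
  extracts; optionally converted to percent of CDW.
- PAM fluorometry: Y(II) = (Fm′ − F)/Fm′, defined for 0 ≤ F ≤ Fm′.

## Synthetic data generator

The generator emulates the reference survey's printed marginals, and its
defaults are fixed at those values:

| parameter | default | emulates |
|---|---|---|
| n_ests | 12,292 | annotated universe size |
| length | log-normal, median 663 bp, σ=0.55, truncated [301, 8268] | length distribution |
| total count | median ≈ 174, floor 42; per-EST log-normal baseline (σ=1.6) | count distribution |
| counts per sample | negative binomial, dispersion 20 | replicate overdispersion |
| library size | 27×10⁶ per sample | sequencing depth |
| design | 2 conditions × 2 replicates | the ±N experiment |
| term catalog | 44 GO_BP + 59 KEGG terms, sizes 31–400 | eligible-term counts |
| DE fractions | 593/12,292 up, 116/12,292 down, \|logFC\| = 1.5 + Exp(1.5) | DE scale |

Counts are integers and FPKM is always computed from them through the same
normalisation code real data use, never sampled directly. The truncation of
lengths slightly raises the realised median (to ≈ 700 bp), still within the
calibration band the tests assert (600–730 bp; total-count median 140–210).

Planting: expression is sampled first; the realised by-level (or by-ratio)
ranking is computed; then a planted term's membership is assigned to the
ESTs occupying ranks drawn uniformly from the target windows — exactly
⌈multiplier × K × w/N⌉ per window (rounded) — with the remaining members
placed uniformly outside the covered ranks. Because annotation never feeds
back into counts, this decouples term assignment from expression sampling
while realising the target window density exactly up to rounding (within
±15 %, asserted). Infeasible plantings (more members demanded than the term
holds, or than a window holds) fail before any sampling. Up-regulated DE
ESTs are placed in the low-abundance portion of the baseline distribution
(quantiles 0.45–1.0 of the descending order) and down-regulated ones in the
high-abundance portion (0.0–0.2), so the DE-placement detector has ground
truth to recover.

What the generator does not emulate: annotation biases (terms are uniform
outside plantings), correlated pathways, length-dependent count bias,
isoform structure, and batch effects. Passing tests therefore demonstrate
detector correctness and calibration under the stated null and planted
alternatives, not robustness to every artefact of real libraries.

## Numerical and interface choices

- Ranks are 1-based; windows are closed intervals [start, start+w−1].
- Bonferroni: p_adj = min(1, m·p_raw).
- Binomial/hypergeometric tails come from scipy survival functions; the
  test suite cross-checks them against direct pmf summation and
  combinatorial enumeration on small problems.
- TSV writers emit full-precision float reprs so read/write round-trips are
  bit-exact; '#'-prefixed lines are comments; encoding is UTF-8.
- All randomness flows through one seeded `numpy.random.Generator`; the
  same seed yields byte-identical exported fixtures.
- Degenerate inputs fail loudly: empty query sets, zero library sizes,
  non-positive biomass, F > Fm′, overlaps beyond set sizes, and plantings
  that cannot fit all raise ValueError before producing output.

## Problem sizes used in validation

The end-to-end validation tests run the full 12,292-EST universe for geometry,
planting recovery (12 simulated tables) and DE placement; the family-wise
error check uses 200 null term-catalog draws across 5 independently
generated tables; oracle-equivalence checks enumerate universes up to
N = 5,000 (geometry) and N = 200 (binomial tails), and hypergeometric
enumeration runs at universe sizes ≤ 12. These sizes were chosen so the
whole suite validates every claim at full scale where the statistic depends
on scale, and at enumerable scale where an independent oracle exists.

## Known limitations

- Flat term sets only: no GO DAG ancestry, so parent/child double counting
  is the caller's concern.
- The binomial window null ignores the without-replacement structure of
  ranks; at K ≪ N the difference is negligible and conservative.
- The stand-in DE test understates false positives on overdispersed
  replicates (see above); supply external p-values for real data.
- The growth summary assumes measurements exist at every 2-day boundary of
  the summarised span and does not fit growth curves.
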