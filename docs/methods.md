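# Methods

## Scope and model

saltmir analyses two un-replicated small-RNA libraries from one plant
tissue under two conditions (control CK and salt-treated Na200). No
biological replication is assumed anywhere: expression inference is a
per-sequence count comparison between two libraries, which is why the exact
count test, not a dispersion-estimating model, is the statistical core.

## Read cleaning

Rules run in a fixed order and the first matching rule claims the read, so
the categories partition the high-quality reads exactly (an invariant the
reports validate):

1. mean Phred < `min_qual` (default 20) → not high quality;
2. the first 8 nt of the 3' adapter are absent → `adapter3_null`;
3. adapter found at position 0 → `insert_null`;
4. insert begins with the last 8 nt of the 5' adapter →
   `adapter5_contaminant`;
5. insert length outside [`min_len`, `max_len`] → `too_short` / `too_long`;
6. insert with ≥ 80 % A or a run of ≥ 10 A's → `polyA`.

The default length window is 18–30 nt; 15–30 is reachable via `min_len=15`.
Conventional cleaning tables have no "too long" row, but a two-sided window
needs one for the partition to hold; we report it separately. "High
quality" has no community definition; mean Phred ≥ 20 is used and
configurable. Adapter matching is an exact 8-mer match (no mismatches):
with synthetic reads this is lossless, and on real data it errs toward
discarding (`adapter3_null`) rather than mis-trimming.

Percentages in all tables are rounded half-up to two decimals and computed
in exact rational arithmetic from the integer counts, so printed-table
arithmetic reproduces bit-for-bit (e.g. 3,190,190 / 3,370,688 → 94.65, which
banker's rounding would print as 94.64).

## Annotation

Tags map to the reference contigs as exact substrings on both strands (a
reverse-strand hit is reported at its forward-strand start with strand
'−'). ncRNA assignment is an exact-substring test against each reference
category in the order rRNA > tRNA > snRNA > snoRNA; only tags surviving the
exclusion are tested as miRNAs. The alternative precedence (miRNA first) is
available via `mirna_first=True`, since summary tables that list miRNA as a
sibling category are ambiguous about the order. Exact substring matching is
the strictest reproducible reading of database-lookup annotation; it will
under-annotate ncRNA fragments carrying sequencing errors.

## Known miRNAs

A tag is a known miRNA if it aligns ungapped to a mature reference with at
most 2 mismatches. When lengths differ (isomiRs), the shorter sequence
slides over the longer within a ±2 nt slack and every unaligned overhang
base of the longer sequence costs one mismatch, so end-shifts and
substitutions share one budget; `length_slack=0` restricts the rule to
substitutions only. Ties between references at equal mismatch count break
lexicographically by name, making results order-independent. A 6-mer
shared-seed prefilter accelerates matching; by pigeonhole (≤ 2 mismatches
over ≥ 18 aligned nt guarantees an exact 6-mer run) it cannot lose a true
match — a property the tests verify against an exhaustive oracle.

Family names normalize by stripping species prefixes, member letters,
paralog indices and arm suffixes; the historically merged families
miR156/157 and miR165/166 are merged via a configurable map. Family ratios
are computed on raw read counts (not TPM), matching how family tables are
conventionally printed; the per-library TPM ratio is emitted separately by
the expression table.

## Novel miRNA hairpins

For each unannotated, genome-mapped tag with at least `min_count` total
reads (default 10 — singletons cannot support an annotation), two candidate
windows are extracted per hit: tag-as-5p (tag + 150 nt downstream) and
tag-as-3p (150 nt upstream + tag), reverse-complemented on '−' hits. The
150 nt flank follows typical plant precursor lengths (~150 nt average).

Folding uses ViennaRNA's MFE fold when the Python bindings are importable;
otherwise a bundled Nussinov-style maximum-weight algorithm with fixed
pseudo-energies (GC −3, AU −2, GU −1 kcal/mol, hairpin loops ≥ 3 nt) is
used and the backend is recorded in the output. The fallback has no loop
penalties, so on arbitrary sequences it overpredicts pairing; it exists so
the fold operation works with zero external dependencies and its fixed
scoring is unit-tested, but hairpin evaluation should be read as calibrated
to the thermodynamic backend.

Criteria, each a named flag (`passes` = all):

- **(a) one arm** — no mature base pairs with another mature base, and all
  mature partners lie on one side;
- **(b) duplex** — within the mature minus its 2-nt 3' overhang, at most 4
  bases unpaired or paired outside the star, and the mature/star pairing
  spans differ by at most 2 nt (asymmetric bulge);
- **(c) star** — the star is derivable from the structure by the canonical
  2-nt 3' overhang rule (`star_end = partner(mature_start) + 2`,
  `star_start = partner(mature_end − 2)`, extrapolated across frayed ends)
  and is disjoint from the mature;
- **(d) energy** — MFE ≤ −18.0 kcal/mol (configurable; chosen from the
  upper end of reported novel-precursor energies);
- **(e) length** — precursor within [60, 400] nt.

Star read counts are filled from the tag set when the star was sequenced;
an unsequenced star does not fail a candidate (stars are frequently
degraded and sequenced once or not at all). Overlapping passing candidates
on one locus collapse to the lowest-MFE one. Specificity depends on the
genome's base composition: at the simulator's default GC of 0.42,
~3–5 % of random 21-mer windows pass all criteria (measured in the test
suite); at GC 0.5 the rate is slightly higher, since random stems pair more
strongly.

## Differential expression

TPM = count / library clean reads × 10⁶; a zero TPM is replaced by 0.01
*on the TPM scale* (not a count pseudocount) so fold changes stay finite;
fold change is log₂(TPM_Na200 / TPM_CK). Σ TPM = 10⁶ per library before the
floor.

The p-value is the exact two-library count test: conditional on the
combined count n = x + y, the treated count is Binomial(n, N₂/(N₁+N₂))
under the null of equal relative abundance — the Audic–Claverie statistic
with the combined total fixed at its observed value. The two-sided p-value
doubles the smaller of P(Y ≤ y) and P(Y ≥ y), capped at 1, and is symmetric
under swapping libraries. `method="ac"` provides the negative-binomial
series form of the same statistic (tails of
P(k|x) = (N₂/N₁)^k (x+k)! / (x! k! (1+N₂/N₁)^(x+k+1))); it conditions on x
rather than on x + y, so its tails are not exactly symmetric — the
conditional-binomial form is the default for that reason. Both are computed
through scipy's exact tail functions, and the default is verified against a
rational-arithmetic oracle to 1e-9 relative on the full x, y ≤ 50 grid.

Calls use strict thresholds (log₂FC > 0.5 with p < 0.05 up; < −0.5 down).
No multiple-testing correction is applied by default, matching the
two-library convention; Benjamini–Hochberg is available via
`bh_correct=True`. Records sort by |log₂FC| descending.

## Target prediction

The miRNA is matched antiparallel and ungapped against every window of the
transcript sense strand; positions count from the miRNA 5' end. Scoring:
Watson–Crick 0, G:U wobble 0.5, anything else 1. The 2.5-point budget over
positions 1–12 only makes sense with half-point wobbles, so G:U = 0.5 is
the default; `no_wobble=True` scores wobbles as full mismatches, under
which a 2.5 budget is equivalent to 2. "Adjacent mismatches" counts the
longest run of positions scoring ≥ 1, i.e. adjacent wobbles do not
constitute adjacent mismatches. Gapped/bulged duplexes are out of scope:
the positional rules (1–9, 10–11, 1–12) are ill-defined under gaps.

## Synthetic studies

The generator emulates the composition of a salt-stress sRNA study: two
libraries of configurable depth (default 200,000 reads; expected counts are
stored at a nominal depth and scale with the simulated one), 50 planted
known miRNAs with miRBase-style names, 5 hairpin precursors with mature,
star (2-nt 3' overhangs) and an unpairable {A,C} loop, and a noise mixture
dominated by unannotatable random tags with an rRNA shoulder plus per-mille
technical artifacts (adapter-only, 5'-contaminant, short, poly-A) —
qualitatively mirroring reported category tables without calibrating to
any one of them. Counts are negative binomial with Var = μ + φμ²
(φ default 0.05, Poisson at 0). Twenty planted expression effects have
|log₂| drawn uniformly from [1, 3] with the lower-side mean count in
[600, 2500] at nominal depth, the regime in which a two-library exact test
has high power; background miRNAs have equal means drawn log-uniformly
from [20, 2000]. Planted target sites are perfect-complement windows with
0–2 G:U wobbles placed outside the 5'-rule region. Features are inserted
collision-free and the manifest records exact loci, so recovery is
measurable: at these defaults the pipeline recovers 100 % of planted known
miRNAs, all hairpins, and calls all planted effects with the correct
direction (the acceptance script reports the measured values per seed).

What the simulator does **not** model: per-cycle sequencing error, PCR
duplicates, isomiR end-heterogeneity around planted matures, expression
correlation between family members, and genomic repeat structure. Passing
recovery tests therefore demonstrates the pipeline's logic is correct under
the stated count model, not robustness to those real-data phenomena.

## Numerical and engineering choices

- All printed percentages/ratios: exact rational arithmetic, half-up
  rounding, two decimals.
- Fold determinism: each backend is deterministic; the fallback's traceback
  prefers leaving the 3' base unpaired, then the smallest partner index.
- Genome mapping concatenates contigs with an 'N' spacer longer than any
  tag, so one substring search serves all contigs and matches cannot
  straddle boundaries.
- Pipeline outputs are byte-deterministic for a fixed configuration;
  `resume=True` reuses the cached clean/collapse stage.
- Degenerate inputs: empty genome, zero library totals, negative counts,
  non-ACGU precursors, and malformed FASTQ records (reported with the
  record index) all raise typed errors before any partial output.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the synthetic study at 200,000
reads per library (the acceptance-scale run) and a 30,000-read version for
session-level tests; the statistical oracle grid covers all count pairs up
to 50, and oracle-equivalence suites use 200–500 randomized cases per
operation. These sizes were chosen to exercise every code path at
meaningful depth while keeping a full run in the minutes range on one CPU.
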