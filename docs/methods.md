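# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices made where the design was
genuinely open.

## Differential methylation testing

Input are per-sample CpG call tables (chrom, 1-based position, strand,
coverage, methylated count). Counts on opposite strands of one CpG
dinucleotide are merged onto the cytosine of the plus strand before testing
(standard RRBS destranding; the minus-strand G sits one base downstream of
the C).

A CpG enters the comparison only when its coverage reaches `min_coverage`
(default 10) in **every** sample of both groups; the filter is deliberately
per-sample rather than on pooled counts so that a single deep library cannot
rescue an uncovered site. Counts are then pooled within each group and the
2×2 table (methylated/unmethylated × control/treated) is tested with a
two-sided Fisher's exact test. The p-value is the sum of hypergeometric
probabilities of all tables with the observed margins that are no more
probable than the observed one, with the classical relative slack 1 + 1e-7
(the convention of R's `fisher.test`). The implementation enumerates the
hypergeometric support directly (log-gamma arithmetic), vectorised over
tables that share margins; a test verifies agreement with exact integer
enumeration to 1e-12 for every table with grand total ≤ 30, and with
`scipy.stats.fisher_exact` on random tables.

The pooled-count exact test was chosen over a per-CpG logistic regression
because it is exactly oracle-checkable and is the standard fallback of
methylation callers when replicate counts are small; group sizes here
default to 2 replicates per condition. A regression backend can be slotted
in behind the same interface without touching the downstream stages.

Benjamini–Hochberg correction is applied per pairwise comparison (one
family per treatment-vs-control contrast), via
`statsmodels.stats.multitest.multipletests`. Records failing q < `q_cut`
(default 0.01) or |Δm| < `diff_cut` (default 25 percent points) are retained
in the output but flagged non-significant, so that downstream consumers can
re-threshold without re-testing.

Tiles are fixed windows (default 200 bp) on the 0-anchored grid of each
chromosome; counts of coverage-eligible CpGs are summed per tile per group
and tested identically. Tiles with no eligible CpG are skipped. A window
different from the step is allowed but warned about, since overlapping tiles
change the multiplicity of tested regions.

The global methylation-shift test is a paired two-sided Wilcoxon signed-rank
test on per-CpG methylation fractions, dropping zero differences; with fewer
than 5 non-zero pairs it degrades to p = 1 with a warning rather than
reporting an uninterpretable statistic. Chromosome-level distribution
summaries use a relaxed effect threshold (≥ 5 points) appropriate for
genome-wide pattern description, not the 25-point calling threshold.

## DMR assembly and origin flags

"Clustering of DMCs" is implemented as assignment to the same fixed 200-bp
grid the tiles live on, not as a sliding merge: this makes the
DMC-derived/tile-derived/both comparison well-defined on identical
coordinates, which is what the origin flags describe. Flags: `C` = DMC
support only with ≥ `min_dmcs` (default 4) members; `M` = significant tile
only; `T` = both (no DMC minimum — the tile already carries region-level
evidence). DMC-only windows below the minimum are recorded in an audit file
with flag `N` and never emitted: a region with support in neither group is a
bookkeeping entry, not a result.

The representative effect size of a window is the tile estimate when a tile
is present, otherwise the mean of member-DMC differences; tiles pool more
reads and are the less noisy estimator. When tile and DMC estimates disagree
in sign the tile sign wins and a conflict record is appended to the audit
file.

Sharing across treatments requires the same grid window **and** the same
direction, so hyper- and hypomethylated overlaps are tallied separately.
Duplicate windows inside one set violate the grid guarantee and raise.

## Annotation conventions

All interval arithmetic is 0-based half-open; overlap means ≥ 1 shared base
(abutting intervals do not overlap). Promoters are TSS − 1 kb to TSS + 1 kb,
strand-aware (roles mirrored on the minus strand), clipped to the
chromosome. CpG-island shores are 2-kb flanks of merged islands, truncated
where they would run into a neighbouring island. Interval queries use an
interval tree; a test checks the engine against an O(n·m) all-pairs scan on
1000-interval fixtures.

Gene assignment goes through promoters (any-overlap), with a nearest-TSS
fallback within a configurable 50 kb for DMRs that touch a cCRE but no
promoter; gene-type proportions are computed over the deduplicated gene
list, not over DMRs. Ranked promoter tables filter on closed diff-meth
intervals (a gene at exactly −70 is inside [−100, −70]) and sort by
|Δm| descending with alphabetical tie-break.

## Repeat elements

A DMC inside nested or overlapping repeat annotations is assigned to the
smallest containing interval (the most specific element in
RepeatMasker-style nesting), ties resolved by sorted order. Family
proportions are unions of per-family intervals over the scope length.
CpG content per sequence is 100·#CG/(L−1) — the denominator counts
dinucleotide positions, and positions involving ambiguous bases are excluded
from both numerator and denominator; sequences shorter than 2 bp are skipped
with a warning. Distribution summaries aggregate families outside the named
set (Alu, MIR, L1, L2, microsatellite, simple repeat) into "Other RE",
keeping the sub-breakdown; low-complexity stays separate from simple repeats
unless the caller merges them. The "chromosome subset" is any user-named
chromosome — nothing is hard-coded to chr21.

## TF cell-identity simulation

Row statistics (min, median, max) for the perturbation formulas are computed
over the real sample columns only, so synthetic profiles cannot shift their
own targets. Perturbed values are clamped to [row min, row max] — the
medium/low formulas can otherwise escape the observed range when the
reference sits near an extreme. Constant rows are a no-op at every level and
flagged.

Order of operations: simulate on the raw tags-per-feature scale, then
z-score all columns (real + synthetic) jointly, then deduplicate, then
cluster. The perturbation formulas are defined on the raw scale, and joint
z-scoring keeps synthetic and real columns comparable; the alternative
reading (normalise first) is available behind a switch in the calling code
by z-scoring before simulation. Z-scores use the population SD (divide by
n); the choice is immaterial at hundreds of samples but is pinned for
testability, and constant rows map to all-zero with a warning.

Deduplication collapses columns with exactly identical value vectors,
keeping the lexicographically first sample id (the generator quantises
values so planted duplicates stay exact); near-duplicates are kept.
Clustering is complete-linkage on Euclidean column distances via
`scipy.cluster.hierarchy.linkage`, checked against a brute-force O(n³)
agglomeration through cophenetic distances on ≤ 12 columns. The
nearest-neighbour report lists, per synthetic profile, the k nearest real
samples by raw distance and the first real sample joined in the dendrogram.

## Synthetic-data model

The generator emulates the *structure* RRBS analysis assumes, not reads:

- **Layout.** Two or more chromosomes; CpG islands (1 kb) and repeat
  elements placed without overlap at multinomially distributed gaps; genes
  with TSS mostly inside islands; accessory tracks (cCRE, DHS, CTCF,
  histone marks, CAGE TSS) placed around TSSs or randomly. CpG positions are
  drawn with geometric gaps whose mean is the per-compartment spacing
  (island 10 bp, repeat 40 bp, background 100 bp by default), making island
  CpG density ≥ 2× background by construction. A requested spacing below
  1 bp/CpG is rejected as a collision.
- **Methylation.** A latent methylation fraction per CpG, drawn once from a
  per-compartment beta baseline — islands ≈ 10% (beta(1,9)), repeats ≈ 80%
  (beta(8,2)), background ≈ 50% (beta(5,5)) — and held fixed across
  replicates and conditions, so replicate noise is purely binomial sampling.
  Treated conditions shift the latent fraction by the planted delta (clamped
  to [0,1]) inside affected regions. Coverage is negative-binomial
  (mean 30, dispersion 10 by default); sites below the coverage filter are
  still emitted — filtering is the caller's contract.
- **Study design.** Control plus three doses, 2 replicates each. The
  replicate count is a modelling choice (the assay design it mirrors did not
  publish one); it is the smallest design in which the per-sample coverage
  filter is distinguishable from a pooled filter. Planted effects default to
  ±40 points, comfortably above the 25-point threshold at 30× coverage, and
  are recorded in a BED6 truth table (delta in the score column).
- **Expression matrix.** 23 promoters × 889 samples with 592 unique columns
  (the surplus are exact duplicates), mirroring the profiled study shape;
  values are non-negative, log-normally distributed with a per-promoter
  scale; 18 promoters are labelled hyper and 5 hypo by default, matching the
  bundled Caco-2 TF table.

What the generator does **not** model: read-level bisulfite conversion,
alignment artefacts, fragment-end biases of the RRBS digest, spatial
correlation of methylation beyond compartments, and biological covariance
between expression and methylation. Passing tests therefore demonstrate the
correctness of the statistical machinery under its own assumptions, not
performance on real libraries.

## Problem sizes and determinism

Calibration runs use two ~0.9-Mb chromosomes (≈ 50k CpGs) for the null
false-positive check and 100 planted regions for recovery; the bundled
end-to-end fixture uses two 0.4-Mb chromosomes with 60 planted regions
across three overlap classes (all three doses / two / one) so the Venn,
repeat and annotation stages all receive non-trivial input. Every stochastic
step flows from a single integer seed through `numpy.random.default_rng`;
fixing the seed fixes every output byte, and the run manifest records seed,
thresholds, package versions and input checksums.

## Known limitations

- The exact test pools replicates and therefore ignores within-group
  overdispersion; with many replicates a beta-binomial or regression test
  would be preferable.
- DMRs are fixed-grid windows; biological regions spanning a grid boundary
  appear as two adjacent windows.
- Duplicate-sample removal is exact-match; replicate libraries with
  independent noise are not collapsed (a name-based collapse can be layered
  on by the caller).
- The cCRE nearest-TSS assignment uses the DMR midpoint, which can differ
  from edge-distance assignment for very wide elements.
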