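# Methods

## Coordinate conventions

All intervals are 0-based half-open internally, as in BED. Two parse-time
dialects exist: `bed0` (identity) and `table1`, which declares a file
1-based inclusive — the convention of printed locus tables and SNAP-style
proxy positions — and shifts starts by −1. A printed span
`chr22: 24234493 - 24237862` therefore becomes `[24234492, 24237862)`,
width 3,370 bp. Overlap is "any overlap" (≥ 1 bp) everywhere, matching
bedtools-intersect defaults; adjacency under half-open coordinates
(`[10,20)` vs `[20,30)`) is not overlap. Chromosome names are compared as
exact strings; inputs sharing no names trigger a warning rather than silent
`chr`-prefix harmonization.

## LD blocks

A block is built from an index SNP's proxy table by keeping proxies with
r² ≥ `r2_threshold` (default 0.9) and distance ≤ `distance_limit_kb`
(default 500 kb, interpreted as SNAP's kb unit) and spanning
`[min, max]` of the surviving positions. The index SNP's own position always
enters the min/max, so an index with no passing proxies yields a degenerate
1-bp block rather than an error. Blocks are grouped by **exact span
equality**, not overlap: the packaged locus table keeps two overlapping
chr9 blocks (rs10818488, rs2900180) as separate rows, which rules out
overlap-based merging. Grouping is idempotent and order-invariant; member
SNP lists are sorted.

The packaged fixture (`ldscape/data/jia_ld_blocks_table.tsv`) carries the
23 JIA risk regions, their 30 index SNPs, and the four Y/N mark columns
(neutrophil and CD4+ T-cell H3K4me1/H3K27ac), stored exactly as printed
(1-based inclusive) and converted on load.

## Histone-mark annotation and enrichment

Per (block, cell type), `has_me1`/`has_ac` are any-overlap flags against the
peak BEDs. Summary counts satisfy the inclusion–exclusion identity
`n_either = n_me1 + n_ac − n_both`, enforced by construction and property
tests.

Genome-wide mark enrichment uses the same counting unit as the TFBS
analysis — the 100-bp genome bin — for consistency (one counting unit
throughout the package). Each bin is cross-classified (overlaps a block) ×
(overlaps a peak) and tested two-sided with Fisher's exact test. A zero
margin (no peaks, or no in-block bins) is a flagged degenerate result with
p = 1 by convention. The odds ratio uses the Haldane–Anscombe +0.5
correction only when a table cell is zero, and that correction is flagged
in the result.

## TFBS enrichment

The background for a given mark is the set of bins overlapping that mark's
peaks. Within each (mark, region class) stratum the per-TF 2×2 table counts
marked bins of that class by (inside an LD block) × (carries ≥ 1 site of the
TF); the four cells always sum to the stratum's marked-bin count. Region
class is assigned to **bins** (the contingency unit), not whole peaks: a bin
is "promoter" iff it overlaps any gene's strand-aware window
`[TSS−5000, TSS+1000)` (mirrored for minus-strand genes, whose TSS is the
5'-most transcribed base); otherwise "distal". A gene without strand is
treated as plus-strand and logged. Each stratum is tested separately and BH
adjustment runs within the stratum — stratification enters the test, not
just the display.

p-values are two-sided (no sidedness is privileged); direction comes from
the odds ratio, with OR = 1 ties labelled "enriched" and flagged.
Significance is BH FDR ≤ 0.05. Display scores rank significant TFs within
each (stratum, direction) group by FDR — lowest FDR receives the highest
rank `r_max` — and report `rank / r_max`, negated for depletion, so scores
lie in (0, 1] / [−1, 0) and the extreme score in every nonempty group is
±1. FDR ties break by larger |log OR|, then TF name. "Blood-cell" filtering
of a clustered TFBS track is delegated to input preparation; a convenience
cell-type column filter is available at parse time.

Fisher's exact test and BH adjustment are delegated to
`scipy.stats.fisher_exact` and `statsmodels.stats.multitest.multipletests`;
the package carries its own independent hypergeometric tail-sum oracle
(`stats.fisher_two_sided_oracle`, with the customary 1 + 1e-7 relative tie
tolerance) used only for cross-checks in tests, never in the pipeline path.

## Long-range interactions

Anchor pairs are canonically ordered (lexicographic by chromosome, then
start) at construction, so `(a, b)` and `(b, a)` records collapse in
deduplication, which groups on exact coordinates and keeps the
lexicographically smallest interaction id with a source-record count.
An interaction is kept iff ≥ 1 anchor overlaps ≥ 1 block;
inter-chromosomal pairs are accepted. Pair class follows from the two
per-anchor promoter-window flags; with a zero-width promoter window every
pair is distal–distal.

The anchor histone-category tally (both marks / ac-only / me1-only /
neither) counts **distinct anchor regions** of the kept unique
interactions; an anchor shared by several interactions is counted once.
This is the convention under which the reference tallies (66 + 2 + 11 + 5 =
84 regions over 42 interactions) are self-consistent, and it is recorded
here as the package's definition. Gene association uses body-or-promoter
overlap with an anchor; genes missing from the FPKM table count at 0 (and
are logged), matching the behaviour of unsequenced small-RNA species.
Coordinates are assumed pre-lifted to one assembly; a preflight check warns
when anchors exceed the stated chromosome sizes instead of attempting any
liftover.

## SNP windows

A gene belongs to a SNP iff its body overlaps
`[position − flank, position + flank]` (default flank 200 kb), clipped at 0
and at the chromosome end when sizes are provided. Body overlap — rather
than TSS-in-window — is the inclusion rule, the more permissive and more
common windowing choice. The union list is the deliverable; pathway
enrichment itself depends on external annotation databases and is out of
scope.

## Synthetic-data generator

The generator emulates the study's inputs on a toy genome (defaults: one
2-Mb and one 1-Mb chromosome) with three non-overlapping zones per
chromosome — blocks (first 60%), background genes (60–85%), and a gene
desert (last 15%) — so planted promoter/distal labels cannot be
contaminated by accident.

* **Blocks**: 12 by default, widths uniform in 40–80 kb, placed
  sequentially with random gaps; one block carries two index SNPs to
  exercise span grouping. Proxy tables place proxies at the exact span
  endpoints with r² = 0.95 (plus a failing r² = 0.5 row per SNP), so block
  reconstruction is exact by design.
* **Peaks and TFBS**: thinned Poisson placement — background rate per kb
  outside blocks, multiplied by θ inside (defaults: 0.05 peaks/kb,
  θ_peak = 5; per-TF site rates 0.2/kb with θ ∈ {5, 1, 0.2} across the
  default five TFs). Widths are uniform in a configurable range. The
  alternative `binwise` mode draws an independent Bernoulli per 100-bp bin
  and emits bin-aligned peaks; under θ = 1 this realizes the *exact* null of
  the binned Fisher test. Interval-mode peaks span several bins, which
  correlates neighbouring bins and makes the raw Fisher test
  anti-conservative under the interval-level null — so calibration claims
  are made (and tested) in binwise mode, while power and direction recovery
  are also exercised on the interval path.
* **Interactions**: planted counts default to 42 unique in-block
  interactions (20 PP / 21 PD / 1 DD), 6 duplicate records (emitted with
  swapped anchor order to exercise canonicalization) and 6 out-of-block
  decoys; the 84 distinct anchors receive a planted histone-category split
  of 66/2/11/5, enforced by rewriting the CD4 peak files around the
  anchors. These defaults mirror the reference study's in-block tallies;
  the genome-wide catalogue size is not reproduced because only in-block
  records survive the first stage.
* **Expression**: FPKM is lognormal (log-mean 1.5, log-sd 1.0 — a
  right-skewed distribution typical of expression data); genes touched by a
  both-marks anchor get a 4× multiplicative shift, emulating the
  qualitative ordering of expression by anchor category.

Identical seeds produce byte-identical bundles (all randomness flows
through one `numpy` Generator; all emitted tables are explicitly sorted).
`table1_scenario()` materializes the packaged 23-block table with one
mid-block peak per Y cell and none per N cell, so annotation reproduces the
printed matrix exactly.

What the generator does **not** emulate: read-level noise, peak-width/shape
distributions of real ChIP-Seq, LD structure derived from population
genetics, correlated TF co-binding, or assembly artefacts. Passing tests
therefore demonstrate the correctness of the interval logic and the
calibration of the statistics under the stated model — not robustness to
real-data idiosyncrasies such as peak-caller bias or cross-assembly errors.

## Problem sizes and numerical choices

Replicate studies in the test suite and acceptance script use a 1-Mb
binwise genome (10,000 bins, ten 8–12-kb blocks, per-bin peak probability
0.05) for the mark-enrichment calibration, and bin-level strata of 20,000
marked background bins (2,000 in-block; per-bin site probability 0.02) for
the TFBS calibration and power studies — sizes chosen so binomial counts
are large enough for the asymptotics being probed while replicate counts
(100–1,000) keep the suite fast. The Fisher oracle is verified exhaustively
over all 2×2 tables with N ≤ 25 and on random tables up to N = 200; full
enumeration of every table to N = 200 is combinatorially out of reach
(~10⁸ tables) and adds nothing beyond the margin classes already covered.

Degenerate inputs are handled by convention rather than exception wherever
a convention is defensible: zero-margin tables → p = 1 flagged; empty
stratum → skipped with a warning; unknown chromosome in a SNP query →
empty set with a warning; duplicate interval records → dropped with a
logged count.

## Known limitations

* Exact-span block grouping will split haplotypes whose proxy sets differ
  by a single variant; that is the recorded convention, not a claim about
  the biology.
* The interval-mode Fisher tests inherit the independence assumption of the
  binned contingency table; with wide features the effective sample size is
  smaller than the bin count and p-values are optimistic. Conclusions on
  real data should lean on effect direction and magnitude, not the p-value
  floor.
* The promoter window is a fixed TSS-anchored rectangle; no
  expression-aware or CAGE-derived promoter definitions are attempted.
* No liftover, tabix, sequence, or peak-calling functionality is included;
  inputs arrive as plain-text BED/BEDPE/TSV on one assembly.
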