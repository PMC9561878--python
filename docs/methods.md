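# Methods

## Overview

`eccatlas` analyzes extrachromosomal circular DNA (eccDNA) in Circle-seq
cohorts. The pipeline has six analysis stages plus a synthetic-data
generator: junction-evidence circle calling from paired-end alignments,
three-tier confidence classification, genomic-context annotation,
cohort-level size/length/consistency statistics, and per-gene differential
abundance between a case group (AIONFH — alcohol-induced osteonecrosis of
the femoral head) and a control group (femoral-neck fracture).

## Circle detection model

A DNA circle excised from reference interval `[s, e)` leaves two read-level
signatures in a linear-reference alignment:

* **Outward-oriented discordant pairs.** A sequencing fragment spanning the
  circle junction places its reverse-strand mate upstream (near `s`) of its
  forward-strand mate (near `e`) — the opposite of the inward FR orientation
  of linear DNA. These pairs localize the junction coarsely: every implied
  interval is contained in the true circle.
* **Soft-clipped (split) reads.** A read crossing the junction aligns with
  its matched block ending exactly at `e` (or starting exactly at `s`); the
  clipped remainder matches the sequence entering the opposite boundary.
  These reads fix the junction at base-pair resolution.

The caller clusters outward pairs (within `cluster_gap_bp`, default 350 bp
≈ insert mean + 3 SD), then refines each candidate by enumerating the
(start, end) pairs voted for by soft-clip positions near the candidate's
two boundaries and keeping the pair with the most *confirming* reads — a
clip of ≥ `clip_match_min_bp` (10 bp) matching the opposite-boundary
sequence with ≤ `clip_mismatch_max` (1) mismatches. Ties break to the
leftmost coordinates for determinism.

Two deliberate extensions keep short circles detectable:

* Circles shorter than ~2 read lengths cannot contain a whole discordant
  fragment, so candidates are *also* seeded from co-located prefix/suffix
  soft-clip clusters alone.
* When only one boundary has clip evidence, the clipped segments are
  realigned (slid base-by-base) across the candidate window to locate the
  other boundary.

A call is emitted only with `n_split + n_discordant >= 2` (two independent
structural read variants, e.g. one split read plus one discordant pair) and
`n_split >= 1` — split support is required because every confidence tier
presupposes it. Support metrics per call: `coverage_fraction` (share of
interval bases with depth ≥ 1) and `cov_increase_start/end`
(`max(0, 1 − flank depth / interior depth)` over 100 bp edge windows,
clamped to [0, 1]; an interior mean of 0 yields 0).

This is a single-fragment, same-chromosome caller: no probabilistic
realignment, no multi-segment or inter-chromosomal circles, no duplicate
marking.

## Confidence tiers

Tiers are nested predicates evaluated per call:

| tier | predicate |
|---|---|
| lconf | split reads ≥ 1 |
| conf  | lconf ∧ coverage_fraction ≥ 0.80 |
| hconf | conf ∧ both edge ratios > 0.5 |

The hconf depth criterion ("region depth more than twice its surroundings")
is operationalized through the edge coverage-increase ratios: a ratio
> 0.5 at a boundary means interior depth is more than twice the flank
depth. An alternative independent genome-mean-depth reading is possible
but is not what the edge metrics measure; the edge-ratio mode is the
default and only built-in mode. Boundary semantics: coverage uses ≥ 0.80,
edges use strict > 0.5. Calls without split support are unclassified and
excluded from tier summaries (with a warning). At cohort level a merged
locus takes the maximum tier any single sample achieved.

## Genomic context

Gene models carry merged exons; introns are the gaps. Each call is
assigned one region class by any-overlap (≥ 1 bp) with precedence
exon > intron > gene_up2k > gene_down2k > intergenic; the 2 kb flanks are
strand-aware (upstream = 5′ of the gene body). Precedence is used because
each circle gets exactly one origin class; it is the simplest total rule.
Per-gene counting increments every overlapped gene (containment mode
available). Chromosome density is circles per Mb against coding genes per
Mb; the correlation is Pearson's r with a two-sided p from the t transform
(n − 2 df), matching the parametric r/p style of the downstream report.
A 50 kb fixed-window scan (`windowed_density`) feeds density tracks.

## Cohort statistics

* **Size classes:** eccDNA ≤ 100 kb < ecDNA, strict at the boundary
  (exactly 100 kb is eccDNA).
* **Length peak:** 1 bp histogram, Gaussian kernel smoothing (bandwidth
  25 bp, config), peak = left edge of the maximal smoothed bin, ties to the
  smaller length. The bandwidth is small enough to preserve a ~358 bp mode
  at cohort scale and large enough to suppress single-bin noise.
* **Locus identity:** calls from different samples are the same eccDNA iff
  chromosomes match and both boundary offsets are within
  `match_tolerance_bp` (default 0 = exact, since no published operational
  definition of "same eccDNA" exists); at tolerance > 0 loci are connected
  components (union-find), represented by their leftmost member.
* **Consistency filter:** keep loci present in ≥ 2 samples of a group.
* **Venn counts:** partition of two consistent-locus sets by identity.
* **Per-gene quantity correlation:** Pearson r between the two groups'
  per-gene totals.

## Differential analysis

Sample columns are total-count scaled to the cohort mean total (the exact
upstream normalization of published tables is unrecoverable; scaling is the
standard simple choice and is switchable off), then averaged per group.
log2FC = log2(case/control) with **substitution** pseudocount: a group mean
that is exactly 0 is replaced by 0.001 before the ratio; nonzero means are
never modified. This is forced by reference tables that print "0.001"
verbatim in the zero group while leaving nonzero means untouched, and it
makes genes absent from one group show |log2FC| ≈ 18–20. Both-zero genes
get NaN and are never significant.

P-values are an exact two-sided Wilcoxon rank-sum: full enumeration of all
C(n₁+n₂, n₁) labelings (group sizes ≤ 8; 3432 labelings at 7 vs 7) of the
midrank sum, p = fraction of labelings at least as extreme as observed; a
seeded Monte-Carlo permutation mode (≥ 10,000 label permutations) and a
tie-corrected normal approximation (groups > 8) are the alternatives. This
deliberately replaces negative-binomial (edgeR-style) testing — dispersion
estimation is out of scope and the output metadata labels the test used.
FDR is Benjamini–Hochberg (statsmodels). Significance = p < 0.05 and
|log2FC| > 1, both strict; direction is the sign of log2FC.

## Synthetic data generator

The generator emulates a two-group Circle-seq cohort at desk scale:

* **Genome:** uniform random nucleotides over 8 default chromosomes of
  110–200 kb (desk-scale stand-ins for the 23 chromosome pairs).
* **Genes:** non-overlapping bodies of 0.5–8 kb (small relative to real
  genes so Poisson-rate counts fit small chromosomes), 1–10 exons, random
  strand; counts Poisson(genes_per_mb × Mb).
* **Circle lengths:** mixture of a lognormal body with mode 358 bp
  (σ = 0.45), a 12% uniform tail (2–50 kb) and an optional ecDNA band
  (100 kb–1 Mb, default fraction 0). Defaults reproduce the three summary
  features reported for femoral-head cohorts — a ~358 bp peak, ~86% of
  circles < 3 kb, and a rare ecDNA class — without asserting a parametric
  truth.
* **Placement:** uniform per chromosome, or proportional to realized gene
  counts when `gene_density_coupling` is on (emulating the positive
  eccDNA/Mb vs genes/Mb correlation).
* **Reads:** junction evidence is written directly as valid soft-clipped
  and outward discordant SAM records (clips copied from the opposite
  boundary sequence), plus uniform concordant background pairs at
  `background_depth` (default 5×); default junction depth 6 splits into
  ~3 split reads and ~3 discordant pairs per circle. Each sample shares a
  30% cohort circle pool (presence probability 0.7) so loci recur across
  samples; the remainder is private.
* A per-gene count simulator (`simulate_gene_counts`) plants multiplicative
  case/control effects on Poisson counts for differential-recovery tests.

What the generator does **not** model: sequencing errors and quality
scores, GC/mappability bias, rolling-circle chimeras, multi-fragment
circles, and any real linkage between circle formation and chromatin
state. Passing recovery tests therefore demonstrate correctness of the
detection logic on clean junction evidence, not performance on real
libraries.

## Determinism and numerical choices

Every stochastic operation is a pure function of (config, seed); derived
seeds come from `numpy.random.SeedSequence` spawns of the global seed and
stay below 2³¹. SAM output is coordinate-sorted with a deterministic
(position, name, flag) sort key, so same-seed runs are byte-identical.
Tie-breaks are always toward the smaller coordinate/length. Degenerate
inputs have defined results: empty depth → edge ratios 0; constant density
vectors → explicit undefined-correlation error; empty locus input at a
cohort tier → error.

## Problem sizes

Default test/report scales: recovery runs use 50 circles over a 0.7 Mb
two-chromosome genome at 5× background (≈ 35k reads, seconds per sample);
length-peak recovery uses 5,000 planted circles; the density sweep uses 40
seeds × 500 circles on 10 chromosomes; the demo pipeline runs 2 × 3–7
samples end-to-end in well under a minute. These sizes give stable
statistics (recall 0.96–1.00; peak within ±15% of 358 bp) while keeping
the whole suite fast.

## Known limitations

* Cohort-scale published counts (hundreds of thousands of circles) are not
  reproducible from synthetic desk-scale data and are not targets; the
  logic that produced them is covered by invariants instead.
* The caller assumes clean flags and a coordinate-sorted SAM; it does not
  rescue circles whose only evidence is ambiguous one-sided clips with
  repetitive flank sequence.
* The exact rank-sum test is discrete: at 7 vs 7 the smallest attainable
  two-sided p is 2/3432 ≈ 5.8e-4, so FDR values on small gene sets are
  coarse.
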