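# Methods

`reachmap` implements a co-localization and gene-regulation analysis for a
chromatin-associated ubiquitin ligase: ChIP peaks are extended into the
genomic neighborhood the ligase can physically reach, the extended regions
are compared against other interval landscapes (a protein-degradation map,
active and repressive histone marks) under a permutation null, target genes
are assigned by TSS proximity, peak sequences are scanned for a consensus
motif, and target-gene sets are tested for expression shifts. This note
records the model, the numerical choices, and what the synthetic data do
and do not establish.

## Coordinate model and interval algebra

All coordinates are 0-based half-open `[start, end)` (BED convention).
Two intervals overlap iff they share at least one base; there is no
minimum-overlap-fraction option. `sort_and_merge` coalesces overlapping
*and abutting* intervals — a merged "region" is a footprint, and abutting
extensions should not create artificial region boundaries. Merging also
fixes the denominators of all downstream fractions: peak-anchored overlap
counts (`n_A_hit`, `frac_A_hit`) are computed on the sets as given, while
base-wise quantities (`bp_intersect`, Jaccard) are always computed on
merged footprints so internal redundancy cannot inflate them.

Replicate consensus supports two rules, because a two-set Venn diagram
does not determine one: `either-anchored-on-A` (replicate-1 peaks that
touch a replicate-2 peak, kept verbatim) and `reciprocal-intersection`
(base-wise intersection of the merged sets). The default is
`either-anchored-on-A`; pipelines echo the mode into their reports.

## Reach-to-flank conversion

A cullin scaffold bridges substrate and conjugating enzyme over a physical
distance R ≈ 100 Å. On solenoidally compacted chromatin, physical distance
maps to linear DNA via the B-DNA helical rise r = 0.34 nm/bp and a fiber
packing ratio κ (dimensionless fold-compaction):

    flank_bp = round(R[Å] · 0.1 nm/Å · κ / r[nm/bp])

κ defaults to 102, the value at which the canonical inputs R = 100 Å and
r = 0.34 nm/bp give a flank of exactly 3,000 bp; it is an explicit,
documented parameter rather than a buried constant because compaction
estimates vary several-fold across fiber models. Rounding is to the
nearest integer base pair. Extension clips at chromosome ends and merges
by default (`merge_after=True`) so that downstream denominators are
unambiguous.

## Permutation null

The null model relocates each query interval uniformly within its own
chromosome, preserving per-chromosome interval counts and the length
multiset ("randomized peaks of equal number and size"). Relocated
intervals may overlap one another by default — the simplest faithful
reading of an intra-chromosomal permutation; a non-overlapping variant
(rejection resampling per chromosome, capped at 1,000 retries) exists for
sensitivity analysis. The query set is permuted and the landscape held
fixed. Fold enrichment is observed / null mean; the empirical p-value is
the add-one estimator (1 + #{null ≥ observed}) / (N + 1) (≤ for the
depletion tail), which cannot be zero and is exact under exchangeability.
N defaults to 1,000; every run requires a seed, and permutation streams
are spawned from a `SeedSequence` so results are reproducible and
independent across permutations. Degenerate cases are flagged rather than
silently coerced: a positive observation against a zero null mean reports
infinite fold with a `null-mean-zero` flag; zero observed and zero null
reports fold 1 with a `zero-signal` flag.

This null preserves neither GC content, mappability, nor distance decay;
covariate-matched shuffles (GAT/regioneR-style) are out of scope.

## 2×2 association testing

`chi2_yates` implements the chi-squared test with Yates' continuity
correction, with the corrected deviation clamped at zero (so perfect
independence gives χ² = 0, p = 1). `mark_association` compares region hit
rates between an active and a repressive mark with rows (hit, not hit)
per mark; the cross-tabulation-of-membership reading degenerates to a
zero margin exactly in the clean planted cases, so the rate-comparison
table is the one reported. Permutation enrichment (vs. the active mark)
and depletion (vs. the repressive mark) are reported alongside the
chi-squared p; the two calibrations answer different questions and
neither replaces the other.

## TSS annotation

Gene models are BED6 with the gene id in the name column; the TSS is the
strand-dependent 5′ end (`start` on `+`, `end − 1` on `−`). Signed
distances are oriented in the gene's reading direction (negative =
upstream). A gene is a target when some peak anchor lies strictly within
`target_max_dist` (default 1,000 bp) of its TSS, on either side — the
window is symmetric because nothing pins it to the upstream side; an
`upstream_only` flag restricts it. Peak anchors default to the interval
midpoint; `summit-if-scored` reads the score column as a summit offset
from the interval start (MACS2 summit-BED style), clipped into the
interval.

Feature categories are assigned with precedence promoter > gene body >
downstream > intergenic. The promoter is 3,000 bp upstream / 0 bp
downstream of the TSS (a CEAS-style convention; exon/intron/UTR
subclassification is out of scope), and the downstream category reuses
the 3,000 bp length past the 3′ end. Both the peak-anchor fractions and
the genome-wide per-base baseline are computed from the same painted
category map, so the two vectors are directly comparable and each sums
to 1. TSS profiles histogram the signed distance to the *nearest* TSS
(ties toward the gene earlier in sorted order) over ±10 kb in 100 bp
half-open bins, normalized to unit in-window mass.

## Expression linkage

The Wilcoxon rank-sum test uses mid-ranks for ties. The p-value is exact
by full enumeration (a subset-sum count over rank assignments) when the
pooled sample is tie-free and C(n_x + n_y, n_x) ≤ 200,000; otherwise a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used. The cutoff and correction are fixed constants for
cross-platform determinism. The gene-set shift test compares target-gene
log2 fold changes against all measured non-target genes by default (an
explicit background set is supported); genes absent from the expression
table are dropped with a logged count. When several gene sets are tested
in one report, Benjamini–Hochberg-adjusted p-values are emitted alongside
the raw ones, labeled.

ddCt quantification treats replicates as unpaired within a condition:
ΔCt per replicate is Ct_gene − mean(Ct_reference in that condition),
ΔΔCt is the condition-mean ΔCt minus the control-condition mean, and
fold = 2^(−ΔΔCt). Dispersion is the SD of replicate ΔCt. By construction
the reference gene and the control condition have fold 1, and a
plate-wide Ct offset in one condition cancels. The two-sample t test is
the pooled-variance (homoscedastic), two-sided version.

## Motif scanning

Motifs are IUPAC consensus strings (default CACGTG, the E-box bound by
the c-MYC/MAX heterodimer); position-weight matrices are a documented
extension point, not implemented. Scanning reports every match start on
both strands, overlaps allowed; an `N` in the sequence never matches; a
palindromic motif is counted once per site, on the forward strand.
Enrichment reuses the intra-chromosomal relocation null — peaks are
relocated and the fixed genome sequence re-scanned — rather than
dinucleotide shuffling, keeping one permutation framework for the whole
package. The statistic is the total hit count (`n_hits`, default) or the
fraction of peaks with ≥ 1 hit. An optional centered window (e.g. 600 bp)
can restrict scanning within large peaks; it is off by default.

## Synthetic data

Generators are pure functions of (config, seed); the global seed fans out
into fixed per-generator substreams, so adding a generator never perturbs
existing fixtures. The default scale — 3 chromosomes × 1 Mb, 300
non-overlapping 2 kb genes, 200 peaks of 200 bp — keeps every analysis in
seconds while leaving the genome sparse enough for exact planted
constructions. Defaults plant: half the peaks within 1 kb of a TSS, a
co-occurring landscape hitting exactly `round(q·n)` peaks (q = 0.5917 by
default), a +0.5 log2FC shift (σ = 0.5) in target genes, and a motif in
every peak. The co-occurrence construction places planted partner
intervals strictly inside internally non-overlapping host peaks and the
remainder uniformly outside the merged peak footprint, then verifies both
directional overlap counts and redraws on the rare failure — so the
planted fraction is recovered *exactly*, not in expectation.

What the synthetic data do not emulate: real chromatin's GC and
mappability structure, peak-width and signal-strength distributions,
clustered TSSs and overlapping transcripts, and read-level noise. Passing
tests therefore demonstrate the correctness and calibration of the
machinery, not field performance on any particular ChIP-seq dataset; the
published overlap percentages for the original study are reproducible
only from the deposited data, and at desk scale the planted-overlap
constructions stand in for them.

## Problem sizes and determinism

The shipped analyses use the toy scale above: permutation runs use
N = 99–1,000 permutations, null-calibration studies use 100–200 replicate
simulations, and type-I-error studies 500 simulations. All results are
deterministic given the config seed; reports embed the effective config.

## Known limitations

- The permutation null ignores sequence covariates (see above).
- Consensus-motif matching cannot grade partial sites; a PWM scanner
  would.
- `feature_distribution` paints full per-base maps, which is exact but
  memory-proportional to genome length — suitable for toy and
  chromosome-arm scale, not for a full mammalian genome in one pass.
- ddCt assumes perfect amplification efficiency (the textbook 2^(−ΔΔCt)
  model).
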