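# reachmap

Co-localization and gene-regulation analysis for chromatin-associated
ubiquitin ligases.

Cullin-RING ubiquitin ligases are rigid scaffolds that can ubiquitinate
substrates over a physical reach of ~100 Å. When such a ligase sits on
chromatin, that reach covers far more than its ChIP peak: on the compacted
fiber, 100 Å of physical distance corresponds to roughly 3,000 bp of linear
DNA. `reachmap` turns this observation into a reusable pipeline for anyone
analyzing where a DNA-tethered enzyme can act:

- **Reach extension** — convert a physical bridging distance R into a
  genomic flank, `flank = round(R·0.1·κ/r)` with helical rise
  r = 0.34 nm/bp and fiber packing ratio κ = 102, and extend peaks into
  "regions under ligase control".
- **Interval algebra** — BED/chrom.sizes I/O, sort/merge/intersect,
  peak-anchored and base-wise overlap statistics, replicate consensus.
- **Permutation-calibrated co-localization** — an intra-chromosomal
  permutation null (randomized peaks of equal number and size within each
  chromosome) yielding fold enrichment and empirical p-values, plus the
  2×2 chi-squared test with Yates' correction.
- **TSS annotation** — strand-aware signed peak-to-TSS distances,
  target-gene assignment (|distance| < 1 kb), promoter/gene-body/
  downstream/intergenic feature distributions with a genome-wide
  baseline, and TSS-relative density profiles.
- **Motif scanning** — IUPAC consensus scanning (default: the E-box
  CACGTG of the c-MYC/MAX heterodimer) with a peak-relocation null.
- **Expression linkage** — Wilcoxon rank-sum shift tests of target gene
  sets (exact by enumeration when feasible), ΔΔCt qPCR quantification
  (fold = 2^(−ΔΔCt) against a reference transcript), and the pooled
  two-sample t test.
- **Synthetic data** — generators with planted, exactly known structure
  (overlap fractions, TSS proximity, expression shifts, motifs, qPCR
  folds) so the full pipeline is testable without any download.

## Worked example

```python
from reachmap import ReachParams, reach_to_bp, overlap_stats
from reachmap.synthetic_data import (SyntheticConfig, simulate_genome,
    simulate_genes, simulate_peaks, simulate_cooccurring_peaks,
    simulate_expression)
from reachmap.reach_extension import extend_intervals
from reachmap.colocalization_stats import PermutationConfig, fold_enrichment
from reachmap.tss_annotation import assign_target_genes
from reachmap.expression_link import gene_set_shift_test

params = ReachParams()  # R = 100 A, r = 0.34 nm/bp, kappa = 102
print("flank:", reach_to_bp(params), "bp")

cfg = SyntheticConfig(seed=1, n_peaks=120)   # 3 x 1 Mb genome, 300 genes
genome, _ = simulate_genome(cfg)
genes = simulate_genes(genome, cfg)
peaks = simulate_peaks(genome, genes, cfg)
landscape = simulate_cooccurring_peaks(peaks, genome, cfg)

regions = extend_intervals(peaks, params.flank_bp, genome)
print("regions:", len(regions), "covering", regions.total_bp, "bp")

ov = overlap_stats(peaks, landscape)
print(f"peak overlap: {100 * ov.frac_A_hit:.2f}%")

enr = fold_enrichment(regions, landscape, genome,
                      PermutationConfig(seed=7, n_perm=999))
print(f"fold enrichment: {enr.fold_enrichment:.2f}, p = {enr.p_empirical:.3g}")

targets, _ = assign_target_genes(peaks, genes)
expr = simulate_expression(genes, targets, cfg)
shift = gene_set_shift_test(expr, targets, alternative="greater")
print(f"{len(targets)} target genes, shift p = {shift.test.p_value:.3g} "
      f"({shift.direction})")
```

prints

```
flank: 3000 bp
regions: 91 covering 637742 bp
peak overlap: 59.17%
fold enrichment: 2.78, p = 0.001
66 target genes, shift p = 2.07e-08 (up)
```

Reading the numbers: the 120 simulated peaks merge into 91 extended
regions once each is widened by the 3 kb reach flank. The co-occurring
landscape was planted to overlap a fraction q = 0.5917 of the peaks, and
the peak-anchored overlap recovers exactly that (71/120 = 59.17%). The
extended regions are ~2.8-fold enriched for the landscape relative to
randomly relocated regions of equal number and size (the smallest
empirical p at 999 permutations is 1/1000). Of the 300 genes, 66 have a
peak within 1 kb of their TSS; their planted +0.5 log2FC upregulation is
detected by the one-sided rank-sum test.

A `reachmap` command-line tool mirrors the library (`reachmap extend`,
`enrich`, `annotate`, `profile`, `shift-test`, `ddct`, `motif`,
`simulate`, `run`); `reachmap run --config analysis.yaml` executes the
whole pipeline and writes `report.json` plus BED/TSV artifacts.

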