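"""Synthetic genomes, gene models, peak sets, sequences and assay tables
with planted, known structure.

Every generator is a pure function of (config, seed): a single global seed
fans out into independent per-generator substreams, so adding a generator
never perturbs the fixtures produced by another. The planted parameters —
the fraction of peaks near TSSs, the exact co-overlap fraction between two
peak sets, the expression shift of a target gene set, per-peak motif
planting, qPCR fold changes — make every pipeline stage testable without
any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .interval_core import GenomeDef, IntervalSet, overlap_stats, sort_and_merge, write_bed
from .motif_scan import MotifDef, scan_consensus
from .tss_annotation import GENE_COLUMNS, GeneSet

__all__ = [
    "SyntheticConfig",
    "simulate_genome",
    "simulate_genes",
    "simulate_peaks",
    "simulate_cooccurring_peaks",
    "simulate_expression",
    "plant_motifs",
    "simulate_ct",
    "write_dataset",
]

# substream ids: stable, append-only
_STREAMS = {
    "genome": 0,
    "genes": 1,
    "peaks": 2,
    "cooccur": 3,
    "expression": 4,
    "motif": 5,
    "ct": 6,
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults give the toy scale used by
    all desk-size analyses (3 chromosomes x 1 Mb, 300 genes, 200 peaks)."""

    seed: int
    n_chrom: int = 3
    chrom_lengths: Optional[Sequence[int]] = None  # default 1 Mb each
    n_genes: int = 300
    gene_length: int = 2000
    n_peaks: int = 200
    peak_length: tuple = ("fixed", 200)  # or ("uniform", L1, L2)
    tss_fraction: float = 0.5
    target_max_dist: int = 1000
    co_overlap_fraction: float = 0.5917
    lfc_shift: float = 0.5
    lfc_sigma: float = 0.5
    motif_prob: float = 1.0
    gc: float = 0.5

    def __post_init__(self) -> None:
        if self.chrom_lengths is None:
            self.chrom_lengths = [1_000_000] * self.n_chrom
        self.chrom_lengths = [int(x) for x in self.chrom_lengths]
        if len(self.chrom_lengths) != self.n_chrom:
            raise ValueError("chrom_lengths must have n_chrom entries")
        if any(x < 1 for x in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        for f in (self.tss_fraction, self.co_overlap_fraction, self.motif_prob, self.gc):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )


def _sample_lengths(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    if spec[0] == "fixed":
        return np.full(n, int(spec[1]), dtype=np.int64)
    if spec[0] == "uniform":
        return rng.integers(int(spec[1]), int(spec[2]) + 1, size=n)
    raise ValueError(f"unknown peak length distribution {spec!r}")


def simulate_genome(config: SyntheticConfig) -> tuple[GenomeDef, dict[str, str]]:
    """i.i.d.-nucleotide chromosomes at the configured GC content."""
    if config.n_chrom < 1:
        raise ValueError("need at least one chromosome")
    rng = config.rng("genome")
    genome = GenomeDef(
        [(f"chr{i + 1}", L) for i, L in enumerate(config.chrom_lengths)]
    )
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {
        name: alphabet[rng.choice(4, size=L, p=p)].tobytes().decode("ascii")
        for name, L in genome.chromosomes
    }
    return genome, seqs


def _spread_counts(rng: np.random.Generator, weights: np.ndarray, n: int) -> np.ndarray:
    return rng.multinomial(n, weights / weights.sum())


def simulate_genes(genome: GenomeDef, config: SyntheticConfig) -> pd.DataFrame:
    """Non-overlapping, uniformly placed genes with random strands."""
    rng = config.rng("genes")
    lengths = np.array([L for _, L in genome.chromosomes], dtype=float)
    counts = _spread_counts(rng, lengths, config.n_genes)
    rows = []
    gid = 0
    g = config.gene_length
    for (name, L), k in zip(genome.chromosomes, counts):
        if k == 0:
            continue
        free = L - k * g
        if free < 0:
            raise ValueError(f"cannot pack {k} genes of {g} bp on {name} ({L} bp)")
        # k distinct offsets in the gap space, sorted, then shifted by the
        # cumulative gene footprint: exact uniform non-overlapping placement
        offsets = np.sort(rng.choice(free + 1, size=k, replace=False))
        starts = offsets + np.arange(k) * g
        strands = rng.choice(np.array(["+", "-"], dtype=object), size=k)
        for s, strand in zip(starts, strands):
            gid += 1
            start, end = int(s), int(s) + g
            tss = start if strand == "+" else end - 1
            tes = end - 1 if strand == "+" else start
            rows.append((f"gene{gid:04d}", name, start, end, strand, tss, tes))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def simulate_peaks(
    genome: GenomeDef, genes: pd.DataFrame, config: SyntheticConfig
) -> IntervalSet:
    """Peaks of which a ``tss_fraction`` share is centered strictly within
    ``target_max_dist`` of a randomly chosen TSS, the remainder uniform."""
    rng = config.rng("peaks")
    n_tss = int(round(config.tss_fraction * config.n_peaks))
    if n_tss > 0 and len(genes) == 0:
        raise ValueError("tss_fraction > 0 requires genes")
    lens = _sample_lengths(rng, config.peak_length, config.n_peaks)
    chroms: list[str] = []
    starts: list[int] = []
    d = config.target_max_dist
    for i in range(n_tss):
        row = genes.iloc[int(rng.integers(0, len(genes)))]
        L = genome.length(row["chrom"])
        half = int(lens[i]) // 2
        lo = max(half, int(row["tss"]) - (d - 1))
        hi = min(L - int(lens[i]) + half, int(row["tss"]) + (d - 1))
        mid = int(rng.integers(lo, hi + 1)) if lo <= hi else min(max(int(row["tss"]), half), L - int(lens[i]) + half)
        chroms.append(str(row["chrom"]))
        starts.append(mid - half)
    weights = np.array([L for _, L in genome.chromosomes], dtype=float)
    bg = _spread_counts(rng, weights, config.n_peaks - n_tss)
    j = n_tss
    for (name, L), k in zip(genome.chromosomes, bg):
        for _ in range(int(k)):
            chroms.append(name)
            starts.append(int(rng.integers(0, L - int(lens[j]) + 1)))
            j += 1
    names = [f"peak{i + 1:04d}" for i in range(config.n_peaks)]
    return IntervalSet(
        chroms,
        starts,
        np.asarray(starts, dtype=np.int64) + lens,
        names=names,
        genome=genome,
    )


def simulate_cooccurring_peaks(
    base: IntervalSet,
    genome: GenomeDef,
    config: SyntheticConfig,
    n_b: Optional[int] = None,
    max_attempts: int = 50,
) -> IntervalSet:
    """A second peak set B planted so that exactly ``round(q * n_A)`` base
    intervals overlap at least one B interval.

    ``round(q * n_A)`` B intervals are placed strictly inside distinct base
    intervals; the remaining B intervals are placed uniformly avoiding the
    merged base footprint. The construction is verified (both frac_A_hit
    and frac_B_hit exact) and re-drawn on the rare failure.
    """
    q = config.co_overlap_fraction
    n_a = len(base)
    if n_a == 0:
        raise ValueError("empty base set")
    n_b = n_a if n_b is None else int(n_b)
    k = int(round(q * n_a))
    if k > n_b:
        raise ValueError("co_overlap_fraction demands more planted B than n_b")
    merged = sort_and_merge(base)
    # hosts must not overlap any other base interval, else planting inside
    # one would make additional base intervals count as hit
    isolated = np.nonzero(~_self_overlap_mask(base))[0]
    if len(isolated) < k:
        raise RuntimeError(
            f"only {len(isolated)} of {n_a} base intervals are free of "
            f"internal overlap; cannot plant {k} exact hits"
        )
    rng = config.rng("cooccur")
    for _ in range(max_attempts):
        lens = _sample_lengths(rng, config.peak_length, n_b)
        hosts = rng.choice(isolated, size=k, replace=False)
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        for i, h in enumerate(hosts):
            hs, he = int(base.starts[h]), int(base.ends[h])
            bl = min(int(lens[i]), he - hs)
            chroms.append(str(base.chroms[h]))
            s = int(rng.integers(hs, he - bl + 1))
            starts.append(s)
            ends.append(s + bl)
        ok = True
        for i in range(k, n_b):
            bl = int(lens[i])
            for _try in range(200):
                ci = int(rng.integers(0, len(genome)))
                cname, L = genome.chromosomes[ci]
                if bl > L:
                    continue
                s = int(rng.integers(0, L - bl + 1))
                cand = _overlaps_any(merged, cname, s, s + bl)
                if not cand:
                    chroms.append(cname)
                    starts.append(s)
                    ends.append(s + bl)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        B = IntervalSet(
            chroms,
            starts,
            ends,
            names=[f"b{i + 1:04d}" for i in range(n_b)],
            genome=genome,
        )
        ov = overlap_stats(base, B)
        if ov.n_A_hit == k and ov.n_B_hit == k:
            return B
    raise RuntimeError(
        "could not realize the exact planted overlap fraction; base intervals "
        "may be internally overlapping or the genome too crowded"
    )


def _self_overlap_mask(iset: IntervalSet) -> np.ndarray:
    """True where an interval overlaps at least one *other* interval."""
    mask = np.zeros(len(iset), dtype=bool)
    for _, ix in iset.groupby_chrom().items():
        order = ix[np.argsort(iset.starts[ix], kind="stable")]
        s, e = iset.starts[order], iset.ends[order]
        for i in range(len(order)):
            j = i + 1
            while j < len(order) and s[j] < e[i]:
                mask[order[i]] = mask[order[j]] = True
                j += 1
    return mask


def _overlaps_any(merged: IntervalSet, chrom: str, start: int, end: int) -> bool:
    groups = merged.groupby_chrom()
    if chrom not in groups:
        return False
    ix = groups[chrom]
    ms, me = merged.starts[ix], merged.ends[ix]
    pos = int(np.searchsorted(ms, end, side="left"))
    return pos > 0 and me[pos - 1] > start


def simulate_expression(
    genes: pd.DataFrame, targets: GeneSet, config: SyntheticConfig
) -> pd.DataFrame:
    """Background log2FC ~ N(0, sigma); target genes ~ N(shift, sigma)."""
    rng = config.rng("expression")
    gids = genes["gene_id"].astype(str)
    is_t = gids.isin(targets.gene_ids).to_numpy()
    lfc = rng.normal(0.0, config.lfc_sigma, size=len(gids))
    lfc[is_t] += config.lfc_shift
    return pd.DataFrame({"gene_id": gids, "log2fc": lfc})


def plant_motifs(
    seqs: Mapping[str, str],
    peaks: IntervalSet,
    motif: MotifDef,
    config: SyntheticConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write the motif consensus at a random offset inside each peak with
    probability ``motif_prob``; returns the edited sequences and the
    bookkeeping of planted (chrom, position) sites."""
    cons = motif.consensus
    if set(cons) - set("ACGT"):
        raise ValueError("planting requires a concrete (ACGT-only) consensus")
    rng = config.rng("motif")
    edited = {c: bytearray(s, "ascii") for c, s in seqs.items()}
    planted = []
    m = len(cons)
    for i in range(len(peaks)):
        s, e = int(peaks.starts[i]), int(peaks.ends[i])
        if e - s < m:
            raise ValueError("motif longer than a peak")
        if rng.random() >= config.motif_prob:
            continue
        pos = int(rng.integers(s, e - m + 1))
        c = str(peaks.chroms[i])
        edited[c][pos : pos + m] = cons.encode("ascii")
        planted.append({"chrom": c, "pos": pos, "peak_index": i})
    return (
        {c: bytes(b).decode("ascii") for c, b in edited.items()},
        pd.DataFrame(planted, columns=["chrom", "pos", "peak_index"]),
    )


def simulate_ct(
    genes: Sequence[str],
    conditions: Sequence[str],
    ref_gene: str,
    fold_map: Mapping[str, Mapping[str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    baseline_ct: float = 20.0,
) -> pd.DataFrame:
    """Replicate Ct values encoding known fold changes.

    ``fold_map[gene][condition]`` is the true fold relative to the control
    condition; missing entries default to 1. Ct = per-gene baseline
    - log2(fold) + N(0, noise_sd) per replicate. The reference gene must
    have fold 1 everywhere. With noise_sd = 0, the ddCt procedure recovers
    the fold map exactly.
    """
    if ref_gene not in genes:
        raise ValueError("reference gene must be among the simulated genes")
    for cond in conditions:
        if float(fold_map.get(ref_gene, {}).get(cond, 1.0)) != 1.0:
            raise ValueError("reference gene fold must be 1 in every condition")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS["ct"]]))
    rows = []
    for gi, gene in enumerate(genes):
        base = baseline_ct + 0.5 * gi  # distinct, stable per-gene baselines
        for cond in conditions:
            fold = float(fold_map.get(gene, {}).get(cond, 1.0))
            if fold <= 0:
                raise ValueError("fold changes must be positive")
            mu = base - np.log2(fold)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "condition": cond,
                        "gene": gene,
                        "replicate": rep,
                        "ct": mu + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                    }
                )
    return pd.DataFrame(rows)


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(outdir, config: SyntheticConfig, motif: Optional[MotifDef] = None) -> dict:
    """Emit a complete synthetic study directory plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    motif = motif or MotifDef()
    genome, seqs = simulate_genome(config)
    genes = simulate_genes(genome, config)
    peaks_a = simulate_peaks(genome, genes, config)
    peaks_b = simulate_cooccurring_peaks(peaks_a, genome, config)
    from .tss_annotation import AnnotationParams, assign_target_genes

    targets, _ = assign_target_genes(
        peaks_a, genes, AnnotationParams(target_max_dist=config.target_max_dist)
    )
    expr = simulate_expression(genes, targets, config)
    seqs, planted = plant_motifs(seqs, peaks_a, motif, config)
    genes_ct = ["RPS14", "SNRPA1", "PHB2"]
    fold_map = {"SNRPA1": {"KD": 2.0}, "PHB2": {"KD": 1.5}}
    ct = simulate_ct(
        genes_ct, ["CTRL", "KD"], "RPS14", fold_map, noise_sd=0.1, seed=config.seed
    )

    with open(outdir / "genome.chrom.sizes", "w") as fh:
        for name, L in genome.chromosomes:
            fh.write(f"{name}\t{L}\n")
    write_fasta(seqs, outdir / "genome.fa")
    genes_bed = genes.copy()
    with open(outdir / "genes.bed", "w") as fh:
        for g in genes_bed.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    write_bed(peaks_a, outdir / "peaksA.bed")
    write_bed(peaks_b, outdir / "peaksB.bed")
    expr.to_csv(outdir / "expr.tsv", sep="\t", index=False)
    ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)
    truth = {
        "seed": config.seed,
        "n_peaks": config.n_peaks,
        "tss_fraction": config.tss_fraction,
        "co_overlap_fraction": config.co_overlap_fraction,
        "planted_overlap_count": int(round(config.co_overlap_fraction * len(peaks_a))),
        "lfc_shift": config.lfc_shift,
        "lfc_sigma": config.lfc_sigma,
        "motif_prob": config.motif_prob,
        "motif": motif.consensus,
        "n_planted_motifs": int(len(planted)),
        "n_target_genes": len(targets),
        "ct_fold_map": {g: dict(v) for g, v in fold_map.items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
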