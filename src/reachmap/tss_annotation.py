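"""Gene models, TSS-proximity target assignment, feature distributions and
TSS-relative peak density profiles.

Gene models are BED6 records whose name column carries the gene id; the TSS
is the strand-dependent 5' end (``start`` on ``+``, ``end - 1`` on ``-``).
Signed peak-to-TSS distances are oriented in the gene's reading direction:
negative = upstream of the TSS, positive = downstream. A gene is a target
of a peak set when some peak anchor lies strictly within ``target_max_dist``
of its TSS (default < 1 kb, on either side).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .colocalization_stats import ContingencyResult, chi2_yates
from .interval_core import GenomeDef, Interval, IntervalSet

__all__ = [
    "GeneModel",
    "AnnotationParams",
    "GeneSet",
    "read_gene_models",
    "gene_table_from_records",
    "signed_tss_distance",
    "peak_anchors",
    "assign_target_genes",
    "feature_distribution",
    "FeatureDistribution",
    "tss_profile",
    "TssProfile",
    "gene_set_overlap_test",
]

logger = logging.getLogger(__name__)

FEATURE_CATEGORIES = ("promoter", "gene_body", "downstream", "intergenic")
# per-base category codes, painted in increasing precedence
_CAT_INTERGENIC, _CAT_DOWNSTREAM, _CAT_BODY, _CAT_PROMOTER = 0, 1, 2, 3
_CODE_TO_NAME = {
    _CAT_PROMOTER: "promoter",
    _CAT_BODY: "gene_body",
    _CAT_DOWNSTREAM: "downstream",
    _CAT_INTERGENIC: "intergenic",
}


@dataclass(frozen=True)
class GeneModel:
    """A gene as an oriented genomic interval with derived TSS/TES."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class AnnotationParams:
    """Windows governing target assignment, promoter definition and profiles.

    target_max_dist
        Strict upper bound (bp) on |anchor - TSS| for target-gene calls.
    promoter_upstream / promoter_downstream
        Promoter window relative to the TSS in gene orientation; also the
        length of the post-TES "downstream" category window.
    profile_window / profile_bin
        Half-width and bin size of the TSS-relative density histogram;
        the bin must divide the full window.
    anchor
        "midpoint" or "summit-if-scored" (score read as summit offset from
        the interval start when present).
    """

    target_max_dist: int = 1000
    promoter_upstream: int = 3000
    promoter_downstream: int = 0
    profile_window: int = 10000
    profile_bin: int = 100
    anchor: str = "midpoint"

    def __post_init__(self) -> None:
        for v in (
            self.target_max_dist,
            self.promoter_upstream,
            self.promoter_downstream,
            self.profile_window,
            self.profile_bin,
        ):
            if v < 0:
                raise ValueError("annotation windows must be >= 0")
        if self.profile_bin == 0 or (2 * self.profile_window) % self.profile_bin:
            raise ValueError("profile_bin must divide 2 * profile_window")
        if self.anchor not in ("midpoint", "summit-if-scored"):
            raise ValueError(f"unknown anchor rule {self.anchor!r}")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids."""

    name: str
    gene_ids: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, ids) -> "GeneSet":
        return cls(name=name, gene_ids=frozenset(str(g) for g in ids))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gid: str) -> bool:
        return gid in self.gene_ids


GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss", "tes"]


def gene_table_from_records(records, genome: Optional[GenomeDef] = None) -> pd.DataFrame:
    """Build the canonical gene table from GeneModel records."""
    rows = []
    seen: set[str] = set()
    for g in records:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
        rows.append((g.gene_id, g.chrom, g.start, g.end, g.strand, g.tss, g.tes))
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if genome is not None and len(df):
        known = df["chrom"].map(lambda c: c in genome)
        n_drop = int((~known).sum())
        if n_drop:
            logger.warning("dropping %d genes on unknown chromosomes", n_drop)
            df = df[known].reset_index(drop=True)
    return df


def read_gene_models(path, genome: Optional[GenomeDef] = None) -> pd.DataFrame:
    """Read gene models from BED6 (name column = gene id, strand required)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: gene models need BED6")
            if f[5] not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: gene strand must be + or -, got {f[5]!r}"
                )
            records.append(
                GeneModel(
                    gene_id=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]), strand=f[5]
                )
            )
    return gene_table_from_records(records, genome=genome)


def peak_anchors(peaks: IntervalSet, params: AnnotationParams) -> np.ndarray:
    """Anchor coordinate of every peak under the configured rule."""
    mid = (peaks.starts + peaks.ends) // 2
    if params.anchor == "midpoint" or peaks.scores is None:
        return mid
    anchors = mid.copy()
    for i, sc in enumerate(peaks.scores):
        if sc is None:
            continue
        summit = peaks.starts[i] + int(sc)
        anchors[i] = min(max(summit, peaks.starts[i]), peaks.ends[i] - 1)
    return anchors


def signed_tss_distance(
    peak: Interval, gene: GeneModel, anchor: str = "midpoint"
) -> int:
    """Signed distance of a peak anchor to a gene's TSS.

    Negative = upstream (5' of the TSS in gene orientation), positive =
    downstream, 0 = exactly at the TSS.
    """
    if peak.chrom != gene.chrom:
        raise ValueError("peak and gene are on different chromosomes")
    a = (peak.start + peak.end) // 2
    if anchor == "summit-if-scored" and peak.score is not None:
        a = min(max(peak.start + int(peak.score), peak.start), peak.end - 1)
    d = a - gene.tss
    return int(d if gene.strand == "+" else -d)


def assign_target_genes(
    peaks: IntervalSet,
    genes: pd.DataFrame,
    params: Optional[AnnotationParams] = None,
    upstream_only: bool = False,
) -> tuple[GeneSet, pd.DataFrame]:
    """Genes with a peak anchor strictly within ``target_max_dist`` of the TSS.

    Returns the target :class:`GeneSet` and an assignment table listing every
    qualifying (peak, gene, signed distance) pair — a peak may hit several
    genes and a gene may collect several peaks.
    """
    params = params or AnnotationParams()
    if len(genes) == 0:
        raise ValueError("empty gene table")
    anchors = peak_anchors(peaks, params)
    pairs: list[tuple[str, str, int]] = []
    gene_by_chrom = {c: sub for c, sub in genes.groupby("chrom", sort=False)}
    for c, ix in peaks.groupby_chrom().items():
        if c not in gene_by_chrom:
            continue
        sub = gene_by_chrom[c]
        tss = sub["tss"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        gids = sub["gene_id"].to_numpy()
        a = anchors[ix]
        diff = a[:, None] - tss[None, :]
        signed = np.where(plus[None, :], diff, -diff)
        mask = np.abs(signed) < params.target_max_dist
        if upstream_only:
            mask &= signed <= 0
        pi, gi = np.nonzero(mask)
        for p, g in zip(pi, gi):
            idx = int(ix[p])
            pname = (
                peaks.names[idx]
                if peaks.names is not None and peaks.names[idx] is not None
                else f"peak_{idx}"
            )
            pairs.append((str(pname), str(gids[g]), int(signed[p, g])))
    table = pd.DataFrame(pairs, columns=["peak", "gene_id", "distance"])
    return GeneSet.from_iterable("targets", table["gene_id"]), table


def _category_maps(
    genes: pd.DataFrame, genome: GenomeDef, params: AnnotationParams
) -> dict[str, np.ndarray]:
    """Per-base category code arrays, painted in increasing precedence."""
    maps = {c: np.zeros(L, dtype=np.uint8) for c, L in genome.chromosomes}
    up, down = params.promoter_upstream, params.promoter_downstream

    def paint(chrom, lo, hi, code):
        L = genome.length(chrom)
        lo, hi = max(int(lo), 0), min(int(hi), L)
        if hi > lo:
            m = maps[chrom]
            seg = m[lo:hi]
            seg[seg < code] = code

    for g in genes.itertuples(index=False):
        if g.chrom not in maps:
            continue
        if g.strand == "+":
            paint(g.chrom, g.end, g.end + up, _CAT_DOWNSTREAM)
        else:
            paint(g.chrom, g.start - up, g.start, _CAT_DOWNSTREAM)
        paint(g.chrom, g.start, g.end, _CAT_BODY)
        if g.strand == "+":
            paint(g.chrom, g.tss - up, g.tss + down, _CAT_PROMOTER)
        else:
            paint(g.chrom, g.tss - down + 1, g.tss + up + 1, _CAT_PROMOTER)
    return maps


@dataclass(frozen=True)
class FeatureDistribution:
    """Peak-anchor category fractions and the genome-wide bp baseline."""

    peak_fractions: dict
    genome_fractions: dict
    n_peaks: int

    def to_dict(self) -> dict:
        return {
            "peak_fractions": dict(self.peak_fractions),
            "genome_fractions": dict(self.genome_fractions),
            "n_peaks": self.n_peaks,
        }


def feature_distribution(
    peaks: IntervalSet,
    genes: pd.DataFrame,
    genome: Optional[GenomeDef] = None,
    params: Optional[AnnotationParams] = None,
) -> FeatureDistribution:
    """Classify peak anchors into promoter / gene body / downstream /
    intergenic (in that precedence) and report the genome-wide bp fraction
    of each category as the "overall genomic prevalence" baseline.
    """
    params = params or AnnotationParams()
    genome = genome if genome is not None else peaks.genome
    if genome is None:
        raise ValueError("a genome is required")
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    maps = _category_maps(genes, genome, params)
    anchors = peak_anchors(peaks, params)
    codes = np.array(
        [maps[str(c)][a] for c, a in zip(peaks.chroms, anchors)], dtype=np.uint8
    )
    peak_counts = np.bincount(codes, minlength=4)
    genome_counts = np.zeros(4, dtype=np.int64)
    for m in maps.values():
        genome_counts += np.bincount(m, minlength=4)
    peak_frac = peak_counts / peak_counts.sum()
    genome_frac = genome_counts / genome_counts.sum()
    order = [_CAT_PROMOTER, _CAT_BODY, _CAT_DOWNSTREAM, _CAT_INTERGENIC]
    return FeatureDistribution(
        peak_fractions={_CODE_TO_NAME[c]: float(peak_frac[c]) for c in order},
        genome_fractions={_CODE_TO_NAME[c]: float(genome_frac[c]) for c in order},
        n_peaks=len(peaks),
    )


@dataclass(frozen=True)
class TssProfile:
    """Binned density of signed anchor-to-nearest-TSS distances."""

    bin_left: np.ndarray
    bin_center: np.ndarray
    density: np.ndarray
    n_in_window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_center, "density": self.density})


def nearest_tss_distances(
    peaks: IntervalSet, genes: pd.DataFrame, params: Optional[AnnotationParams] = None
) -> np.ndarray:
    """Signed distance of each peak anchor to its nearest TSS (NaN when the
    peak's chromosome carries no gene). Ties in |distance| break toward the
    gene earlier in (chrom, start, gene_id) sorted order."""
    params = params or AnnotationParams()
    anchors = peak_anchors(peaks, params)
    out = np.full(len(peaks), np.nan)
    gs = genes.sort_values(["chrom", "start", "gene_id"], kind="stable")
    gene_by_chrom = {c: sub for c, sub in gs.groupby("chrom", sort=False)}
    for c, ix in peaks.groupby_chrom().items():
        if c not in gene_by_chrom:
            continue
        sub = gene_by_chrom[c]
        tss = sub["tss"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        a = anchors[ix]
        diff = a[:, None] - tss[None, :]
        signed = np.where(plus[None, :], diff, -diff)
        best = np.argmin(np.abs(signed), axis=1)  # first minimum = earlier gene
        out[ix] = signed[np.arange(len(ix)), best]
    return out


def tss_profile(
    peaks: IntervalSet, genes: pd.DataFrame, params: Optional[AnnotationParams] = None
) -> TssProfile:
    """Histogram of signed nearest-TSS distances over [-window, +window),
    half-open bins, normalized to unit mass over the window."""
    params = params or AnnotationParams()
    w, b = params.profile_window, params.profile_bin
    edges = np.arange(-w, w + b, b)
    d = nearest_tss_distances(peaks, genes, params)
    d = d[~np.isnan(d)]
    in_window = d[(d >= -w) & (d < w)]
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    if len(in_window):
        idx = ((in_window + w) // b).astype(int)
        np.add.at(counts, idx, 1)
        density = counts / counts.sum()
    else:
        warnings.warn("no peak anchor within the profile window of any TSS")
        density = counts.astype(float)
    return TssProfile(
        bin_left=edges[:-1],
        bin_center=edges[:-1] + b / 2.0,
        density=density,
        n_in_window=int(counts.sum()),
    )


def gene_set_overlap_test(
    targets_a: GeneSet, targets_b: GeneSet, universe: GeneSet
) -> tuple[ContingencyResult, float]:
    """Association of two target-gene sets over a declared gene universe.

    Returns the Yates chi-squared on the 2x2 membership table (in A x in B)
    and the overlap fraction |A ∩ B| / |A|.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    if len(targets_a) == 0 or len(targets_b) == 0:
        raise ValueError("empty gene set")
    A = targets_a.gene_ids & universe.gene_ids
    B = targets_b.gene_ids & universe.gene_ids
    if A != targets_a.gene_ids or B != targets_b.gene_ids:
        raise ValueError("gene sets must be subsets of the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(universe) - a - b - c
    return chi2_yates(a, b, c, d), a / len(A)
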