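"""IUPAC consensus motif scanning and relocation-null motif enrichment.

The scanner matches a degenerate consensus (default: the E-box CACGTG bound
by the c-MYC/MAX heterodimer) on both strands, overlaps allowed; an ``N`` in
the sequence never matches. Palindromic motifs are reported once per
position, on the forward strand. Enrichment within peaks is calibrated by
relocating the peaks within their chromosomes (the same intra-chromosomal
permutation null used for interval co-localization) and re-scanning the
fixed genome sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

from .colocalization_stats import (
    PermutationConfig,
    PermutationResult,
    _summarize_null,
    permute_intrachrom,
)
from .interval_core import GenomeDef, IntervalSet

__all__ = ["MotifDef", "scan_consensus", "motif_enrichment", "reverse_complement"]

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    """An IUPAC consensus motif; palindromy is derived, not declared."""

    consensus: str = "CACGTG"
    name: str = "E-box"

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        if not cons:
            raise ValueError("empty consensus")
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)}")
        object.__setattr__(self, "consensus", cons)

    @property
    def palindromic(self) -> bool:
        return reverse_complement(self.consensus) == self.consensus

    def __len__(self) -> int:
        return len(self.consensus)

    def regex(self, reverse: bool = False) -> re.Pattern:
        cons = reverse_complement(self.consensus) if reverse else self.consensus
        # sequence N never matches, so the classes exclude it by construction
        return re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in cons) + "))")


def scan_consensus(sequence: str, motif: MotifDef) -> list[tuple[int, str]]:
    """All motif match start positions on both strands, overlaps allowed.

    Palindromic motifs are reported once per site, on the forward strand.
    Returns (position, strand) pairs sorted by position.
    """
    seq = sequence.upper()
    if set(seq) - {"A", "C", "G", "T", "N"}:
        raise ValueError("sequence must be over {A, C, G, T, N}")
    hits = [(m.start(), "+") for m in motif.regex().finditer(seq)]
    if not motif.palindromic:
        hits += [(m.start(), "-") for m in motif.regex(reverse=True).finditer(seq)]
    return sorted(hits)


def _fetch(seqs, chrom: str, start: int, end: int) -> str:
    """Sequence slice from a dict of strings or a pyfaidx.Fasta-like object."""
    if isinstance(seqs, Mapping):
        s = seqs[chrom]
        if end > len(s):
            raise ValueError(f"{chrom}:{start}-{end} beyond sequence bounds")
        return s[start:end]
    return str(seqs[chrom][start:end])


def _count_hits(peaks: IntervalSet, seqs, motif: MotifDef, window_bp: Optional[int]):
    total = 0
    n_with = 0
    for i in range(len(peaks)):
        s, e = int(peaks.starts[i]), int(peaks.ends[i])
        if window_bp is not None and e - s > window_bp:
            mid = (s + e) // 2
            s, e = mid - window_bp // 2, mid + window_bp // 2
        hits = scan_consensus(_fetch(seqs, str(peaks.chroms[i]), s, e), motif)
        total += len(hits)
        n_with += bool(hits)
    return total, n_with


def motif_enrichment(
    peaks: IntervalSet,
    seqs,
    motif: MotifDef,
    genome: Optional[GenomeDef] = None,
    config: Optional[PermutationConfig] = None,
    statistic: str = "n_hits",
    window_bp: Optional[int] = None,
) -> PermutationResult:
    """Motif enrichment in peak sequences against a relocation null.

    ``statistic`` is ``"n_hits"`` (total match count over all peaks) or
    ``"frac_peaks_hit"`` (fraction of peaks with at least one match).
    ``window_bp`` optionally restricts scanning to a centered window of each
    peak. The null relocates the peaks within their chromosomes and
    re-scans the same, fixed genome sequence.
    """
    if config is None:
        raise ValueError("a PermutationConfig (with a seed) is required")
    if statistic not in ("n_hits", "frac_peaks_hit"):
        raise ValueError(f"unknown motif statistic {statistic!r}")
    genome = genome if genome is not None else peaks.genome
    if genome is None:
        raise ValueError("a genome is required")

    def stat(ps: IntervalSet) -> float:
        total, n_with = _count_hits(ps, seqs, motif, window_bp)
        return float(total) if statistic == "n_hits" else n_with / len(ps)

    observed = stat(peaks)
    children = np.random.SeedSequence(config.seed).spawn(config.n_perm)
    null = np.empty(config.n_perm, dtype=float)
    for i, child in enumerate(children):
        perm = permute_intrachrom(
            peaks,
            genome,
            seed=np.random.default_rng(child),
            allow_self_overlap=config.allow_self_overlap,
        )
        null[i] = stat(perm)
    return _summarize_null(
        observed, null, config.tail, config.n_perm, config.seed, statistic
    )
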