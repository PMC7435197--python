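"""Genomic interval data model and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Two intervals overlap iff they share at least one base
(``a.start < b.end and b.start < a.end``); abutting intervals (gap 0) do not
overlap but are coalesced by :func:`sort_and_merge`, which gives "region"
semantics to merged peak domains and unambiguous denominators downstream.

The containers here are deliberately thin: a :class:`GenomeDef` pins the
coordinate universe (chromosome names and lengths), an :class:`IntervalSet`
holds parallel numpy arrays so that the permutation-null machinery can
recompute overlap statistics thousands of times cheaply.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeDef",
    "Interval",
    "IntervalSet",
    "OverlapResult",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "sort_and_merge",
    "overlap_stats",
    "consensus",
]

_STRANDS = {"+", "-", "."}


class GenomeDef:
    """Ordered chromosome names and lengths; the coordinate universe.

    Parameters
    ----------
    chromosomes
        Iterable of ``(name, length)`` pairs. Names must be unique, lengths
        positive integers. Input order is preserved and defines the sort
        order used by all interval operations.
    """

    __slots__ = ("_names", "_lengths", "_rank")

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        names: list[str] = []
        lengths: dict[str, int] = {}
        for name, length in chromosomes:
            name = str(name)
            if name in lengths:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if not float(length).is_integer() or int(length) < 1:
                raise ValueError(
                    f"chromosome {name!r} has non-positive or non-integer "
                    f"length {length!r}"
                )
            names.append(name)
            lengths[name] = int(length)
        if not names:
            raise ValueError("empty genome definition")
        self._names = tuple(names)
        self._lengths = lengths
        self._rank = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        return [(n, self._lengths[n]) for n in self._names]

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def rank(self, chrom: str) -> int:
        return self._rank[chrom]

    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self._names)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeDef) and self.chromosomes == other.chromosomes

    def __repr__(self) -> str:
        return f"GenomeDef({len(self)} chromosomes, {self.total_bp()} bp)"


@dataclass(frozen=True)
class Interval:
    """A single genomic region in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """A collection of intervals backed by parallel numpy arrays.

    ``sorted_flag`` asserts (chrom-rank, start, end) ordering; ``merged_flag``
    additionally asserts that no two intervals on one chromosome overlap or
    abut. Both are set by :func:`sort_and_merge` and invalidated by any
    constructor that cannot guarantee them.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        names: Optional[Sequence[Optional[str]]] = None,
        scores: Optional[Sequence[Optional[float]]] = None,
        strands: Optional[Sequence[str]] = None,
        genome: Optional[GenomeDef] = None,
        sorted_flag: bool = False,
        merged_flag: bool = False,
    ):
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        n = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == n):
            raise ValueError("chroms/starts/ends length mismatch")
        if n and (np.any(self.starts < 0) or np.any(self.starts >= self.ends)):
            raise ValueError("every interval needs 0 <= start < end")
        self.names = None if names is None else np.asarray(names, dtype=object)
        self.scores = None if scores is None else np.asarray(scores, dtype=object)
        self.strands = (
            np.full(n, ".", dtype=object)
            if strands is None
            else np.asarray(strands, dtype=object)
        )
        self.genome = genome
        if genome is not None and n:
            for c in set(self.chroms.tolist()):
                if c not in genome:
                    raise ValueError(f"chromosome {c!r} not in genome")
            lens = np.array([genome.length(c) for c in self.chroms], dtype=np.int64)
            if np.any(self.ends > lens):
                bad = int(np.argmax(self.ends > lens))
                raise ValueError(
                    f"interval {self.chroms[bad]}:{self.starts[bad]}-"
                    f"{self.ends[bad]} exceeds chromosome length"
                )
        self.sorted_flag = bool(sorted_flag)
        self.merged_flag = bool(merged_flag)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_intervals(
        cls, intervals: Iterable[Interval], genome: Optional[GenomeDef] = None
    ) -> "IntervalSet":
        ivs = list(intervals)
        return cls(
            [i.chrom for i in ivs],
            [i.start for i in ivs],
            [i.end for i in ivs],
            names=[i.name for i in ivs],
            scores=[i.score for i in ivs],
            strands=[i.strand for i in ivs],
            genome=genome,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, genome: Optional[GenomeDef] = None
    ) -> "IntervalSet":
        return cls(
            df["chrom"].to_numpy(dtype=object),
            df["start"].to_numpy(),
            df["end"].to_numpy(),
            names=df["name"].to_numpy(dtype=object) if "name" in df else None,
            scores=df["score"].to_numpy(dtype=object) if "score" in df else None,
            strands=df["strand"].to_numpy(dtype=object) if "strand" in df else None,
            genome=genome,
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        if self.names is not None:
            data["name"] = self.names
        if self.scores is not None:
            data["score"] = self.scores
        data["strand"] = self.strands
        return pd.DataFrame(data)

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.chroms)

    def __iter__(self) -> Iterator[Interval]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Interval:
        return Interval(
            str(self.chroms[i]),
            int(self.starts[i]),
            int(self.ends[i]),
            name=None if self.names is None else self.names[i],
            score=None if self.scores is None else self.scores[i],
            strand=str(self.strands[i]),
        )

    def subset(self, index: np.ndarray) -> "IntervalSet":
        return IntervalSet(
            self.chroms[index],
            self.starts[index],
            self.ends[index],
            names=None if self.names is None else self.names[index],
            scores=None if self.scores is None else self.scores[index],
            strands=self.strands[index],
            genome=self.genome,
        )

    @property
    def total_bp(self) -> int:
        """Sum of interval lengths (overlapping bases counted repeatedly)."""
        return int(np.sum(self.ends - self.starts))

    def chrom_order(self) -> list[str]:
        if self.genome is not None:
            return list(self.genome.names)
        seen: dict[str, None] = {}
        for c in sorted(set(self.chroms.tolist())):
            seen[c] = None
        return list(seen)

    def groupby_chrom(self) -> dict[str, np.ndarray]:
        """Index arrays per chromosome, in set order."""
        out: dict[str, list[int]] = {}
        for i, c in enumerate(self.chroms):
            out.setdefault(str(c), []).append(i)
        return {c: np.asarray(ix, dtype=np.intp) for c, ix in out.items()}


# -- I/O -------------------------------------------------------------------


def read_chrom_sizes(path) -> GenomeDef:
    """Parse a two-column whitespace-delimited ``chrom.sizes`` file."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name length'")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from exc
            pairs.append((fields[0], length))
    if not pairs:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return GenomeDef(pairs)


def _skip_bed_line(line: str) -> bool:
    s = line.strip()
    return (
        not s
        or s.startswith("#")
        or s.startswith("track")
        or s.startswith("browser")
    )


def read_bed(path, genome: Optional[GenomeDef] = None) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet`.

    Records with ``end <= start`` raise; track/browser/comment lines are
    skipped. When a genome is supplied, intervals beyond chromosome bounds
    raise.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[Optional[str]] = []
    scores: list[Optional[float]] = []
    strands: list[str] = []
    any_meta = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _skip_bed_line(line):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinate") from exc
            if end <= start or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            chroms.append(f[0])
            starts.append(start)
            ends.append(end)
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score: Optional[float] = None
            if len(f) > 4 and f[4] != ".":
                try:
                    score = float(f[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable score") from exc
            strand = f[5] if len(f) > 5 else "."
            if strand not in _STRANDS:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            names.append(name)
            scores.append(score)
            strands.append(strand)
            any_meta = any_meta or name is not None or score is not None or strand != "."
    return IntervalSet(
        chroms,
        starts,
        ends,
        names=names if any_meta else None,
        scores=scores if any_meta else None,
        strands=strands,
        genome=genome,
    )


def write_bed(iset: IntervalSet, path) -> None:
    """Write BED6 when name/score/strand carry information, else BED3."""
    bed6 = (
        (iset.names is not None and any(n is not None for n in iset.names))
        or (iset.scores is not None and any(s is not None for s in iset.scores))
        or any(s != "." for s in iset.strands)
    )
    buf = io.StringIO()
    for i in range(len(iset)):
        row = [str(iset.chroms[i]), str(int(iset.starts[i])), str(int(iset.ends[i]))]
        if bed6:
            name = iset.names[i] if iset.names is not None else None
            score = iset.scores[i] if iset.scores is not None else None
            row += [
                "." if name is None else str(name),
                "0" if score is None else format(score, "g"),
                str(iset.strands[i]),
            ]
        buf.write("\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# -- algebra ---------------------------------------------------------------


def _check_genomes(A: IntervalSet, B: IntervalSet) -> None:
    if A.genome is not None and B.genome is not None and A.genome != B.genome:
        raise ValueError("interval sets are on different genomes")


def sort_and_merge(iset: IntervalSet) -> IntervalSet:
    """Sort by (chrom, start, end) and coalesce overlapping/abutting runs.

    Total covered bp is invariant; the result carries sorted and merged
    flags. Names/scores/strands are dropped — a merged region is a new
    object, not any single input record.
    """
    order = iset.chrom_order()
    rank = {c: i for i, c in enumerate(order)}
    if len(iset) == 0:
        return IntervalSet(
            [], [], [], genome=iset.genome, sorted_flag=True, merged_flag=True
        )
    keys = np.lexsort(
        (iset.ends, iset.starts, np.array([rank[str(c)] for c in iset.chroms]))
    )
    chroms = iset.chroms[keys]
    starts = iset.starts[keys]
    ends = iset.ends[keys]
    out_c: list[str] = []
    out_s: list[int] = []
    out_e: list[int] = []
    i = 0
    n = len(chroms)
    while i < n:
        c = chroms[i]
        j = i
        while j < n and chroms[j] == c:
            j += 1
        s, e = starts[i:j], ends[i:j]
        cummax = np.maximum.accumulate(e)
        # a new run starts where the next start strictly exceeds everything
        # seen so far (start == cummax means abutting -> merge)
        new_run = np.empty(j - i, dtype=bool)
        new_run[0] = True
        new_run[1:] = s[1:] > cummax[:-1]
        run_id = np.cumsum(new_run) - 1
        n_runs = run_id[-1] + 1
        run_start = s[new_run]
        run_end = np.zeros(n_runs, dtype=np.int64)
        np.maximum.at(run_end, run_id, e)
        out_c.extend([str(c)] * n_runs)
        out_s.extend(run_start.tolist())
        out_e.extend(run_end.tolist())
        i = j
    return IntervalSet(
        out_c, out_s, out_e, genome=iset.genome, sorted_flag=True, merged_flag=True
    )


def _merged_arrays(iset: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    m = iset if iset.merged_flag else sort_and_merge(iset)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c, ix in m.groupby_chrom().items():
        out[c] = (m.starts[ix], m.ends[ix])
    return out


def _hits_mask(
    iset: IntervalSet, merged: dict[str, tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Boolean mask: which intervals of *iset* overlap the merged landscape."""
    hit = np.zeros(len(iset), dtype=bool)
    for c, ix in iset.groupby_chrom().items():
        if c not in merged:
            continue
        ms, me = merged[c]
        if len(ms) == 0:
            continue
        s, e = iset.starts[ix], iset.ends[ix]
        # number of landscape intervals with start < e
        pos = np.searchsorted(ms, e, side="left")
        ok = pos > 0
        ok[ok] = me[pos[ok] - 1] > s[ok]
        hit[ix] = ok
    return hit


def _intersect_bp(a: tuple[np.ndarray, np.ndarray], b) -> int:
    """Intersection bp of two merged, sorted interval arrays (one chrom)."""
    sa, ea = a
    sb, eb = b
    i = j = 0
    total = 0
    while i < len(sa) and j < len(sb):
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if hi > lo:
            total += int(hi - lo)
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return total


@dataclass(frozen=True)
class OverlapResult:
    """Peak-anchored and base-wise overlap statistics of two interval sets."""

    n_A: int
    n_B: int
    n_A_hit: int
    frac_A_hit: float
    n_B_hit: int
    frac_B_hit: float
    bp_intersect: int
    jaccard: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def overlap_stats(A: IntervalSet, B: IntervalSet) -> OverlapResult:
    """All pairwise overlap statistics between sets A and B.

    Hit counts are computed on the sets exactly as given (the caller decides
    whether to merge first); base-wise quantities are computed on the merged
    footprints, so they are insensitive to internal redundancy.
    """
    _check_genomes(A, B)
    mA, mB = _merged_arrays(A), _merged_arrays(B)
    n_A, n_B = len(A), len(B)
    n_A_hit = int(_hits_mask(A, mB).sum())
    n_B_hit = int(_hits_mask(B, mA).sum())
    inter = sum(_intersect_bp(mA[c], mB[c]) for c in mA if c in mB)
    bp_A = sum(int((e - s).sum()) for s, e in mA.values())
    bp_B = sum(int((e - s).sum()) for s, e in mB.values())
    union = bp_A + bp_B - inter
    return OverlapResult(
        n_A=n_A,
        n_B=n_B,
        n_A_hit=n_A_hit,
        frac_A_hit=n_A_hit / n_A if n_A else 0.0,
        n_B_hit=n_B_hit,
        frac_B_hit=n_B_hit / n_B if n_B else 0.0,
        bp_intersect=inter,
        jaccard=inter / union if union else 0.0,
    )


def consensus(A: IntervalSet, B: IntervalSet, mode: str = "either-anchored-on-A") -> IntervalSet:
    """Replicate-consensus peaks.

    ``either-anchored-on-A``
        A's intervals that overlap at least one B interval, unmodified.
    ``reciprocal-intersection``
        Base-wise intersection of the merged footprints of A and B.
    """
    _check_genomes(A, B)
    if mode == "either-anchored-on-A":
        return A.subset(np.nonzero(_hits_mask(A, _merged_arrays(B)))[0])
    if mode == "reciprocal-intersection":
        mA, mB = _merged_arrays(A), _merged_arrays(B)
        order = A.chrom_order()
        out_c: list[str] = []
        out_s: list[int] = []
        out_e: list[int] = []
        for c in order:
            if c not in mA or c not in mB:
                continue
            sa, ea = mA[c]
            sb, eb = mB[c]
            i = j = 0
            while i < len(sa) and j < len(sb):
                lo = max(sa[i], sb[j])
                hi = min(ea[i], eb[j])
                if hi > lo:
                    out_c.append(c)
                    out_s.append(int(lo))
                    out_e.append(int(hi))
                if ea[i] < eb[j]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(
            out_c, out_s, out_e, genome=A.genome, sorted_flag=True, merged_flag=True
        )
    raise ValueError(f"unknown consensus mode {mode!r}")
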