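"""Permutation-calibrated interval co-localization and 2x2 association tests.

The null model is an intra-chromosomal permutation: each query interval is
relocated uniformly within its own chromosome, preserving per-chromosome
interval counts and the multiset of interval lengths ("randomized peaks of
equal number and size"). Fold enrichment is the observed co-localization
statistic divided by its permutation-null mean; the empirical p-value uses
the add-one estimator (1 + k) / (N + 1), which can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats as _st

from .interval_core import GenomeDef, IntervalSet, OverlapResult, overlap_stats

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "ContingencyResult",
    "MarkAssociation",
    "permute_intrachrom",
    "fold_enrichment",
    "chi2_yates",
    "mark_association",
]

_STATISTICS = ("frac_A_hit", "n_A_hit", "bp_intersect", "jaccard")


@dataclass
class PermutationConfig:
    """Settings of a permutation enrichment run.

    ``statistic`` names a field of :class:`~reachmap.interval_core
    .OverlapResult`; ``tail`` selects enrichment ("greater") or depletion
    ("less"). The seed is mandatory — every null distribution must be
    reproducible.
    """

    seed: int
    n_perm: int = 1000
    statistic: str = "frac_A_hit"
    allow_self_overlap: bool = True
    tail: str = "greater"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.statistic not in _STATISTICS:
            raise ValueError(
                f"statistic must be one of {_STATISTICS}, got {self.statistic!r}"
            )
        if self.tail not in ("greater", "less"):
            raise ValueError("tail must be 'greater' or 'less'")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic against its intra-chromosomal permutation null."""

    observed: float
    null_mean: float
    null_sd: float
    fold_enrichment: float
    p_empirical: float
    n_perm: int
    seed: int
    tail: str
    statistic: str
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["flags"] = list(self.flags)
        return d


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 chi-squared test with Yates' continuity correction."""

    table: tuple[int, int, int, int]
    chi2_yates: float
    p_value: float
    df: int = 1

    def to_dict(self) -> dict:
        return {
            "table": list(self.table),
            "chi2_yates": self.chi2_yates,
            "p_value": self.p_value,
            "df": self.df,
        }


def permute_intrachrom(
    iset: IntervalSet,
    genome: Optional[GenomeDef] = None,
    seed: Union[int, np.random.Generator, None] = None,
    allow_self_overlap: bool = True,
    max_retries: int = 1000,
) -> IntervalSet:
    """Relocate every interval uniformly within its own chromosome.

    Per chromosome, the output preserves the interval count and the length
    multiset; each new start is uniform on ``[0, chrom_length - length]``.
    With ``allow_self_overlap=False`` the whole chromosome is re-sampled
    until the placement is mutually non-overlapping (abutting allowed),
    giving up after ``max_retries`` attempts.
    """
    genome = genome if genome is not None else iset.genome
    if genome is None:
        raise ValueError("a genome is required to permute intervals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new_starts = iset.starts.copy()
    lengths = iset.ends - iset.starts
    for c, ix in iset.groupby_chrom().items():
        L = genome.length(c)
        lens = lengths[ix]
        if np.any(lens > L):
            raise ValueError(f"interval longer than chromosome {c!r}")
        high = L - lens + 1
        if allow_self_overlap:
            new_starts[ix] = rng.integers(0, high)
            continue
        for _ in range(max_retries):
            cand = rng.integers(0, high)
            order = np.argsort(cand, kind="stable")
            s, e = cand[order], (cand + lens)[order]
            if np.all(s[1:] >= e[:-1]):
                new_starts[ix] = cand
                break
        else:
            raise RuntimeError(
                f"could not place {len(ix)} non-overlapping intervals on "
                f"{c!r} within {max_retries} retries"
            )
    return IntervalSet(
        iset.chroms.copy(),
        new_starts,
        new_starts + lengths,
        names=None if iset.names is None else iset.names.copy(),
        scores=None if iset.scores is None else iset.scores.copy(),
        strands=iset.strands.copy(),
        genome=genome,
    )


def _summarize_null(
    observed: float, null: np.ndarray, tail: str, n_perm: int, seed: int, statistic: str
) -> PermutationResult:
    null_mean = float(np.mean(null))
    null_sd = float(np.std(null, ddof=1)) if len(null) > 1 else 0.0
    flags: tuple[str, ...] = ()
    if null_mean > 0:
        fold = observed / null_mean
    elif observed > 0:
        fold = float("inf")
        flags = ("null-mean-zero",)
    else:
        fold = 1.0
        flags = ("zero-signal",)
    if tail == "greater":
        k = int(np.sum(null >= observed))
    else:
        k = int(np.sum(null <= observed))
    return PermutationResult(
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        fold_enrichment=fold,
        p_empirical=(1 + k) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        tail=tail,
        statistic=statistic,
        flags=flags,
    )


def fold_enrichment(
    A: IntervalSet,
    B: IntervalSet,
    genome: Optional[GenomeDef] = None,
    config: Optional[PermutationConfig] = None,
) -> PermutationResult:
    """Permutation-calibrated co-localization of query A against landscape B.

    A is randomized (equal number and size, intra-chromosomal), B is held
    fixed; the chosen overlap statistic of each permutation forms the null.
    """
    if config is None:
        raise ValueError("a PermutationConfig (with a seed) is required")
    genome = genome if genome is not None else A.genome
    if genome is None:
        raise ValueError("a genome is required")
    observed = getattr(overlap_stats(A, B), config.statistic)
    children = np.random.SeedSequence(config.seed).spawn(config.n_perm)
    null = np.empty(config.n_perm, dtype=float)
    for i, child in enumerate(children):
        perm = permute_intrachrom(
            A,
            genome,
            seed=np.random.default_rng(child),
            allow_self_overlap=config.allow_self_overlap,
        )
        null[i] = getattr(overlap_stats(perm, B), config.statistic)
    return _summarize_null(
        observed, null, config.tail, config.n_perm, config.seed, config.statistic
    )


def chi2_yates(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Chi-squared test with Yates' continuity correction on a 2x2 table.

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d)),
    with the corrected deviation clamped at zero, p from chi2(1 df).
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("all four table margins must be positive")
    dev = max(abs(a * d - b * c) - n / 2, 0.0)
    chi2 = n * dev * dev / (margins[0] * margins[1] * margins[2] * margins[3])
    return ContingencyResult(
        table=(a, b, c, d), chi2_yates=float(chi2), p_value=float(_st.chi2.sf(chi2, 1))
    )


@dataclass(frozen=True)
class MarkAssociation:
    """Enrichment vs. one chromatin mark, depletion vs. another, plus a 2x2
    comparison of the two hit rates."""

    pos: PermutationResult
    neg: PermutationResult
    contingency: ContingencyResult
    n_regions: int
    frac_pos_hit: float
    frac_neg_hit: float

    def to_dict(self) -> dict:
        return {
            "pos": self.pos.to_dict(),
            "neg": self.neg.to_dict(),
            "contingency": self.contingency.to_dict(),
            "n_regions": self.n_regions,
            "frac_pos_hit": self.frac_pos_hit,
            "frac_neg_hit": self.frac_neg_hit,
        }


def mark_association(
    regions: IntervalSet,
    mark_pos: IntervalSet,
    mark_neg: IntervalSet,
    genome: Optional[GenomeDef] = None,
    config: Optional[PermutationConfig] = None,
) -> MarkAssociation:
    """Test regions for enrichment of an active mark and depletion of a
    repressive mark.

    The 2x2 table compares the region hit rate of the two marks:
    rows (hit, not hit) for mark_pos and mark_neg, tested with Yates'
    chi-squared.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if config is None:
        raise ValueError("a PermutationConfig (with a seed) is required")
    from dataclasses import replace

    pos = fold_enrichment(regions, mark_pos, genome, replace(config, tail="greater"))
    neg = fold_enrichment(
        regions, mark_neg, genome, replace(config, seed=config.seed + 1, tail="less")
    )
    ov_pos = overlap_stats(regions, mark_pos)
    ov_neg = overlap_stats(regions, mark_neg)
    n = len(regions)
    cont = chi2_yates(
        ov_pos.n_A_hit, n - ov_pos.n_A_hit, ov_neg.n_A_hit, n - ov_neg.n_A_hit
    )
    return MarkAssociation(
        pos=pos,
        neg=neg,
        contingency=cont,
        n_regions=n,
        frac_pos_hit=ov_pos.frac_A_hit,
        frac_neg_hit=ov_neg.frac_A_hit,
    )
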