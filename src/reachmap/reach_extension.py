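"""Convert a ubiquitin-ligase bridging reach into a genomic flank.

A cullin scaffold can bridge a substrate and the ubiquitin-conjugating
machinery over a physical distance R (in Angstrom). On compacted solenoidal
chromatin, a physical distance maps to a much longer stretch of linear DNA:
with a B-DNA helical rise of r nm/bp and a fiber packing ratio kappa
(fold-compaction of linear DNA within the fiber),

    flank_bp = round(R * 0.1 nm/A * kappa / r)

With the defaults R = 100 A, r = 0.34 nm/bp, kappa = 102 this gives a
3,000 bp flank, which extended peak coordinates into "regions under ligase
control" on either side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .interval_core import GenomeDef, IntervalSet, sort_and_merge

__all__ = ["ReachParams", "reach_to_bp", "extend_intervals"]

#: B-DNA helical rise, nm per bp.
DEFAULT_RISE_NM_PER_BP = 0.34
#: Solenoid fiber packing ratio (dimensionless fold-compaction).
DEFAULT_PACKING_RATIO = 102.0


@dataclass
class ReachParams:
    """Physical-reach parameters and the derived genomic flank.

    ``flank_bp`` may be set directly (overriding derivation) or left None,
    in which case it is derived as ``round(R * 0.1 * kappa / r)``.
    """

    reach_angstrom: float = 100.0
    rise_nm_per_bp: float = DEFAULT_RISE_NM_PER_BP
    packing_ratio: float = DEFAULT_PACKING_RATIO
    flank_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.reach_angstrom < 0:
            raise ValueError("reach must be >= 0")
        if self.rise_nm_per_bp <= 0:
            raise ValueError("helical rise must be positive")
        if self.packing_ratio < 1:
            raise ValueError("packing ratio must be >= 1")
        if self.flank_bp is None:
            self.flank_bp = reach_to_bp(self)
        elif self.flank_bp < 0:
            raise ValueError("flank must be >= 0")


def reach_to_bp(params: ReachParams) -> int:
    """Linear DNA length (bp) spanned by a physical reach on the fiber."""
    if params.rise_nm_per_bp <= 0:
        raise ValueError("helical rise must be positive")
    nm = params.reach_angstrom * 0.1
    return int(round(nm * params.packing_ratio / params.rise_nm_per_bp))


def extend_intervals(
    iset: IntervalSet,
    flank_bp: int,
    genome: Optional[GenomeDef] = None,
    merge_after: bool = True,
) -> IntervalSet:
    """Extend every interval by ``flank_bp`` on both sides, clipped to the
    chromosome, optionally merging the result.

    The genome is required (either attached to the set or passed) because
    clipping at chromosome ends is undefined without it.
    """
    if flank_bp < 0:
        raise ValueError("flank must be >= 0")
    genome = genome if genome is not None else iset.genome
    if genome is None:
        raise ValueError("a genome is required to clip extended intervals")
    lens = np.array([genome.length(str(c)) for c in iset.chroms], dtype=np.int64)
    starts = np.maximum(iset.starts - flank_bp, 0)
    ends = np.minimum(iset.ends + flank_bp, lens)
    out = IntervalSet(
        iset.chroms.copy(),
        starts,
        ends,
        names=None if iset.names is None else iset.names.copy(),
        scores=None if iset.scores is None else iset.scores.copy(),
        strands=iset.strands.copy(),
        genome=genome,
    )
    return sort_and_merge(out) if merge_after else out
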