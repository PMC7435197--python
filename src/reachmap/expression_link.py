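"""Linking ChIP-defined target genes to expression changes.

Provides the Wilcoxon rank-sum test (exact by enumeration when feasible,
normal approximation with tie-corrected variance and continuity correction
otherwise), the gene-set expression-shift test built on it, relative qPCR
quantification by the ddCt method (fold = 2^(-ddCt) against a reference
transcript and a control condition), and the pooled-variance two-sample
t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _st

from .tss_annotation import GeneSet

__all__ = [
    "ExpressionTable",
    "RankSumResult",
    "ShiftTestResult",
    "DdctResult",
    "read_expression_table",
    "read_ct_table",
    "wilcoxon_rank_sum",
    "gene_set_shift_test",
    "ddct",
    "t_test_homoscedastic",
    "bh_adjust",
]

logger = logging.getLogger(__name__)

#: exact Wilcoxon enumeration is used when C(n_x + n_y, n_x) is at most this
EXACT_ENUM_LIMIT = 200_000


def read_expression_table(path) -> pd.DataFrame:
    """TSV with columns gene_id, log2fc[, p]; gene ids must be unique."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df or "log2fc" not in df:
        raise ValueError("expression table needs columns gene_id, log2fc")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in expression table")
    if not np.all(np.isfinite(df["log2fc"].to_numpy(dtype=float))):
        raise ValueError("log2fc must be finite")
    return df


def read_ct_table(path) -> pd.DataFrame:
    """TSV with columns condition, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    need = {"condition", "gene", "replicate", "ct"}
    if not need.issubset(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(need)}")
    return df


# alias documenting the in-memory container for expression data
ExpressionTable = pd.DataFrame


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon rank-sum test result; W is the rank sum of sample x."""

    w_statistic: float
    n_x: int
    n_y: int
    p_value: float
    method: str  # "exact" | "normal-approx"
    alternative: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _exact_ranksum_cdf(n_x: int, n_y: int) -> np.ndarray:
    """counts[w] = number of n_x-subsets of ranks 1..n with rank sum w."""
    n = n_x + n_y
    max_w = n_x * n + 1  # loose upper bound on the achievable sum
    dp = np.zeros((n_x + 1, max_w), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n_x), 0, -1):
            dp[k, r:] += dp[k - 1, :-r]
    return dp[n_x]


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with mid-ranks for ties.

    Exact p by full enumeration of rank assignments when the samples are
    tie-free and C(n_x + n_y, n_x) <= 200,000; otherwise normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n_x, n_y = len(x), len(y)
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks = _st.rankdata(pooled)  # mid-ranks
    w = float(ranks[:n_x].sum())
    has_ties = len(np.unique(pooled)) < n

    if not has_ties and comb(n, n_x) <= EXACT_ENUM_LIMIT:
        counts = _exact_ranksum_cdf(n_x, n_y)
        total = counts.sum()
        wi = int(round(w))
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(w, n_x, n_y, float(p), "exact", alternative)

    mean = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_x * n_y * (n + 1) / 12.0
    if n > 1:
        var -= n_x * n_y * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        # all observations identical: no evidence of shift
        return RankSumResult(w, n_x, n_y, 1.0, "normal-approx", alternative)
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w - mean - 0.5) / sd
        p = _st.norm.sf(z)
    elif alternative == "less":
        z = (w - mean + 0.5) / sd
        p = _st.norm.cdf(z)
    else:
        z = (abs(w - mean) - 0.5) / sd
        p = 2.0 * _st.norm.sf(max(z, 0.0))
    return RankSumResult(w, n_x, n_y, float(min(p, 1.0)), "normal-approx", alternative)


@dataclass(frozen=True)
class ShiftTestResult:
    """Gene-set expression shift against a background set."""

    test: RankSumResult
    n_targets: int
    n_background: int
    median_targets: float
    median_background: float
    n_dropped: int

    @property
    def direction(self) -> str:
        d = self.median_targets - self.median_background
        return "up" if d > 0 else ("down" if d < 0 else "none")

    def to_dict(self) -> dict:
        return {
            "test": self.test.to_dict(),
            "n_targets": self.n_targets,
            "n_background": self.n_background,
            "median_targets": self.median_targets,
            "median_background": self.median_background,
            "n_dropped": self.n_dropped,
            "direction": self.direction,
        }


def gene_set_shift_test(
    expr: pd.DataFrame,
    targets: GeneSet,
    background: Union[str, GeneSet] = "all-non-target",
    alternative: str = "two-sided",
) -> ShiftTestResult:
    """Compare log2 fold changes of target genes against a background.

    ``background`` is either the literal ``"all-non-target"`` (every measured
    gene outside the target set) or an explicit :class:`GeneSet`. Genes
    absent from the expression table are dropped with a logged count.
    """
    gids = expr["gene_id"].astype(str)
    lfc = expr["log2fc"].to_numpy(dtype=float)
    in_t = gids.isin(targets.gene_ids).to_numpy()
    n_dropped = len(targets) - int(in_t.sum())
    if isinstance(background, GeneSet):
        in_b = gids.isin(background.gene_ids).to_numpy() & ~in_t
        n_dropped += len(background) - int(
            gids.isin(background.gene_ids).to_numpy().sum()
        )
    else:
        if background != "all-non-target":
            raise ValueError(f"unknown background {background!r}")
        in_b = ~in_t
    if n_dropped:
        logger.warning("%d gene-set members absent from expression table", n_dropped)
    xs, ys = lfc[in_t], lfc[in_b]
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError("no overlap between gene sets and expression table")
    res = wilcoxon_rank_sum(xs, ys, alternative=alternative)
    return ShiftTestResult(
        test=res,
        n_targets=len(xs),
        n_background=len(ys),
        median_targets=float(np.median(xs)),
        median_background=float(np.median(ys)),
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class DdctResult:
    """Per (condition, gene) relative quantification by the ddCt method."""

    table: pd.DataFrame  # condition, gene, mean_ct, delta_ct, delta_ct_sd,
    #                      delta_delta_ct, fold
    ref_gene: str
    control_condition: str

    def fold(self, condition: str, gene: str) -> float:
        sub = self.table[
            (self.table["condition"] == condition) & (self.table["gene"] == gene)
        ]
        if len(sub) != 1:
            raise KeyError(f"no unique row for ({condition!r}, {gene!r})")
        return float(sub["fold"].iloc[0])


def ddct(ct_table: pd.DataFrame, ref_gene: str, control_condition: str) -> DdctResult:
    """Relative expression fold changes from replicate Ct values.

    Per replicate, dCt = Ct_gene - mean(Ct_ref within the condition);
    ddCt = mean dCt in the condition minus mean dCt in the control
    condition; fold = 2^(-ddCt). Replicates are treated as unpaired within a
    condition; dispersion is the SD of replicate dCt values.
    """
    need = {"condition", "gene", "ct"}
    if not need.issubset(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(need)}")
    conditions = ct_table["condition"].unique().tolist()
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not in table")
    ref_mean: dict[str, float] = {}
    for cond in conditions:
        ref = ct_table[
            (ct_table["condition"] == cond) & (ct_table["gene"] == ref_gene)
        ]["ct"]
        if len(ref) == 0:
            raise ValueError(
                f"reference gene {ref_gene!r} missing in condition {cond!r}"
            )
        ref_mean[cond] = float(ref.mean())

    rows = []
    dct_mean: dict[tuple[str, str], float] = {}
    for (cond, gene), grp in ct_table.groupby(["condition", "gene"], sort=False):
        cts = grp["ct"].to_numpy(dtype=float)
        dct = cts - ref_mean[cond]
        dct_mean[(cond, gene)] = float(dct.mean())
        rows.append(
            {
                "condition": cond,
                "gene": gene,
                "mean_ct": float(cts.mean()),
                "delta_ct": float(dct.mean()),
                "delta_ct_sd": float(dct.std(ddof=1)) if len(dct) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    ddcts = []
    for r in table.itertuples(index=False):
        key = (control_condition, r.gene)
        if key not in dct_mean:
            raise ValueError(f"gene {r.gene!r} missing in control condition")
        ddcts.append(r.delta_ct - dct_mean[key])
    table["delta_delta_ct"] = ddcts
    table["fold"] = 2.0 ** (-table["delta_delta_ct"])
    return DdctResult(table=table, ref_gene=ref_gene, control_condition=control_condition)


def t_test_homoscedastic(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided pooled-variance (homoscedastic) two-sample t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 replicates")
    sp2 = (
        (len(x) - 1) * np.var(x, ddof=1) + (len(y) - 1) * np.var(y, ddof=1)
    ) / (len(x) + len(y) - 2)
    if sp2 <= 0:
        if np.mean(x) == np.mean(y):
            return {"t": 0.0, "df": len(x) + len(y) - 2, "p": 1.0}
        raise ValueError("zero pooled variance with unequal means")
    res = _st.ttest_ind(x, y, equal_var=True)
    return {
        "t": float(res.statistic),
        "df": len(x) + len(y) - 2,
        "p": float(res.pvalue),
    }


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return _st.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
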