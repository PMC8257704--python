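"""Gene-set overlap summaries and two-group enrichment-score comparisons.

Overlap percentages are exact rational arithmetic rendered at two decimals
with half-up rounding (270/894 renders "30.20", 102/416 renders "24.52").
Score comparisons use the unpaired two-tailed two-sample t test, pooled
variance by default (classical Student), Welch optionally. No multiple-testing
correction is applied: each comparison is a single planned contrast.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .target_annotation import GeneAnnotation

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Raised for undefined overlap or comparison inputs."""


def round_half_up(x: Fraction, decimals: int = 2) -> float:
    """Exact half-up rounding of a rational to the given number of decimals."""
    scale = 10**decimals
    scaled = x * scale
    floor = scaled.numerator // scaled.denominator
    remainder = scaled - floor
    if remainder * 2 >= 1:
        floor += 1
    return floor / scale


@dataclass(frozen=True)
class OverlapSummary:
    """Venn-style overlap of two gene sets with a directional percentage."""

    set_a_name: str
    set_b_name: str
    n_a: int
    n_b: int
    n_intersection: int
    pct_a_in_b: float  # 100 * n_intersection / n_a, half-up at 2 decimals

    @property
    def pct_rendered(self) -> str:
        return f"{self.pct_a_in_b:.2f}"


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-sample t-test result between two score groups."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    t_stat: float
    df: float
    p_two_sided: float
    variant: str  # "pooled" or "welch"


def overlap(
    set_a: set[str],
    set_b: set[str],
    set_a_name: str = "set_a",
    set_b_name: str = "set_b",
) -> OverlapSummary:
    """Exact overlap counts and the a-in-b percentage.

    Counts are symmetric; the percentage is directional (fraction of ``set_a``
    found in ``set_b``). An empty ``set_a`` leaves the percentage undefined and
    is rejected.
    """
    if not set_a:
        raise StatsError("set_a is empty: overlap percentage is undefined")
    inter = len(set_a & set_b)
    pct = round_half_up(Fraction(100 * inter, len(set_a)))
    return OverlapSummary(set_a_name, set_b_name, len(set_a), len(set_b), inter, pct)


def compare_scores(
    scores_group1: Sequence[float],
    scores_group2: Sequence[float],
    variant: str = "pooled",
) -> GroupComparison:
    """Unpaired two-tailed t test on two score groups.

    Pooled-variance Student t by default (df = n1 + n2 - 2); Welch optional.
    If every value in both groups is identical the statistic degenerates to
    t = 0, p = 1 (zero pooled variance with unequal means cannot occur).
    """
    if variant not in ("pooled", "welch"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    g1 = np.asarray(scores_group1, dtype=float)
    g2 = np.asarray(scores_group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise StatsError(f"each group needs n >= 2 (got {g1.size}, {g2.size})")
    if not (np.all(np.isfinite(g1)) and np.all(np.isfinite(g2))):
        raise StatsError("scores must be finite")
    mean1, mean2 = float(g1.mean()), float(g2.mean())
    pooled = variant == "pooled"
    if g1.var(ddof=1) == 0.0 and g2.var(ddof=1) == 0.0:
        # zero variance in both groups; means must coincide (same constant) or
        # the t statistic would be infinite — the identical-constant case is
        # the only one a score table can produce, handled as t=0, p=1.
        if mean1 == mean2:
            df = float(g1.size + g2.size - 2) if pooled else float("nan")
            return GroupComparison(g1.size, g2.size, mean1, mean2, 0.0, df, 1.0, variant)
        raise StatsError("zero within-group variance with differing means")
    res = stats.ttest_ind(g1, g2, equal_var=pooled)
    df = float(g1.size + g2.size - 2) if pooled else float(res.df)
    return GroupComparison(
        n1=int(g1.size),
        n2=int(g2.size),
        mean1=mean1,
        mean2=mean2,
        t_stat=float(res.statistic),
        df=df,
        p_two_sided=float(res.pvalue),
        variant=variant,
    )


@dataclass(frozen=True)
class StratifiedReport:
    """Overlap + score comparison of m6A-modified vs unmodified targets."""

    overlap_summary: OverlapSummary
    comparison: GroupComparison | None
    comparison_computable: bool
    per_gene: pd.DataFrame
    n_unscored: int


def stratified_overlap_report(
    annotations: Sequence[GeneAnnotation],
    scores: Mapping[str, float],
    variant: str = "pooled",
) -> StratifiedReport:
    """Fig-1-style composite: Venn counts plus the modified-vs-unmodified score test.

    set_a = target genes; set_b = m6A-modified genes (gene-set membership AND
    motif in UTR); the intersection is the m6A-modified targets. Scores are
    per-gene; target genes missing from the score table are logged and
    excluded from the comparison but kept in the overlap. With fewer than two
    scored genes in either stratum the comparison is marked not computable.
    """
    targets = {a.gene_id for a in annotations if a.is_target}
    m6a_genes = {a.gene_id for a in annotations if a.m6a_in_gene_set and a.ggach_in_utr}
    summary = overlap(targets, m6a_genes, "targets", "m6a_modified_genes")

    rows = []
    for a in annotations:
        if not a.is_target:
            continue
        rows.append(
            {
                "gene_id": a.gene_id,
                "m6a_modified_target": a.m6a_modified_target,
                "score": scores.get(a.gene_id, math.nan),
            }
        )
    per_gene = pd.DataFrame(rows, columns=["gene_id", "m6a_modified_target", "score"])
    n_unscored = int(per_gene["score"].isna().sum()) if len(per_gene) else 0
    if n_unscored:
        logger.info("%d target genes have no enrichment score", n_unscored)
    extra = set(scores) - {a.gene_id for a in annotations}
    if extra:
        logger.info("%d scored genes absent from annotations (ignored)", len(extra))

    scored = per_gene.dropna(subset=["score"])
    g_mod = scored.loc[scored["m6a_modified_target"], "score"].to_numpy()
    g_unmod = scored.loc[~scored["m6a_modified_target"], "score"].to_numpy()
    if g_mod.size >= 2 and g_unmod.size >= 2:
        comparison = compare_scores(g_mod, g_unmod, variant=variant)
        computable = True
    else:
        comparison = None
        computable = False
    return StratifiedReport(summary, comparison, computable, per_gene, n_unscored)
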