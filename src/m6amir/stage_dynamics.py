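"""Stage-wise regulation calls and down:up ratio summaries for target sets.

Each gene is called DOWN, UP or UNCHANGED from the log2 ratio of a comparison
stage to a reference stage (symmetric fold-change threshold, default 1.5).
Summaries report the down:up ratio per target set, the fold difference of
those ratios between two sets, and within-set down-regulated percentages
stratified by m6A status using down/(down+up) — UNCHANGED genes are excluded
from the percentage, matching the two-category rendering of developmental
(P1→P23) and pressure-overload (Sham→TAC) comparisons. Because the field
rarely states the fold-change cutoff behind "down/up" counts, a sensitivity
sweep over several thresholds is provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .overlap_stats import round_half_up

logger = logging.getLogger(__name__)

CALL_DOWN = "DOWN"
CALL_UP = "UP"
CALL_UNCHANGED = "UNCHANGED"
CALL_NOT_COMPUTABLE = "NOT_COMPUTABLE"

DEFAULT_FC_THRESHOLD = 1.5
SENSITIVITY_THRESHOLDS = (1.2, 1.5, 2.0)


class StageError(ValueError):
    """Raised for malformed stage matrices or undefined summaries."""


@dataclass
class StageMatrix:
    """Gene × stage non-negative abundances with a designated reference stage.

    ``values`` is a pandas DataFrame indexed by gene_id with stage labels as
    columns; duplicates in either axis are rejected.
    """

    values: pd.DataFrame
    reference_stage: str

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise StageError(f"duplicate gene ids: {', '.join(map(str, dupes))}")
        if self.values.columns.duplicated().any():
            raise StageError("duplicate stage labels")
        if self.reference_stage not in self.values.columns:
            raise StageError(f"reference stage {self.reference_stage!r} not in stage labels")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise StageError("abundances must be finite and non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_labels(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class RegulationCall:
    """Direction call for one gene between the reference and a comparison stage."""

    gene_id: str
    log2_ratio: float  # NaN when not computable (0/0 without pseudocount)
    call: str


@dataclass(frozen=True)
class RatioSummary:
    """Down/up/unchanged counts for a target set with m6A-stratified percentages."""

    n_down: int
    n_up: int
    n_unchanged: int
    n_not_computable: int
    down_up_ratio: float  # inf when n_up == 0 and n_down > 0
    ratio_defined: bool
    stratified_pct_down: dict[str, float | None]  # per m6A stratum, 2-dp half-up


def call_regulation(
    matrix: StageMatrix,
    comparison_stage: str,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = 0.0,
) -> list[RegulationCall]:
    """Per-gene log2((cmp + pc) / (ref + pc)) with a symmetric threshold.

    DOWN when log2_ratio <= -log2(fc_threshold), UP when >= +log2(fc_threshold),
    UNCHANGED otherwise. With pseudocount 0, a zero reference value makes the
    ratio non-computable for that gene; such genes are flagged NOT_COMPUTABLE,
    logged, and excluded from downstream counts. A zero comparison value with
    a positive reference is an unbounded decrease (DOWN, log2 ratio -inf).
    """
    if comparison_stage not in matrix.stage_labels:
        raise StageError(f"comparison stage {comparison_stage!r} not in stage labels")
    if comparison_stage == matrix.reference_stage:
        raise StageError("comparison stage must differ from the reference stage")
    if fc_threshold < 1.0:
        raise StageError(f"fc_threshold must be >= 1, got {fc_threshold}")
    if pseudocount < 0.0:
        raise StageError("pseudocount must be >= 0")
    cut = math.log2(fc_threshold)
    ref = matrix.values[matrix.reference_stage].to_numpy(dtype=float) + pseudocount
    cmp_ = matrix.values[comparison_stage].to_numpy(dtype=float) + pseudocount
    calls: list[RegulationCall] = []
    n_nc = 0
    for gene, r, c in zip(matrix.gene_ids, ref, cmp_):
        if r == 0.0:
            calls.append(RegulationCall(gene, float("nan"), CALL_NOT_COMPUTABLE))
            n_nc += 1
            continue
        # c == 0 with a positive reference is an unbounded decrease: DOWN.
        lr = math.log2(c / r) if c > 0.0 else float("-inf")
        if lr <= -cut:
            call = CALL_DOWN
        elif lr >= cut:
            call = CALL_UP
        else:
            call = CALL_UNCHANGED
        calls.append(RegulationCall(gene, lr, call))
    if n_nc:
        logger.info("%d genes not computable at pseudocount %g", n_nc, pseudocount)
    return calls


def _summary(calls: Sequence[RegulationCall], m6a_status: Mapping[str, bool]) -> RatioSummary:
    n_down = sum(c.call == CALL_DOWN for c in calls)
    n_up = sum(c.call == CALL_UP for c in calls)
    n_unch = sum(c.call == CALL_UNCHANGED for c in calls)
    n_nc = sum(c.call == CALL_NOT_COMPUTABLE for c in calls)
    if n_up > 0:
        ratio, defined = n_down / n_up, True
    elif n_down > 0:
        ratio, defined = float("inf"), False
    else:
        ratio, defined = float("nan"), False
    strat: dict[str, float | None] = {}
    for label, flag in (("m6a_modified", True), ("unmodified", False)):
        d = sum(c.call == CALL_DOWN and bool(m6a_status.get(c.gene_id, False)) == flag for c in calls)
        u = sum(c.call == CALL_UP and bool(m6a_status.get(c.gene_id, False)) == flag for c in calls)
        strat[label] = round_half_up(Fraction(100 * d, d + u)) if d + u else None
    return RatioSummary(n_down, n_up, n_unch, n_nc, ratio, defined, strat)


def summarize_ratios(
    calls_set_a: Sequence[RegulationCall],
    calls_set_b: Sequence[RegulationCall],
    m6a_status: Mapping[str, bool],
) -> tuple[RatioSummary, RatioSummary, float]:
    """Per-set down:up ratios, stratified percentages, and the A-vs-B fold difference.

    The fold difference is ratio_A / ratio_B; it is NaN (not computable) when
    either ratio is undefined (no up-regulated genes) or zero-denominator.
    """
    if not calls_set_a or not calls_set_b:
        raise StageError("call lists must be non-empty")
    a = _summary(calls_set_a, m6a_status)
    b = _summary(calls_set_b, m6a_status)
    if a.ratio_defined and b.ratio_defined and b.down_up_ratio > 0:
        fold = a.down_up_ratio / b.down_up_ratio
    else:
        fold = float("nan")
    return a, b, fold


def threshold_sensitivity(
    matrix: StageMatrix,
    comparison_stage: str,
    thresholds: Sequence[float] = SENSITIVITY_THRESHOLDS,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Down/up/unchanged counts at several fold-change thresholds.

    Brackets the direction-count summary against the (often unstated) cutoff
    choice; counts of DOWN and UP are weakly decreasing in the threshold.
    """
    rows = []
    for fc in thresholds:
        calls = call_regulation(matrix, comparison_stage, fc_threshold=fc, pseudocount=pseudocount)
        rows.append(
            {
                "fc_threshold": fc,
                "n_down": sum(c.call == CALL_DOWN for c in calls),
                "n_up": sum(c.call == CALL_UP for c in calls),
                "n_unchanged": sum(c.call == CALL_UNCHANGED for c in calls),
                "n_not_computable": sum(c.call == CALL_NOT_COMPUTABLE for c in calls),
            }
        )
    return pd.DataFrame(rows)


def multi_stage_summaries(
    matrix: StageMatrix,
    calls_by_gene_set: Mapping[str, Sequence[str]],
    m6a_status: Mapping[str, bool],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = 0.0,
) -> dict[str, dict[str, RatioSummary]]:
    """Repeated pairwise calls of every non-reference stage against the reference.

    ``calls_by_gene_set`` maps a set name (e.g. a miRNA) to its member genes;
    returns summaries[stage][set_name]. Covers multi-stage developmental
    trajectories and the Sham-vs-TAC two-stage case alike.
    """
    out: dict[str, dict[str, RatioSummary]] = {}
    for stage in matrix.stage_labels:
        if stage == matrix.reference_stage:
            continue
        calls = call_regulation(matrix, stage, fc_threshold=fc_threshold, pseudocount=pseudocount)
        by_gene = {c.gene_id: c for c in calls}
        out[stage] = {}
        for name, genes in calls_by_gene_set.items():
            subset = [by_gene[g] for g in genes if g in by_gene]
            out[stage][name] = _summary(subset, m6a_status)
    return out
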