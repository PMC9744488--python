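"""Dual-amplicon decomposition of RNAi RT-qPCR signal into mRNA and dsRNA.

A nested amplicon (fully inside the dsRNA template) amplifies both residual
endogenous mRNA and maternally transmitted dsRNA; a semi-nested amplicon
(one primer outside the template) amplifies endogenous mRNA only.  Comparing
percent-of-wild-type between the two therefore isolates the transmitted-dsRNA
contribution, quantifies how much a nested amplicon understates knockdown,
and — at stages of low endogenous expression, where the nested signal can
exceed 100% of wild type — detects dsRNA transmission outright.  Tiling the
dsRNA region with several nested amplicons tests whether the full-length
molecule is transmitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .qpcr import Amplicon, DsRnaRegion, Nesting, PairingError, classify_amplicon

__all__ = [
    "StageSeries",
    "DsRnaCall",
    "SpanResult",
    "classify_expression_level",
    "estimate_dsrna_component",
    "call_dsrna_detection",
    "assess_persistence",
    "infer_transmitted_span",
    "LOW_EXPRESSION_FRACTION",
    "DETECTION_SD_FACTOR",
]

LOW_EXPRESSION_FRACTION = 0.10  # of the stage-series maximum wild-type ratio
DETECTION_SD_FACTOR = 3.0
PERSISTENCE_CV_MAX = 0.25
TREND_ALPHA = 0.05


@dataclass(frozen=True)
class StageSeries:
    """Percent-of-wild-type time course for one amplicon.

    Stages are ordered by window start (hours after egg lay); each stage
    carries the across-replicate mean and SD of %WT, and the wild-type
    expression ratio used for expression-level classification.
    """

    gene: str
    amplicon: str
    nesting: Nesting
    stage_starts_h: tuple[float, ...]
    pct_wt: tuple[float, ...]
    pct_wt_sd: tuple[float, ...]
    r_wt: tuple[float, ...]
    r_rnai: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.stage_starts_h)
        if not (len(self.pct_wt) == len(self.pct_wt_sd) == len(self.r_wt) == n):
            raise ValueError("stage series fields must have equal length")
        if any(b <= a for a, b in zip(self.stage_starts_h, self.stage_starts_h[1:])):
            raise ValueError("stages must be strictly ordered by start time")
        if any(p < 0 for p in self.pct_wt):
            raise ValueError("%WT cannot be negative")


@dataclass(frozen=True)
class DsRnaCall:
    gene: str
    stage_start_h: float
    detected: bool
    signal_pct: float  # percentage points of %WT attributable to dsRNA
    basis: str  # "nested_vs_semi" or "low_expression_excess"

    def __post_init__(self) -> None:
        if self.detected and self.signal_pct < 0:
            raise ValueError("detected calls need signal_pct >= 0")


@dataclass(frozen=True)
class SpanResult:
    covered_bp: int
    full_length: bool
    region_bp: int
    detected_amplicons: tuple[str, ...]


def classify_expression_level(
    r_wt: Sequence[float], *, low_fraction: float = LOW_EXPRESSION_FRACTION
) -> list[str]:
    """Label each stage 'low' or 'moderate_high' by wild-type expression.

    A stage is low when its wild-type ratio falls below ``low_fraction``
    (default 10%) of the maximum across stages.  It is the expression level,
    not the developmental stage per se, that governs when transmitted dsRNA
    dominates the nested-amplicon signal.
    """
    r = np.asarray(r_wt, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 stages")
    peak = r.max()
    if peak == 0:
        warnings.warn("all-zero wild-type series; every stage labelled low")
        return ["low"] * r.size
    return ["low" if v < low_fraction * peak else "moderate_high" for v in r]


def estimate_dsrna_component(pct_nested: float, pct_semi: float) -> float:
    """Percentage points of nested-amplicon %WT attributable to dsRNA.

    Under the decomposition model the nested amplicon reports mRNA + dsRNA
    and the semi-nested amplicon mRNA only, so the dsRNA component is the
    excess of nested over semi-nested %WT, clamped at zero (negative
    differences are measurement noise; the model constrains dsRNA >= 0).
    """
    diff = pct_nested - pct_semi
    if diff < 0:
        warnings.warn(
            f"nested %WT ({pct_nested:.3g}) below semi-nested ({pct_semi:.3g}); "
            "clamping dsRNA component to 0"
        )
        return 0.0
    return diff


def call_dsrna_detection(
    nested: StageSeries,
    semi: StageSeries,
    *,
    sd_factor: float = DETECTION_SD_FACTOR,
    low_fraction: float = LOW_EXPRESSION_FRACTION,
) -> list[DsRnaCall]:
    """Per-stage dsRNA detection from a paired nested/semi-nested series.

    dsRNA is called at a stage when the nested excess over the semi-nested
    amplicon exceeds ``sd_factor`` times the pooled replicate SD of the
    difference, or when the nested signal exceeds 100% of wild type at a
    low-expression stage (more RNA in RNAi than wild-type samples can only
    come from transmitted dsRNA).
    """
    if nested.stage_starts_h != semi.stage_starts_h:
        raise PairingError("nested and semi-nested series have different stages")
    if nested.nesting != Nesting.NESTED or semi.nesting != Nesting.SEMI_NESTED:
        raise ValueError("series must be one nested and one semi-nested amplicon")
    levels = classify_expression_level(nested.r_wt, low_fraction=low_fraction)
    calls = []
    for i, t in enumerate(nested.stage_starts_h):
        diff = nested.pct_wt[i] - semi.pct_wt[i]
        pooled_sd = float(np.hypot(nested.pct_wt_sd[i], semi.pct_wt_sd[i]))
        by_diff = diff > sd_factor * pooled_sd
        by_excess = nested.pct_wt[i] > 100.0 and levels[i] == "low"
        detected = bool(by_diff or by_excess)
        calls.append(
            DsRnaCall(
                gene=nested.gene,
                stage_start_h=t,
                detected=detected,
                signal_pct=max(0.0, diff) if detected else 0.0,
                basis="low_expression_excess" if by_excess and not by_diff
                else "nested_vs_semi",
            )
        )
    return calls


def assess_persistence(
    r_rnai: Sequence[float],
    *,
    cv_max: float = PERSISTENCE_CV_MAX,
    alpha: float = TREND_ALPHA,
) -> tuple[str, float]:
    """Is the nested-amplicon RNAi signal stable across low-expression stages?

    Returns ``("stable" | "declining", cv)``.  Stable requires a coefficient
    of variation below ``cv_max`` and no significant monotone decreasing
    trend (one-sided test on the regression slope of ratio vs stage index).
    A stable signal across stages where endogenous mRNA is negligible means
    the transmitted dsRNA persists in the egg rather than being degraded.
    """
    r = np.asarray(r_rnai, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 low-expression stages")
    cv = float(r.std(ddof=1) / r.mean()) if r.mean() > 0 else np.inf
    res = stats.linregress(np.arange(r.size), r)
    declining_trend = res.slope < 0 and (res.pvalue / 2) < alpha
    status = "stable" if (cv < cv_max and not declining_trend) else "declining"
    return status, cv


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    """Total bp covered by the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return sum(e - s + 1 for s, e in merged)


def infer_transmitted_span(
    amplicons: Sequence[Amplicon],
    calls: dict[str, bool],
    region: DsRnaRegion,
) -> SpanResult:
    """Span of the dsRNA molecule evidenced as transmitted.

    ``calls`` maps amplicon name -> detected.  The covered span is the union
    of the detected *nested* amplicon intervals; ``full_length`` is True when
    every nested amplicon tiling the region was detected — the strongest
    statement the tiling supports about transmission of the entire molecule.
    """
    nested = [a for a in amplicons
              if classify_amplicon(a, region) == Nesting.NESTED]
    detected = [a for a in nested if calls.get(a.name, False)]
    covered = _union_length([(a.start, a.end) for a in detected])
    full = bool(nested) and all(calls.get(a.name, False) for a in nested)
    return SpanResult(
        covered_bp=covered,
        full_length=full,
        region_bp=region.length,
        detected_amplicons=tuple(a.name for a in detected),
    )
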