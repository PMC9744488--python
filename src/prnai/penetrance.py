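"""Penetrance, survival, fecundity and waning analysis for pRNAi cohorts.

Offspring from periodic egg collections are scored into six cuticle
categories.  Penetrance at a timepoint is the percentage of scored offspring
showing the gene-specific phenotype, with the two minor categories
(non-specific defects and empty eggs) excluded from the denominator:

    penetrance = 100 * (cat1 + cat2) / (wt_hatched + wt_unhatched + cat1 + cat2)

Collections are pooled forward in time until each timepoint has at least 10
offspring in the denominator; a pooled timepoint is labelled by the earliest
collection start (days post injection).  Waning is the terminal decline of
penetrance to zero as the maternal dsRNA reservoir depletes; an experiment is
deemed fully waned once three consecutive collections contain only
wild-type offspring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CollectionRecord",
    "CohortLog",
    "PenetrancePoint",
    "WaningResult",
    "CATEGORIES",
    "pool_collections",
    "penetrance",
    "penetrance_series",
    "survival_curve",
    "fecundity",
    "detect_waning",
]

CATEGORIES = ("wt_hatched", "wt_unhatched", "phen_cat1", "phen_cat2",
              "nonspecific", "empty")
SCORED = CATEGORIES[:4]  # categories entering the penetrance denominator
MIN_POOL_N = 10
ZERO_RUN = 3  # consecutive all-wild-type collections ending an experiment
WANING_START_FRACTION = 0.50  # of the pre-waning series maximum


@dataclass(frozen=True)
class CollectionRecord:
    """Scored offspring of one egg-collection window."""

    treatment: str
    start_dpi: float
    end_dpi: float
    wt_hatched: int = 0
    wt_unhatched: int = 0
    phen_cat1: int = 0
    phen_cat2: int = 0
    nonspecific: int = 0
    empty: int = 0

    def __post_init__(self) -> None:
        if self.end_dpi <= self.start_dpi:
            raise ValueError("end_dpi must exceed start_dpi")
        for cat in CATEGORIES:
            if getattr(self, cat) < 0:
                raise ValueError(f"{cat} count cannot be negative")

    @property
    def scored_n(self) -> int:
        """Penetrance denominator: the four major categories."""
        return sum(getattr(self, c) for c in SCORED)

    @property
    def total_n(self) -> int:
        return sum(getattr(self, c) for c in CATEGORIES)


@dataclass(frozen=True)
class PenetrancePoint:
    timepoint_dpi: float
    penetrance: float  # % of scored offspring with the specific phenotype
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.penetrance <= 100.0):
            raise ValueError("penetrance must lie in [0, 100]")


@dataclass(frozen=True)
class WaningResult:
    waned: bool
    waning_start_dpi: float | None
    waning_end_dpi: float | None
    duration_days: float | None
    terminated: bool  # three consecutive zero collections observed


@dataclass
class CohortLog:
    """Daily bookkeeping of one female cohort.

    ``days`` are experiment days (dpi); ``female_deaths`` and ``eggs`` are
    per-day counts aligned with ``days``.
    """

    days: np.ndarray
    female_deaths: np.ndarray
    eggs: np.ndarray
    n_initial: int

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.female_deaths = np.asarray(self.female_deaths, dtype=int)
        self.eggs = np.asarray(self.eggs, dtype=int)
        if not (self.days.size == self.female_deaths.size == self.eggs.size):
            raise ValueError("cohort log arrays must align")
        if self.female_deaths.sum() > self.n_initial:
            raise ValueError("more deaths than initial females")

    def females_alive(self) -> np.ndarray:
        """Population size per day (deaths take effect on their day)."""
        return self.n_initial - np.cumsum(self.female_deaths)


def _merge(records: Sequence[CollectionRecord]) -> CollectionRecord:
    first, last = records[0], records[-1]
    totals = {c: sum(getattr(r, c) for r in records) for c in CATEGORIES}
    return CollectionRecord(
        treatment=first.treatment, start_dpi=first.start_dpi,
        end_dpi=last.end_dpi, **totals,
    )


def pool_collections(
    records: Sequence[CollectionRecord], min_n: int = MIN_POOL_N
) -> list[CollectionRecord]:
    """Pool consecutive collections until each has >= ``min_n`` scored offspring.

    Records must be ordered and non-overlapping.  Pooling merges forward: a
    short collection absorbs the following ones until the penetrance
    denominator reaches ``min_n``.  A terminal remainder below ``min_n`` is
    merged into the previous pool (with a warning).  Category totals are
    conserved exactly.
    """
    records = list(records)
    for a, b in zip(records, records[1:]):
        if b.start_dpi < a.end_dpi:
            raise ValueError(
                f"overlapping collection windows at {a.end_dpi} / {b.start_dpi} dpi"
            )
    pools: list[list[CollectionRecord]] = []
    current: list[CollectionRecord] = []
    for rec in records:
        current.append(rec)
        if sum(r.scored_n for r in current) >= min_n:
            pools.append(current)
            current = []
    if current:
        if pools:
            warnings.warn(
                f"terminal remainder of {sum(r.scored_n for r in current)} scored "
                f"offspring (< {min_n}) merged into the previous pool"
            )
            pools[-1].extend(current)
        else:
            pools.append(current)  # nothing to merge into; keep undersized pool
    return [_merge(p) for p in pools]


def penetrance(record: CollectionRecord) -> PenetrancePoint:
    """Percent gene-specific phenotype among scored offspring.

    Non-specific defects and empty eggs are excluded from the denominator;
    the timepoint is the collection start (dpi).
    """
    n = record.scored_n
    if n == 0:
        raise ValueError(
            f"collection at {record.start_dpi} dpi has an empty penetrance denominator"
        )
    affected = record.phen_cat1 + record.phen_cat2
    return PenetrancePoint(
        timepoint_dpi=record.start_dpi, penetrance=100.0 * affected / n, n=n
    )


def penetrance_series(
    records: Sequence[CollectionRecord], min_n: int = MIN_POOL_N
) -> list[PenetrancePoint]:
    """Pool then score: the standard path from raw collections to a time course."""
    return [penetrance(r) for r in pool_collections(records, min_n)]


def survival_curve(cohort: CohortLog) -> pd.DataFrame:
    """Fraction of initial females alive per day.

    A right-continuous, non-increasing step function starting at 1 (day
    values before the first death map to 1).
    """
    alive = cohort.females_alive()
    frac = alive / cohort.n_initial
    return pd.DataFrame({"day": cohort.days, "surviving_fraction": frac})


def fecundity(eggs: float, females_alive: float, days: float) -> float:
    """Eggs per female per day."""
    if females_alive <= 0 or days <= 0:
        raise ValueError("need positive female count and interval length")
    return eggs / (females_alive * days)


def detect_waning(
    points: Sequence[PenetrancePoint],
    *,
    zero_run: int = ZERO_RUN,
    start_fraction: float = WANING_START_FRACTION,
) -> WaningResult:
    """Locate the waning interval of a penetrance time course.

    Waning ends at the first of at least ``zero_run`` consecutive
    zero-penetrance collections (the experiment-termination rule); it starts
    at the last timepoint before that with penetrance at or above
    ``start_fraction`` of the pre-waning series maximum.  With no qualifying
    zero run the knockdown has not waned.
    """
    if len(points) < 5:
        raise ValueError("need at least 5 timepoints to assess waning")
    pen = np.asarray([p.penetrance for p in points])
    t = np.asarray([p.timepoint_dpi for p in points])

    end_idx = None
    run = 0
    for i, v in enumerate(pen):
        run = run + 1 if v == 0 else 0
        if run >= zero_run:
            end_idx = i - zero_run + 1
            break
    if end_idx is None:
        return WaningResult(False, None, None, None, False)

    before = pen[:end_idx]
    if before.size == 0 or before.max() == 0:
        return WaningResult(True, None, float(t[end_idx]), None, True)
    threshold = start_fraction * before.max()
    start_candidates = np.nonzero(before >= threshold)[0]
    start_idx = int(start_candidates[-1])
    return WaningResult(
        waned=True,
        waning_start_dpi=float(t[start_idx]),
        waning_end_dpi=float(t[end_idx]),
        duration_days=float(t[end_idx] - t[start_idx]),
        terminated=True,
    )
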