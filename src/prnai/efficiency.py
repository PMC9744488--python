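"""Per-well amplification efficiency and CP from raw fluorescence curves.

Implements a window-of-linearity estimator in the family of baseline-corrected
log-linear methods widely used for qPCR: estimate and subtract the baseline
fluorescence, select 4-6 consecutive cycles in the exponential phase
maximizing the linear fit of log10(F) versus cycle, and report the per-well
efficiency E = 10**slope.  CP is the fractional cycle at which the corrected
fluorescence crosses a common per-amplicon threshold placed inside the
windows, so that CP differences are directly comparable across wells of the
same amplicon.

The baseline is refined by minimizing the residual sum of squares of the
log-linear fit over candidate baselines: on an exact exponential-plus-offset
curve the residual vanishes at the true offset, making the estimator exact up
to optimizer tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import gmean

__all__ = [
    "AmplificationCurve",
    "EfficiencyFit",
    "subtract_baseline",
    "fit_window_of_linearity",
    "amplicon_mean_efficiency",
    "assign_common_threshold",
    "analyze_curves",
]

MIN_CYCLES = 15
LIFTOFF_SD_FACTOR = 10.0
PLATEAU_FRACTION = 0.85  # exponential window must stay below this fraction of plateau
MIN_WINDOW, MAX_WINDOW = 4, 6
R2_QC = 0.99
E_QC_LOW, E_QC_HIGH = 1.0, 2.2


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's fluorescence-by-cycle series (cycles 1..C)."""

    sample_id: str
    amplicon: str
    tech_replicate: int
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "fluorescence", f)
        if f.size < MIN_CYCLES:
            raise ValueError(f"need >= {MIN_CYCLES} cycles, got {f.size}")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence readings must be finite")

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(1, self.fluorescence.size + 1)


@dataclass(frozen=True)
class EfficiencyFit:
    sample_id: str
    amplicon: str
    tech_replicate: int
    baseline: float
    window: tuple[int, int]  # first and last cycle of the fitted window
    slope: float  # log10 fluorescence per cycle
    intercept: float
    r2: float
    efficiency: float  # fold per cycle, 10**slope
    cp: float | None  # set once a common per-amplicon threshold exists
    qc_pass: bool
    qc_reason: str = ""


def _liftoff_cycle(f: np.ndarray) -> int | None:
    """First cycle index (0-based) where fluorescence exceeds the early
    baseline by 10 x the SD of the first five cycles."""
    early = f[:5]
    mu, sd = early.mean(), early.std(ddof=1)
    floor = max(sd, 1e-12 * max(abs(mu), 1.0))
    above = np.nonzero(f > mu + LIFTOFF_SD_FACTOR * floor)[0]
    return int(above[0]) if above.size else None


def subtract_baseline(curve: AmplificationCurve) -> tuple[np.ndarray, float, bool]:
    """Estimate and subtract the baseline fluorescence offset.

    Returns ``(corrected, baseline, amplified)``; ``amplified`` is False when
    no lift-off is detectable (flat or noise-only curve), in which case the
    early-cycle mean is returned as the baseline.
    """
    f = curve.fluorescence
    lift = _liftoff_cycle(f)
    if lift is None:
        b = float(f[:5].mean())
        return f - b, b, False
    b = _refine_baseline(f)
    return f - b, b, True


def _exp_phase_mask(f: np.ndarray, baseline: float) -> np.ndarray:
    """Cycles usable for log-linear fitting: positive corrected signal below
    the plateau ceiling."""
    corrected = f - baseline
    plateau = corrected.max()
    return (corrected > 0) & (corrected < PLATEAU_FRACTION * plateau)


def _window_sse(logf: np.ndarray, cyc: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares line through (cyc, logf): (slope, intercept, sse, r2)."""
    n = logf.size
    x = cyc.astype(float)
    xm, ym = x.mean(), logf.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (logf - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = logf - (intercept + slope * x)
    sse = float((resid**2).sum())
    syy = float(((logf - ym) ** 2).sum())
    r2 = 1.0 - sse / syy if syy > 0 else 1.0
    return float(slope), float(intercept), sse, float(r2)


def _best_window(f: np.ndarray, baseline: float) -> tuple[int, int, float, float, float] | None:
    """Best 4-6 cycle window by R^2 of log10(F - baseline) vs cycle.

    Returns (start_idx, end_idx inclusive, slope, intercept, r2) or None.
    """
    mask = _exp_phase_mask(f, baseline)
    corrected = f - baseline
    best = None
    n = f.size
    for w in range(MAX_WINDOW, MIN_WINDOW - 1, -1):
        for s in range(0, n - w + 1):
            idx = slice(s, s + w)
            if not mask[idx].all():
                continue
            logf = np.log10(corrected[idx])
            cyc = np.arange(s + 1, s + w + 1)
            slope, intercept, sse, r2 = _window_sse(logf, cyc)
            if slope <= 0:
                continue
            if best is None or r2 > best[4] + 1e-12:
                best = (s, s + w - 1, slope, intercept, r2)
        if best is not None and best[4] > R2_QC:
            break  # prefer the widest window that already fits well
    return best


def _refine_baseline(f: np.ndarray) -> float:
    """Baseline minimizing the log-linear residual over the best window.

    On F(c) = b + F0 * E**c the residual is exactly zero at the true b, so
    the minimizer recovers it to optimizer precision.  The search is
    restricted to the neighbourhood of the early-cycle fluorescence level:
    far below it the log transform degenerates (log(F - b) ~ log(-b) becomes
    linear in F for any curve) and the residual is spuriously small.
    """
    scale = float(f.max() - f.min())
    early = f[:5]
    spread = float(early.max() - early.min())
    b0 = float(early.mean())
    lo = b0 - 5.0 * (spread + 1e-6 * max(scale, 1.0))
    hi = float(f.min()) - 1e-12 * max(scale, 1.0)
    if hi <= lo:
        return b0

    def cost(b: float) -> float:
        win = _best_window(f, b)
        if win is None:
            return np.inf
        s, e, slope, intercept, _ = win
        logf = np.log10(f[s : e + 1] - b)
        cyc = np.arange(s + 1, e + 2)
        resid = logf - (intercept + slope * cyc)
        return float((resid**2).sum())

    res = minimize_scalar(
        cost, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-13 * max(scale, 1.0), "maxiter": 200},
    )
    b = float(res.x) if np.isfinite(res.fun) else b0
    # polish in a narrow bracket around the located minimum
    span = max(1e-4 * (hi - lo), 1e-12 * max(scale, 1.0))
    res2 = minimize_scalar(
        cost, bounds=(max(lo, b - span), min(hi, b + span)), method="bounded",
        options={"xatol": 1e-15 * max(scale, 1.0), "maxiter": 200},
    )
    if np.isfinite(res2.fun) and res2.fun <= res.fun:
        b = float(res2.x)
    return b


def _polish(f: np.ndarray, s: int, e: int, baseline: float, slope: float,
            intercept: float, r2: float) -> tuple[float, float, float, float]:
    """Joint local refinement of (baseline, slope, intercept) on the window.

    Minimizes the same log-linear residual with the baseline free, starting
    from the scalar-search solution; on noiseless exponentials this converges
    to machine precision.  Kept only when it does not worsen the fit.
    """
    from scipy.optimize import least_squares

    cyc = np.arange(s + 1, e + 2, dtype=float)
    fw = f[s : e + 1]
    b_hi = float(fw.min())

    def resid(p):
        b, sl, ic = p
        return np.log10(fw - b) - (ic + sl * cyc)

    span = max(b_hi - baseline, 1e-9 * max(abs(b_hi), 1.0))
    try:
        res = least_squares(
            resid, [baseline, slope, intercept],
            bounds=([baseline - 10 * span, 0.0, -np.inf],
                    [b_hi - 1e-15 * max(abs(b_hi), 1.0), np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
    except ValueError:
        return baseline, slope, intercept, r2
    logf = np.log10(fw - res.x[0])
    syy = float(((logf - logf.mean()) ** 2).sum())
    sse = float((resid(res.x) ** 2).sum())
    new_r2 = 1.0 - sse / syy if syy > 0 else 1.0
    if new_r2 >= r2 and res.x[1] > 0:
        return float(res.x[0]), float(res.x[1]), float(res.x[2]), new_r2
    return baseline, slope, intercept, r2


def fit_window_of_linearity(curve: AmplificationCurve) -> EfficiencyFit:
    """Fit one well: baseline, window of linearity, efficiency.

    ``cp`` is left unset; call :func:`assign_common_threshold` on all fits of
    an amplicon to place the common threshold and derive comparable CPs.
    """
    corrected, baseline, amplified = subtract_baseline(curve)
    ident = dict(
        sample_id=curve.sample_id,
        amplicon=curve.amplicon,
        tech_replicate=curve.tech_replicate,
    )
    if not amplified:
        return EfficiencyFit(
            **ident, baseline=baseline, window=(0, 0), slope=np.nan,
            intercept=np.nan, r2=np.nan, efficiency=np.nan, cp=None,
            qc_pass=False, qc_reason="no_amplification",
        )
    win = _best_window(curve.fluorescence, baseline)
    if win is None:
        return EfficiencyFit(
            **ident, baseline=baseline, window=(0, 0), slope=np.nan,
            intercept=np.nan, r2=np.nan, efficiency=np.nan, cp=None,
            qc_pass=False, qc_reason="no_exponential_window",
        )
    s, e, slope, intercept, r2 = win
    baseline, slope, intercept, r2 = _polish(
        curve.fluorescence, s, e, baseline, slope, intercept, r2
    )
    eff = 10.0**slope
    qc = True
    reason = ""
    if r2 < R2_QC:
        qc, reason = False, "poor_linearity"
    elif not (E_QC_LOW < eff <= E_QC_HIGH):
        qc, reason = False, "efficiency_out_of_range"
    return EfficiencyFit(
        **ident, baseline=baseline, window=(s + 1, e + 1), slope=slope,
        intercept=intercept, r2=r2, efficiency=eff, cp=None,
        qc_pass=qc, qc_reason=reason,
    )


def _window_midpoint_fluorescence(fit: EfficiencyFit) -> float:
    mid = 0.5 * (fit.window[0] + fit.window[1])
    return 10.0 ** (fit.intercept + fit.slope * mid)


def assign_common_threshold(fits: Sequence[EfficiencyFit]) -> list[EfficiencyFit]:
    """Set CPs from one common threshold per amplicon.

    The threshold is the geometric mean of the window-midpoint fluorescences
    of the QC-passing wells; each well's CP is the fractional cycle at which
    its fitted log-linear phase crosses that threshold.
    """
    passing = [f for f in fits if f.qc_pass]
    if not passing:
        return list(fits)
    thr = float(gmean([_window_midpoint_fluorescence(f) for f in passing]))
    out = []
    for f in fits:
        if f.qc_pass:
            cp = (math.log10(thr) - f.intercept) / f.slope
            out.append(replace(f, cp=float(cp)))
        else:
            out.append(f)
    return out


def amplicon_mean_efficiency(
    fits: Sequence[EfficiencyFit], *, outlier_frac: float = 0.05, min_fits: int = 3
) -> float:
    """Mean efficiency over QC-passing fits of one amplicon, excluding wells
    deviating more than ``outlier_frac`` (default 5%) from the median."""
    eff = np.asarray([f.efficiency for f in fits if f.qc_pass], dtype=float)
    if eff.size < min_fits:
        raise ValueError(f"{eff.size} QC-passing fits, need >= {min_fits}")
    med = np.median(eff)
    kept = eff[np.abs(eff - med) <= outlier_frac * med]
    return float(kept.mean())


def analyze_curves(curves_long: pd.DataFrame) -> pd.DataFrame:
    """Raw long-format curve table -> per-well table for ratio computation.

    Input columns: sample_id, amplicon, tech_replicate, cycle, fluorescence.
    Output columns: sample_id, amplicon, tech_replicate, cp, efficiency,
    qc_pass (the well-table schema of the ratio pipeline), plus baseline,
    window and r2 diagnostics.

    Wells whose efficiency deviates more than 5% from the amplicon median are
    additionally flagged as QC failures, mirroring the per-amplicon outlier
    rule used for the mean efficiency.
    """
    fits_by_amp: dict[str, list[EfficiencyFit]] = {}
    for (sid, amp, rep), grp in curves_long.groupby(
        ["sample_id", "amplicon", "tech_replicate"]
    ):
        grp = grp.sort_values("cycle")
        curve = AmplificationCurve(sid, amp, int(rep), grp["fluorescence"].to_numpy())
        fits_by_amp.setdefault(amp, []).append(fit_window_of_linearity(curve))

    rows = []
    for amp, fits in fits_by_amp.items():
        fits = assign_common_threshold(fits)
        effs = np.asarray([f.efficiency for f in fits if f.qc_pass])
        med = np.median(effs) if effs.size else np.nan
        for f in fits:
            qc = f.qc_pass
            reason = f.qc_reason
            if qc and effs.size and abs(f.efficiency - med) > 0.05 * med:
                qc, reason = False, "efficiency_outlier"
            rows.append({
                "sample_id": f.sample_id,
                "amplicon": f.amplicon,
                "tech_replicate": f.tech_replicate,
                "cp": f.cp if f.cp is not None else np.nan,
                "efficiency": f.efficiency,
                "qc_pass": qc,
                "qc_reason": reason,
                "baseline": f.baseline,
                "window_start": f.window[0],
                "window_end": f.window[1],
                "r2": f.r2,
            })
    return pd.DataFrame(rows).sort_values(
        ["amplicon", "sample_id", "tech_replicate"]
    ).reset_index(drop=True)
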