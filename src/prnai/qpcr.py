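"""Efficiency-corrected RT-qPCR quantification for parental-RNAi experiments.

The central quantity is the relative expression ratio

    R = E_target ** dCP_target / E_ref ** dCP_ref,   dCP = CP(control) - CP(sample)

where E is the mean per-amplicon amplification efficiency (fold per cycle)
and CP the mean quantification cycle of the technical replicates.  Knockdown
strength is expressed as percent of wild type, 100 * R_RNAi / R_WT, paired by
developmental stage window and collection date.

Amplicons are classified against the dsRNA template region on the transcript:
an amplicon fully contained in the region is *nested* (its RT-qPCR signal
reports endogenous mRNA plus any transmitted dsRNA), one partially
overlapping is *semi-nested* (one primer lies outside the dsRNA template, so
it reports endogenous mRNA only), and one with no overlap is *outside*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Nesting",
    "Amplicon",
    "DsRnaRegion",
    "SampleMeta",
    "WellMeasurement",
    "ExpressionRatio",
    "PercentWT",
    "classify_amplicon",
    "mean_cp",
    "expression_ratio",
    "control_pool_cp",
    "percent_wt",
    "amplicon_mean_efficiency",
    "compute_ratios",
    "compute_percent_wt",
    "InsufficientReplicatesError",
    "PairingError",
]


class InsufficientReplicatesError(ValueError):
    """Fewer than the required number of QC-passing technical replicates."""


class PairingError(ValueError):
    """RNAi/WT measurements do not share stage window and collection date."""


class Nesting(str, Enum):
    NESTED = "nested"
    SEMI_NESTED = "semi_nested"
    OUTSIDE = "outside"


@dataclass(frozen=True)
class Amplicon:
    """RT-qPCR amplicon as a 1-based inclusive interval on the transcript."""

    name: str
    gene: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"amplicon {self.name}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"amplicon {self.name}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DsRnaRegion:
    """Transcript interval used as the dsRNA template (1-based inclusive)."""

    gene: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("dsRNA region: need end >= start >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    gene: str
    treatment: str  # "WT" or "RNAi"
    stage_start_h: float
    stage_end_h: float
    collection_date: str
    bio_replicate: int

    def __post_init__(self) -> None:
        if not (self.stage_end_h > self.stage_start_h >= 0):
            raise ValueError(
                f"sample {self.sample_id}: need stage_end_h > stage_start_h >= 0"
            )
        if self.treatment not in ("WT", "RNAi"):
            raise ValueError(f"sample {self.sample_id}: treatment must be WT or RNAi")


@dataclass(frozen=True)
class WellMeasurement:
    sample_id: str
    amplicon: str
    tech_replicate: int
    cp: float
    efficiency: float
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.cp <= 0:
            raise ValueError("cp must be positive")
        if self.qc_pass and self.efficiency <= 1:
            raise ValueError("efficiency must exceed 1 for a QC-passing well")


@dataclass(frozen=True)
class ExpressionRatio:
    sample_id: str
    target_gene: str
    R: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("expression ratio must be positive")


@dataclass(frozen=True)
class PercentWT:
    gene: str
    stage_start_h: float
    stage_end_h: float
    collection_date: str
    pct: float

    def __post_init__(self) -> None:
        if self.pct < 0:
            raise ValueError("percent of wild type cannot be negative")

    @property
    def rounded(self) -> int:
        """Display convention: nearest integer percent."""
        return int(round(self.pct))


def classify_amplicon(amplicon: Amplicon, region: DsRnaRegion) -> Nesting:
    """Classify an amplicon relative to the dsRNA template region.

    nested      : region.start <= amplicon.start and amplicon.end <= region.end
    semi_nested : overlap of >= 1 bp but not nested
    outside     : zero overlap
    """
    if amplicon.gene != region.gene:
        raise ValueError(
            f"gene mismatch: amplicon {amplicon.name} is on {amplicon.gene!r}, "
            f"region on {region.gene!r}"
        )
    if region.start <= amplicon.start and amplicon.end <= region.end:
        return Nesting.NESTED
    overlap = min(amplicon.end, region.end) - max(amplicon.start, region.start) + 1
    if overlap >= 1:
        return Nesting.SEMI_NESTED
    return Nesting.OUTSIDE


def mean_cp(wells: Sequence[WellMeasurement], min_wells: int = 2) -> float:
    """Arithmetic mean CP over QC-passing technical replicates.

    Raises :class:`InsufficientReplicatesError` with fewer than ``min_wells``
    passing wells.
    """
    passing = [w.cp for w in wells if w.qc_pass]
    if len(passing) < min_wells:
        raise InsufficientReplicatesError(
            f"{len(passing)} QC-passing wells, need >= {min_wells}"
        )
    return float(np.mean(passing))


def expression_ratio(
    e_target: float, dcp_target: float, e_ref: float, dcp_ref: float
) -> float:
    """Efficiency-corrected relative expression ratio.

    ``dcp`` is CP(control) - CP(sample); efficiencies are fold per cycle
    (ideal doubling = 2.0) and must exceed 1.
    """
    if e_target <= 1 or e_ref <= 1:
        raise ValueError("amplification efficiencies must exceed 1")
    return e_target**dcp_target / e_ref**dcp_ref


def control_pool_cp(cps: Sequence[float], efficiency: float) -> float:
    """CP of a computational equimolar pool of samples, per amplicon.

    A physically pooled control averages template *amounts*, not cycles, so
    the pool CP is -log_E(mean_s E^(-CP_s)): back-transform each sample CP to
    a relative template quantity, average, and transform back.
    """
    if len(cps) == 0:
        raise ValueError("control pool needs at least one sample CP")
    if efficiency <= 1:
        raise ValueError("efficiency must exceed 1")
    cps = np.asarray(cps, dtype=float)
    # log-sum-exp in base E for numerical stability at large CP
    log_q = -cps * math.log(efficiency)
    m = log_q.max()
    pooled = m + math.log(np.mean(np.exp(log_q - m)))
    return float(-pooled / math.log(efficiency))


def percent_wt(r_rnai: ExpressionRatio, r_wt: ExpressionRatio, *,
               gene: str | None = None,
               stage: tuple[float, float] = (0.0, 1.0),
               collection_date: str = "") -> PercentWT:
    """Percent of wild type: 100 * R_RNAi / R_WT for a matched timepoint."""
    if r_rnai.target_gene != r_wt.target_gene:
        raise PairingError(
            f"gene mismatch: {r_rnai.target_gene!r} vs {r_wt.target_gene!r}"
        )
    if r_wt.R == 0:
        raise ValueError("wild-type ratio is zero")
    return PercentWT(
        gene=gene or r_rnai.target_gene,
        stage_start_h=stage[0],
        stage_end_h=stage[1],
        collection_date=collection_date,
        pct=100.0 * r_rnai.R / r_wt.R,
    )


def amplicon_mean_efficiency(
    efficiencies: Sequence[float], *, outlier_frac: float = 0.05, min_fits: int = 3
) -> float:
    """Mean per-amplicon efficiency after excluding wells deviating more than
    ``outlier_frac`` (default 5%) from the median."""
    eff = np.asarray([e for e in efficiencies if np.isfinite(e)], dtype=float)
    if eff.size < min_fits:
        raise InsufficientReplicatesError(
            f"{eff.size} efficiency fits, need >= {min_fits}"
        )
    med = np.median(eff)
    kept = eff[np.abs(eff - med) <= outlier_frac * med]
    return float(kept.mean())


# ---------------------------------------------------------------------------
# Table-level pipeline

_CP_OUTLIER_CYCLES = 0.5  # well CP deviating more than this from replicate median fails QC


def _well_qc(group: pd.DataFrame) -> pd.Series:
    """Per-well QC within one sample x amplicon replicate set.

    A well fails if it was already flagged upstream (``qc_pass`` False from
    the efficiency module) or if its CP deviates > 0.5 cycles from the
    replicate median.
    """
    ok = group["qc_pass"].astype(bool).to_numpy()
    cp = group["cp"].to_numpy(dtype=float)
    if ok.sum() >= 1:
        med = np.median(cp[ok])
        ok = ok & (np.abs(cp - med) <= _CP_OUTLIER_CYCLES)
    return pd.Series(ok, index=group.index)


def compute_ratios(
    samples: pd.DataFrame,
    wells: pd.DataFrame,
    reference: str,
    *,
    min_wells: int = 2,
) -> pd.DataFrame:
    """Per-sample efficiency-corrected expression ratios against a pooled control.

    Parameters
    ----------
    samples
        Sample sheet: sample_id, gene, treatment, stage_start_h, stage_end_h,
        collection_date, bio_replicate.
    wells
        Well table: sample_id, amplicon, tech_replicate, cp, efficiency,
        qc_pass.
    reference
        Name of the reference-gene amplicon (single-reference normalization).

    Returns
    -------
    DataFrame with one row per sample x target amplicon: sample metadata,
    amplicon, mean CPs, per-amplicon mean efficiencies, and the ratio R.

    The control CP per amplicon is the CP of an equimolar computational pool
    of every sample of the experiment (WT and RNAi, all timepoints, all
    biological replicates).
    """
    wells = wells.copy()
    if "qc_pass" not in wells.columns:
        wells["qc_pass"] = True
    wells["qc_pass"] = (
        wells.groupby(["sample_id", "amplicon"], group_keys=False)
        .apply(_well_qc, include_groups=False)
        .reindex(wells.index)
    )

    # per (sample, amplicon) mean CP over QC-passing wells
    rows = []
    for (sid, amp), grp in wells.groupby(["sample_id", "amplicon"]):
        passing = grp[grp["qc_pass"]]
        if len(passing) < min_wells:
            continue
        rows.append({"sample_id": sid, "amplicon": amp,
                     "mean_cp": passing["cp"].mean()})
    cp_tab = pd.DataFrame(rows)
    if cp_tab.empty:
        raise InsufficientReplicatesError("no sample x amplicon with enough passing wells")

    # per-amplicon mean efficiency over QC-passing wells
    eff = {}
    for amp, grp in wells[wells["qc_pass"]].groupby("amplicon"):
        eff[amp] = amplicon_mean_efficiency(grp["efficiency"].to_numpy())
    cp_tab["efficiency"] = cp_tab["amplicon"].map(eff)

    # pooled control CP per amplicon
    ctrl = {
        amp: control_pool_cp(grp["mean_cp"].to_numpy(), eff[amp])
        for amp, grp in cp_tab.groupby("amplicon")
    }
    cp_tab["control_cp"] = cp_tab["amplicon"].map(ctrl)
    cp_tab["dcp"] = cp_tab["control_cp"] - cp_tab["mean_cp"]

    ref_tab = cp_tab[cp_tab["amplicon"] == reference][["sample_id", "efficiency", "dcp"]]
    if ref_tab.empty:
        raise ValueError(f"reference amplicon {reference!r} has no valid measurements")
    ref_tab = ref_tab.rename(columns={"efficiency": "e_ref", "dcp": "dcp_ref"})

    out = cp_tab[cp_tab["amplicon"] != reference].merge(ref_tab, on="sample_id")
    out["R"] = out.apply(
        lambda r: expression_ratio(r["efficiency"], r["dcp"], r["e_ref"], r["dcp_ref"]),
        axis=1,
    )
    out = out.merge(samples, on="sample_id", how="left")
    cols = [
        "sample_id", "gene", "treatment", "stage_start_h", "stage_end_h",
        "collection_date", "bio_replicate", "amplicon", "mean_cp",
        "efficiency", "control_cp", "R",
    ]
    return out[cols].sort_values(["amplicon", "stage_start_h", "sample_id"]).reset_index(drop=True)


def compute_percent_wt(ratios: pd.DataFrame) -> pd.DataFrame:
    """Pair RNAi with WT ratios and summarize percent-of-wild-type.

    Pairing is by (amplicon, stage window, collection date, biological
    replicate); biological replicates are then summarized as mean +/- one
    standard deviation of per-replicate %WT.  The mean WT ratio per stage is
    carried along for downstream expression-level classification.
    """
    keys = ["amplicon", "stage_start_h", "stage_end_h", "collection_date", "bio_replicate"]
    wt = ratios[ratios["treatment"] == "WT"]
    kd = ratios[ratios["treatment"] == "RNAi"]
    merged = kd.merge(wt[keys + ["R"]], on=keys, suffixes=("_rnai", "_wt"))
    if merged.empty:
        raise PairingError("no RNAi/WT pairs share stage window, date and replicate")
    merged["pct_wt"] = 100.0 * merged["R_rnai"] / merged["R_wt"]

    grp_keys = ["gene", "amplicon", "stage_start_h", "stage_end_h", "collection_date"]
    summary = (
        merged.groupby(grp_keys)
        .agg(
            pct_wt_mean=("pct_wt", "mean"),
            pct_wt_sd=("pct_wt", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            n_replicates=("pct_wt", "size"),
            r_wt_mean=("R_wt", "mean"),
            r_rnai_mean=("R_rnai", "mean"),
        )
        .reset_index()
        .sort_values(["amplicon", "stage_start_h"])
        .reset_index(drop=True)
    )
    return summary
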