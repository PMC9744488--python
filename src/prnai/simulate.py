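"""Seeded generators for every input family, with known ground truth.

Three families of synthetic data mirror the experimental designs the analysis
modules consume:

* **qPCR** — per-well CP/efficiency tables (and optional raw fluorescence
  curves) from a mixture model of endogenous mRNA and transmitted dsRNA.  The
  endogenous template of a stage window is the window-average of a
  developmental expression profile M(t); RNAi scales it by a knockdown factor
  k; nested amplicons in RNAi samples additionally see a constant dsRNA
  template D per egg (transmission at saturating levels).  At zero noise the
  closed forms hold exactly: semi-nested %WT = 100 k and nested
  %WT = 100 (M k + D) / M per stage.
* **Orthology tables** — per-level orthogroup TSVs over a compact metazoan
  taxonomy with planted clade losses, clade duplications, redundant isoforms,
  partial-length members and wider-level-only (discordant) species.
* **pRNAi cohorts** — per-female dsRNA reservoirs decaying with a planted
  half-life drive offspring phenotype probability through a sigmoid link;
  scored collections, female deaths and egg counts emulate a months-long
  penetrance time course with eventual waning.

All generators take an explicit seed and are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .penetrance import CATEGORIES, CollectionRecord
from .phyloprofile import Taxonomy
from .qpcr import Amplicon, DsRnaRegion, Nesting, classify_amplicon

__all__ = [
    "ExpressionProfileSpec",
    "SimConfig",
    "simulate_qpcr",
    "simulate_exponential_curves",
    "default_taxonomy",
    "simulate_orthology",
    "simulate_cohort",
    "EMBRYOGENESIS_SPAN_H",
]

EMBRYOGENESIS_SPAN_H = 72.0  # beetle embryogenesis lasts about three days
MAX_CYCLES = 40
CP_AT_PEAK = 20.0  # CP of one peak-abundance template unit at efficiency 2


# ---------------------------------------------------------------------------
# qPCR generator

@dataclass(frozen=True)
class ExpressionProfileSpec:
    """Developmental expression profile M(t) over embryogenesis.

    ``unimodal_pulse`` is a single Gaussian pulse (early serosa-specifier
    style), ``bimodal`` the sum of two pulses separated by a low trough
    (chitin-synthase style), ``late_onset`` a sigmoidal ramp.  Peak abundance
    is in arbitrary template units.
    """

    shape: str = "unimodal_pulse"
    peak_times_h: tuple[float, ...] = (8.0,)
    widths_h: tuple[float, ...] = (4.0,)
    peak_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("unimodal_pulse", "bimodal", "late_onset"):
            raise ValueError(f"unknown profile shape {self.shape!r}")
        if self.peak_abundance < 0:
            raise ValueError("peak abundance must be >= 0")
        for t in self.peak_times_h:
            if not (0 <= t <= EMBRYOGENESIS_SPAN_H):
                raise ValueError("peak times must lie within embryogenesis (0-72 h)")

    def abundance(self, t_h: np.ndarray | float) -> np.ndarray:
        """Template abundance at time(s) t (hours after egg lay)."""
        t = np.asarray(t_h, dtype=float)
        if self.shape == "late_onset":
            t0 = self.peak_times_h[0]
            w = self.widths_h[0]
            out = self.peak_abundance / (1.0 + np.exp(-(t - t0) / w))
        else:
            out = np.zeros_like(t)
            for mu, w in zip(self.peak_times_h, self.widths_h):
                out = out + np.exp(-0.5 * ((t - mu) / w) ** 2)
            out = self.peak_abundance * out
        return out

    def window_mean(self, start_h: float, end_h: float, n_grid: int = 257) -> float:
        """Average abundance over a stage window — a broad egg collection
        pools embryos across the window, diluting any expression peak."""
        grid = np.linspace(start_h, end_h, n_grid)
        return float(np.trapezoid(self.abundance(grid), grid) / (end_h - start_h))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the qPCR generator.

    ``knockdown_k`` is the residual fraction of endogenous expression after
    RNAi; ``dsrna_level`` the transmitted dsRNA template per egg (same units
    as the expression profile, constant across stages by default);
    ``sigma_cp`` the technical CP noise in cycles; ``sigma_bio`` the
    biological lognormal SD on endogenous template.  ``efficiency`` maps
    amplicon name -> true amplification efficiency; unlisted amplicons use
    ``base_efficiency`` minus ``efficiency_length_slope`` per bp above 100 bp
    (longer amplicons amplify less efficiently).
    """

    knockdown_k: float = 0.05
    dsrna_level: float = 0.25
    sigma_cp: float = 0.15
    sigma_bio: float = 0.0
    n_tech: int = 3
    n_bio: int = 3
    seed: int = 0
    base_efficiency: float = 1.90
    efficiency: Mapping[str, float] = field(default_factory=dict)
    efficiency_length_slope: float = 0.0  # efficiency lost per bp above 100 bp
    dsrna_detectability: float = 1.0  # scales how much dsRNA the RT captures
    dsrna_decay_per_stage: float = 1.0  # < 1 models a decaying dsRNA reservoir

    def __post_init__(self) -> None:
        if not (0 < self.knockdown_k <= 1):
            raise ValueError("knockdown factor must lie in (0, 1]")
        if min(self.dsrna_level, self.sigma_cp, self.sigma_bio) < 0:
            raise ValueError("noise and dsRNA parameters must be >= 0")

    def true_efficiency(self, amplicon: Amplicon) -> float:
        if amplicon.name in self.efficiency:
            return float(self.efficiency[amplicon.name])
        e = self.base_efficiency - self.efficiency_length_slope * max(
            amplicon.length - 100, 0
        )
        return float(np.clip(e, 1.05, 2.0))


def _cp_from_template(q: float, e: float, m_peak: float) -> float:
    """Analytic CP: calibrated so one peak-unit template reads CP 20 at E=2."""
    c0 = CP_AT_PEAK + math.log(m_peak) / math.log(2.0)
    return c0 - math.log(q) / math.log(e)


def simulate_qpcr(
    profile: ExpressionProfileSpec,
    amplicons: Sequence[Amplicon],
    region: DsRnaRegion,
    stages: Sequence[tuple[float, float]],
    config: SimConfig,
    *,
    reference: str = "ref",
    return_curves: bool = False,
) -> dict[str, pd.DataFrame]:
    """Generate a full qPCR experiment: sample sheet, well table, ground truth.

    Amplicons on the target gene are classified against the dsRNA region;
    the amplicon named ``reference`` (on another gene, constitutive) provides
    normalization.  Per well the template is

        q = (M_stage * k_treatment + D * is_nested * is_RNAi) * bio_noise

    and CP = C0 - log_E(q) + N(0, sigma_cp); the CP jitter is realized as a
    template jitter q * E**(-eps) so that optional raw curves and the well
    table describe the same wells.  Wells with zero template are censored at
    the maximum cycle and flagged as QC failures.

    Returns a dict with ``samples``, ``wells``, ``truth`` (and ``curves`` in
    long format when requested) in the TSV schemas of the analysis modules.
    """
    rng = np.random.default_rng(config.seed)
    target_amps = [a for a in amplicons if a.name != reference]
    ref_amp = next(a for a in amplicons if a.name == reference)
    nesting = {a.name: classify_amplicon(a, region) for a in target_amps
               if a.gene == region.gene}
    m_peak = profile.peak_abundance

    samples, wells, truth, curve_rows = [], [], [], []
    for si, (s0, s1) in enumerate(stages):
        m_stage = profile.window_mean(s0, s1)
        d_stage = (config.dsrna_level * config.dsrna_detectability
                   * config.dsrna_decay_per_stage**si)
        for treatment in ("WT", "RNAi"):
            k = config.knockdown_k if treatment == "RNAi" else 1.0
            for b in range(1, config.n_bio + 1):
                sid = f"{treatment}_st{si}_b{b}"
                samples.append({
                    "sample_id": sid, "gene": region.gene, "treatment": treatment,
                    "stage_start_h": s0, "stage_end_h": s1,
                    "collection_date": "batch1", "bio_replicate": b,
                })
                bio = math.exp(rng.normal(0.0, config.sigma_bio)) \
                    if config.sigma_bio > 0 else 1.0
                q_m = m_stage * k * bio
                truth.append({
                    "sample_id": sid, "stage_start_h": s0, "M": m_stage,
                    "D": d_stage if treatment == "RNAi" else 0.0, "k": k,
                    "bio_factor": bio,
                })
                for amp in amplicons:
                    e = config.true_efficiency(amp)
                    if amp.name == reference:
                        q = 1.0 * m_peak  # constitutive reference gene
                    elif nesting.get(amp.name) == Nesting.NESTED and treatment == "RNAi":
                        q = q_m + d_stage
                    else:
                        q = q_m
                    for tr in range(1, config.n_tech + 1):
                        eps = rng.normal(0.0, config.sigma_cp) \
                            if config.sigma_cp > 0 else 0.0
                        if q <= 0:
                            wells.append({
                                "sample_id": sid, "amplicon": amp.name,
                                "tech_replicate": tr, "cp": float(MAX_CYCLES),
                                "efficiency": e, "qc_pass": False,
                            })
                            continue
                        q_jit = q * e ** (-eps)
                        cp = _cp_from_template(q_jit, e, m_peak)
                        wells.append({
                            "sample_id": sid, "amplicon": amp.name,
                            "tech_replicate": tr, "cp": cp,
                            "efficiency": e, "qc_pass": True,
                        })
                        if return_curves:
                            curve_rows.append((sid, amp.name, tr, q_jit / m_peak, e))

    out = {
        "samples": pd.DataFrame(samples),
        "wells": pd.DataFrame(wells),
        "truth": pd.DataFrame(truth),
    }
    if return_curves:
        out["curves"] = _curves_from_templates(curve_rows, rng)
    return out


def _logistic_curve(x0: float, e: float, plateau: float, n_cycles: int) -> np.ndarray:
    """Amplification with efficiency declining as product accumulates."""
    x = np.empty(n_cycles)
    cur = x0
    for c in range(n_cycles):
        cur = cur * (1.0 + (e - 1.0) * max(0.0, 1.0 - cur / plateau))
        x[c] = cur
    return x


def _curves_from_templates(rows, rng, *, baseline: float = 0.05,
                           plateau: float = 1.0, x0_at_peak: float = 1e-6,
                           read_noise: float = 0.005) -> pd.DataFrame:
    recs = []
    for sid, amp, tr, rel_q, e in rows:
        x = _logistic_curve(rel_q * x0_at_peak, e, plateau, MAX_CYCLES)
        noise = rng.normal(0.0, read_noise, MAX_CYCLES) if read_noise > 0 else 0.0
        f = baseline + x * (1.0 + noise)
        for c in range(MAX_CYCLES):
            recs.append({"sample_id": sid, "amplicon": amp, "tech_replicate": tr,
                         "cycle": c + 1, "fluorescence": f[c]})
    return pd.DataFrame(recs)


def simulate_exponential_curves(
    n: int,
    *,
    e_range: tuple[float, float] = (1.6, 2.0),
    seed: int = 0,
    noise: float = 0.0,
    baseline: float = 0.1,
    plateau: float = 10.0,
    f0_range_log10: tuple[float, float] = (-7.0, -4.0),
    n_cycles: int = MAX_CYCLES,
) -> tuple[list, pd.DataFrame]:
    """Exponential-plus-baseline curves with planted efficiencies.

    F(c) = baseline + min(F0 * E**c, plateau), optionally with multiplicative
    read noise on the signal.  Returns (curves, truth table); curves are
    :class:`~prnai.efficiency.AmplificationCurve` objects.
    """
    from .efficiency import AmplificationCurve

    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1)
    curves, truth = [], []
    for i in range(n):
        e = rng.uniform(*e_range)
        f0 = 10.0 ** rng.uniform(*f0_range_log10) * plateau
        x = np.minimum(f0 * e**cycles, plateau)
        mult = 1.0 + rng.normal(0.0, noise, n_cycles) if noise > 0 else 1.0
        f = baseline + x * mult
        curves.append(AmplificationCurve("sim", "amp", i, f))
        truth.append({"well": i, "E": e, "F0": f0, "baseline": baseline})
    return curves, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Orthology generator

_DEFAULT_TAXONOMY = """\
Metazoa
  Vertebrata
    Danio_rerio
    Homo_sapiens
    Xenopus_laevis
  Arthropoda
    Chelicerata
      Ixodes_scapularis
      Parasteatoda_tepidariorum
      Centruroides_sculpturatus
    Hexapoda
      Entognatha
        Folsomia_candida
        Orchesella_cincta
      Insecta
        Coleoptera
          Tribolium_castaneum
          Anoplophora_glabripennis
          Dendroctonus_ponderosae
        Lepidoptera
          Bombyx_mori
          Danaus_plexippus
          Heliconius_melpomene
        Diptera
          Drosophila_melanogaster
          Anopheles_gambiae
          Aedes_aegypti
        Hemiptera
          Heteroptera
            Cimex_lectularius
            Halyomorpha_halys
            Oncopeltus_fasciatus
            Rhodnius_prolixus
          Sternorrhyncha
            Acyrthosiphon_pisum
            Bemisia_tabaci
            Diaphorina_citri
        Hymenoptera
          Apis_mellifera
          Nasonia_vitripennis
          Solenopsis_invicta
"""

DEFAULT_LEVELS = ("Metazoa", "Arthropoda", "Hexapoda", "Insecta")


def default_taxonomy() -> Taxonomy:
    """Compact metazoan taxonomy (28 species) used by the orthology generator."""
    return Taxonomy.from_indented(_DEFAULT_TAXONOMY)


def simulate_orthology(
    *,
    taxonomy: Taxonomy | None = None,
    loss_clades: Sequence[str] = ("Heteroptera", "Diptera"),
    dup_clades: Sequence[str] = ("Lepidoptera",),
    discordant_species: Sequence[str] = ("Centruroides_sculpturatus",),
    isoform_rate: float = 0.3,
    outlier_rate: float = 0.15,
    levels: Sequence[str] = DEFAULT_LEVELS,
    mean_length: float = 500.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-level orthogroup tables with planted evolutionary events.

    Every species carries one true gene copy except members of
    ``loss_clades`` (0 copies), members of ``dup_clades`` (2 copies) and
    ``discordant_species`` (0 at their most restrictive level, but one
    divergent member in the widest-level clustering only — emulating a
    protein pulled into the family solely by the wider analysis).  Redundant
    isoform rows (rate per protein) and short partial fragments (rate per
    species) are layered on top; curation should remove both.

    Returns (long table in the loader schema, ground-truth dict).
    """
    taxonomy = taxonomy or default_taxonomy()
    rng = np.random.default_rng(seed)
    for clade in list(loss_clades) + list(dup_clades):
        if clade not in taxonomy.nodes:
            raise ValueError(f"planted clade {clade!r} not in taxonomy")

    loss_species = {s for c in loss_clades for s in taxonomy.clade_species(c)}
    dup_species = {s for c in dup_clades for s in taxonomy.clade_species(c)}
    truth_counts: dict[str, int] = {}
    for sp in sorted(taxonomy.species):
        if sp in loss_species or sp in discordant_species:
            truth_counts[sp] = 0
        elif sp in dup_species:
            truth_counts[sp] = 2
        else:
            truth_counts[sp] = 1

    # invent loci and isoforms once; reuse across levels for consistency
    proteins: dict[str, list[tuple[str, int]]] = {}
    for sp in sorted(taxonomy.species):
        members = []
        for g in range(truth_counts[sp]):
            length = int(rng.normal(mean_length, 30))
            members.append((f"{sp}_g{g + 1}-PA", length))
            if rng.random() < isoform_rate:  # redundant shorter isoform
                members.append((f"{sp}_g{g + 1}-PB", int(length * rng.uniform(0.6, 0.95))))
        if truth_counts[sp] > 0 and rng.random() < outlier_rate:
            members.append((f"{sp}_frag1-PA", int(mean_length * 0.30)))
        proteins[sp] = members

    rows = []
    for level in levels:
        clade = set(taxonomy.clade_species(level))
        og_id = f"OG_{level}"
        for sp in sorted(clade):
            for pid, length in proteins.get(sp, []):
                rows.append({"level": level, "og_id": og_id, "species": sp,
                             "protein_id": pid, "length": length})
        if level == max(levels, key=lambda l: len(taxonomy.clade_species(l))):
            for sp in discordant_species:  # divergent wider-level-only member
                rows.append({"level": level, "og_id": og_id, "species": sp,
                             "protein_id": f"{sp}_div1-PA",
                             "length": int(mean_length * 1.1)})
    table = pd.DataFrame(rows)
    truth = {
        "copy_number": truth_counts,
        "loss_clades": sorted(loss_clades),
        "dup_clades": sorted(dup_clades),
        "discordant_species": sorted(discordant_species),
    }
    return table, truth


# ---------------------------------------------------------------------------
# Cohort generator

def _default_fecundity(age_days: np.ndarray) -> np.ndarray:
    """Eggs per female per day as a function of female age: ramp to a
    plateau of ~5 by day 10, then slow decline after day 80."""
    age = np.asarray(age_days, dtype=float)
    ramp = 1.0 / (1.0 + np.exp(-(age - 5.0) / 2.0))
    decline = 1.0 / (1.0 + np.exp((age - 110.0) / 15.0))
    return 5.0 * ramp * decline


def simulate_cohort(
    *,
    n_females: int = 12,
    half_life_days: float = 6.0,
    plateau_days: float = 55.0,
    hill: float = 8.0,
    mortality_hazard: float = 0.004,
    fecundity_curve: Callable[[np.ndarray], np.ndarray] = _default_fecundity,
    collection_interval_days: float = 4.0,
    experiment_days: int = 130,
    reservoir_cv: float = 0.15,
    seed: int = 0,
    treatment: str = "RNAi",
) -> tuple[list[CollectionRecord], pd.DataFrame, dict]:
    """Months-long pRNAi cohort with reservoir-depletion waning.

    Each female starts with a dsRNA reservoir (lognormal spread
    ``reservoir_cv``) that decays with half-life ``half_life_days``; an
    offspring is affected with probability
    sigmoid(hill * (log2 reservoir - log2 threshold) * ln 2), with the
    threshold placed so the median female crosses it at ``plateau_days`` —
    penetrance therefore plateaus near 100% and wanes around that day over an
    interval set by the half-life and the link steepness.  Deaths follow a
    constant daily hazard; egg output follows the age-dependent fecundity
    curve.  For ``treatment="WT"`` no offspring are affected.

    Returns (collection records, daily cohort log, ground truth).  The truth
    includes the deterministic expected penetrance of the median female at
    each collection, from which the planted waning interval is defined.
    """
    rng = np.random.default_rng(seed)
    days = np.arange(1, experiment_days + 1, dtype=float)

    log2_r0 = rng.normal(0.0, reservoir_cv / math.log(2), n_females)
    # threshold placed so the median female's reservoir crosses it at
    # plateau_days; a non-depleting reservoir never reaches it
    log2_thresh = (-plateau_days / half_life_days
                   if math.isfinite(half_life_days) else -math.inf)

    def p_affected(log2_r0_i: float, t: float) -> float:
        if treatment != "RNAi":
            return 0.0
        if not math.isfinite(log2_thresh):
            return 1.0
        log2_r = log2_r0_i - t / half_life_days
        z = hill * (log2_r - log2_thresh) * math.log(2.0)
        return 1.0 / (1.0 + math.exp(-z))

    alive = np.ones(n_females, dtype=bool)
    deaths = np.zeros(days.size, dtype=int)
    eggs_per_day = np.zeros(days.size, dtype=int)
    egg_mothers: list[list[int]] = []

    for di, day in enumerate(days):
        dead_today = alive & (rng.random(n_females) < mortality_hazard)
        alive &= ~dead_today
        deaths[di] = int(dead_today.sum())
        n_alive = int(alive.sum())
        rate = float(fecundity_curve(np.array([day]))[0])
        n_eggs = rng.poisson(rate * n_alive) if n_alive else 0
        eggs_per_day[di] = n_eggs
        mothers = rng.choice(np.nonzero(alive)[0], size=n_eggs).tolist() if n_eggs else []
        egg_mothers.append(mothers)

    cohort = pd.DataFrame({
        "day": days.astype(int),
        "females_alive": n_females - np.cumsum(deaths),
        "female_deaths": deaths,
        "eggs": eggs_per_day,
    })

    records: list[CollectionRecord] = []
    expected = []
    start = 1.0
    while start <= experiment_days:
        end = min(start + collection_interval_days, experiment_days + 1.0)
        day_idx = np.nonzero((days >= start) & (days < end))[0]
        counts = dict.fromkeys(CATEGORIES, 0)
        for di in day_idx:
            for mother in egg_mothers[di]:
                u = rng.random()
                if u < 0.05:
                    counts["empty"] += 1
                    continue
                if u < 0.07:
                    counts["nonspecific"] += 1
                    continue
                if rng.random() < p_affected(log2_r0[mother], days[di]):
                    cat = "phen_cat1" if rng.random() < 0.6 else "phen_cat2"
                else:
                    cat = "wt_hatched" if rng.random() < 0.9 else "wt_unhatched"
                counts[cat] += 1
        records.append(CollectionRecord(treatment=treatment, start_dpi=start,
                                        end_dpi=end, **counts))
        mid = 0.5 * (start + min(end, experiment_days))
        p_mid = p_affected(0.0, mid)
        exp_alive = n_females * (1.0 - mortality_hazard) ** mid
        exp_n = float(sum(
            fecundity_curve(np.array([d]))[0] * exp_alive * 0.93  # scored fraction
            for d in days[day_idx]
        ))
        expected.append({
            "start_dpi": start,
            "expected_penetrance": 100.0 * p_mid,
            "expected_scored_n": exp_n,
            "expected_affected": p_mid * exp_n,
        })
        start = end

    truth = {
        "half_life_days": half_life_days,
        "plateau_days": plateau_days,
        "expected_penetrance": pd.DataFrame(expected),
        "collection_interval_days": collection_interval_days,
    }
    return records, cohort, truth


def planted_waning(truth: dict):
    """Ground-truth waning interval implied by the generator's expectations.

    Builds the deterministic penetrance series of the median female at the
    generator's collection schedule — a collection counts as zero when it is
    expected to contain fewer than half an affected offspring — and applies
    the same waning rule the analysis uses, so planted and detected intervals
    are directly comparable.
    """
    from .penetrance import PenetrancePoint, detect_waning

    exp = truth["expected_penetrance"]
    points = [
        PenetrancePoint(
            timepoint_dpi=float(r.start_dpi),
            penetrance=0.0 if r.expected_affected < 0.5
            else float(min(100.0, r.expected_penetrance)),
            n=max(int(round(r.expected_scored_n)), 10),
        )
        for r in exp.itertuples()
    ]
    return detect_waning(points)
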