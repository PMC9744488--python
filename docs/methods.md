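# Methods

This note documents the models, defaults and numerical choices behind
`prnai`, and what the synthetic-data validation does and does not establish.

## Expression quantification

The expression ratio is the efficiency-corrected ΔΔCt form
R = E_t^ΔCP_t / E_r^ΔCP_r with ΔCP = CP(control) − CP(sample), a single
reference amplicon, and per-amplicon mean efficiencies. Efficiencies are
fold-per-cycle (ideal doubling 2.0) and must exceed 1.

**Pooled control.** The experimental control of this design is a physical
pool of all samples (both treatments, all timepoints, all biological
replicates). A physical pool averages template *amounts*, not cycles, so the
computational control CP per amplicon is −log_E(mean_s E^(−CP_s)): each
sample CP is back-transformed to a relative quantity, averaged, and
transformed back (computed with a log-sum-exp to stay stable at high CP).
Whether such a pool is assembled before or after reverse transcription does
not change this arithmetic. Because the same pooled control enters both
R_RNAi and R_WT, it cancels exactly in %WT; it matters only for the
individual R values.

**Replicate QC.** A well fails if flagged by the efficiency module or if its
CP deviates more than 0.5 cycles from its technical-replicate median; a mean
CP requires at least two passing wells. Per-amplicon mean efficiency excludes
wells deviating more than 5% from the median and requires three fits. These
mirror common window-of-linearity practice; the 0.5-cycle and 5% bounds are
conventional, not fitted.

**Reporting.** %WT is stored unrounded; display rounds to the nearest
integer percent. Biological replicates are summarized as mean ± one SD.
Coordinates are 1-based inclusive on the mature transcript (primer-table
convention); an amplicon's length is end − start + 1.

## Amplification-efficiency estimation

Per-well curves are fit in three steps:

1. **Lift-off**: first cycle where fluorescence exceeds the mean of the
   first five cycles by ten times their SD; no such cycle ⇒ flagged
   no-amplification.
2. **Baseline**: the offset *b* minimizing the residual sum of squares of a
   linear fit of log10(F − b) versus cycle over the best window. On
   F = b + F0·E^c the residual vanishes exactly at the true *b*. The search
   is restricted to a neighbourhood of the early-cycle level because far
   below it the transform degenerates (log(F − b) ≈ log(−b) + F/(−b) is
   nearly linear in F for *any* curve, producing a spurious minimum). A
   bounded scalar search is followed by a joint Levenberg–Marquardt polish of
   (baseline, slope, intercept), which reaches machine precision on noiseless
   curves.
3. **Window of linearity**: among 4–6 consecutive cycles with positive
   corrected signal below 85% of plateau, the window maximizing R² (widest
   window preferred when it already exceeds the QC bound). E = 10^slope;
   QC requires R² ≥ 0.99 and 1 < E ≤ 2.2.

CP is the fractional cycle at which the fitted log-linear phase crosses a
common per-amplicon threshold, the geometric mean of window-midpoint
fluorescences of passing wells. A common threshold makes CP differences
comparable across wells: on noiseless curves, doubling the starting template
lowers CP by exactly log_E 2. Window bounds, the plateau ceiling and QC
thresholds are module constants exposed for configuration; they follow the
published description of the window-of-linearity method family rather than
any particular program's internals, which this package does not reproduce
bit-exactly.

## dsRNA decomposition model

The model is deliberately minimal: a nested amplicon amplifies endogenous
mRNA plus transmitted dsRNA (random-primed reverse transcription converts
both), a semi-nested amplicon amplifies mRNA only (one primer has no
template in the dsRNA-derived cDNA; partial detection is not modeled), and
the per-egg dsRNA amount D is constant across stages (transmission at
saturating levels). Consequences used throughout:

* semi-nested %WT = 100·k (k = residual expression after knockdown);
* nested %WT = 100·(M·k + D)/M for stage mean mRNA M — which exceeds 100%
  whenever M is small relative to D;
* the dsRNA component in percentage points is the nested excess,
  max(0, pct_nested − pct_semi), clamped because D ≥ 0.

A stage counts as **low-expression** when its wild-type ratio is below 10%
of the series maximum — this separates trough/late stages from peak stages
without per-gene tuning. Detection at a stage requires the nested excess to
exceed 3× the pooled replicate SD (√(sd_n² + sd_s²), the SD of a difference
of independent means), or a nested signal above 100 %WT at a low-expression
stage. Persistence across ≥3 low-expression stages is "stable" when the CV
of nested RNAi ratios is < 0.25 and no one-sided decreasing regression trend
is significant at α = 0.05. The transmitted span is the union of detected
nested amplicon intervals; "full length" means every nested amplicon in the
tiling was detected. All thresholds are keyword arguments.

The **staging-dilution effect** follows from the same algebra: a broad
collection window averages M over low-expression periods, shrinking the
wild-type baseline and inflating nested %WT, while the semi-nested readout
(100·k) is unaffected in expectation. The property suite verifies this on
unimodal profiles.

## Orthology copy-number profiling

Curation codifies what is usually done by eye: (i) members of one species
sharing a gene-locus key (protein-id prefix before the last `-`/`.` token;
regex configurable) collapse to the longest isoform; (ii) members shorter
than 40% or longer than 250% of the within-group median length are dropped
as partial or chimeric/oversized. These bounds are this package's
operationalization of visual curation, not published thresholds.

Reconciliation takes each species' count from the most taxonomically
restrictive clustering level covering it (the LCA level being the most
specific and reliable); presence only at a wider level is flagged discordant
and the restrictive 0 kept. Clade losses require every sampled species of a
clade with ≥3 sampled species to be at 0 while the nearest sampled sister
clade retains the family — the floor avoids promoting scattered
single-species absences, which often reflect incomplete gene sets, into
loss calls. Clade duplications require ≥80% of sampled species at ≥2
copies. Traversal is top-down and stops at the first call, so reported
clades are maximal. The rendered grid sorts species within each clade
ascending by copy number with name tie-break (the figure convention
specifies ordering but not direction), colors counts {0, 1, 2, ≥3}, and
asterisks discordant species; the companion TSV round-trips losslessly.

BLAST hit tables can be attached as presence evidence only; running
orthology clustering, BLAST searches, alignment or tree inference is out of
scope (FASTA export and newick ingestion are provided for those external
steps).

## Penetrance time course

Penetrance = 100·(cat1 + cat2)/(wt_hatched + wt_unhatched + cat1 + cat2);
the two minor categories (non-specific defects, empty eggs) are excluded
from the denominator but retained in outputs. Collections pool forward until
the denominator reaches 10; a terminal remainder merges backward. Timepoints
are collection-start dpi; overlapping windows are rejected. Survival is the
complete-observation step function (the independent Kaplan–Meier estimator
is used as a cross-check in the tests); fecundity is eggs per female-day.

Waning ends at the first of ≥3 consecutive zero-penetrance collections (the
experiment-termination rule) and starts at the last prior timepoint at or
above 50% of the pre-waning maximum. The 50% rule is this package's
operationalization — published time courses describe waning intervals
descriptively without a formal start criterion — and is configurable.

## Synthetic-data generators

The generators define the study conditions; their defaults are fixed, seeded
and reproducible byte-for-byte.

**qPCR.** Expression profiles are a unimodal Gaussian pulse (peak 8 h, width
4 h — an early extraembryonic-specifier profile), a bimodal double pulse, or
a late-onset sigmoid, over a 72-h embryogenesis. Stage templates are window
averages of M(t). Template per well:
q = (M·k_treatment + D·is_nested·is_RNAi)·bio_noise, with lognormal
biological noise on template and Gaussian technical noise on CP (the
standard qPCR error structure); the CP jitter is realized as template jitter
q·E^(−ε) so the analytic well table and the optional raw curves describe the
same wells. CP = C0 − log_E q with C0 calibrated so one peak-unit template
reads CP 20 at E = 2 (a realistic dynamic range; otherwise arbitrary). Raw
curves follow logistic amplification (per-cycle efficiency declining as
product accumulates) with baseline 0.05, plateau 1.0 and 0.5% read noise.
Default conditions: k = 0.05, D = 0.25 peak-units, σ_CP = 0.15 cycles,
3 technical × 3 biological replicates, E = 1.90, optionally declining with
amplicon length. Zero-template wells are censored at cycle 40 and flagged.

**Orthology.** A 28-species metazoan taxonomy with clustering levels
Metazoa ⊃ Arthropoda ⊃ Hexapoda ⊃ Insecta. Default planted events mirror the
biological pattern of interest: losses in Heteroptera and Diptera, a
duplication in Lepidoptera, one chelicerate discordant species present only
in the Metazoa-level clustering, isoform rate 0.3, partial-fragment rate
0.15, lengths ~N(500, 30) aa.

**Cohorts.** Each of 12 females holds a dsRNA reservoir (lognormal spread,
CV 0.15) decaying with half-life 6 days; offspring are affected with
probability sigmoid(hill·(log2 r − log2 threshold)·ln 2), hill = 8, with the
threshold placed so the median female crosses it at day 55 — penetrance
plateaus near 100% for ~8 weeks and then wanes over ~10 days, the sharp
strain-like pattern. Deaths follow a constant 0.004/day hazard; egg output
follows an age ramp to ~5 eggs/female/day with late decline; collections run
every 4 days for 130 days; scored categories are drawn multinomially
(5% empty, 2% non-specific, affected split 60/40 between the two phenotype
categories, unaffected 90/10 hatched/unhatched). The planted waning interval
is defined by applying the same waning rule to the deterministic expected
penetrance of the median female, with a collection counting as zero when it
is expected to contain fewer than half an affected offspring — making
planted and detected intervals directly comparable.

**What passing tests show.** Parameter recovery on these generators
demonstrates internal consistency: the analyses invert the data-generating
model they assume. Real data add hazards the generators omit — primer-dimer
and multi-phase amplification, inhibitors, cross-paralogue amplification,
stage-window misassignment, orthology-clustering errors beyond isoforms and
fragments, and per-female heterogeneity richer than a lognormal reservoir.
Results on real data therefore depend on those assumptions holding
approximately, and the nested/semi-nested decomposition in particular
assumes semi-nested amplicons detect no dsRNA at all.

## Problem sizes

Validation uses 200 wells per efficiency condition, 3×3 replicates per qPCR
experiment over 1–2 stage windows, 20 seeds for the staging-dilution
property, 28-species orthology tables, and 130-day cohorts of 12 females —
sizes chosen to match the scale of the corresponding desk experiments while
keeping the full suite fast.

## Known limitations

* The dsRNA detectability of the RT step is a single scale factor; siRNA
  pools and dicing kinetics are not modeled.
* Cross-paralogue signal (a nested amplicon weakly detecting a paralogue) is
  not corrected; per-amplicon values are reported without harmonizing the
  spread among nested fragments.
* The orthology pipeline ingests clustering exports; it cannot rescue genes
  missing from the underlying gene sets (the motivation for the separate
  BLAST-evidence annotations).
* Waning detection assumes the zero-run termination rule was followed; a
  truncated experiment returns "not waned" rather than extrapolating.
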