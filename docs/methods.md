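# Methods

This package implements, as tested reusable code, a tiered molecular
diagnostic workflow for infant (< ~1 year) gliomas and the downstream
clinical subgrouping and survival analyses, together with a synthetic-data
generator that exercises the whole pipeline end to end.

## The tiered calling strategy

Tier 1 consists of cheap targeted assays run on every sample:

* **ddPCR hotspot assays** (BRAF V600E; the H3F3A K28M and G35R loci, which
  are wild type throughout this age group);
* **the FGFR1 exon-8/exon-16 ddPCR pair** detecting tyrosine-kinase-domain
  (TKD) duplication;
* **a count-panel (nCounter-style) fusion panel** with junction probes for
  the recurrent fusions plus reporter-tag systems on ALK, ROS1 and NTRK2.

Tier 2 (targeted RNA-seq, whole-transcriptome fusion-caller consensus,
pre-called copy-number events) is consulted only for tier-1-negative
samples; a tier-1 positive always short-circuits tier 2. When several assays
within one tier are positive, a configured precedence (SNV hotspot >
junction probe > tag imbalance > FGFR1-TKD in tier 1; targeted RNA-seq >
whole-transcriptome > CNV in tier 2) selects one driver and the conflict is
logged. These tumors are overwhelmingly single-driver, so conflicts are rare
by construction.

## ddPCR quantification and calling rules

With `k` of `n` droplets positive, target occupancy is the digital-PCR
maximum-likelihood estimator `lambda = -ln(1 - k/n)` copies/droplet, and
concentration is `lambda / V` with droplet volume `V` = 0.85 nL (the
vendor-standard volume; configurable). The mutant allele fraction (MAF) is
`100 * lambda_mut / (lambda_mut + lambda_wt)`, i.e. computed from
Poisson-corrected concentrations rather than raw positive fractions; at the
low occupancies relevant here the two nearly coincide, and the raw variant
is selectable (`corrected_maf: false`).

Calling rules (all in `DdpcrConfig`, defaults as published for this assay
suite):

* **hotspot positivity** — MAF ≥ 1% in *both* duplicate runs AND ≥ 50
  fluorescent droplets per replicate. "Fluorescent droplets" is interpreted
  as positives summed over both channels within a replicate, required of
  each replicate.
* **CDKN2A deletion** — calibrated copy-number value strictly < 1.2.
  The copy-number value is `2 * (lambda_target/lambda_ref) / r2`, where `r2`
  is the target/reference ratio of a two-copy control. Lambdas are averaged
  across duplicates before ratio formation.
* **FGFR1 TKD duplication** — exon16:exon8 concentration ratio ≥ 1.125
  (boundary inclusive, since the printed rule names 1.125 itself as called
  duplicated; the CDKN2A boundary is exclusive by its "<" phrasing). Both
  boundaries are configurable.

A saturated partition (`k = n`) raises rather than returning an infinite
lambda. `scripts/acceptance.py` recovers all three decision boundaries by
bisection over synthetic titrations at 1e-6 (ratio, copy number) and 1e-4
(MAF) resolution.

## Count-panel processing

Per batch of lanes:

1. **Background**: each lane's negative-control spikes define a Poisson
   background threshold `B = mean + 2*sqrt(mean)`; non-control counts are
   floored at zero after subtracting `B`. A pure mean subtraction is
   selectable. The platform documentation gives no formula, so the
   mean + 2*sqrt(mean) form (a ~97.7% Poisson bound) is this package's
   operationalization.
2. **Housekeeping normalization**: lanes are scaled so the geometric mean of
   ABCF1/ALAS1/CLTC/HPRT1 matches the batch reference (arithmetic mean of
   per-lane geometric means). A lane with a zero housekeeper fails QC and is
   excluded with a logged reason. The step is idempotent on normalized lanes.
3. **Outlier calling**: per fusion probe, *across* lanes of the batch
   (a junction probe is silent in fusion-negative samples, so the
   cross-sample distribution isolates expressing outliers), a lane is
   flagged when its normalized value exceeds the extreme-outlier fence
   `Q3 + 3*IQR`. Quartiles use linear interpolation between order statistics
   (numpy/R type-7), fixed and tested against a sort-based oracle because
   near-fence calls depend on the convention. An additional absolute floor
   (default 50 normalized counts) suppresses calls on probes that are silent
   cohort-wide, where the fence degenerates to zero and any background
   residual would otherwise be flagged; minimum-count floors are standard
   practice on count panels. At least 8 lanes are required per batch for
   stable quartiles (configurable).
4. **Reporter-tag imbalance**: for each monitored gene,
   `r = log2(mean(downstream tags) + 1) - log2(mean(upstream tags) + 1)`;
   lanes are standardized against the batch with a robust z-score
   (`1.4826 * MAD` scale; IQR/1.349 fallback when the MAD is zero, logged).
   A lane is called when `z >= 5` and its mean downstream count clears the
   expression floor. The z cutoff and the pseudocount of 1 are this
   package's choices — the qualitative rule ("tags differ significantly
   across the breakpoint") is not quantified in the assay description. The
   pseudocount breaks exact invariance of `r` under raw lane scaling; the
   score is computed after housekeeping normalization, where global lane
   scale has been removed, and the remaining dependence (via the
   background-threshold granularity) is tested to be < 0.25 log2 units.

## Fusion annotation, consensus and pathway classes

Kinase-domain exon spans for ALK, ROS1, NTRK1/2/3, MET, FGFR1, BRAF and RAF1
ship as an editable TSV (`infantglioma/data/kinase_domains.tsv`). A 3'
kinase partner retains its TKD when the breakpoint exon is ≤ the first
kinase-domain exon; a 5' kinase partner (FGFR1-TACC1) retains it when the
breakpoint is ≥ the last kinase-domain exon. Non-retaining fusions are
flagged non-activating and never drive a call.

Whole-transcriptome candidates from the four supported callers are merged
when they share the gene pair and breakpoints within a 1-exon tolerance
(single-linkage clustering in deterministic order; the merge is order
independent). Consensus requires support from ≥ 2 of 4 callers. Both knobs
are configuration; the source study names the callers but no consensus rule.

Pathway classes are a fixed mapping: ALK/ROS1/NTRK/MET fusions → RTK;
KIAA1549-BRAF, BRAF V600E, FGFR1 fusion or TKD duplication, PML-RAF1 and
MYBL1 gain → RAS/MAPK.

## Subgroups and summaries

Group 1 = hemispheric RTK, Group 2 = hemispheric RAS/MAPK, Group 3 = midline
RAS/MAPK; every other combination (midline RTK, driver-negative, location
"other") is UNCLASSIFIED — this package's convention, recorded in each
assignment's rationale. Optic pathway/hypothalamic tumors count as midline.
Summary percentages are rounded half-up to one decimal; mixed-grade tumors
count as HGG in "HGG-enriched" fractions (this makes the Group 1 high-grade
fraction 24/29 = 82.8%; switchable).

## The reference fixture

`build_paper_fixture()` is a pure constructor of 118 samples satisfying
every published marginal simultaneously (see the module docstring for the
list; `tests/test_fixture.py` asserts them one by one). Attributes the
publication does not pin jointly are fixed deterministically, in
construction order:

* BRAF V600E splits 5 (Group 2) / 16 (Group 3); all Group 3 V600E tumors are
  optic pathway/hypothalamic (16/31 OPHG ≈ "half of OPHG"), and no non-OPHG
  Group 3 tumor carries V600E. KIAA1549-BRAF splits 6/22.
* The single midline RTK tumor is an ALK-fused HGG, reconciling 29/30
  hemispheric RTK with 25/30 high-grade-or-mixed RTK.
* The 3 mixed-grade Group 1 tumors are ALK-fused (ROS1/NTRK/MET are
  restricted to HGG); all 5 Group 1 LGG are ALK-fused.
* Group 3's single non-BRAF driver is the FGFR1 TKD duplication.
* Samples outside the three groups carry driver NONE; "Unknown" surgery
  rows in the published table are mapped to "none".
* Ages are set to the group medians; survival fields are synthetic
  placeholders (all censored) and are never used in cohort fractions.

`noiseless_assays()` renders each sample's raw assay data at expected values
(12,000 droplets per replicate, wild-type occupancy 0.5 copies/droplet, VAF
0.30 for V600E carriers, TKD ratio 1.5, count lanes at their means), so the
full calling pipeline — not the truth labels — reproduces the fractions.

## The synthetic generator

Defaults are the reference-cohort marginals: driver frequencies 28/118
KIAA1549-BRAF, 21/118 V600E, …, 32/118 driver-negative; location and grade
drawn from the per-driver conditionals (RTK hemispheric 29/30, RAS/MAPK
hemispheric 17/56, RAS/MAPK always LGG). Noise defaults: droplet totals
uniform on [10,000, 15,000]; mutant VAF uniform on [0.20, 0.45];
negative-control mean 4 counts; housekeeping means 300–1200 with 20% CV and
a log-normal lane size factor (sigma 0.2); junction-probe fold change 50x
over background; reporter-tag baseline 25 counts with a 10x downstream step
in fused samples; each transcriptome caller detects a true fusion with
probability 0.9 and ±1-exon breakpoint jitter.

Survival times are exponential with group-specific medians (defaults from
the published per-group medians: OS 1.9/3.6/6.5 years, PFS ≈ 1.1 years);
the progression hazard is additive so PFS ≤ OS holds record by record, and
censoring is an independent exponential calibrated so the expected censored
fraction of OS equals the configured rate (default 0.3); rate 1 censors
everything. Only Kaplan-Meier summaries of the real cohort are published, so
no distributional shape beyond the exponential convenience is claimed.

What the generator does *not* emulate: FFPE degradation and assay dropout,
batch effects across cartridges, droplet misclassification near the
fluorescence threshold, multi-driver tumors, dependent censoring, and
cohort-level correlations beyond driver→location/grade. Passing tests
therefore demonstrate correctness of the calling rules and statistics under
the stated noise model, not clinical performance on archival tissue.

## Survival statistics

Endpoints: OS = diagnosis to death (event) or last follow-up (censored);
PFS = diagnosis to progression requiring a management change, censored at
last follow-up; PFS ≤ OS is enforced. The Kaplan-Meier estimator is
implemented directly (product-limit, Greenwood variance); 95% bands are
computed on the log-survival scale — matching the R `survival` default the
original analyses used — with log(-log) selectable, clipped to [0, 1]. Point
estimates are right-continuous step evaluations; queries beyond follow-up
return the last value with a truncation flag. The log-rank test and the Cox
model (partial likelihood, Efron tie handling, Wald tests) are provided by
lifelines behind this module's interface; tests validate them against
hand-computed O−E/V on four subjects and brute-force partial-likelihood grid
search (agreement ≤ 1e-3), and the log-rank type-I error against a
500-replicate permutation null. The published per-patient survival data are
not available, so the study's survival percentages are validated by these
oracles and simulations, not by reproduction.

## Numerical choices and edge cases

* Saturated droplet partitions, zero reference concentrations, batches below
  the minimum lane count, missing tag sides, unknown probe classes, orphan
  sample ids, and contradictory duplicate hotspot records all raise typed
  errors rather than degrade silently.
* Quantile convention: linear interpolation (type 7), tested against a
  sort-based oracle on vectors of length ≤ 12.
* Cox tie handling is Efron only (the backing implementation offers no
  Breslow option); ties are absent from the simulated data by construction.
* All stochastic generators take an explicit seed or `numpy` Generator;
  identical seeds give byte-identical outputs.

## Problem sizes

The shipped analyses use the 118-sample fixture, a 200-sample synthetic
cohort for end-to-end recovery (99.3% of assay-covered drivers recovered at
default noise, 0 false calls on 58 driver-negative samples, seed 1), 2,000
replicates at 12,000 droplets for estimator-bias checks, 500 permutation
replicates for the log-rank null, and five 60-lane batches for detection
operating characteristics.
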