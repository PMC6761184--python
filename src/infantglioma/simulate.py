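"""Synthetic cohort and raw-assay simulation.

The generator produces cohorts with latent ground truth (driver, location,
grade, censored survival times) and the raw data each assay would emit:

* droplet partitions — droplet totals drawn uniformly from the configured
  range; positive counts per channel are Binomial(n, 1 - exp(-lambda)), the
  exact forward model of digital PCR;
* count lanes — negative controls ~ Poisson(background); housekeepers
  log-normal around configured means, scaled by a per-lane size factor; the
  probe matching the sample's fusion elevated by the configured fold change;
  reporter tags flat for fusion-negative samples and stepped at the
  breakpoint for fused samples;
* transcriptome fusion-caller output — each of the four callers reports the
  true fusion with a configured detection probability and +/-1-exon
  breakpoint jitter;
* survival — exponential event times with group-specific medians and
  independent exponential censoring calibrated to the target censoring
  fraction; progression times are coupled so PFS <= OS by construction.

Default frequencies and conditional distributions are the marginals of the
118-sample reference cohort, so a large simulated cohort reproduces its
structure in expectation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import ConfigurationError
from .ddpcr import DropletAssayResult, Replicate
from .models import Driver, FusionRecord, Grade, LatentTruth, Location, Surgery
from .nanostring import CountLane, Panel, default_panel

# fusion drivers and the panel probe that carries their junction signal
PROBE_FOR_DRIVER: Dict[Driver, Optional[str]] = {
    Driver.KIAA1549_BRAF: "KIAA1549-BRAF",
    Driver.FGFR1_TACC1: "FGFR1-TACC1",
    Driver.ALK_FUSION: "CCDC88A-ALK",
    Driver.ROS1_FUSION: "GOPC-ROS1",
    Driver.NTRK_FUSION: "ETV6-NTRK3",
    Driver.MET_FUSION: None,  # not on the panel; tier-2 discovery only
    Driver.PML_RAF1: None,
}

# canonical whole-transcriptome fusion identity per driver (g5, e5, g3, e3)
WTS_FUSION_FOR_DRIVER: Dict[Driver, tuple] = {
    Driver.KIAA1549_BRAF: ("KIAA1549", 16, "BRAF", 9),
    Driver.FGFR1_TACC1: ("FGFR1", 17, "TACC1", 7),
    Driver.PML_RAF1: ("PML", 4, "RAF1", 8),
    Driver.ALK_FUSION: ("CCDC88A", 24, "ALK", 20),
    Driver.ROS1_FUSION: ("GOPC", 8, "ROS1", 35),
    Driver.NTRK_FUSION: ("ETV6", 5, "NTRK3", 14),
    Driver.MET_FUSION: ("CLIP2", 12, "MET", 15),
}

# reference-cohort marginals used as default frequencies (counts out of 118)
_DEFAULT_DRIVER_COUNTS = {
    Driver.KIAA1549_BRAF: 28,
    Driver.BRAF_V600E: 21,
    Driver.FGFR1_TACC1: 3,
    Driver.FGFR1_TKD: 2,
    Driver.PML_RAF1: 1,
    Driver.MYBL1_GAIN: 1,
    Driver.ALK_FUSION: 12,
    Driver.ROS1_FUSION: 8,
    Driver.NTRK_FUSION: 7,
    Driver.MET_FUSION: 3,
    Driver.NONE: 32,
}

RTK_DRIVERS = (
    Driver.ALK_FUSION,
    Driver.ROS1_FUSION,
    Driver.NTRK_FUSION,
    Driver.MET_FUSION,
)


@dataclass
class SimulationConfig:
    n_samples: int = 118
    driver_frequencies: Dict[Driver, float] = field(
        default_factory=lambda: {
            d: c / 118 for d, c in _DEFAULT_DRIVER_COUNTS.items()
        }
    )
    # droplet assay
    droplet_range: tuple = (10000, 15000)
    droplet_volume_nl: float = 0.85
    wild_type_lambda: float = 0.5  # wild-type copies/droplet
    mutant_vaf_range: tuple = (0.2, 0.45)
    fgfr1_dup_true_ratio: float = 1.5  # 3 copies of exon 16 vs 2 of exon 8
    # count lane
    negative_control_mean: float = 4.0
    housekeeping_means: Dict[str, float] = field(
        default_factory=lambda: {"ABCF1": 600.0, "ALAS1": 400.0, "CLTC": 1200.0, "HPRT1": 300.0}
    )
    housekeeping_cv: float = 0.2
    fusion_fold_change: float = 50.0
    tag_baseline: float = 25.0
    tag_fold_change: float = 10.0
    lane_size_sigma: float = 0.2  # lognormal sigma of the per-lane size factor
    # transcriptome fusion callers
    caller_detection_prob: float = 0.9
    # survival (years), keyed by clinical group
    median_pfs_years: Dict[str, float] = field(
        default_factory=lambda: {"GROUP1": 1.1, "GROUP2": 1.2, "GROUP3": 1.1, "UNCLASSIFIED": 1.1}
    )
    median_os_years: Dict[str, float] = field(
        default_factory=lambda: {"GROUP1": 1.9, "GROUP2": 3.6, "GROUP3": 6.5, "UNCLASSIFIED": 3.0}
    )
    censoring_rate: float = 0.3
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        probs = np.array(list(self.driver_frequencies.values()), dtype=float)
        if np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError("driver frequencies must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("driver frequencies must sum to 1")
        lo, hi = self.droplet_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid droplet range")
        if self.wild_type_lambda < 0:
            raise ConfigurationError("wild-type concentration must be non-negative")
        for medians in (self.median_pfs_years, self.median_os_years):
            if any(m <= 0 for m in medians.values()):
                raise ConfigurationError("survival medians must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("censoring rate must lie in [0, 1]")
        return self


def _location_for(driver: Driver, rng: np.random.Generator) -> Location:
    if driver in RTK_DRIVERS:
        return Location.HEMISPHERIC if rng.random() < 29 / 30 else Location.MIDLINE
    if driver is Driver.NONE or driver is Driver.OTHER:
        return Location.HEMISPHERIC if rng.random() < 19 / 32 else Location.MIDLINE
    # RAS/MAPK: 17 hemispheric vs 39 midline in the reference cohort
    return Location.HEMISPHERIC if rng.random() < 17 / 56 else Location.MIDLINE


def _grade_for(driver: Driver, rng: np.random.Generator) -> Grade:
    if driver in RTK_DRIVERS:
        u = rng.random()
        if u < 21 / 30:
            return Grade.HGG
        if u < 24 / 30:
            return Grade.MIXED
        return Grade.LGG
    if driver is Driver.NONE or driver is Driver.OTHER:
        return Grade.HGG if rng.random() < 0.3 else Grade.LGG
    return Grade.LGG  # RAS/MAPK alterations are exclusive to low-grade tumors


def generate_cohort(config: SimulationConfig, seed: Optional[int] = None) -> List[LatentTruth]:
    """Draw a cohort of latent truths; identical seeds give identical cohorts."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    drivers = sorted(config.driver_frequencies, key=lambda d: d.value)
    probs = np.array([config.driver_frequencies[d] for d in drivers])
    cohort: List[LatentTruth] = []
    for i in range(config.n_samples):
        driver = drivers[rng.choice(len(drivers), p=probs)]
        location = _location_for(driver, rng)
        grade = _grade_for(driver, rng)
        vaf = 0.0
        if driver is Driver.BRAF_V600E:
            vaf = float(rng.uniform(*config.mutant_vaf_range))
        midline_lgg = location is Location.MIDLINE and grade is Grade.LGG
        cohort.append(
            LatentTruth(
                sample_id=f"SIM{i + 1:04d}",
                true_driver=driver,
                location=location,
                grade=grade,
                histology="pilocytic_astrocytoma" if midline_lgg else "glioma_NOS",
                opg_flag=bool(midline_lgg and rng.random() < 31 / 39),
                age_at_dx_months=float(np.clip(rng.normal(6.5, 3.3), 0.0, 14.9)),
                surgery=Surgery(
                    rng.choice(
                        [s.value for s in Surgery], p=[0.05, 0.3, 0.45, 0.2]
                    )
                ),
                true_vaf=vaf,
            )
        )
    return cohort


def simulate_ddpcr_assay(
    truth: LatentTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    target: str = "BRAF_V600E",
) -> DropletAssayResult:
    """Two-replicate two-channel droplet assay for one hotspot target.

    The mutant channel concentration is lambda_wt * vaf / (1 - vaf), so the
    recovered MAF has expectation equal to the latent VAF.
    """
    if config.wild_type_lambda < 0:
        raise ConfigurationError("negative concentration")
    vaf = truth.true_vaf if (target == "BRAF_V600E" and truth.true_driver is Driver.BRAF_V600E) else 0.0
    lam_wt = config.wild_type_lambda
    lam_mut = lam_wt * vaf / (1.0 - vaf) if vaf > 0 else 0.0
    reps = []
    lo, hi = config.droplet_range
    for _ in range(2):
        n = int(rng.integers(lo, hi + 1))
        reps.append(
            Replicate(
                n_droplets=n,
                positive_mut=int(rng.binomial(n, 1.0 - math.exp(-lam_mut))),
                positive_wt=int(rng.binomial(n, 1.0 - math.exp(-lam_wt))),
            )
        )
    return DropletAssayResult(
        sample_id=truth.sample_id,
        target=target,
        replicates=reps,
        droplet_volume_nl=config.droplet_volume_nl,
    )


def simulate_fgfr1_assays(
    truth: LatentTruth, config: SimulationConfig, rng: np.random.Generator
) -> List[DropletAssayResult]:
    """Single-channel exon-8 / exon-16 droplet assays for the FGFR1 duplication test."""
    lam8 = config.wild_type_lambda
    ratio = config.fgfr1_dup_true_ratio if truth.true_driver is Driver.FGFR1_TKD else 1.0
    lam16 = lam8 * ratio
    lo, hi = config.droplet_range
    out = []
    for target, lam in (("FGFR1_EXON8", lam8), ("FGFR1_EXON16", lam16)):
        reps = []
        for _ in range(2):
            n = int(rng.integers(lo, hi + 1))
            reps.append(
                Replicate(
                    n_droplets=n,
                    positive_mut=int(rng.binomial(n, 1.0 - math.exp(-lam))),
                    positive_wt=0,
                )
            )
        out.append(
            DropletAssayResult(
                sample_id=truth.sample_id,
                target=target,
                replicates=reps,
                droplet_volume_nl=config.droplet_volume_nl,
            )
        )
    return out


def simulate_count_lane(
    truth: LatentTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    panel: Optional[Panel] = None,
    partner_known: bool = True,
    size_factor: Optional[float] = None,
) -> CountLane:
    """One sample's raw count lane under the configured noise model.

    ``partner_known=False`` suppresses the junction-probe signal (the fusion
    partner is not on the panel) while reporter tags still step at the
    breakpoint — the scenario the imbalance score exists for.
    """
    panel = panel or default_panel()
    sf = (
        float(rng.lognormal(0.0, config.lane_size_sigma))
        if size_factor is None
        else size_factor
    )
    driver_probe = PROBE_FOR_DRIVER.get(truth.true_driver)
    fused_gene = None
    if truth.true_driver in WTS_FUSION_FOR_DRIVER:
        fused_gene = WTS_FUSION_FOR_DRIVER[truth.true_driver][2]

    counts: Dict[str, float] = {}
    for probe in sorted(panel.probe_class):
        cls = panel.probe_class[probe]
        if cls == "negative_control":
            counts[probe] = float(rng.poisson(config.negative_control_mean))
        elif cls == "housekeeping":
            mean = config.housekeeping_means[probe]
            noisy = mean * float(
                rng.lognormal(0.0, math.sqrt(math.log(1 + config.housekeeping_cv**2)))
            )
            counts[probe] = float(rng.poisson(sf * noisy))
        elif cls == "fusion":
            mean = config.negative_control_mean
            if partner_known and probe == driver_probe:
                mean *= config.fusion_fold_change
            counts[probe] = float(rng.poisson(sf * mean))
        else:  # reporter_tag
            info = panel.tags[probe]
            mean = config.tag_baseline
            if fused_gene == info.gene and info.side == "downstream":
                mean *= config.tag_fold_change
            counts[probe] = float(rng.poisson(sf * mean))
    return CountLane(sample_id=truth.sample_id, counts=counts, panel=panel)


def simulate_wts_records(
    truth: LatentTruth, config: SimulationConfig, rng: np.random.Generator
) -> List[FusionRecord]:
    """Per-caller transcriptome fusion candidates for one sample."""
    if truth.true_driver not in WTS_FUSION_FOR_DRIVER:
        return []
    g5, e5, g3, e3 = WTS_FUSION_FOR_DRIVER[truth.true_driver]
    records = []
    from .drivers import DEFAULT_CALLERS

    for caller in DEFAULT_CALLERS:
        if rng.random() < config.caller_detection_prob:
            records.append(
                FusionRecord(
                    gene_5p=g5,
                    gene_3p=g3,
                    exon_5p=e5 + int(rng.integers(-1, 2)),
                    exon_3p=max(1, e3 + int(rng.integers(-1, 2))),
                    source="wts",
                    supporting_callers=frozenset({caller}),
                )
            )
    return records


def simulate_survival(
    cohort: Sequence[LatentTruth],
    groups: Dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Fill censored PFS/OS times in place, given per-sample group labels.

    OS ~ Exponential with the group's median; progression hazard is added on
    top so PFS is exponential at its own (shorter) median with PFS <= OS by
    construction. An independent exponential censoring time, calibrated so
    the expected censored fraction equals ``censoring_rate``, truncates both
    endpoints; ``censoring_rate=1`` censors every record.
    """
    config.validate()
    for truth in cohort:
        group = groups.get(truth.sample_id, "UNCLASSIFIED")
        med_os = config.median_os_years[group]
        med_pfs = min(config.median_pfs_years[group], med_os)
        rate_os = math.log(2.0) / med_os
        rate_pfs = math.log(2.0) / med_pfs
        t_os = float(rng.exponential(1.0 / rate_os))
        extra = rate_pfs - rate_os
        t_prog = float(rng.exponential(1.0 / extra)) if extra > 0 else math.inf
        t_pfs = min(t_os, t_prog)
        q = config.censoring_rate
        if q >= 1.0:
            censor = float(rng.exponential(1.0 / rate_os))
            truth.os_years, truth.os_event = censor, 0
            truth.pfs_years, truth.pfs_event = min(censor, t_pfs), 0
            continue
        if q <= 0.0:
            censor = math.inf
        else:
            rate_c = rate_os * q / (1.0 - q)
            censor = float(rng.exponential(1.0 / rate_c))
        truth.os_years = min(t_os, censor)
        truth.os_event = int(t_os <= censor)
        truth.pfs_years = min(t_pfs, censor)
        truth.pfs_event = int(t_pfs <= censor)
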