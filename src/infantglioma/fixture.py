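"""Deterministic 118-sample reference cohort and noiseless assay synthesis.

The fixture encodes, sample by sample, every published marginal of the
118-patient molecularly characterized cohort:

* 65 hemispheric + 53 midline tumors;
* RAS/MAPK drivers (56 total): KIAA1549-BRAF 28, BRAF V600E 21, FGFR1-TACC1 3,
  FGFR1 kinase-domain duplication 2, PML-RAF1 1, MYBL1 gain 1;
* RTK drivers (30 total; 29 hemispheric, 1 midline): ALK 12, ROS1 8, NTRK 7,
  MET 3; 25/30 high-grade or mixed;
* group sizes 29 / 17 / 39 with Group 1 histology 5 LGG + 21 HGG + 3 mixed,
  Group 3 all LGG (27 pilocytic, 31 optic pathway/hypothalamic, 38/39
  BRAF-altered), Group 2 with 6/17 non-BRAF RAS/MAPK events, and gross-total
  resections 12 / 9 / 3.

Joint attributes the publication does not pin down are allocated
deterministically in construction (= sorted sample-id) order; the choices are
documented in docs/methods.md. Survival fields are synthetic placeholders
(group-median times, all censored) and are never inputs to cohort fractions.

``noiseless_assays`` renders the raw data every assay would produce for the
fixture at exactly its expected values, so the full calling pipeline can be
exercised deterministically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .ddpcr import DropletAssayResult, Replicate
from .models import Driver, FusionRecord, Grade, LatentTruth, Location, Surgery
from .nanostring import CountLane, Panel, default_panel
from .simulate import PROBE_FOR_DRIVER, WTS_FUSION_FOR_DRIVER

_N_DROPLETS = 12000
_LAMBDA_WT = 0.5
_FIXTURE_VAF = 0.30
_FGFR1_DUP_RATIO = 1.5


def _surgery_sequence(none: int, biopsy: int, partial: int, gtr: int) -> List[Surgery]:
    return (
        [Surgery.NONE] * none
        + [Surgery.BIOPSY] * biopsy
        + [Surgery.PARTIAL] * partial
        + [Surgery.GTR] * gtr
    )


def build_paper_fixture() -> List[LatentTruth]:
    """The deterministic reference cohort (pure constructor, no randomness)."""
    spec: List[dict] = []

    # --- Group 1: 29 hemispheric RTK-driven -------------------------------
    g1_drivers = (
        [(Driver.ALK_FUSION, Grade.LGG)] * 5
        + [(Driver.ALK_FUSION, Grade.MIXED)] * 3
        + [(Driver.ALK_FUSION, Grade.HGG)] * 3
        + [(Driver.ROS1_FUSION, Grade.HGG)] * 8
        + [(Driver.NTRK_FUSION, Grade.HGG)] * 7
        + [(Driver.MET_FUSION, Grade.HGG)] * 3
    )
    g1_surgery = _surgery_sequence(2, 5, 10, 12)
    for (driver, grade), surgery in zip(g1_drivers, g1_surgery):
        histology = {
            Grade.LGG: "ganglioglioma",
            Grade.MIXED: "mixed_glioma",
            Grade.HGG: "glioblastoma",
        }[grade]
        spec.append(
            dict(
                driver=driver,
                location=Location.HEMISPHERIC,
                grade=grade,
                histology=histology,
                opg=False,
                age=2.8,
                surgery=surgery,
            )
        )

    # --- the single midline RTK tumor (outside the three groups) ----------
    spec.append(
        dict(
            driver=Driver.ALK_FUSION,
            location=Location.MIDLINE,
            grade=Grade.HGG,
            histology="glioblastoma",
            opg=False,
            age=2.8,
            surgery=Surgery.BIOPSY,
        )
    )

    # --- Group 2: 17 hemispheric RAS/MAPK-driven (all LGG) ----------------
    g2_drivers = (
        [Driver.KIAA1549_BRAF] * 6
        + [Driver.BRAF_V600E] * 5
        + [Driver.FGFR1_TACC1] * 3
        + [Driver.FGFR1_TKD]
        + [Driver.PML_RAF1]
        + [Driver.MYBL1_GAIN]
    )
    g2_histology = (
        ["pilocytic_astrocytoma"] * 4
        + ["ganglioglioma"] * 6
        + ["diffuse_astrocytoma"]
        + ["low_grade_glioma_NOS"] * 2
        + ["other_glioma"] * 4
    )
    g2_surgery = _surgery_sequence(1, 3, 4, 9)
    for driver, histology, surgery in zip(g2_drivers, g2_histology, g2_surgery):
        spec.append(
            dict(
                driver=driver,
                location=Location.HEMISPHERIC,
                grade=Grade.LGG,
                histology=histology,
                opg=False,
                age=8.3,
                surgery=surgery,
            )
        )

    # --- Group 3: 39 midline RAS/MAPK-driven (all LGG) --------------------
    # 16 BRAF V600E (all optic pathway/hypothalamic), 22 KIAA1549-BRAF
    # (15 OPHG), 1 FGFR1 kinase-domain duplication (non-OPHG).
    g3_drivers = (
        [(Driver.BRAF_V600E, True)] * 16
        + [(Driver.KIAA1549_BRAF, True)] * 15
        + [(Driver.KIAA1549_BRAF, False)] * 7
        + [(Driver.FGFR1_TKD, False)]
    )
    g3_histology = (
        ["pilocytic_astrocytoma"] * 27
        + ["diffuse_astrocytoma"] * 3
        + ["low_grade_glioma_NOS"] * 8
        + ["other_glioma"]
    )
    g3_surgery = _surgery_sequence(2, 13, 21, 3)
    for (driver, opg), histology, surgery in zip(g3_drivers, g3_histology, g3_surgery):
        spec.append(
            dict(
                driver=driver,
                location=Location.MIDLINE,
                grade=Grade.LGG,
                histology=histology,
                opg=opg,
                age=7.5,
                surgery=surgery,
            )
        )

    # --- driver-negative samples: 19 hemispheric + 13 midline -------------
    for i in range(19):
        grade = Grade.HGG if i < 9 else Grade.LGG
        spec.append(
            dict(
                driver=Driver.NONE,
                location=Location.HEMISPHERIC,
                grade=grade,
                histology="high_grade_glioma_NOS" if grade is Grade.HGG else "low_grade_glioma_NOS",
                opg=False,
                age=6.0,
                surgery=Surgery.BIOPSY,
            )
        )
    for _ in range(13):
        spec.append(
            dict(
                driver=Driver.NONE,
                location=Location.MIDLINE,
                grade=Grade.LGG,
                histology="low_grade_glioma_NOS",
                opg=False,
                age=6.0,
                surgery=Surgery.BIOPSY,
            )
        )

    assert len(spec) == 118
    cohort: List[LatentTruth] = []
    for i, entry in enumerate(spec):
        driver = entry["driver"]
        cohort.append(
            LatentTruth(
                sample_id=f"IG{i + 1:03d}",
                true_driver=driver,
                location=entry["location"],
                grade=entry["grade"],
                histology=entry["histology"],
                opg_flag=entry["opg"],
                age_at_dx_months=entry["age"],
                surgery=entry["surgery"],
                true_vaf=_FIXTURE_VAF if driver is Driver.BRAF_V600E else 0.0,
                # synthetic placeholder follow-up, all censored
                pfs_years=1.1,
                pfs_event=0,
                os_years=3.0,
                os_event=0,
            )
        )
    return cohort


@dataclass
class AssayBundle:
    """Raw assay data for a cohort, keyed the way the pipeline consumes it."""

    droplet_assays: List[DropletAssayResult] = field(default_factory=list)
    count_lanes: List[CountLane] = field(default_factory=list)
    wts_records: Dict[str, List[FusionRecord]] = field(default_factory=dict)
    targeted_records: Dict[str, List[FusionRecord]] = field(default_factory=dict)
    cnv_events: List[tuple] = field(default_factory=list)  # (sample_id, gene, event)


def _expected_positives(lam: float, n: int = _N_DROPLETS) -> int:
    return round(n * (1.0 - math.exp(-lam)))


def _two_channel_assay(sample_id: str, target: str, vaf: float) -> DropletAssayResult:
    lam_wt = _LAMBDA_WT
    lam_mut = lam_wt * vaf / (1.0 - vaf) if vaf > 0 else 0.0
    rep = Replicate(
        n_droplets=_N_DROPLETS,
        positive_mut=_expected_positives(lam_mut),
        positive_wt=_expected_positives(lam_wt),
    )
    return DropletAssayResult(sample_id=sample_id, target=target, replicates=[rep, Replicate(**rep.__dict__)])


def _single_channel_assay(sample_id: str, target: str, lam: float) -> DropletAssayResult:
    rep = Replicate(n_droplets=_N_DROPLETS, positive_mut=_expected_positives(lam), positive_wt=0)
    return DropletAssayResult(sample_id=sample_id, target=target, replicates=[rep, Replicate(**rep.__dict__)])


def _noiseless_lane(truth: LatentTruth, panel: Panel) -> CountLane:
    neg_mean = 4.0
    hk_means = {"ABCF1": 600.0, "ALAS1": 400.0, "CLTC": 1200.0, "HPRT1": 300.0}
    fold = 50.0
    tag_baseline, tag_fold = 25.0, 10.0
    driver_probe = PROBE_FOR_DRIVER.get(truth.true_driver)
    fused_gene = (
        WTS_FUSION_FOR_DRIVER[truth.true_driver][2]
        if truth.true_driver in WTS_FUSION_FOR_DRIVER
        else None
    )
    counts: Dict[str, float] = {}
    for probe, cls in panel.probe_class.items():
        if cls == "negative_control":
            counts[probe] = neg_mean
        elif cls == "housekeeping":
            counts[probe] = hk_means[probe]
        elif cls == "fusion":
            counts[probe] = neg_mean * fold if probe == driver_probe else neg_mean
        else:
            info = panel.tags[probe]
            stepped = fused_gene == info.gene and info.side == "downstream"
            counts[probe] = tag_baseline * (tag_fold if stepped else 1.0)
    return CountLane(sample_id=truth.sample_id, counts=counts, panel=panel)


def noiseless_assays(cohort: List[LatentTruth], panel: Optional[Panel] = None) -> AssayBundle:
    """Raw assay data at expected values for every fixture sample.

    Tier 1: hotspot droplet assays (BRAF V600E and the two histone loci, the
    latter always wild type in this cohort), FGFR1 exon-8/16 droplet assays,
    and one count lane per sample. Tier 2: whole-transcriptome fusion-caller
    records for the fusions absent from the panel (MET, PML-RAF1) and the
    pre-called MYBL1 copy-number gain.
    """
    panel = panel or default_panel()
    bundle = AssayBundle()
    tier2_callers = ("defuse", "tophat", "ericscript")
    for truth in cohort:
        vaf = truth.true_vaf if truth.true_driver is Driver.BRAF_V600E else 0.0
        bundle.droplet_assays.append(_two_channel_assay(truth.sample_id, "BRAF_V600E", vaf))
        for histone in ("H3F3A_K28M", "H3F3A_G35R"):
            bundle.droplet_assays.append(_two_channel_assay(truth.sample_id, histone, 0.0))
        ratio = _FGFR1_DUP_RATIO if truth.true_driver is Driver.FGFR1_TKD else 1.0
        bundle.droplet_assays.append(
            _single_channel_assay(truth.sample_id, "FGFR1_EXON8", _LAMBDA_WT)
        )
        bundle.droplet_assays.append(
            _single_channel_assay(truth.sample_id, "FGFR1_EXON16", _LAMBDA_WT * ratio)
        )
        bundle.count_lanes.append(_noiseless_lane(truth, panel))
        if truth.true_driver in (Driver.MET_FUSION, Driver.PML_RAF1):
            g5, e5, g3, e3 = WTS_FUSION_FOR_DRIVER[truth.true_driver]
            bundle.wts_records[truth.sample_id] = [
                FusionRecord(
                    gene_5p=g5,
                    gene_3p=g3,
                    exon_5p=e5,
                    exon_3p=e3,
                    source="wts",
                    supporting_callers=frozenset({caller}),
                )
                for caller in tier2_callers
            ]
        if truth.true_driver is Driver.MYBL1_GAIN:
            bundle.cnv_events.append((truth.sample_id, "MYBL1", "gain"))
    return bundle
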