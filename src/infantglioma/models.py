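"""Shared domain types for the infant-glioma profiling pipeline.

The vocabulary mirrors the diagnostic workflow: each tumor sample carries
clinical annotations (location, grade, surgery, age at diagnosis), a set of
assay results, and — after integration — a single molecular driver, a pathway
class (RTK vs RAS/MAPK), and a clinical subgroup:

* Group 1 — hemispheric, RTK-driven (ALK/ROS1/NTRK/MET fusions)
* Group 2 — hemispheric, RAS/MAPK-driven
* Group 3 — midline, RAS/MAPK-driven
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Driver(str, Enum):
    """Enumerated molecular drivers recognized by the tiered assays."""

    KIAA1549_BRAF = "KIAA1549_BRAF"
    BRAF_V600E = "BRAF_V600E"
    FGFR1_TACC1 = "FGFR1_TACC1"
    FGFR1_TKD = "FGFR1_TKD"
    PML_RAF1 = "PML_RAF1"
    MYBL1_GAIN = "MYBL1_GAIN"
    ALK_FUSION = "ALK_FUSION"
    ROS1_FUSION = "ROS1_FUSION"
    NTRK_FUSION = "NTRK_FUSION"
    MET_FUSION = "MET_FUSION"
    OTHER = "OTHER"
    NONE = "NONE"


class Location(str, Enum):
    HEMISPHERIC = "hemispheric"
    MIDLINE = "midline"
    OTHER = "other"


class Grade(str, Enum):
    LGG = "LGG"
    HGG = "HGG"
    MIXED = "mixed"


class Surgery(str, Enum):
    NONE = "none"
    BIOPSY = "biopsy"
    PARTIAL = "partial"
    GTR = "GTR"


class Pathway(str, Enum):
    RTK = "RTK"
    RAS_MAPK = "RAS_MAPK"
    OTHER = "OTHER"
    NONE = "NONE"


class Group(str, Enum):
    GROUP1 = "GROUP1"
    GROUP2 = "GROUP2"
    GROUP3 = "GROUP3"
    UNCLASSIFIED = "UNCLASSIFIED"


#: drivers whose positive signal is a point mutation quantified by ddPCR
SNV_DRIVERS = frozenset({Driver.BRAF_V600E})

#: canonical BRAF alterations (used for "BRAF-altered" cohort fractions)
BRAF_DRIVERS = frozenset({Driver.KIAA1549_BRAF, Driver.BRAF_V600E})


@dataclass
class LatentTruth:
    """Ground truth for one simulated (or fixture) sample.

    ``true_vaf`` is the mutant allele fraction in [0, 1] and is positive only
    for SNV drivers. Survival fields are event/censoring times in years; the
    progression-free time never exceeds the overall-survival time.
    """

    sample_id: str
    true_driver: Driver
    location: Location
    grade: Grade
    histology: str
    opg_flag: bool
    age_at_dx_months: float
    surgery: Surgery
    true_vaf: float = 0.0
    pfs_years: Optional[float] = None
    pfs_event: Optional[int] = None
    os_years: Optional[float] = None
    os_event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.age_at_dx_months < 0:
            raise ValueError(f"{self.sample_id}: negative age at diagnosis")
        if not 0.0 <= self.true_vaf <= 1.0:
            raise ValueError(f"{self.sample_id}: true_vaf outside [0, 1]")
        if (self.true_vaf > 0) != (self.true_driver in SNV_DRIVERS):
            raise ValueError(
                f"{self.sample_id}: true_vaf must be positive iff the driver is an SNV"
            )
        if (
            self.pfs_years is not None
            and self.os_years is not None
            and self.pfs_years > self.os_years + 1e-12
        ):
            raise ValueError(f"{self.sample_id}: PFS time exceeds OS time")


@dataclass
class FusionRecord:
    """One candidate gene fusion (exon coordinates are 1-based inclusive)."""

    gene_5p: str
    gene_3p: str
    exon_5p: Optional[int] = None
    exon_3p: Optional[int] = None
    source: str = "wts"  # panel1 | panel2_imbalance | targeted_rnaseq | wts
    supporting_callers: frozenset = frozenset()
    tkd_retained: Optional[bool] = None
    pathway: Optional[Pathway] = None

    def __post_init__(self) -> None:
        if not self.gene_5p or not self.gene_3p:
            raise ValueError("fusion partners must be non-empty gene symbols")
        for exon in (self.exon_5p, self.exon_3p):
            if exon is not None and exon < 1:
                raise ValueError("exon indices are 1-based (>= 1)")
        self.supporting_callers = frozenset(self.supporting_callers)

    @property
    def gene_pair(self) -> tuple:
        return (self.gene_5p, self.gene_3p)


@dataclass
class GeneModel:
    """Kinase-domain exon span (1-based inclusive) for one kinase gene."""

    gene: str
    kd_start_exon: int
    kd_end_exon: int

    def __post_init__(self) -> None:
        if self.kd_start_exon > self.kd_end_exon:
            raise ValueError(f"{self.gene}: kinase-domain span start > end")


@dataclass
class EvidenceItem:
    """One positive assay observation feeding driver integration."""

    kind: str  # snv_hotspot | panel_fusion | tag_imbalance | fgfr1_tkd |
    #            targeted_rnaseq | wts | cnv
    driver: Driver
    detail: str = ""


@dataclass
class DriverCall:
    """The integrated per-sample driver with its pathway and evidence tier."""

    sample_id: str
    driver: Driver
    pathway: Pathway
    evidence_tier: Optional[int]  # 1, 2, or None when no assay was positive
    evidence: list = field(default_factory=list)


@dataclass
class SubgroupAssignment:
    sample_id: str
    group: Group
    rationale: str


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float  # years
    event: int  # 1 = event observed, 0 = censored
    endpoint: str = "OS"  # OS | PFS
    group: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.sample_id}: survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event indicator must be 0 or 1")
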