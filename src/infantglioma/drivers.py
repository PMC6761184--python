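"""Fusion annotation, multi-caller consensus, and tiered driver integration.

The diagnostic strategy is tiered: cheap targeted assays first (tier 1 —
ddPCR hotspots, the count fusion panel, tag-imbalance reporters, the FGFR1
kinase-domain duplication assay), with transcriptome-wide discovery (tier 2 —
targeted RNA-seq, whole-transcriptome fusion-caller consensus, pre-called
copy-number events) reserved for tier-1-negative samples. A sample positive
in tier 1 never consults tier 2.

Fusions are classified by which partner carries the kinase: a 3' kinase gene
is activating when the breakpoint lies at or upstream of the first
kinase-domain exon (the tyrosine kinase domain is retained in the chimeric
transcript); a 5' kinase gene (e.g. FGFR1-TACC1) retains its domain when the
breakpoint lies at or beyond the last kinase-domain exon.
"""
from __future__ import annotations

import csv
import logging
from collections import defaultdict
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence

from .config import IntegrationConfig
from .models import Driver, DriverCall, EvidenceItem, FusionRecord, GeneModel, Pathway

log = logging.getLogger(__name__)

RTK_GENES = frozenset({"ALK", "ROS1", "NTRK1", "NTRK2", "NTRK3", "MET"})
RAS_MAPK_GENES = frozenset({"BRAF", "RAF1", "FGFR1"})

DEFAULT_CALLERS = ("defuse", "tophat", "ericscript", "fusionmap")


class InputIntegrityError(ValueError):
    """Contradictory duplicate records for one assay."""


def load_gene_models(path: Optional[str] = None) -> Dict[str, GeneModel]:
    """Kinase-domain exon spans, from the built-in annotation TSV by default."""
    if path is None:
        source = resources.files("infantglioma.data").joinpath("kinase_domains.tsv")
        text = source.read_text()
    else:
        with open(path) as handle:
            text = handle.read()
    models: Dict[str, GeneModel] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        models[row["gene"]] = GeneModel(
            gene=row["gene"],
            kd_start_exon=int(row["kd_start_exon"]),
            kd_end_exon=int(row["kd_end_exon"]),
        )
    return models


def annotate_fusion(
    fusion: FusionRecord, models: Optional[Dict[str, GeneModel]] = None
) -> FusionRecord:
    """Annotate kinase-domain retention and pathway class.

    The class comes from the kinase (altered) partner: 3' preferentially,
    otherwise 5'. Fusions whose kinase gene is absent from the annotation are
    returned with ``tkd_retained`` unknown (logged).
    """
    models = models if models is not None else load_gene_models()
    retained: Optional[bool] = None
    kinase_gene: Optional[str] = None
    if fusion.gene_3p in models:
        kinase_gene = fusion.gene_3p
        if fusion.exon_3p is not None:
            retained = fusion.exon_3p <= models[kinase_gene].kd_start_exon
    elif fusion.gene_5p in models:
        kinase_gene = fusion.gene_5p
        if fusion.exon_5p is not None:
            retained = fusion.exon_5p >= models[kinase_gene].kd_end_exon
    else:
        log.warning(
            "no kinase annotation for %s-%s; domain retention unknown",
            fusion.gene_5p,
            fusion.gene_3p,
        )
    if kinase_gene in RTK_GENES:
        pathway = Pathway.RTK
    elif kinase_gene in RAS_MAPK_GENES:
        pathway = Pathway.RAS_MAPK
    else:
        pathway = Pathway.OTHER
    return FusionRecord(
        gene_5p=fusion.gene_5p,
        gene_3p=fusion.gene_3p,
        exon_5p=fusion.exon_5p,
        exon_3p=fusion.exon_3p,
        source=fusion.source,
        supporting_callers=fusion.supporting_callers,
        tkd_retained=retained,
        pathway=pathway,
    )


def driver_from_fusion(fusion: FusionRecord) -> Driver:
    """Map an annotated fusion's gene pair onto the driver enumeration."""
    g5, g3 = fusion.gene_5p, fusion.gene_3p
    for gene in (g3, g5):
        if gene == "ALK":
            return Driver.ALK_FUSION
        if gene == "ROS1":
            return Driver.ROS1_FUSION
        if gene in ("NTRK1", "NTRK2", "NTRK3"):
            return Driver.NTRK_FUSION
        if gene == "MET":
            return Driver.MET_FUSION
    if (g5, g3) == ("KIAA1549", "BRAF"):
        return Driver.KIAA1549_BRAF
    if (g5, g3) == ("PML", "RAF1"):
        return Driver.PML_RAF1
    if "FGFR1" in (g5, g3) and "TACC1" in (g5, g3):
        return Driver.FGFR1_TACC1
    return Driver.OTHER


def _breakpoints_close(a: FusionRecord, b: FusionRecord, tolerance: int) -> bool:
    for ea, eb in ((a.exon_5p, b.exon_5p), (a.exon_3p, b.exon_3p)):
        if ea is not None and eb is not None and abs(ea - eb) > tolerance:
            return False
    return True


def consensus_fusions(
    records: Iterable[FusionRecord],
    min_support: int = 2,
    breakpoint_tolerance: int = 1,
    callers: Sequence[str] = DEFAULT_CALLERS,
) -> List[FusionRecord]:
    """Merge per-caller fusion candidates into consensus records.

    Records sharing the gene pair with breakpoints within the exon tolerance
    are merged (callers unioned; the modal breakpoint, ties to the smaller
    exon, is kept). Consensus records supported by fewer than ``min_support``
    callers are dropped. Merging is associative: the result depends only on
    the multiset of input records.
    """
    known = set(callers)
    by_pair: Dict[tuple, List[FusionRecord]] = defaultdict(list)
    for rec in records:
        for caller in rec.supporting_callers:
            if caller not in known:
                raise ValueError(f"unknown fusion caller {caller!r}")
        by_pair[rec.gene_pair].append(rec)

    merged: List[FusionRecord] = []
    for pair in sorted(by_pair):
        # cluster by breakpoint proximity, scanning records in sorted order
        clusters: List[List[FusionRecord]] = []
        for rec in sorted(
            by_pair[pair], key=lambda r: (r.exon_5p or 0, r.exon_3p or 0)
        ):
            for cluster in clusters:
                # single linkage: within tolerance of any member joins the cluster
                if any(_breakpoints_close(rec, other, breakpoint_tolerance) for other in cluster):
                    cluster.append(rec)
                    break
            else:
                clusters.append([rec])
        for cluster in clusters:
            callers_union = frozenset().union(*(r.supporting_callers for r in cluster))
            if len(callers_union) < min_support:
                continue

            def modal(exons: List[int]) -> Optional[int]:
                if not exons:
                    return None
                return min(sorted(set(exons)), key=lambda e: (-exons.count(e), e))

            merged.append(
                FusionRecord(
                    gene_5p=pair[0],
                    gene_3p=pair[1],
                    exon_5p=modal([r.exon_5p for r in cluster if r.exon_5p is not None]),
                    exon_3p=modal([r.exon_3p for r in cluster if r.exon_3p is not None]),
                    source=cluster[0].source,
                    supporting_callers=callers_union,
                )
            )
    return merged


def pathway_class(driver: Driver) -> Pathway:
    """Fixed driver -> pathway mapping."""
    if driver in (
        Driver.ALK_FUSION,
        Driver.ROS1_FUSION,
        Driver.NTRK_FUSION,
        Driver.MET_FUSION,
    ):
        return Pathway.RTK
    if driver in (
        Driver.KIAA1549_BRAF,
        Driver.BRAF_V600E,
        Driver.FGFR1_TACC1,
        Driver.FGFR1_TKD,
        Driver.PML_RAF1,
        Driver.MYBL1_GAIN,
    ):
        return Pathway.RAS_MAPK
    if driver is Driver.NONE:
        return Pathway.NONE
    if driver is Driver.OTHER:
        return Pathway.OTHER
    raise ValueError(f"unknown driver enumerant {driver!r}")


def _check_no_contradictions(items: Sequence[EvidenceItem]) -> None:
    seen: Dict[tuple, str] = {}
    for item in items:
        key = (item.kind, item.driver)
        if key in seen and seen[key] != item.detail and item.kind == "snv_hotspot":
            raise InputIntegrityError(
                f"contradictory duplicate {item.kind} records for {item.driver}"
            )
        seen.setdefault(key, item.detail)


def _pick(items: Sequence[EvidenceItem], precedence: Sequence[str]) -> Optional[EvidenceItem]:
    order = {kind: rank for rank, kind in enumerate(precedence)}
    candidates = sorted(
        (item for item in items if item.kind in order),
        key=lambda item: (order[item.kind], item.driver.value),
    )
    if not candidates:
        return None
    if len({(c.kind, c.driver) for c in candidates}) > 1:
        log.info(
            "multiple positive assays; precedence selects %s (%s)",
            candidates[0].driver,
            candidates[0].kind,
        )
    return candidates[0]


def integrate_sample(
    sample_id: str,
    tier1: Sequence[EvidenceItem],
    tier2: Sequence[EvidenceItem] = (),
    cfg: Optional[IntegrationConfig] = None,
) -> DriverCall:
    """Collapse the tiered evidence into exactly one driver call.

    Any tier-1 positive fixes the driver from tier 1 and tier-2 evidence is
    ignored. Among simultaneous positives the configured precedence decides,
    logging the conflict. No positives in either tier => driver NONE.
    """
    cfg = cfg or IntegrationConfig()
    _check_no_contradictions(list(tier1) + list(tier2))
    chosen = _pick(tier1, cfg.tier1_precedence)
    tier = 1
    evidence: List[EvidenceItem] = list(tier1)
    if chosen is None:
        chosen = _pick(tier2, cfg.tier2_precedence)
        tier = 2
        evidence = evidence + list(tier2)
    if chosen is None:
        return DriverCall(
            sample_id=sample_id,
            driver=Driver.NONE,
            pathway=Pathway.NONE,
            evidence_tier=None,
            evidence=[],
        )
    return DriverCall(
        sample_id=sample_id,
        driver=chosen.driver,
        pathway=pathway_class(chosen.driver),
        evidence_tier=tier,
        evidence=evidence,
    )
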