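"""End-to-end orchestration: assay calling -> driver integration ->
subgrouping -> cohort summary (-> survival when endpoints are present).

The stages are pure functions over in-memory objects; file-based entry
points live in :mod:`infantglioma.io` and the CLI.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import ddpcr, nanostring
from .config import PipelineConfig
from .ddpcr import DropletAssayResult, HOTSPOT_TARGETS
from .drivers import (
    annotate_fusion,
    consensus_fusions,
    driver_from_fusion,
    integrate_sample,
    load_gene_models,
)
from .fixture import AssayBundle
from .models import (
    Driver,
    DriverCall,
    EvidenceItem,
    FusionRecord,
    LatentTruth,
    Location,
    SubgroupAssignment,
)
from .nanostring import CountLane
from .subgroups import classify_cohort, cohort_summary, cohort_table

log = logging.getLogger(__name__)

IMBALANCE_GENE_DRIVER = {
    "ALK": Driver.ALK_FUSION,
    "ROS1": Driver.ROS1_FUSION,
    "NTRK1": Driver.NTRK_FUSION,
    "NTRK2": Driver.NTRK_FUSION,
    "NTRK3": Driver.NTRK_FUSION,
}


class ReconciliationError(ValueError):
    """Assay rows reference sample ids absent from the sample sheet."""


@dataclass
class PipelineResult:
    calls: List[DriverCall]
    assignments: List[SubgroupAssignment]
    cohort: pd.DataFrame
    summary: dict
    ddpcr_calls: list = field(default_factory=list)
    panel_calls: list = field(default_factory=list)
    imbalance_calls: list = field(default_factory=list)
    qc_failed_lanes: list = field(default_factory=list)


def call_ddpcr_assays(
    assays: Sequence[DropletAssayResult], cfg: PipelineConfig
) -> Dict[str, dict]:
    """Group droplet assays per sample and apply the published calling rules.

    Returns per-sample dicts with hotspot calls, the FGFR1 duplication call,
    and the CDKN2A deletion call when the assay pair is present.
    """
    by_sample: Dict[str, Dict[str, DropletAssayResult]] = defaultdict(dict)
    for assay in assays:
        if assay.target in by_sample[assay.sample_id]:
            raise ValueError(
                f"duplicate assay for {assay.sample_id}/{assay.target}"
            )
        by_sample[assay.sample_id][assay.target] = assay

    results: Dict[str, dict] = {}
    for sample_id, targets in by_sample.items():
        entry: dict = {"hotspots": [], "fgfr1": None, "cdkn2a": None}
        for target in HOTSPOT_TARGETS:
            if target in targets:
                entry["hotspots"].append(ddpcr.call_hotspot(targets[target], cfg.ddpcr))
        if "FGFR1_EXON8" in targets and "FGFR1_EXON16" in targets:
            lam8 = ddpcr.mean_lambda(targets["FGFR1_EXON8"])
            lam16 = ddpcr.mean_lambda(targets["FGFR1_EXON16"])
            call = ddpcr.call_fgfr1_tkd(
                ddpcr.QuantResult(lam16, 0.0, 0),
                ddpcr.QuantResult(lam8, 0.0, 0),
                cfg.ddpcr,
            )
            call.sample_id = sample_id
            entry["fgfr1"] = call
        if "CDKN2A" in targets and ddpcr.CN_REFERENCE_TARGET in targets:
            lam_t = ddpcr.mean_lambda(targets["CDKN2A"])
            lam_r = ddpcr.mean_lambda(targets[ddpcr.CN_REFERENCE_TARGET])
            cn = ddpcr.copy_number_value(
                ddpcr.QuantResult(lam_t, 0.0, 0), ddpcr.QuantResult(lam_r, 0.0, 0), 1.0
            )
            entry["cdkn2a"] = ddpcr.CopyNumberCall(
                sample_id=sample_id, cn_value=cn, deleted=ddpcr.call_cdkn2a(cn, cfg.ddpcr)
            )
        results[sample_id] = entry
    return results


def _panel_evidence(call, panel) -> Optional[EvidenceItem]:
    partners = panel.fusion_partners.get(call.probe_id)
    if partners is None:
        return None
    g5, e5, g3, e3 = partners
    fusion = annotate_fusion(
        FusionRecord(gene_5p=g5, gene_3p=g3, exon_5p=e5, exon_3p=e3, source="panel1")
    )
    if fusion.tkd_retained is False:
        log.info("%s: %s breakpoint past the kinase domain; non-activating", call.sample_id, call.probe_id)
        return None
    return EvidenceItem(
        kind="panel_fusion", driver=driver_from_fusion(fusion), detail=call.probe_id
    )


def _fusion_table_evidence(
    records: Sequence[FusionRecord], kind: str, cfg: PipelineConfig
) -> List[EvidenceItem]:
    consensus = consensus_fusions(
        records,
        min_support=cfg.integration.min_caller_support if kind == "wts" else 1,
        breakpoint_tolerance=cfg.integration.breakpoint_tolerance_exons,
    )
    items = []
    models = load_gene_models()
    for rec in consensus:
        annotated = annotate_fusion(rec, models)
        if annotated.tkd_retained is False:
            log.info(
                "%s-%s consensus breakpoint past the kinase domain; non-activating",
                rec.gene_5p,
                rec.gene_3p,
            )
            continue
        driver = driver_from_fusion(annotated)
        items.append(
            EvidenceItem(kind=kind, driver=driver, detail=f"{rec.gene_5p}-{rec.gene_3p}")
        )
    return items


def assemble_evidence(
    sample_id: str,
    ddpcr_entry: Optional[dict],
    panel_calls: Sequence,
    imbalance_calls: Sequence,
    wts_records: Sequence[FusionRecord],
    targeted_records: Sequence[FusionRecord],
    cnv_events: Sequence[tuple],
    cfg: PipelineConfig,
    panel=None,
) -> tuple:
    """Convert per-assay calls into (tier1, tier2) evidence items."""
    panel = panel or nanostring.default_panel()
    tier1: List[EvidenceItem] = []
    tier2: List[EvidenceItem] = []
    if ddpcr_entry:
        for hotspot in ddpcr_entry["hotspots"]:
            if hotspot.positive:
                driver = (
                    Driver.BRAF_V600E if hotspot.target == "BRAF_V600E" else Driver.OTHER
                )
                tier1.append(
                    EvidenceItem(kind="snv_hotspot", driver=driver, detail=hotspot.target)
                )
        fgfr1 = ddpcr_entry.get("fgfr1")
        if fgfr1 is not None and fgfr1.duplicated:
            tier1.append(
                EvidenceItem(kind="fgfr1_tkd", driver=Driver.FGFR1_TKD, detail="exon16:exon8")
            )
    for call in panel_calls:
        if call.sample_id == sample_id and call.flagged:
            item = _panel_evidence(call, panel)
            if item is not None:
                tier1.append(item)
    for call in imbalance_calls:
        if call.sample_id == sample_id and call.flagged:
            driver = IMBALANCE_GENE_DRIVER.get(call.gene)
            if driver is not None:
                tier1.append(
                    EvidenceItem(kind="tag_imbalance", driver=driver, detail=call.gene)
                )
    if targeted_records:
        tier2.extend(_fusion_table_evidence(targeted_records, "targeted_rnaseq", cfg))
    if wts_records:
        tier2.extend(_fusion_table_evidence(wts_records, "wts", cfg))
    for _, gene, event in cnv_events:
        if gene == "MYBL1" and event == "gain":
            tier2.append(EvidenceItem(kind="cnv", driver=Driver.MYBL1_GAIN, detail="MYBL1 gain"))
        else:
            tier2.append(EvidenceItem(kind="cnv", driver=Driver.OTHER, detail=f"{gene} {event}"))
    return tier1, tier2


def samples_frame(cohort: Sequence[LatentTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in cohort],
            "location": [t.location.value for t in cohort],
            "grade": [t.grade.value for t in cohort],
            "histology": [t.histology for t in cohort],
            "opg": [t.opg_flag for t in cohort],
            "age_at_dx_months": [t.age_at_dx_months for t in cohort],
            "surgery": [t.surgery.value for t in cohort],
            "pfs_years": [t.pfs_years for t in cohort],
            "pfs_event": [t.pfs_event for t in cohort],
            "os_years": [t.os_years for t in cohort],
            "os_event": [t.os_event for t in cohort],
        }
    )


def run_cohort(
    samples: pd.DataFrame,
    bundle: AssayBundle,
    cfg: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run calling, integration and classification over one cohort.

    ``samples`` is the sample sheet (one row per sample); ``bundle`` carries
    the raw assay data. Every assay's sample id must appear in the sheet.
    """
    cfg = (cfg or PipelineConfig()).validate()
    known = set(samples["sample_id"])
    orphans = sorted(
        {a.sample_id for a in bundle.droplet_assays if a.sample_id not in known}
        | {l.sample_id for l in bundle.count_lanes if l.sample_id not in known}
        | {s for s in bundle.wts_records if s not in known}
        | {e[0] for e in bundle.cnv_events if e[0] not in known}
    )
    if orphans:
        raise ReconciliationError(f"assay rows for unknown samples: {', '.join(orphans)}")

    ddpcr_results = call_ddpcr_assays(bundle.droplet_assays, cfg)
    panel_calls: list = []
    imbalance_calls: list = []
    qc_failed: list = []
    if bundle.count_lanes:
        panel_calls, imbalance_calls, qc_failed = nanostring.call_batch(
            bundle.count_lanes, cfg.nanostring
        )
    panel = bundle.count_lanes[0].panel if bundle.count_lanes else None

    cnv_by_sample: Dict[str, List[tuple]] = defaultdict(list)
    for event in bundle.cnv_events:
        cnv_by_sample[event[0]].append(event)

    calls: List[DriverCall] = []
    for sample_id in samples["sample_id"]:
        tier1, tier2 = assemble_evidence(
            sample_id,
            ddpcr_results.get(sample_id),
            panel_calls,
            imbalance_calls,
            bundle.wts_records.get(sample_id, []),
            bundle.targeted_records.get(sample_id, []),
            cnv_by_sample.get(sample_id, []),
            cfg,
            panel=panel,
        )
        calls.append(integrate_sample(sample_id, tier1, tier2, cfg.integration))

    locations = {
        row.sample_id: Location(row.location) for row in samples.itertuples()
    }
    assignments = classify_cohort(calls, locations)
    cohort = cohort_table(samples, calls, assignments)
    summary = cohort_summary(cohort)
    return PipelineResult(
        calls=calls,
        assignments=assignments,
        cohort=cohort,
        summary=summary,
        ddpcr_calls=list(ddpcr_results.values()),
        panel_calls=panel_calls,
        imbalance_calls=imbalance_calls,
        qc_failed_lanes=qc_failed,
    )
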