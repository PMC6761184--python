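"""Count-panel (nCounter-style) QC, normalization and fusion calling.

A lane is one sample's vector of raw probe counts. Probes fall into four
classes: fusion junction probes, housekeeping transcripts (ABCF1, ALAS1,
CLTC, HPRT1), negative-control spikes, and reporter tags tiled before and
after the breakpoint hotspot of a monitored kinase gene.

Processing order per batch:

1. background correction — each lane's negative-control spikes define a
   threshold B = mean + 2*sqrt(mean) (Poisson background model); counts are
   floored at zero after subtracting B;
2. housekeeping normalization — lanes are scaled so that the geometric mean
   of the four housekeepers equals the batch reference (the arithmetic mean
   of per-lane housekeeping geometric means);
3. fusion-probe outlier calling — per probe, across the batch, a lane is
   flagged when its normalized value exceeds Q3 + 3*IQR (linear-interpolation
   quantiles) and an absolute expression floor;
4. reporter-tag imbalance — per monitored gene, the log2 ratio of mean
   downstream to mean upstream tag counts, standardized against the batch by
   a robust z-score; large positive scores indicate a fusion with an unknown
   5' partner.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .config import NanostringConfig

log = logging.getLogger(__name__)

PROBE_CLASSES = ("fusion", "housekeeping", "negative_control", "reporter_tag")
HOUSEKEEPERS = ("ABCF1", "ALAS1", "CLTC", "HPRT1")


class PanelDefinitionError(ValueError):
    """The probe panel violates a structural requirement."""


class BatchSizeError(ValueError):
    """Too few lanes for stable cross-sample quartiles."""


class LaneQCError(ValueError):
    """A lane failed QC (e.g. a housekeeper at zero after correction)."""


@dataclass(frozen=True)
class TagInfo:
    gene: str
    tag_index: int  # 1-based position along the transcript
    side: str  # "upstream" | "downstream" of the breakpoint hotspot


@dataclass
class Panel:
    """Probe metadata shared by all lanes of a batch."""

    probe_class: Dict[str, str]
    fusion_partners: Dict[str, tuple] = field(default_factory=dict)  # probe -> (g5, e5, g3, e3)
    tags: Dict[str, TagInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, cls in self.probe_class.items():
            if cls not in PROBE_CLASSES:
                raise PanelDefinitionError(f"unknown probe class {cls!r} for {probe}")
        if not self.probes_of("negative_control"):
            raise PanelDefinitionError("panel must include negative-control probes")
        if len(self.probes_of("housekeeping")) < 4:
            raise PanelDefinitionError("panel must include >= 4 housekeeping probes")

    def probes_of(self, cls: str) -> List[str]:
        return sorted(p for p, c in self.probe_class.items() if c == cls)

    @property
    def monitored_genes(self) -> List[str]:
        return sorted({t.gene for t in self.tags.values()})

    def tag_probes(self, gene: str, side: str) -> List[str]:
        return sorted(
            p for p, t in self.tags.items() if t.gene == gene and t.side == side
        )


@dataclass
class CountLane:
    sample_id: str
    counts: Dict[str, float]
    panel: Panel

    def __post_init__(self) -> None:
        for probe, value in self.counts.items():
            if value < 0:
                raise ValueError(f"{self.sample_id}/{probe}: negative count")
            if probe not in self.panel.probe_class:
                raise PanelDefinitionError(f"{self.sample_id}: unknown probe {probe}")

    def probe_class(self, probe: str) -> str:
        return self.panel.probe_class[probe]


@dataclass
class FusionPanelCall:
    sample_id: str
    probe_id: str
    value: float
    q1: float
    q3: float
    iqr: float
    flagged: bool


@dataclass
class ImbalanceCall:
    sample_id: str
    gene: str
    log2_ratio: float
    robust_z: float
    flagged: bool


def default_panel() -> Panel:
    """The built-in fusion panel: junction probes for the recurrent fusions,
    the four housekeepers, eight negative controls, and 6 reporter tags (3
    upstream, 3 downstream of the breakpoint hotspot) for ALK, ROS1, NTRK2."""
    probe_class: Dict[str, str] = {}
    fusion_partners = {
        "KIAA1549-BRAF": ("KIAA1549", 16, "BRAF", 9),
        "FGFR1-TACC1": ("FGFR1", 17, "TACC1", 7),
        "CCDC88A-ALK": ("CCDC88A", 24, "ALK", 20),
        "PPP1CB-ALK": ("PPP1CB", 6, "ALK", 20),
        "ETV6-NTRK3": ("ETV6", 5, "NTRK3", 14),
        "TPM3-NTRK1": ("TPM3", 8, "NTRK1", 10),
        "GOPC-ROS1": ("GOPC", 8, "ROS1", 35),
    }
    for probe in fusion_partners:
        probe_class[probe] = "fusion"
    for hk in HOUSEKEEPERS:
        probe_class[hk] = "housekeeping"
    for i in range(1, 9):
        probe_class[f"NEG_{i}"] = "negative_control"
    tags: Dict[str, TagInfo] = {}
    for gene in ("ALK", "ROS1", "NTRK2"):
        for idx in range(1, 7):
            side = "upstream" if idx <= 3 else "downstream"
            probe = f"{gene}_tag{idx}"
            probe_class[probe] = "reporter_tag"
            tags[probe] = TagInfo(gene=gene, tag_index=idx, side=side)
    return Panel(probe_class=probe_class, fusion_partners=fusion_partners, tags=tags)


def background_threshold(lane: CountLane, cfg: Optional[NanostringConfig] = None) -> float:
    cfg = cfg or NanostringConfig()
    negs = [lane.counts[p] for p in lane.panel.probes_of("negative_control")]
    if not negs:
        raise PanelDefinitionError("no negative-control probes on panel")
    mean = float(np.mean(negs))
    if cfg.background_mode == "mean":
        return mean
    return mean + 2.0 * math.sqrt(mean)


def background_correct(lane: CountLane, cfg: Optional[NanostringConfig] = None) -> CountLane:
    """Subtract the lane's negative-control threshold, flooring at zero.

    Negative-control probes are passed through unchanged.
    """
    threshold = background_threshold(lane, cfg)
    corrected = {}
    for probe, value in lane.counts.items():
        if lane.probe_class(probe) == "negative_control":
            corrected[probe] = value
        else:
            corrected[probe] = max(0.0, value - threshold)
    return CountLane(sample_id=lane.sample_id, counts=corrected, panel=lane.panel)


def housekeeping_geomean(lane: CountLane) -> float:
    values = [lane.counts[p] for p in lane.panel.probes_of("housekeeping")]
    if any(v <= 0 for v in values):
        raise LaneQCError(f"{lane.sample_id}: housekeeper at zero after correction")
    return float(np.exp(np.mean(np.log(values))))


def normalize_housekeeping(lane: CountLane, cohort_reference: float) -> CountLane:
    """Scale all non-control probes so lane housekeeping geomean matches the reference."""
    factor = cohort_reference / housekeeping_geomean(lane)
    normalized = {}
    for probe, value in lane.counts.items():
        if lane.probe_class(probe) == "negative_control":
            normalized[probe] = value
        else:
            normalized[probe] = value * factor
    return CountLane(sample_id=lane.sample_id, counts=normalized, panel=lane.panel)


def normalize_batch(
    lanes: Sequence[CountLane], cfg: Optional[NanostringConfig] = None
) -> tuple:
    """Background-correct and housekeeping-normalize a batch.

    Returns (normalized lanes, batch reference, QC-failed sample ids). Lanes
    with a zero housekeeper after correction are excluded with a logged reason.
    """
    corrected, failed = [], []
    for lane in lanes:
        corr = background_correct(lane, cfg)
        try:
            housekeeping_geomean(corr)
        except LaneQCError as err:
            log.warning("lane QC fail: %s", err)
            failed.append(lane.sample_id)
            continue
        corrected.append(corr)
    if not corrected:
        return [], float("nan"), failed
    reference = float(np.mean([housekeeping_geomean(lane) for lane in corrected]))
    normalized = [normalize_housekeeping(lane, reference) for lane in corrected]
    return normalized, reference, failed


def call_fusion_outliers(
    lanes: Sequence[CountLane], cfg: Optional[NanostringConfig] = None
) -> List[FusionPanelCall]:
    """Flag, per fusion probe, lanes whose normalized value exceeds the
    extreme-outlier fence Q3 + 3*IQR across the batch.

    Quartiles use the linear-interpolation convention (numpy default). An
    additional absolute floor (``min_normalized_count``) suppresses calls on
    probes that are silent cohort-wide, where the fence degenerates to zero.
    """
    cfg = cfg or NanostringConfig()
    if len(lanes) < cfg.min_batch_lanes:
        raise BatchSizeError(
            f"{len(lanes)} lanes < minimum batch size {cfg.min_batch_lanes}"
        )
    panel = lanes[0].panel
    calls: List[FusionPanelCall] = []
    for probe in panel.probes_of("fusion"):
        values = np.array([lane.counts[probe] for lane in lanes], dtype=float)
        q1, q3 = np.quantile(values, [0.25, 0.75])
        iqr = q3 - q1
        fence = q3 + cfg.iqr_multiplier * iqr
        for lane, value in zip(lanes, values):
            flagged = bool(value > fence and value >= cfg.min_normalized_count)
            calls.append(
                FusionPanelCall(
                    sample_id=lane.sample_id,
                    probe_id=probe,
                    value=float(value),
                    q1=float(q1),
                    q3=float(q3),
                    iqr=float(iqr),
                    flagged=flagged,
                )
            )
    return calls


def tag_log_ratio(lane: CountLane, gene: str, pseudocount: float = 1.0) -> float:
    """log2(mean downstream + pc) - log2(mean upstream + pc) for one gene."""
    up = lane.panel.tag_probes(gene, "upstream")
    down = lane.panel.tag_probes(gene, "downstream")
    if len(up) < 2 or len(down) < 2:
        raise PanelDefinitionError(f"{gene}: need >= 2 tags on each side of the breakpoint")
    mean_up = float(np.mean([lane.counts[p] for p in up]))
    mean_down = float(np.mean([lane.counts[p] for p in down]))
    return math.log2(mean_down + pseudocount) - math.log2(mean_up + pseudocount)


def reporter_imbalance(
    lanes: Sequence[CountLane], gene: str, cfg: Optional[NanostringConfig] = None
) -> List[ImbalanceCall]:
    """Score every lane's 3'/5' tag imbalance for one monitored gene.

    The per-lane statistic r is standardized against the batch with a robust
    z-score, z = (r - median) / (1.4826 * MAD); when the MAD is zero the
    spread falls back to the IQR / 1.349 (logged), and a degenerate batch
    (zero spread) treats any r above the median as infinitely extreme. A lane
    is called when z >= the cutoff AND its mean downstream tag count clears
    the lane's background threshold.
    """
    cfg = cfg or NanostringConfig()
    ratios = np.array([tag_log_ratio(lane, gene, cfg.imbalance_pseudocount) for lane in lanes])
    center = float(np.median(ratios))
    mad = float(np.median(np.abs(ratios - center)))
    spread = 1.4826 * mad
    if spread == 0.0:
        q1, q3 = np.quantile(ratios, [0.25, 0.75])
        spread = (q3 - q1) / 1.349
        log.info("%s: MAD is zero, falling back to IQR-scaled spread", gene)
    calls: List[ImbalanceCall] = []
    for lane, r in zip(lanes, ratios):
        if spread > 0:
            z = (float(r) - center) / spread
        else:
            z = math.inf if r > center else 0.0
        down = lane.panel.tag_probes(gene, "downstream")
        mean_down = float(np.mean([lane.counts[p] for p in down]))
        expressed = mean_down >= cfg.min_normalized_count
        calls.append(
            ImbalanceCall(
                sample_id=lane.sample_id,
                gene=gene,
                log2_ratio=float(r),
                robust_z=float(z),
                flagged=bool(z >= cfg.imbalance_z and expressed),
            )
        )
    return calls


def call_batch(
    lanes: Sequence[CountLane], cfg: Optional[NanostringConfig] = None
) -> tuple:
    """Run the full lane workflow; returns (outlier calls, imbalance calls, qc_failed)."""
    cfg = cfg or NanostringConfig()
    normalized, _, failed = normalize_batch(lanes, cfg)
    if not normalized:
        return [], [], failed
    outliers = call_fusion_outliers(normalized, cfg)
    imbalance: List[ImbalanceCall] = []
    for gene in normalized[0].panel.monitored_genes:
        imbalance.extend(reporter_imbalance(normalized, gene, cfg))
    return outliers, imbalance, failed
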