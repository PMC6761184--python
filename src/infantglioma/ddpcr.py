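"""Droplet digital PCR quantification and rule-based calling.

A ddPCR reaction partitions the sample into n droplets (10,000-15,000 on the
instrument used here). With target molecules Poisson-distributed across
droplets at mean occupancy lambda (copies/droplet), the fraction of positive
droplets is p = 1 - exp(-lambda), so the standard digital-PCR estimator is

    lambda_hat = -ln(1 - k/n)

for k positive droplets out of n. Concentration in copies/uL follows by
dividing by the droplet volume. The mutant allele fraction (MAF) is the
mutant-channel concentration as a percent of total gene copies.

Calling rules (all thresholds in :class:`~infantglioma.config.DdpcrConfig`):

* hotspot mutations: positive iff MAF >= 1% in BOTH duplicate runs and each
  replicate shows >= 50 fluorescent (positive) droplets summed over channels;
* CDKN2A: deleted iff the calibrated copy-number value is strictly < 1.2;
* FGFR1 kinase-domain duplication: duplicated iff the exon16/exon8
  concentration ratio is >= 1.125 (boundary inclusive).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import DdpcrConfig

HOTSPOT_TARGETS = ("BRAF_V600E", "H3F3A_K28M", "H3F3A_G35R")
#: reference gene identifier carried verbatim from the assay sheet
CN_REFERENCE_TARGET = "APB31"


class SaturationError(ValueError):
    """All droplets positive: lambda is unbounded and the assay must be diluted."""


class AssayDesignError(ValueError):
    """Input violates the duplicate assay design."""


@dataclass
class Replicate:
    n_droplets: int
    positive_mut: int
    positive_wt: int

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        for k in (self.positive_mut, self.positive_wt):
            if k < 0 or k > self.n_droplets:
                raise ValueError("positive counts must lie in [0, n_droplets]")

    @property
    def signal_droplets(self) -> int:
        """Droplets with fluorescent signal, summed over both channels."""
        return self.positive_mut + self.positive_wt


@dataclass
class DropletAssayResult:
    sample_id: str
    target: str
    replicates: list
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("at least one replicate required")


@dataclass
class QuantResult:
    lambda_hat: float  # copies/droplet
    concentration: float  # copies/uL
    n_positive_total: int
    maf_pct: Optional[float] = None


@dataclass
class HotspotCall:
    sample_id: str
    target: str
    positive: bool
    replicate_mafs: list = field(default_factory=list)


@dataclass
class CopyNumberCall:
    sample_id: str
    cn_value: float
    deleted: bool


@dataclass
class FgfrTkdCall:
    sample_id: str
    ratio: float
    duplicated: bool


def quantify_target(positive: int, total: int, droplet_volume_nl: float = 0.85) -> QuantResult:
    """Poisson-corrected quantification from a droplet partition.

    Raises :class:`SaturationError` when every droplet is positive (lambda
    undefined) and ``ValueError`` for impossible counts.
    """
    if total <= 0:
        raise ValueError("total droplets must be positive")
    if positive < 0 or positive > total:
        raise ValueError("positive droplets must lie in [0, total]")
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    if positive == total:
        raise SaturationError(f"{positive}/{total} droplets positive: assay saturated")
    lam = -math.log1p(-positive / total) + 0.0  # normalize -0.0 at zero positives
    concentration = lam / (droplet_volume_nl * 1e-3)  # nL -> uL
    return QuantResult(lambda_hat=lam, concentration=concentration, n_positive_total=positive)


def mutant_allele_fraction(lambda_mut: float, lambda_wt: float) -> float:
    """MAF in percent: 100 * lambda_mut / (lambda_mut + lambda_wt)."""
    if lambda_mut < 0 or lambda_wt < 0:
        raise ValueError("lambdas must be non-negative")
    total = lambda_mut + lambda_wt
    if total == 0:
        raise ValueError("undefined fraction: both channel concentrations are zero")
    return 100.0 * lambda_mut / total


def replicate_maf(rep: Replicate, corrected: bool = True) -> float:
    """Per-replicate MAF, from Poisson-corrected lambdas (default) or raw fractions."""
    if corrected:
        lam_mut = quantify_target(rep.positive_mut, rep.n_droplets).lambda_hat
        lam_wt = quantify_target(rep.positive_wt, rep.n_droplets).lambda_hat
        return mutant_allele_fraction(lam_mut, lam_wt)
    return mutant_allele_fraction(rep.positive_mut, rep.positive_wt)


def hotspot_positive(
    mafs: Sequence[float], signal_droplets: Sequence[int], cfg: Optional[DdpcrConfig] = None
) -> bool:
    """The duplicate-run positivity rule, as a pure decision function.

    Positive iff every replicate reaches the MAF threshold AND every replicate
    carries at least the minimum number of fluorescent droplets.
    """
    cfg = cfg or DdpcrConfig()
    if len(mafs) != 2 or len(signal_droplets) != 2:
        raise AssayDesignError("the hotspot design requires exactly two replicates")
    return all(m >= cfg.maf_threshold_pct for m in mafs) and all(
        s >= cfg.min_signal_droplets for s in signal_droplets
    )


def call_hotspot(assay: DropletAssayResult, cfg: Optional[DdpcrConfig] = None) -> HotspotCall:
    """Apply the duplicate-run MAF rule to a two-channel hotspot assay."""
    cfg = cfg or DdpcrConfig()
    if len(assay.replicates) != 2:
        raise AssayDesignError(
            f"{assay.sample_id}/{assay.target}: expected 2 replicates, "
            f"got {len(assay.replicates)}"
        )
    mafs = [replicate_maf(rep, corrected=cfg.corrected_maf) for rep in assay.replicates]
    signals = [rep.signal_droplets for rep in assay.replicates]
    return HotspotCall(
        sample_id=assay.sample_id,
        target=assay.target,
        positive=hotspot_positive(mafs, signals, cfg),
        replicate_mafs=mafs,
    )


def mean_lambda(assay: DropletAssayResult, channel: str = "mut") -> float:
    """Average Poisson-corrected lambda across replicates for one channel."""
    lams = []
    for rep in assay.replicates:
        k = rep.positive_mut if channel == "mut" else rep.positive_wt
        lams.append(quantify_target(k, rep.n_droplets, assay.droplet_volume_nl).lambda_hat)
    return sum(lams) / len(lams)


def copy_number_value(
    target: QuantResult, reference: QuantResult, two_copy_calibrator_ratio: float
) -> float:
    """Copy-number value calibrated against the two-copy control's target/reference ratio."""
    if reference.lambda_hat <= 0:
        raise ZeroDivisionError("reference concentration is zero")
    if two_copy_calibrator_ratio <= 0:
        raise ValueError("calibrator ratio must be positive")
    return 2.0 * (target.lambda_hat / reference.lambda_hat) / two_copy_calibrator_ratio


def call_cdkn2a(cn_value: float, cfg: Optional[DdpcrConfig] = None) -> bool:
    """True (deleted) iff the copy-number value is strictly below the boundary."""
    cfg = cfg or DdpcrConfig()
    if cn_value < 0:
        raise ValueError("copy-number value must be non-negative")
    return cn_value < cfg.cdkn2a_deleted_below


def call_fgfr1_tkd(
    exon16: QuantResult, exon8: QuantResult, cfg: Optional[DdpcrConfig] = None
) -> FgfrTkdCall:
    """Duplicated iff the exon16/exon8 ratio reaches the boundary (inclusive)."""
    cfg = cfg or DdpcrConfig()
    if exon8.lambda_hat <= 0:
        raise ZeroDivisionError("no exon-8 signal: ratio undefined")
    ratio = exon16.lambda_hat / exon8.lambda_hat
    return FgfrTkdCall(sample_id="", ratio=ratio, duplicated=ratio >= cfg.fgfr1_dup_ratio)
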