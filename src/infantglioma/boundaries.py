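"""Calling-boundary recovery by bisection over synthetic titrations.

Each function probes the corresponding calling operation with noiseless
inputs spanning a bracket known to contain the decision boundary, and
bisects to the switch point. Used to verify that the configured thresholds
are applied exactly as published (1.125 exon ratio, 1.2 copy-number value,
1% mutant allele frequency).
"""
from __future__ import annotations

from typing import Callable, Optional, Tuple

from .config import DdpcrConfig
from .ddpcr import QuantResult, call_cdkn2a, call_fgfr1_tkd, hotspot_positive


def bisect_boundary(
    predicate: Callable[[float], bool], lo: float, hi: float, tol: float
) -> Tuple[float, int]:
    """Smallest x in [lo, hi] with predicate(x) True, to within ``tol``.

    Requires predicate False at ``lo`` and True at ``hi``. Returns the
    boundary and the number of predicate evaluations.
    """
    evaluations = 2
    if predicate(lo):
        raise ValueError("predicate already true at the lower bracket")
    if not predicate(hi):
        raise ValueError("predicate false at the upper bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        evaluations += 1
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi), evaluations


def fgfr1_ratio_boundary(
    cfg: Optional[DdpcrConfig] = None, lo: float = 1.0, hi: float = 1.3, tol: float = 1e-6
) -> Tuple[float, int]:
    """Exon16:exon8 ratio at which the duplication call switches on."""
    cfg = cfg or DdpcrConfig()

    def duplicated(ratio: float) -> bool:
        return call_fgfr1_tkd(
            QuantResult(ratio, 0.0, 0), QuantResult(1.0, 0.0, 0), cfg
        ).duplicated

    return bisect_boundary(duplicated, lo, hi, tol)


def cdkn2a_boundary(
    cfg: Optional[DdpcrConfig] = None, lo: float = 0.5, hi: float = 2.5, tol: float = 1e-6
) -> Tuple[float, int]:
    """Copy-number value at which the deletion call switches off."""
    cfg = cfg or DdpcrConfig()
    return bisect_boundary(lambda cn: not call_cdkn2a(cn, cfg), lo, hi, tol)


def maf_boundary(
    cfg: Optional[DdpcrConfig] = None,
    lo: float = 0.1,
    hi: float = 5.0,
    tol: float = 1e-4,
    signal_droplets: int = 60,
) -> Tuple[float, int]:
    """Minimum per-replicate MAF (%) at which the duplicate-run hotspot call
    turns positive, with the droplet floor satisfied in both replicates."""
    cfg = cfg or DdpcrConfig()

    def positive(maf: float) -> bool:
        return hotspot_positive((maf, maf), (signal_droplets, signal_droplets), cfg)

    return bisect_boundary(positive, lo, hi, tol)
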