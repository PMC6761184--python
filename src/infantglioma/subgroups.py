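"""Clinical subgroup assignment and cohort summary tables.

Subgroups are a pure function of pathway class and tumor location:

* Group 1 — RTK pathway, hemispheric
* Group 2 — RAS/MAPK pathway, hemispheric
* Group 3 — RAS/MAPK pathway, midline

Every other combination (midline RTK, OTHER/NONE pathways, location "other")
is UNCLASSIFIED — a convention of this pipeline, recorded in the rationale.

Percentages in summaries are rounded half-up to one decimal; mixed-grade
tumors count as high grade in "HGG-enriched" fractions (switchable).
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .models import (
    BRAF_DRIVERS,
    Driver,
    DriverCall,
    Grade,
    Group,
    Location,
    Pathway,
    SubgroupAssignment,
)


class ClassificationError(ValueError):
    """A sample cannot be assigned (e.g. missing location)."""


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to the reporting precision."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    exact = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def assign_subgroup(
    sample_id: str, pathway: Pathway, location: Optional[Location]
) -> SubgroupAssignment:
    if location is None:
        raise ClassificationError(f"{sample_id}: missing tumor location")
    pathway = Pathway(pathway)
    location = Location(location)
    if location is Location.HEMISPHERIC and pathway is Pathway.RTK:
        group = Group.GROUP1
    elif location is Location.HEMISPHERIC and pathway is Pathway.RAS_MAPK:
        group = Group.GROUP2
    elif location is Location.MIDLINE and pathway is Pathway.RAS_MAPK:
        group = Group.GROUP3
    else:
        group = Group.UNCLASSIFIED
    return SubgroupAssignment(
        sample_id=sample_id,
        group=group,
        rationale=f"pathway={pathway.value}, location={location.value}",
    )


def classify_cohort(
    calls: Sequence[DriverCall], locations: Dict[str, Location]
) -> List[SubgroupAssignment]:
    return [
        assign_subgroup(call.sample_id, call.pathway, locations.get(call.sample_id))
        for call in calls
    ]


def cohort_table(
    samples: pd.DataFrame,
    calls: Sequence[DriverCall],
    assignments: Sequence[SubgroupAssignment],
) -> pd.DataFrame:
    """Join clinical annotations, driver calls and group labels on sample_id."""
    frame = samples.set_index("sample_id", drop=False)
    call_frame = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "driver": [c.driver.value for c in calls],
            "pathway": [c.pathway.value for c in calls],
            "evidence_tier": [c.evidence_tier for c in calls],
        }
    ).set_index("sample_id")
    group_frame = pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "group": [a.group.value for a in assignments],
        }
    ).set_index("sample_id")
    return frame.join(call_frame).join(group_frame).reset_index(drop=True)


def cohort_summary(cohort: pd.DataFrame, mixed_counts_as_hgg: bool = True) -> dict:
    """Counts and percentages summarizing a classified cohort.

    ``cohort`` must carry columns sample_id, location, grade, histology,
    surgery, driver, pathway, group. Returns a dict of plain tables plus the
    named fractions the cohort report quotes (each with numerator,
    denominator, and half-up-rounded percent).
    """
    if cohort.empty:
        return {"n": 0, "tables": {}, "fractions": {}}
    n = len(cohort)
    tables = {
        "driver_counts": cohort["driver"].value_counts().sort_index().to_dict(),
        "pathway_by_location": (
            cohort.groupby(["location", "pathway"]).size().unstack(fill_value=0).to_dict()
        ),
        "group_sizes": cohort["group"].value_counts().sort_index().to_dict(),
        "histology_by_group": (
            cohort.groupby(["group", "grade"]).size().unstack(fill_value=0).to_dict()
        ),
        "surgery_by_group": (
            cohort.groupby(["group", "surgery"]).size().unstack(fill_value=0).to_dict()
        ),
    }

    def fraction(name: str, mask_num, mask_den) -> None:
        num = int(mask_num.sum())
        den = int(mask_den.sum()) if mask_den is not None else n
        fractions[name] = {
            "numerator": num,
            "denominator": den,
            "percent": pct(num, den) if den else float("nan"),
        }

    fractions: dict = {}
    is_ras = cohort["pathway"] == Pathway.RAS_MAPK.value
    is_rtk = cohort["pathway"] == Pathway.RTK.value
    hemi = cohort["location"] == Location.HEMISPHERIC.value
    midline = cohort["location"] == Location.MIDLINE.value
    g1 = cohort["group"] == Group.GROUP1.value
    g2 = cohort["group"] == Group.GROUP2.value
    g3 = cohort["group"] == Group.GROUP3.value
    hgg_like = [Grade.HGG.value]
    if mixed_counts_as_hgg:
        hgg_like.append(Grade.MIXED.value)

    fraction("ras_mapk_of_cohort", is_ras, None)
    fraction(
        "kiaa1549_braf_of_cohort", cohort["driver"] == Driver.KIAA1549_BRAF.value, None
    )
    fraction("rtk_of_cohort", is_rtk, None)
    fraction("rtk_hemispheric", is_rtk & hemi, is_rtk)
    fraction("group1_hgg", g1 & cohort["grade"].isin(hgg_like), g1)
    fraction("group2_of_hemispheric", g2, hemi)
    fraction("midline_ras_mapk", midline & is_ras, midline)
    fraction(
        "group3_braf",
        g3 & cohort["driver"].isin([d.value for d in BRAF_DRIVERS]),
        g3,
    )
    fraction(
        "group3_pilocytic",
        g3 & cohort["histology"].str.contains("pilocytic", case=False, na=False),
        g3,
    )
    return {"n": n, "tables": tables, "fractions": fractions}
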