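"""Plain-text file formats for the pipeline.

Conventions: TSV (tab-separated, UTF-8, no quoting in identifiers) for
sample sheets, count matrices and fusion tables; CSV for droplet exports,
mirroring the instrument convention. Exon coordinates are 1-based inclusive.

The sample sheet's free-text anatomical site is mapped onto the fixed
location vocabulary {hemispheric, midline, other} via a documented table;
unknown sites are rejected with a row-numbered message.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd

from .ddpcr import DropletAssayResult, Replicate
from .models import FusionRecord
from .nanostring import CountLane, Panel, TagInfo

SAMPLE_SHEET_REQUIRED = ("sample_id", "location", "grade")

#: anatomical-site vocabulary -> canonical location
LOCATION_VOCABULARY: Dict[str, str] = {
    "hemispheric": "hemispheric",
    "cerebral": "hemispheric",
    "frontal": "hemispheric",
    "temporal": "hemispheric",
    "parietal": "hemispheric",
    "occipital": "hemispheric",
    "midline": "midline",
    "thalamic": "midline",
    "optic pathway": "midline",
    "hypothalamic": "midline",
    "ophg": "midline",
    "brainstem": "midline",
    "cerebellar": "other",
    "posterior fossa": "other",
    "spinal": "other",
    "other": "other",
}

GRADES = {"LGG", "HGG", "mixed"}
SURGERIES = {"none", "biopsy", "partial", "GTR"}


class FormatError(ValueError):
    """A file violates its documented format."""


def read_sample_sheet(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for column in SAMPLE_SHEET_REQUIRED:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    locations = []
    for i, row in enumerate(frame.itertuples(), start=2):  # header is line 1
        site = str(row.location).strip().lower()
        if site not in LOCATION_VOCABULARY:
            raise FormatError(f"{path}:{i}: unknown location {row.location!r}")
        locations.append(LOCATION_VOCABULARY[site])
        if row.grade not in GRADES:
            raise FormatError(f"{path}:{i}: unknown grade {row.grade!r}")
        if hasattr(row, "surgery") and row.surgery not in SURGERIES:
            raise FormatError(f"{path}:{i}: unknown surgery {row.surgery!r}")
    frame["location"] = locations
    return frame


def write_sample_sheet(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_droplet_csv(path) -> List[DropletAssayResult]:
    frame = pd.read_csv(path)
    required = {"sample_id", "target", "replicate", "n_droplets", "positive_mut", "positive_wt"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    assays = []
    for (sample_id, target), rows in frame.groupby(["sample_id", "target"], sort=True):
        rows = rows.sort_values("replicate")
        reps = [
            Replicate(
                n_droplets=int(r.n_droplets),
                positive_mut=int(r.positive_mut),
                positive_wt=int(r.positive_wt),
            )
            for r in rows.itertuples()
        ]
        assays.append(
            DropletAssayResult(sample_id=str(sample_id), target=str(target), replicates=reps)
        )
    return assays


def write_droplet_csv(assays: Sequence[DropletAssayResult], path) -> None:
    rows = []
    for assay in assays:
        for i, rep in enumerate(assay.replicates, start=1):
            rows.append(
                {
                    "sample_id": assay.sample_id,
                    "target": assay.target,
                    "replicate": i,
                    "n_droplets": rep.n_droplets,
                    "positive_mut": rep.positive_mut,
                    "positive_wt": rep.positive_wt,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counts_matrix(path) -> List[CountLane]:
    """Count matrix TSV: rows = probes; metadata columns probe_id,
    probe_class, gene, tag_index, tag_side; remaining columns = lanes."""
    frame = pd.read_csv(path, sep="\t")
    meta_cols = ["probe_id", "probe_class", "gene", "tag_index", "tag_side"]
    for column in meta_cols:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing column {column!r}")
    if frame["probe_id"].duplicated().any():
        dupes = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
        raise FormatError(f"{path}: duplicate probe_id {dupes}")
    probe_class = dict(zip(frame["probe_id"], frame["probe_class"]))
    tags = {}
    for row in frame.itertuples():
        if row.probe_class == "reporter_tag":
            tags[row.probe_id] = TagInfo(
                gene=str(row.gene), tag_index=int(row.tag_index), side=str(row.tag_side)
            )
    # fusion partner/exon annotation is keyed by the probe's junction name;
    # probes matching the built-in panel inherit its partner annotation
    from .nanostring import default_panel

    builtin = default_panel().fusion_partners
    partners = {p: builtin[p] for p in probe_class if p in builtin}
    panel = Panel(probe_class=probe_class, tags=tags, fusion_partners=partners)
    lanes = []
    for column in frame.columns:
        if column in meta_cols:
            continue
        values = frame[column]
        if not (values == values.astype(float).round()).all() or (values < 0).any():
            raise FormatError(f"{path}: lane {column} has negative or non-integer counts")
        lanes.append(
            CountLane(
                sample_id=str(column),
                counts=dict(zip(frame["probe_id"], values.astype(float))),
                panel=panel,
            )
        )
    return lanes


def write_counts_matrix(lanes: Sequence[CountLane], path) -> None:
    if not lanes:
        raise ValueError("no lanes to write")
    panel = lanes[0].panel
    probes = sorted(panel.probe_class)
    rows = []
    for probe in probes:
        tag = panel.tags.get(probe)
        row = {
            "probe_id": probe,
            "probe_class": panel.probe_class[probe],
            "gene": tag.gene if tag else "",
            "tag_index": tag.tag_index if tag else "",
            "tag_side": tag.side if tag else "",
        }
        for lane in lanes:
            row[lane.sample_id] = int(lane.counts[probe])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fusion_tsv(path) -> Dict[str, List[FusionRecord]]:
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene_5p", "exon_5p", "gene_3p", "exon_3p", "caller", "source"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    by_sample: Dict[str, List[FusionRecord]] = {}
    for row in frame.itertuples():
        record = FusionRecord(
            gene_5p=str(row.gene_5p),
            gene_3p=str(row.gene_3p),
            exon_5p=int(row.exon_5p) if pd.notna(row.exon_5p) else None,
            exon_3p=int(row.exon_3p) if pd.notna(row.exon_3p) else None,
            source=str(row.source),
            supporting_callers=frozenset({str(row.caller)}),
        )
        by_sample.setdefault(str(row.sample_id), []).append(record)
    return by_sample


def write_fusion_tsv(records_by_sample: Dict[str, List[FusionRecord]], path) -> None:
    rows = []
    for sample_id in sorted(records_by_sample):
        for rec in records_by_sample[sample_id]:
            for caller in sorted(rec.supporting_callers):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "gene_5p": rec.gene_5p,
                        "exon_5p": rec.exon_5p,
                        "gene_3p": rec.gene_3p,
                        "exon_3p": rec.exon_3p,
                        "caller": caller,
                        "source": rec.source,
                    }
                )
    pd.DataFrame(
        rows,
        columns=["sample_id", "gene_5p", "exon_5p", "gene_3p", "exon_3p", "caller", "source"],
    ).to_csv(path, sep="\t", index=False)


def read_cnv_tsv(path) -> List[tuple]:
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene", "event"}
    if required - set(frame.columns):
        raise FormatError(f"{path}: CNV table needs columns {sorted(required)}")
    return [(str(r.sample_id), str(r.gene), str(r.event)) for r in frame.itertuples()]


def write_cnv_tsv(events: Sequence[tuple], path) -> None:
    pd.DataFrame(events, columns=["sample_id", "gene", "event"]).to_csv(
        path, sep="\t", index=False
    )


def write_drivers_tsv(calls, path) -> None:
    pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "driver": [c.driver.value for c in calls],
            "pathway": [c.pathway.value for c in calls],
            "evidence_tier": [c.evidence_tier if c.evidence_tier else "" for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def write_groups_tsv(assignments, path) -> None:
    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "group": [a.group.value for a in assignments],
            "rationale": [a.rationale for a in assignments],
        }
    ).to_csv(path, sep="\t", index=False)


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
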