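#!/usr/bin/env python
"""Simulate a 200-sample synthetic cohort at default noise (seed 1): latent
truth, droplet partitions, count lanes, transcriptome fusion-caller output,
CNV events and censored survival times; write everything under
results/synthetic_cohort/."""
from pathlib import Path

import numpy as np
import pandas as pd

from infantglioma import io as pio
from infantglioma.drivers import pathway_class
from infantglioma.models import Driver
from infantglioma.pipeline import samples_frame
from infantglioma.simulate import (
    SimulationConfig,
    generate_cohort,
    simulate_count_lane,
    simulate_ddpcr_assay,
    simulate_fgfr1_assays,
    simulate_survival,
    simulate_wts_records,
)
from infantglioma.subgroups import assign_subgroup

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_cohort"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(n_samples=200, seed=SEED).validate()
    rng = np.random.default_rng(SEED)
    cohort = generate_cohort(sim)
    # survival is driven by the latent group (truth side, not the pipeline's)
    groups = {
        t.sample_id: assign_subgroup(
            t.sample_id, pathway_class(t.true_driver), t.location
        ).group.value
        for t in cohort
    }
    simulate_survival(cohort, groups, sim, rng)

    assays, lanes, wts, cnv = [], [], {}, []
    for t in cohort:
        assays.append(simulate_ddpcr_assay(t, sim, rng))
        assays.extend(simulate_fgfr1_assays(t, sim, rng))
        lanes.append(simulate_count_lane(t, sim, rng))
        records = simulate_wts_records(t, sim, rng)
        if records:
            wts[t.sample_id] = records
        if t.true_driver is Driver.MYBL1_GAIN:
            cnv.append((t.sample_id, "MYBL1", "gain"))

    pio.write_sample_sheet(samples_frame(cohort), OUT / "samples.tsv")
    pio.write_droplet_csv(assays, OUT / "droplets.csv")
    pio.write_counts_matrix(lanes, OUT / "counts.tsv")
    pio.write_fusion_tsv(wts, OUT / "fusions.tsv")
    pio.write_cnv_tsv(cnv, OUT / "cnv.tsv")
    pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in cohort],
            "true_driver": [t.true_driver.value for t in cohort],
            "group": [groups[t.sample_id] for t in cohort],
        }
    ).to_csv(OUT / "truth.tsv", sep="\t", index=False)

    events = sum(t.os_event for t in cohort)
    print(f"simulated {len(cohort)} samples (seed {SEED}) -> {OUT}")
    print(f"observed OS events: {events}/{len(cohort)} "
          f"(target censoring {sim.censoring_rate:.0%})")


if __name__ == "__main__":
    main()
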