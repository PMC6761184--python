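"""Synthetic cohort and raw-assay generators."""
import math

import numpy as np
import pytest

from infantglioma.config import ConfigurationError
from infantglioma.ddpcr import replicate_maf
from infantglioma.models import Driver, Grade, LatentTruth, Location, Surgery
from infantglioma.nanostring import call_batch, normalize_batch
from infantglioma.simulate import (
    SimulationConfig,
    generate_cohort,
    simulate_count_lane,
    simulate_ddpcr_assay,
    simulate_fgfr1_assays,
    simulate_survival,
    simulate_wts_records,
)
from infantglioma.survival import km_estimate, km_median
from infantglioma.models import SurvivalRecord


def truth(driver=Driver.NONE, sample_id="s0", vaf=0.0, location=Location.HEMISPHERIC):
    return LatentTruth(
        sample_id=sample_id,
        true_driver=driver,
        location=location,
        grade=Grade.LGG,
        histology="glioma_NOS",
        opg_flag=False,
        age_at_dx_months=5.0,
        surgery=Surgery.PARTIAL,
        true_vaf=vaf,
    )


class TestCohortGeneration:
    def test_same_seed_gives_identical_cohorts(self):
        cfg = SimulationConfig(n_samples=40, seed=7)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(n_samples=40)
        assert generate_cohort(cfg, seed=1) != generate_cohort(cfg, seed=2)

    def test_degenerate_frequencies(self):
        cfg = SimulationConfig(
            n_samples=50, driver_frequencies={Driver.NONE: 1.0}, seed=0
        )
        cohort = generate_cohort(cfg)
        assert len(cohort) == 50
        assert all(t.true_driver is Driver.NONE for t in cohort)

    def test_driver_marginal_within_binomial_bound(self):
        p = 0.237
        cfg = SimulationConfig(
            n_samples=10000,
            driver_frequencies={Driver.KIAA1549_BRAF: p, Driver.NONE: 1 - p},
            seed=3,
        )
        cohort = generate_cohort(cfg)
        frac = sum(t.true_driver is Driver.KIAA1549_BRAF for t in cohort) / len(cohort)
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / 10000)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": -1},
            {"driver_frequencies": {Driver.NONE: 0.5}},
            {"driver_frequencies": {Driver.NONE: 1.5, Driver.OTHER: -0.5}},
            {"droplet_range": (0, 100)},
            {"censoring_rate": 1.5},
            {"median_os_years": {"GROUP1": -1.0}},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs).validate()


class TestDropletSimulation:
    def test_wild_type_sample_has_no_mutant_droplets(self):
        rng = np.random.default_rng(0)
        assay = simulate_ddpcr_assay(truth(), SimulationConfig(), rng)
        assert all(rep.positive_mut == 0 for rep in assay.replicates)

    def test_seeded_determinism(self):
        cfg = SimulationConfig()
        t = truth(Driver.BRAF_V600E, vaf=0.3)
        a = simulate_ddpcr_assay(t, cfg, np.random.default_rng(5))
        b = simulate_ddpcr_assay(t, cfg, np.random.default_rng(5))
        assert a.replicates == b.replicates

    def test_droplet_totals_within_configured_range(self):
        rng = np.random.default_rng(2)
        assay = simulate_ddpcr_assay(truth(), SimulationConfig(), rng)
        for rep in assay.replicates:
            assert 10000 <= rep.n_droplets <= 15000

    def test_monte_carlo_maf_recovery(self):
        """Mean recovered MAF over 2000 replicates within 0.5 points of 10%."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        t = truth(Driver.BRAF_V600E, vaf=0.10)
        mafs = []
        for _ in range(1000):  # 2 replicates per assay
            assay = simulate_ddpcr_assay(t, cfg, rng)
            mafs.extend(replicate_maf(rep) for rep in assay.replicates)
        assert np.mean(mafs) == pytest.approx(10.0, abs=0.5)

    def test_fgfr1_duplication_ratio_simulated(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(4)
        assays = simulate_fgfr1_assays(truth(Driver.FGFR1_TKD), cfg, rng)
        targets = {a.target for a in assays}
        assert targets == {"FGFR1_EXON8", "FGFR1_EXON16"}


class TestCountLaneSimulation:
    def test_null_cohort_produces_no_fusion_calls(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        lanes = [
            simulate_count_lane(truth(sample_id=f"n{i}"), cfg, rng) for i in range(50)
        ]
        outliers, imbalance, failed = call_batch(lanes)
        assert not failed
        assert not any(c.flagged for c in outliers)
        assert not any(c.flagged for c in imbalance)

    def test_unknown_partner_elevates_downstream_tags_only(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        lane = simulate_count_lane(
            truth(Driver.ALK_FUSION, "f1"), cfg, rng, partner_known=False, size_factor=1.0
        )
        down = np.mean([lane.counts[f"ALK_tag{i}"] for i in (4, 5, 6)])
        up = np.mean([lane.counts[f"ALK_tag{i}"] for i in (1, 2, 3)])
        assert down > 5 * up
        assert lane.counts["CCDC88A-ALK"] < 30  # junction probe stays at background

    def test_size_factor_scales_expected_counts(self):
        cfg = SimulationConfig()

        def mean_hk(sf, seed):
            rng = np.random.default_rng(seed)
            lanes = [
                simulate_count_lane(truth(sample_id=f"s{i}"), cfg, rng, size_factor=sf)
                for i in range(40)
            ]
            return np.mean([lane.counts["CLTC"] for lane in lanes])

        assert mean_hk(2.0, 8) / mean_hk(1.0, 8) == pytest.approx(2.0, rel=0.1)

    def test_fused_probe_elevated_by_fold_change(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(6)
        lane = simulate_count_lane(
            truth(Driver.KIAA1549_BRAF, "f1"), cfg, rng, size_factor=1.0
        )
        assert lane.counts["KIAA1549-BRAF"] > 100  # ~ background * 50


class TestWtsSimulation:
    def test_callers_report_with_breakpoint_jitter(self):
        cfg = SimulationConfig(caller_detection_prob=1.0)
        rng = np.random.default_rng(2)
        records = simulate_wts_records(truth(Driver.MET_FUSION), cfg, rng)
        assert len(records) == 4
        assert all(r.gene_pair == ("CLIP2", "MET") for r in records)
        assert all(abs(r.exon_3p - 15) <= 1 for r in records)

    def test_no_records_for_non_fusion_drivers(self):
        rng = np.random.default_rng(2)
        assert simulate_wts_records(truth(Driver.NONE), SimulationConfig(), rng) == []


class TestSurvivalSimulation:
    def _cohort(self, n, seed=0):
        return [truth(sample_id=f"s{i}") for i in range(n)], {
            f"s{i}": "GROUP2" for i in range(n)
        }

    def test_full_censoring(self):
        cohort, groups = self._cohort(30)
        cfg = SimulationConfig(censoring_rate=1.0)
        simulate_survival(cohort, groups, cfg, np.random.default_rng(1))
        assert all(t.os_event == 0 and t.pfs_event == 0 for t in cohort)

    def test_pfs_never_exceeds_os(self):
        cohort, groups = self._cohort(500)
        simulate_survival(cohort, groups, SimulationConfig(), np.random.default_rng(2))
        assert all(t.pfs_years <= t.os_years + 1e-12 for t in cohort)

    def test_km_recovers_exponential_median(self):
        cohort, groups = self._cohort(5000)
        cfg = SimulationConfig(
            median_os_years={"GROUP2": 2.0},
            median_pfs_years={"GROUP2": 2.0},
            censoring_rate=0.0,
        )
        simulate_survival(cohort, groups, cfg, np.random.default_rng(3))
        records = [
            SurvivalRecord(t.sample_id, t.os_years, t.os_event) for t in cohort
        ]
        assert km_median(km_estimate(records)) == pytest.approx(2.0, abs=0.1)

    def test_censoring_fraction_near_target(self):
        cohort, groups = self._cohort(4000)
        cfg = SimulationConfig(censoring_rate=0.3)
        simulate_survival(cohort, groups, cfg, np.random.default_rng(4))
        censored = np.mean([1 - t.os_event for t in cohort])
        assert censored == pytest.approx(0.3, abs=0.03)
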