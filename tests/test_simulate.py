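"""Generator contracts: determinism, planted truth, calibrated noise."""

import numpy as np
import pandas as pd
import pytest

from kinasign.errors import ValidationError
from kinasign.motifs import match_motif
from kinasign.simulate import (
    SimulationConfig,
    generate_clinical_cohort,
    generate_growth_curves,
    generate_motif_library,
    generate_proteome_and_sites,
    generate_site_matrix,
    simulate_all,
)
from kinasign.preclinical import tgi


class TestConfigValidation:
    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(missing_rate_base=1.2)
        with pytest.raises(ValidationError):
            SimulationConfig(censor_rate=-0.1)

    def test_unknown_hazard_kinase_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(kinase_hr={"NOT_A_KINASE": 2.0})

    def test_nonpositive_hazard_ratio_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(kinase_hr={"CDK6": 0.0})


class TestMotifLibraryGeneration:
    def test_default_counts_match_the_327_motif_annotation(self):
        lib = generate_motif_library(SimulationConfig(seed=0))
        counts = lib.counts()
        assert len(lib) == 327
        assert counts == {"kinase": 224, "phosphatase": 23, "sh2": 80}

    def test_zero_counts_give_empty_library(self):
        cfg = SimulationConfig(seed=0, n_kinase_motifs=0,
                               n_phosphatase_motifs=0, n_sh2_motifs=0)
        assert len(generate_motif_library(cfg)) == 0

    def test_same_seed_identical_patterns(self):
        cfg = SimulationConfig(seed=5)
        a = generate_motif_library(cfg)
        b = generate_motif_library(cfg)
        assert [m.pattern_string() for m in a] == [m.pattern_string() for m in b]

    def test_different_seed_differs(self):
        a = generate_motif_library(SimulationConfig(seed=1))
        b = generate_motif_library(SimulationConfig(seed=2))
        assert [m.pattern_string() for m in a] != [m.pattern_string() for m in b]


class TestProteomeAndSites:
    def test_planted_window_satisfies_its_motif(self, small_cfg, small_library,
                                               small_sites):
        _, annotations = small_sites
        for sid, row in annotations.head(50).iterrows():
            motif = small_library[row["planted_motif"]]
            assert match_motif(row["flank"], motif), sid

    def test_no_active_kinases_means_no_active_labels(self):
        cfg = SimulationConfig(seed=1, n_sites=50, n_proteins=5,
                               n_kinase_motifs=10, n_phosphatase_motifs=0,
                               n_sh2_motifs=0, active_kinases=[])
        lib = generate_motif_library(cfg)
        _, ann = generate_proteome_and_sites(cfg, lib)
        assert not ann["planted_motif"].isin(cfg.active_kinases).any()

    def test_every_active_kinase_gets_substrates(self):
        cfg = SimulationConfig(seed=1, n_sites=50, n_proteins=5,
                               n_kinase_motifs=10, n_phosphatase_motifs=0,
                               n_sh2_motifs=0,
                               active_kinases=["KIN_009", "KIN_010"])
        lib = generate_motif_library(cfg)
        _, ann = generate_proteome_and_sites(cfg, lib)
        counts = ann["planted_motif"].value_counts()
        assert counts["KIN_009"] >= 1 and counts["KIN_010"] >= 1

    def test_sites_without_proteins_rejected(self):
        cfg = SimulationConfig(seed=1, n_sites=10, n_proteins=0,
                               n_kinase_motifs=5, n_phosphatase_motifs=0,
                               n_sh2_motifs=0)
        lib = generate_motif_library(cfg)
        with pytest.raises(ValidationError):
            generate_proteome_and_sites(cfg, lib)

    def test_flank_agrees_with_extract_flank_on_protein(self, small_cfg,
                                                        small_library):
        from kinasign.motifs import extract_flank
        proteins, ann = generate_proteome_and_sites(small_cfg, small_library)
        for sid, row in ann.head(40).iterrows():
            seq = proteins[row["protein_id"]]
            window = extract_flank(seq, row["position"], row["residue"])
            assert window == row["flank"], sid


class TestSiteMatrix:
    def test_planted_log2fc_recovered_on_average(self):
        cfg = SimulationConfig(seed=10, n_sites=600, n_proteins=30,
                               n_kinase_motifs=30, n_phosphatase_motifs=0,
                               n_sh2_motifs=0, active_kinases=["KIN_001"],
                               effect_log2fc=2.0, noise_sd=0.3,
                               missing_rate_base=0.0)
        lib = generate_motif_library(cfg)
        _, ann = generate_proteome_and_sites(cfg, lib)
        m = generate_site_matrix(cfg, ann)
        log2 = np.log2(m.intensities)
        rel = [s for s in m.samples if m.sample_groups[s] == "relapsed"]
        non = [s for s in m.samples if m.sample_groups[s] == "non-relapsed"]
        planted = ann.index[ann["planted_motif"] == "KIN_001"]
        fc = log2.loc[planted, rel].mean(axis=1) - log2.loc[planted, non].mean(axis=1)
        assert abs(fc.mean() - 2.0) < 0.2

    def test_zero_missing_rate_gives_complete_matrix(self):
        cfg = SimulationConfig(seed=11, n_sites=200, n_proteins=10,
                               n_kinase_motifs=10, n_phosphatase_motifs=0,
                               n_sh2_motifs=0, missing_rate_base=0.0)
        lib = generate_motif_library(cfg)
        _, ann = generate_proteome_and_sites(cfg, lib)
        assert generate_site_matrix(cfg, ann).intensities.notna().all().all()

    def test_dropout_prefers_low_intensity(self):
        cfg = SimulationConfig(seed=12, n_sites=2000, n_proteins=100,
                               n_kinase_motifs=10, n_phosphatase_motifs=0,
                               n_sh2_motifs=0, missing_rate_base=0.3)
        lib = generate_motif_library(cfg)
        _, ann = generate_proteome_and_sites(cfg, lib)
        m = generate_site_matrix(cfg, ann)
        log2 = np.log2(m.intensities)
        miss_frac = m.intensities.isna().mean(axis=1)
        site_mean = log2.mean(axis=1, skipna=True)
        low = miss_frac[site_mean < site_mean.quantile(0.2)].mean()
        high = miss_frac[site_mean > site_mean.quantile(0.8)].mean()
        assert low > high

    def test_null_sites_reject_at_nominal_rate(self):
        """No planted effect: per-site two-sample t at alpha=0.05 rejects
        ~5% of 1000 null sites."""
        from scipy import stats
        cfg = SimulationConfig(seed=13, n_sites=1000, n_proteins=50,
                               n_kinase_motifs=10, n_phosphatase_motifs=0,
                               n_sh2_motifs=0, active_kinases=[],
                               missing_rate_base=0.0, effect_log2fc=0.0)
        lib = generate_motif_library(cfg)
        _, ann = generate_proteome_and_sites(cfg, lib)
        m = generate_site_matrix(cfg, ann)
        log2 = np.log2(m.intensities)
        rel = [s for s in m.samples if m.sample_groups[s] == "relapsed"]
        non = [s for s in m.samples if m.sample_groups[s] == "non-relapsed"]
        _, p = stats.ttest_ind(log2[rel], log2[non], axis=1)
        assert abs((p < 0.05).mean() - 0.05) < 0.03

    def test_nonpositive_noise_rejected(self, small_sites):
        _, ann = small_sites
        with pytest.raises(ValidationError):
            generate_site_matrix(
                SimulationConfig(seed=1, noise_sd=0.0), ann
            )

    def test_seed_determinism(self, small_cfg, small_library):
        _, ann = generate_proteome_and_sites(small_cfg, small_library)
        a = generate_site_matrix(small_cfg, ann)
        b = generate_site_matrix(small_cfg, ann)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)


class TestClinicalCohort:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=20, n_patients=50)
        a, ta = generate_clinical_cohort(cfg)
        b, tb = generate_clinical_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_about_a_quarter_high_per_kinase(self):
        cohort, truth = generate_clinical_cohort(
            SimulationConfig(seed=21, n_patients=1000))
        fracs = truth.drop(columns="k_high").mean()
        assert ((fracs - 0.25).abs() < 0.02).all()

    def test_censoring_fraction_near_target(self):
        cohort, _ = generate_clinical_cohort(
            SimulationConfig(seed=22, n_patients=3000, censor_rate=0.6,
                             kinase_hr={}))
        assert abs((1 - cohort["event"].mean()) - 0.6) < 0.07

    def test_covariates_within_documented_ranges(self):
        cohort, _ = generate_clinical_cohort(
            SimulationConfig(seed=23, n_patients=200))
        assert cohort["T"].isin([1, 2, 3, 4]).all()
        assert cohort["N"].isin([0, 1, 2, 3]).all()
        assert cohort["G"].isin([1, 2, 3]).all()
        assert cohort["age"].between(25, 90).all()
        assert (cohort["time"] > 0).all()


class TestGrowthCurves:
    def test_all_unit_multipliers_give_zero_tgi(self):
        cfg = SimulationConfig(seed=30, growth_noise_sd=0.0,
                               growth_effect={"vehicle": 1.0, "drug": 1.0})
        growth = generate_growth_curves(cfg)
        res = tgi(growth[growth["arm"] == "drug"],
                  growth[growth["arm"] == "vehicle"])
        assert res.tgi == pytest.approx(0.0, abs=1e-9)

    def test_static_treated_doubling_vehicle_gives_fifty(self):
        """Noise 0, treated multiplier 0, vehicle doubling over the window:
        plugging the growth ratios into the TGI formula gives 50."""
        days = 21.0
        rate = np.log(2.0) / days  # vehicle doubles by the final day
        cfg = SimulationConfig(seed=31, growth_noise_sd=0.0,
                               growth_rate_vehicle=rate,
                               growth_effect={"vehicle": 1.0, "drug": 0.0})
        growth = generate_growth_curves(cfg)
        res = tgi(growth[growth["arm"] == "drug"],
                  growth[growth["arm"] == "vehicle"])
        assert res.vehicle_ratio == pytest.approx(2.0)
        assert res.treated_ratio == pytest.approx(1.0)
        assert res.tgi == pytest.approx(50.0)

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=32,
                               growth_effect={"vehicle": 1.0, "drug": 0.5})
        pd.testing.assert_frame_equal(generate_growth_curves(cfg),
                                      generate_growth_curves(cfg))

    def test_missing_vehicle_arm_rejected(self):
        with pytest.raises(ValidationError):
            generate_growth_curves(
                SimulationConfig(seed=33, growth_effect={"drug": 0.5}))


class TestSimulateAll:
    def test_writes_all_inputs_and_truth(self, tmp_path):
        cfg = SimulationConfig(seed=40, n_sites=60, n_proteins=6,
                               n_kinase_motifs=6, n_phosphatase_motifs=2,
                               n_sh2_motifs=2, n_patients=20,
                               active_kinases=["KIN_001"])
        out = simulate_all(cfg, tmp_path)
        for name in ("motifs.tsv", "proteome.fasta", "sites.tsv",
                     "clinical.csv", "growth.csv", "truth.json"):
            assert (tmp_path / name).exists(), name
        assert out["truth"]["seed"] == 40
        assert out["truth"]["active_kinases"] == ["KIN_001"]

    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=41, n_sites=60, n_proteins=6,
                               n_kinase_motifs=6, n_phosphatase_motifs=0,
                               n_sh2_motifs=0, n_patients=20)
        simulate_all(cfg, tmp_path / "a")
        simulate_all(cfg, tmp_path / "b")
        for name in ("motifs.tsv", "proteome.fasta", "sites.tsv",
                     "clinical.csv", "growth.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name
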