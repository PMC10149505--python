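"""The synthetic-cohort generator and its ground-truth ledger."""

import numpy as np
import pytest

import omicscreen as osc
from omicscreen.datatypes import OmicsMatrix
from omicscreen.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_plates,
    simulate_survival,
)


def tiny(seed=40, **kw):
    defaults = dict(n_proteins=60, n_surface=20, n_genes=60, seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        m1, a1, v1, t1 = simulate_cohort(tiny())
        m2, a2, v2, t2 = simulate_cohort(tiny())
        for key in m1:
            np.testing.assert_array_equal(m1[key].values, m2[key].values)
        assert a1 == a2 and v1 == v2
        assert t1.true_curves == t2.true_curves
        assert t1.differential_features == t2.differential_features

    def test_different_seed_differs(self):
        m1, *_ = simulate_cohort(tiny(seed=1))
        m2, *_ = simulate_cohort(tiny(seed=2))
        assert not np.array_equal(m1["proteome"].values, m2["proteome"].values)

    def test_plate_determinism(self):
        cfg = tiny()
        _, _, _, truth = simulate_cohort(cfg)
        assert simulate_plates(truth, cfg) == simulate_plates(truth, cfg)


class TestPlantedEffects:
    def test_zero_differential_fraction_empty_ledger(self):
        _, _, _, truth = simulate_cohort(tiny(differential_fraction=0.0))
        assert truth.differential_features == {}

    def test_planted_fold_change_recovered_empirically(self):
        # log2 FC = 1 at noise sd 0.1 over 10+25 samples: the tumor/BPH
        # geometric-mean ratio on the normalized scale must sit near 2
        cfg = tiny(
            seed=41,
            protein_noise_sd=0.1,
            batch_sd=0.0,
            loading_sd=0.0,
            reference_noise_sd=0.0,
            differential_fraction=0.2,
        )
        matrices, annotations, _, truth = simulate_cohort(cfg)
        rel = osc.reference_ratio_log2(osc.median_normalize(matrices["proteome"]), annotations)
        groups = {a.sample_id: a.group for a in annotations}
        tumor_cols = [s for s in rel.sample_ids if groups[s] == "tumor"]
        bph_cols = [s for s in rel.sample_ids if groups[s] == "BPH"]
        up_ratios, down_ratios = [], []
        for feature, layers in truth.differential_features.items():
            lfc = layers["proteome"]
            row = rel.data.loc[feature]
            ratio = 2.0 ** (row[tumor_cols].mean() - row[bph_cols].mean())
            (up_ratios if lfc > 0 else down_ratios).append(ratio if lfc > 0 else 1.0 / ratio)
        for ratios in (up_ratios, down_ratios):
            assert ratios
            geo_mean = float(np.exp(np.mean(np.log(ratios))))
            assert 1.8 <= geo_mean <= 2.2

    def test_noise_free_curves_recovered_exactly(self):
        cfg = tiny(viability_noise_cv=0.0, n_drugs=3, screen_n_bph=2, screen_n_tumor=2)
        _, _, _, truth = simulate_cohort(cfg)
        plates = simulate_plates(truth, cfg)
        fits, seven, lic50 = osc.screen_pipeline(plates)
        for fit in fits:
            b, c, e = truth.true_curves[(fit.cell_id, fit.drug)]
            # solver-tolerance agreement on the viability scale
            doses = np.array(truth.doses_uM)
            np.testing.assert_allclose(
                osc.loglogistic3(doses, fit.b, fit.c, fit.e),
                osc.loglogistic3(doses, b, c, e),
                atol=5e-3,
            )

    def test_selective_drugs_shift_recorded_with_sign(self):
        _, _, _, truth = simulate_cohort(tiny(seed=43))
        assert len(truth.selective_drugs) == 5
        # tumor models are made more sensitive: resistance score drops
        assert all(shift < 0 for shift in truth.selective_drugs.values())

    def test_coupling_ledger_well_formed(self):
        _, _, _, truth = simulate_cohort(tiny(seed=44))
        assert len(truth.protein_drug_couplings) == 5
        for (protein, drug), (sign, strength) in truth.protein_drug_couplings.items():
            assert sign in (-1, 1) and 0 <= strength <= 1


class TestPlates:
    def test_single_pair_design_counts(self):
        cfg = tiny(n_drugs=1, screen_n_bph=1, screen_n_tumor=0)
        _, _, _, truth = simulate_cohort(cfg)
        plates = simulate_plates(truth, cfg)
        treatment = [r for r in plates if r.well_type == "treatment"]
        assert len(treatment) == 7 * 3
        assert len({r.dose for r in treatment}) == 7

    def test_noiseless_signal_matches_curve_value(self):
        cfg = tiny(viability_noise_cv=0.0, n_drugs=1, screen_n_bph=1, screen_n_tumor=0)
        _, _, _, truth = simulate_cohort(cfg)
        (cell, drug), (b, c, e) = next(iter(truth.true_curves.items()))
        truth.true_curves[(cell, drug)] = (1.0, 0.0, 1.0)
        plates = simulate_plates(truth, cfg)
        dmso = np.mean([r.signal for r in plates if r.well_type == "dmso_control"])
        at_one = [r.signal for r in plates if r.well_type == "treatment" and r.dose == 1.0]
        assert at_one and all(s / dmso == pytest.approx(0.5) for s in at_one)

    def test_positive_controls_near_total_kill(self):
        cfg = tiny(n_drugs=2, screen_n_bph=2, screen_n_tumor=2)
        _, _, _, truth = simulate_cohort(cfg)
        plates = simulate_plates(truth, cfg)
        dmso = np.mean([r.signal for r in plates if r.well_type == "dmso_control"])
        pos = np.mean([r.signal for r in plates if r.well_type == "positive_control"])
        assert pos < 0.05 * dmso

    def test_missing_curve_is_error(self):
        cfg = tiny(n_drugs=2, screen_n_bph=2, screen_n_tumor=1)
        _, _, _, truth = simulate_cohort(cfg)
        truth.true_curves.pop(next(iter(truth.true_curves)))
        with pytest.raises(ValueError, match="no true curve"):
            simulate_plates(truth, cfg)


class TestLayers:
    def test_surfaceome_missingness_is_intensity_dependent(self, small_cohort):
        matrices, *_ = small_cohort
        run = matrices["surfaceome_run1"]
        observed = run.values[~np.isnan(run.values)]
        per_feature_missing = np.isnan(run.values).mean(axis=1)
        per_feature_mean = np.nanmean(np.log2(run.values), axis=1)
        ok = np.isfinite(per_feature_mean)
        r = np.corrcoef(per_feature_mean[ok], per_feature_missing[ok])[0, 1]
        assert r < -0.3  # lower intensity -> more missing
        assert observed.size > 0

    def test_transcriptome_counts_are_integers_and_tpm_sums_to_1e6(self, small_cohort):
        matrices, *_ = small_cohort
        counts = matrices["transcriptome_counts"].data
        tpm = matrices["transcriptome"].data
        assert np.array_equal(counts.to_numpy(), np.round(counts.to_numpy()))
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6)

    def test_proteome_reference_channels_present_per_batch(self, small_cohort):
        matrices, annotations, *_ = small_cohort
        refs = [a for a in annotations if a.reference_flag]
        assert len(refs) == 4
        assert {a.batch for a in refs} == {"B1", "B2", "B3", "B4"}
        for a in refs:
            assert a.sample_id in matrices["proteome"].sample_ids

    def test_config_validation_fires_before_generation(self):
        with pytest.raises(ValueError, match="dilution"):
            simulate_cohort(tiny(dilution_factor=1.0))
        with pytest.raises(ValueError, match="n_surface"):
            simulate_cohort(tiny(n_surface=1000))


class TestNoiseMonotonicity:
    def test_estimator_variance_does_not_shrink_with_noise(self):
        # variance of the per-feature group-difference estimate across
        # 100 replicate cohorts at two noise levels
        def variances(noise_sd, seeds):
            diffs = []
            for seed in seeds:
                cfg = tiny(
                    seed=seed,
                    n_proteins=5,
                    n_surface=2,
                    n_genes=5,
                    protein_noise_sd=noise_sd,
                    differential_fraction=0.0,
                    batch_sd=0.0,
                    loading_sd=0.0,
                )
                matrices, annotations, *_ = simulate_cohort(cfg)
                logd = np.log2(matrices["proteome"].data.iloc[:, :35])
                groups = [a.group for a in annotations if not a.reference_flag]
                tumor = logd.loc[:, [g == "tumor" for g in groups]].mean(axis=1)
                bph = logd.loc[:, [g == "BPH" for g in groups]].mean(axis=1)
                diffs.extend((tumor - bph).tolist())
            return np.var(diffs)

        seeds = range(100, 200)
        assert variances(0.8, seeds) > variances(0.2, seeds)


class TestSimulateSurvival:
    def test_record_count_and_groups(self):
        records = simulate_survival(30, 2.0, 0.2, seed=45)
        assert len(records) == 60
        assert {r.group for r in records} == {"group1", "group2"}

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_survival(1, 2.0, 0.2, seed=0)
        with pytest.raises(ValueError):
            simulate_survival(10, -1.0, 0.2, seed=0)
        with pytest.raises(ValueError):
            simulate_survival(10, 2.0, 1.5, seed=0)

    def test_censoring_rate_close_to_requested(self):
        records = simulate_survival(2000, 1.0, 0.3, seed=46)
        frac_censored = np.mean([not r.event for r in records])
        assert 0.25 <= frac_censored <= 0.35
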