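"""Synthetic cohort generator: distributional fidelity, determinism,
ground-truth convergence, inclusion criteria."""

import numpy as np
import pandas as pd
import pytest

from cpmkit import denoise as dn
from cpmkit import neo, synth


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        spec = synth.CohortSpec(n_subjects=10, n_families=5, seed=1)
        a, _ = synth.generate_cohort(spec)
        b, _ = synth.generate_cohort(spec)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_identity_intercorrelation_recovered(self):
        spec = synth.CohortSpec(
            n_subjects=5000, n_families=5000, familial_trait_corr=0.0,
            trait_model=synth.LatentTraitModel(
                trait_intercorrelation=np.eye(5)), seed=2)
        cohort, _ = synth.generate_cohort(spec)
        c = np.corrcoef(cohort.latent_traits(), rowvar=False)
        off = c[np.triu_indices(5, 1)]
        assert np.max(np.abs(off)) < 0.05

    def test_sibling_trait_correlation_matches_coefficient(self):
        spec = synth.CohortSpec(n_subjects=4000, n_families=2000,
                                family_size_dist={2: 1.0},
                                familial_trait_corr=0.5, seed=3)
        cohort, _ = synth.generate_cohort(spec)
        tr = cohort.latent_traits()
        fam = cohort.family_ids
        assert (fam[::2] == fam[1::2]).all()
        for j in range(5):
            r = np.corrcoef(tr[::2, j], tr[1::2, j])[0, 1]
            assert r == pytest.approx(0.5, abs=0.05)

    def test_default_trait_correlations_emulated(self):
        spec = synth.CohortSpec(n_subjects=5000, n_families=2200, seed=4)
        cohort, _ = synth.generate_cohort(spec)
        c = np.corrcoef(cohort.latent_traits(), rowvar=False)
        # Neuroticism anticorrelated with C/E/A; those three positive
        assert c[4, 1] < -0.3 and c[4, 2] < -0.25 and c[4, 3] < -0.2
        assert c[1, 2] > 0.15 and c[1, 3] > 0.12 and c[2, 3] > 0.2

    def test_confounds_correlate_with_traits(self):
        spec = synth.CohortSpec(n_subjects=5000, n_families=2500, seed=5)
        cohort, _ = synth.generate_cohort(spec)
        o = cohort.latent_traits()[:, 0]
        gf = cohort.table["gF"].to_numpy(float)
        assert np.corrcoef(o, gf)[0, 1] > 0.12

    def test_invalid_psd_rejected(self):
        bad = np.eye(5)
        bad[0, 1] = bad[1, 0] = 1.2
        with pytest.raises(ValueError, match="semi-definite"):
            synth.CohortSpec(trait_model=synth.LatentTraitModel(
                trait_intercorrelation=bad)).validate()

    def test_impossible_family_partition_rejected(self):
        with pytest.raises(ValueError, match="n_families"):
            synth.CohortSpec(n_subjects=5, n_families=10).validate()

    def test_shares_must_sum_below_one(self):
        with pytest.raises(ValueError, match="shares"):
            synth.CohortSpec(fingerprint_share=0.6, familial_fc_share=0.3,
                             session_share=0.2).validate()


class TestSerialization:
    def test_ground_truth_round_trips_through_spec(self):
        import json
        tm = synth.LatentTraitModel(signal_effect={"O": 0.3},
                                    n_signal_edges=20)
        spec = synth.CohortSpec(n_subjects=12, n_families=6, n_parcels=16,
                                seed=13, trait_model=tm,
                                confound_effects={"gF": (np.arange(5), 0.2)})
        blob = json.dumps(synth.spec_to_dict(spec))
        spec2 = synth.spec_from_dict(json.loads(blob))
        c1, t1 = synth.generate_cohort(spec)
        c2, t2 = synth.generate_cohort(spec2)
        pd.testing.assert_frame_equal(c1.table, c2.table)
        assert np.array_equal(t1.signal_edges["O"], t2.signal_edges["O"])
        assert np.array_equal(t1.signal_gamma["O"], t2.signal_gamma["O"])
        i = 3
        a = t1.target_correlation(c1.subject_ids[i], 1,
                                  c1.table["family_id"][i], i)
        b = t2.target_correlation(c2.subject_ids[i], 1,
                                  c2.table["family_id"][i], i)
        assert np.array_equal(a, b)


class TestItemResponses:
    def test_responses_bounded(self, small_cohort):
        _, cohort, _ = small_cohort
        items = synth.generate_item_responses(cohort, seed=0)
        vals = items[[f"item_{i}" for i in range(1, 61)]].to_numpy()
        assert vals.min() >= 0 and vals.max() <= 4

    def test_noiseless_scoring_is_monotone_in_latent_trait(self):
        spec = synth.CohortSpec(n_subjects=200, n_families=200, seed=6)
        cohort, _ = synth.generate_cohort(spec)
        model = synth.LatentTraitModel(item_noise_sd=0.0)
        items = synth.generate_item_responses(cohort, model, seed=6)
        scores = neo.score_neoffi(items)
        for f in neo.FACTORS:
            order = np.argsort(cohort.table[f"latent_{f}"].to_numpy())
            s = scores[f].to_numpy()[order]
            assert np.all(np.diff(s) >= 0)

    def test_default_noise_lands_alpha_in_reliability_regime(self):
        spec = synth.CohortSpec(n_subjects=884, n_families=400, seed=7)
        cohort, _ = synth.generate_cohort(spec)
        items = synth.generate_item_responses(cohort, seed=7)
        for f in neo.FACTORS:
            assert 0.7 <= neo.cronbach_alpha(items, f) <= 0.9


class TestRunTimeSeries:
    def test_noiseless_limit_sessions_identical(self):
        spec = synth.CohortSpec(
            n_subjects=4, n_families=2, n_parcels=20, seed=8,
            fingerprint_share=1.0, familial_fc_share=0.0, session_share=0.0,
            white_noise_share=0.0, run_innovation_share=0.0)
        cohort, truth = synth.generate_cohort(spec)
        r1 = synth.generate_run_timeseries(cohort, truth, "REST1_LR",
                                           n_timepoints=120, fix_like=True)
        r2 = synth.generate_run_timeseries(cohort, truth, "REST2_RL",
                                           n_timepoints=120, fix_like=True)
        for a, b in zip(r1, r2):
            assert np.allclose(a.parcels(), b.parcels())

    def test_empirical_fc_converges_to_target(self):
        spec = synth.CohortSpec(n_subjects=2, n_families=2, n_parcels=30,
                                seed=9)
        cohort, truth = synth.generate_cohort(spec)
        run = synth.generate_run_timeseries(
            cohort, truth, "REST1_LR", n_timepoints=20000, fix_like=True)[0]
        emp = np.corrcoef(run.parcels(), rowvar=False)
        tgt = truth.target_correlation(cohort.subject_ids[0], 1,
                                       cohort.table["family_id"][0], 0)
        assert np.max(np.abs(emp - tgt)) < 0.05

    def test_injected_drift_removed_by_detrending(self, small_cohort):
        spec, cohort, truth = small_cohort
        art = synth.ArtifactModel(drift=3.0, motion_coupling=0.0,
                                  spike_prob=0.0)
        run = synth.generate_run_timeseries(
            cohort, truth, "REST1_LR", n_timepoints=600, artifacts=art,
            subjects=cohort.subject_ids[:1])[0]

        def half_mean_shift(x):
            return abs(x[:300].mean(0) - x[300:].mean(0)).max()

        raw_shift = half_mean_shift(run.parcels())
        detrended = dn.legendre_detrend(run, 3, roles=("parcel",))
        det_shift = half_mean_shift(detrended.parcels())
        assert raw_shift > 5 * det_shift

    def test_run_has_required_metadata(self, demo_run):
        assert demo_run.motion_params.shape == (300, 6)
        assert demo_run.fd.shape == (300,)
        assert (demo_run.fd >= 0).all()
        roles = set(demo_run.channel_roles)
        assert {"parcel", "WM", "CSF", "global"} <= roles

    def test_too_few_parcels_rejected(self):
        with pytest.raises(ValueError):
            synth.CohortSpec(n_subjects=4, n_families=2, n_parcels=1).validate()


class TestInclusionCriteria:
    def _cohort(self, **overrides):
        base = {
            "subject_id": ["S0"], "family_id": ["F0"], "mmse": [30],
            "neuropsych_complete": [True], "fmri_complete": [True],
            "run_motion_rms_1": [0.1], "run_motion_rms_2": [0.1],
            "run_motion_rms_3": [0.1], "run_motion_rms_4": [0.1],
        }
        base.update(overrides)
        return synth.Cohort(table=pd.DataFrame(base))

    def test_mmse_26_excluded(self):
        kept, log = synth.apply_inclusion_criteria(self._cohort(mmse=[26]))
        assert kept.n == 0
        assert log.iloc[0]["reason"] == "MMSE"

    def test_mmse_27_kept(self):
        kept, log = synth.apply_inclusion_criteria(self._cohort(mmse=[27]))
        assert kept.n == 1 and log.empty

    def test_single_bad_run_excludes_for_motion(self):
        kept, log = synth.apply_inclusion_criteria(
            self._cohort(run_motion_rms_3=[0.16]))
        assert kept.n == 0
        assert log.iloc[0]["reason"] == "motion"

    def test_all_passing_cohort_unchanged(self):
        c = self._cohort()
        kept, log = synth.apply_inclusion_criteria(c)
        assert log.empty
        pd.testing.assert_frame_equal(kept.table, c.table)

    def test_exclusion_order_completeness_before_mmse(self):
        kept, log = synth.apply_inclusion_criteria(
            self._cohort(mmse=[20], neuropsych_complete=[False]))
        assert log.iloc[0]["reason"] == "completeness"

    def test_missing_column_named(self):
        c = self._cohort()
        c.table.drop(columns="mmse", inplace=True)
        with pytest.raises(ValueError, match="mmse"):
            synth.apply_inclusion_criteria(c)
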