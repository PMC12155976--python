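"""Synthetic cohort generator: determinism, clock inversion, recovery harness."""

import numpy as np
import pandas as pd
import pytest

import epiaccel as ea
from epiaccel import dataset as ds
from epiaccel.errors import InfeasibleTargetError, ValidationError
from epiaccel.synthetic import DEFAULT_TRAJECTORIES, SiteTrajectory, expected_clock_age


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        params = ea.CohortParams(n_subjects=8, seed=123)
        a = ea.generate_cohort(params)
        b = ea.generate_cohort(params)
        pd.testing.assert_frame_equal(a.dataset.data, b.dataset.data)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        ea.write_cohort_csv(a.dataset, pa)
        ea.write_cohort_csv(b.dataset, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        a = ea.generate_cohort(ea.CohortParams(seed=1))
        b = ea.generate_cohort(ea.CohortParams(seed=2))
        assert not a.dataset.data.equals(b.dataset.data)

    def test_complete_pairs_and_six_month_spacing(self, cohort10):
        lds = cohort10.dataset
        assert lds.n_subjects == 10 and lds.n_obs == 20
        a0, a6 = lds.paired(ds.AGE)
        assert np.allclose(a6 - a0, 0.5, atol=1e-12)

    def test_clock_reproduces_intended_dnam_age(self, cohort10):
        ages = ea.batch_compute(cohort10.dataset.data)
        data = cohort10.dataset.data
        keys = data[ds.SUBJECT] + "_" + data[ds.TIMEPOINT]
        intended = np.array([cohort10.truth.intended_dnam_age[k] for k in keys])
        assert np.allclose(ages.to_numpy(), intended, atol=1e-6)

    def test_noiseless_null_yields_zero_acceleration(self):
        params = ea.CohortParams(
            n_subjects=10,
            seed=5,
            sigma_subject=0.0,
            sigma_resid=0.0,
            treatment_shift=0.0,
            igf_slope=0.0,
        )
        syn = ea.generate_cohort(params)
        lds = syn.dataset.with_columns(dnam_age=ea.batch_compute(syn.dataset.data))
        lds, _ = ea.add_age_acceleration(lds)
        assert np.allclose(lds.data[ds.ACCEL], 0.0, atol=1e-9)

    def test_igf_treatment_ratio_near_multiplier(self):
        syn = ea.generate_cohort(ea.CohortParams(n_subjects=400, seed=7))
        i0, i6 = syn.dataset.paired("igf1")
        ratio = np.median(i6) / np.median(i0)
        assert ratio == pytest.approx(2.8, rel=0.15)
        assert np.median(i0) == pytest.approx(120.5, rel=0.15)

    def test_truth_records_configured_values(self, cohort10):
        t = cohort10.truth
        assert t.treatment_shift == -1.8
        assert t.igf_slope == 0.011
        assert len(t.subject_intercepts) == 10

    def test_trajectory_leaving_bounds_is_rejected_before_sampling(self):
        bad = dict(DEFAULT_TRAJECTORIES)
        bad["methC1-KLF14"] = SiteTrajectory(98.0, 1.0, 0.5)  # exceeds 100% by age 15
        with pytest.raises(ValidationError, match="KLF14"):
            ea.generate_cohort(ea.CohortParams(seed=0, site_trajectories=bad))

    def test_expected_clock_age_tracks_chronological_age(self, clock):
        params = ea.CohortParams()
        for age in (6.0, 10.0, 15.0):
            assert expected_clock_age(age, params, clock) == pytest.approx(age, abs=0.6)


class TestInvertClock:
    def test_fixed_point(self, clock):
        ref = ea.MethylationProfile("r", {k: 40.0 for k in clock.site_keys})
        t = ea.compute_dnam_age(ref, clock)
        out = ea.invert_clock(t, ref, clock)
        assert out.values == ref.values

    def test_round_trip_for_random_targets(self, clock):
        rng = np.random.default_rng(0)
        ref = ea.MethylationProfile("r", {k: 40.0 for k in clock.site_keys})
        ref_age = ea.compute_dnam_age(ref, clock)
        for t in rng.uniform(ref_age - 30, ref_age + 30, 100):
            out = ea.invert_clock(float(t), ref, clock)
            assert ea.compute_dnam_age(out, clock) == pytest.approx(t, abs=1e-9)

    def test_minimum_norm_shift_follows_the_coefficient_direction(self, clock):
        ref = ea.MethylationProfile("r", {k: 40.0 for k in clock.site_keys})
        t0 = ea.compute_dnam_age(ref, clock)
        delta = 5.0
        out = ea.invert_clock(t0 + delta, ref, clock)
        coefs = clock.coefficients
        norm2 = float(coefs @ coefs)  # verified by hand: ~1.1864904940808751
        for site in clock.sites:
            step = out.values[site.site_key] - 40.0
            assert step == pytest.approx(site.coefficient * delta / norm2, abs=1e-9)

    def test_infeasible_target_names_the_binding_site(self, clock):
        ref = ea.MethylationProfile("r", {k: 1.0 for k in clock.site_keys})
        with pytest.raises(InfeasibleTargetError, match="methC1-KLF14"):
            ea.invert_clock(-200.0, ref, clock)


class TestRecoveryExperiment:
    def test_single_replicate_reports_without_coverage(self):
        params = ea.CohortParams(n_subjects=10, igf_slope=0.0)
        rep = ea.recovery_experiment(params, n_reps=1, seed=4)
        assert rep.n_reps == 1 and len(rep.estimates) == 1
        assert rep.shift_coverage is None

    def test_rmse_of_shift_estimate_shrinks_with_cohort_size(self):
        rmses = []
        for n in (20, 80, 320):
            params = ea.CohortParams(n_subjects=n, igf_slope=0.0)
            rep = ea.recovery_experiment(params, n_reps=25, seed=11)
            assert rep.n_failed == 0
            rmses.append(rep.shift_rmse)
        assert rmses[0] > rmses[1] > rmses[2]

    def test_covariate_recovery_tracks_generator_slope(self):
        params = ea.CohortParams(n_subjects=120)
        rep = ea.recovery_experiment(params, n_reps=20, seed=3, covariate="igf1")
        assert rep.covariate == "igf1"
        assert rep.covariate_truth == 0.011
        assert abs(rep.covariate_bias) < 0.01
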