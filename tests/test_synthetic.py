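"""Generator contracts: determinism, calibration targets, round trips."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from acticohort import (
    CATEGORIES,
    STATES,
    ActivityProfile,
    CohortConfig,
    annotate_epochs,
    classify_regimen,
    default_group_profiles,
    epochs_to_subject_summary,
    generate_cohort,
    generate_recording,
    inject_nonwear,
    is_valid_subject,
    mark_valid_days,
    met_cutpoints_in_enmo,
    perturb_profile,
    process_recording,
    reference_fractions,
    simulate_subject,
    write_fixtures,
)

from conftest import make_profile


class TestProfileInvariants:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            make_profile(state_fractions={"sleep_sedentary": 0.5, "light": 0.3,
                                          "moderate": 0.1, "vigorous": 0.05})

    def test_medians_must_be_ordered(self):
        with pytest.raises(ValueError, match="ordered"):
            make_profile(enmo_median_mg={"sleep_sedentary": 60.0, "light": 52.0,
                                         "moderate": 190.0, "vigorous": 550.0})

    def test_bout_means_must_be_positive(self):
        with pytest.raises(ValueError):
            make_profile(bout_mean_min={"sleep_sedentary": 0.0, "light": 3.0,
                                        "moderate": 2.0, "vigorous": 1.0})

    def test_weekend_modulation_shifts_into_sedentary(self):
        p = make_profile(weekend_modulation=0.8)
        wd, we = p.fractions_for_weekday(0), p.fractions_for_weekday(5)
        assert we["light"] < wd["light"] and we["moderate"] < wd["moderate"]
        assert we["sleep_sedentary"] > wd["sleep_sedentary"]
        assert sum(we.values()) == pytest.approx(1.0)


class TestReferenceFractions:
    def test_single_state_profile(self):
        p = make_profile(state_fractions={"sleep_sedentary": 1.0, "light": 0.0,
                                          "moderate": 0.0, "vigorous": 0.0},
                         enmo_sigma={s: 0.0 for s in STATES},
                         enmo_median_mg={"sleep_sedentary": 5.0, "light": 52.0,
                                         "moderate": 190.0, "vigorous": 550.0})
        rf = reference_fractions(p)
        assert rf["sedentary"] == pytest.approx(1.0)

    def test_sums_to_one_for_random_profiles(self, rng):
        for _ in range(20):
            f = rng.dirichlet(np.ones(4))
            p = make_profile(state_fractions=dict(zip(STATES, f)))
            assert sum(reference_fractions(p).values()) == pytest.approx(1.0)

    def test_matches_monte_carlo_oracle(self, rng):
        p = make_profile(state_fractions={"sleep_sedentary": 0.6, "light": 0.3,
                                          "moderate": 0.1, "vigorous": 0.0})
        edges = met_cutpoints_in_enmo()
        n = 200_000
        weights = p.state_fractions
        counts = np.zeros(4)
        for j, s in enumerate(STATES):
            if weights[s] == 0:
                continue
            draws = p.enmo_median_mg[s] * np.exp(
                p.enmo_sigma[s] * rng.standard_normal(n)
            )
            bands = np.searchsorted(edges, draws)
            counts += weights[s] * np.bincount(bands, minlength=4) / n
        rf = reference_fractions(p, weekday_mix=(1, 0))
        for c, mc in zip(CATEGORIES, counts):
            assert rf[c] == pytest.approx(mc, abs=3e-3)


class TestRecordingGeneration:
    def test_determinism_bit_identical(self):
        p = make_profile()
        a = generate_recording(p, n_days=1, sampling_rate_hz=2.0, seed=9)
        b = generate_recording(p, n_days=1, sampling_rate_hz=2.0, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_recording(make_profile(), n_days=0, seed=1)

    def test_sedentary_only_profile_classifies_sedentary(self):
        p = make_profile(
            state_fractions={"sleep_sedentary": 1.0, "light": 0.0,
                             "moderate": 0.0, "vigorous": 0.0},
            enmo_median_mg={"sleep_sedentary": 5.0, "light": 52.0,
                            "moderate": 190.0, "vigorous": 550.0},
        )
        rec = generate_recording(p, n_days=1, sampling_rate_hz=2.0, seed=3)
        ep = annotate_epochs(process_recording(rec))
        frac_sed = (ep["category"] == "sedentary").mean()
        assert frac_sed >= 0.95

    def test_constant_enmo_without_noise_inverts_exactly(self):
        p = make_profile(
            state_fractions={"sleep_sedentary": 0.0, "light": 1.0,
                             "moderate": 0.0, "vigorous": 0.0},
            enmo_median_mg={"sleep_sedentary": 5.0, "light": 100.0,
                            "moderate": 190.0, "vigorous": 550.0},
            enmo_sigma={s: 0.0 for s in STATES},
            noise_sd_mg=0.0,
        )
        rec = generate_recording(p, n_days=1, sampling_rate_hz=2.0, seed=4)
        ep = process_recording(rec)
        np.testing.assert_allclose(ep["enmo_mg"], 100.0, atol=0.5)


class TestInjectNonwear:
    def test_empty_schedule_is_identity(self):
        rec = generate_recording(make_profile(), n_days=1, sampling_rate_hz=1.0, seed=5)
        out = inject_nonwear(rec, [])
        assert np.array_equal(out.samples, rec.samples)

    def test_out_of_range_interval_rejected(self):
        rec = generate_recording(make_profile(), n_days=1, sampling_rate_hz=1.0, seed=5)
        with pytest.raises(ValueError):
            inject_nonwear(rec, [(1400.0, 60.0)])

    def test_overlapping_intervals_rejected(self):
        rec = generate_recording(make_profile(), n_days=1, sampling_rate_hz=1.0, seed=5)
        with pytest.raises(ValueError):
            inject_nonwear(rec, [(100.0, 60.0), (120.0, 60.0)])

    def test_injected_gap_is_gravity_only(self):
        rec = generate_recording(make_profile(), n_days=1, sampling_rate_hz=1.0, seed=5)
        out = inject_nonwear(rec, [(300.0, 120.0)])
        gap = out.samples[300 * 60:420 * 60]
        np.testing.assert_array_equal(gap, np.tile([0.0, 0.0, 1.0], (gap.shape[0], 1)))


class TestPerturbation:
    def test_group_means_preserved_across_subjects(self, group_profiles):
        rng = np.random.default_rng(77)
        p = group_profiles["APM"]
        draws = np.array(
            [[perturb_profile(p, rng).state_fractions[s] for s in STATES]
             for _ in range(3000)]
        )
        base = np.array([p.state_fractions[s] for s in STATES])
        np.testing.assert_allclose(draws.mean(axis=0), base, atol=0.01)

    def test_fractions_remain_simplex(self, group_profiles):
        rng = np.random.default_rng(78)
        for _ in range(200):
            f = perturb_profile(group_profiles["HC"], rng).state_fractions
            vals = np.array(list(f.values()))
            assert (vals >= 0).all()
            assert vals.sum() == pytest.approx(1.0)


class TestCohortGeneration:
    def test_degenerate_benzodiazepine_probability(self):
        cfg = CohortConfig(
            n_per_group=(30, 30, 0),
            class_probs={**CohortConfig().class_probs, "benzodiazepine": (1.0, 1.0)},
            seed=1,
        )
        cohort = generate_cohort(cfg)
        assert (cohort["n_benzodiazepine"] >= 1).all()

    def test_empty_cohort_no_error(self):
        cohort = generate_cohort(CohortConfig(n_per_group=(0, 0, 0)))
        assert len(cohort) == 0

    def test_fga_prevalence_converges(self):
        probs = {c: (p, p) for c, (p, _) in CohortConfig().class_probs.items()}
        probs["fga"] = (0.376, 0.376)
        cohort = generate_cohort(CohortConfig(n_per_group=(3100, 3100, 0),
                                              class_probs=probs, seed=11))
        prevalence = (cohort["n_fga"] > 0).mean()
        assert prevalence == pytest.approx(0.376, abs=0.02)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_group=(-1, 0, 0))
        with pytest.raises(ValueError):
            CohortConfig(p_residential=1.2)

    def test_determinism(self):
        a = generate_cohort(CohortConfig(n_per_group=(20, 20, 5), seed=3))
        b = generate_cohort(CohortConfig(n_per_group=(20, 20, 5), seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_group_labels_match_regimen_classifier(self):
        cohort = generate_cohort(CohortConfig(n_per_group=(50, 50, 5), seed=4))
        pats = cohort[cohort["group"] != "HC"]
        for _, row in pats.iterrows():
            assert classify_regimen(row) == row["group"]


class TestFixtures:
    def test_fixture_set_is_deterministic(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        files1 = write_fixtures(d1, seed=5, n_days=1, sampling_rate_hz=2.0)
        files2 = write_fixtures(d2, seed=5, n_days=1, sampling_rate_hz=2.0)
        assert len(files1) == 7  # 3 x (csv + yaml) + cohort
        for f1, f2 in zip(files1, files2):
            h1 = hashlib.sha256(f1.read_bytes()).hexdigest()
            h2 = hashlib.sha256(f2.read_bytes()).hexdigest()
            assert h1 == h2, f1.name

    def test_fixture_recordings_round_trip_and_validate(self, tmp_path):
        from acticohort.io import read_recording_csv

        files = write_fixtures(tmp_path, seed=6, n_days=7, sampling_rate_hz=2.0)
        csvs = [f for f in files if f.suffix == ".csv" and f.name != "cohort.csv"]
        assert len(csvs) == 3
        rec = read_recording_csv(csvs[0])
        epochs = process_recording(rec)
        assert is_valid_subject(mark_valid_days(epochs))


def test_simulate_subject_deterministic_and_valid(group_profiles):
    rec1, prof1 = simulate_subject(group_profiles["APP"], 12, "s", n_days=7,
                                   sampling_rate_hz=2.0)
    rec2, prof2 = simulate_subject(group_profiles["APP"], 12, "s", n_days=7,
                                   sampling_rate_hz=2.0)
    assert np.array_equal(rec1.samples, rec2.samples)
    assert prof1.state_fractions == prof2.state_fractions
    ep = process_recording(rec1)
    assert is_valid_subject(mark_valid_days(ep))
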