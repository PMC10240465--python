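"""Synthetic cohort: covariates, determinism, artifacts, calibration, I/O."""

import numpy as np
import pytest
import scipy.stats
from dataclasses import replace

from edsleep.io_preprocess import ConfigurationError
from edsleep.synth_cohort import (
    CovariateParams,
    GeneratorConfig,
    HIGH_ESS_PROFILE,
    LOW_ESS_PROFILE,
    generate_cohort,
    inject_artifacts,
    sample_covariates,
    synthesize_recording,
    write_cohort,
)


class TestCovariates:
    def test_default_cohort_has_72_subjects(self):
        records = sample_covariates(GeneratorConfig(seed=1))
        assert len(records) == 72
        groups = [r.group for r in records]
        assert groups.count("high") == 31 and groups.count("low") == 41
        for r in records:
            assert (r.group == "high") == (r.ess >= 20)
            assert (r.group == "low") == (r.ess < 5)

    def test_degenerate_group_size_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_covariates(GeneratorConfig(n_high=0)).copy()

    def test_invalid_ess_range_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(ess_high_range=(24, 20)).validate()

    def test_ess_mean_matches_uniform_oracle(self):
        # oracle: closed-form mean of the uniform integer range [20, 24]
        ess = []
        for seed in range(1000):
            cfg = GeneratorConfig(n_high=2, n_low=2, seed=seed)
            ess.extend(r.ess for r in sample_covariates(cfg) if r.group == "high")
        ess = np.asarray(ess, dtype=float)
        midpoint = (20 + 24) / 2
        se = ess.std(ddof=1) / np.sqrt(len(ess))
        assert abs(ess.mean() - midpoint) < 3 * se

    def test_covariate_moments_match_parameters(self):
        cfg = GeneratorConfig(n_high=400, n_low=400, seed=3)
        records = sample_covariates(cfg)
        high = [r for r in records if r.group == "high"]
        ages = np.array([r.age for r in high])
        bmis = np.array([r.bmi for r in high])
        female = np.mean([r.sex == "female" for r in high])
        p = cfg.covariate_params
        assert ages.mean() == pytest.approx(p.age_mean_high, abs=3 * 14.5 / 20)
        assert bmis.mean() == pytest.approx(p.bmi_mean_high, abs=3 * 9.9 / 20 + 0.5)
        assert female == pytest.approx(p.female_prop_high, abs=0.08)

    def test_leakage_shifts_high_group(self):
        base = CovariateParams()
        leaky = replace(base, leakage=1.0)
        assert leaky.group_params("high")["age_mean"] < base.group_params("high")["age_mean"]
        assert leaky.group_params("low") == base.group_params("low")


class TestSynthesis:
    def test_identical_seeds_bit_identical(self):
        cfg = GeneratorConfig(n_high=2, n_low=2, duration_s=200.0, seed=4)
        a = synthesize_recording(HIGH_ESS_PROFILE, cfg, 3)
        b = synthesize_recording(HIGH_ESS_PROFILE, cfg, 3)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = synthesize_recording(HIGH_ESS_PROFILE, cfg, 4)
        assert not np.array_equal(a.samples, c.samples)

    def test_annotations_bracket_window(self):
        cfg = GeneratorConfig(n_high=2, n_low=2, duration_s=300.0, seed=4)
        rec = synthesize_recording(LOW_ESS_PROFILE, cfg, 0)
        span = rec.annotation_onset("N1") - rec.annotation_onset("LIGHTS_OUT")
        assert span >= 180.0

    def test_single_band_profile_dominates(self):
        # nearly all oscillator mass in alpha -> alpha has the largest
        # normalized fraction downstream
        from edsleep.io_preprocess import highpass, make_epoch_grid, notch
        from edsleep.spectral_features import (
            average_and_normalize,
            band_power_fractions,
            epoch_periodogram,
        )

        prof = replace(
            HIGH_ESS_PROFILE,
            band_fractions=(
                ("delta", 0.02), ("theta", 0.02), ("alpha", 0.92),
                ("beta", 0.02), ("low_gamma", 0.02),
            ),
            pac_depth=0.0,
        )
        cfg = GeneratorConfig(
            n_high=2, n_low=2, duration_s=200.0, seed=6, artifact_rate=0.0
        )
        rec = notch(highpass(synthesize_recording(prof, cfg, 0)))
        grid = make_epoch_grid(rec)
        norm = average_and_normalize(epoch_periodogram(grid.data, rec.fs))
        _, mean = band_power_fractions(norm)
        assert max(mean, key=mean.get) == "alpha"

    def test_calibrated_fractions_recovered_without_jitter(self):
        from edsleep.io_preprocess import highpass, make_epoch_grid, notch
        from edsleep.spectral_features import (
            average_and_normalize,
            band_power_fractions,
            epoch_periodogram,
        )

        cfg = GeneratorConfig(
            n_high=2, n_low=2, duration_s=220.0, seed=8,
            artifact_rate=0.0, subject_sd=0.0,
        )
        means = []
        for subj in range(3):
            rec = notch(highpass(synthesize_recording(HIGH_ESS_PROFILE, cfg, subj)))
            grid = make_epoch_grid(rec)
            norm = average_and_normalize(epoch_periodogram(grid.data, rec.fs))
            _, mean = band_power_fractions(norm)
            means.append(mean)
        for band, target in HIGH_ESS_PROFILE.fractions.items():
            got = np.mean([m[band] for m in means])
            assert got == pytest.approx(target, abs=0.01)


class TestArtifacts:
    def test_rate_zero_leaves_recording_untouched(self):
        cfg = GeneratorConfig(n_high=2, n_low=2, duration_s=200.0, seed=4,
                              artifact_rate=0.0)
        rec = synthesize_recording(HIGH_ESS_PROFILE, cfg, 0)
        out, truth = inject_artifacts(rec, cfg, 0)
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert not truth.any()

    def test_event_count_within_poisson_interval(self):
        cfg = GeneratorConfig(n_high=2, n_low=2, duration_s=600.0, seed=4,
                              artifact_rate=6.0)
        rec = synthesize_recording(HIGH_ESS_PROFILE, cfg, 0)
        _, _, events = inject_artifacts(rec, cfg, 0, return_events=True)
        lam = 60.0
        lo, hi = scipy.stats.poisson.interval(0.99, lam)
        assert lo <= len(events) <= hi

    def test_transient_amplitude_exceeds_5_sigma(self):
        cfg = GeneratorConfig(n_high=2, n_low=2, duration_s=300.0, seed=7,
                              artifact_rate=8.0)
        rec = synthesize_recording(HIGH_ESS_PROFILE, cfg, 1)
        out, truth, events = inject_artifacts(rec, cfg, 1, return_events=True)
        sd = rec.samples.std(axis=1)
        fs = int(rec.fs)
        checked = 0
        for ev in events:
            if ev["kind"] != "transient":
                continue
            c = ev["channels"][0]
            e = int(ev["onset_s"] + 0.075)  # event midpoint epoch
            if e >= truth.shape[0] or not truth[e, c]:
                continue
            seg = out.samples[c, e * fs : (e + 1) * fs] - rec.samples[c, e * fs : (e + 1) * fs]
            assert np.abs(seg).max() >= 5 * sd[c]
            checked += 1
        assert checked >= 1

    def test_truth_epochs_contain_large_samples(self):
        cfg = GeneratorConfig(n_high=2, n_low=2, duration_s=300.0, seed=9)
        rec = synthesize_recording(HIGH_ESS_PROFILE, cfg, 0)
        out, truth = inject_artifacts(rec, cfg, 0)
        assert truth.shape == (300, 6)
        fs = int(rec.fs)
        delta = np.abs(out.samples - rec.samples)
        sd = rec.samples.std(axis=1)
        for e, c in zip(*np.nonzero(truth)):
            assert delta[c, e * fs : (e + 1) * fs].max() >= 3 * sd[c]


class TestCoherencePlacement:
    def test_configured_pair_exceeds_all_others(self, small_features):
        table = small_features.table.values
        target = table["coh_C4-O2_delta"].mean()
        others = [
            c for c in table.columns
            if c.startswith("coh_") and c.endswith("_delta") and "C4-O2" not in c
        ]
        assert len(others) == 14
        assert target > max(table[c].mean() for c in others)


class TestWriteCohort:
    def test_manifest_and_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(n_high=2, n_low=2, duration_s=200.0, seed=5)
        cohort = generate_cohort(cfg)
        manifest = write_cohort(tmp_path / "out", cohort)
        assert len(manifest["edf"]) == 4
        assert len(manifest["events"]) == 4
        from edsleep.edf import EDF_PHYS_MAX
        from edsleep.io_preprocess import read_edf

        rec = cohort.recordings["S001"]
        back = read_edf(manifest["edf"][0])
        step = 2 * EDF_PHYS_MAX / 65535
        assert np.abs(back.samples - rec.samples).max() <= step

    def test_empty_cohort_valid_csv_header(self, tmp_path):
        from edsleep.synth_cohort import Cohort, read_covariates

        cfg = GeneratorConfig(n_high=2, n_low=2, duration_s=200.0, seed=5)
        cohort = Cohort(config=cfg, subjects=[])
        manifest = write_cohort(tmp_path / "empty", cohort)
        assert manifest["edf"] == []
        assert read_covariates(manifest["covariates"]) == []

    def test_covariates_csv_roundtrip(self, tmp_path):
        from edsleep.synth_cohort import read_covariates

        cfg = GeneratorConfig(n_high=2, n_low=2, duration_s=200.0, seed=5)
        cohort = generate_cohort(cfg)
        manifest = write_cohort(tmp_path / "cov", cohort)
        rows = read_covariates(manifest["covariates"])
        assert [r["subject_id"] for r in rows] == [s.subject_id for s in cohort.subjects]
        assert set(rows[0]) == {"subject_id", "group", "ess", "age", "sex", "bmi"}
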