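"""Synthetic cohort generator: determinism, counts, oracles, scaling laws."""

import numpy as np
import pytest

from musclenet import io as mio
from musclenet.coherence import BandDefinition, band_msc, msc
from musclenet.features import time_features
from musclenet.synthetic import (
    BandDrive,
    CohortParams,
    ParameterError,
    cohort_subjects,
    expected_msc,
    generate_cohort,
    generate_recording,
)


def pair_drive(gamma_a=0.5, gamma_b=0.5, lo=1.0, hi=4.0, name="delta"):
    return BandDrive(
        name, lo, hi, ("SCM-L", "SC-L"), {"SCM-L": gamma_a, "SC-L": gamma_b}
    )


class TestExpectedMsc:
    """Closed-form coherence oracle: gamma_c * gamma_d inside a shared band."""

    @pytest.mark.parametrize(
        "ga,gb,expected", [(1.0, 1.0, 1.0), (0.5, 0.5, 0.25), (0.9, 0.0, 0.0)]
    )
    def test_product_rule(self, ga, gb, expected):
        p = CohortParams(
            n_per_group=1, duration_s=2.0, n_trials=1,
            band_drives=[pair_drive(ga, gb)],
        )
        assert expected_msc(p, ("SCM-L", "SC-L"), "delta") == pytest.approx(expected)

    def test_uncovered_pair_is_zero(self):
        p = CohortParams(
            n_per_group=1, duration_s=2.0, n_trials=1, band_drives=[pair_drive()]
        )
        assert expected_msc(p, ("SCM-L", "UT-R"), "delta") == 0.0
        assert expected_msc(p, ("SCM-L", "SC-L"), "theta") == 0.0

    def test_group_effect_enters_through_gamma(self):
        p = CohortParams(n_per_group=1, duration_s=2.0, n_trials=1)
        base = expected_msc(p, ("SCM-L", "SC-L"), "delta")
        cnp_curv = expected_msc(
            p, ("SCM-L", "SC-L"), "delta", group="CNP", task="curvilinear"
        )
        assert base == pytest.approx(0.25)
        assert cnp_curv == pytest.approx(0.0625)
        # no effect planted in rectilinear gait
        assert expected_msc(
            p, ("SCM-L", "SC-L"), "delta", group="CNP", task="rectilinear"
        ) == pytest.approx(base)


class TestParameterValidation:
    def test_invalid_band_edges(self):
        with pytest.raises(ParameterError):
            CohortParams(duration_s=2.0, band_drives=[pair_drive(lo=4.0, hi=4.0)])
        with pytest.raises(ParameterError):
            CohortParams(duration_s=2.0, band_drives=[pair_drive(lo=10, hi=600)])

    def test_gamma_out_of_range(self):
        with pytest.raises(ParameterError):
            CohortParams(duration_s=2.0, band_drives=[pair_drive(gamma_a=1.2)])

    def test_non_integer_sample_count(self):
        with pytest.raises(ParameterError):
            CohortParams(duration_s=2.0005, fs=999.0)

    def test_fs_must_clear_band_edges(self):
        # a band edge at or above Nyquist is unrealizable
        with pytest.raises(ParameterError):
            CohortParams(duration_s=2.0, fs=50.0, band_drives=[pair_drive(lo=20, hi=25)])


class TestGenerateRecording:
    def test_shape_and_finiteness(self):
        p = CohortParams(n_per_group=1, duration_s=6.0, n_trials=1)
        rec = generate_recording(p, "S1", "control", "rectilinear", 1)
        assert rec.samples.shape == (6, 6000)
        assert np.all(np.isfinite(rec.samples))

    def test_deterministic_streams_independent_of_order(self):
        p = CohortParams(n_per_group=2, duration_s=2.0, n_trials=2, seed=5)
        a = generate_recording(p, "CNP01", "CNP", "curvilinear", 2)
        # interleave other recordings, then regenerate the same one
        generate_recording(p, "CTL01", "control", "rectilinear", 1)
        b = generate_recording(p, "CNP01", "CNP", "curvilinear", 2)
        assert np.array_equal(a.samples, b.samples)

    def test_identical_shared_drive_gives_unit_coherence(self):
        # gamma = 1 on one pair, no measurement noise, flat envelope
        # (stride_hz = 0): the two channels carry the same underlying drive.
        p = CohortParams(
            n_per_group=1, duration_s=60.0, n_trials=1, stride_hz=0.0,
            band_drives=[pair_drive(1.0, 1.0)], noise_floor=0.0, seed=2,
        )
        rec = generate_recording(p, "S1", "control", "rectilinear", 1)
        spec = msc(rec.channel("SCM-L"), rec.channel("SC-L"), rec.fs)
        assert band_msc(spec, BandDefinition("delta", 1, 4)) > 0.97

    def test_no_shared_drive_gives_bias_level_coherence(self):
        p = CohortParams(
            n_per_group=1, duration_s=60.0, n_trials=1,
            band_drives=[pair_drive(0.0, 0.0)], noise_floor=0.0, seed=3,
        )
        rec = generate_recording(p, "S1", "control", "rectilinear", 1)
        spec = msc(rec.channel("SCM-L"), rec.channel("SC-L"), rec.fs)
        # 120 segments -> bias ~ 1/120; generous headroom
        assert band_msc(spec, BandDefinition("delta", 1, 4)) < 0.05

    def test_amplitude_scale_feature_scaling_law(self):
        """Doubling amplitude doubles MAV/RMS and quadruples VAR/SSI (raw signal)."""
        common = dict(
            n_per_group=1, duration_s=4.0, n_trials=1, noise_floor=0.0, seed=9
        )
        p1 = CohortParams(**common)
        p2 = CohortParams(
            amplitude_scale={"control:rectilinear:SCM-L": 2.0}, **common
        )
        r1 = generate_recording(p1, "S1", "control", "rectilinear", 1)
        r2 = generate_recording(p2, "S1", "control", "rectilinear", 1)
        f1 = time_features(r1.channel("SCM-L"))
        f2 = time_features(r2.channel("SCM-L"))
        for feat in ("MAV", "RMS", "WL"):
            assert f2[feat] == pytest.approx(2.0 * f1[feat], rel=1e-9)
        for feat in ("VAR", "SSI"):
            assert f2[feat] == pytest.approx(4.0 * f1[feat], rel=1e-9)


class TestGenerateCohort:
    def test_counts_and_round_trip(self, tmp_path):
        p = CohortParams(n_per_group=2, duration_s=2.0, n_trials=2, seed=4)
        manifest = generate_cohort(p, tmp_path / "cohort")
        # 2 groups x 2 subjects x 2 tasks x 2 trials
        assert len(manifest) == 16
        assert sorted(manifest["group"].unique()) == ["CNP", "control"]
        recs = mio.load_cohort(tmp_path / "cohort" / "manifest.csv")
        assert len(recs) == 16
        assert recs[0].samples.shape == (6, 2000)
        regenerated = generate_recording(p, recs[0].subject_id, recs[0].group,
                                         recs[0].task, recs[0].trial_index)
        np.testing.assert_allclose(recs[0].samples, regenerated.samples, atol=1e-12)

    def test_same_seed_is_bit_identical(self, tmp_path):
        p = CohortParams(n_per_group=1, duration_s=2.0, n_trials=1, seed=8)
        generate_cohort(p, tmp_path / "a")
        generate_cohort(p, tmp_path / "b")
        for sub in ("manifest.csv", "recordings/CNP01_curvilinear_t1.csv"):
            assert (tmp_path / "a" / sub).read_bytes() == (
                tmp_path / "b" / sub
            ).read_bytes()

    def test_refuses_to_clobber_existing_manifest(self, tmp_path):
        p = CohortParams(n_per_group=1, duration_s=2.0, n_trials=1)
        generate_cohort(p, tmp_path)
        with pytest.raises(FileExistsError):
            generate_cohort(p, tmp_path)
        generate_cohort(p, tmp_path, overwrite=True)

    def test_subject_ordering(self):
        p = CohortParams(n_per_group=3, duration_s=2.0, n_trials=1)
        subs = cohort_subjects(p)
        assert len(subs) == 6
        assert subs[0] == ("CNP01", "CNP")
        assert subs[3] == ("CTL01", "control")
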