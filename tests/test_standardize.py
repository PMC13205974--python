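"""Standardization: mirror map, peak detection, biphasic resampling, SG."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patellakin.exceptions import (
    AlreadyMirroredError,
    InvalidArgumentError,
    MalformedCycleError,
)
from patellakin.standardize import (
    DOFTrajectory,
    biphasic_resample,
    build_feature_matrix,
    find_peak_frame,
    mirror_if_left,
    sg_filter,
    smooth_standardized,
    summarize_dof,
)
from patellakin.synthetic import default_templates, sample_phenotype_trajectory


def traj_from_tz(tz, laterality="right", sid="t"):
    samples = np.zeros((len(tz), 6))
    samples[:, 2] = tz
    return DOFTrajectory(sid, laterality, samples)


class TestMirror:
    def test_left_sample_mapping(self):
        samples = np.tile([1.0, 2, 3, 4, 5, 6], (5, 1))
        out = mirror_if_left(DOFTrajectory("L", "left", samples))
        assert np.allclose(out.samples[0], [-1, 2, 3, 4, -5, -6])
        assert out.mirrored

    def test_right_passes_through(self):
        samples = np.tile([1.0, 2, 3, 4, 5, 6], (5, 1))
        out = mirror_if_left(DOFTrajectory("R", "right", samples))
        assert np.allclose(out.samples, samples)

    def test_double_mirror_guard(self):
        samples = np.zeros((5, 6))
        out = mirror_if_left(DOFTrajectory("L", "left", samples))
        with pytest.raises(AlreadyMirroredError):
            mirror_if_left(out)

    def test_exact_left_right_pair_gives_identical_features(self):
        """A left knee generated as the exact mirror of a right knee yields
        the same standardized feature row after mirroring."""
        _, dof = sample_phenotype_trajectory(default_templates()[0], 24, seed=8)
        right = DOFTrajectory("R", "right", dof)
        from patellakin.anatomy import mirror_dof

        left = DOFTrajectory("L", "left", mirror_dof(dof))
        rows = []
        for traj in (mirror_if_left(right), mirror_if_left(left)):
            k = find_peak_frame(traj)
            std = smooth_standardized(biphasic_resample(traj, k))
            rows.append(std.dof("Tx"))
        assert np.max(np.abs(rows[0] - rows[1])) < 1e-9


class TestFindPeakFrame:
    def test_simple_and_tied_maxima(self):
        assert find_peak_frame(traj_from_tz([0, 5, 9, 4, 1])) == 2
        assert find_peak_frame(traj_from_tz([0, 9, 9, 4, 1])) == 1

    def test_boundary_peak_rejected(self):
        with pytest.raises(MalformedCycleError):
            find_peak_frame(traj_from_tz([9, 5, 3, 2, 1]))
        with pytest.raises(MalformedCycleError):
            find_peak_frame(traj_from_tz([0, 1, 2, 3, 9]))

    def test_generated_cohort_never_malformed(self):
        template = default_templates()[2]
        for seed in range(1000):
            _, dof = sample_phenotype_trajectory(template, 23, seed=seed)
            find_peak_frame(DOFTrajectory("s", "right", dof))  # must not raise


class TestBiphasicResample:
    def test_linear_ramps_reproduced(self):
        n, k = 49, 24
        tz = np.concatenate([np.linspace(0, 10, k + 1), np.linspace(10, 0, n - k)[1:]])
        std = biphasic_resample(traj_from_tz(tz), k)
        out = std.dof("Tz")
        assert np.allclose(out[:25], np.linspace(0, 10, 25), atol=1e-9)
        assert np.allclose(out[25:], np.linspace(10, 0, 25), atol=1e-9)

    def test_extremum_preservation(self):
        template = default_templates()[0]
        _, dof = sample_phenotype_trajectory(template, 27, seed=3)
        traj = DOFTrajectory("s", "right", dof)
        k = find_peak_frame(traj)
        std = biphasic_resample(traj, k)
        assert std.dof("Tz")[24] == dof[k, 2]
        assert np.isclose(std.dof("Tz").max(), dof[:, 2].max())

    def test_constant_series_gives_constant_output(self):
        samples = np.full((9, 6), 3.7)
        std = biphasic_resample(DOFTrajectory("c", "right", samples), 4)
        assert np.allclose(std.series, 3.7)

    def test_output_bounded_by_raw_range(self):
        _, dof = sample_phenotype_trajectory(default_templates()[1], 22, seed=14)
        traj = DOFTrajectory("s", "right", dof)
        std = biphasic_resample(traj, find_peak_frame(traj))
        for d in range(6):
            assert std.series[:, d].max() <= dof[:, d].max() + 1e-12
            assert std.series[:, d].min() >= dof[:, d].min() - 1e-12

    def test_out_of_range_kpeak_rejected(self):
        traj = traj_from_tz([0, 1, 9, 1, 0])
        for bad in (0, 4):
            with pytest.raises(InvalidArgumentError):
                biphasic_resample(traj, bad)


class TestSavitzkyGolay:
    def test_interior_kernel_matches_normal_equation_oracle(self):
        """The (7,2) interior response equals convolution with the kernel
        obtained by solving the local least-squares normal equations."""
        x = np.arange(-3, 4, dtype=float)
        A = np.vander(x, 3, increasing=True)  # fit a + b t + c t^2
        kernel = np.linalg.solve(A.T @ A, A.T)[0]  # value at t=0
        assert np.allclose(kernel, np.array([-2, 3, 6, 7, 6, 3, -2]) / 21, atol=1e-12)
        rng = np.random.default_rng(0)
        series = rng.normal(0, 1, 31)
        smoothed = sg_filter(series)
        conv = np.convolve(series, kernel[::-1], mode="valid")
        assert np.allclose(smoothed[3:-3], conv, atol=1e-10)

    def test_quadratic_reproduced_exactly(self):
        t = np.arange(20.0)
        series = 0.3 * t**2 - 2 * t + 5
        assert np.allclose(sg_filter(series), series, atol=1e-9)

    def test_constant_unchanged(self):
        assert np.allclose(sg_filter(np.full(15, 4.2)), 4.2)

    @pytest.mark.parametrize("window,order,n", [(6, 2, 20), (7, 7, 20), (7, 2, 5)])
    def test_invalid_filter_configs(self, window, order, n):
        with pytest.raises(InvalidArgumentError):
            sg_filter(np.zeros(n), window, order)

    def test_smoothing_suppresses_noise_but_keeps_peaks(self):
        """On noisy standardized series the filter reduces total squared
        second difference while changing the Tx peak by < 0.5 mm."""
        rng = np.random.default_rng(5)
        _, dof = sample_phenotype_trajectory(default_templates()[0], 26, seed=6)
        traj = DOFTrajectory("s", "right", dof + rng.normal(0, 0.1, dof.shape))
        std = biphasic_resample(traj, find_peak_frame(traj))
        sm = smooth_standardized(std)
        d2 = lambda x: float(np.sum(np.diff(x, n=2, axis=0) ** 2))
        assert d2(sm.series) < d2(std.series)
        assert abs(sm.dof("Tx").max() - std.dof("Tx").max()) < 0.5


class TestSummaries:
    def test_peak_and_range(self):
        samples = np.zeros((5, 6))
        samples[:, 0] = [0, 1, 3, 2, 0]
        s = summarize_dof(DOFTrajectory("x", "right", samples))
        assert s.peaks["Tx"] == 3 and s.ranges["Tx"] == 3

    def test_flat_curve(self):
        s = summarize_dof(np.zeros((6, 6)), subject_id="flat")
        assert s.max_lateral_displacement == 0 and s.lateral_range_of_motion == 0

    def test_type1_cohort_mean_peak_matches_group_parameter(self):
        """Mean cycle-max lateral excursion of a large simulated dominant-
        lateral cohort reproduces the 35.11 mm group mean."""
        template = default_templates()[0]
        peaks = []
        for seed in range(2000):
            _, dof = sample_phenotype_trajectory(template, 25, seed=seed)
            peaks.append(summarize_dof(DOFTrajectory("s", "right", dof)).max_lateral_displacement)
        assert abs(np.mean(peaks) - 35.11) < 0.3


class TestFeatureMatrix:
    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(st.integers(min_value=1, max_value=8))
    def test_shape_and_row_identity(self, n_subjects):
        stds = []
        for i in range(n_subjects):
            _, dof = sample_phenotype_trajectory(default_templates()[1], 21, seed=100 + i)
            traj = DOFTrajectory(f"s{i}", "right", dof)
            stds.append(smooth_standardized(biphasic_resample(traj, find_peak_frame(traj))))
        X = build_feature_matrix(stds)
        assert X.shape == (n_subjects, 50)
        assert np.allclose(X.iloc[0].to_numpy(), stds[0].dof("Tx"))

    def test_inconsistent_lengths_rejected(self):
        _, dof = sample_phenotype_trajectory(default_templates()[1], 21, seed=1)
        traj = DOFTrajectory("a", "right", dof)
        a = biphasic_resample(traj, find_peak_frame(traj), points_per_phase=25)
        b = biphasic_resample(traj, find_peak_frame(traj), points_per_phase=10)
        with pytest.raises(InvalidArgumentError):
            build_feature_matrix([a, b])
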