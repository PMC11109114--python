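"""Unit and property tests for binned specific-energy distributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from microdose import (
    BinnedDistribution,
    CellDoseSample,
    build_distribution,
    convolution_count,
    convolve,
    cumulative,
    normal_reference,
    read_cell_dose_csv,
    read_spectrum_csv,
    rebin,
    replicate_frequency_errors,
    rmse,
    summarize,
    write_spectrum_csv,
)
from microdose.distributions import write_cell_dose_csv


def histogram_oracle(samples, edges):
    """Independent counting oracle: half-open bins, last bin closed."""
    samples = np.asarray(samples, dtype=float)
    probs = np.zeros(len(edges) - 1)
    for i in range(len(edges) - 1):
        if i < len(edges) - 2:
            mask = (samples >= edges[i]) & (samples < edges[i + 1])
        else:
            mask = (samples >= edges[i]) & (samples <= edges[i + 1])
        probs[i] = mask.sum()
    return probs / samples.size


class TestBuildDistribution:
    def test_direct_counting(self):
        dist = build_distribution([0.5, 1.5, 1.5, 1.5], n_bins=2, range=(0, 2))
        np.testing.assert_allclose(dist.probabilities, [0.25, 0.75])
        np.testing.assert_allclose(dist.bin_edges, [0, 1, 2])

    def test_degenerate_constant_sample(self):
        dist = build_distribution([3.0, 3.0, 3.0], bin_width=1.0)
        assert (dist.probabilities == 1.0).sum() == 1
        assert dist.probabilities.sum() == 1.0

    def test_matches_counting_oracle_on_gamma_draws(self, rng):
        draws = rng.gamma(2.0, 1.0, 100_000)
        dist = build_distribution(draws, bin_width=0.25)
        expected = histogram_oracle(draws, dist.bin_edges)
        np.testing.assert_array_equal(dist.probabilities, expected)

    def test_bin_width_pads_range_to_integer_bins(self):
        dist = build_distribution([0.1, 1.7], bin_width=0.5)
        assert dist.bin_edges[-1] == pytest.approx(2.0)
        assert dist.n_bins == 4

    @pytest.mark.parametrize(
        "samples, kwargs",
        [
            ([], {"n_bins": 5}),
            ([1.0, np.nan], {"n_bins": 5}),
            ([1.0, np.inf], {"n_bins": 5}),
            ([-0.5, 1.0], {"n_bins": 5}),
            ([1.0, 2.0], {"bin_width": 0.0}),
            ([1.0, 2.0], {"bin_width": -1.0}),
            ([1.0, 5.0], {"n_bins": 4, "range": (0, 2)}),  # range misses max
        ],
    )
    def test_invalid_inputs_rejected(self, samples, kwargs):
        with pytest.raises(ValueError):
            build_distribution(samples, **kwargs)


class TestInvariantsOfType:
    def test_nonuniform_bins_rejected(self):
        with pytest.raises(ValueError):
            BinnedDistribution(np.array([0, 1, 3.0]), np.array([0.5, 0.5]))

    def test_mass_must_sum_to_one(self):
        with pytest.raises(ValueError):
            BinnedDistribution(np.array([0, 1, 2.0]), np.array([0.5, 0.4]))

    def test_negative_specific_energy_rejected(self):
        with pytest.raises(ValueError):
            CellDoseSample(values=np.array([1.0, -0.1]), macroscopic_dose=5.0)


class TestCumulative:
    def test_known_values(self):
        dist = BinnedDistribution(np.array([0, 1, 2.0]), np.array([0.25, 0.75]))
        np.testing.assert_allclose(cumulative(dist), [0.25, 1.0])

    def test_single_bin(self):
        dist = BinnedDistribution(np.array([0, 1.0]), np.array([1.0]))
        np.testing.assert_allclose(cumulative(dist), [1.0])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_monotone_and_ends_at_one(self, weights):
        w = np.asarray(weights) + 1e-9
        probs = w / w.sum()
        dist = BinnedDistribution(np.arange(len(probs) + 1, dtype=float), probs)
        cum = cumulative(dist)
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] == pytest.approx(1.0, abs=1e-9)


class TestSummarize:
    def test_two_point_population_std(self):
        s = summarize(np.array([5.0, 15.0]))
        assert (s.mean, s.std, s.dispersion) == (10.0, 5.0, 0.5)

    def test_constant_sample_has_zero_dispersion(self):
        assert summarize(np.array([4.0, 4.0, 4.0])).dispersion == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            summarize(np.array([0.0, 0.0]))

    def test_binned_moments_close_to_raw_moments(self, rng):
        x = rng.gamma(3.0, 2.0, 50_000)
        dist = build_distribution(x, bin_width=0.05)
        raw, binned = summarize(x), summarize(dist)
        assert abs(binned.mean - raw.mean) < 0.5 * dist.bin_width
        assert binned.dispersion == pytest.approx(raw.dispersion, rel=0.02)


class TestNormalReference:
    def test_symmetry_about_central_bin(self):
        summ = summarize(np.array([4.0, 6.0]))  # mean 5, std 1
        ref = normal_reference(summ, np.linspace(0, 10, 11))
        np.testing.assert_allclose(ref.probabilities, ref.probabilities[::-1], atol=1e-12)

    def test_zero_sigma_degenerates_to_single_bin(self):
        from microdose import DistributionSummary

        ref = normal_reference(
            DistributionSummary(mean=2.5, std=0.0, dispersion=0.0),
            np.linspace(0, 5, 6),
        )
        assert ref.probabilities[2] == 1.0
        assert ref.probabilities.sum() == 1.0

    def test_matches_quadrature_oracle(self):
        from microdose import DistributionSummary

        mu, sigma = 3.0, 1.2
        edges = np.linspace(0, 8, 17)
        ref = normal_reference(
            DistributionSummary(mean=mu, std=sigma, dispersion=sigma / mu), edges
        )
        masses = np.array(
            [
                integrate.quad(stats.norm(mu, sigma).pdf, lo, hi, epsrel=1e-10)[0]
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        masses /= masses.sum()
        np.testing.assert_allclose(ref.probabilities, masses, rtol=1e-6)

    def test_empty_range_rejected(self):
        from microdose import DistributionSummary

        with pytest.raises(ValueError):
            normal_reference(
                DistributionSummary(mean=1000.0, std=0.1, dispersion=1e-4),
                np.linspace(0, 1, 5),
            )


class TestRmse:
    def make(self, probs):
        return BinnedDistribution(np.arange(len(probs) + 1, dtype=float), np.asarray(probs))

    def test_identical_is_zero(self):
        d = self.make([0.3, 0.7])
        assert rmse(d, d) == 0.0

    def test_opposite_unit_masses(self):
        assert rmse(self.make([1, 0]), self.make([0, 1])) == pytest.approx(1.0)

    def test_closed_form_example(self):
        assert rmse(self.make([0.5, 0.5]), self.make([0.25, 0.75])) == pytest.approx(0.25)

    def test_symmetric_on_random_pairs(self, rng):
        for _ in range(10):
            a = rng.dirichlet(np.ones(20))
            b = rng.dirichlet(np.ones(20))
            assert rmse(self.make(a), self.make(b)) == pytest.approx(
                rmse(self.make(b), self.make(a))
            )

    def test_mismatched_grids_rejected(self):
        a = self.make([0.5, 0.5])
        b = BinnedDistribution(np.array([0, 2, 4.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="identical bin edges"):
            rmse(a, b)
        c = self.make([0.25, 0.25, 0.5])
        with pytest.raises(ValueError):
            rmse(a, c)


class TestConvolutionCount:
    @pytest.mark.parametrize("D, D1, expected", [(500, 5, 100), (5, 5, 1), (100, 1, 100)])
    def test_integer_ratios(self, D, D1, expected):
        assert convolution_count(D, D1) == expected

    @pytest.mark.parametrize("D, D1", [(7, 2), (5, 3), (0, 5), (-5, 5), (5, 0)])
    def test_invalid_ratios_rejected(self, D, D1):
        with pytest.raises(ValueError):
            convolution_count(D, D1)


class TestConvolve:
    def test_identity_for_single_event(self, gamma_f1):
        assert convolve(gamma_f1, 1) is gamma_f1

    def test_delta_spectrum_shifts_to_v_z0(self):
        probs = np.zeros(8)
        probs[2] = 1.0  # z0 = 2.5 with unit bins
        f1 = BinnedDistribution(np.arange(9, dtype=float), probs)
        f3 = convolve(f1, 3)
        # all mass in the bin containing 3 * z0 = 7.5
        assert f3.probabilities[7] == pytest.approx(1.0)

    def test_delta_even_v_splits_edge_atom(self):
        probs = np.zeros(8)
        probs[2] = 1.0
        f1 = BinnedDistribution(np.arange(9, dtype=float), probs)
        f2 = convolve(f1, 2)
        # 2 * z0 = 5.0 is a bin edge; mass split between bins 4 and 5,
        # preserving the mean exactly
        np.testing.assert_allclose(f2.probabilities[4:6], [0.5, 0.5])
        assert summarize(f2).mean == pytest.approx(2 * summarize(f1).mean)

    @pytest.mark.parametrize("v", [2, 25, 100])
    def test_moment_additivity(self, gamma_f1, v):
        s1 = summarize(gamma_f1)
        sv = summarize(convolve(gamma_f1, v))
        assert sv.mean == pytest.approx(v * s1.mean, rel=5e-3)
        assert sv.std**2 == pytest.approx(v * s1.std**2, rel=5e-3)

    def test_matches_monte_carlo_sum_oracle(self, gamma_f1, rng):
        v, n = 10, 20_000
        fv = convolve(gamma_f1, v)
        idx = rng.choice(gamma_f1.n_bins, size=(n, v), p=gamma_f1.probabilities)
        sums = ((idx + rng.uniform(0, 1, size=(n, v))) * gamma_f1.bin_width).sum(axis=1)
        emp = build_distribution(
            sums, bin_width=gamma_f1.bin_width, range=(0.0, float(fv.bin_edges[-1]))
        )
        assert np.abs(emp.probabilities - fv.probabilities).max() < 0.02

    def test_binary_exponentiation_equals_sequential(self, gamma_f1):
        fast = convolve(gamma_f1, 7)
        slow = convolve(gamma_f1, 7, sequential=True)
        np.testing.assert_allclose(fast.probabilities, slow.probabilities, atol=1e-12)

    def test_dispersion_strictly_decreases_with_v(self, gamma_f1):
        disps = [summarize(convolve(gamma_f1, v)).dispersion for v in (1, 2, 5, 20, 60)]
        assert all(a > b for a, b in zip(disps, disps[1:]))

    def test_invalid_inputs_rejected(self, gamma_f1):
        with pytest.raises(ValueError):
            convolve(gamma_f1, 0)
        shifted = BinnedDistribution(np.array([1, 2, 3.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="start at 0"):
            convolve(shifted, 2)

    @settings(deadline=None, max_examples=25)
    @given(
        weights=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=12),
        v=st.integers(min_value=1, max_value=9),
    )
    def test_mass_conserved(self, weights, v):
        w = np.asarray(weights) + 1e-6
        f1 = BinnedDistribution(np.arange(len(w) + 1, dtype=float), w / w.sum())
        fv = convolve(f1, v)
        assert fv.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(fv.probabilities >= 0)


class TestRebin:
    def test_mass_and_mean_preserved(self, gamma_f1):
        fv = convolve(gamma_f1, 4)
        coarse = rebin(fv, n_bins=40)
        assert coarse.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert summarize(coarse).mean == pytest.approx(
            summarize(fv).mean, abs=coarse.bin_width
        )

    def test_truncating_range_rejected(self, gamma_f1):
        with pytest.raises(ValueError, match="cover"):
            rebin(gamma_f1, n_bins=10, range=(0.0, gamma_f1.bin_edges[-1] / 2))


class TestReplicateFrequencyErrors:
    def test_identical_replicates_have_zero_error(self):
        rep = np.array([0.5, 1.5, 1.5])
        dist = replicate_frequency_errors([rep, rep.copy()], n_bins=2, range=(0, 2))
        np.testing.assert_array_equal(dist.bin_errors, [0.0, 0.0])

    def test_two_point_sample_std(self):
        # per-bin probs {0.4, 0.6} and {0.6, 0.4}
        rep1 = np.array([0.5] * 2 + [1.5] * 3)
        rep2 = np.array([0.5] * 3 + [1.5] * 2)
        dist = replicate_frequency_errors([rep1, rep2], n_bins=2, range=(0, 2))
        np.testing.assert_allclose(dist.probabilities, [0.5, 0.5])
        np.testing.assert_allclose(dist.bin_errors, [0.14142136, 0.14142136], rtol=1e-6)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            replicate_frequency_errors([np.array([1.0, 2.0])], n_bins=2)

    def test_errors_shrink_with_cell_count(self, rng):
        def mean_err(n):
            reps = [rng.gamma(2.0, 1.0, n) for _ in range(6)]
            d = replicate_frequency_errors(reps, bin_width=0.5, range=(0, 25))
            return d.bin_errors.mean()

        ratio = mean_err(1_000) / mean_err(16_000)
        assert 2.0 < ratio < 8.0  # expected 4x for a 16x cell count


class TestCsvInterchange:
    def test_spectrum_round_trip(self, gamma_f1, tmp_path):
        path = tmp_path / "spec.csv"
        write_spectrum_csv(gamma_f1, path)
        assert path.read_text().startswith("# units=mGy")
        back = read_spectrum_csv(path)
        np.testing.assert_allclose(back.bin_edges, gamma_f1.bin_edges)
        np.testing.assert_allclose(back.probabilities, gamma_f1.probabilities)

    def test_spectrum_with_errors_round_trip(self, tmp_path):
        dist = BinnedDistribution(
            np.array([0, 1, 2.0]), np.array([0.25, 0.75]), bin_errors=np.array([0.01, 0.02])
        )
        path = tmp_path / "spec.csv"
        write_spectrum_csv(dist, path)
        back = read_spectrum_csv(path)
        np.testing.assert_allclose(back.bin_errors, dist.bin_errors)

    def test_cell_dose_round_trip(self, tmp_path):
        samples = [
            CellDoseSample(np.array([1.0, 2.0, 3.0]), macroscopic_dose=10.0, replicate_id=0),
            CellDoseSample(np.array([1.5, 2.5]), macroscopic_dose=10.0, replicate_id=1),
        ]
        path = tmp_path / "doses.csv"
        write_cell_dose_csv(samples, path)
        back = read_cell_dose_csv(path)
        assert len(back) == 2
        np.testing.assert_allclose(back[0].values, samples[0].values)
        assert back[1].replicate_id == 1
        assert back[0].macroscopic_dose == 10.0

    def test_mixed_dose_file_rejected(self, tmp_path):
        samples = [
            CellDoseSample(np.array([1.0]), macroscopic_dose=10.0),
            CellDoseSample(np.array([1.0]), macroscopic_dose=20.0),
        ]
        with pytest.raises(ValueError):
            write_cell_dose_csv(samples, tmp_path / "bad.csv")
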