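import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonerec.rqa import (
    DistanceMatrix,
    RecurrenceConfig,
    ami_first_minimum,
    embed,
    pairwise_distances,
    recurrence,
    select_radius,
)


def brute_force_percent(series, m, L, radius):
    """Independent O(N^2) oracle for percent recurrence."""
    x = np.asarray(series, dtype=float)
    n_epochs = len(x) - (m - 1) * L
    epochs = [x[i : i + (m - 1) * L + 1 : L] for i in range(n_epochs)]
    count = 0
    pairs = 0
    for i in range(n_epochs):
        for j in range(i + 1, n_epochs):
            pairs += 1
            if np.sqrt(np.sum((epochs[i] - epochs[j]) ** 2)) < radius:
                count += 1
    return 100.0 * count / pairs


class TestEmbed:
    def test_worked_example_shape(self, worked_series):
        emb = embed(worked_series, m=3, L=1)
        assert emb.n_epochs == 8
        np.testing.assert_array_equal(emb.rows[0], [7, 8, 10])
        np.testing.assert_array_equal(emb.rows[-1], [11, 10, 8])

    def test_m1_is_identity(self, worked_series):
        emb = embed(worked_series, m=1, L=1)
        np.testing.assert_array_equal(emb.rows[:, 0], worked_series)

    def test_too_short(self, worked_series):
        with pytest.raises(ValueError, match="13"):
            embed(worked_series, m=5, L=3)

    @given(
        n=st.integers(5, 60),
        m=st.integers(1, 4),
        L=st.integers(1, 3),
    )
    @settings(max_examples=40, deadline=None)
    def test_epoch_count_and_content(self, n, m, L, rng):
        if n < (m - 1) * L + 1:
            return
        x = rng.standard_normal(n)
        emb = embed(x, m, L)
        assert emb.n_epochs == n - (m - 1) * L
        i = emb.n_epochs // 2
        np.testing.assert_array_equal(emb.rows[i], [x[i + j * L] for j in range(m)])


class TestPairwiseDistances:
    def test_printed_anchor_values(self, worked_series, worked_distances):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        assert dm.values[4, 0] == pytest.approx(1.732051, abs=1e-5)
        assert dm.values[5, 0] == pytest.approx(1.41421, abs=1e-5)
        for (r, c), expected in worked_distances.items():
            assert dm.values[r - 1, c - 1] == pytest.approx(expected, abs=1e-5)

    def test_zero_diagonal_and_symmetry(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        np.testing.assert_array_equal(np.diag(dm.values), 0.0)
        np.testing.assert_array_equal(dm.values, dm.values.T)

    def test_needs_two_epochs(self):
        with pytest.raises(ValueError, match="2 epochs"):
            pairwise_distances(embed([1.0, 2.0, 3.0], m=3, L=1))


class TestSelectRadius:
    def test_gaussian_percentile_keeps_two_pairs(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        radius = select_radius(dm, "gaussian_percentile", 0.05)
        # any radius between the 2nd and 3rd smallest distances yields the
        # reference count of 2 recurrent pairs
        assert 1.732051 < radius < 3.0
        assert recurrence(dm, radius).recurrence_count == 2

    def test_absolute(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        assert select_radius(dm, "absolute", 1.5) == 1.5
        assert recurrence(dm, 1.5).recurrence_count == 1  # only 1.41421 < 1.5

    def test_empirical_percentile_zero(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        radius = select_radius(dm, "empirical_percentile", 0.0)
        assert radius == pytest.approx(dm.condensed().min())
        # strict inequality: nothing below the smallest distance
        assert recurrence(dm, radius).recurrence_count == 0

    def test_fraction_of_mean(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        assert select_radius(dm, "fraction_of_mean_distance", 0.1) == pytest.approx(
            0.1 * dm.condensed().mean()
        )

    def test_parameter_validation(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        with pytest.raises(ValueError):
            select_radius(dm, "gaussian_percentile", 1.5)
        with pytest.raises(ValueError):
            select_radius(dm, "empirical_percentile", -0.1)
        with pytest.raises(ValueError):
            select_radius(dm, "absolute", 0.0)
        with pytest.raises(ValueError, match="policy"):
            select_radius(dm, "nope", 0.1)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RecurrenceConfig(m=0)
        with pytest.raises(ValueError):
            RecurrenceConfig(radius_policy="nope")


class TestRecurrence:
    def test_worked_example_counts(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        for radius in (1.74, 2.0, 2.9):
            res = recurrence(dm, radius)
            assert res.pair_count == 28
            assert res.recurrence_count == 2
            assert res.recurrence_rate == pytest.approx(2 / 28)
            assert round(res.recurrence_rate, 3) == 0.071
            assert round(res.percent_recurrence, 1) == 7.1

    def test_plot_marks_the_two_pairs(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        plot = recurrence(dm, 2.0).recurrence_plot
        assert plot[0, 4] == plot[4, 0] == 1
        assert plot[0, 5] == plot[5, 0] == 1
        assert plot.sum() == 4
        np.testing.assert_array_equal(np.diag(plot), 0)

    def test_huge_radius_gives_100(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        res = recurrence(dm, dm.condensed().max() + 1)
        assert res.percent_recurrence == 100.0

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal(50)
        dm = pairwise_distances(embed(x, 3, 1))
        radius = select_radius(dm, "fraction_of_mean_distance", 0.1)
        res = recurrence(dm, radius)
        assert res.percent_recurrence == pytest.approx(
            brute_force_percent(x, 3, 1, radius)
        )

    def test_radius_must_be_positive(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        with pytest.raises(ValueError):
            recurrence(dm, 0.0)


class TestRecurrenceProperties:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 40))
        m = int(rng.integers(1, 4))
        x = rng.standard_normal(n)
        dm = pairwise_distances(embed(x, m, 1))
        radius = select_radius(dm, "fraction_of_mean_distance", 0.2)
        assert recurrence(dm, radius).percent_recurrence == pytest.approx(
            brute_force_percent(x, m, 1, radius)
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_radius(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(30)
        dm = pairwise_distances(embed(x, 2, 1))
        radii = np.linspace(0.01, dm.condensed().max() * 1.1, 20)
        percents = [recurrence(dm, r).percent_recurrence for r in radii]
        assert np.all(np.diff(percents) >= 0)

    def test_constant_series_full_recurrence(self):
        dm = pairwise_distances(embed(np.full(20, 3.5), 3, 2))
        np.testing.assert_array_equal(dm.values, 0.0)
        assert recurrence(dm, 1e-9).percent_recurrence == 100.0

    def test_periodic_signal_zero_distance_at_period(self):
        period = 8
        x = np.sin(2 * np.pi * np.arange(64) / period)
        dm = pairwise_distances(embed(x, 1, 1))
        idx = np.arange(0, 64 - period)
        np.testing.assert_allclose(dm.values[idx, idx + period], 0.0, atol=1e-12)


class TestAMI:
    def test_quarter_period_minimum(self):
        # noisy sinusoid, 20 samples/cycle: first MI minimum at the quarter
        # period (lag 5); mild dithering avoids the degenerate on-grid
        # histogram of a perfectly sampled sinusoid
        rng = np.random.default_rng(42)
        t = np.arange(2000)
        x = np.sin(2 * np.pi * t / 20) + 0.05 * rng.standard_normal(2000)
        res = ami_first_minimum(x, 10)
        assert not res.no_minimum
        assert res.lag == 5

    def test_clean_sinusoid_minimum_in_decorrelation_valley(self):
        # exactly on-grid sinusoid: MI valley is flat; the first minimum
        # still falls strictly inside the half-period
        t = np.arange(2000)
        res = ami_first_minimum(np.sin(2 * np.pi * t / 20), 10)
        assert 2 <= res.lag <= 8

    def test_white_noise_flagged_flat(self, rng):
        res = ami_first_minimum(rng.standard_normal(2000), 20)
        assert res.no_minimum
        assert res.lag == 20
        assert np.all(res.mi_values[1:] < 0.3)

    def test_short_series_warns(self, rng):
        with pytest.warns(UserWarning, match="unreliable"):
            ami_first_minimum(rng.standard_normal(100), 10)

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ami_first_minimum(np.ones(100), 10)

    def test_max_lag_bound(self, rng):
        with pytest.raises(ValueError, match="max_lag"):
            ami_first_minimum(rng.standard_normal(30), 20)


class TestDistanceMatrixType:
    def test_condensed_matches_square(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        cond = dm.condensed()
        assert len(cond) == 28
        assert sorted(cond) == sorted(
            dm.values[i, j] for i in range(8) for j in range(i + 1, 8)
        )

    def test_select_radius_accepts_raw_arrays(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        r1 = select_radius(dm, "fraction_of_mean_distance", 0.1)
        r2 = select_radius(dm.values, "fraction_of_mean_distance", 0.1)
        r3 = select_radius(dm.condensed(), "fraction_of_mean_distance", 0.1)
        assert r1 == r2 == r3

    def test_distance_matrix_metric_tag(self, worked_series):
        dm = pairwise_distances(embed(worked_series, 3, 1))
        assert dm.metric == "euclidean"
        assert isinstance(dm, DistanceMatrix)
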