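"""Base schedule generators: densities, quantile, Poisson gap, averaging, RU."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nusched import (
    SamplingSchedule,
    apply_uniform_prefix,
    averaged_schedule,
    density_exponential,
    density_sine_chord,
    density_uniform,
    poisson_gap_schedule,
    quantile_schedule,
    random_unweighted_schedule,
)


class TestDensities:
    def test_sine_chord_values(self):
        d = density_sine_chord(3, math.pi / 2, math.pi)
        np.testing.assert_allclose(d.values, [1.0, math.sin(3 * math.pi / 4), 0.0])

    def test_sine_chord_symmetric_middle_peak(self):
        d = density_sine_chord(5, math.pi / 6, 5 * math.pi / 6)
        expected = np.sin(np.linspace(math.pi / 6, 5 * math.pi / 6, 5))
        np.testing.assert_allclose(d.values, expected)
        assert d.values.argmax() == 2
        np.testing.assert_allclose(d.values, d.values[::-1])

    def test_invalid_chord_rejected(self):
        with pytest.raises(ValueError):
            density_sine_chord(8, math.pi, math.pi / 2)

    def test_exponential_values(self):
        d = density_exponential(4, 1.0)
        np.testing.assert_allclose(
            d.values, [1.0, math.exp(-1 / 3), math.exp(-2 / 3), math.exp(-1)]
        )

    def test_exponential_large_decay_near_uniform(self):
        d = density_exponential(4, 1e9)
        np.testing.assert_allclose(d.values, np.ones(4), rtol=1e-8)

    def test_exponential_invalid_decay(self):
        with pytest.raises(ValueError):
            density_exponential(4, 0.0)


class TestQuantile:
    def test_full_coverage(self):
        s = quantile_schedule(8, 8, density_uniform(8))
        assert s.indices.tolist() == list(range(8))

    def test_uniform_midpoint_rule(self):
        s = quantile_schedule(8, 4, density_uniform(8))
        assert s.indices.tolist() == [0, 2, 4, 6]

    def test_count_and_uniqueness(self):
        s = quantile_schedule(256, 52, density_uniform(256))
        assert s.sample_count == 52
        assert np.unique(s.indices).size == 52

    def test_zero_mass_density_rejected(self):
        from nusched import WeightingDensity

        zero = WeightingDensity("zero", np.zeros(8), {})
        with pytest.raises(ValueError):
            quantile_schedule(8, 2, zero)

    def test_oversubscription_rejected(self):
        with pytest.raises(ValueError):
            quantile_schedule(4, 5, density_uniform(4))

    def test_deterministic(self):
        a = quantile_schedule(128, 24)
        b = quantile_schedule(128, 24)
        assert a == b

    def test_guarantee_last_flag(self):
        s = quantile_schedule(64, 10, density_exponential(64, 0.2))
        assert s.mask[-1] == 0  # heavy early weighting misses the end
        forced = quantile_schedule(
            64, 10, density_exponential(64, 0.2), guarantee_last=True
        )
        assert forced.mask[-1] == 1
        assert forced.sample_count == 10

    def test_early_weighting_shifts_samples_earlier(self):
        # monotonicity: more early mass -> weakly earlier sample placement
        flat = quantile_schedule(64, 12, density_uniform(64)).indices
        early = quantile_schedule(64, 12, density_exponential(64, 0.3)).indices
        assert (early <= flat).all()


class TestPoissonGap:
    def test_counts_and_endpoints(self):
        s = poisson_gap_schedule(128, 32, seed=7)
        assert s.sample_count == 32
        assert s.mask[0] == 1 and s.mask[127] == 1

    def test_full_coverage_forces_zero_gaps(self):
        s = poisson_gap_schedule(16, 16, seed=123)
        assert s.indices.tolist() == list(range(16))

    def test_deterministic_for_fixed_seed(self):
        assert poisson_gap_schedule(128, 32, 7) == poisson_gap_schedule(128, 32, 7)

    def test_seed_variation(self):
        schedules = {
            tuple(poisson_gap_schedule(128, 32, s).indices) for s in range(8)
        }
        assert len(schedules) > 1

    @pytest.mark.parametrize("seed", range(250))
    def test_last_point_guaranteed(self, seed):
        assert poisson_gap_schedule(128, 32, seed).mask[-1] == 1

    def test_gaps_shorter_at_early_times(self):
        # the sinusoidal ramp makes early gaps short on average
        early, late = [], []
        for seed in range(50):
            idx = poisson_gap_schedule(256, 64, seed).indices
            gaps = np.diff(idx) - 1
            early.append(gaps[: len(gaps) // 4].mean())
            late.append(gaps[-len(gaps) // 4 :].mean())
        assert np.mean(early) < np.mean(late)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            poisson_gap_schedule(16, 1, seed=0)


class TestAveraged:
    def test_full_coverage(self):
        s = averaged_schedule(8, 8, density_uniform(8), replicates=3, seed=5)
        assert s.indices.tolist() == list(range(8))

    def test_single_replicate_is_one_draw(self):
        a = averaged_schedule(64, 16, density_uniform(64), replicates=1, seed=9)
        b = averaged_schedule(64, 16, density_uniform(64), replicates=1, seed=9)
        assert a == b
        assert a.sample_count == 16

    def test_converges_to_quantile_schedule(self):
        avg = averaged_schedule(64, 16, density_uniform(64), replicates=5000, seed=1)
        qs = quantile_schedule(64, 16, density_uniform(64))
        deviation = np.abs(avg.indices - qs.indices).mean()
        assert deviation < 1.0


class TestRandomUnweighted:
    def test_counts_with_backfill(self):
        s = random_unweighted_schedule(128, 26, seed=3, backfill=6)
        assert s.sample_count == 32
        assert np.unique(s.indices).size == 32

    def test_full_coverage(self):
        s = random_unweighted_schedule(8, 8, seed=0)
        assert s.indices.tolist() == list(range(8))

    def test_backfill_splits_largest_gap(self):
        # samples {0, 9}: the single interior gap 1..8 gets its floor midpoint
        base = random_unweighted_schedule(10, 2, seed=0)
        # find a seed realizing {0, 9}
        seed = next(
            s
            for s in range(500)
            if random_unweighted_schedule(10, 2, seed=s).indices.tolist() == [0, 9]
        )
        filled = random_unweighted_schedule(10, 2, seed=seed, backfill=1)
        assert filled.indices.tolist() == [0, 4, 9]

    def test_backfill_reduces_largest_gap(self):
        from nusched import gap_statistics

        for seed in range(20):
            plain = random_unweighted_schedule(128, 26, seed=seed)
            filled = random_unweighted_schedule(128, 26, seed=seed, backfill=6)
            assert gap_statistics(filled)[0] <= gap_statistics(plain)[0]

    def test_overfull_rejected(self):
        with pytest.raises(ValueError):
            random_unweighted_schedule(10, 8, seed=0, backfill=3)


class TestUniformPrefix:
    def test_zero_prefix_is_identity(self):
        s = quantile_schedule(32, 8)
        assert apply_uniform_prefix(s, 0) == s

    def test_prefix_forces_leading_indices(self):
        s = SamplingSchedule.from_indices([1, 3, 5, 7], 8)
        out = apply_uniform_prefix(s, 2)
        assert out.indices.tolist() == [0, 1, 3, 5]

    def test_full_schedule_unchanged(self):
        s = SamplingSchedule(np.ones(16, dtype=int))
        assert apply_uniform_prefix(s, 4) == s

    def test_sample_count_preserved(self):
        for seed in range(10):
            s = random_unweighted_schedule(64, 12, seed=seed)
            out = apply_uniform_prefix(s, 3)
            assert out.sample_count == 12
            assert out.mask[:3].tolist() == [1, 1, 1]

    def test_prefix_exceeding_samples_rejected(self):
        s = SamplingSchedule.from_indices([5], 8)
        with pytest.raises(ValueError):
            apply_uniform_prefix(s, 3)


@settings(max_examples=60, derandomize=True)
@given(
    N=st.integers(min_value=4, max_value=200),
    frac=st.floats(min_value=0.05, max_value=1.0),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_generators_return_requested_counts(N, frac, seed):
    n = max(2, int(frac * N))
    for sched in (
        quantile_schedule(N, n, density_uniform(N)),
        poisson_gap_schedule(N, n, seed),
        averaged_schedule(N, n, density_uniform(N), replicates=3, seed=seed),
        random_unweighted_schedule(N, n, seed),
    ):
        assert sched.sample_count == n
        idx = sched.indices
        assert (np.diff(idx) > 0).all()
        assert 0 <= idx[0] and idx[-1] < N
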