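import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spicpms import (
    IntensityDistribution,
    corrected_sample,
    modal_background,
    particle_count,
    run_correction,
    scale_background,
    subtract_distributions,
    tail_filter,
    transition_intensity,
)


def _dist(freqs, dwell=10.0):
    return IntensityDistribution(freqs, n=float(sum(freqs.values())), dwell_time=dwell)


def brute_force_particle_count(sample_freqs, bgd_freqs):
    """Independent re-derivation of the particle count: enumerate every
    intensity, form the per-intensity sample-minus-blank difference, and add
    the magnitudes on the negative side."""
    keys = sorted(set(sample_freqs) | set(bgd_freqs))
    total = 0.0
    for i in keys:
        d = sample_freqs.get(i, 0) - bgd_freqs.get(i, 0)
        if d < 0:
            total += -d
    return total


# strategy: paired histograms over intensities 0..5 with equal window totals
@st.composite
def equal_n_histograms(draw):
    n_bins = draw(st.integers(2, 6))
    sample = [draw(st.integers(0, 20)) for _ in range(n_bins)]
    total = sum(sample)
    if total == 0:
        sample[0] = 1
        total = 1
    # random composition of the same total for the blank
    cuts = sorted(
        draw(
            st.lists(
                st.integers(0, total), min_size=n_bins - 1, max_size=n_bins - 1
            )
        )
    )
    bgd = (
        [cuts[0]]
        + [cuts[k] - cuts[k - 1] for k in range(1, n_bins - 1)]
        + [total - cuts[-1]]
    )
    s = {i: f for i, f in enumerate(sample) if f}
    b = {i: f for i, f in enumerate(bgd) if f}
    return s, b


class TestSubtract:
    def test_worked_example(self, worked_sample, worked_blank):
        diff = subtract_distributions(worked_sample, worked_blank)
        assert diff.signed
        assert diff.frequencies == {0: -1.0, 1: -1.0, 2: 2.0}

    def test_identity(self, worked_sample):
        diff = subtract_distributions(worked_sample, worked_sample)
        assert all(f == 0 for f in diff.frequencies.values())

    def test_mismatched_n_rejected(self, worked_sample):
        other = _dist({0: 6, 1: 6})
        with pytest.raises(ValueError, match="window totals differ"):
            subtract_distributions(worked_sample, other)

    def test_mismatched_dwell_rejected(self, worked_sample):
        other = IntensityDistribution({0: 10}, n=10, dwell_time=4.0)
        with pytest.raises(ValueError, match="dwell times differ"):
            subtract_distributions(worked_sample, other)

    @given(equal_n_histograms())
    def test_antisymmetry(self, pair):
        s, b = pair
        ds = subtract_distributions(_dist(s), _dist(b)).frequencies
        db = subtract_distributions(_dist(b), _dist(s)).frequencies
        assert set(ds) == set(db)
        assert all(ds[i] == -db[i] for i in ds)

    @given(equal_n_histograms())
    def test_zero_sum(self, pair):
        s, b = pair
        diff = subtract_distributions(_dist(s), _dist(b))
        assert sum(diff.frequencies.values()) == pytest.approx(0.0, abs=1e-9)


class TestParticleCount:
    def test_worked_example(self, worked_sample, worked_blank):
        diff = subtract_distributions(worked_sample, worked_blank)
        assert particle_count(diff) == 2.0

    def test_no_particles(self, worked_sample):
        diff = subtract_distributions(worked_sample, worked_sample)
        assert particle_count(diff) == 0.0

    def test_negative_mass_equals_positive_mass_on_random_pairs(self):
        """On 100 seeded random equal-N histogram pairs the negative and
        positive sides of the difference balance exactly."""
        rng = np.random.default_rng(2022)
        for _ in range(100):
            n_bins = rng.integers(2, 12)
            sample = rng.integers(0, 30, n_bins)
            total = int(sample.sum()) or 1
            sample[0] += total - sample.sum() if sample.sum() == 0 else 0
            bgd = rng.multinomial(int(sample.sum()), np.ones(n_bins) / n_bins)
            s = _dist({i: int(f) for i, f in enumerate(sample) if f})
            b = _dist({i: int(f) for i, f in enumerate(bgd) if f})
            diff = subtract_distributions(s, b)
            neg = sum(-f for f in diff.frequencies.values() if f < 0)
            pos = sum(f for f in diff.frequencies.values() if f > 0)
            assert neg == pos == particle_count(diff)


class TestScaleBackground:
    def test_worked_example(self, worked_blank):
        scaled = scale_background(worked_blank, 8, 10)
        assert scaled.frequencies == {0: pytest.approx(4.8), 1: pytest.approx(3.2)}
        assert scaled.n == 8

    def test_identity_when_no_particles(self, worked_blank):
        scaled = scale_background(worked_blank, 10, 10)
        assert scaled.frequencies == worked_blank.frequencies

    def test_zero_limit(self, worked_blank):
        scaled = scale_background(worked_blank, 0, 10)
        assert all(f == 0 for f in scaled.frequencies.values())

    def test_excess_rejected(self, worked_blank):
        with pytest.raises(ValueError):
            scale_background(worked_blank, 11, 10)

    @given(equal_n_histograms(), st.integers(0, 100))
    def test_sum_identity(self, pair, n_np):
        _, b = pair
        dist = _dist(b)
        n_bgd = max(dist.n - n_np, 0.0)
        scaled = scale_background(dist, n_bgd, dist.n)
        assert sum(scaled.frequencies.values()) == pytest.approx(n_bgd, abs=1e-9)


class TestCorrectedSample:
    def test_worked_example(self, worked_sample, worked_blank):
        scaled = scale_background(worked_blank, 8, 10)
        diff = corrected_sample(worked_sample, scaled)
        assert diff.frequencies == {
            0: pytest.approx(0.2),
            1: pytest.approx(-0.2),
            2: pytest.approx(2.0),
        }

    def test_zero_background_returns_sample(self, worked_sample, worked_blank):
        scaled = scale_background(worked_blank, 0, 10)
        diff = corrected_sample(worked_sample, scaled)
        for i, f in worked_sample.frequencies.items():
            assert diff.freq(i) == f

    def test_residual_negative_mass_shrinks(self):
        """The particle-count rescaling reduces the spurious negative range
        of the raw difference on simulated polydisperse pairs."""
        from spicpms import build_distribution, preset, simulate_pair

        for seed in (0, 1, 2):
            cfg = preset("polydisperse", seed=seed)
            sample, blank, _ = simulate_pair(cfg)
            s, b = build_distribution(sample), build_distribution(blank)
            raw = subtract_distributions(s, b)
            n_np = particle_count(raw)
            scaled = scale_background(b, s.n - n_np, s.n)
            corr = corrected_sample(s, scaled)
            raw_neg = sum(-f for f in raw.frequencies.values() if f < 0)
            corr_neg = sum(-f for f in corr.frequencies.values() if f < 0)
            assert corr_neg <= raw_neg


class TestTransitionIntensity:
    def test_worked_example(self, worked_sample, worked_blank):
        scaled = scale_background(worked_blank, 8, 10)
        assert transition_intensity(corrected_sample(worked_sample, scaled)) == 1

    def test_all_positive(self):
        diff = IntensityDistribution({2: 3.0}, n=0, dwell_time=10.0, signed=True)
        assert transition_intensity(diff) == -1

    def test_last_crossing_governs(self):
        diff = IntensityDistribution(
            {3: -1.0, 5: 2.0, 7: -0.5, 9: 4.0}, n=0, dwell_time=10.0, signed=True
        )
        assert transition_intensity(diff) == 7


class TestModalBackground:
    def test_argmax(self):
        dist = _dist({38: 10, 40: 55, 42: 12})
        assert modal_background(dist) == 40

    def test_tie_break(self):
        assert modal_background(_dist({1: 5, 2: 5})) == 1

    def test_poisson_mode_near_lambda(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(40.0, 50_000)
        vals, freq = np.unique(counts, return_counts=True)
        dist = _dist({int(v): int(f) for v, f in zip(vals, freq)})
        assert abs(modal_background(dist) - 40) <= 2


class TestRunCorrection:
    def test_blank_against_itself(self, worked_blank):
        res = run_correction(worked_blank, worked_blank)
        assert res.n_particles == 0
        assert res.net_intensities.size == 0
        assert res.n_background == worked_blank.n

    def test_worked_example_chain(self, worked_sample, worked_blank):
        res = run_correction(worked_sample, worked_blank)
        assert res.n_particles == 2
        assert res.n_background == 8
        assert res.transition_intensity == 1
        assert res.modal_background == 0
        assert list(res.net_intensities) == [2, 2]

    def test_conservation(self, worked_sample, worked_blank):
        res = run_correction(worked_sample, worked_blank)
        assert res.n_particles + res.n_background == worked_sample.n

    @given(equal_n_histograms())
    def test_matches_brute_force_oracle(self, pair):
        s, b = pair
        res = run_correction(_dist(s), _dist(b))
        assert res.n_particles == brute_force_particle_count(s, b)
        assert res.n_particles + res.n_background == sum(s.values())

    def test_simulated_count_recovery(self):
        """~500 injected high-intensity particles are recovered within
        Poisson sampling error."""
        from spicpms import build_distribution, preset, simulate_pair

        cfg = preset("polydisperse", seed=123)
        sample, blank, truth = simulate_pair(cfg)
        res = run_correction(build_distribution(sample), build_distribution(blank))
        assert abs(res.n_particles - truth.n_particles) <= 3 * np.sqrt(
            truth.n_particles
        )


class TestTailFilter:
    def test_tail_rule(self):
        assert tail_filter({100: 50, 150: 12, 200: 3}) == {100: 50, 150: 12}

    def test_zero_min_keeps_all(self):
        bins = {100: 3, 150: 50}
        assert tail_filter(bins, 0.0) == bins

    def test_interior_bins_protected(self):
        bins = {100: 3, 150: 50}
        assert tail_filter(bins, 10.0) == bins

    def test_successive_tail_bins_removed(self):
        assert tail_filter({1: 20, 2: 5, 3: 4}, 10.0) == {1: 20}
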