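import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ecmquant.distributions import (
    BIN_ANGLES,
    OrientationDistribution,
    average_distributions,
    circular_mean_orientation,
    compare_distributions,
    normalize_distribution,
    orientation_index,
    read_histogram_csv,
    total_variation,
    write_histogram_csv,
)


def _dist(freq, **kw):
    freq = np.asarray(freq, dtype=float)
    return OrientationDistribution(freq / freq.sum(), **kw)


def _delta(angle_deg, **kw):
    f = np.zeros(180)
    f[int(angle_deg) + 90] = 1.0
    return OrientationDistribution(f, **kw)


def _random_dist(seed):
    rng = np.random.default_rng(seed)
    return _dist(rng.random(180) ** 3 + 1e-9)


class TestCircularMean:
    def test_delta_at_30(self):
        m = circular_mean_orientation(_delta(30))
        assert m.degrees == pytest.approx(30.0, abs=1e-9)
        assert not m.degenerate

    def test_equal_mass_at_plus_minus_80_gives_minus_90(self):
        # hand evaluation of the doubling formula: doubled angles -160 and
        # +160 average to 180, halved to 90, canonically -90
        f = np.zeros(180)
        f[-80 + 90] = 0.5
        f[80 + 90] = 0.5
        m = circular_mean_orientation(OrientationDistribution(f))
        assert m.degrees == pytest.approx(-90.0, abs=1e-9)

    def test_uniform_is_degenerate(self):
        m = circular_mean_orientation(_dist(np.ones(180)))
        assert m.degenerate
        assert m.degrees == 0.0
        assert m.resultant_length < 1e-6

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            circular_mean_orientation(
                OrientationDistribution(np.zeros(180), normalized=False)
            )


class TestNormalize:
    def test_zero_mean_distribution_unchanged(self):
        f = np.zeros(180)
        f[90 - 10] = 0.5
        f[90 + 10] = 0.5  # symmetric about 0
        dist = OrientationDistribution(f)
        out = normalize_distribution(dist)
        assert np.allclose(out.frequencies, f)
        assert out.relative_to_mean

    def test_single_bin_moves_to_center(self):
        out = normalize_distribution(_delta(85))
        assert out.frequencies[90] == 1.0
        assert out.mean_orientation == pytest.approx(85.0)

    def test_wrap_rule_via_explicit_reindexing_oracle(self):
        # heavy mass at -40 with a satellite at +85; the satellite must land
        # at (85 - shift) wrapped into [-90, 90) by +/-180
        f = np.zeros(180)
        f[-40 + 90] = 0.9
        f[85 + 90] = 0.1
        dist = OrientationDistribution(f)
        shift = int(np.floor(circular_mean_orientation(dist).degrees + 0.5))
        out = normalize_distribution(dist)

        expected = np.zeros(180)
        for i, freq in enumerate(f):  # independent per-bin reindexing
            alpha = (i - 90) - shift
            while alpha < -90:
                alpha += 180
            while alpha >= 90:
                alpha -= 180
            expected[alpha + 90] += freq
        assert np.allclose(out.frequencies, expected)
        satellite = (85 - shift + 90) % 180 - 90
        assert out.frequencies[satellite + 90] == pytest.approx(0.1)

    def test_mass_conserved_and_mean_centred(self):
        for seed in range(20):
            out = normalize_distribution(_random_dist(seed))
            assert np.isclose(out.frequencies.sum(), 1.0)
            m = circular_mean_orientation(out)
            if not m.degenerate:
                assert abs(m.degrees) <= 0.5

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent(self, seed):
        once = normalize_distribution(_random_dist(seed))
        twice = normalize_distribution(once)
        assert np.allclose(once.frequencies, twice.frequencies)

    def test_isotropic_input_warns_and_passes_through(self):
        uniform = _dist(np.ones(180))
        with pytest.warns(UserWarning, match="isotropic"):
            out = normalize_distribution(uniform)
        assert out.degenerate_mean
        assert np.allclose(out.frequencies, uniform.frequencies)


class TestAverage:
    def test_identical_replicates_average_to_themselves(self):
        d = normalize_distribution(_random_dist(1))
        out = average_distributions([d] * 5)
        assert np.allclose(out.frequencies, d.frequencies)

    def test_fourteen_replicates_match_brute_force_oracle(self):
        # fourteen replicate histograms, the biological replicate structure
        dists = [normalize_distribution(_random_dist(s)) for s in range(14)]
        out = average_distributions(dists)
        expected = sum(d.frequencies for d in dists) / 14.0
        assert np.allclose(out.frequencies, expected)
        assert np.isclose(out.frequencies.sum(), 1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_distributions([])

    def test_raw_distribution_rejected(self):
        raw = _random_dist(0)  # not mean-centred
        with pytest.raises(ValueError):
            average_distributions([raw])


class TestOrientationIndex:
    def test_uniform_is_zero(self):
        u = OrientationDistribution(np.full(180, 1 / 180), relative_to_mean=True)
        assert abs(orientation_index(u)) < 1e-12

    def test_delta_at_zero_is_one(self):
        assert orientation_index(_delta(0, relative_to_mean=True)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_equal_mass_at_plus_minus_45_is_zero(self):
        f = np.zeros(180)
        f[90 - 45] = 0.5
        f[90 + 45] = 0.5
        d = OrientationDistribution(f, relative_to_mean=True)
        assert orientation_index(d) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_in_minus_one_one(self):
        for seed in range(10):
            s = orientation_index(normalize_distribution(_random_dist(seed)))
            assert -1.0 <= s <= 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(-179, 179))
    def test_invariant_under_raw_histogram_rotation(self, seed, shift):
        # normalize-then-OI commutes with circular shifts of the raw bins
        raw = _random_dist(seed)
        rotated = OrientationDistribution(np.roll(raw.frequencies, shift))
        s1 = orientation_index(normalize_distribution(raw))
        s2 = orientation_index(normalize_distribution(rotated))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_non_centred_input_rejected(self):
        with pytest.raises(ValueError):
            orientation_index(_random_dist(0))


def _mannwhitney_oracle(x, y):
    """Brute-force U (pairwise comparisons) + tie-corrected normal p."""
    x = np.asarray(x)[:, None]
    y = np.asarray(y)[None, :]
    u = float(np.sum(x > y) + 0.5 * np.sum(x == y))
    n1, n2 = x.shape[0], y.shape[1]
    n = n1 + n2
    pooled = np.concatenate([x.ravel()[:n1], y.ravel()[:n2]])
    _, counts = np.unique(np.concatenate([np.squeeze(x, 1), np.squeeze(y, 0)]), return_counts=True)
    tie = np.sum(counts.astype(float) ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    z = (u - n1 * n2 / 2.0) / math.sqrt(var)
    return u, 2.0 * sps.norm.sf(abs(z))


class TestCompare:
    def test_identical_distributions(self):
        d = normalize_distribution(_random_dist(4))
        res = compare_distributions(d, d)
        assert res.U == 180 * 180 / 2
        assert res.p_value > 0.9

    def test_uniform_vs_peaked_rejects_and_matches_oracle(self):
        uniform = OrientationDistribution(np.full(180, 1 / 180), relative_to_mean=True)
        f = np.full(180, 0.1 / 169)
        f[90 - 5 : 90 + 6] = 0.9 / 11  # 90% of mass within +/-5 degrees
        peaked = OrientationDistribution(f / f.sum(), relative_to_mean=True)

        res = compare_distributions(uniform, peaked)
        assert res.p_value < 0.05
        u, p = _mannwhitney_oracle(uniform.frequencies, peaked.frequencies)
        assert res.U == pytest.approx(u, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=2e-3)  # continuity corr.

    def test_rank_test_ignores_bin_order(self):
        a = OrientationDistribution(np.full(180, 1 / 180), relative_to_mean=True)
        b = normalize_distribution(_random_dist(6))
        permuted = OrientationDistribution(
            np.roll(b.frequencies, 61), normalized=True, relative_to_mean=True
        )
        assert compare_distributions(a, b).U == compare_distributions(a, permuted).U

    def test_angles_mode(self):
        with pytest.warns(UserWarning, match="isotropic"):
            a = normalize_distribution(
                OrientationDistribution(
                    np.full(180, 1 / 180), total_count=1800
                )
            )
        f = np.zeros(180)
        f[90] = 0.8
        f[70] = 0.2
        b = OrientationDistribution(f, total_count=1000, relative_to_mean=True)
        res = compare_distributions(a, b, mode="angles")
        assert res.mode == "angles"
        assert res.n1 == 1800 and res.n2 == 1000
        assert 0.0 <= res.p_value <= 1.0

    def test_angles_mode_requires_counts(self):
        d = normalize_distribution(_random_dist(7))
        with pytest.raises(ValueError):
            compare_distributions(d, d, mode="angles")

    def test_unknown_mode_rejected(self):
        d = normalize_distribution(_random_dist(7))
        with pytest.raises(ValueError):
            compare_distributions(d, d, mode="medians")


class TestCsvRoundtrip:
    def test_roundtrip(self, tmp_path):
        d = normalize_distribution(_random_dist(9))
        path = tmp_path / "hist.csv"
        write_histogram_csv(d, path)
        back = read_histogram_csv(path, relative_to_mean=True)
        assert np.allclose(back.frequencies, d.frequencies, atol=1e-12)
        assert back.normalized
        assert total_variation(back, d) < 1e-9

    def test_malformed_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("angle_deg,frequency\n0,1.0\n")
        with pytest.raises(ValueError):
            read_histogram_csv(path)
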