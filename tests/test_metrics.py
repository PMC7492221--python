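import numpy as np
import pytest

from rhythm_mtl import metrics as rm
from rhythm_mtl.hourly import HourlySeries


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_sampen(x, m, r):
    """O(n^2) literal template counting (Chebyshev, self-matches
    excluded, both lengths counted over the first n-m start positions)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_t = n - m

    def count(k):
        total = 0
        for i in range(n_t):
            for j in range(i + 1, n_t):
                d = max(abs(x[i + q] - x[j + q]) for q in range(k))
                if d <= r:
                    total += 1
        return total

    u_m, u_m1 = count(m), count(m + 1)
    if u_m == 0 or u_m1 == 0:
        return float("nan")
    return -np.log(u_m1 / u_m)


def brute_force_m10_l5(profile):
    ext = list(profile) + list(profile)
    m10 = max(np.mean(ext[s : s + 10]) for s in range(24))
    l5 = min(np.mean(ext[s : s + 5]) for s in range(24))
    return m10, l5


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

class TestSampleEntropy:
    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(10, 61))
            x = rng.normal(size=n)
            r = 0.25 * x.std()
            ours = rm.sample_entropy(x, m=2, r=r)
            oracle = brute_force_sampen(x, 2, r)
            if np.isnan(oracle):
                assert np.isnan(ours)
            else:
                assert abs(ours - oracle) < 1e-10

    def test_periodic_series_brute_force(self):
        x = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1], dtype=float)
        ours = rm.sample_entropy(x, m=2, r=0.2)
        oracle = brute_force_sampen(x, 2, 0.2)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_constant_series_is_zero(self):
        assert rm.sample_entropy(np.full(20, 3.0), m=2, r=0.1) == 0.0

    def test_too_short_returns_nan(self):
        assert np.isnan(rm.sample_entropy(np.arange(3.0), m=2, r=0.1))

    def test_degenerate_counts_return_nan(self):
        # strictly increasing with big steps: no matches at either length
        assert np.isnan(rm.sample_entropy(np.arange(0, 100, 10.0), m=2, r=0.5))

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            rm.sample_entropy(np.arange(10.0), m=0, r=0.1)
        with pytest.raises(ValueError):
            rm.sample_entropy(np.arange(10.0), m=2, r=-1)


class TestCoarseGrain:
    def test_identity_at_scale_one(self):
        x = np.random.default_rng(1).normal(size=17)
        np.testing.assert_array_equal(rm.coarse_grain(x, 1), x)

    def test_pairs(self):
        np.testing.assert_allclose(
            rm.coarse_grain(np.array([1.0, 2, 3, 4, 5, 6]), 2), [1.5, 3.5, 5.5]
        )

    def test_partial_block_dropped(self):
        np.testing.assert_allclose(
            rm.coarse_grain(np.array([1.0, 2, 3, 4, 5, 6, 7]), 3), [2.0, 5.0]
        )

    def test_rejects_bad_scale(self):
        with pytest.raises(ValueError):
            rm.coarse_grain(np.arange(5.0), 0)


class TestMultiscaleEntropy:
    def test_scale_one_equals_sample_entropy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=120)
        series = HourlySeries(start="2023-01-01", values=x)
        mse = rm.multiscale_entropy(series)
        direct = rm.sample_entropy(x, m=2, r=0.25 * x.std())
        assert mse[0] == pytest.approx(direct, abs=1e-12)

    def test_constant_series_all_missing(self):
        series = HourlySeries(start="2023-01-01", values=np.full(100, 2.0))
        assert np.isnan(rm.multiscale_entropy(series)).all()

    def test_white_noise_trend_non_increasing(self):
        # coarse-graining averages out white noise: entropy falls with scale
        rng = np.random.default_rng(3)
        firsts, lasts = [], []
        for _ in range(100):
            x = rng.normal(size=240)
            mse = rm.multiscale_entropy(HourlySeries(start="2023-01-01", values=x))
            if not (np.isnan(mse[0]) or np.isnan(mse[5])):
                firsts.append(mse[0])
                lasts.append(mse[5])
        assert np.mean(firsts) > np.mean(lasts)


# ---------------------------------------------------------------------------
# periodogram band power
# ---------------------------------------------------------------------------

class TestPsd:
    def test_parseval(self):
        rng = np.random.default_rng(4)
        for n in (48, 100, 336):
            x = rng.normal(size=n)
            freqs, power = rm.psd_periodogram(x)
            from scipy.signal import detrend

            xd = detrend(x, type="linear")
            assert power.sum() == pytest.approx(xd.var(), abs=1e-8)

    def test_constant_series_zero_power(self):
        series = HourlySeries(start="2023-01-01", values=np.full(96, 5.0))
        band = rm.psd_band_power(series)
        finite = [v for v in band.values() if not np.isnan(v)]
        assert finite and all(abs(v) < 1e-20 for v in finite)

    def test_pure_circadian_cosine_concentrates_power(self):
        t = np.arange(336)
        x = np.cos(2 * np.pi * t / 24)
        series = HourlySeries(start="2023-01-01", values=x)
        band = rm.psd_band_power(series)
        total = np.nansum(list(band.values()))
        circadian = sum(band[p] for p in (22.0, 27.0, 28.0))
        assert circadian / total >= 0.95

    def test_amplitude_ratio_of_two_cosines(self):
        t = np.arange(336)
        a, b = 3.0, 1.5
        x = a * np.cos(2 * np.pi * t / 24) + b * np.cos(2 * np.pi * t / 8)
        series = HourlySeries(start="2023-01-01", values=x)
        band = rm.psd_band_power(series)
        ratio = band[22.0] / band[8.0]  # 24 h lands in the 22 h band
        # linear detrending leaks a little power between bins
        assert ratio == pytest.approx(a**2 / b**2, rel=1e-3)

    def test_too_long_periods_missing(self):
        series = HourlySeries(start="2023-01-01", values=np.random.default_rng(5).normal(size=48))
        band = rm.psd_band_power(series)
        assert np.isnan(band[512.0]) and np.isnan(band[64.0])
        assert not np.isnan(band[24.0]) if 24.0 in band else True

    def test_all_masked_missing(self):
        series = HourlySeries(
            start="2023-01-01", values=np.zeros(48), mask=np.zeros(48, dtype=bool)
        )
        assert all(np.isnan(v) for v in rm.psd_band_power(series).values())


# ---------------------------------------------------------------------------
# M10 / L5 / relative amplitude
# ---------------------------------------------------------------------------

class TestM10L5:
    def _series_from_profile(self, profile, days=3):
        values = np.tile(profile, days)
        return HourlySeries(start="2023-01-01", values=values)

    def test_daytime_block(self):
        profile = np.zeros(24)
        profile[8:18] = 1.0
        m10, l5 = rm.m10_l5(self._series_from_profile(profile))
        assert m10 == 1.0 and l5 == 0.0

    def test_constant(self):
        m10, l5 = rm.m10_l5(self._series_from_profile(np.full(24, 2.5)))
        assert m10 == 2.5 and l5 == 2.5

    def test_matches_exhaustive_start_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            profile = rng.uniform(0, 10, 24)
            m10, l5 = rm.m10_l5(self._series_from_profile(profile))
            om10, ol5 = brute_force_m10_l5(profile)
            assert m10 == pytest.approx(om10, abs=1e-12)
            assert l5 == pytest.approx(ol5, abs=1e-12)

    def test_missing_hour_bin_gives_nan(self):
        values = np.ones(48)
        mask = np.ones(48, dtype=bool)
        mask[5] = mask[29] = False  # hour 5 never observed
        series = HourlySeries(start="2023-01-01", values=values, mask=mask)
        m10, l5 = rm.m10_l5(series)
        assert np.isnan(m10) and np.isnan(l5)


class TestRelativeAmplitude:
    @pytest.mark.parametrize(
        "m10,l5,expected", [(1.0, 0.0, 1.0), (2.0, 2.0, 0.0), (3.0, 1.0, 0.5)]
    )
    def test_values(self, m10, l5, expected):
        assert rm.relative_amplitude(m10, l5) == pytest.approx(expected)

    def test_zero_denominator_missing(self):
        assert np.isnan(rm.relative_amplitude(0.0, 0.0))

    def test_range_property(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            l5 = rng.uniform(0, 5)
            m10 = l5 + rng.uniform(0, 5)
            ra = rm.relative_amplitude(m10, l5)
            assert 0.0 <= ra <= 1.0


# ---------------------------------------------------------------------------
# template deviation
# ---------------------------------------------------------------------------

class TestTemplateDeviation:
    def test_identical_days_all_zero(self):
        profile = np.random.default_rng(8).uniform(0, 5, 24)
        series = HourlySeries(start="2023-01-01", values=np.tile(profile, 4))
        np.testing.assert_allclose(rm.template_deviation(series), np.zeros(6))

    def test_perturbed_hour_matches_hand_computation(self):
        profile = np.ones(24)
        values = np.tile(profile, 3).astype(float)
        values[2 * 24 + 5] += 3.0  # last day, hour 5, bumped by 3
        series = HourlySeries(start="2023-01-01", values=values)
        # template: hour 5 mean = 1 + 3/3 = 2, others 1
        # day deviation: days 0,1 differ only at hour 5 by 1 -> 1/24
        # day 2 differs at hour 5 by |4-2| = 2 -> 2/24
        dev = rm.template_deviation(series)
        per_day = np.array([1 / 24, 1 / 24, 2 / 24])
        assert dev[0] == pytest.approx(per_day.mean())
        assert dev[1] == pytest.approx(np.median(per_day))
        assert dev[2] == pytest.approx(per_day.std())
        assert dev[3] == dev[4] == dev[5] == pytest.approx(2 / 24)

    def test_last_day_equal_to_template(self):
        # symmetric perturbation on days 0 and 1 leaves day 2 on template
        values = np.tile(np.ones(24), 3)
        values[5] += 1.0
        values[24 + 5] -= 1.0
        series = HourlySeries(start="2023-01-01", values=values)
        dev = rm.template_deviation(series)
        assert dev[3] == pytest.approx(0.0)

    def test_under_two_days_missing(self):
        series = HourlySeries(start="2023-01-01", values=np.ones(30))
        assert np.isnan(rm.template_deviation(series)).all()


# ---------------------------------------------------------------------------
# IS / IV
# ---------------------------------------------------------------------------

class TestInterdayStability:
    def test_periodic_days_give_one(self):
        profile = np.random.default_rng(9).uniform(0, 5, 24)
        series = HourlySeries(start="2023-01-01", values=np.tile(profile, 7))
        assert rm.interday_stability(series) == pytest.approx(1.0, abs=1e-12)

    def test_iid_noise_expectation(self):
        rng = np.random.default_rng(10)
        vals = []
        for _ in range(200):
            x = rng.normal(size=14 * 24)
            vals.append(rm.interday_stability(HourlySeries(start="2023-01-01", values=x)))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1 / 14) < 3 * se

    def test_constant_missing(self):
        series = HourlySeries(start="2023-01-01", values=np.full(96, 1.0))
        assert np.isnan(rm.interday_stability(series))


class TestIntradayVariability:
    def test_alternating_sequence_exactly_four(self):
        x = np.resize([1.0, -1.0], 96)
        assert rm.intraday_variability(
            HourlySeries(start="2023-01-01", values=x)
        ) == pytest.approx(4.0, abs=1e-12)

    def test_gaussian_noise_near_two(self):
        rng = np.random.default_rng(11)
        vals = [
            rm.intraday_variability(
                HourlySeries(start="2023-01-01", values=rng.normal(size=240))
            )
            for _ in range(200)
        ]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.05)

    def test_slow_sinusoid_small(self):
        t = np.arange(240)
        x = np.cos(2 * np.pi * t / 24)
        assert rm.intraday_variability(HourlySeries(start="2023-01-01", values=x)) < 0.1

    def test_constant_missing(self):
        series = HourlySeries(start="2023-01-01", values=np.full(96, 2.0))
        assert np.isnan(rm.intraday_variability(series))
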