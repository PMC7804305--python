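import numpy as np
import pytest

from tempomics import StudyConfig
from tempomics.preprocess import TimeSeriesSet, unit_normalize
from tempomics.simulate import SimDesign, simulate_archetype, simulate_null
from tempomics.spectral import (
    AutocorrelationVector,
    NullCutoffs,
    SpectralError,
    _autocorrelations_batch,
    autocorrelation_vector,
    autocorrelations,
    bootstrap_cutoffs,
    classify_dataset,
    classify_series,
    lomb_scargle_periodogram,
)


def classical_periodogram(x):
    """Independent oracle: |DFT|^2 / N of the mean-centered series."""
    x = np.asarray(x, dtype=float)
    n_times = x.size
    xc = x - x.mean()
    f = np.fft.rfft(xc)
    return (np.abs(f) ** 2 / n_times)[1 : n_times // 2 + 1]


def circular_autocorrelation(x):
    """Independent oracle: direct circular autocorrelation of the data."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    n = x.size // 2
    c = np.array([np.sum(xc * np.roll(xc, -l)) for l in range(n + 1)])
    return c / c[0]


class TestLombScargle:
    @pytest.mark.parametrize("n_times", [10, 13, 23, 24, 34])
    def test_matches_classical_periodogram_even_sampling(self, rng, n_times):
        t = np.arange(n_times, dtype=float)
        x = rng.normal(size=n_times)
        power, _ = lomb_scargle_periodogram(x, t)
        oracle = classical_periodogram(x)
        np.testing.assert_allclose(power, oracle, rtol=1e-8, atol=1e-12)

    def test_pure_cosine_peaks_at_its_frequency(self):
        t = np.arange(24.0)
        x = np.cos(2 * np.pi * 2 * t / 24)
        power, freqs = lomb_scargle_periodogram(x, t)
        assert np.argmax(power) == 1  # k = 2 is the second grid frequency
        assert freqs[1] == pytest.approx(2 / 24)

    def test_too_few_points_errors(self):
        with pytest.raises(SpectralError, match=">= 4"):
            lomb_scargle_periodogram(np.array([1.0, 2, 3]), np.arange(3.0))

    def test_missing_points_omitted(self, rng):
        t = np.arange(24.0)
        x = rng.normal(size=24)
        x[[2, 9, 15]] = np.nan
        power, _ = lomb_scargle_periodogram(x, t)
        assert np.all(power >= 0) and np.all(np.isfinite(power))

    def test_uneven_sampling_runs(self, rng):
        t = np.sort(rng.uniform(0, 24, 16))
        x = rng.normal(size=16)
        power, _ = lomb_scargle_periodogram(x, t)
        assert np.all(power >= 0)


class TestAutocorrelations:
    def test_rho0_is_one(self, rng):
        acv = autocorrelation_vector(rng.normal(size=24), np.arange(24.0))
        assert acv.rho[0] == pytest.approx(1.0, abs=1e-9)

    def test_alternating_series_rho1_near_minus_one(self):
        x = (-1.0) ** np.arange(24) + 5.0
        acv = autocorrelation_vector(x, np.arange(24.0))
        assert abs(acv.rho[1] - (-1.0)) < 0.05

    @pytest.mark.parametrize("n_times", [8, 15, 24])
    def test_matches_circular_autocorrelation(self, rng, n_times):
        x = rng.normal(size=n_times)
        acv = autocorrelation_vector(x, np.arange(n_times, dtype=float))
        oracle = circular_autocorrelation(x)
        np.testing.assert_allclose(acv.rho, oracle, atol=1e-6)

    def test_rho_bounded(self, rng):
        for _ in range(20):
            x = rng.normal(size=24)
            x[rng.integers(0, 24, 4)] = np.nan
            if np.isnan(x).sum() > 6:
                continue
            acv = autocorrelation_vector(x, np.arange(24.0))
            assert np.all(np.abs(acv.rho) <= 1 + 1e-6)

    def test_batch_equals_per_series(self, rng):
        x = rng.normal(size=(50, 24))
        rho_batch, _ = _autocorrelations_batch(x)
        for i in range(50):
            acv = autocorrelation_vector(x[i], np.arange(24.0))
            np.testing.assert_allclose(rho_batch[i], acv.rho, atol=1e-9)

    def test_wrong_power_length_errors(self):
        with pytest.raises(SpectralError):
            autocorrelations(np.ones(5), 24)


class TestBootstrapCutoffs:
    def test_deterministic_given_seed(self, rng):
        pool = rng.normal(size=5000)
        a = bootstrap_cutoffs(pool, 24, n_boot=2000, seed=3)
        b = bootstrap_cutoffs(pool, 24, n_boot=2000, seed=3)
        np.testing.assert_array_equal(a.rho_c, b.rho_c)
        assert a.max_c == b.max_c and a.min_c == b.min_c

    def test_median_at_half(self, rng):
        pool = rng.normal(size=5000)
        mid = bootstrap_cutoffs(pool, 24, n_boot=5000, p=0.5, seed=4)
        strict = bootstrap_cutoffs(pool, 24, n_boot=5000, p=0.01, seed=4)
        # p = 0.5 gives the null median: near zero and far below the 99th pct
        assert np.all(mid.rho_c < strict.rho_c)
        assert abs(mid.rho_c[0]) < 0.1

    def test_pool_smaller_than_series_errors(self):
        with pytest.raises(SpectralError, match="pool"):
            bootstrap_cutoffs(np.ones(10) + np.arange(10), 24, n_boot=1000)

    def test_nboot_floor(self, rng):
        with pytest.raises(SpectralError):
            bootstrap_cutoffs(rng.normal(size=100), 10, n_boot=10)

    def test_invariant_max_above_min(self, rng):
        cut = bootstrap_cutoffs(rng.normal(size=2000), 24, n_boot=2000, seed=5)
        assert cut.max_c > cut.min_c

    def test_json_roundtrip(self, rng, tmp_path):
        cut = bootstrap_cutoffs(rng.normal(size=2000), 24, n_boot=1000, seed=5)
        p = tmp_path / "cut.json"
        cut.to_json(p)
        back = NullCutoffs.from_json(p)
        np.testing.assert_array_equal(back.rho_c, cut.rho_c)
        assert back.n_boot == cut.n_boot and back.seed == cut.seed


def _cutoffs(rho_c, max_c=0.9, min_c=-0.9, n_times=24):
    return NullCutoffs(
        n_times=n_times,
        rho_c=np.asarray(rho_c, dtype=float),
        max_c=max_c,
        min_c=min_c,
        n_boot=1000,
        p=0.01,
        seed=0,
        pool_size=1000,
    )


def _acv(rho, n_times=24):
    return AutocorrelationVector(
        rho=np.asarray(rho, dtype=float), periodogram=np.empty(0), n_times=n_times
    )


class TestClassifySeries:
    def test_lowest_lag_wins(self):
        rho = np.zeros(13)
        rho[0] = 1.0
        rho[1] = 0.6  # above cutoff
        rho[3] = 0.7  # also above
        label, lag = classify_series(_acv(rho), np.zeros(24), _cutoffs(np.full(12, 0.5)))
        assert label == "Lag 1" and lag == 1

    def test_spikemax_before_spikemin(self):
        rho = np.zeros(13)
        rho[0] = 1.0
        values = np.zeros(24)
        values[5] = 2.0  # above max_c
        values[9] = -2.0  # below min_c
        label, _ = classify_series(_acv(rho), values, _cutoffs(np.full(12, 0.5)))
        assert label == "SpikeMax"

    def test_unclassified_when_inside_cutoffs(self):
        rho = np.zeros(13)
        rho[0] = 1.0
        label, _ = classify_series(_acv(rho), np.zeros(24), _cutoffs(np.full(12, 0.5)))
        assert label == "unclassified"

    def test_tie_at_cutoff_is_significant(self):
        rho = np.zeros(13)
        rho[0] = 1.0
        rho[2] = 0.5  # exactly equal
        label, lag = classify_series(_acv(rho), np.zeros(24), _cutoffs(np.full(12, 0.5)))
        assert label == "Lag 2" and lag == 2

    def test_spike_requires_strict_exceedance(self):
        rho = np.zeros(13)
        rho[0] = 1.0
        values = np.zeros(24)
        values[3] = 0.9  # equals max_c: not a spike
        label, _ = classify_series(_acv(rho), values, _cutoffs(np.full(12, 0.5)))
        assert label == "unclassified"

    def test_length_mismatch_errors(self):
        with pytest.raises(SpectralError, match="length"):
            classify_series(
                _acv(np.zeros(13), n_times=24), np.zeros(24), _cutoffs(np.full(5, 0.5), n_times=10)
            )


def _ts(values, omic="mRNA", frame="TFH1"):
    values = np.atleast_2d(values)
    return TimeSeriesSet(
        omic,
        frame,
        [f"a{i}" for i in range(values.shape[0])],
        np.arange(values.shape[1], dtype=float),
        values,
    )


class TestClassifyDataset:
    def test_empty_dataset_warns(self, small_config):
        ts = _ts(np.empty((0, 24)))
        with pytest.warns(UserWarning):
            cs = classify_dataset(ts, small_config)
        assert cs.records == []

    def test_every_series_gets_exactly_one_label(self, rng, small_config):
        vals = np.vstack([unit_normalize(v) for v in rng.normal(size=(100, 24))])
        cs = classify_dataset(_ts(vals), small_config)
        assert len(cs.records) == 100
        valid = {"SpikeMax", "SpikeMin", "unclassified"} | {
            f"Lag {l}" for l in range(1, 13)
        }
        assert all(r.class_label in valid for r in cs.records)

    def test_deterministic(self, rng, small_config):
        vals = np.vstack([unit_normalize(v) for v in rng.normal(size=(50, 24))])
        a = classify_dataset(_ts(vals), small_config)
        b = classify_dataset(_ts(vals), small_config)
        assert [r.class_label for r in a.records] == [r.class_label for r in b.records]
        np.testing.assert_array_equal(a.cutoffs.rho_c, b.cutoffs.rho_c)

    def test_lowest_lag_exclusivity(self, rng, small_config):
        vals = np.vstack([unit_normalize(v) for v in rng.normal(size=(300, 24))])
        cs = classify_dataset(_ts(vals), small_config)
        for r in cs.records:
            if r.lag is not None:
                assert np.all(r.rho[1 : r.lag] < cs.cutoffs.rho_c[: r.lag - 1])

    def test_type_one_rate_near_nominal(self, rng):
        # 2000 pure-noise series at p = 0.05: per-lag positive rate ~ 5 %
        cfg = StudyConfig(p=0.05, n_boot=20000, seed=8)
        vals = np.vstack([unit_normalize(v) for v in rng.normal(size=(2000, 24))])
        cs = classify_dataset(_ts(vals), cfg)
        frac = np.mean([r.rho[1] >= cs.cutoffs.rho_c[0] for r in cs.records])
        tol = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < tol

    def test_injected_trends_recovered(self, null_cutoffs_24, small_config):
        # 50 smooth lag-1 archetypes at SNR 2 against a null-calibrated cutoff
        design = SimDesign(snr=2.0)
        hits = 0
        for rep in range(50):
            x, _ = simulate_archetype("lag1-up", 24, seed=500 + rep, design=design)
            u = unit_normalize(x)
            acv = autocorrelation_vector(u, np.arange(24.0))
            label, _ = classify_series(acv, u, null_cutoffs_24)
            hits += label == "Lag 1"
        assert hits >= 40  # >= 80 %
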