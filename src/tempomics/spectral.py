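"""Spectral trend classification: Lomb-Scargle periodograms, lag
autocorrelations, bootstrap null cutoffs, and the Lag / SpikeMax / SpikeMin
class assignment.

The periodogram is evaluated on the Fourier grid f_k = k/(N*dt),
k = 1..floor(N/2), so that its inverse cosine transform lands exactly on
integer lags; for complete evenly sampled series the resulting lag
autocorrelations coincide with the circular autocorrelation of the data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import TimeSeriesSet

_DEGENERATE = 1e-9  # relative threshold for a vanishing sin^2 sum (Nyquist)


class SpectralError(ValueError):
    pass


@dataclass
class AutocorrelationVector:
    """Autocorrelations rho_0..rho_n (n = floor(N/2)) with their periodogram."""

    rho: np.ndarray
    periodogram: np.ndarray
    n_times: int

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.periodogram = np.asarray(self.periodogram, dtype=float)

    @property
    def n_lags(self) -> int:
        return self.rho.size - 1


@dataclass
class NullCutoffs:
    """Bootstrap-calibrated per-lag cutoffs plus spike extremes for length N."""

    n_times: int
    rho_c: np.ndarray  # cutoff for lags 1..n
    max_c: float
    min_c: float
    n_boot: int
    p: float
    seed: int
    pool_size: int

    def __post_init__(self) -> None:
        self.rho_c = np.asarray(self.rho_c, dtype=float)
        if not np.all(np.isfinite(self.rho_c)):
            raise SpectralError("non-finite autocorrelation cutoffs")
        if not self.max_c > self.min_c:
            raise SpectralError("spike cutoffs must satisfy max_c > min_c")

    def to_dict(self) -> dict:
        return {
            "n_times": self.n_times,
            "rho_c": self.rho_c.tolist(),
            "max_c": self.max_c,
            "min_c": self.min_c,
            "n_boot": self.n_boot,
            "p": self.p,
            "seed": self.seed,
            "pool_size": self.pool_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NullCutoffs":
        return cls(**{**d, "rho_c": np.asarray(d["rho_c"])})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NullCutoffs":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ClassifiedSeries:
    analyte_id: str
    omic: str
    class_label: str  # "Lag l" / "SpikeMax" / "SpikeMin" / "unclassified"
    lag: int | None
    rho: np.ndarray
    values: np.ndarray
    group: str | None = None
    subgroup: str | None = None


@dataclass
class ClassifiedSet:
    time_frame: str
    times: np.ndarray
    records: list[ClassifiedSeries] = field(default_factory=list)
    cutoffs: NullCutoffs | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_lags(self) -> int:
        if self.records:
            return self.records[0].rho.size - 1
        return self.times.size // 2

    def by_class(self) -> dict[str, list[ClassifiedSeries]]:
        out: dict[str, list[ClassifiedSeries]] = {}
        for r in self.records:
            out.setdefault(r.class_label, []).append(r)
        return out

    def classed_records(self) -> list[ClassifiedSeries]:
        return [r for r in self.records if r.class_label != "unclassified"]


# -- periodogram and autocorrelations ---------------------------------------


def _grid(times: np.ndarray) -> tuple[int, float]:
    times = np.asarray(times, dtype=float)
    n_times = times.size
    dt = (times[-1] - times[0]) / (n_times - 1)
    return n_times, dt


def lomb_scargle_periodogram(
    values: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Lomb-Scargle power at the Fourier grid frequencies of the time grid.

    ``values`` may hold NaN for missing timepoints, which are simply left out
    of the least-squares fit. The series is mean-centered over observed
    points. Returns (power, frequencies) for f_k = k/(N*dt), k = 1..floor(N/2).
    At a degenerate frequency (the Nyquist on an even grid, where the sine
    basis vanishes) the single-component form is used, which makes the even
    complete-sampling case agree exactly with the classical periodogram.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape != times.shape:
        raise SpectralError("values and times must have the same length")
    n_times, dt = _grid(times)
    obs = ~np.isnan(values)
    t = times[obs]
    x = values[obs]
    if x.size < 4:
        raise SpectralError(f"need >= 4 observed points, got {x.size}")
    x = x - x.mean()
    n = n_times // 2
    freqs = np.arange(1, n + 1) / (n_times * dt)
    omega = 2.0 * np.pi * freqs
    wt = omega[:, None] * t[None, :]  # (n, m)
    tau = np.arctan2(np.sin(2 * wt).sum(axis=1), np.cos(2 * wt).sum(axis=1)) / (
        2.0 * omega
    )
    arg = wt - (omega * tau)[:, None]
    c = np.cos(arg)
    s = np.sin(arg)
    cc = (c * c).sum(axis=1)
    ss = (s * s).sum(axis=1)
    xc = c @ x
    xs = s @ x
    power = np.empty(n)
    degen = ss <= _DEGENERATE * (cc + ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        power[~degen] = 0.5 * (
            xc[~degen] ** 2 / cc[~degen] + xs[~degen] ** 2 / ss[~degen]
        )
    power[degen] = xc[degen] ** 2 / cc[degen]
    if np.any(power < 0) or not np.all(np.isfinite(power)):
        raise SpectralError("periodogram produced invalid power values")
    return power, freqs


def _lag_cosine_matrix(n_times: int) -> tuple[np.ndarray, np.ndarray]:
    """Cosine transform matrix mapping grid powers to integer-lag
    autocovariances, with the Nyquist component half-weighted on even grids."""
    n = n_times // 2
    k = np.arange(1, n + 1)
    lags = np.arange(0, n + 1)
    cosmat = np.cos(2.0 * np.pi * np.outer(lags, k) / n_times)  # (n+1, n)
    weights = np.ones(n)
    if n_times % 2 == 0:
        weights[-1] = 0.5
    return cosmat, weights


def autocorrelations(power: np.ndarray, n_times: int) -> AutocorrelationVector:
    """Inverse Fourier (cosine) transform of the periodogram to lag
    autocorrelations rho_0..rho_n, normalized so rho_0 = 1."""
    power = np.asarray(power, dtype=float)
    n = n_times // 2
    if power.size != n:
        raise SpectralError(f"expected {n} power values for N={n_times}, got {power.size}")
    cosmat, weights = _lag_cosine_matrix(n_times)
    r = cosmat @ (weights * power)
    if r[0] <= 0:
        raise SpectralError("zero total spectral power (constant series?)")
    return AutocorrelationVector(rho=r / r[0], periodogram=power, n_times=n_times)


def autocorrelation_vector(values: np.ndarray, times: np.ndarray) -> AutocorrelationVector:
    """Convenience: periodogram + inverse transform for one series."""
    power, _ = lomb_scargle_periodogram(values, times)
    return autocorrelations(power, np.asarray(times).size)


def _autocorrelations_batch(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fast path for complete, evenly sampled rows: classical periodogram via
    rFFT followed by the same inverse cosine transform. Algebraically equal to
    the Lomb-Scargle path on even grids (asserted in tests).

    Returns (rho, power), shapes (m, n+1) and (m, n)."""
    x = values - values.mean(axis=1, keepdims=True)
    m, n_times = x.shape
    n = n_times // 2
    f = np.fft.rfft(x, axis=1)
    power = (f.real**2 + f.imag**2)[:, 1 : n + 1] / n_times
    cosmat, weights = _lag_cosine_matrix(n_times)
    r = (weights * power) @ cosmat.T  # (m, n+1)
    r0 = r[:, 0]
    if np.any(r0 <= 0):
        raise SpectralError("zero total spectral power in batch input")
    return r / r0[:, None], power


# -- bootstrap null calibration ----------------------------------------------


def bootstrap_cutoffs(
    pool: np.ndarray,
    n_times: int,
    n_boot: int = 100_000,
    p: float = 0.01,
    seed: int = 0,
    chunk: int = 50_000,
) -> NullCutoffs:
    """Calibrate per-lag and spike cutoffs from a resampling null.

    Simulates ``n_boot`` complete series of length ``n_times`` by drawing with
    replacement from ``pool`` (the dataset's observed values), computes their
    autocorrelations and per-series extremes, and returns the (1-p) quantile
    per lag (rho_c), the (1-p) quantile of maxima (max_c) and the p quantile
    of minima (min_c). Deterministic given ``seed``.
    """
    pool = np.asarray(pool, dtype=float).ravel()
    pool = pool[~np.isnan(pool)]
    if pool.size < n_times:
        raise SpectralError(
            f"bootstrap pool ({pool.size} values) smaller than series length {n_times}"
        )
    if n_boot < 1000:
        raise SpectralError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    n = n_times // 2
    rho_parts, max_parts, min_parts = [], [], []
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        sample = pool[rng.integers(0, pool.size, size=(b, n_times))]
        # constant resamples (possible for tiny pools) carry no spectral info
        spread = sample.max(axis=1) > sample.min(axis=1)
        if not np.all(spread):
            sample = sample[spread]
        if sample.shape[0]:
            rho_parts.append(_autocorrelations_batch(sample)[0][:, 1:])
            max_parts.append(sample.max(axis=1))
            min_parts.append(sample.min(axis=1))
        done += b
    rho_null = np.concatenate(rho_parts, axis=0)
    maxima = np.concatenate(max_parts)
    minima = np.concatenate(min_parts)
    rho_c = np.quantile(rho_null, 1.0 - p, axis=0)
    max_c = float(np.quantile(maxima, 1.0 - p))
    min_c = float(np.quantile(minima, p))
    assert rho_c.size == n
    return NullCutoffs(
        n_times=n_times,
        rho_c=rho_c,
        max_c=max_c,
        min_c=min_c,
        n_boot=n_boot,
        p=p,
        seed=seed,
        pool_size=int(pool.size),
    )


# -- classification -----------------------------------------------------------


def classify_series(
    acv: AutocorrelationVector, values: np.ndarray, cutoffs: NullCutoffs
) -> tuple[str, int | None]:
    """Assign one series to Lag l / SpikeMax / SpikeMin / unclassified.

    Lag l is the lowest lag i with rho_i >= rho_ci. Series with no
    significant lag fall through to the spike checks: SpikeMax when the
    observed maximum strictly exceeds max_c, otherwise SpikeMin when the
    observed minimum is strictly below min_c, otherwise unclassified.
    """
    if acv.n_times != cutoffs.n_times:
        raise SpectralError(
            f"series length {acv.n_times} does not match cutoffs for {cutoffs.n_times}"
        )
    sig = np.nonzero(acv.rho[1:] >= cutoffs.rho_c)[0]
    if sig.size:
        lag = int(sig[0]) + 1
        return f"Lag {lag}", lag
    obs = values[~np.isnan(values)]
    if obs.size and float(obs.max()) > cutoffs.max_c:
        return "SpikeMax", None
    if obs.size and float(obs.min()) < cutoffs.min_c:
        return "SpikeMin", None
    return "unclassified", None


def _is_even_grid(times: np.ndarray) -> bool:
    d = np.diff(times)
    return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-12))


def dataset_autocorrelations(ts: TimeSeriesSet) -> list[AutocorrelationVector]:
    """Autocorrelation vectors for every series, batching complete rows on
    even grids through the fast classical path."""
    n_times = ts.n_times
    complete = ~np.isnan(ts.values).any(axis=1)
    out: list[AutocorrelationVector | None] = [None] * ts.n_series
    if _is_even_grid(ts.times) and complete.any():
        idx = np.nonzero(complete)[0]
        rho, power = _autocorrelations_batch(ts.values[idx])
        for j, i in enumerate(idx):
            out[i] = AutocorrelationVector(
                rho=rho[j], periodogram=power[j], n_times=n_times
            )
    for i in range(ts.n_series):
        if out[i] is None:
            out[i] = autocorrelation_vector(ts.values[i], ts.times)
    return out  # type: ignore[return-value]


def classify_dataset(
    ts: TimeSeriesSet, config, cutoffs: NullCutoffs | None = None
) -> ClassifiedSet:
    """Classify every series of a preprocessed set.

    Cutoffs default to a bootstrap null built from the set's own pooled
    observed values (seeded from ``config.seed``); pass ``cutoffs`` to reuse
    a calibration from a wider dataset.
    """
    if ts.n_series == 0:
        warnings.warn("classify_dataset called on an empty dataset", stacklevel=2)
        return ClassifiedSet(time_frame=ts.time_frame, times=ts.times, records=[])
    if cutoffs is None:
        pool = ts.values[~np.isnan(ts.values)]
        cutoffs = bootstrap_cutoffs(
            pool, ts.n_times, n_boot=config.n_boot, p=config.p, seed=config.seed
        )
    acvs = dataset_autocorrelations(ts)
    records = []
    for aid, acv, row in zip(ts.analyte_ids, acvs, ts.values):
        label, lag = classify_series(acv, row, cutoffs)
        records.append(
            ClassifiedSeries(
                analyte_id=aid,
                omic=ts.omic_label,
                class_label=label,
                lag=lag,
                rho=acv.rho,
                values=row.copy(),
            )
        )
    return ClassifiedSet(
        time_frame=ts.time_frame, times=ts.times, records=records, cutoffs=cutoffs
    )
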