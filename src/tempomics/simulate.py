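"""Synthetic longitudinal multi-omics study generator with ground truth.

Emulates the study design the pipeline targets: two paired 24-point hourly
frames (baseline day and perturbation day), a 34-point daily frame, several
omic layers, smooth perturbation-response archetypes (raised-cosine pulses),
single-timepoint spikes, circadian backgrounds shared between the paired
days, zero-inflation and missingness.

Signal-to-noise is defined in RMS terms: a pulse with SNR s has standard
deviation (over the whole series) equal to s * noise_sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import OmicsMatrix

ARCHETYPES = (
    "null",
    "circadian",
    "lag1-up",
    "lag1-down",
    "early-daily",
    "late-daily",
    "spike-max",
    "spike-min",
)


class SimulationError(ValueError):
    pass


@dataclass
class SimDesign:
    """Knobs for a full synthetic study.

    Hourly frames have ``hourly_n`` points; the perturbation lands between
    hourly points ``vax_index`` and ``vax_index + 1`` on the second day and
    on day index ``daily_vax_index`` of the daily frame. Archetype fractions
    apply per omic; the remainder is unstructured null.
    """

    analytes_per_omic: dict[str, int] = field(
        default_factory=lambda: {"mRNA": 800, "protein": 300, "EV_miRNA": 300}
    )
    hourly_n: int = 24
    daily_n: int = 34
    vax_index: int = 4
    fever_window: tuple[int, int] = (11, 15)
    daily_vax_index: int = 2
    early_days: int = 11
    baseline: float = 10.0
    noise_sd: float = 1.0
    snr: float = 3.0
    spike_magnitude: float = 8.0
    circadian_fraction: float = 0.15
    perturb_fraction: float = 0.10
    spike_fraction: float = 0.02
    zero_rate: float = 0.01
    missing_rate: float = 0.01
    intensity_omics: tuple[str, ...] = ("protein",)
    intensity_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("circadian_fraction", "perturb_fraction", "spike_fraction",
                     "zero_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.circadian_fraction + self.perturb_fraction + self.spike_fraction > 1:
            raise SimulationError("archetype fractions exceed 1")
        if not 0 <= self.vax_index < self.hourly_n - 1:
            raise SimulationError("vax_index outside the hourly grid")
        if not 0 <= self.daily_vax_index < self.daily_n:
            raise SimulationError("daily_vax_index outside the daily grid")
        a, b = self.fever_window
        if not 0 <= a <= b < self.hourly_n:
            raise SimulationError("fever window outside the hourly grid")
        self.intensity_omics = tuple(self.intensity_omics)


def _raised_cosine(n: int, start: int, stop: int) -> np.ndarray:
    """Unit-peak raised-cosine pulse over [start, stop] (inclusive)."""
    p = np.zeros(n)
    width = stop - start
    if width <= 0:
        p[start] = 1.0
        return p
    idx = np.arange(start, stop + 1)
    p[idx] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (idx - start) / width))
    return p


def _scale_to_snr(profile: np.ndarray, snr: float, noise_sd: float) -> np.ndarray:
    sd = float(np.std(profile))
    if sd == 0 or snr == 0:
        return np.zeros_like(profile)
    return profile * (snr * noise_sd / sd)


def _mean_profile(
    archetype: str, n: int, design: SimDesign, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Noise-free mean profile for one archetype plus its true parameters."""
    d = design
    params: dict = {}
    if archetype == "null":
        return np.zeros(n), params
    if archetype == "circadian":
        phase = rng.uniform(0, 2 * np.pi)
        prof = np.cos(2 * np.pi * np.arange(n) / n + phase)
        params["phase"] = phase
        return _scale_to_snr(prof, d.snr, d.noise_sd), params
    if archetype in ("lag1-up", "lag1-down"):
        start = d.vax_index + 1
        stop = min(n - 1, d.fever_window[1])
        prof = _raised_cosine(n, start, stop)
        if archetype == "lag1-down":
            prof = -prof
        params.update(window=(start, stop))
        return _scale_to_snr(prof, d.snr, d.noise_sd), params
    if archetype == "early-daily":
        start = d.daily_vax_index
        stop = min(n - 1, start + d.early_days)
        params.update(window=(start, stop))
        return _scale_to_snr(_raised_cosine(n, start, stop), d.snr, d.noise_sd), params
    if archetype == "late-daily":
        start = min(n - 2, d.daily_vax_index + d.early_days + 1)
        stop = n - 1
        params.update(window=(start, stop))
        return _scale_to_snr(_raised_cosine(n, start, stop), d.snr, d.noise_sd), params
    if archetype in ("spike-max", "spike-min"):
        pos = int(rng.integers(1, n))  # never at the reference timepoint
        prof = np.zeros(n)
        prof[pos] = d.spike_magnitude * d.noise_sd
        if archetype == "spike-min":
            prof[pos] *= -1
        params["spike_index"] = pos
        return prof, params
    raise SimulationError(f"unknown archetype {archetype!r}")


def simulate_archetype(
    archetype: str,
    n_times: int,
    seed: int,
    design: SimDesign | None = None,
) -> tuple[np.ndarray, dict]:
    """One series of the given archetype: baseline + mean profile + noise.

    Returns (values, truth) where truth records the archetype and its true
    parameters. SNR 0 reduces every smooth archetype to the null generator.
    """
    if archetype not in ARCHETYPES:
        raise SimulationError(f"unknown archetype {archetype!r}")
    design = design or SimDesign()
    rng = np.random.default_rng(seed)
    profile, params = _mean_profile(archetype, n_times, design, rng)
    values = design.baseline + profile + rng.normal(0, design.noise_sd, n_times)
    truth = {"archetype": archetype, **params}
    return values, truth


def simulate_null(
    n_series: int,
    n_times: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline: float = 10.0,
    omic_label: str = "sim",
    time_frame: str = "TFH1",
) -> OmicsMatrix:
    """Structure-free matrix: baseline plus i.i.d. Gaussian noise."""
    if n_series < 1 or n_times < 1:
        raise SimulationError("n_series and n_times must be >= 1")
    rng = np.random.default_rng(seed)
    values = baseline + rng.normal(0, noise_sd, (n_series, n_times))
    ids = [f"{omic_label}_{i:05d}" for i in range(n_series)]
    return OmicsMatrix(
        omic_label, time_frame, ids, np.arange(n_times, dtype=float), values
    )


def _apply_dropout(
    values: np.ndarray,
    zero_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
    zeros_as_nan: bool = False,
) -> np.ndarray:
    # intensities are non-negative; clipped zeros read as missing downstream
    out = np.maximum(values, 0.0)
    if zero_rate > 0:
        out[rng.random(out.shape) < zero_rate] = np.nan if zeros_as_nan else 0.0
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = np.nan
    return out


def _assign_archetypes(
    n: int, frame: str, design: SimDesign, rng: np.random.Generator
) -> list[str]:
    n_circ = int(round(design.circadian_fraction * n))
    n_pert = int(round(design.perturb_fraction * n))
    n_spike = int(round(design.spike_fraction * n))
    if frame == "hourly":
        kinds = (
            ["circadian"] * n_circ
            + ["lag1-up"] * (n_pert - n_pert // 2)
            + ["lag1-down"] * (n_pert // 2)
            + ["spike-max"] * (n_spike - n_spike // 2)
            + ["spike-min"] * (n_spike // 2)
        )
    else:
        kinds = (
            ["early-daily"] * (n_pert - n_pert // 2)
            + ["late-daily"] * (n_pert // 2)
            + ["spike-max"] * (n_spike - n_spike // 2)
            + ["spike-min"] * (n_spike // 2)
        )
    kinds += ["null"] * (n - len(kinds))
    rng.shuffle(kinds)
    return kinds


def simulate_study(design: SimDesign) -> tuple[dict[tuple[str, str], OmicsMatrix], pd.DataFrame]:
    """Full multi-omic study: matrices per (omic, frame) plus a truth table.

    TFH1 carries circadian + null structure; TFH2 repeats each analyte's
    circadian profile (fresh noise) and adds the perturbation archetypes, so
    the paired difference isolates the perturbation. TFD carries early/late
    daily responses. Zero-inflation and missingness are applied last.
    Fully reproducible from (design, seed).
    """
    rng = np.random.default_rng(design.seed)
    matrices: dict[tuple[str, str], OmicsMatrix] = {}
    truth_rows = []
    t_hour = np.arange(design.hourly_n, dtype=float)
    t_day = np.arange(design.daily_n, dtype=float)

    def _finalize(v: np.ndarray, omic: str) -> np.ndarray:
        if omic in design.intensity_omics:
            # intensity-type layers live on an exponential (log-normal) scale,
            # which the Box-Cox stage of the pipeline is meant to undo
            v = np.exp(v - design.baseline) * design.intensity_scale
            return _apply_dropout(
                v, design.zero_rate, design.missing_rate, rng, zeros_as_nan=True
            )
        return _apply_dropout(v, design.zero_rate, design.missing_rate, rng)
    for omic, n_analytes in design.analytes_per_omic.items():
        ids = [f"{omic}_{i:05d}" for i in range(n_analytes)]
        # hourly frames: perturbation archetypes act only on day 2
        kinds_h = _assign_archetypes(n_analytes, "hourly", design, rng)
        base_profiles = np.zeros((n_analytes, design.hourly_n))
        pert_profiles = np.zeros((n_analytes, design.hourly_n))
        for i, kind in enumerate(kinds_h):
            if kind == "circadian":
                prof, _ = _mean_profile("circadian", design.hourly_n, design, rng)
                base_profiles[i] = prof
            elif kind != "null":
                prof, params = _mean_profile(kind, design.hourly_n, design, rng)
                pert_profiles[i] = prof
        v1 = design.baseline + base_profiles + rng.normal(
            0, design.noise_sd, (n_analytes, design.hourly_n)
        )
        v2 = design.baseline + base_profiles + pert_profiles + rng.normal(
            0, design.noise_sd, (n_analytes, design.hourly_n)
        )
        matrices[(omic, "TFH1")] = OmicsMatrix(
            omic, "TFH1", ids, t_hour, _finalize(v1, omic)
        )
        matrices[(omic, "TFH2")] = OmicsMatrix(
            omic, "TFH2", ids, t_hour, _finalize(v2, omic)
        )
        # daily frame
        kinds_d = _assign_archetypes(n_analytes, "daily", design, rng)
        vd = design.baseline + rng.normal(
            0, design.noise_sd, (n_analytes, design.daily_n)
        )
        for i, kind in enumerate(kinds_d):
            if kind != "null":
                prof, _ = _mean_profile(kind, design.daily_n, design, rng)
                vd[i] += prof
        matrices[(omic, "TFD")] = OmicsMatrix(
            omic, "TFD", ids, t_day, _finalize(vd, omic), time_unit="d"
        )
        for i, aid in enumerate(ids):
            truth_rows.append(
                {
                    "omic": omic,
                    "analyte_id": aid,
                    "hourly_archetype": kinds_h[i],
                    "daily_archetype": kinds_d[i],
                }
            )
    truth = pd.DataFrame(truth_rows)
    return matrices, truth


def simulate_counts(
    n_series: int,
    n_times: int,
    seed: int = 0,
    log_mean: float = 2.0,
    log_sd: float = 1.0,
    zero_rate: float = 0.2,
) -> OmicsMatrix:
    """Count-level mode (Poisson-lognormal with zero-inflation) for exercising
    the count preprocessing rules (noise floor, zero tagging)."""
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.normal(log_mean, log_sd, (n_series, 1)))
    values = rng.poisson(lam, (n_series, n_times)).astype(float)
    values[rng.random(values.shape) < zero_rate] = 0.0
    ids = [f"count_{i:05d}" for i in range(n_series)]
    return OmicsMatrix(
        "counts", "TFH1", ids, np.arange(n_times, dtype=float), values
    )
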