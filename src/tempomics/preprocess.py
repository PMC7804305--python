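"""Filtering and normalization turning raw matrices into classifiable series.

Fixed stage order: tag_and_floor -> filter_series -> normalize_to_reference
-> (paired_difference for TFdelta) -> unit_normalize. Intensity-type omics
(e.g. proteomics) are Box-Cox transformed per timepoint column first.
Missing values are never imputed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import OmicsMatrix

DropRecord = tuple[str, str, str]  # analyte_id, stage, reason

_CONST_RTOL = 1e-12


class PreprocessError(ValueError):
    pass


@dataclass
class TimeSeriesSet:
    """Post-filter, normalized series ready for classification."""

    omic_label: str
    time_frame: str
    analyte_ids: list[str]
    times: np.ndarray
    values: np.ndarray  # (m, N); NaN = missing
    time_unit: str = "h"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_series(self) -> int:
        return len(self.analyte_ids)

    @property
    def n_times(self) -> int:
        return int(self.times.size)


def tag_and_floor(m: OmicsMatrix, noise_floor: float = 1.0) -> OmicsMatrix:
    """Tag exact zeros as missing and raise sub-floor intensities to the floor.

    Values must be non-negative; 0 < value < noise_floor becomes
    ``noise_floor``; values >= noise_floor pass through.
    """
    v = m.values
    if v.size and np.any(v < 0):
        bad = np.argwhere(v < 0)[0]
        raise PreprocessError(
            f"negative intensity for analyte {m.analyte_ids[bad[0]]!r} "
            f"at timepoint index {bad[1]}"
        )
    out = v.copy()
    out[v == 0] = np.nan
    low = (v > 0) & (v < noise_floor)
    out[low] = noise_floor
    res = m.copy()
    res.values = out
    return res


def _is_constant(observed: np.ndarray) -> bool:
    if observed.size == 0:
        return True
    span = np.max(observed) - np.min(observed)
    return span <= _CONST_RTOL * max(1.0, np.max(np.abs(observed)))


def filter_series(
    m: OmicsMatrix, max_missing_fraction: float = 0.25
) -> tuple[OmicsMatrix, list[DropRecord]]:
    """Drop series with > max_missing_fraction of timepoints missing or with
    constant observed values. Strict inequality: exactly N/4 missing is kept.
    Idempotent. Returns survivors plus a drop log."""
    n = m.n_times
    keep = []
    drops: list[DropRecord] = []
    for i, aid in enumerate(m.analyte_ids):
        row = m.values[i]
        n_missing = int(np.isnan(row).sum())
        if n_missing > max_missing_fraction * n:
            drops.append((aid, "filter_series", f"{n_missing}/{n} timepoints missing"))
            continue
        if _is_constant(row[~np.isnan(row)]):
            drops.append((aid, "filter_series", "constant observed values"))
            continue
        keep.append(i)
    if not keep:
        warnings.warn(
            f"filter_series removed every series from {m.omic_label}/{m.time_frame}",
            stacklevel=2,
        )
    res = OmicsMatrix(
        m.omic_label,
        m.time_frame,
        [m.analyte_ids[i] for i in keep],
        m.times.copy(),
        m.values[keep].copy() if keep else np.empty((0, n)),
        m.time_unit,
    )
    return res, drops


def normalize_to_reference(
    m: OmicsMatrix, ref_index: int
) -> tuple[OmicsMatrix, list[DropRecord]]:
    """Subtract the reference-timepoint value from each series.

    Series whose reference value is missing are dropped (logged); the
    reference position becomes exactly 0 and missing values stay missing.
    """
    if not 0 <= ref_index < m.n_times:
        raise PreprocessError(f"reference index {ref_index} outside time grid")
    keep = []
    drops: list[DropRecord] = []
    for i, aid in enumerate(m.analyte_ids):
        if np.isnan(m.values[i, ref_index]):
            drops.append((aid, "normalize_to_reference", "reference timepoint missing"))
        else:
            keep.append(i)
    vals = m.values[keep] - m.values[keep, ref_index][:, None] if keep else np.empty((0, m.n_times))
    res = OmicsMatrix(
        m.omic_label,
        m.time_frame,
        [m.analyte_ids[i] for i in keep],
        m.times.copy(),
        vals,
        m.time_unit,
    )
    return res, drops


def boxcox_transform(
    column: np.ndarray, lmbda: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform one timepoint column across analytes.

    Fits lambda by maximum profile log-likelihood unless given. Non-positive
    values trigger an additive shift of (1 - min), which is returned.
    Missing values (NaN) pass through untouched.

    Returns (transformed column, lambda, shift).
    """
    col = np.asarray(column, dtype=float)
    obs = ~np.isnan(col)
    x = col[obs]
    if x.size < 10:
        raise PreprocessError(
            f"Box-Cox needs >= 10 observed values per column, got {x.size}"
        )
    shift = 0.0
    if np.min(x) <= 0:
        shift = 1.0 - np.min(x)
        x = x + shift
    if _is_constant(x):
        raise PreprocessError("Box-Cox on a degenerate (constant) column")
    if lmbda is None:
        y, fitted = stats.boxcox(x)
    else:
        y, fitted = stats.boxcox(x, lmbda=lmbda), float(lmbda)
    out = col.copy()
    out[obs] = y
    return out, float(fitted), shift


def boxcox_matrix(m: OmicsMatrix) -> tuple[OmicsMatrix, list[float], list[float]]:
    """Apply :func:`boxcox_transform` to every timepoint column (per sample)."""
    res = m.copy()
    lambdas, shifts = [], []
    for j in range(m.n_times):
        res.values[:, j], lam, shift = boxcox_transform(m.values[:, j])
        lambdas.append(lam)
        shifts.append(shift)
    return res, lambdas, shifts


def paired_difference(
    tf2: OmicsMatrix, tf1: OmicsMatrix
) -> tuple[OmicsMatrix, list[DropRecord]]:
    """Paired per-timepoint differences tf2 - tf1 over the shared analytes.

    Analytes absent from either frame are dropped (logged); a difference is
    missing when either operand is missing. The caller re-applies
    :func:`filter_series` afterwards.
    """
    if tf2.n_times != tf1.n_times or not np.allclose(tf2.times, tf1.times):
        raise PreprocessError("paired_difference requires identical timepoint grids")
    if tf2.time_unit != tf1.time_unit:
        raise PreprocessError("paired_difference requires identical time units")
    idx1 = {a: i for i, a in enumerate(tf1.analyte_ids)}
    drops: list[DropRecord] = []
    keep2, keep1 = [], []
    for i, aid in enumerate(tf2.analyte_ids):
        if aid in idx1:
            keep2.append(i)
            keep1.append(idx1[aid])
        else:
            drops.append((aid, "paired_difference", "absent from first frame"))
    for aid in tf1.analyte_ids:
        if aid not in set(tf2.analyte_ids):
            drops.append((aid, "paired_difference", "absent from second frame"))
    vals = (
        tf2.values[keep2] - tf1.values[keep1]
        if keep2
        else np.empty((0, tf2.n_times))
    )
    res = OmicsMatrix(
        tf2.omic_label,
        "TFdelta",
        [tf2.analyte_ids[i] for i in keep2],
        tf2.times.copy(),
        vals,
        tf2.time_unit,
    )
    return res, drops


def unit_normalize(series: np.ndarray) -> np.ndarray:
    """Scale a series so the L2 norm over its observed values is 1."""
    s = np.asarray(series, dtype=float)
    obs = ~np.isnan(s)
    norm = float(np.sqrt(np.sum(s[obs] ** 2)))
    if norm == 0 or not np.isfinite(norm):
        raise PreprocessError("cannot unit-normalize a zero-norm series")
    return s / norm


def _unit_normalize_matrix(m: OmicsMatrix) -> OmicsMatrix:
    res = m.copy()
    for i in range(len(res.analyte_ids)):
        res.values[i] = unit_normalize(res.values[i])
    return res


def preprocess_matrix(
    m: OmicsMatrix,
    config,
    kind: str = "counts",
    unit_norm: bool = True,
) -> tuple[TimeSeriesSet, list[DropRecord]]:
    """Run the full single-frame pipeline on one matrix.

    ``kind`` selects the initial normalization: ``counts`` applies the noise
    floor (zeros tagged missing), ``intensity`` applies per-column Box-Cox.
    """
    drops: list[DropRecord] = []
    prov: dict = {"kind": kind, "box_cox": False, "unit_normalized": False}
    if kind == "counts":
        m = tag_and_floor(m, config.noise_floor)
        if config.log_transform:
            v = m.values
            m = m.copy()
            m.values = np.log2(v)
            prov["log2"] = True
    elif kind == "intensity":
        m, lambdas, shifts = boxcox_matrix(m)
        # per-sample standardization: aligns columns whose fitted lambdas
        # (and hence transformed scales) differ
        mu = np.nanmean(m.values, axis=0)
        sd = np.nanstd(m.values, axis=0)
        m.values = (m.values - mu) / np.where(sd > 0, sd, 1.0)
        prov.update(box_cox=True, boxcox_lambdas=lambdas, boxcox_shifts=shifts,
                    column_standardized=True)
    else:
        raise PreprocessError(f"unknown matrix kind {kind!r}")
    m, d = filter_series(m, config.max_missing_fraction)
    drops += d
    ref = config.reference_index.get(m.time_frame, 0)
    m, d = normalize_to_reference(m, ref)
    drops += d
    prov["reference_index"] = ref
    # reference subtraction can leave a numerically constant (all ~0) series
    m, d = filter_series(m, config.max_missing_fraction)
    drops += d
    if unit_norm:
        m = _unit_normalize_matrix(m)
        prov["unit_normalized"] = True
    ts = TimeSeriesSet(
        m.omic_label, m.time_frame, m.analyte_ids, m.times, m.values, m.time_unit, prov
    )
    return ts, drops


def preprocess_paired(
    tfh2: OmicsMatrix,
    tfh1: OmicsMatrix,
    config,
    kind: str = "counts",
) -> tuple[TimeSeriesSet, list[DropRecord]]:
    """Build the TFdelta set: per-frame pipeline (without unit normalization),
    paired differencing, re-filter, then unit normalization."""
    s2, d2 = preprocess_matrix(tfh2, config, kind, unit_norm=False)
    s1, d1 = preprocess_matrix(tfh1, config, kind, unit_norm=False)
    m2 = OmicsMatrix(s2.omic_label, s2.time_frame, s2.analyte_ids, s2.times, s2.values, s2.time_unit)
    m1 = OmicsMatrix(s1.omic_label, s1.time_frame, s1.analyte_ids, s1.times, s1.values, s1.time_unit)
    delta, d3 = paired_difference(m2, m1)
    delta, d4 = filter_series(delta, config.max_missing_fraction)
    delta = _unit_normalize_matrix(delta)
    prov = {
        "kind": kind,
        "box_cox": kind == "intensity",
        "unit_normalized": True,
        "paired": ("TFH2", "TFH1"),
    }
    ts = TimeSeriesSet(
        delta.omic_label,
        "TFdelta",
        delta.analyte_ids,
        delta.times,
        delta.values,
        delta.time_unit,
        prov,
    )
    return ts, d2 + d1 + d3 + d4
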