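"""Reading and writing the study's on-disk artifacts.

Matrices are plain delimited text: first row holds sampling times, first
column analyte ids, empty cells or ``NA`` denote missing values.
Classification tables are TSV, class-count summaries JSON.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .spectral import ClassifiedSet

MISSING_SENTINELS = {"", "NA", "NaN", "nan"}


class ParseError(ValueError):
    """Malformed matrix file (bad header, duplicate id, non-numeric cell)."""


@dataclass
class OmicsMatrix:
    """Analyte x timepoint intensity matrix with a missing mask (NaN).

    ``values`` has one row per analyte and one column per sampling time;
    missing measurements are stored as NaN.
    """

    omic_label: str
    time_frame: str
    analyte_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    time_unit: str = "h"

    def __post_init__(self) -> None:
        self.analyte_ids = list(self.analyte_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.analyte_ids)) != len(self.analyte_ids):
            seen: set[str] = set()
            dup = next(a for a in self.analyte_ids if a in seen or seen.add(a))
            raise ParseError(f"duplicate analyte id {dup!r}")
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ParseError("sampling times must be strictly increasing")
        if self.values.shape != (len(self.analyte_ids), self.times.size):
            raise ParseError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.analyte_ids)} analytes x {self.times.size} times"
            )

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_ids)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.omic_label,
            self.time_frame,
            list(self.analyte_ids),
            self.times.copy(),
            self.values.copy(),
            self.time_unit,
        )


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    omic_label: str,
    time_frame: str,
    time_unit: str = "h",
) -> OmicsMatrix:
    """Parse a delimited matrix file into a validated :class:`OmicsMatrix`.

    First row: sampling times. First column: analyte ids. Empty cells or
    ``NA`` mark missing values. Raises :class:`ParseError` naming the
    offending row/column on malformed input.
    """
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows or len(rows[0]) < 2:
        raise ParseError(f"{path}: header must hold at least one sampling time")
    header = rows[0][1:]
    times = []
    for ci, cell in enumerate(header):
        try:
            times.append(float(cell))
        except ValueError:
            raise ParseError(
                f"{path}: header column {ci + 2} is not a numeric time: {cell!r}"
            ) from None
    ids: list[str] = []
    seen: set[str] = set()
    values = np.full((len(rows) - 1, len(times)), np.nan)
    for ri, row in enumerate(rows[1:], start=2):
        if len(row) != len(times) + 1:
            raise ParseError(
                f"{path}: row {ri} has {len(row) - 1} value cells, expected {len(times)}"
            )
        aid = row[0]
        if aid in seen:
            raise ParseError(f"{path}: duplicate analyte id {aid!r} at row {ri}")
        seen.add(aid)
        ids.append(aid)
        for ci, cell in enumerate(row[1:]):
            if cell.strip() in MISSING_SENTINELS:
                continue
            try:
                values[ri - 2, ci] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row {ri}, column {ci + 2}: {cell!r}"
                ) from None
    return OmicsMatrix(omic_label, time_frame, ids, np.array(times), values, time_unit)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write an :class:`OmicsMatrix` as delimited text (missing -> empty cell)."""
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["analyte_id"] + [repr(float(t)) for t in m.times])
        for aid, row in zip(m.analyte_ids, m.values):
            w.writerow([aid] + ["" if np.isnan(v) else repr(float(v)) for v in row])


# -- classification tables ---------------------------------------------------


def write_classification(classified: "ClassifiedSet", path: str | Path) -> None:
    """Write one TSV row per classified series (lossless round-trip).

    Columns: analyte_id, omic, time_frame, class, lag, group, subgroup,
    rho_0..rho_n, x_0..x_{N-1}. Floats are written at full precision.
    """
    path = Path(path)
    if not classified.records:
        warnings.warn("writing empty classification table", stacklevel=2)
    n_lags = classified.n_lags
    n_times = classified.times.size
    cols = (
        ["analyte_id", "omic", "time_frame", "class", "lag", "group", "subgroup"]
        + [f"rho_{k}" for k in range(n_lags + 1)]
        + [f"x_{i}" for i in range(n_times)]
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["#times"] + [repr(float(t)) for t in classified.times])
        w.writerow(cols)
        for r in classified.records:
            row = [
                r.analyte_id,
                r.omic,
                classified.time_frame,
                r.class_label,
                "" if r.lag is None else str(r.lag),
                r.group or "",
                r.subgroup or "",
            ]
            row += [repr(float(v)) for v in r.rho]
            row += ["" if np.isnan(v) else repr(float(v)) for v in r.values]
            w.writerow(row)


def read_classification(path: str | Path) -> "ClassifiedSet":
    """Read a classification TSV written by :func:`write_classification`."""
    from .spectral import ClassifiedSeries, ClassifiedSet

    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if len(rows) < 2 or rows[0][0] != "#times":
        raise ParseError(f"{path}: not a classification table")
    times = np.array([float(c) for c in rows[0][1:]])
    header = rows[1]
    rho_cols = [i for i, c in enumerate(header) if c.startswith("rho_")]
    x_cols = [i for i, c in enumerate(header) if c.startswith("x_")]
    records = []
    frame = None
    for row in rows[2:]:
        frame = row[2]
        rho = np.array([float(row[i]) for i in rho_cols])
        vals = np.array([np.nan if row[i] == "" else float(row[i]) for i in x_cols])
        records.append(
            ClassifiedSeries(
                analyte_id=row[0],
                omic=row[1],
                class_label=row[3],
                lag=None if row[4] == "" else int(row[4]),
                rho=rho,
                values=vals,
                group=row[5] or None,
                subgroup=row[6] or None,
            )
        )
    return ClassifiedSet(time_frame=frame or "", times=times, records=records)


# -- class-count summaries ---------------------------------------------------


def summarize_counts(classified: "ClassifiedSet | Iterable[ClassifiedSet]") -> pd.DataFrame:
    """Per omic per time frame: totals and per-class counts.

    ``classed`` equals lag1 + spike_max + spike_min + other_lags by
    construction; ``other_lags`` aggregates every Lag class with lag >= 2.
    """
    from .spectral import ClassifiedSet  # noqa: F401 - typing only

    sets = [classified] if hasattr(classified, "records") else list(classified)
    rows = []
    for cs in sets:
        by_omic: dict[str, list] = {}
        for r in cs.records:
            by_omic.setdefault(r.omic, []).append(r)
        for omic in sorted(by_omic):
            recs = by_omic[omic]
            lag1 = sum(1 for r in recs if r.class_label == "Lag 1")
            smax = sum(1 for r in recs if r.class_label == "SpikeMax")
            smin = sum(1 for r in recs if r.class_label == "SpikeMin")
            other = sum(
                1 for r in recs if r.lag is not None and r.lag >= 2
            )
            rows.append(
                {
                    "omic": omic,
                    "time_frame": cs.time_frame,
                    "total_series": len(recs),
                    "total_classed": lag1 + smax + smin + other,
                    "lag_1": lag1,
                    "spike_max": smax,
                    "spike_min": smin,
                    "other_lags": other,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "omic",
            "time_frame",
            "total_series",
            "total_classed",
            "lag_1",
            "spike_max",
            "spike_min",
            "other_lags",
        ],
    )


def write_counts_json(counts: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(counts.to_dict(orient="records"), indent=2))


def write_drop_log(drops: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Drop log TSV: analyte, pipeline stage, reason."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["analyte_id", "stage", "reason"])
        for rec in drops:
            w.writerow(list(rec))
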