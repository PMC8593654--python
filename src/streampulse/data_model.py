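"""Domain types and delimited-text I/O for monitoring time series.

All timestamps are timezone-naive local time.  A timestamp ``t`` on a grid
with spacing ``dt`` labels the half-open interval ``[t, t + dt)``, so
composite windows tile the record without overlap.

Missing samples (maintenance / quality-check gaps) are kept as explicit gap
rows, never silently dropped: downstream exposure emulation needs to account
for the fraction of missing samples inside each composite window.

Values below the limit of quantification (LOQ) are stored as measured when
available.  Substitution (LOQ/2 for factor analysis, LOQ for composite
emulation) is applied downstream per context, never at read time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundMeta",
    "ConcentrationMatrix",
    "HydroSeries",
    "read_compound_metadata",
    "write_compound_metadata",
    "read_concentration_table",
    "write_concentration_table",
    "read_timeseries",
    "write_timeseries",
    "align_to_grid",
    "rebin_conserving",
]

CHEM_CLASSES = frozenset(
    {"fungicide", "herbicide", "insecticide", "TP_fungicide", "TP_herbicide"}
)


@dataclass(frozen=True)
class CompoundMeta:
    """Per-compound metadata.

    Parameters
    ----------
    compound_id : str
        Short identifier, used as the column name in concentration tables.
    chem_class : str
        One of ``fungicide``, ``herbicide``, ``insecticide``,
        ``TP_fungicide``, ``TP_herbicide`` (TP = transformation product).
    legacy : bool
        True for withdrawn substances whose occurrence reflects historical
        contamination (these dilute during events instead of pulsing).
    loq : float
        Limit of quantification, ng/l.  Strictly positive.
    error_fraction : float
        Relative measurement error ``a`` in [0, 1]; enters the per-cell
        uncertainty as ``sqrt((a*x)**2 + loq**2)``.
    aqs : float or None
        Acute quality standard, ng/l, if defined for this compound.
    rac : float or None
        Regulatory acceptable concentration, ng/l, if defined.
    """

    compound_id: str
    chem_class: str
    legacy: bool
    loq: float
    error_fraction: float
    aqs: float | None = None
    rac: float | None = None

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValueError(
                f"{self.compound_id}: unknown chem_class {self.chem_class!r}"
            )
        if not self.loq > 0:
            raise ValueError(f"{self.compound_id}: loq must be > 0, got {self.loq}")
        if not 0.0 <= self.error_fraction <= 1.0:
            raise ValueError(
                f"{self.compound_id}: error_fraction must be in [0, 1], "
                f"got {self.error_fraction}"
            )
        for name, value in (("aqs", self.aqs), ("rac", self.rac)):
            if value is not None and not value > 0:
                raise ValueError(f"{self.compound_id}: {name} must be > 0 if present")


def _infer_spacing(index: pd.DatetimeIndex) -> pd.Timedelta:
    if len(index) < 2:
        raise ValueError("need at least two timestamps to infer grid spacing")
    diffs = pd.Series(index).diff().dropna()
    if (diffs <= pd.Timedelta(0)).any():
        bad = int(np.argmax((diffs <= pd.Timedelta(0)).to_numpy()))
        raise ValueError(f"timestamps not strictly increasing at row {bad + 1}")
    return diffs.min()


@dataclass
class ConcentrationMatrix:
    """An n x m matrix of concentrations on a regular time grid.

    ``values`` is a DataFrame indexed by timestamp with one column per
    compound (ng/l).  ``below_loq`` flags cells with value < LOQ of the
    compound; ``gap`` flags rows where any cell is missing (maintenance /
    QC gaps).  Values inside gap rows are NaN.
    """

    values: pd.DataFrame
    compounds: list[CompoundMeta]
    below_loq: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    gap: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = [c.compound_id for c in self.compounds]
        if list(self.values.columns) != ids:
            raise ValueError("values columns must match compound metadata order")
        spacing = _infer_spacing(self.values.index)
        expected = pd.date_range(
            self.values.index[0], self.values.index[-1], freq=spacing
        )
        if not self.values.index.equals(expected):
            raise ValueError("timestamps are not on a regular grid")
        if self.below_loq is None or self.gap is None:
            self.recompute_masks()
        finite = self.values.to_numpy()
        if np.nanmin(finite, initial=0.0) < 0:
            raise ValueError("negative concentration in matrix")

    # -- derived properties -------------------------------------------------

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.values.index

    @property
    def spacing(self) -> pd.Timedelta:
        return _infer_spacing(self.values.index)

    @property
    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    @property
    def loq(self) -> pd.Series:
        return pd.Series(
            [c.loq for c in self.compounds], index=self.compound_ids, dtype=float
        )

    def recompute_masks(self) -> None:
        """Masks are pure functions of values and LOQ; recomputing is idempotent."""
        loq = self.loq
        self.gap = self.values.isna().any(axis=1)
        # NaN < loq is False, so gap cells are never flagged censored
        self.below_loq = self.values.lt(loq, axis=1)

    def drop_gaps(self) -> "ConcentrationMatrix":
        """Return a copy without gap rows (the grid is no longer contiguous)."""
        keep = ~self.gap
        out = ConcentrationMatrix.__new__(ConcentrationMatrix)
        out.values = self.values.loc[keep]
        out.compounds = list(self.compounds)
        out.below_loq = self.below_loq.loc[keep]
        out.gap = self.gap.loc[keep]
        return out

    def select(self, compound_ids: Sequence[str]) -> "ConcentrationMatrix":
        order = {c.compound_id: c for c in self.compounds}
        compounds = [order[cid] for cid in compound_ids]
        return ConcentrationMatrix(
            values=self.values[list(compound_ids)].copy(), compounds=compounds
        )


@dataclass
class HydroSeries:
    """Rainfall (mm per step) and stream water level (cm), each on its own
    regular grid — typically 10-min rain and 15-min level."""

    rain: pd.Series
    water_level: pd.Series

    def __post_init__(self) -> None:
        for name, s in (("rain", self.rain), ("water_level", self.water_level)):
            if len(s) == 0:
                raise ValueError(f"{name} series is empty")
            if len(s) >= 2:
                _infer_spacing(s.index)
            if (s.dropna() < 0).any():
                raise ValueError(f"{name} contains negative values")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_META_COLUMNS = ["compound_id", "chem_class", "legacy", "loq", "error_fraction", "aqs", "rac"]


def read_compound_metadata(path: str | Path | io.IOBase) -> list[CompoundMeta]:
    """Read a compound metadata CSV (columns: compound_id, chem_class,
    legacy, loq, error_fraction, aqs, rac; empty aqs/rac = absent)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_META_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            CompoundMeta(
                compound_id=str(row["compound_id"]),
                chem_class=str(row["chem_class"]),
                legacy=bool(row["legacy"]),
                loq=float(row["loq"]),
                error_fraction=float(row["error_fraction"]),
                aqs=None if pd.isna(row.get("aqs", np.nan)) else float(row["aqs"]),
                rac=None if pd.isna(row.get("rac", np.nan)) else float(row["rac"]),
            )
        )
    return out


def write_compound_metadata(compounds: Sequence[CompoundMeta], path: str | Path) -> None:
    rows = [
        {
            "compound_id": c.compound_id,
            "chem_class": c.chem_class,
            "legacy": c.legacy,
            "loq": c.loq,
            "error_fraction": c.error_fraction,
            "aqs": c.aqs,
            "rac": c.rac,
        }
        for c in compounds
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def read_concentration_table(
    path: str | Path | io.IOBase,
    meta: Sequence[CompoundMeta] | str | Path,
    fmt: str = "wide",
) -> ConcentrationMatrix:
    """Read a concentration table into a :class:`ConcentrationMatrix`.

    Wide format: one ``timestamp`` column plus one column per compound;
    an empty cell is a gap.  Long format: columns ``timestamp``,
    ``compound``, ``value``.  The grid is completed: a missing instant on
    the regular grid becomes an explicit gap row.

    Raises
    ------
    ValueError
        On non-monotone timestamps (with the offending row index), unknown
        compound columns, or negative concentrations.
    """
    if not isinstance(meta, (list, tuple)):
        meta = read_compound_metadata(meta)
    df = pd.read_csv(path, float_precision="round_trip")
    if "timestamp" not in df.columns:
        raise ValueError("table must have a 'timestamp' column")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if fmt == "long":
        df = df.pivot(index="timestamp", columns="compound", values="value")
        df = df.rename_axis(None, axis=1).reset_index()
    elif fmt != "wide":
        raise ValueError(f"unknown format {fmt!r}")

    known = {c.compound_id for c in meta}
    data_cols = [c for c in df.columns if c != "timestamp"]
    unknown = set(data_cols) - known
    if unknown:
        raise ValueError(f"unknown compound columns: {sorted(unknown)}")

    ts = pd.DatetimeIndex(df["timestamp"])
    diffs = pd.Series(ts).diff().dropna()
    nonpos = diffs <= pd.Timedelta(0)
    if nonpos.any():
        bad = int(np.argmax(nonpos.to_numpy())) + 1
        raise ValueError(f"non-monotone timestamps at row {bad}")

    values = df.set_index("timestamp")[data_cols].astype(float)
    neg = values.lt(0)
    if neg.any().any():
        row = int(np.argmax(neg.any(axis=1).to_numpy()))
        raise ValueError(f"negative concentration at row {row}")

    # complete the grid: missing instants become gap rows
    spacing = diffs.min()
    full = pd.date_range(ts[0], ts[-1], freq=spacing)
    values = values.reindex(full)

    compounds = [c for c in meta if c.compound_id in data_cols]
    values = values[[c.compound_id for c in compounds]]
    return ConcentrationMatrix(values=values, compounds=compounds)


def write_concentration_table(
    matrix: ConcentrationMatrix, path: str | Path, fmt: str = "wide"
) -> None:
    """Write a concentration table (gap cells become empty cells)."""
    df = matrix.values.copy()
    df.index.name = "timestamp"
    if fmt == "wide":
        df.to_csv(path)
    elif fmt == "long":
        long = df.stack(future_stack=True).rename("value").reset_index()
        long.columns = ["timestamp", "compound", "value"]
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_timeseries(path: str | Path | io.IOBase, value_name: str = "value") -> pd.Series:
    """Read a (timestamp, value) CSV into a Series indexed by timestamp."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if "timestamp" not in cols or len(cols) != 2:
        raise ValueError("expected exactly columns: timestamp, <value>")
    value_col = next(c for c in cols if c != "timestamp")
    s = pd.Series(
        df[value_col].astype(float).to_numpy(),
        index=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])),
        name=value_name,
    )
    return s


def write_timeseries(series: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame(
        {"timestamp": series.index, series.name or "value": series.to_numpy()}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Grid alignment
# ---------------------------------------------------------------------------


def rebin_conserving(series: pd.Series, target_spacing: pd.Timedelta) -> pd.Series:
    """Rebin an accumulation series (mm per step) onto a new grid, conserving
    total mass for any spacing ratio.

    The source mass is treated as uniformly distributed over each half-open
    source interval; the cumulative-mass curve is interpolated at the target
    bin edges and differenced.
    """
    if len(series) == 0:
        raise ValueError("cannot rebin an empty series")
    target_spacing = pd.Timedelta(target_spacing)
    src_spacing = _infer_spacing(series.index) if len(series) > 1 else target_spacing
    start = series.index[0]
    end = series.index[-1] + src_spacing

    src_edges = np.append(
        series.index.view("int64"), (series.index[-1] + src_spacing).value
    ).astype(float)
    cum = np.concatenate([[0.0], np.cumsum(series.to_numpy(dtype=float))])

    n_bins = int(np.ceil((end - start) / target_spacing))
    tgt_edges = start.value + np.arange(n_bins + 1) * target_spacing.value
    cum_t = np.interp(tgt_edges.astype(float), src_edges, cum)
    binned = np.diff(cum_t)
    index = pd.DatetimeIndex(tgt_edges[:-1].astype("datetime64[ns]"))
    return pd.Series(binned, index=index, name=series.name)


def interpolate_at(series: pd.Series, target_index: pd.DatetimeIndex) -> pd.Series:
    """Linear interpolation of an instantaneous series at target instants
    (constant extrapolation at the ends)."""
    x = series.index.view("int64").astype(float)
    y = series.to_numpy(dtype=float)
    xt = target_index.view("int64").astype(float)
    return pd.Series(np.interp(xt, x, y), index=target_index, name=series.name)


def align_to_grid(hydro: HydroSeries, target_spacing: pd.Timedelta) -> HydroSeries:
    """Put rainfall and water level on a common grid.

    Rainfall (an accumulation) is rebinned mass-conservingly; water level
    (an instantaneous state) is linearly interpolated at the target
    instants.  The grids start at each series' own first timestamp.
    """
    target_spacing = pd.Timedelta(target_spacing)
    rain = rebin_conserving(hydro.rain, target_spacing)
    n = int(
        np.ceil(
            (hydro.water_level.index[-1] - hydro.water_level.index[0]) / target_spacing
        )
    )
    level_index = hydro.water_level.index[0] + target_spacing * np.arange(n + 1)
    level = interpolate_at(hydro.water_level, pd.DatetimeIndex(level_index))
    return HydroSeries(rain=rain, water_level=level)
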