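"""Reading dendrometer-band measurements into tidy per-tree series.

A dendrometer band is a steel or plastic collar around the bole whose
gap, measured with digital calipers (~0.01 mm resolution), tracks the
tree's circumference change through the season.  Two transforms put the
raw field sheet into model-ready form: calendar dates become 1-based
day-of-year, and caliper gap (mm) becomes DBH (cm) using the band
circumference recorded at installation:

    dbh_t = (circumference_cm + (gap_mm_t - gap_mm_first) / 10) / pi

so the first record's DBH is circumference/pi and growth is referenced
to the installation gap.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_SERIES_LENGTH = 6

__all__ = ["BandSeries", "to_doy", "gap_to_dbh", "read_band_csv", "write_band_csv"]


@dataclass
class BandSeries:
    """One tree-year of (day-of-year, DBH) observations.

    ``doy`` is strictly increasing, 1-based within the year; ``dbh`` is in
    cm and positive; at least six points are required for a usable fit.
    """

    tree_id: str
    year: int
    doy: np.ndarray
    dbh: np.ndarray

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=float)
        self.dbh = np.asarray(self.dbh, dtype=float)
        if self.doy.shape != self.dbh.shape or self.doy.ndim != 1:
            raise ValueError("doy and dbh must be 1-d vectors of equal length")
        if len(self.doy) < MIN_SERIES_LENGTH:
            raise ValueError(
                f"series {self.tree_id!r}/{self.year}: need at least "
                f"{MIN_SERIES_LENGTH} points, got {len(self.doy)}"
            )
        if np.any(np.diff(self.doy) <= 0):
            raise ValueError(f"series {self.tree_id!r}/{self.year}: doy not strictly increasing")
        if np.any((self.doy < 1) | (self.doy > 366)):
            raise ValueError(f"series {self.tree_id!r}/{self.year}: doy outside 1..366")
        if np.any(self.dbh <= 0):
            raise ValueError(f"series {self.tree_id!r}/{self.year}: non-positive dbh")

    def __len__(self) -> int:
        return len(self.doy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": self.tree_id,
                "year": self.year,
                "doy": self.doy.astype(int),
                "dbh_cm": self.dbh,
            }
        )


def to_doy(year: int, month: int, day: int) -> int:
    """1-based day of the year for a Gregorian date (Jan 1 -> 1, leap aware)."""
    try:
        date = _dt.date(int(year), int(month), int(day))
    except (ValueError, OverflowError) as exc:
        raise ValueError(f"invalid calendar date ({year}, {month}, {day}): {exc}") from exc
    return date.timetuple().tm_yday


def gap_to_dbh(gap_mm, circumference_cm: float) -> np.ndarray:
    """Convert caliper gap readings (mm) to DBH (cm).

    Growth is referenced to the first (installation) reading, so the first
    record's DBH equals circumference/pi exactly.
    """
    gap_mm = np.asarray(gap_mm, dtype=float)
    if not np.isfinite(circumference_cm) or circumference_cm <= 0:
        raise ValueError("band circumference at installation must be positive")
    if np.any(gap_mm < 0):
        raise ValueError("caliper gap cannot be negative")
    return (circumference_cm + (gap_mm - gap_mm.flat[0]) / 10.0) / math.pi


@dataclass
class ColumnMap:
    """CSV column mapping; either a date column or a doy (+year) column,
    and either a dbh column or a gap column with circumference."""

    tree_id: str = "tree_id"
    date: str | None = "date"
    doy: str | None = None
    year: str | None = None
    dbh_cm: str | None = "dbh_cm"
    gap_mm: str | None = None
    circumference_cm: str | None = None
    skipped: list = field(default_factory=list)


def read_band_csv(path, columns: ColumnMap | None = None) -> list[BandSeries]:
    """Read a band-measurement CSV into one :class:`BandSeries` per tree-year.

    Rows are sorted by day of year and duplicate days are collapsed by the
    mean.  Series shorter than six points are skipped with a logged
    warning (recorded on ``columns.skipped``); everything else is strict.
    """
    cm = columns or ColumnMap()
    df = pd.read_csv(path)
    if cm.tree_id not in df.columns:
        raise ValueError(f"missing tree id column {cm.tree_id!r} in {path}")

    if cm.date and cm.date in df.columns:
        dates = pd.to_datetime(df[cm.date], errors="raise")
        df["_year"] = dates.dt.year
        df["_doy"] = dates.dt.dayofyear
    elif cm.doy and cm.doy in df.columns:
        df["_doy"] = df[cm.doy].astype(int)
        if cm.year and cm.year in df.columns:
            df["_year"] = df[cm.year].astype(int)
        else:
            df["_year"] = 0  # unknown year; doy given directly
    else:
        raise ValueError("need a date column or a doy column")

    out: list[BandSeries] = []
    for (tree_id, year), grp in df.groupby([cm.tree_id, "_year"], sort=True):
        if cm.dbh_cm and cm.dbh_cm in grp.columns and grp[cm.dbh_cm].notna().any():
            dbh = grp[cm.dbh_cm].astype(float).to_numpy()
            tidy = pd.DataFrame({"doy": grp["_doy"].to_numpy(), "dbh": dbh})
        elif cm.gap_mm and cm.gap_mm in grp.columns:
            if not (cm.circumference_cm and cm.circumference_cm in grp.columns):
                raise ValueError(
                    f"tree {tree_id!r}: gap measurements require the band "
                    "circumference recorded at installation"
                )
            grp = grp.sort_values("_doy", kind="stable")
            circ = float(grp[cm.circumference_cm].iloc[0])
            dbh = gap_to_dbh(grp[cm.gap_mm].astype(float).to_numpy(), circ)
            tidy = pd.DataFrame({"doy": grp["_doy"].to_numpy(), "dbh": dbh})
        else:
            raise ValueError(f"tree {tree_id!r}: need a dbh column or a gap column")

        tidy = tidy.groupby("doy", as_index=False)["dbh"].mean().sort_values("doy")
        if len(tidy) < MIN_SERIES_LENGTH:
            logger.warning(
                "series %s/%s has %d < %d points; skipped",
                tree_id, year, len(tidy), MIN_SERIES_LENGTH,
            )
            cm.skipped.append((str(tree_id), int(year)))
            continue
        out.append(
            BandSeries(
                tree_id=str(tree_id),
                year=int(year),
                doy=tidy["doy"].to_numpy(dtype=float),
                dbh=tidy["dbh"].to_numpy(dtype=float),
            )
        )
    return out


def write_band_csv(series: list[BandSeries], path) -> None:
    """Write tidy series (tree_id, year, doy, dbh_cm), re-readable by
    :func:`read_band_csv` with ``ColumnMap(date=None, doy='doy', year='year')``."""
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)
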