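"""GPS telemetry reading, screening, and movement-rate summaries.

Fixes are held in a pandas DataFrame with columns ``animal_id`` (str),
``t`` (timezone-aware UTC timestamps), ``x``/``y`` (projected meters),
``dop`` (dilution of precision, dimensionless), and optionally ``herd``.
A "track" is the time-ordered frame of a single animal.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["animal_id", "t", "x", "y", "dop"]

#: Fix-quality screen: fixes are retained when DOP is strictly below this.
MAX_DOP = 10.0


def validate_fixes(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and basic invariants; returns the frame time-sorted."""
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fix table is missing columns: {missing}")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in fix table")
    if (df["dop"] < 0).any():
        raise ValueError("negative DOP values in fix table")
    t = pd.to_datetime(df["t"], utc=True)
    out = df.assign(t=t).sort_values(["animal_id", "t"], kind="stable")
    dup = out.duplicated(subset=["animal_id", "t"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (animal, timestamp) fixes")
    return out.reset_index(drop=True)


def read_fixes(path: str | Path, utc_offset_hours: float = 0.0) -> pd.DataFrame:
    """Read a telemetry CSV, skipping malformed rows with a logged count.

    Timestamps are parsed as UTC; ``utc_offset_hours`` declares the offset
    of local-time inputs (positive east of Greenwich) and is subtracted.
    """
    raw = pd.read_csv(path, dtype={"animal_id": str})
    n_raw = len(raw)
    t = pd.to_datetime(raw.get("timestamp", raw.get("t")), utc=True, errors="coerce")
    if utc_offset_hours:
        t = t - pd.Timedelta(hours=utc_offset_hours)
    df = pd.DataFrame({
        "animal_id": raw["animal_id"],
        "t": t,
        "x": pd.to_numeric(raw["x"], errors="coerce"),
        "y": pd.to_numeric(raw["y"], errors="coerce"),
        "dop": pd.to_numeric(raw["dop"], errors="coerce"),
    })
    if "herd" in raw.columns:
        df["herd"] = raw["herd"]
    bad = df[["t", "x", "y", "dop"]].isna().any(axis=1) | df["animal_id"].isna()
    if bad.any():
        logger.warning("skipped %d malformed rows of %d", int(bad.sum()), n_raw)
    return validate_fixes(df[~bad])


def write_fixes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={"t": "timestamp"}).copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def filter_by_dop(df: pd.DataFrame, max_dop: float = MAX_DOP) -> pd.DataFrame:
    """Keep fixes with DOP strictly below ``max_dop`` (order preserved).

    The inequality is strict: a fix with DOP exactly equal to the threshold
    is discarded.
    """
    if (df["dop"] < 0).any():
        raise ValueError("negative DOP values in fix table")
    return df[df["dop"] < max_dop].copy()


def daily_movement_rate(track: pd.DataFrame) -> pd.DataFrame:
    """Daily movement rate (km/day) for one animal's track.

    Each step between consecutive fixes is assigned to the calendar date
    (UTC) of its *later* fix.  For date *d*,
    ``rate = sum(step lengths) / sum(step durations)`` over the steps
    assigned to *d*, in km/day.  Days inside the deployment with no step
    ending on them are present with NaN rate (coverage flag).

    Returns a DataFrame indexed by date with columns ``rate`` (km/day),
    ``span_days`` (total duration of the contributing steps, days) and
    ``n_steps``.  ``sum(rate * span_days)`` over non-missing days equals
    the total path length of the track in km (conservation).
    """
    if track["animal_id"].nunique() > 1:
        raise ValueError("daily_movement_rate expects a single animal's track")
    track = track.sort_values("t", kind="stable")
    t = track["t"].to_numpy()
    if len(track) < 2:
        dates = pd.DatetimeIndex(t).date if len(track) else []
        return pd.DataFrame({"rate": np.nan, "span_days": 0.0, "n_steps": 0},
                            index=pd.Index(dates, name="date"))
    xy = track[["x", "y"]].to_numpy(dtype=float)
    step_km = np.hypot(*np.diff(xy, axis=0).T) / 1000.0
    dt_days = np.diff(t).astype("timedelta64[ns]").astype(float) / 86400e9
    if (dt_days <= 0).any():
        raise ValueError("track timestamps are not strictly increasing")
    step_date = pd.DatetimeIndex(t[1:]).normalize()

    g = pd.DataFrame({"len": step_km, "dur": dt_days}, index=step_date)
    agg = g.groupby(level=0).agg(len=("len", "sum"), dur=("dur", "sum"),
                                 n=("len", "size"))
    full = pd.date_range(pd.DatetimeIndex(t).min().normalize(),
                         pd.DatetimeIndex(t).max().normalize(), freq="D")
    agg = agg.reindex(full)
    out = pd.DataFrame({
        "rate": agg["len"] / agg["dur"],
        "span_days": agg["dur"].fillna(0.0),
        "n_steps": agg["n"].fillna(0).astype(int),
    })
    out.index = out.index.date
    out.index.name = "date"
    return out


def clip_to_season(track: pd.DataFrame, start, end,
                   tolerance: pd.Timedelta = pd.Timedelta(days=1),
                   ) -> tuple[pd.DataFrame, bool]:
    """Fixes inside the half-open window [start, end) plus a coverage flag.

    The season is *complete* for this animal iff its deployment spans the
    whole window: first fix <= start + tolerance and last fix >= end -
    tolerance.  Incomplete seasons are excluded from UD estimation
    downstream.
    """
    start = pd.Timestamp(start, tz="UTC") if pd.Timestamp(start).tz is None else pd.Timestamp(start)
    end = pd.Timestamp(end, tz="UTC") if pd.Timestamp(end).tz is None else pd.Timestamp(end)
    if end <= start:
        raise ValueError(f"empty season window: {start} .. {end}")
    clipped = track[(track["t"] >= start) & (track["t"] < end)].copy()
    if len(track) == 0 or len(clipped) == 0:
        return clipped, False
    complete = (track["t"].min() <= start + tolerance
                and track["t"].max() >= end - tolerance)
    return clipped, bool(complete)
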