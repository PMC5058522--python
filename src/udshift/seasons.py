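"""Biological season delineation from daily movement rates.

Seasons of migratory ungulates show up as level shifts in the daily
movement-rate series: residency periods are slow, migrations fast.  This
module segments each individual's rate-vs-day-of-year series into
piecewise-constant periods by recursive binary partitioning (greedy SSE
splitting with a cost-complexity pruning rule), then aggregates the
per-individual transition dates into population season onsets.

The day-of-year axis is treated as a circle so that a winter season
spanning the calendar-year boundary is a single segment: the first split
of the circle places a *pair* of boundaries, and later splits subdivide
arcs as in ordinary recursive partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

DAYS = 365


def _doy_array(rates) -> np.ndarray:
    """Coerce input to a length-365 array of mean rate per day-of-year."""
    if isinstance(rates, pd.DataFrame):
        rates = rates["rate"]
    if isinstance(rates, pd.Series) and not isinstance(rates.index, pd.RangeIndex):
        idx = pd.DatetimeIndex(pd.to_datetime(rates.index))
        doy = np.minimum(idx.dayofyear, DAYS)
        out = np.full(DAYS, np.nan)
        grouped = pd.Series(rates.to_numpy(), index=doy).groupby(level=0).mean()
        out[grouped.index.to_numpy() - 1] = grouped.to_numpy()
        return out
    arr = np.asarray(rates, dtype=float)
    if arr.shape != (DAYS,):
        raise ValueError(f"expected a length-{DAYS} day-of-year series, got {arr.shape}")
    return arr


class _ArcSSE:
    """O(1) SSE of circular arcs via prefix sums over the doubled series."""

    def __init__(self, rates: np.ndarray):
        d = np.concatenate([rates, rates])
        ok = np.isfinite(d)
        v = np.where(ok, d, 0.0)
        self.s1 = np.concatenate([[0.0], np.cumsum(v)])
        self.s2 = np.concatenate([[0.0], np.cumsum(v * v)])
        self.c = np.concatenate([[0], np.cumsum(ok.astype(int))])

    def sse(self, s, e):
        """SSE of arc [s, e) on the doubled index (vectorizable)."""
        n = self.c[e] - self.c[s]
        tot = self.s1[e] - self.s1[s]
        sq = self.s2[e] - self.s2[s]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sq - np.where(n > 0, tot * tot / np.maximum(n, 1), 0.0)
        return np.maximum(out, 0.0)


def _best_interior_split(acc: _ArcSSE, s: int, e: int, min_len: int):
    """Best cut c in [s+min_len, e-min_len] minimizing within-arc SSE."""
    lo, hi = s + min_len, e - min_len
    if hi < lo:
        return None, np.inf
    cuts = np.arange(lo, hi + 1)
    total = acc.sse(s, cuts) + acc.sse(cuts, e)
    k = int(np.argmin(total))
    return int(cuts[k]), float(total[k])


def _best_circle_pair(acc: _ArcSSE, min_len: int):
    """Best first split of the circle: a pair (b1, b2) of boundaries."""
    best = (None, None, np.inf)
    for b1 in range(0, DAYS):
        lo, hi = b1 + min_len, b1 + DAYS - min_len
        if hi < lo:
            continue
        b2 = np.arange(lo, hi + 1)
        total = acc.sse(b1, b2) + acc.sse(b2, b1 + DAYS)
        k = int(np.argmin(total))
        if total[k] < best[2]:
            best = (b1, int(b2[k]), float(total[k]))
    return best


def partition_rate_series(rates, max_segments: int = 6,
                          min_segment_days: int = 14,
                          prune: float = 0.05) -> list[int]:
    """Segment a day-of-year movement-rate series into seasons.

    Parameters
    ----------
    rates
        Length-365 array (day 1 at index 0, NaN = no coverage), or a
        date-indexed Series/DataFrame from
        :func:`udshift.telemetry.daily_movement_rate`.
    max_segments
        Upper bound on the number of seasons.
    min_segment_days
        Shortest admissible season.
    prune
        Cost-complexity stopping rule: a split is accepted only if it
        reduces the current total SSE by at least this fraction.

    Returns
    -------
    Sorted list of onset days-of-year (1-based).  An onset at day *d*
    means the new season begins on day *d*.  Empty list = single season.
    """
    r = _doy_array(rates)
    n_ok = int(np.isfinite(r).sum())
    if n_ok < 2 * min_segment_days:
        raise ValueError(
            f"series has {n_ok} usable days; need at least {2 * min_segment_days}")
    acc = _ArcSSE(r)
    total_sse = float(acc.sse(0, DAYS))
    if max_segments < 2 or total_sse == 0.0:
        return []

    b1, b2, pair_sse = _best_circle_pair(acc, min_segment_days)
    if b1 is None or total_sse - pair_sse < prune * total_sse:
        return []
    arcs = [(b1, b2), (b2, b1 + DAYS)]
    current = pair_sse

    while len(arcs) < max_segments:
        best = (None, None, -np.inf)  # (arc index, cut, reduction)
        for i, (s, e) in enumerate(arcs):
            cut, split_sse = _best_interior_split(acc, s, e, min_segment_days)
            if cut is None:
                continue
            reduction = float(acc.sse(s, e)) - split_sse
            if reduction > best[2]:
                best = (i, cut, reduction)
        if best[0] is None or best[2] < prune * current:
            break
        i, cut, reduction = best
        s, e = arcs.pop(i)
        arcs[i:i] = [(s, cut), (cut, e)]
        current -= reduction

    onsets = sorted({s % DAYS + 1 for s, _ in arcs})
    return onsets


def partition_sse(rates, onsets: list[int]) -> float:
    """Total SSE of the circular partition defined by ``onsets``."""
    r = _doy_array(rates)
    acc = _ArcSSE(r)
    if not onsets:
        return float(acc.sse(0, DAYS))
    b = sorted((o - 1) % DAYS for o in onsets)
    bounds = b + [b[0] + DAYS]
    return float(sum(acc.sse(s, e) for s, e in zip(bounds[:-1], bounds[1:])))


def circular_median(days: np.ndarray) -> float:
    """Median of day-of-year values on the circle (result in (0, 365])."""
    days = np.sort(np.asarray(days, dtype=float))
    if days.size == 0:
        raise ValueError("empty cluster")
    # cut the circle at the largest gap, then take the ordinary median
    gaps = np.diff(np.concatenate([days, [days[0] + DAYS]]))
    cut = int(np.argmax(gaps)) + 1
    unwrapped = np.concatenate([days[cut:], days[:cut] + DAYS]) if cut < days.size else days
    med = float(np.median(unwrapped))
    return (med - 1) % DAYS + 1


@dataclass
class SeasonPartition:
    """Population-level season windows on the circular year."""

    onsets: list[int]                  # sorted day-of-year, one per season
    labels: list[str] = field(default_factory=list)
    method: str = "circular_median"

    def __post_init__(self):
        if len(self.onsets) < 2:
            raise ValueError("a season partition needs at least 2 onsets")
        if sorted(self.onsets) != list(self.onsets):
            raise ValueError("onsets must be sorted")
        if not self.labels:
            self.labels = [f"season_{i + 1}" for i in range(len(self.onsets))]
        if len(self.labels) != len(self.onsets) or len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique and match onsets")

    @property
    def k(self) -> int:
        return len(self.onsets)

    def windows(self, year: int) -> list[tuple[str, pd.Timestamp, pd.Timestamp]]:
        """Half-open [start, end) season windows for the year starting at
        the first onset; the last season wraps into the next calendar year."""
        out = []
        base = pd.Timestamp(year=year, month=1, day=1, tz="UTC")
        nxt = pd.Timestamp(year=year + 1, month=1, day=1, tz="UTC")
        for i, (label, onset) in enumerate(zip(self.labels, self.onsets)):
            start = base + pd.Timedelta(days=onset - 1)
            if i + 1 < len(self.onsets):
                end = base + pd.Timedelta(days=self.onsets[i + 1] - 1)
            else:
                end = nxt + pd.Timedelta(days=self.onsets[0] - 1)
            out.append((label, start, end))
        return out


def aggregate_onsets(per_individual_onsets: list[list[int]], k: int,
                     method: str = "circular_median",
                     labels: list[str] | None = None) -> SeasonPartition:
    """Cluster pooled per-individual onsets into ``k`` population onsets.

    Onsets from all individuals are pooled on the circular day-of-year
    axis, cut into ``k`` contiguous clusters at the ``k`` largest circular
    gaps, and summarized per cluster by the circular median (or mean).
    """
    pooled = np.array(sorted(d for ons in per_individual_onsets for d in ons),
                      dtype=float)
    if np.unique(pooled).size < k:
        raise ValueError(
            f"only {np.unique(pooled).size} distinct onsets pooled; "
            f"cannot support k={k}, try a smaller k")
    gaps = np.diff(np.concatenate([pooled, [pooled[0] + DAYS]]))
    # indices after which a cut is placed: the k largest gaps
    cut_after = np.sort(np.argsort(gaps)[-k:])
    clusters = []
    start = (cut_after[-1] + 1) % pooled.size
    order = np.concatenate([np.arange(start, pooled.size), np.arange(0, start)])
    ends = [(c - start) % pooled.size for c in cut_after]
    prev = 0
    for e in sorted(ends):
        clusters.append(pooled[order[prev:e + 1]])
        prev = e + 1
    stat = circular_median if method == "circular_median" else _circular_mean
    onsets = sorted(int(round(stat(c))) for c in clusters)
    if len(set(onsets)) < k:
        raise ValueError("clusters collapse to fewer than k distinct onsets; "
                         "try a smaller k")
    return SeasonPartition(onsets, labels or [], method)


def _circular_mean(days: np.ndarray) -> float:
    theta = 2 * np.pi * (np.asarray(days, dtype=float) - 1) / DAYS
    ang = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return (ang * DAYS / (2 * np.pi)) % DAYS + 1


class SeasonPartitioner(BaseEstimator):
    """Estimate population season onsets from individual movement rates.

    Parameters
    ----------
    k : int, default 6
        Number of seasons to recover at the population level.
    min_segment_days : int, default 14
        Shortest admissible season in the per-individual partitioning.
    prune : float, default 0.05
        Minimum fractional SSE reduction for a split to be accepted.
    max_segments : int or None
        Cap on per-individual segments; defaults to ``k``.
    aggregate : {"circular_median", "circular_mean"}
        Cluster summary statistic for the population onsets.
    labels : list of str or None
        Season names (assigned in onset order).

    Attributes
    ----------
    individual_onsets_ : list of list of int
    partition_ : SeasonPartition
    onsets_ : list of int
    """

    def __init__(self, k: int = 6, min_segment_days: int = 14,
                 prune: float = 0.05, max_segments: int | None = None,
                 aggregate: str = "circular_median",
                 labels: list[str] | None = None):
        self.k = k
        self.min_segment_days = min_segment_days
        self.prune = prune
        self.max_segments = max_segments
        self.aggregate = aggregate
        self.labels = labels

    def fit(self, X, y=None):
        """Fit on a list of per-individual daily-rate series."""
        max_seg = self.max_segments or self.k
        self.individual_onsets_ = []
        for series in X:
            try:
                ons = partition_rate_series(series, max_segments=max_seg,
                                            min_segment_days=self.min_segment_days,
                                            prune=self.prune)
            except ValueError:
                continue  # series too short: this individual contributes nothing
            if ons:
                self.individual_onsets_.append(ons)
        if not self.individual_onsets_:
            raise ValueError("no individual produced any season onsets")
        self.partition_ = aggregate_onsets(
            self.individual_onsets_, self.k,
            method=self.aggregate, labels=self.labels)
        self.onsets_ = self.partition_.onsets
        return self
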