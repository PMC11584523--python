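"""Per-supercluster tunnel-dynamics statistics.

Operates on per-replicate bottleneck-radius time series (absent where the
tunnel was not detected in a frame): detection frequency, bottleneck-radius
summaries and histograms, open-state dwell durations, cluster discovery
curves, and distinct-supercluster counts.

Conventions: a frame counts as *detected* when its bottleneck radius is
strictly greater than the detection threshold; a frame is *open* when the
radius is at or above the open threshold; frames without a detected tunnel
are closed for dwell purposes (an undetected tunnel has no radius at or
above the threshold).  Runs touching either end of the series have unknown
true duration and carry a censored flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BottleneckSeries",
    "StatsParams",
    "BRSummary",
    "DwellRun",
    "Histogram",
    "DiscoveryCurve",
    "bottleneck_series_from_radius",
    "detection_frequency",
    "br_summary",
    "br_histogram",
    "open_state_runs",
    "dwell_histogram",
    "first_detection_times",
    "discovery_curve",
    "count_distinct_superclusters",
]


@dataclass
class BottleneckSeries:
    """Per-supercluster, per-replicate bottleneck-radius time series.

    ``values[f]`` is the bottleneck radius (A) of the supercluster's tunnel
    in frame f, or NaN where no member tunnel was detected; ``lengths`` is
    the matching tunnel-length series.
    """

    supercluster_id: int
    replicate_id: str
    condition: str
    frame_spacing: float  # ns
    values: np.ndarray
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)


def bottleneck_series_from_radius(
    values: np.ndarray,
    frame_spacing: float,
    replicate_id: str = "r0",
    condition: str = "default",
    supercluster_id: int = 1,
    detection_limit: float = 0.7,
) -> BottleneckSeries:
    """Wrap a raw radius series, masking frames a probe could not traverse.

    Radii below ``detection_limit`` (the probe radius) are recorded as
    absent, mimicking what geometric detection would report.
    """
    v = np.asarray(values, dtype=float).copy()
    v[v < detection_limit] = np.nan
    return BottleneckSeries(
        supercluster_id=supercluster_id,
        replicate_id=replicate_id,
        condition=condition,
        frame_spacing=frame_spacing,
        values=v,
    )


def _default_br_edges() -> np.ndarray:
    return np.round(np.arange(0.7, 3.0 + 1e-9, 0.1), 10)


def _default_dwell_edges() -> np.ndarray:
    return np.geomspace(0.02, 8.0, 13)


@dataclass(frozen=True)
class StatsParams:
    """Thresholds and binning for the dynamics statistics.

    detection_threshold
        A frame counts as detected when BR is strictly above this (A).
    open_threshold
        A frame is open when BR is at or above this (A).
    br_bin_edges, dwell_bin_edges
        Histogram edges (A / ns); mass beyond the last edge goes to an
        open overflow bin.
    censoring_policy
        'flag' keeps boundary-touching runs flagged but excludes them from
        histograms; 'drop' removes them; 'include' keeps them everywhere.
    """

    detection_threshold: float = 0.7
    open_threshold: float = 1.4
    br_bin_edges: np.ndarray = dc_field(default_factory=_default_br_edges)
    dwell_bin_edges: np.ndarray = dc_field(default_factory=_default_dwell_edges)
    censoring_policy: str = "flag"

    def __post_init__(self) -> None:
        if self.open_threshold < self.detection_threshold:
            raise ValueError("open_threshold must be >= detection_threshold")
        for edges in (self.br_bin_edges, self.dwell_bin_edges):
            e = np.asarray(edges, dtype=float)
            if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")
        if self.censoring_policy not in ("drop", "include", "flag"):
            raise ValueError("censoring_policy must be drop, include or flag")


@dataclass(frozen=True)
class BRSummary:
    mean_br: float
    max_br: float
    mean_length: float | None


@dataclass(frozen=True)
class DwellRun:
    duration: float  # ns
    censored: bool


@dataclass
class Histogram:
    """Normalized histogram with an open overflow bin beyond the last edge."""

    bin_edges: np.ndarray
    frequencies: np.ndarray  # len(bin_edges) - 1
    overflow: float

    @property
    def total(self) -> float:
        return float(self.frequencies.sum() + self.overflow)


# --------------------------------------------------------------------------
# Frame-level statistics
# --------------------------------------------------------------------------

def detection_frequency(
    series: BottleneckSeries, params: StatsParams = StatsParams()
) -> float:
    """Fraction of frames with a detected tunnel (BR strictly > threshold)."""
    if series.n_frames == 0:
        raise ValueError("empty series")
    v = series.values
    return float(
        np.sum(series.present & (v > params.detection_threshold)) / series.n_frames
    )


def br_summary(series: BottleneckSeries) -> BRSummary | None:
    """Mean BR, max BR and mean length over detected frames; None if none."""
    present = series.present
    if not present.any():
        return None
    v = series.values[present]
    mean_length = None
    if series.lengths is not None:
        mean_length = float(np.nanmean(series.lengths[present]))
    return BRSummary(
        mean_br=float(v.mean()), max_br=float(v.max()), mean_length=mean_length
    )


def _histogram(values: np.ndarray, edges: np.ndarray) -> Histogram:
    edges = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    # np.histogram closes the last bin; move exact-last-edge hits and
    # anything beyond to the open overflow bin
    in_last = np.sum((values >= edges[-2]) & (values < edges[-1]))
    counts[-1] = in_last
    overflow = np.sum(values >= edges[-1])
    n = len(values)
    return Histogram(
        bin_edges=edges,
        frequencies=counts / n,
        overflow=float(overflow / n),
    )


def br_histogram(
    series: BottleneckSeries, params: StatsParams = StatsParams()
) -> Histogram:
    """Distribution of detected bottleneck radii over ``br_bin_edges``.

    Counts of present values in half-open bins, normalized by the number
    of detected frames; values beyond the last edge land in the overflow
    bin so the masses sum to one (values below the first edge, possible
    only when the probe radius is below it, are excluded).
    """
    present = series.present
    if not present.any():
        raise ValueError("no detected frames")
    return _histogram(series.values[present], params.br_bin_edges)


# --------------------------------------------------------------------------
# Open-state dwell analysis
# --------------------------------------------------------------------------

def open_state_runs(
    series: BottleneckSeries, params: StatsParams = StatsParams()
) -> list[DwellRun]:
    """Maximal runs of consecutive open frames (BR >= open threshold).

    Duration is run length times the frame spacing; absent frames are
    closed.  Runs touching either series boundary are censored and removed
    when ``censoring_policy='drop'``.
    """
    if series.n_frames == 0:
        raise ValueError("empty series")
    is_open = series.present & (series.values >= params.open_threshold)
    padded = np.concatenate([[False], is_open, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    runs = []
    for s, e in zip(starts, ends):
        censored = s == 0 or e == series.n_frames
        if censored and params.censoring_policy == "drop":
            continue
        runs.append(
            DwellRun(duration=(e - s) * series.frame_spacing, censored=censored)
        )
    return runs


def dwell_histogram(
    runs_per_replicate: Sequence[Sequence[DwellRun]],
    params: StatsParams = StatsParams(),
) -> tuple[Histogram, np.ndarray, np.ndarray]:
    """Across-replicate mean and SD of normalized dwell-duration histograms.

    Returns ``(mean_histogram, sd_per_bin, sd_overflow_and_mean)`` where
    the mean histogram holds the across-replicate average frequency per
    bin; the second value is the per-bin SD (ddof=1) and the third the
    overflow-bin SD.  Censored runs contribute only under
    ``censoring_policy='include'``; a replicate with zero runs contributes
    an all-zero histogram (logged).
    """
    if len(runs_per_replicate) < 2:
        raise ValueError("at least two replicates are required")
    edges = np.asarray(params.dwell_bin_edges, dtype=float)
    per_rep = []
    for i, runs in enumerate(runs_per_replicate):
        durations = np.array(
            [
                r.duration
                for r in runs
                if params.censoring_policy == "include" or not r.censored
            ]
        )
        if len(durations) == 0:
            logger.warning("replicate %d has zero dwell runs", i)
            per_rep.append(np.zeros(len(edges)))  # bins + overflow
            continue
        h = _histogram(durations, edges)
        per_rep.append(np.concatenate([h.frequencies, [h.overflow]]))
    stacked = np.stack(per_rep)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1)
    hist = Histogram(bin_edges=edges, frequencies=mean[:-1], overflow=float(mean[-1]))
    return hist, sd[:-1], sd[-1]


# --------------------------------------------------------------------------
# Discovery curves and counts
# --------------------------------------------------------------------------

@dataclass
class DiscoveryCurve:
    """Cumulative count of distinct superclusters first seen by time t."""

    times: np.ndarray  # ns, union grid over replicates
    mean_counts: np.ndarray
    min_counts: np.ndarray
    max_counts: np.ndarray
    saturation_times: dict[str, float | None]  # replicate -> last first-detection


def first_detection_times(
    superclusters: Sequence, replicate_id: str
) -> list[float]:
    """First-detection time (ns) of each supercluster in one replicate."""
    times = []
    for sc in superclusters:
        for (cond, rep), bs in sc.series.items():
            if rep != replicate_id:
                continue
            present = np.flatnonzero(bs.present)
            if present.size:
                times.append(float(present[0] * bs.frame_spacing))
    return sorted(times)


def discovery_curve(
    first_times: Mapping[str, Sequence[float]]
) -> DiscoveryCurve:
    """Step functions of distinct-cluster discovery, aggregated over replicates."""
    if not first_times:
        raise ValueError("at least one replicate is required")
    saturation: dict[str, float | None] = {}
    for rep, ts in first_times.items():
        if len(ts) == 0:
            logger.warning("replicate %r discovered zero superclusters", rep)
            saturation[rep] = None
        else:
            saturation[rep] = float(max(ts))
    grid = np.unique(
        np.concatenate([np.asarray(ts, dtype=float) for ts in first_times.values()])
        if any(len(ts) for ts in first_times.values())
        else np.array([0.0])
    )
    counts = np.stack(
        [
            np.searchsorted(np.sort(np.asarray(ts, dtype=float)), grid, side="right")
            for ts in first_times.values()
        ]
    )
    return DiscoveryCurve(
        times=grid,
        mean_counts=counts.mean(axis=0),
        min_counts=counts.min(axis=0),
        max_counts=counts.max(axis=0),
        saturation_times=saturation,
    )


def count_distinct_superclusters(
    superclusters: Sequence, condition: str
) -> int:
    """Superclusters with at least one member tunnel from the condition."""
    return sum(
        1
        for sc in superclusters
        if any(
            cond == condition and bs.present.any()
            for (cond, _), bs in sc.series.items()
        )
    )
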