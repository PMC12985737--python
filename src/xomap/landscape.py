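"""Crossover landscapes: normalized distributions, cM/Mb tracks, hotspot usage.

Crossovers enter every statistic at the midpoint of their breakpoint
interval (an optional smear mode spreads each crossover uniformly over its
interval instead). Distributions are normalized to the total number of OK
crossovers, so tracks from populations of different size are directly
comparable and differences between two normalized tracks sum to zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .xo_mapper import CallStatus, CrossoverCall

__all__ = [
    "TrackMode",
    "LandscapeTrack",
    "HotspotAnnotation",
    "HotspotUsage",
    "ok_midpoints",
    "build_distribution",
    "moving_average_cm_per_mb",
    "track_integral_cm",
    "differential_track",
    "hotspot_usage",
    "hotspot_reduction",
    "read_hotspot_bed",
    "write_hotspot_bed",
    "write_bedgraph",
    "write_usage_tsv",
]


class TrackMode(str, enum.Enum):
    NORMALIZED_FRACTION = "NORMALIZED_FRACTION"
    CM_PER_MB = "CM_PER_MB"
    DIFFERENCE = "DIFFERENCE"


@dataclass
class LandscapeTrack:
    """Binned track over the interval.

    For NORMALIZED_FRACTION and DIFFERENCE the rows are non-overlapping
    bins. For CM_PER_MB the rows are overlapping sliding windows of fixed
    ``window`` length advanced by ``step``; the grid overhangs the
    interval start so that every position inside the interval is covered
    by exactly ``window / step`` windows, which makes the track's
    integral conserve the interval's genetic length exactly.
    """

    starts: np.ndarray  # bp, 1-based window/bin starts
    ends: np.ndarray  # exclusive
    values: np.ndarray
    mode: TrackMode
    window: int | None = None
    step: int | None = None
    interval: tuple[int, int] | None = None  # clipping span for output

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.starts.shape == self.ends.shape == self.values.shape):
            raise ValueError("starts, ends and values must have equal length")
        if (self.ends <= self.starts).any():
            raise ValueError("every bin must have positive width")
        if self.mode is TrackMode.NORMALIZED_FRACTION:
            if abs(self.values.sum() - 1.0) > 1e-9:
                raise ValueError("normalized fractions must sum to 1")
            if (self.values < 0).any():
                raise ValueError("normalized fractions must be non-negative")
        elif self.mode is TrackMode.CM_PER_MB and (self.values < 0).any():
            raise ValueError("cM/Mb values must be non-negative")


@dataclass(frozen=True)
class HotspotAnnotation:
    """Named hotspot span, 1-based half-open [start, end)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"hotspot {self.name}: end must exceed start")


@dataclass(frozen=True)
class HotspotUsage:
    """Share of mapped crossovers falling in each hotspot span."""

    shares: dict[str, float]
    background: float
    n_calls: int

    def __post_init__(self) -> None:
        total = sum(self.shares.values()) + self.background
        if any(s < 0 for s in self.shares.values()) or self.background < 0:
            raise ValueError("shares must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("hotspot shares plus background must sum to 1")


def _validate_hotspots(annotations: list[HotspotAnnotation]) -> None:
    spans = sorted(annotations, key=lambda h: h.start)
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end:
            raise ValueError(f"hotspot spans overlap: {a.name} and {b.name}")


def ok_midpoints(calls: list[CrossoverCall]) -> np.ndarray:
    """Midpoints of the OK calls, sorted."""
    mids = np.array(
        [c.midpoint for c in calls if c.status is CallStatus.OK], dtype=np.int64
    )
    mids.sort()
    return mids


def build_distribution(
    calls: list[CrossoverCall],
    bin_edges,
    smear: bool = False,
) -> LandscapeTrack:
    """Normalized crossover distribution over the given bins.

    ``bin_edges`` are increasing bp coordinates (typically the marker
    positions, so bins are inter-marker intervals). Each OK call
    contributes mass 1/N at its midpoint, or, with ``smear=True``,
    uniformly over its breakpoint interval. Calls outside the binned
    range are an error — the bins must cover the mapped interval.
    """
    edges = np.asarray(bin_edges, dtype=np.int64)
    if edges.size < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin_edges must be at least 2 strictly increasing values")
    ok = [c for c in calls if c.status is CallStatus.OK]
    if not ok:
        raise ValueError("no OK crossover calls: normalization undefined")
    n = len(ok)
    if smear:
        counts = np.zeros(edges.size - 1)
        for c in ok:
            lo, hi = c.left_pos, c.right_pos
            overlap = np.clip(
                np.minimum(hi, edges[1:]) - np.maximum(lo, edges[:-1]), 0, None
            )
            if overlap.sum() == 0:
                raise ValueError(f"call {c.recombinant_id} outside binned range")
            counts += overlap / (hi - lo)
    else:
        mids = ok_midpoints(calls)
        if mids[0] < edges[0] or mids[-1] >= edges[-1]:
            raise ValueError("call midpoints must lie within the binned range")
        counts, _ = np.histogram(mids, bins=edges)
    return LandscapeTrack(
        starts=edges[:-1],
        ends=edges[1:],
        values=counts / n,
        mode=TrackMode.NORMALIZED_FRACTION,
        interval=(int(edges[0]), int(edges[-1])),
    )


def moving_average_cm_per_mb(
    calls: list[CrossoverCall],
    interval_cm: float,
    interval: tuple[int, int],
    window: int = 1000,
    step: int = 100,
) -> LandscapeTrack:
    """Sliding-window crossover rate in cM/Mb.

    The interval's total genetic length ``interval_cm`` is apportioned to
    windows by the fraction of OK-call midpoints each contains, divided
    by the window length in Mb. Windows have fixed length, advance by
    ``step`` and are grid-aligned to the interval start; the grid starts
    ``window - step`` before the interval so edge positions receive full
    window coverage. When ``window`` is a multiple of ``step`` the track
    integrates back to ``interval_cm`` exactly (see track_integral_cm).
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if interval_cm < 0:
        raise ValueError("interval_cm must be non-negative")
    start, end = interval
    if end <= start:
        raise ValueError("interval end must exceed start")
    mids = ok_midpoints(calls)
    n = mids.size
    starts = np.arange(start - window + step, end, step, dtype=np.int64)
    ends = starts + window
    if n > 0:
        counts = np.searchsorted(mids, ends, side="left") - np.searchsorted(
            mids, starts, side="left"
        )
    else:
        counts = np.zeros(starts.size)
    frac = counts / n if n > 0 else counts.astype(float)
    values = interval_cm * frac / (window / 1e6)
    return LandscapeTrack(
        starts=starts,
        ends=ends,
        values=values,
        mode=TrackMode.CM_PER_MB,
        window=window,
        step=step,
        interval=(start, end),
    )


def track_integral_cm(track: LandscapeTrack) -> float:
    """Genetic length implied by a cM/Mb track: sum(value) * step in Mb."""
    if track.mode is not TrackMode.CM_PER_MB or track.step is None:
        raise ValueError("integral is defined for sliding-window cM/Mb tracks")
    return float(track.values.sum() * track.step / 1e6)


def differential_track(
    sample: LandscapeTrack, control: LandscapeTrack
) -> LandscapeTrack:
    """Elementwise sample − control over identical normalized bins."""
    for t in (sample, control):
        if t.mode is not TrackMode.NORMALIZED_FRACTION:
            raise ValueError("differential tracks require normalized inputs")
    if not (
        np.array_equal(sample.starts, control.starts)
        and np.array_equal(sample.ends, control.ends)
    ):
        raise ValueError("sample and control bins differ")
    return LandscapeTrack(
        starts=sample.starts.copy(),
        ends=sample.ends.copy(),
        values=sample.values - control.values,
        mode=TrackMode.DIFFERENCE,
        interval=sample.interval,
    )


def hotspot_usage(
    calls: list[CrossoverCall], annotations: list[HotspotAnnotation]
) -> HotspotUsage:
    """Fraction of OK crossover midpoints within each hotspot span."""
    _validate_hotspots(annotations)
    mids = ok_midpoints(calls)
    if mids.size == 0:
        raise ValueError("no OK crossover calls")
    shares = {}
    inside = 0
    for h in annotations:
        k = int(((mids >= h.start) & (mids < h.end)).sum())
        shares[h.name] = k / mids.size
        inside += k
    return HotspotUsage(
        shares=shares,
        background=(mids.size - inside) / mids.size,
        n_calls=int(mids.size),
    )


def hotspot_reduction(
    sample: HotspotUsage, control: HotspotUsage, hotspot: str
) -> float:
    """Percent reduction of a hotspot's normalized crossover share.

    ``100 * (1 - sample_share / control_share)``; negative values mean
    enhancement in the sample relative to the control.
    """
    if hotspot not in sample.shares or hotspot not in control.shares:
        raise ValueError(f"hotspot {hotspot!r} missing from usage summary")
    c = control.shares[hotspot]
    if c == 0:
        raise ValueError(f"control share for {hotspot!r} is zero: reduction undefined")
    return 100.0 * (1.0 - sample.shares[hotspot] / c)


# ---------------------------------------------------------------------------
# I/O: BED hotspot annotations, bedGraph tracks, usage tables


def read_hotspot_bed(path) -> list[HotspotAnnotation]:
    """Read hotspot spans from BED (0-based half-open → 1-based half-open)."""
    spans = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[3] if len(fields) > 3 else f"hotspot{len(spans) + 1}"
            spans.append(HotspotAnnotation(name, int(fields[1]) + 1, int(fields[2]) + 1))
    _validate_hotspots(spans)
    return spans


def write_hotspot_bed(annotations: list[HotspotAnnotation], path, chrom: str = ".") -> None:
    with open(path, "w") as fh:
        for h in sorted(annotations, key=lambda a: a.start):
            fh.write(f"{chrom}\t{h.start - 1}\t{h.end - 1}\t{h.name}\n")


def write_bedgraph(track: LandscapeTrack, path, chrom: str = ".") -> None:
    """Write a track as bedGraph (0-based half-open rows).

    Sliding-window tracks are resampled to each window's central
    ``step``-long segment so rows tile the interval without overlap;
    segments are clipped to the interval span.
    """
    if track.mode is TrackMode.CM_PER_MB and track.window and track.step:
        centre_off = (track.window - track.step) // 2
        starts = track.starts + centre_off
        ends = starts + track.step
    else:
        starts, ends = track.starts, track.ends
    lo, hi = track.interval if track.interval else (starts.min(), ends.max())
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, track.values):
            cs, ce = max(int(s), lo), min(int(e), hi)
            if ce <= cs:
                continue
            fh.write(f"{chrom}\t{cs - 1}\t{ce - 1}\t{v:.6g}\n")


def write_usage_tsv(usage: HotspotUsage, path) -> None:
    rows = [dict(region=k, share=v) for k, v in usage.shares.items()]
    rows.append(dict(region="background", share=usage.background))
    df = pd.DataFrame(rows)
    df["n_calls"] = usage.n_calls
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
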