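"""Zoom tiers and payload reduction.

A genome browser spans an enormous zoom range — a whole chromosome is on
the order of a million times denser than the base-pair view — so the
granularity of the data must follow the zoom level.  The ladder here has
three tiers, driven by *bases per pixel* (bp/px):

* ``sequence``  — at most 1/8 bp/px (>= 8 px per base, room for letters):
  individual residues are drawn.
* ``individual`` — up to ``individual_threshold`` bp/px (default 1000):
  every feature is drawn as its own glyph.
* ``summary`` — beyond that: features are reduced to fixed-width bins
  carrying a count, a coverage fraction and the maximum score.  Bin
  widths snap to powers of 10 so cached tiers are reusable across nearby
  zoom levels.

Reducing the payload to the tier's granularity before it is stored or
shipped is what keeps both network traffic and the client cache
proportional to what the screen can actually show.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

from .das_protocol import DasFeature, GenomicSegment
from .errors import ArgumentError

SEQUENCE_THRESHOLD_BPP = 1.0 / 8.0
DEFAULT_INDIVIDUAL_THRESHOLD_BPP = 1000.0


@dataclass(frozen=True)
class ZoomTier:
    """Rendering granularity for a bases-per-pixel ratio."""

    bases_per_pixel: float
    kind: str  # sequence | individual | summary
    bin_width: int | None = None

    def __post_init__(self):
        if self.bases_per_pixel <= 0:
            raise ArgumentError("bases_per_pixel must be positive")
        if self.kind not in ("sequence", "individual", "summary"):
            raise ArgumentError(f"unknown tier kind {self.kind!r}")
        if self.kind == "summary" and (self.bin_width is None or self.bin_width < 1):
            raise ArgumentError("summary tier requires a positive bin_width")

    @property
    def label(self) -> str:
        """Cache-key label: tiers with one label share cached payloads."""
        return f"bin:{self.bin_width}" if self.kind == "summary" else self.kind


@dataclass(frozen=True)
class SummaryBin:
    """Fixed-width bin summarizing the features that overlap it."""

    bin_start: int
    bin_stop: int
    count: int
    coverage_fraction: float
    max_score: float | None = None

    def __post_init__(self):
        if self.bin_stop < self.bin_start:
            raise ArgumentError("bin_stop < bin_start")
        if self.count < 0:
            raise ArgumentError("negative bin count")
        if not (0.0 <= self.coverage_fraction <= 1.0 + 1e-9):
            raise ArgumentError(f"coverage_fraction {self.coverage_fraction} outside [0,1]")


def snap_bin_width(bases_per_pixel: float) -> int:
    """Smallest power of 10 that is >= bases_per_pixel."""
    return int(10 ** math.ceil(math.log10(bases_per_pixel)))


def choose_tier(
    viewport,
    individual_threshold: float = DEFAULT_INDIVIDUAL_THRESHOLD_BPP,
) -> ZoomTier:
    """Pick the granularity tier for a viewport.

    Boundaries are inclusive on the finer side: exactly 1/8 bp/px is
    still the sequence tier, exactly ``individual_threshold`` bp/px is
    still the individual tier.
    """
    span = viewport.stop - viewport.start + 1
    if span < 1 or viewport.pixel_width < 1:
        raise ArgumentError("viewport must span >= 1 base over >= 1 pixel")
    bpp = span / viewport.pixel_width
    if bpp <= SEQUENCE_THRESHOLD_BPP:
        return ZoomTier(bases_per_pixel=bpp, kind="sequence")
    if bpp <= individual_threshold:
        return ZoomTier(bases_per_pixel=bpp, kind="individual")
    return ZoomTier(bases_per_pixel=bpp, kind="summary", bin_width=snap_bin_width(bpp))


def bin_edges(window: GenomicSegment, bin_width: int) -> list[tuple[int, int]]:
    """Contiguous bins tiling the window; the last one may be short."""
    edges = []
    pos = window.start
    while pos <= window.stop:
        edges.append((pos, min(pos + bin_width - 1, window.stop)))
        pos += bin_width
    return edges


def summarize(
    features: Sequence[DasFeature], window: GenomicSegment, bin_width: int
) -> list[SummaryBin]:
    """Bin features over a window.

    A feature increments the count of *every* bin its interval overlaps
    (not just the bin holding its midpoint), so long features keep their
    visual mass at low zoom.  ``coverage_fraction`` is the fraction of
    the bin's bases covered by at least one feature.
    """
    if bin_width < 1:
        raise ArgumentError("bin_width must be >= 1")
    edges = bin_edges(window, bin_width)
    n = len(edges)
    counts = [0] * n
    max_scores: list[float | None] = [None] * n
    per_bin_intervals: list[list[tuple[int, int]]] = [[] for _ in range(n)]

    for f in features:
        if not window.overlaps(f.start, f.stop):
            continue
        lo = max(f.start, window.start)
        hi = min(f.stop, window.stop)
        first = (lo - window.start) // bin_width
        last = (hi - window.start) // bin_width
        for i in range(first, last + 1):
            counts[i] += 1
            b_start, b_stop = edges[i]
            per_bin_intervals[i].append((max(lo, b_start), min(hi, b_stop)))
            if f.score is not None:
                ms = max_scores[i]
                max_scores[i] = f.score if ms is None else max(ms, f.score)

    bins = []
    for i, (b_start, b_stop) in enumerate(edges):
        covered = _union_length(per_bin_intervals[i])
        bins.append(
            SummaryBin(
                bin_start=b_start,
                bin_stop=b_stop,
                count=counts[i],
                coverage_fraction=covered / (b_stop - b_start + 1),
                max_score=max_scores[i],
            )
        )
    return bins


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bases in the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi + 1:
            total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo + 1
    return total


Payload = Union[list[DasFeature], list[SummaryBin]]


def reduce_payload(
    features: Sequence[DasFeature], tier: ZoomTier, window: GenomicSegment
) -> Payload:
    """Reduce a feature list to the tier's granularity over a window.

    Sequence and individual tiers keep the features that overlap the
    window, unmodified (glyph clipping happens at render time); the
    summary tier replaces them with bins.
    """
    if tier.kind == "summary":
        return summarize(features, window, tier.bin_width)
    return [f for f in features if window.overlaps(f.start, f.stop)]
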