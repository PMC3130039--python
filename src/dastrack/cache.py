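"""In-memory interval cache keyed by (source, segment, tier).

The client asks for data only when the viewport needs it; everything
received is kept in memory so panning and zooming re-fetch nothing.
``plan_fetch`` splits a wanted range into the sub-ranges already held
and the sub-ranges that must still be requested; ``insert`` records new
payloads; ``evict_to`` enforces a byte budget with LRU order, optionally
expiring entries past a TTL first (the short-lived server-proxy role).

Recency is a monotonic counter bumped on plan_fetch hits and inserts —
no wall clock involved, so eviction order is deterministic and testable.
Payloads at different tiers are independent entries: a summary is never
fabricated from cached individual features, which keeps the cache
semantics exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ArgumentError

DEFAULT_BUDGET_BYTES = 256 * 1024 * 1024  # typical client footprint ceiling
DEFAULT_TTL_SECONDS = 300.0  # proxy role: keep preprocessed data briefly


@dataclass(frozen=True)
class CacheKey:
    source_url: str
    segment_id: str
    tier_label: str  # "sequence", "individual" or "bin:<width>"

    def __post_init__(self):
        if not (self.source_url and self.segment_id and self.tier_label):
            raise ArgumentError("cache key fields must be non-empty")


class IntervalSet:
    """Sorted, disjoint, adjacency-merged 1-based inclusive intervals.

    The normal form: intervals are ordered by start, pairwise disjoint,
    and two intervals that touch (stop + 1 == next start) are merged.
    """

    __slots__ = ("intervals",)

    def __init__(self, intervals: list[tuple[int, int]] | None = None):
        self.intervals: list[tuple[int, int]] = []
        for lo, hi in intervals or []:
            self.add(lo, hi)

    def __repr__(self) -> str:
        return f"IntervalSet({self.intervals!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_bases(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.intervals)

    def contains(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.intervals)

    def add(self, lo: int, hi: int) -> None:
        """Insert [lo, hi], merging overlaps and adjacencies."""
        if lo > hi:
            raise ArgumentError(f"bad interval [{lo}, {hi}]")
        merged = []
        placed = False
        for s, e in self.intervals:
            if e + 1 < lo:  # strictly left, not even adjacent
                merged.append((s, e))
            elif hi + 1 < s:  # strictly right
                if not placed:
                    merged.append((lo, hi))
                    placed = True
                merged.append((s, e))
            else:  # overlap or adjacency: absorb
                lo = min(lo, s)
                hi = max(hi, e)
        if not placed:
            merged.append((lo, hi))
        merged.sort()
        self.intervals = merged

    def intersect(self, lo: int, hi: int) -> "IntervalSet":
        out = IntervalSet()
        for s, e in self.intervals:
            if e < lo or s > hi:
                continue
            out.add(max(s, lo), min(e, hi))
        return out

    def gaps_within(self, lo: int, hi: int) -> "IntervalSet":
        """Sub-ranges of [lo, hi] not covered by this set."""
        out = IntervalSet()
        cursor = lo
        for s, e in self.intervals:
            if e < lo:
                continue
            if s > hi:
                break
            if s > cursor:
                out.add(cursor, min(s - 1, hi))
            cursor = max(cursor, e + 1)
            if cursor > hi:
                break
        if cursor <= hi:
            out.add(cursor, hi)
        return out


@dataclass
class CacheEntry:
    key: CacheKey
    held: IntervalSet = field(default_factory=IntervalSet)
    payloads: dict[tuple[int, int], object] = field(default_factory=dict)
    last_access: int = 0
    inserted_at: float = 0.0
    size_bytes: int = 0


def _default_size(payload) -> int:
    if isinstance(payload, (str, bytes)):
        return len(payload)
    raise ArgumentError(
        "cannot infer size_bytes for a non-text payload; pass size_bytes explicitly"
    )


def _payload_matches_tier(payload, tier_label: str) -> bool:
    # Opaque text payloads are trusted; model-object payloads are checked.
    from .das_protocol import DasFeature
    from .zoom import SummaryBin

    if isinstance(payload, (str, bytes)) or not isinstance(payload, (list, tuple)):
        return True
    want_bins = tier_label.startswith("bin:")
    for item in payload:
        if isinstance(item, SummaryBin) and not want_bins:
            return False
        if isinstance(item, DasFeature) and want_bins:
            return False
    return True


class IntervalCache:
    """LRU + TTL cache of per-(source, segment, tier) interval payloads."""

    def __init__(self):
        self.entries: dict[CacheKey, CacheEntry] = {}
        self._clock = 0  # monotonic recency counter

    # -- bookkeeping --------------------------------------------------

    def _tick(self) -> int:
        self._clock += 1
        return self._clock

    def total_size(self) -> int:
        return sum(e.size_bytes for e in self.entries.values())

    # -- operations ---------------------------------------------------

    def plan_fetch(self, key: CacheKey, want: tuple[int, int]) -> tuple[IntervalSet, IntervalSet]:
        """Split a wanted range into (covered, missing).

        ``covered`` and ``missing`` partition ``want`` exactly;
        ``covered`` is a subset of what the entry holds.  A hit (any
        coverage) bumps the entry's recency.
        """
        lo, hi = want
        if lo > hi:
            raise ArgumentError(f"bad wanted range [{lo}, {hi}]")
        entry = self.entries.get(key)
        if entry is None or not entry.held:
            empty = IntervalSet()
            empty_missing = IntervalSet([(lo, hi)])
            return empty, empty_missing
        covered = entry.held.intersect(lo, hi)
        missing = entry.held.gaps_within(lo, hi)
        if covered:
            entry.last_access = self._tick()
        return covered, missing

    def insert(
        self,
        key: CacheKey,
        interval: tuple[int, int],
        payload,
        now: float = 0.0,
        size_bytes: int | None = None,
    ) -> CacheEntry:
        """Record a fetched payload for an interval under a key."""
        lo, hi = interval
        if lo > hi:
            raise ArgumentError(f"bad interval [{lo}, {hi}]")
        if not _payload_matches_tier(payload, key.tier_label):
            raise ArgumentError(
                f"payload kind does not match tier {key.tier_label!r}"
            )
        size = _default_size(payload) if size_bytes is None else size_bytes
        entry = self.entries.get(key)
        if entry is None:
            entry = CacheEntry(key=key, inserted_at=now)
            self.entries[key] = entry
        entry.held.add(lo, hi)
        entry.payloads[(lo, hi)] = payload
        entry.size_bytes += size
        entry.last_access = self._tick()
        return entry

    def payloads_for(self, key: CacheKey, want: tuple[int, int]) -> list[object]:
        """Stored payloads whose intervals overlap the wanted range."""
        entry = self.entries.get(key)
        if entry is None:
            return []
        lo, hi = want
        return [
            p
            for (s, e), p in sorted(entry.payloads.items())
            if s <= hi and e >= lo
        ]

    def evict_to(
        self,
        budget_bytes: int,
        now: float = 0.0,
        ttl_seconds: float | None = None,
    ) -> list[CacheKey]:
        """Expire TTL-stale entries, then drop LRU entries down to budget.

        Eviction granularity is the whole entry (one key); returns the
        evicted keys in eviction order.  Surviving entries are untouched.
        """
        if budget_bytes < 0:
            raise ArgumentError("budget_bytes must be >= 0")
        evicted: list[CacheKey] = []
        if ttl_seconds is not None:
            for key in list(self.entries):
                if now - self.entries[key].inserted_at > ttl_seconds:
                    del self.entries[key]
                    evicted.append(key)
        if self.total_size() > budget_bytes:
            by_recency = sorted(self.entries.values(), key=lambda e: e.last_access)
            for entry in by_recency:
                if self.total_size() <= budget_bytes:
                    break
                del self.entries[entry.key]
                evicted.append(entry.key)
        return evicted
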