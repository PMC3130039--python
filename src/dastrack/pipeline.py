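"""Fetch-plan-reduce-render pipeline gluing the modules together.

One call per track: choose the zoom tier for the viewport, ask the
cache which sub-ranges are missing, fetch only those from the DAS
source, reduce each fetched payload to the tier's granularity before
storing it, and assemble the track for rendering.  Repeating a render
over a cached window fetches nothing — panning and zooming get cheaper
the longer a session runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cache import CacheKey, IntervalCache
from .das_protocol import DasClient, DasFeature, GenomicSegment, SequenceBlock
from .render import Track, TrackStyle
from .zoom import ZoomTier, choose_tier, reduce_payload


@dataclass
class FetchReport:
    """What one track build actually did on the wire."""

    tier_label: str = ""
    bases_fetched: int = 0
    requests_made: int = 0
    bases_from_cache: int = 0


def _align_to_bins(lo: int, hi: int, bin_width: int) -> tuple[int, int]:
    """Expand a range to the bin grid anchored at base 1, so summary
    payloads from different fetches share identical bin edges."""
    lo2 = ((lo - 1) // bin_width) * bin_width + 1
    hi2 = ((hi - 1) // bin_width + 1) * bin_width
    return lo2, hi2


def _cache_key(source_url: str, segment_id: str, tier: ZoomTier, type_filter: str | None) -> CacheKey:
    label = tier.label if type_filter is None else f"{tier.label}|{type_filter}"
    return CacheKey(source_url=source_url, segment_id=segment_id, tier_label=label)


def build_feature_track(
    client: DasClient,
    cache: IntervalCache,
    viewport,
    label: str,
    style: TrackStyle,
    type_filter: str | None = None,
    individual_threshold: float = 1000.0,
) -> tuple[Track, FetchReport]:
    """Assemble one annotation track for a viewport, fetching lazily.

    The payload is reduced to the tier *before* insertion, so the cache
    only ever holds data at the resolution the zoom level needs.
    """
    tier = choose_tier(viewport, individual_threshold)
    if tier.kind == "sequence":
        # annotations over a base-level window still render individually
        tier = ZoomTier(bases_per_pixel=tier.bases_per_pixel, kind="individual")
    key = _cache_key(client.source.base_url, viewport.segment_id, tier, type_filter)
    report = FetchReport(tier_label=key.tier_label)

    covered, missing = cache.plan_fetch(key, (viewport.start, viewport.stop))
    report.bases_from_cache = covered.total_bases()
    for lo, hi in missing:
        if tier.kind == "summary":
            lo, hi = _align_to_bins(lo, hi, tier.bin_width)
            cov2, miss2 = cache.plan_fetch(key, (lo, hi))
            pieces = list(miss2)
        else:
            pieces = [(lo, hi)]
        for p_lo, p_hi in pieces:
            doc = client.features(viewport.segment_id, p_lo, p_hi)
            feats = doc.features
            if type_filter is not None:
                feats = [f for f in feats if f.type_id == type_filter]
            window = GenomicSegment(viewport.segment_id, p_lo, p_hi)
            payload = reduce_payload(feats, tier, window)
            cache.insert(key, (p_lo, p_hi), payload, size_bytes=_payload_size(payload))
            report.bases_fetched += p_hi - p_lo + 1
            report.requests_made += 1

    merged = _collect(cache, key, viewport, tier)
    track = Track(
        label=label,
        payload=merged,
        style=style,
        tier=tier,
        segment_id=viewport.segment_id,
    )
    return track, report


def build_sequence_track(
    client: DasClient,
    cache: IntervalCache,
    viewport,
    label: str = "sequence",
    style: TrackStyle | None = None,
) -> tuple[Track, FetchReport]:
    """Assemble the residue track for a base-level viewport."""
    tier = choose_tier(viewport)
    style = style or TrackStyle(track_height=16, fg_color="#000000")
    key = _cache_key(client.source.base_url, viewport.segment_id, tier, None)
    report = FetchReport(tier_label=key.tier_label)

    covered, missing = cache.plan_fetch(key, (viewport.start, viewport.stop))
    report.bases_from_cache = covered.total_bases()
    for lo, hi in missing:
        block = client.sequence(viewport.segment_id, lo, hi)
        cache.insert(key, (lo, hi), block, size_bytes=len(block.residues))
        report.bases_fetched += hi - lo + 1
        report.requests_made += 1

    residues = _stitch_residues(cache, key, viewport)
    block = SequenceBlock(
        segment=GenomicSegment(viewport.segment_id, viewport.start, viewport.stop),
        residues=residues,
    )
    return (
        Track(label=label, payload=block, style=style, tier=tier, segment_id=viewport.segment_id),
        report,
    )


def _payload_size(payload) -> int:
    # Nominal per-record byte costs of the JSON interchange encoding.
    return sum(120 if isinstance(p, DasFeature) else 60 for p in payload)


def _collect(cache: IntervalCache, key: CacheKey, viewport, tier: ZoomTier):
    pieces = cache.payloads_for(key, (viewport.start, viewport.stop))
    if tier.kind == "summary":
        seen: dict[int, object] = {}
        for piece in pieces:
            for b in piece:
                if viewport.start <= b.bin_stop and b.bin_start <= viewport.stop:
                    seen.setdefault(b.bin_start, b)
        return [seen[k] for k in sorted(seen)]
    seen_f: dict[str, DasFeature] = {}
    for piece in pieces:
        for f in piece:
            if viewport.start <= f.stop and f.start <= viewport.stop:
                seen_f.setdefault(f.feature_id, f)
    return sorted(seen_f.values(), key=lambda f: (f.start, f.stop, f.feature_id))


def _stitch_residues(cache: IntervalCache, key: CacheKey, viewport) -> str:
    chars = ["N"] * viewport.span
    for block in cache.payloads_for(key, (viewport.start, viewport.stop)):
        seg = block.segment
        lo = max(seg.start, viewport.start)
        hi = min(seg.stop, viewport.stop)
        for pos in range(lo, hi + 1):
            chars[pos - viewport.start] = block.residues[pos - seg.start]
    return "".join(chars)
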