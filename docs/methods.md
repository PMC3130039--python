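# Methods

`dastrack` is a headless client for the Distributed Annotation System
(DAS 1.53): it fetches annotations on genomic reference sequences from
DAS sources over HTTP/XML, keeps them in an interval cache, reduces
them to a zoom-appropriate granularity, and draws multi-track genome
views to SVG or PNG. This note records the models, defaults and design
choices behind each stage, and what the synthetic test genome does and
does not show about real data.

## Coordinate model

All public coordinates are 1-based inclusive, exactly as DAS XML states
them. Segments (chromosomes) are addressed by id; a feature is an
interval `[start, stop]` with a type, optional score, strand
(`forward`/`reverse`/`unstranded`) and optional group membership. The
parsers enforce `1 <= start <= stop` and reject violating records
per-record — one corrupt feature produces an entry in the document's
error report without blanking the rest of the track. Unknown XML
elements and attributes are ignored, because real DAS servers vary in
dialect.

## Zoom tiers and payload reduction

The zoom measure is bases per pixel (bp/px = viewport span / pixel
width). Three tiers, with boundaries inclusive on the finer side:

| tier | condition | what is drawn |
|---|---|---|
| `sequence` | bp/px ≤ 1/8 | one letter per base (8 px minimum per letter) |
| `individual` | bp/px ≤ 1000 (configurable) | one glyph per feature |
| `summary` | bp/px > 1000 | histogram of per-bin counts |

A whole chromosome at screen width is orders of magnitude denser than
the base view, so above the individual tier features are reduced to
fixed-width `SummaryBin`s carrying a count, a coverage fraction (union
of feature bases over bin bases) and the maximum score. A feature
increments the count of *every* bin it overlaps rather than only its
midpoint bin: long features keep their visual mass at low zoom, and the
conservation law "Σ bin counts = Σ per-feature overlapped-bin counts"
holds exactly and is tested against a brute-force oracle.

Bin widths snap to the smallest power of 10 ≥ bp/px so that nearby zoom
levels share one cached tier. Bins tile the window contiguously from
its start; the last bin may be short rather than overhang. The
1/8 and 1000 bp/px thresholds are configuration defaults (there is no
canonical value); 1/8 gives letters 8 px of room, and 1000 bp/px keeps
individual glyphs at least a millipixel from degeneracy while bounding
the per-request feature count on dense tracks.

Payloads are reduced to the tier *before* they are cached or
serialized, so memory and traffic track what the screen can show. The
JSON interchange envelope (see `payload-schema.json`) is versioned,
canonical (sorted keys, fixed separators) and therefore
byte-deterministic; readers reject unknown versions.

## Interval cache

The cache is keyed by (source URL, segment, tier label); a summary tier
at bin width 1000 has label `bin:1000`, so different granularities are
independent entries and a summary is never fabricated from cached
individual features — cache contents always equal what the source
would have sent for that tier.

Per key, coverage is an `IntervalSet`: sorted, pairwise disjoint,
adjacency-merged 1-based intervals. `plan_fetch` partitions a wanted
range into covered and missing sub-ranges exactly (property-tested
against a per-base bitmap); a base once inserted is never reported
missing again, which is what makes repeated pans and zooms free.

Eviction is LRU over whole entries, driven by a monotonic counter
bumped on hits and inserts — no wall clock, so eviction order is
deterministic and testable. An optional TTL (default 300 s) expires
entries first, mirroring a short-lived proxy cache that still
propagates upstream data updates; the byte budget (default 256 MiB)
then removes least-recently-used entries. Sizes are byte lengths for
text payloads and a nominal per-record estimate (120 B/feature,
60 B/bin, the approximate JSON encoding cost) for model objects. The
cache is memory-only by design; there is no disk persistence.

## Rendering

The pixel x of base `pos` in a viewport `[start, stop]` of width `W` is
`floor((pos - start) * W / span)` — the left edge of the base's pixel
cell. The inverse uses a ceiling division and recovers every base
exactly whenever `span ≤ W`, keeping base-level views pixel-accurate.

Overlapping features are stacked by greedy first-fit "bumping":
features sorted by (start, stop, id), each placed in the lowest row
with `min_gap_px` clearance in pixel space. Because starts are sorted,
checking a row's rightmost occupant suffices; the test suite verifies
equality with an independent full-scan first-fit on 10⁴ features.

Glyphs: `box`, `line`, `tick`, `arrow` (orientation as a right- or
left-pointing head; narrow or unstranded arrows fall back to boxes) and
`histogram` for summary bins, normalized to the window's maximum count
so low-zoom views always show structure. Feature labels are drawn only
on glyphs ≥ 30 px wide. Glyphs are clipped to the viewport; rows that
no longer fit in the track height are dropped rather than overdrawn.

Drawing goes through one command list replayed by two backends: a
hand-written SVG text serializer (byte-deterministic by construction)
and Pillow for PNG. A composed view is a ruler (1/2/5 × 10ᵏ tick steps,
at most `target_ticks` ticks) above the tracks in declared order;
total height is exactly ruler + Σ track heights, and every track must
share the container's segment. Linked views (adjacent windows, same
center at another zoom) are pure viewport arithmetic
(`adjacent_viewport`, `zoomed_viewport`).

## Sessions

A session file is pretty-printed JSON with sorted keys and an explicit
format version (`session-schema.json`): viewers with viewports, track
lists and styles, link groups, and registered source URLs — never
data, so reloading re-fetches current annotations. Link invariants are
validated both before save and after load: zoom-linked viewers must
share segment and integer center; adjacency-linked viewers must abut
(`previous.stop + 1 == next.start`). Errors name the offending viewers
by index.

## Synthetic source

The mock DAS source generates a deterministic genome from a seed: per
segment, i.i.d. uniform A/C/G/T residues, then each feature class in
order. Class defaults model a small annotated assembly: 300 gene-like
spans (log-uniform lengths 2–200 kb, stranded), 1500 exon-like
intervals (0.1–2 kb, 60 % grouped in runs of 2–5 sharing a group id),
2000 scored repeat-like intervals and 500 single-base variants per
chromosome, on chr1 (1 Mb) and chr2 (0.5 Mb). Start positions are
uniform over valid placements; lengths are log-uniform (mean
`(b−a)/ln(b/a)`, checked by Monte Carlo against the closed form);
scores uniform on [0, 1].

The emitters produce DAS 1.53 documents (DASGFF features, sequence,
entry_points, sources with capability elements) that round-trip
losslessly through the parsers; the server answers the DAS request
grammar over local HTTP, returning features *overlapping* a range
(not contained in it) and DAS `ERRORSEGMENT` documents for unknown or
malformed segments.

What the mock does not emulate: non-uniform feature placement
(clustering, chromosome-end effects), inter-feature correlation,
realistic sequence composition, server-side type filtering, chunked or
compressed transfer, and network failure modes beyond an optional fixed
delay. Tests passing against the mock therefore demonstrate protocol,
cache, reduction and rendering correctness — not robustness to every
real server dialect.

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately compact
problems chosen to exercise every code path: segments of 10⁵–10⁶ bp,
10³–10⁴ features, 500-event cache histories, 100-session round trips
and 10⁴-draw distribution checks. Per-base oracles are restricted to
≤ 10⁵ bp segments where exhaustive bitmaps are exact and cheap.
Floating point enters only through bp/px, coverage fractions and
scores; all interval arithmetic is integer, and scores are serialized
with `repr` so XML and JSON round trips are exact.

## Known limitations

- DAS writeback, alignment/structure commands and stylesheet XML are
  not implemented; styles come from the package's own config file.
- Eviction granularity is whole cache entries; a giant single entry can
  only be evicted wholesale.
- Wiggle-style continuous signal is summarized only as per-bin count,
  coverage and max score.
- PNG text rendering uses Pillow's built-in bitmap font; PNG output is
  deterministic within an environment but not pixel-stable across
  Pillow versions (SVG output is byte-stable everywhere).
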