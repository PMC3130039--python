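# dastrack

A headless client for the **Distributed Annotation System (DAS)** — the
HTTP/XML protocol through which genome and annotation databases share
features on reference sequences — plus a track renderer that draws
those annotations from base level up to whole chromosomes.

Genome browsers face a brutal zoom range: a chromosome view must be
about a million times denser than the base-pair view and still be
informative, and dense tracks cannot be re-fetched on every pan.
`dastrack` packages the data-management core such a browser needs, as a
library and CLI:

- **Protocol** (`das_protocol`): DAS 1.53 request grammar; parsers for
  `sources`, `entry_points`, `sequence` and `features` documents;
  translation to a compact versioned JSON payload; GFF3 export. All
  coordinates are 1-based inclusive, as in DAS itself.
- **Zoom model** (`zoom`): the granularity tier for a viewport from its
  bases-per-pixel ratio — `sequence` (≤ 1/8 bp/px), `individual`
  (≤ 1000 bp/px), `summary` beyond — and reduction of feature lists to
  fixed-width bins (count, coverage fraction, max score) above the
  individual range, so data is only moved and stored at the resolution
  the screen needs.
- **Cache** (`cache`): an interval cache keyed by (source, segment,
  tier). `plan_fetch` splits a wanted range into covered and missing
  sub-ranges, so a base fetched once is never fetched again; LRU
  eviction to a byte budget with optional TTL expiry.
- **Renderer** (`render`): pixel mapping
  `x = ⌊(pos − start)·W / span⌋`, greedy first-fit bump layout, 1/2/5
  ruler ticks, five glyphs (box, line, arrow, tick, histogram), and
  composition of ruler + tracks into deterministic SVG or PNG.
- **Sessions** (`session`): the whole application state — viewers,
  viewports, tracks, styles, link groups — in a flat, diffable,
  versioned text file that stores URLs, not data.
- **Mock source** (`mock_source`): a seeded synthetic genome emitted as
  spec-conformant DAS XML, optionally over local HTTP, so the entire
  stack runs and tests offline.

## Worked example

Serve the default synthetic genome (two chromosomes, four annotation
classes) and browse it:

```sh
dastrack mock serve --port 8025 --seed 42 &

dastrack sources http://127.0.0.1:8025/das/mock
# http://127.0.0.1:8025/das/mock  dastrack mock source  MockAsm_1  entry_points,features,sequence,sources

dastrack entry-points http://127.0.0.1:8025/das/mock
# chr1  1000000
# chr2  500000
```

Render a 100 kb window with gene arrows and exon boxes:

```sh
dastrack render --source http://127.0.0.1:8025/das/mock \
    --segment chr1 --range 1,100000 --width 1000 \
    --track gene:arrow --track exon --out view.png --verbose
# tier: individual (100 bp/px)
# track gene: fetched 100000 bases in 1 requests (0 from cache)
# track exon: fetched 100000 bases in 1 requests (0 from cache)
# wrote view.png (200000 bases fetched)
```

100 000 bp across 1000 px is 100 bp/px — within the individual tier,
so every feature got its own glyph. Zoom out to the whole chromosome at
250 px and the tier changes:

```sh
dastrack render --source http://127.0.0.1:8025/das/mock \
    --segment chr1 --range 1,1000000 --width 250 \
    --track all:histogram --out chr1.svg --verbose
# tier: bin:10000 (4e+03 bp/px)
# track features: fetched 1000000 bases in 1 requests (0 from cache)
# wrote chr1.svg (1000000 bases fetched)
```

At 4000 bp/px the payload was reduced server-style to 10 kb summary
bins (the smallest power of 10 ≥ bp/px) and drawn as a density
histogram — 100 bins instead of 4300 features. Export a region as
GFF3, or snapshot the state as a session with a zoom-linked context
viewer and rebuild it later:

```sh
dastrack export gff3 --source http://127.0.0.1:8025/das/mock \
    --segment chr1 --range 1,50000 --out region.gff3
# wrote 207 features to region.gff3

dastrack session save --source http://127.0.0.1:8025/das/mock \
    --segment chr1 --range 450001,460000 --track exon \
    --overview-factor 20 --out demo.session
# saved session with 2 viewer(s) to demo.session

dastrack session render demo.session --out-dir imgs
# imgs/viewer-00.png
# imgs/viewer-01.png
```

The two images share a center: a 10 kb close-up and its 200 kb
context, one per viewer. Exit codes are stable: 1 usage, 2 network,
3 parse/version, 4 timeout.

See `docs/methods.md` for the models and defaults, and
`docs/payload-schema.json` / `docs/session-schema.json` /
`docs/mock-genome-spec.md` for the file formats.

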