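"""Deterministic synthetic DAS source, for building and testing offline.

Real DAS sources live on the network; this module stands in for them
with a seeded generator of chromosomes and annotations, emitters that
speak spec-conformant DAS 1.53 XML, and an optional local HTTP server.
The same genome spec can therefore drive pure-function round-trip tests
(emit -> parse), in-process transport tests, and true end-to-end runs
over a socket.

Determinism: one RNG stream per spec, consumed in a documented order —
for each segment its residues, then each feature class in declared
order (lengths, start positions, scores, orientations, group runs).
Identical seeds give field-identical output.  Adding or reordering a
class *does* shift later draws; stability across spec edits is not
promised, only stability for a fixed spec.
"""

from __future__ import annotations

import threading
import urllib.parse
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

import numpy as np
from lxml import etree

from .das_protocol import DasFeature, DasSourceRef, GenomicSegment
from .errors import ArgumentError, ValidationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MOCK_CAPABILITIES = ("entry_points", "features", "sequence", "sources")


@dataclass(frozen=True)
class FeatureClass:
    """One synthetic annotation class (e.g. gene-like, repeat-like)."""

    type_id: str
    count: int
    min_len: int
    max_len: int
    category: str | None = None
    method: str = "simulation"
    scored: bool = False
    stranded: bool = False
    grouped_fraction: float = 0.0

    def __post_init__(self):
        if self.count < 0:
            raise ArgumentError("count must be >= 0")
        if not (1 <= self.min_len <= self.max_len):
            raise ArgumentError("need 1 <= min_len <= max_len")
        if not (0.0 <= self.grouped_fraction <= 1.0):
            raise ArgumentError("grouped_fraction must be in [0, 1]")


# Default genome: a small two-chromosome assembly with the annotation
# mix a genomic DAS source typically serves — long stranded gene-like
# spans, shorter grouped exon-like intervals, scored repeat-like
# intervals, and single-base variant-like ticks.
DEFAULT_SEGMENTS = (("chr1", 1_000_000), ("chr2", 500_000))
DEFAULT_CLASSES = (
    FeatureClass("gene", count=300, min_len=2_000, max_len=200_000,
                 category="transcription", stranded=True),
    FeatureClass("exon", count=1_500, min_len=100, max_len=2_000,
                 category="transcription", stranded=True, grouped_fraction=0.6),
    FeatureClass("repeat", count=2_000, min_len=200, max_len=5_000,
                 category="repeat", scored=True),
    FeatureClass("variant", count=500, min_len=1, max_len=1,
                 category="variation", scored=True),
)


@dataclass(frozen=True)
class MockGenomeSpec:
    seed: int = 42
    segments: tuple[tuple[str, int], ...] = DEFAULT_SEGMENTS
    feature_classes: tuple[FeatureClass, ...] = DEFAULT_CLASSES
    title: str = "dastrack mock source"
    coordinate_system: str = "MockAsm_1"

    def __post_init__(self):
        for seg_id, length in self.segments:
            if length < 1:
                raise ArgumentError(f"segment {seg_id!r} length must be >= 1")


def spec_from_yaml(path: str) -> MockGenomeSpec:
    """Load a genome spec from YAML.

    Expected shape (all keys optional, defaults apply)::

        seed: 42
        segments: [[chr1, 1000000], [chr2, 500000]]
        feature_classes:
          - {type_id: gene, count: 300, min_len: 2000, max_len: 200000,
             stranded: true, scored: false, grouped_fraction: 0.0,
             category: transcription, method: simulation}
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        obj = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "seed" in obj:
        kwargs["seed"] = int(obj["seed"])
    if "segments" in obj:
        kwargs["segments"] = tuple((str(s), int(n)) for s, n in obj["segments"])
    if "feature_classes" in obj:
        kwargs["feature_classes"] = tuple(FeatureClass(**fc) for fc in obj["feature_classes"])
    for key in ("title", "coordinate_system"):
        if key in obj:
            kwargs[key] = str(obj[key])
    return MockGenomeSpec(**kwargs)


def sample_loguniform(rng: np.random.Generator, a: float, b: float, size: int) -> np.ndarray:
    """Log-uniform draws on [a, b]: exp of a uniform on [ln a, ln b].

    The closed-form mean is (b - a) / ln(b / a) for a < b.
    """
    if a <= 0 or b < a:
        raise ArgumentError("need 0 < a <= b")
    if a == b:
        return np.full(size, float(a))
    return np.exp(rng.uniform(np.log(a), np.log(b), size))


def loguniform_mean(a: float, b: float) -> float:
    if a == b:
        return float(a)
    return (b - a) / np.log(b / a)


def generate_annotation_set(
    spec: MockGenomeSpec,
) -> dict[str, tuple[list[DasFeature], str]]:
    """Generate the full synthetic genome: per-segment features + residues."""
    rng = np.random.default_rng(spec.seed)
    out: dict[str, tuple[list[DasFeature], str]] = {}
    for seg_id, seg_len in spec.segments:
        residues = _BASES[rng.integers(0, 4, seg_len)].tobytes().decode("ascii")
        features: list[DasFeature] = []
        for cls in spec.feature_classes:
            features.extend(_generate_class(rng, cls, seg_id, seg_len))
        out[seg_id] = (features, residues)
    return out


def _generate_class(
    rng: np.random.Generator, cls: FeatureClass, seg_id: str, seg_len: int
) -> list[DasFeature]:
    n = cls.count
    lengths = np.clip(
        np.rint(sample_loguniform(rng, cls.min_len, cls.max_len, n)).astype(np.int64),
        1,
        seg_len,
    )
    # start uniform over the valid placements [1, L - len + 1]
    starts = 1 + np.floor(rng.random(n) * (seg_len - lengths + 1)).astype(np.int64)
    scores = rng.random(n) if cls.scored else None
    strands = rng.integers(0, 2, n) if cls.stranded else None

    group_ids: list[str | None] = [None] * n
    if cls.grouped_fraction > 0:
        target = int(round(cls.grouped_fraction * n))
        assigned = 0
        group_no = 0
        while assigned < target:
            run = int(rng.integers(2, 6))  # gene-like runs of 2-5 members
            gid = f"{cls.type_id}_grp_{seg_id}_{group_no:04d}"
            for j in range(assigned, min(assigned + run, n)):
                group_ids[j] = gid
            assigned += run
            group_no += 1

    features = []
    for i in range(n):
        start = int(starts[i])
        stop = start + int(lengths[i]) - 1
        orientation = "unstranded"
        if strands is not None:
            orientation = "forward" if strands[i] == 0 else "reverse"
        features.append(
            DasFeature(
                feature_id=f"{cls.type_id}.{seg_id}.{i:05d}",
                label=f"{cls.type_id}-{i:05d}",
                type_id=cls.type_id,
                type_category=cls.category,
                method=cls.method,
                start=start,
                stop=stop,
                score=float(scores[i]) if scores is not None else None,
                orientation=orientation,
                group_id=group_ids[i],
            )
        )
    return features


# ---------------------------------------------------------------------------
# DAS XML emitters
# ---------------------------------------------------------------------------

def _xml(root: etree._Element) -> str:
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True).decode(
        "utf-8"
    )


def emit_features_xml(segment: GenomicSegment, features: list[DasFeature]) -> str:
    """DAS features (DASGFF) document for a segment window."""
    root = etree.Element("DASGFF")
    gff = etree.SubElement(root, "GFF", version="1.0")
    seg = etree.SubElement(
        gff,
        "SEGMENT",
        id=segment.segment_id,
        start=str(segment.start),
        stop=str(segment.stop),
    )
    if segment.version:
        seg.set("version", segment.version)
    for f in features:
        f_el = etree.SubElement(seg, "FEATURE", id=f.feature_id)
        if f.label is not None:
            f_el.set("label", f.label)
        type_el = etree.SubElement(f_el, "TYPE", id=f.type_id)
        if f.type_category is not None:
            type_el.set("category", f.type_category)
        type_el.text = f.type_id
        if f.method is not None:
            m = etree.SubElement(f_el, "METHOD", id=f.method)
            m.text = f.method
        etree.SubElement(f_el, "START").text = str(f.start)
        etree.SubElement(f_el, "END").text = str(f.stop)
        etree.SubElement(f_el, "SCORE").text = "-" if f.score is None else repr(f.score)
        etree.SubElement(f_el, "ORIENTATION").text = {
            "forward": "+",
            "reverse": "-",
            "unstranded": "0",
        }[f.orientation]
        etree.SubElement(f_el, "PHASE").text = "-" if f.phase is None else str(f.phase)
        for note in f.notes:
            etree.SubElement(f_el, "NOTE").text = note
        if f.link is not None:
            link = etree.SubElement(f_el, "LINK", href=f.link)
            link.text = f.link
        if f.group_id is not None:
            etree.SubElement(f_el, "GROUP", id=f.group_id)
    return _xml(root)


def emit_error_segment_xml(segment_id: str) -> str:
    """DAS error for a query on an unknown/unparseable segment."""
    root = etree.Element("DASGFF")
    gff = etree.SubElement(root, "GFF", version="1.0")
    etree.SubElement(gff, "ERRORSEGMENT", id=segment_id)
    return _xml(root)


def emit_sequence_xml(segment: GenomicSegment, residues: str) -> str:
    if len(residues) != segment.span:
        raise ValidationError(
            f"{len(residues)} residues for span {segment.span} of {segment.segment_id!r}"
        )
    root = etree.Element("DASSEQUENCE")
    seq = etree.SubElement(
        root,
        "SEQUENCE",
        id=segment.segment_id,
        start=str(segment.start),
        stop=str(segment.stop),
    )
    if segment.version:
        seq.set("version", segment.version)
    seq.text = residues
    return _xml(root)


def emit_entry_points_xml(spec: MockGenomeSpec, base_url: str) -> str:
    root = etree.Element("DASEP")
    ep = etree.SubElement(root, "ENTRY_POINTS", href=f"{base_url}/entry_points")
    for seg_id, length in spec.segments:
        el = etree.SubElement(ep, "SEGMENT", id=seg_id, start="1", stop=str(length))
        el.text = seg_id
    return _xml(root)


def emit_sources_xml(spec: MockGenomeSpec, base_url: str) -> str:
    root = etree.Element("SOURCES")
    src = etree.SubElement(root, "SOURCE", uri=base_url, title=spec.title)
    ver = etree.SubElement(src, "VERSION", uri=base_url)
    coord = etree.SubElement(ver, "COORDINATES", authority="Mock", version="1")
    coord.text = spec.coordinate_system
    for cap in MOCK_CAPABILITIES:
        etree.SubElement(
            ver, "CAPABILITY", type=f"das1:{cap}", query_uri=f"{base_url}/{cap}"
        )
    return _xml(root)


def source_ref(spec: MockGenomeSpec, base_url: str) -> DasSourceRef:
    """The DasSourceRef the emitted sources document describes."""
    return DasSourceRef(
        base_url=base_url,
        title=spec.title,
        capabilities=frozenset(MOCK_CAPABILITIES),
        coordinate_system=spec.coordinate_system,
    )


# ---------------------------------------------------------------------------
# Responder: shared command logic for transport + HTTP server
# ---------------------------------------------------------------------------

class MockResponder:
    """Answers DAS commands for one generated genome.

    Feature coordinates are held in per-segment numpy arrays so range
    queries (vectorized overlap tests) return exactly the features
    *overlapping* — not contained in — the requested range, matching
    common DAS server behaviour.
    """

    def __init__(self, spec: MockGenomeSpec, base_url: str = "http://mock.local/das/mock"):
        self.spec = spec
        self.base_url = base_url.rstrip("/")
        self.data = generate_annotation_set(spec)
        self.lengths = dict(spec.segments)
        self._index: dict[str, tuple[list[DasFeature], np.ndarray, np.ndarray]] = {}
        for seg_id, (features, _) in self.data.items():
            ordered = sorted(features, key=lambda f: (f.start, f.stop, f.feature_id))
            starts = np.fromiter((f.start for f in ordered), dtype=np.int64, count=len(ordered))
            stops = np.fromiter((f.stop for f in ordered), dtype=np.int64, count=len(ordered))
            self._index[seg_id] = (ordered, starts, stops)

    def features_overlapping(self, seg_id: str, start: int, stop: int) -> list[DasFeature]:
        ordered, starts, stops = self._index[seg_id]
        hit = np.nonzero((starts <= stop) & (stops >= start))[0]
        return [ordered[i] for i in hit]

    def respond(
        self,
        command: str,
        segment_id: str | None = None,
        start: int | None = None,
        stop: int | None = None,
    ) -> tuple[int, str]:
        """Return (HTTP status, XML body) for a DAS command."""
        if command == "sources":
            return 200, emit_sources_xml(self.spec, self.base_url)
        if command == "entry_points":
            return 200, emit_entry_points_xml(self.spec, self.base_url)
        if command not in ("features", "sequence"):
            return 400, emit_error_segment_xml(command)
        if segment_id is None:
            return 400, emit_error_segment_xml("missing-segment")
        if segment_id not in self.lengths:
            return 404, emit_error_segment_xml(segment_id)
        length = self.lengths[segment_id]
        lo = 1 if start is None else start
        hi = length if stop is None else stop
        if not (1 <= lo <= hi):
            return 400, emit_error_segment_xml(segment_id)
        hi = min(hi, length)
        window = GenomicSegment(segment_id=segment_id, start=lo, stop=hi)
        if command == "features":
            return 200, emit_features_xml(window, self.features_overlapping(segment_id, lo, hi))
        residues = self.data[segment_id][1][lo - 1 : hi]
        return 200, emit_sequence_xml(window, residues)

    def handle_url(self, url: str) -> tuple[int, str]:
        """Route a full request URL to :meth:`respond`."""
        parsed = urllib.parse.urlparse(url)
        command = parsed.path.rsplit("/", 1)[-1]
        query = urllib.parse.parse_qs(parsed.query)
        segment_id = start = stop = None
        if "segment" in query:
            raw = query["segment"][0]
            if ":" in raw:
                segment_id, _, rng = raw.partition(":")
                try:
                    s, _, e = rng.partition(",")
                    start, stop = int(s), int(e)
                except ValueError:
                    return 400, emit_error_segment_xml(raw)
            else:
                segment_id = raw
        return self.respond(command, segment_id, start, stop)


class MockTransport:
    """In-process transport serving a MockResponder (no sockets).

    Tracks every requested URL, so tests can assert cache behaviour
    ("second render fetches nothing").
    """

    def __init__(self, responder: MockResponder):
        self.responder = responder
        self.requests: list[str] = []

    def get(self, url: str) -> str:
        self.requests.append(url)
        status, body = self.responder.handle_url(url)
        if status != 200:
            from .errors import TransportError

            raise TransportError(f"mock source answered {status} for {url}:\n{body}")
        return body


# ---------------------------------------------------------------------------
# Local HTTP server
# ---------------------------------------------------------------------------

class MockDasServer:
    """The mock source over real HTTP on localhost.

    Use as a context manager::

        with MockDasServer(spec) as server:
            client = DasClient(source_ref(spec, server.base_url))
    """

    def __init__(self, spec: MockGenomeSpec, port: int = 0, delay_seconds: float = 0.0):
        self.spec = spec
        self._delay = delay_seconds
        responder_holder: dict = {}

        class Handler(BaseHTTPRequestHandler):
            def do_GET(handler):  # noqa: N805 - stdlib handler signature
                if self._delay:
                    import time

                    time.sleep(self._delay)
                status, body = responder_holder["responder"].handle_url(handler.path)
                payload = body.encode("utf-8")
                handler.send_response(status)
                handler.send_header("Content-Type", "text/xml")
                handler.send_header("Content-Length", str(len(payload)))
                handler.end_headers()
                handler.wfile.write(payload)

            def log_message(handler, *args):  # quiet
                pass

        self._httpd = ThreadingHTTPServer(("127.0.0.1", port), Handler)
        self.port = self._httpd.server_address[1]
        self.base_url = f"http://127.0.0.1:{self.port}/das/mock"
        self.responder = MockResponder(spec, base_url=self.base_url)
        responder_holder["responder"] = self.responder
        self._thread: threading.Thread | None = None

    def start(self) -> "MockDasServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def __enter__(self) -> "MockDasServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()
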