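"""DAS 1.53 protocol layer: requests, XML parsing, JSON payloads, GFF3.

The Distributed Annotation System (DAS) is a REST-like protocol for
sharing annotations on biological sequences: a *source* is an HTTP
endpoint answering a small set of commands (``sources``,
``entry_points``, ``sequence``, ``features``, ``types``) with XML
documents.  This module owns the translation between those documents and
the in-memory domain model, and between the model and the compact JSON
interchange payload used everywhere downstream of the protocol edge.

Coordinates are 1-based inclusive throughout the public model, exactly
as DAS XML states them; no half-open arithmetic crosses this module's
boundary.
"""

from __future__ import annotations

import json
import socket
import urllib.error
import urllib.request
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

from lxml import etree

from .errors import (
    ArgumentError,
    CapabilityError,
    DasParseError,
    DasSchemaError,
    PayloadVersionError,
    RecordValidationError,
    TransportError,
    TransportTimeout,
    ValidationError,
)

DAS_COMMANDS = frozenset(
    {"sources", "entry_points", "sequence", "features", "types", "stylesheet"}
)

PAYLOAD_FORMAT = "dastrack.payload"
PAYLOAD_VERSION = "1"

_ORIENT_FROM_XML = {"+": "forward", "-": "reverse", "0": "unstranded", ".": "unstranded"}
_ORIENT_TO_XML = {"forward": "+", "reverse": "-", "unstranded": "0"}
_ORIENT_TO_GFF = {"forward": "+", "reverse": "-", "unstranded": "."}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def normalize_base_url(url: str) -> str:
    """Strip trailing slashes so URL joining is idempotent."""
    url = url.strip()
    while url.endswith("/"):
        url = url[:-1]
    return url


@dataclass(frozen=True)
class DasSourceRef:
    """A registered DAS source: where it lives and what it can answer."""

    base_url: str
    title: str = ""
    capabilities: frozenset[str] = frozenset()
    coordinate_system: str = ""

    def __post_init__(self):
        if not self.base_url:
            raise ValidationError("DAS source base_url must be non-empty")
        object.__setattr__(self, "base_url", normalize_base_url(self.base_url))
        object.__setattr__(self, "capabilities", frozenset(self.capabilities))


@dataclass(frozen=True)
class GenomicSegment:
    """A named reference sequence window, 1-based inclusive."""

    segment_id: str
    start: int
    stop: int
    version: str | None = None
    total_length: int | None = None

    def __post_init__(self):
        if not (1 <= self.start <= self.stop):
            raise ValidationError(
                f"segment {self.segment_id!r}: need 1 <= start <= stop, "
                f"got [{self.start}, {self.stop}]"
            )
        if self.total_length is not None and self.stop > self.total_length:
            raise ValidationError(
                f"segment {self.segment_id!r}: stop {self.stop} exceeds "
                f"total length {self.total_length}"
            )

    @property
    def span(self) -> int:
        return self.stop - self.start + 1

    def overlaps(self, start: int, stop: int) -> bool:
        return self.start <= stop and start <= self.stop


@dataclass(frozen=True)
class DasFeature:
    """One annotated interval on a segment.

    ``orientation`` is one of ``forward`` / ``reverse`` / ``unstranded``
    (DAS ``+`` / ``-`` / ``0``); ``phase`` is the codon phase 0/1/2 when
    meaningful.  ``notes`` is a tuple so features stay hashable.
    """

    feature_id: str
    start: int
    stop: int
    type_id: str
    label: str | None = None
    type_category: str | None = None
    method: str | None = None
    score: float | None = None
    orientation: str = "unstranded"
    phase: int | None = None
    group_id: str | None = None
    link: str | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if not (1 <= self.start <= self.stop):
            raise ValidationError(
                f"feature {self.feature_id!r}: need 1 <= start <= stop, "
                f"got [{self.start}, {self.stop}]"
            )
        if self.score is not None and not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValidationError(f"feature {self.feature_id!r}: score must be finite")
        if self.orientation not in _ORIENT_TO_XML:
            raise ValidationError(
                f"feature {self.feature_id!r}: bad orientation {self.orientation!r}"
            )
        if self.phase not in (None, 0, 1, 2):
            raise ValidationError(f"feature {self.feature_id!r}: bad phase {self.phase!r}")
        object.__setattr__(self, "notes", tuple(self.notes))

    @property
    def span(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class SequenceBlock:
    """Residues for a segment window; length must equal the window span."""

    segment: GenomicSegment
    residues: str

    def __post_init__(self):
        if len(self.residues) != self.segment.span:
            raise ValidationError(
                f"sequence for {self.segment.segment_id!r}: {len(self.residues)} "
                f"residues for a span of {self.segment.span}"
            )


@dataclass
class FeatureDocument:
    """Result of parsing a DAS features document.

    Iterable as ``(segment, features)`` for convenience; ``errors``
    collects per-record validation failures (bad records are dropped,
    the rest of the document still parses).
    """

    segment: GenomicSegment
    features: list[DasFeature]
    errors: list[RecordValidationError] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        return iter((self.segment, self.features))


# ---------------------------------------------------------------------------
# Request construction
# ---------------------------------------------------------------------------

def build_request(
    source: DasSourceRef,
    command: str,
    segment_id: str | None = None,
    start: int | None = None,
    stop: int | None = None,
) -> str:
    """Build a DAS request URL: ``base/command?segment=ID:START,STOP``.

    A bare ``?segment=ID`` requests the whole segment; commands without a
    segment (``sources``, ``entry_points``) take no query at all.
    """
    if command not in DAS_COMMANDS:
        raise ArgumentError(f"unknown DAS command {command!r}")
    if source.capabilities and command not in source.capabilities:
        raise CapabilityError(
            f"source {source.base_url!r} does not advertise {command!r} "
            f"(has: {', '.join(sorted(source.capabilities))})"
        )
    if (start is not None or stop is not None) and segment_id is None:
        raise ArgumentError("a coordinate range requires a segment_id")
    if (start is None) != (stop is None):
        raise ArgumentError("start and stop must be given together")
    if start is not None and stop is not None and start > stop:
        raise ArgumentError(f"start {start} > stop {stop}")

    url = f"{source.base_url}/{command}"
    if segment_id is not None:
        if start is not None:
            url += f"?segment={segment_id}:{start},{stop}"
        else:
            url += f"?segment={segment_id}"
    return url


# ---------------------------------------------------------------------------
# XML parsing
# ---------------------------------------------------------------------------

def _parse_xml(xml_text: str | bytes) -> etree._Element:
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        return etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        line = exc.lineno if exc.lineno else None
        raise DasParseError(f"malformed DAS XML: {exc.msg}", line=line) from exc


def _segment_from_element(el: etree._Element) -> GenomicSegment:
    seg_id = el.get("id")
    if seg_id is None:
        raise DasSchemaError("SEGMENT element lacks an id attribute")
    start = int(el.get("start", "1"))
    stop_attr = el.get("stop")
    if stop_attr is None:
        raise DasSchemaError(f"SEGMENT {seg_id!r} lacks a stop attribute")
    return GenomicSegment(
        segment_id=seg_id,
        start=start,
        stop=int(stop_attr),
        version=el.get("version"),
    )


def _text(el: etree._Element | None) -> str | None:
    if el is None or el.text is None:
        return None
    stripped = el.text.strip()
    return stripped or None


def parse_features(xml_text: str | bytes) -> FeatureDocument:
    """Parse a DAS features (DASGFF) document.

    One :class:`DasFeature` per ``FEATURE`` element, document order
    preserved.  Unknown elements and attributes are ignored — DAS server
    dialects vary.  Records violating coordinate sanity are collected in
    ``errors`` instead of failing the whole document.
    """
    root = _parse_xml(xml_text)
    seg_el = root.find(".//SEGMENT")
    if seg_el is None:
        raise DasSchemaError("features document contains no SEGMENT element")
    segment = _segment_from_element(seg_el)

    features: list[DasFeature] = []
    errors: list[RecordValidationError] = []
    for f_el in seg_el.findall("FEATURE"):
        fid = f_el.get("id", "")
        try:
            start_el = f_el.find("START")
            end_el = f_el.find("END")
            if start_el is None or end_el is None:
                raise RecordValidationError(fid, "missing START or END")
            start = int(start_el.text)
            stop = int(end_el.text)
            type_el = f_el.find("TYPE")
            score_txt = _text(f_el.find("SCORE"))
            orient_txt = _text(f_el.find("ORIENTATION")) or "0"
            phase_txt = _text(f_el.find("PHASE"))
            group_el = f_el.find("GROUP")
            link_el = f_el.find("LINK")
            try:
                feature = DasFeature(
                    feature_id=fid,
                    label=f_el.get("label"),
                    type_id=(type_el.get("id") if type_el is not None else None) or "unknown",
                    type_category=type_el.get("category") if type_el is not None else None,
                    method=_text(f_el.find("METHOD"))
                    or (f_el.find("METHOD").get("id") if f_el.find("METHOD") is not None else None),
                    start=start,
                    stop=stop,
                    score=None if score_txt in (None, "-") else float(score_txt),
                    orientation=_ORIENT_FROM_XML.get(orient_txt, "unstranded"),
                    phase=None if phase_txt in (None, "-") else int(phase_txt),
                    group_id=group_el.get("id") if group_el is not None else None,
                    link=link_el.get("href") if link_el is not None else None,
                    notes=tuple(t for n in f_el.findall("NOTE") if (t := _text(n))),
                )
            except ValidationError as exc:
                raise RecordValidationError(fid, str(exc)) from exc
            features.append(feature)
        except RecordValidationError as exc:
            errors.append(exc)
    return FeatureDocument(segment=segment, features=features, errors=errors)


def parse_sources(xml_text: str | bytes) -> list[DasSourceRef]:
    """Parse a DAS ``sources`` document (or a legacy DSN listing).

    Capabilities come from ``CAPABILITY`` elements (``das1:`` prefixes
    stripped).  Legacy DSN entries advertise nothing, so they get the
    one command every annotation source must implement: ``features``.
    """
    root = _parse_xml(xml_text)
    refs: list[DasSourceRef] = []
    if root.tag == "DASDSN":
        for dsn in root.findall("DSN"):
            src = dsn.find("SOURCE")
            mapmaster = _text(dsn.find("MAPMASTER"))
            base = mapmaster or (src.get("id") if src is not None else None)
            if not base:
                continue
            refs.append(
                DasSourceRef(
                    base_url=base,
                    title=_text(src) or (src.get("id") if src is not None else ""),
                    capabilities=frozenset({"features"}),
                )
            )
        return refs

    for src in root.findall(".//SOURCE"):
        caps: set[str] = set()
        base_url: str | None = None
        coord = ""
        for ver in src.findall("VERSION"):
            for cap in ver.findall("CAPABILITY"):
                cap_type = cap.get("type", "")
                name = cap_type.split(":", 1)[-1]
                if name in DAS_COMMANDS:
                    caps.add(name)
                    query_uri = cap.get("query_uri")
                    if query_uri and base_url is None:
                        # query_uri points at base/command; strip the command
                        trimmed = normalize_base_url(query_uri)
                        if trimmed.endswith("/" + name):
                            trimmed = trimmed[: -(len(name) + 1)]
                        base_url = trimmed
            coord_el = ver.find("COORDINATES")
            if coord_el is not None and not coord:
                coord = (
                    _text(coord_el)
                    or " ".join(
                        v for v in (coord_el.get("authority"), coord_el.get("version")) if v
                    )
                )
        base_url = base_url or src.get("uri")
        if not base_url:
            continue
        refs.append(
            DasSourceRef(
                base_url=base_url,
                title=src.get("title", ""),
                capabilities=frozenset(caps),
                coordinate_system=coord,
            )
        )
    return refs


def parse_sequence(xml_text: str | bytes) -> SequenceBlock:
    """Parse a DAS sequence document into a :class:`SequenceBlock`.

    Residue case is preserved (soft-masked regions are lowercase);
    whitespace introduced by XML line wrapping is removed before the
    length check.
    """
    root = _parse_xml(xml_text)
    seq_el = root.find(".//SEQUENCE")
    if seq_el is None:
        raise DasSchemaError("sequence document contains no SEQUENCE element")
    segment = _segment_from_element(seq_el)
    residues = "".join((seq_el.text or "").split())
    if len(residues) != segment.span:
        raise ValidationError(
            f"sequence for {segment.segment_id!r} declares span {segment.span} "
            f"but carries {len(residues)} residues"
        )
    return SequenceBlock(segment=segment, residues=residues)


def parse_entry_points(xml_text: str | bytes) -> list[GenomicSegment]:
    """Parse a DAS entry_points document: the source's segments + lengths."""
    root = _parse_xml(xml_text)
    ep = root.find(".//ENTRY_POINTS")
    if ep is None:
        raise DasSchemaError("entry_points document contains no ENTRY_POINTS element")
    segments = []
    for el in ep.findall("SEGMENT"):
        seg = _segment_from_element(el)
        segments.append(replace(seg, total_length=seg.stop))
    return segments


# ---------------------------------------------------------------------------
# JSON interchange payload
# ---------------------------------------------------------------------------

def _feature_to_obj(f: DasFeature) -> dict:
    obj: dict = {"id": f.feature_id, "start": f.start, "stop": f.stop, "type": f.type_id}
    if f.label is not None:
        obj["label"] = f.label
    if f.type_category is not None:
        obj["category"] = f.type_category
    if f.method is not None:
        obj["method"] = f.method
    if f.score is not None:
        obj["score"] = f.score
    if f.orientation != "unstranded":
        obj["orientation"] = f.orientation
    if f.phase is not None:
        obj["phase"] = f.phase
    if f.group_id is not None:
        obj["group"] = f.group_id
    if f.link is not None:
        obj["link"] = f.link
    if f.notes:
        obj["notes"] = list(f.notes)
    return obj


def _feature_from_obj(obj: dict) -> DasFeature:
    return DasFeature(
        feature_id=obj["id"],
        start=obj["start"],
        stop=obj["stop"],
        type_id=obj["type"],
        label=obj.get("label"),
        type_category=obj.get("category"),
        method=obj.get("method"),
        score=obj.get("score"),
        orientation=obj.get("orientation", "unstranded"),
        phase=obj.get("phase"),
        group_id=obj.get("group"),
        link=obj.get("link"),
        notes=tuple(obj.get("notes", ())),
    )


def features_to_json(segment: GenomicSegment, payload: Sequence, tier) -> str:
    """Serialize a tier-appropriate payload to canonical JSON text.

    ``tier`` is a :class:`~dastrack.zoom.ZoomTier`.  Individual and
    sequence tiers carry features; summary tiers carry bins.  The
    envelope is versioned and keys are sorted, so serialization is
    byte-deterministic.  For a dense feature set the summary payload is
    strictly smaller than the individual one — data travels and is
    stored only at the resolution the zoom level needs.
    """
    from .zoom import SummaryBin  # local import to avoid a module cycle

    kind = "bins" if tier.kind == "summary" else "features"
    if kind == "bins":
        if any(not isinstance(p, SummaryBin) for p in payload):
            raise ArgumentError("summary tier requires SummaryBin payload")
        items = [
            {
                "start": b.bin_start,
                "stop": b.bin_stop,
                "count": b.count,
                "coverage": round(b.coverage_fraction, 6),
                **({"max_score": b.max_score} if b.max_score is not None else {}),
            }
            for b in payload
        ]
    else:
        if any(not isinstance(p, DasFeature) for p in payload):
            raise ArgumentError(f"{tier.kind} tier requires DasFeature payload")
        items = [_feature_to_obj(f) for f in payload]

    envelope = {
        "format": PAYLOAD_FORMAT,
        "version": PAYLOAD_VERSION,
        "segment": {"id": segment.segment_id, "start": segment.start, "stop": segment.stop},
        "tier": {
            "kind": tier.kind,
            "bases_per_pixel": tier.bases_per_pixel,
            **({"bin_width": tier.bin_width} if tier.bin_width is not None else {}),
        },
        "kind": kind,
        "payload": items,
    }
    return json.dumps(envelope, sort_keys=True, separators=(",", ":"))


def payload_from_json(text: str):
    """Parse payload JSON back into ``(segment, payload_list, tier)``.

    Rejects envelopes whose format-version string is unknown.
    """
    from .zoom import SummaryBin, ZoomTier

    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DasParseError(f"payload is not valid JSON: {exc}") from exc
    if obj.get("format") != PAYLOAD_FORMAT or obj.get("version") != PAYLOAD_VERSION:
        raise PayloadVersionError(
            f"unknown payload format/version: {obj.get('format')!r} {obj.get('version')!r}"
        )
    seg = obj["segment"]
    segment = GenomicSegment(segment_id=seg["id"], start=seg["start"], stop=seg["stop"])
    t = obj["tier"]
    tier = ZoomTier(
        bases_per_pixel=t["bases_per_pixel"], kind=t["kind"], bin_width=t.get("bin_width")
    )
    if obj["kind"] == "bins":
        payload = [
            SummaryBin(
                bin_start=b["start"],
                bin_stop=b["stop"],
                count=b["count"],
                coverage_fraction=b["coverage"],
                max_score=b.get("max_score"),
            )
            for b in obj["payload"]
        ]
    else:
        payload = [_feature_from_obj(o) for o in obj["payload"]]
    return segment, payload, tier


# ---------------------------------------------------------------------------
# GFF3 export
# ---------------------------------------------------------------------------

def _gff3_escape(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace("&", "%26")
        .replace(",", "%2C")
        .replace("\t", "%09")
        .replace("\n", "%0A")
    )


def export_gff3(features: Sequence[DasFeature], segment: GenomicSegment) -> str:
    """Write features as GFF3 text (1-based inclusive, like DAS itself)."""
    lines = ["##gff-version 3"]
    lines.append(
        f"##sequence-region {segment.segment_id} {segment.start} {segment.stop}"
    )
    for f in features:
        attrs = [f"ID={_gff3_escape(f.feature_id)}"]
        if f.label:
            attrs.append(f"Name={_gff3_escape(f.label)}")
        if f.group_id:
            attrs.append(f"group_id={_gff3_escape(f.group_id)}")
        for note in f.notes:
            attrs.append(f"Note={_gff3_escape(note)}")
        lines.append(
            "\t".join(
                [
                    segment.segment_id,
                    f.method or ".",
                    f.type_id,
                    str(f.start),
                    str(f.stop),
                    "." if f.score is None else repr(f.score),
                    _ORIENT_TO_GFF[f.orientation],
                    "." if f.phase is None else str(f.phase),
                    ";".join(attrs),
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Transport seam
# ---------------------------------------------------------------------------

class HttpTransport:
    """Fetch text over HTTP with a configurable timeout (default 30 s).

    The single seam through which the package touches the network, so
    tests can substitute :class:`CannedTransport`.  Timeouts raise the
    retryable :class:`~dastrack.errors.TransportTimeout`.
    """

    def __init__(self, timeout_seconds: float = 30.0):
        self.timeout_seconds = timeout_seconds

    def get(self, url: str) -> str:
        try:
            with urllib.request.urlopen(url, timeout=self.timeout_seconds) as resp:
                return resp.read().decode("utf-8")
        except socket.timeout as exc:
            raise TransportTimeout(f"timed out after {self.timeout_seconds}s: {url}") from exc
        except urllib.error.URLError as exc:
            if isinstance(exc.reason, socket.timeout):
                raise TransportTimeout(
                    f"timed out after {self.timeout_seconds}s: {url}"
                ) from exc
            raise TransportError(f"fetch failed: {url} ({exc})") from exc


class CannedTransport:
    """Test transport answering from a fixed ``url -> text`` mapping."""

    def __init__(self, responses: dict[str, str]):
        self.responses = dict(responses)
        self.requests: list[str] = []

    def get(self, url: str) -> str:
        self.requests.append(url)
        try:
            return self.responses[url]
        except KeyError:
            raise TransportError(f"no canned response for {url}") from None


class DasClient:
    """Thin command wrapper binding a source reference to a transport."""

    def __init__(self, source: DasSourceRef, transport=None):
        self.source = source
        self.transport = transport or HttpTransport()

    def _fetch(self, command: str, segment_id=None, start=None, stop=None) -> str:
        url = build_request(self.source, command, segment_id, start, stop)
        return self.transport.get(url)

    def features(self, segment_id: str, start: int | None = None, stop: int | None = None) -> FeatureDocument:
        return parse_features(self._fetch("features", segment_id, start, stop))

    def sequence(self, segment_id: str, start: int | None = None, stop: int | None = None) -> SequenceBlock:
        return parse_sequence(self._fetch("sequence", segment_id, start, stop))

    def entry_points(self) -> list[GenomicSegment]:
        return parse_entry_points(self._fetch("entry_points"))

    def sources(self) -> list[DasSourceRef]:
        return parse_sources(self._fetch("sources"))
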