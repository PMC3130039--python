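"""DAS request grammar, XML parsing, JSON payloads and GFF3 export."""

import json

import pytest

from dastrack.das_protocol import (
    CannedTransport,
    DasClient,
    DasFeature,
    DasSourceRef,
    GenomicSegment,
    build_request,
    export_gff3,
    features_to_json,
    parse_entry_points,
    parse_features,
    parse_sequence,
    parse_sources,
    payload_from_json,
)
from dastrack.errors import (
    ArgumentError,
    CapabilityError,
    DasParseError,
    DasSchemaError,
    PayloadVersionError,
    TransportError,
    ValidationError,
)
from dastrack.mock_source import (
    MockGenomeSpec,
    emit_features_xml,
    emit_sequence_xml,
    emit_sources_xml,
    generate_annotation_set,
    source_ref,
)
from dastrack.zoom import ZoomTier, choose_tier, summarize
from dastrack.render import Viewport

ALL_CAPS = frozenset({"sources", "entry_points", "sequence", "features", "types", "stylesheet"})


def _src(url="http://example.org/das/hg19"):
    return DasSourceRef(base_url=url, capabilities=ALL_CAPS)


class TestBuildRequest:
    @pytest.mark.parametrize(
        "url,command,seg,start,stop,expected",
        [
            (
                "http://example.org/das/hg19", "features", "1", 100, 200,
                "http://example.org/das/hg19/features?segment=1:100,200",
            ),
            (
                "http://example.org/das/hg19", "entry_points", None, None, None,
                "http://example.org/das/hg19/entry_points",
            ),
            # trailing-slash normalization is idempotent
            (
                "http://example.org/das/hg19/", "sequence", "X", None, None,
                "http://example.org/das/hg19/sequence?segment=X",
            ),
        ],
    )
    def test_request_grammar(self, url, command, seg, start, stop, expected):
        assert build_request(_src(url), command, seg, start, stop) == expected

    def test_unadvertised_command_rejected(self):
        src = DasSourceRef(base_url="http://x.org/das/s", capabilities=frozenset({"features"}))
        with pytest.raises(CapabilityError):
            build_request(src, "sequence", "1")

    def test_range_without_segment_rejected(self):
        with pytest.raises(ArgumentError):
            build_request(_src(), "features", None, 1, 10)

    def test_inverted_range_rejected(self):
        with pytest.raises(ArgumentError):
            build_request(_src(), "features", "1", 200, 100)


FEATURES_ONE = """<?xml version="1.0"?>
<DASGFF><GFF version="1.0">
  <SEGMENT id="chrT" start="1" stop="1000">
    <FEATURE id="f1"><TYPE id="exon">exon</TYPE>
      <START>5</START><END>10</END>
      <SCORE>-</SCORE><ORIENTATION>+</ORIENTATION><PHASE>-</PHASE>
    </FEATURE>
  </SEGMENT>
</GFF></DASGFF>"""


class TestParseFeatures:
    def test_single_feature_echo(self):
        segment, features = parse_features(FEATURES_ONE)
        assert segment.segment_id == "chrT"
        assert len(features) == 1
        f = features[0]
        assert (f.start, f.stop, f.type_id, f.orientation) == (5, 10, "exon", "forward")

    def test_empty_segment_gives_empty_list(self):
        xml = '<DASGFF><GFF><SEGMENT id="chrT" start="1" stop="99"/></GFF></DASGFF>'
        segment, features = parse_features(xml)
        assert features == []
        assert segment.stop == 99

    def test_mock_roundtrip_seed42(self, chr1_features, chr1_segment):
        sample = chr1_features[:100]
        doc = parse_features(emit_features_xml(chr1_segment, sample))
        assert doc.features == sample
        assert doc.errors == []

    def test_malformed_xml_names_line(self):
        with pytest.raises(DasParseError) as exc:
            parse_features("<DASGFF>\n<GFF>\n<oops\n")
        assert exc.value.line is not None

    def test_missing_segment_is_schema_error(self):
        with pytest.raises(DasSchemaError):
            parse_features("<DASGFF><GFF/></DASGFF>")

    def test_bad_record_collected_not_fatal(self):
        xml = FEATURES_ONE.replace(
            "</FEATURE>",
            "</FEATURE><FEATURE id=\"bad\"><TYPE id=\"exon\"/>"
            "<START>50</START><END>40</END></FEATURE>",
        )
        doc = parse_features(xml)
        assert len(doc.features) == 1  # good record survives
        assert len(doc.errors) == 1
        assert "bad" in str(doc.errors[0])

    def test_unknown_elements_ignored(self):
        xml = FEATURES_ONE.replace("<START>", "<FANCY custom='1'>x</FANCY><START>")
        _, features = parse_features(xml)
        assert len(features) == 1


class TestParseSources:
    def test_mock_sources_roundtrip(self, default_spec):
        base = "http://mock.local/das/mock"
        refs = parse_sources(emit_sources_xml(default_spec, base))
        assert refs == [source_ref(default_spec, base)]

    def test_two_sources(self):
        xml = """<SOURCES>
          <SOURCE uri="http://a.org/das/a" title="A">
            <VERSION uri="v"><CAPABILITY type="das1:features" query_uri="http://a.org/das/a/features"/></VERSION>
          </SOURCE>
          <SOURCE uri="http://b.org/das/b" title="B">
            <VERSION uri="v"><CAPABILITY type="das1:features" query_uri="http://b.org/das/b/features"/></VERSION>
          </SOURCE>
        </SOURCES>"""
        refs = parse_sources(xml)
        assert [r.base_url for r in refs] == ["http://a.org/das/a", "http://b.org/das/b"]

    def test_empty_document(self):
        assert parse_sources("<SOURCES/>") == []

    def test_legacy_dsn_listing(self):
        xml = """<DASDSN><DSN>
          <SOURCE id="hg19">Human</SOURCE>
          <MAPMASTER>http://x.org/das/hg19</MAPMASTER>
        </DSN></DASDSN>"""
        refs = parse_sources(xml)
        assert refs[0].base_url == "http://x.org/das/hg19"
        assert "features" in refs[0].capabilities


class TestParseSequence:
    def test_tiny_block(self):
        xml = '<DASSEQUENCE><SEQUENCE id="1" start="1" stop="4">ACGT</SEQUENCE></DASSEQUENCE>'
        block = parse_sequence(xml)
        assert block.residues == "ACGT"
        assert block.segment.span == 4

    def test_case_preserved(self):
        xml = '<DASSEQUENCE><SEQUENCE id="1" start="1" stop="4">AcgT</SEQUENCE></DASSEQUENCE>'
        assert parse_sequence(xml).residues == "AcgT"

    def test_length_mismatch_rejected(self):
        xml = '<DASSEQUENCE><SEQUENCE id="1" start="1" stop="4">ACG</SEQUENCE></DASSEQUENCE>'
        with pytest.raises(ValidationError):
            parse_sequence(xml)

    def test_mock_roundtrip_seed7(self):
        spec = MockGenomeSpec(seed=7, segments=(("chrS", 2_000),), feature_classes=())
        _, residues = generate_annotation_set(spec)["chrS"]
        seg = GenomicSegment("chrS", 1, 2_000)
        block = parse_sequence(emit_sequence_xml(seg, residues))
        assert block.residues == residues


class TestJsonPayload:
    def test_empty_payload_valid_json(self, chr1_segment):
        tier = ZoomTier(bases_per_pixel=10.0, kind="individual")
        obj = json.loads(features_to_json(chr1_segment, [], tier))
        assert obj["payload"] == []
        assert obj["kind"] == "features"

    def test_roundtrip_byte_identical(self, chr1_features, chr1_segment):
        tier = ZoomTier(bases_per_pixel=10.0, kind="individual")
        text = features_to_json(chr1_segment, chr1_features[:200], tier)
        segment, payload, tier2 = payload_from_json(text)
        assert payload == chr1_features[:200]
        assert features_to_json(segment, payload, tier2) == text

    def test_bins_roundtrip(self, chr1_features, chr1_segment):
        tier = ZoomTier(bases_per_pixel=2000.0, kind="summary", bin_width=10_000)
        bins = summarize(chr1_features, chr1_segment, 10_000)
        text = features_to_json(chr1_segment, bins, tier)
        _, payload, _ = payload_from_json(text)
        assert payload == bins

    def test_summary_payload_smaller_for_dense_set(self, chr1_features, chr1_segment):
        """Zoomed-out payloads shrink: data travels at the needed resolution."""
        ind_tier = ZoomTier(bases_per_pixel=100.0, kind="individual")
        sum_tier = ZoomTier(bases_per_pixel=5000.0, kind="summary", bin_width=5_000)
        individual = features_to_json(chr1_segment, chr1_features, ind_tier)
        bins = summarize(chr1_features, chr1_segment, 5_000)
        summary = features_to_json(chr1_segment, bins, sum_tier)
        assert len(summary.encode()) < len(individual.encode())

    def test_payload_tier_mismatch_rejected(self, chr1_features, chr1_segment):
        sum_tier = ZoomTier(bases_per_pixel=5000.0, kind="summary", bin_width=5_000)
        with pytest.raises(ArgumentError):
            features_to_json(chr1_segment, chr1_features[:5], sum_tier)

    def test_unknown_version_rejected(self, chr1_segment):
        tier = ZoomTier(bases_per_pixel=10.0, kind="individual")
        text = features_to_json(chr1_segment, [], tier).replace('"version":"1"', '"version":"99"')
        with pytest.raises(PayloadVersionError):
            payload_from_json(text)


class TestGff3:
    def test_empty_list_header_only(self, chr1_segment):
        text = export_gff3([], chr1_segment)
        lines = text.strip().split("\n")
        assert lines[0] == "##gff-version 3"
        assert all(line.startswith("#") for line in lines)

    def test_column_mapping(self, chr1_segment):
        f = DasFeature(feature_id="f1", start=5, stop=10, type_id="exon", orientation="forward")
        row = export_gff3([f], chr1_segment).strip().split("\n")[-1].split("\t")
        assert (row[3], row[4], row[6]) == ("5", "10", "+")

    def test_roundtrip_recovers_coordinates(self, chr1_features, chr1_segment):
        sample = chr1_features[:500]
        strand_map = {"+": "forward", "-": "reverse", ".": "unstranded"}
        recovered = []
        for line in export_gff3(sample, chr1_segment).strip().split("\n"):
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            recovered.append((int(cols[3]), int(cols[4]), strand_map[cols[6]], cols[2]))
        assert recovered == [(f.start, f.stop, f.orientation, f.type_id) for f in sample]


class TestClientTransport:
    def test_canned_transport_feeds_client(self, chr1_features, chr1_segment):
        spec_url = "http://example.org/das/mock"
        ref = DasSourceRef(base_url=spec_url, capabilities=frozenset({"features"}))
        url = build_request(ref, "features", "chr1", 1, 1_000_000)
        transport = CannedTransport({url: emit_features_xml(chr1_segment, chr1_features[:10])})
        client = DasClient(ref, transport)
        doc = client.features("chr1", 1, 1_000_000)
        assert doc.features == chr1_features[:10]
        assert transport.requests == [url]

    def test_missing_response_is_transport_error(self):
        ref = DasSourceRef(base_url="http://x.org/das/s", capabilities=frozenset({"features"}))
        client = DasClient(ref, CannedTransport({}))
        with pytest.raises(TransportError):
            client.features("chr1")


def test_coordinate_sanity_is_enforced_not_clamped():
    with pytest.raises(ValidationError):
        GenomicSegment("chr1", 10, 5)
    with pytest.raises(ValidationError):
        DasFeature(feature_id="f", start=0, stop=5, type_id="t")


def test_entry_points_parse(default_spec):
    from dastrack.mock_source import emit_entry_points_xml

    segs = parse_entry_points(emit_entry_points_xml(default_spec, "http://m/das/mock"))
    assert [(s.segment_id, s.total_length) for s in segs] == [("chr1", 1_000_000), ("chr2", 500_000)]
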