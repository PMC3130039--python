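"""Pixel mapping, bump layout, rulers, glyph rendering, composition."""

import pytest

from dastrack.das_protocol import DasFeature, GenomicSegment, SequenceBlock
from dastrack.errors import ArgumentError, ContainerError
from dastrack.render import (
    Track,
    TrackContainer,
    TrackStyle,
    Viewport,
    adjacent_viewport,
    assign_rows,
    compose_view,
    genome_to_pixel,
    pixel_to_genome,
    render_track,
    tick_marks,
    zoomed_viewport,
)
from dastrack.zoom import ZoomTier, choose_tier, summarize


def oracle_first_fit(features, viewport, min_gap_px):
    """Independent bump layout: per-row pixel-interval occupancy scan."""
    rows: list[list[tuple[int, int]]] = []
    result = {}
    for f in sorted(features, key=lambda f: (f.start, f.stop, f.feature_id)):
        x1 = genome_to_pixel(f.start, viewport)
        x2 = max(x1, genome_to_pixel(f.stop, viewport))
        for r, occupied in enumerate(rows):
            if all(x1 > b + min_gap_px or x2 + min_gap_px < a for a, b in occupied):
                occupied.append((x1, x2))
                result[f.feature_id] = r
                break
        else:
            rows.append([(x1, x2)])
            result[f.feature_id] = len(rows) - 1
    return result, len(rows)


class TestPixelMapping:
    def test_viewport_endpoints(self):
        vp = Viewport("chr1", 1, 1000, 1000)
        assert genome_to_pixel(1, vp) == 0
        assert genome_to_pixel(1000, vp) == 999

    def test_left_edge_formula(self):
        vp = Viewport("chr1", 1, 10, 100)
        assert genome_to_pixel(5, vp) == 40

    def test_positions_outside_viewport_map_outside(self):
        vp = Viewport("chr1", 100, 199, 100)
        assert genome_to_pixel(50, vp) < 0
        assert genome_to_pixel(300, vp) > 99

    @pytest.mark.parametrize("span,width", [(10, 100), (100, 100), (997, 1000), (3, 10)])
    def test_roundtrip_identity_when_span_fits(self, span, width):
        vp = Viewport("chr1", 11, 10 + span, width)
        for pos in range(vp.start, vp.stop + 1):
            assert pixel_to_genome(genome_to_pixel(pos, vp), vp) == pos


class TestViewportArithmetic:
    def test_adjacent_windows_abut(self):
        vp = Viewport("chr1", 1001, 2000, 500)
        nxt = adjacent_viewport(vp, "next")
        prv = adjacent_viewport(vp, "previous")
        assert (nxt.start, nxt.stop) == (2001, 3000)
        assert (prv.start, prv.stop) == (1, 1000)
        assert prv.stop + 1 == vp.start and vp.stop + 1 == nxt.start

    def test_zoomed_keeps_center(self):
        vp = Viewport("chr1", 4001, 6000, 500)
        out = zoomed_viewport(vp, 4.0)
        assert out.span == 8000
        assert abs(out.center - vp.center) <= 1


class TestAssignRows:
    def test_disjoint_features_share_row_zero(self):
        vp = Viewport("chr1", 1, 1000, 1000)
        feats = [
            DasFeature(feature_id=f"f{i}", start=100 * i + 1, stop=100 * i + 50, type_id="t")
            for i in range(5)
        ]
        layout = assign_rows(feats, vp, TrackStyle(min_gap_px=2))
        assert set(layout.row_of.values()) == {0}

    def test_mutual_overlap_stacks_three_rows(self):
        vp = Viewport("chr1", 1, 1000, 1000)
        feats = [
            DasFeature(feature_id=f"f{i}", start=100, stop=500, type_id="t") for i in range(3)
        ]
        layout = assign_rows(feats, vp, TrackStyle())
        assert sorted(layout.row_of.values()) == [0, 1, 2]
        assert layout.n_rows == 3

    @pytest.mark.parametrize("min_gap", [0, 2, 5])
    def test_matches_oracle_and_never_collides(self, dense_layout_features, min_gap):
        vp = Viewport("chr1", 1, 1_000_000, 1000)
        style = TrackStyle(min_gap_px=min_gap)
        layout = assign_rows(dense_layout_features, vp, style)
        oracle_rows, oracle_n = oracle_first_fit(dense_layout_features, vp, min_gap)
        assert layout.row_of == oracle_rows
        assert layout.n_rows == oracle_n
        # pairwise safety within each row
        by_row: dict[int, list] = {}
        for f in dense_layout_features:
            by_row.setdefault(layout.row_of[f.feature_id], []).append(f)
        for feats in by_row.values():
            extents = sorted(
                (genome_to_pixel(f.start, vp), max(genome_to_pixel(f.start, vp), genome_to_pixel(f.stop, vp)))
                for f in feats
            )
            for (_, prev_x2), (next_x1, _) in zip(extents, extents[1:]):
                assert next_x1 > prev_x2 + min_gap


class TestTickMarks:
    def test_round_span(self):
        step, positions = tick_marks(Viewport("chr1", 1, 1000, 1000), 10)
        assert step == 100
        assert positions == list(range(100, 1001, 100))

    def test_awkward_span_picks_smallest_valid_step(self):
        vp = Viewport("chr1", 1, 1234, 1000)
        # independent enumeration of the 1/2/5 ladder
        candidates = sorted(m * 10**k for k in range(5) for m in (1, 2, 5))
        expected = next(s for s in candidates if 1234 / s <= 10)
        step, positions = tick_marks(vp, 10)
        assert step == expected == 200
        assert positions == list(range(200, 1201, 200))

    def test_single_base_span(self):
        step, positions = tick_marks(Viewport("chr1", 7, 7, 100), 10)
        assert step == 1
        assert positions == [7]


class TestRenderTrack:
    def test_empty_payload_is_pure_background(self):
        vp = Viewport("chr1", 1, 1000, 200)
        style = TrackStyle(track_height=30, bg_color="#ffffff")
        layer = render_track([], vp, style, choose_tier(vp))
        img = layer.to_image()
        assert img.size == (200, 30)
        assert img.getcolors() == [(200 * 30, (255, 255, 255))]

    def test_single_box_pixel_extent_matches_mapping(self):
        vp = Viewport("chr1", 1, 1000, 1000)
        f = DasFeature(feature_id="f", start=401, stop=500, type_id="t")
        style = TrackStyle(glyph="box", fg_color="#000000", show_labels=False)
        img = render_track([f], vp, style, choose_tier(vp)).to_image()
        xs = [x for x in range(1000) for y in range(style.track_height)
              if img.getpixel((x, y)) != (255, 255, 255)]
        assert min(xs) == genome_to_pixel(401, vp) == 400
        assert max(xs) == 499

    def test_clipping_at_viewport_edges(self):
        vp = Viewport("chr1", 500, 1499, 100)
        f = DasFeature(feature_id="f", start=1, stop=5000, type_id="t")
        layer = render_track([f], vp, TrackStyle(show_labels=False), choose_tier(vp))
        for cmd in layer.commands:
            assert cmd[1] >= 0 and cmd[3] <= 99  # rect x0/x1 stay inside

    def test_identical_calls_give_identical_svg(self, chr1_features):
        vp = Viewport("chr1", 1, 50_000, 800)
        style = TrackStyle(glyph="arrow")
        a = render_track(chr1_features, vp, style, choose_tier(vp)).svg_elements(0)
        b = render_track(chr1_features, vp, style, choose_tier(vp)).svg_elements(0)
        assert a == b

    def test_histogram_draws_bars(self, chr1_features):
        vp = Viewport("chr1", 1, 1_000_000, 100)
        tier = choose_tier(vp)
        bins = summarize(chr1_features, GenomicSegment("chr1", 1, 1_000_000), tier.bin_width)
        layer = render_track(bins, vp, TrackStyle(glyph="histogram"), tier)
        assert any(cmd[0] == "rect" for cmd in layer.commands)

    def test_sequence_letters(self):
        vp = Viewport("chr1", 1, 10, 100)
        block = SequenceBlock(GenomicSegment("chr1", 1, 10), "ACGTACGTAC")
        layer = render_track(block, vp, TrackStyle(), choose_tier(vp))
        letters = [cmd[3] for cmd in layer.commands if cmd[0] == "text"]
        assert letters == list("ACGTACGTAC")

    def test_payload_tier_mismatch_rejected(self, chr1_features):
        vp = Viewport("chr1", 1, 1_000_000, 100)
        with pytest.raises(ArgumentError):
            render_track(chr1_features[:10], vp, TrackStyle(), choose_tier(vp))


class TestComposeView:
    def _tracks(self, chr1_features, vp):
        tier = choose_tier(vp)
        return [
            Track("genes", [f for f in chr1_features if f.type_id == "gene"][:50],
                  TrackStyle(track_height=40), tier, "chr1"),
            Track("exons", [f for f in chr1_features if f.type_id == "exon"][:50],
                  TrackStyle(track_height=60), tier, "chr1"),
        ]

    def test_zero_tracks_is_ruler_only(self):
        doc = compose_view(TrackContainer(viewport=Viewport("chr1", 1, 1000, 500)))
        assert doc.height == 20
        assert "<svg" in doc.to_svg()

    def test_height_is_additive(self, chr1_features):
        vp = Viewport("chr1", 1, 50_000, 800)
        doc = compose_view(TrackContainer(viewport=vp, tracks=self._tracks(chr1_features, vp)))
        assert doc.height == 20 + 40 + 60
        assert doc.to_image().size == (800, 120)

    def test_segment_mismatch_rejected(self, chr1_features):
        vp = Viewport("chr1", 1, 50_000, 800)
        tracks = self._tracks(chr1_features, vp)
        tracks[1].segment_id = "chr2"
        with pytest.raises(ContainerError):
            compose_view(TrackContainer(viewport=vp, tracks=tracks))

    def test_compose_is_byte_deterministic(self, chr1_features):
        vp = Viewport("chr1", 1, 50_000, 800)
        svg1 = compose_view(TrackContainer(viewport=vp, tracks=self._tracks(chr1_features, vp))).to_svg()
        svg2 = compose_view(TrackContainer(viewport=vp, tracks=self._tracks(chr1_features, vp))).to_svg()
        assert svg1.encode() == svg2.encode()
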