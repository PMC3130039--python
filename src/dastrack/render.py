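"""Track rendering: glyphs, bump layout, rulers, and view composition.

Instead of one document element per annotation, every feature is drawn
as a glyph straight onto an image — the approach that lets a browser
pan thousands of features by moving a single image.  Here the canvas is
a file: the same drawing commands render to deterministic SVG text or,
via Pillow, to PNG.

Pixel mapping: the pixel coordinate of a base is the left edge of its
pixel cell, ``x = floor((pos - start) * width / span)``.  This choice
makes the mapping exactly invertible at high zoom (span <= width), so
base-level views stay pixel-accurate.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field, replace
from typing import Sequence

from PIL import Image, ImageDraw

from .das_protocol import DasFeature, SequenceBlock
from .errors import ArgumentError, ContainerError
from .zoom import SummaryBin, ZoomTier

GLYPHS = ("box", "line", "arrow", "tick", "histogram")

LABEL_MIN_GLYPH_PX = 30  # labels only on glyphs wide enough to read
RULER_HEIGHT_PX = 20


# ---------------------------------------------------------------------------
# Geometry types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Viewport:
    """A segment window drawn at a fixed pixel width."""

    segment_id: str
    start: int
    stop: int
    pixel_width: int

    def __post_init__(self):
        if self.start > self.stop:
            raise ArgumentError(f"viewport start {self.start} > stop {self.stop}")
        if self.pixel_width < 1:
            raise ArgumentError("pixel_width must be >= 1")

    @property
    def span(self) -> int:
        return self.stop - self.start + 1

    @property
    def bases_per_pixel(self) -> float:
        return self.span / self.pixel_width

    @property
    def center(self) -> int:
        return (self.start + self.stop) // 2


@dataclass(frozen=True)
class TrackStyle:
    """How one track draws its payload."""

    glyph: str = "box"
    fg_color: str = "#1f3d99"
    bg_color: str = "#ffffff"
    track_height: int = 40
    row_height: int = 12
    min_gap_px: int = 2
    show_labels: bool = True

    def __post_init__(self):
        if self.glyph not in GLYPHS:
            raise ArgumentError(f"unknown glyph {self.glyph!r} (choose from {GLYPHS})")
        if self.track_height < 1 or self.row_height < 1:
            raise ArgumentError("heights must be >= 1")
        if self.min_gap_px < 0:
            raise ArgumentError("min_gap_px must be >= 0")


@dataclass
class TrackLayout:
    """Bump layout: which stacking row each feature occupies."""

    row_of: dict[str, int]
    n_rows: int


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

def genome_to_pixel(pos: int, viewport: Viewport) -> int:
    """Left pixel edge of a base's cell; unclamped (may fall outside)."""
    return (pos - viewport.start) * viewport.pixel_width // viewport.span


def pixel_to_genome(x: int, viewport: Viewport) -> int:
    """First base whose pixel cell starts at or after x.

    Exact inverse of :func:`genome_to_pixel` whenever span <= width.
    """
    span = viewport.span
    return viewport.start + (-((-x * span) // viewport.pixel_width))


def adjacent_viewport(viewport: Viewport, direction: str) -> Viewport:
    """The abutting next/previous window at the same zoom level."""
    span = viewport.span
    if direction == "next":
        return replace(viewport, start=viewport.stop + 1, stop=viewport.stop + span)
    if direction == "previous":
        new_start = max(1, viewport.start - span)
        return replace(viewport, start=new_start, stop=viewport.start - 1) if viewport.start > 1 else viewport
    raise ArgumentError(f"direction must be 'next' or 'previous', not {direction!r}")


def zoomed_viewport(viewport: Viewport, factor: float, total_length: int | None = None) -> Viewport:
    """Same center at span x factor (factor > 1 zooms out)."""
    if factor <= 0:
        raise ArgumentError("zoom factor must be positive")
    new_span = max(1, round(viewport.span * factor))
    center = viewport.center
    start = max(1, center - new_span // 2)
    stop = start + new_span - 1
    if total_length is not None and stop > total_length:
        stop = total_length
        start = max(1, stop - new_span + 1)
    return replace(viewport, start=start, stop=stop)


# ---------------------------------------------------------------------------
# Bump layout
# ---------------------------------------------------------------------------

def assign_rows(
    features: Sequence[DasFeature], viewport: Viewport, style: TrackStyle
) -> TrackLayout:
    """Greedy first-fit stacking so overlapping glyphs never collide.

    Features are taken in (start, stop, feature_id) order; each goes to
    the lowest row whose previous occupant ends at least ``min_gap_px``
    pixels to the left of the new glyph's start.
    """
    ordered = sorted(features, key=lambda f: (f.start, f.stop, f.feature_id))
    row_last_px: list[int] = []  # rightmost occupied pixel per row
    row_of: dict[str, int] = {}
    for f in ordered:
        x1 = genome_to_pixel(f.start, viewport)
        x2 = max(x1, genome_to_pixel(f.stop, viewport))
        placed = False
        for row, last in enumerate(row_last_px):
            if x1 > last + style.min_gap_px:
                row_of[f.feature_id] = row
                row_last_px[row] = x2
                placed = True
                break
        if not placed:
            row_of[f.feature_id] = len(row_last_px)
            row_last_px.append(x2)
    return TrackLayout(row_of=row_of, n_rows=len(row_last_px))


# ---------------------------------------------------------------------------
# Ruler
# ---------------------------------------------------------------------------

_TICK_MANTISSAS = (1, 2, 5)


def tick_marks(viewport: Viewport, target_ticks: int = 10) -> tuple[int, list[int]]:
    """Ruler step and positions: the smallest 1/2/5 x 10^k step giving
    at most ``target_ticks`` ticks across the viewport span."""
    if target_ticks < 2:
        raise ArgumentError("target_ticks must be >= 2")
    span = viewport.span
    step = None
    k = 0
    while step is None:
        for m in _TICK_MANTISSAS:
            candidate = m * 10**k
            if span / candidate <= target_ticks:
                step = candidate
                break
        k += 1
    first = ((viewport.start + step - 1) // step) * step
    positions = list(range(first, viewport.stop + 1, step))
    return step, positions


# ---------------------------------------------------------------------------
# Drawing primitives (dual-backend command list)
# ---------------------------------------------------------------------------

@dataclass
class Layer:
    """A rendered track band: a command list replayable to SVG or PNG.

    Commands: ("rect", x0, y0, x1, y1, color) with inclusive pixel
    corners, ("poly", points, color), ("text", x, y, string, color,
    anchor, size).  All x coordinates are already clipped to the layer.
    """

    width: int
    height: int
    bg_color: str
    commands: list = field(default_factory=list)

    def rect(self, x0: int, y0: int, x1: int, y1: int, color: str) -> None:
        if x1 < 0 or x0 > self.width - 1:
            return
        x0, x1 = max(0, x0), min(self.width - 1, x1)
        self.commands.append(("rect", x0, y0, x1, y1, color))

    def poly(self, points: list[tuple[int, int]], color: str) -> None:
        clipped = [(min(max(x, 0), self.width - 1), y) for x, y in points]
        self.commands.append(("poly", clipped, color))

    def text(self, x: int, y: int, s: str, color: str, anchor: str = "start", size: int = 10) -> None:
        self.commands.append(("text", min(max(x, 0), self.width - 1), y, s, color, anchor, size))

    # -- backends -----------------------------------------------------

    def to_image(self) -> Image.Image:
        img = Image.new("RGB", (self.width, self.height), self.bg_color)
        draw = ImageDraw.Draw(img)
        _replay_pil(draw, self.commands, 0)
        return img

    def svg_elements(self, y_offset: int) -> list[str]:
        out = [
            f'<rect x="0" y="{y_offset}" width="{self.width}" '
            f'height="{self.height}" fill="{self.bg_color}"/>'
        ]
        out.extend(_svg_commands(self.commands, y_offset))
        return out


def _replay_pil(draw: ImageDraw.ImageDraw, commands: list, dy: int) -> None:
    for cmd in commands:
        if cmd[0] == "rect":
            _, x0, y0, x1, y1, color = cmd
            draw.rectangle([x0, y0 + dy, x1, y1 + dy], fill=color)
        elif cmd[0] == "poly":
            _, points, color = cmd
            draw.polygon([(x, y + dy) for x, y in points], fill=color)
        elif cmd[0] == "text":
            _, x, y, s, color, anchor, size = cmd
            pil_anchor = {"start": "ls", "middle": "ms", "end": "rs"}[anchor]
            draw.text((x, y + dy), s, fill=color, anchor=pil_anchor)


def _svg_commands(commands: list, dy: int) -> list[str]:
    out = []
    for cmd in commands:
        if cmd[0] == "rect":
            _, x0, y0, x1, y1, color = cmd
            out.append(
                f'<rect x="{x0}" y="{y0 + dy}" width="{x1 - x0 + 1}" '
                f'height="{y1 - y0 + 1}" fill="{color}"/>'
            )
        elif cmd[0] == "poly":
            _, points, color = cmd
            pts = " ".join(f"{x},{y + dy}" for x, y in points)
            out.append(f'<polygon points="{pts}" fill="{color}"/>')
        elif cmd[0] == "text":
            _, x, y, s, color, anchor, size = cmd
            out.append(
                f'<text x="{x}" y="{y + dy}" fill="{color}" '
                f'font-family="monospace" font-size="{size}" '
                f'text-anchor="{anchor}">{html.escape(s)}</text>'
            )
    return out


# ---------------------------------------------------------------------------
# Track rendering
# ---------------------------------------------------------------------------

def render_track(
    payload,
    viewport: Viewport,
    style: TrackStyle,
    tier: ZoomTier,
    layout: TrackLayout | None = None,
) -> Layer:
    """Draw one track's payload into a :class:`Layer`.

    Individual/sequence tiers expect features (plus an optional
    precomputed bump layout); the summary tier expects bins and draws a
    count histogram normalized to the window maximum; the sequence tier
    additionally accepts a :class:`SequenceBlock` to letter the bases.
    Output is deterministic for fixed inputs.
    """
    layer = Layer(width=viewport.pixel_width, height=style.track_height, bg_color=style.bg_color)

    if tier.kind == "summary":
        if not all(isinstance(b, SummaryBin) for b in payload):
            raise ArgumentError("summary tier needs a SummaryBin payload")
        _draw_histogram(layer, payload, viewport, style)
        return layer

    if isinstance(payload, SequenceBlock):
        if tier.kind != "sequence":
            raise ArgumentError("residues can only be drawn at the sequence tier")
        _draw_sequence(layer, payload, viewport, style)
        return layer

    if not all(isinstance(f, DasFeature) for f in payload):
        raise ArgumentError(f"{tier.kind} tier needs a DasFeature payload")
    if layout is None:
        layout = assign_rows(payload, viewport, style)
    _draw_features(layer, payload, layout, viewport, style)
    return layer


def _feature_pixels(f: DasFeature, viewport: Viewport) -> tuple[int, int]:
    """Clipped inclusive pixel extent of a feature's glyph."""
    x1 = genome_to_pixel(max(f.start, viewport.start), viewport)
    x2 = max(x1, genome_to_pixel(min(f.stop, viewport.stop), viewport))
    return max(0, x1), min(viewport.pixel_width - 1, x2)


def _draw_features(layer, features, layout, viewport, style) -> None:
    max_rows = max(1, style.track_height // style.row_height)
    for f in sorted(features, key=lambda f: (f.start, f.stop, f.feature_id)):
        if not (f.start <= viewport.stop and f.stop >= viewport.start):
            continue
        row = layout.row_of.get(f.feature_id, 0)
        if row >= max_rows:
            continue  # overflow rows are dropped rather than overdrawn
        x1, x2 = _feature_pixels(f, viewport)
        y0 = row * style.row_height
        y1 = y0 + style.row_height - 2
        glyph = style.glyph
        if glyph == "tick":
            layer.rect(x1, y0, x1, y1, style.fg_color)
        elif glyph == "line":
            mid = (y0 + y1) // 2
            layer.rect(x1, mid, x2, mid, style.fg_color)
        elif glyph == "arrow" and f.orientation != "unstranded" and x2 - x1 >= 6:
            head = min(6, x2 - x1)
            mid = (y0 + y1) // 2
            if f.orientation == "forward":
                layer.rect(x1, y0, x2 - head, y1, style.fg_color)
                layer.poly([(x2 - head, y0), (x2, mid), (x2 - head, y1)], style.fg_color)
            else:
                layer.rect(x1 + head, y0, x2, y1, style.fg_color)
                layer.poly([(x1 + head, y0), (x1, mid), (x1 + head, y1)], style.fg_color)
        else:  # box, or arrow fallback when too narrow / unstranded
            layer.rect(x1, y0, x2, y1, style.fg_color)
        if style.show_labels and f.label and (x2 - x1 + 1) >= LABEL_MIN_GLYPH_PX:
            layer.text(x1 + 2, y1 - 1, f.label, style.bg_color, size=max(6, style.row_height - 4))


def _draw_histogram(layer, bins, viewport, style) -> None:
    max_count = max((b.count for b in bins), default=0)
    if max_count == 0:
        return
    h = style.track_height
    for b in bins:
        if b.count == 0:
            continue
        x1 = max(0, genome_to_pixel(max(b.bin_start, viewport.start), viewport))
        x2 = min(
            viewport.pixel_width - 1,
            max(x1, genome_to_pixel(min(b.bin_stop, viewport.stop), viewport)),
        )
        bar = max(1, round(b.count / max_count * (h - 2)))
        layer.rect(x1, h - 1 - bar, x2, h - 1, style.fg_color)


def _draw_sequence(layer, block: SequenceBlock, viewport: Viewport, style: TrackStyle) -> None:
    if viewport.bases_per_pixel > 1:
        raise ArgumentError("sequence rendering needs >= 1 px per base")
    seg = block.segment
    y_base = min(style.track_height - 3, style.row_height)
    for pos in range(max(viewport.start, seg.start), min(viewport.stop, seg.stop) + 1):
        letter = block.residues[pos - seg.start]
        x0 = genome_to_pixel(pos, viewport)
        x1 = genome_to_pixel(pos + 1, viewport) - 1
        layer.text((x0 + x1) // 2, y_base, letter, style.fg_color, anchor="middle")


# ---------------------------------------------------------------------------
# View composition
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """One track inside a container: a label, a payload, and a style."""

    label: str
    payload: object
    style: TrackStyle
    tier: ZoomTier
    segment_id: str | None = None  # checked against the container viewport


@dataclass
class TrackContainer:
    """Tracks sharing one region at one zoom level, drawn together."""

    viewport: Viewport
    tracks: list[Track] = field(default_factory=list)


@dataclass
class ImageDocument:
    """A composed view, serializable as SVG text or a PNG image."""

    width: int
    height: int
    layers: list[tuple[int, Layer]]  # (y offset, layer)
    overlay: Layer  # ruler + track labels, drawn on top

    def to_svg(self) -> str:
        parts = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{self.width}" '
            f'height="{self.height}" viewBox="0 0 {self.width} {self.height}">'
        ]
        for dy, layer in self.layers:
            parts.extend(layer.svg_elements(dy))
        parts.extend(_svg_commands(self.overlay.commands, 0))
        parts.append("</svg>")
        return "\n".join(parts) + "\n"

    def to_image(self) -> Image.Image:
        img = Image.new("RGB", (self.width, self.height), self.overlay.bg_color)
        draw = ImageDraw.Draw(img)
        for dy, layer in self.layers:
            draw.rectangle([0, dy, self.width - 1, dy + layer.height - 1], fill=layer.bg_color)
            _replay_pil(draw, layer.commands, dy)
        _replay_pil(draw, self.overlay.commands, 0)
        return img

    def save(self, path: str) -> None:
        if str(path).lower().endswith(".svg"):
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(self.to_svg())
        else:
            self.to_image().save(path, format="PNG")


def compose_view(
    container: TrackContainer,
    ruler_height: int = RULER_HEIGHT_PX,
    target_ticks: int = 10,
) -> ImageDocument:
    """Stack a ruler and the container's tracks into one document.

    Total height is the ruler plus the sum of track heights; every track
    must live on the container viewport's segment.
    """
    vp = container.viewport
    for t in container.tracks:
        if t.segment_id is not None and t.segment_id != vp.segment_id:
            raise ContainerError(
                f"track {t.label!r} is on segment {t.segment_id!r}, "
                f"container is on {vp.segment_id!r}"
            )

    total_height = ruler_height + sum(t.style.track_height for t in container.tracks)
    overlay = Layer(width=vp.pixel_width, height=total_height, bg_color="#ffffff")
    _draw_ruler(overlay, vp, ruler_height, target_ticks)

    layers: list[tuple[int, Layer]] = []
    y = ruler_height
    for t in container.tracks:
        layer = render_track(t.payload, vp, t.style, t.tier)
        layers.append((y, layer))
        if t.label:
            overlay.text(2, y + 8, t.label, "#444444", size=8)
        y += t.style.track_height
    return ImageDocument(width=vp.pixel_width, height=total_height, layers=layers, overlay=overlay)


def _draw_ruler(layer: Layer, vp: Viewport, height: int, target_ticks: int) -> None:
    baseline = height - 1
    layer.rect(0, baseline, vp.pixel_width - 1, baseline, "#000000")
    _, positions = tick_marks(vp, target_ticks)
    for pos in positions:
        x = genome_to_pixel(pos, vp)
        if 0 <= x < vp.pixel_width:
            layer.rect(x, baseline - 4, x, baseline, "#000000")
            layer.text(x, baseline - 6, _format_bp(pos), "#000000", anchor="middle", size=8)


def _format_bp(pos: int) -> str:
    if pos % 1_000_000 == 0 and pos >= 1_000_000:
        return f"{pos // 1_000_000}M"
    if pos % 1_000 == 0 and pos >= 1_000:
        return f"{pos // 1_000}k"
    return str(pos)
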