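"""Session persistence: the whole application state in a flat text file.

A session snapshots every viewer (its viewport, its tracks and their
styles, and how it is linked to other viewers) plus the registered
sources, as pretty-printed JSON with canonical key order — shareable,
diffable and stable byte-for-byte.  Sessions store source URLs, never
data: rebuilding a session re-fetches (or re-serves from the mock),
so a shared session file stays small and always shows current data.

Link roles tie viewers together: ``same_region_other_zoom`` viewers
keep a common segment and center at different zoom levels (a close-up
plus its context), ``adjacent_next`` / ``adjacent_previous`` viewers
extend a region with abutting windows at the same zoom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .das_protocol import DasSourceRef
from .errors import DasParseError, PayloadVersionError, ValidationError
from .render import TrackStyle, Viewport

SESSION_FORMAT = "dastrack.session"
SESSION_VERSION = "1"

LINK_ROLES = ("independent", "same_region_other_zoom", "adjacent_next", "adjacent_previous")


@dataclass(frozen=True)
class ViewerState:
    viewport: Viewport
    tracks: tuple[tuple[str, str, TrackStyle], ...] = ()  # (source_url, label, style)
    link_group: str | None = None
    link_role: str = "independent"

    def __post_init__(self):
        if self.link_role not in LINK_ROLES:
            raise ValidationError(f"unknown link_role {self.link_role!r}")
        if self.link_role != "independent" and not self.link_group:
            raise ValidationError(f"link_role {self.link_role!r} requires a link_group")
        object.__setattr__(self, "tracks", tuple(tuple(t) for t in self.tracks))


@dataclass(frozen=True)
class SessionState:
    viewers: tuple[ViewerState, ...] = ()
    registered_sources: tuple[DasSourceRef, ...] = ()
    format_version: str = SESSION_VERSION

    def __post_init__(self):
        object.__setattr__(self, "viewers", tuple(self.viewers))
        object.__setattr__(self, "registered_sources", tuple(self.registered_sources))


def validate_session(state: SessionState) -> None:
    """Check cross-viewer link-group invariants; raise naming offenders.

    Viewers are named by their position in the session (``viewer[i]``).
    """
    groups: dict[str, list[tuple[int, ViewerState]]] = {}
    for i, v in enumerate(state.viewers):
        if v.link_role != "independent" and v.link_group:
            groups.setdefault(v.link_group, []).append((i, v))

    for group, members in groups.items():
        sync = [(i, v) for i, v in members if v.link_role == "same_region_other_zoom"]
        if len(sync) > 1:
            (i0, v0) = sync[0]
            for i, v in sync[1:]:
                if v.viewport.segment_id != v0.viewport.segment_id:
                    raise ValidationError(
                        f"link group {group!r}: viewer[{i0}] and viewer[{i}] "
                        f"are zoom-linked but on different segments"
                    )
                if v.viewport.center != v0.viewport.center:
                    raise ValidationError(
                        f"link group {group!r}: viewer[{i0}] and viewer[{i}] "
                        f"are zoom-linked but have different centers "
                        f"({v0.viewport.center} vs {v.viewport.center})"
                    )
        for i, v in members:
            if v.link_role == "adjacent_next":
                if not any(
                    w.viewport.stop + 1 == v.viewport.start
                    and w.viewport.segment_id == v.viewport.segment_id
                    for j, w in members
                    if j != i
                ):
                    raise ValidationError(
                        f"link group {group!r}: viewer[{i}] claims adjacent_next "
                        f"but no group member abuts it on the left"
                    )
            elif v.link_role == "adjacent_previous":
                if not any(
                    v.viewport.stop + 1 == w.viewport.start
                    and w.viewport.segment_id == v.viewport.segment_id
                    for j, w in members
                    if j != i
                ):
                    raise ValidationError(
                        f"link group {group!r}: viewer[{i}] claims adjacent_previous "
                        f"but no group member abuts it on the right"
                    )


# ---------------------------------------------------------------------------
# (De)serialization
# ---------------------------------------------------------------------------

def _style_to_obj(s: TrackStyle) -> dict:
    return {
        "glyph": s.glyph,
        "fg_color": s.fg_color,
        "bg_color": s.bg_color,
        "track_height": s.track_height,
        "row_height": s.row_height,
        "min_gap_px": s.min_gap_px,
        "show_labels": s.show_labels,
    }


def _viewer_to_obj(v: ViewerState) -> dict:
    return {
        "viewport": {
            "segment_id": v.viewport.segment_id,
            "start": v.viewport.start,
            "stop": v.viewport.stop,
            "pixel_width": v.viewport.pixel_width,
        },
        "tracks": [
            {"source_url": src, "label": label, "style": _style_to_obj(style)}
            for src, label, style in v.tracks
        ],
        "link_group": v.link_group,
        "link_role": v.link_role,
    }


def save_session(state: SessionState) -> str:
    """Serialize a session to canonical flat text (validated first)."""
    validate_session(state)
    obj = {
        "format": SESSION_FORMAT,
        "format_version": state.format_version,
        "viewers": [_viewer_to_obj(v) for v in state.viewers],
        "registered_sources": [
            {
                "base_url": s.base_url,
                "title": s.title,
                "capabilities": sorted(s.capabilities),
                "coordinate_system": s.coordinate_system,
            }
            for s in state.registered_sources
        ],
    }
    return json.dumps(obj, sort_keys=True, indent=2) + "\n"


def load_session(text: str) -> SessionState:
    """Parse and re-validate a session file; inverse of save_session."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DasParseError(f"session file is not valid JSON: {exc}") from exc
    if not isinstance(obj, dict) or obj.get("format") != SESSION_FORMAT:
        raise DasParseError("not a session file (missing format marker)")
    version = obj.get("format_version")
    if version != SESSION_VERSION:
        raise PayloadVersionError(f"unknown session format_version {version!r}")

    try:
        viewers = tuple(
            ViewerState(
                viewport=Viewport(
                    segment_id=v["viewport"]["segment_id"],
                    start=v["viewport"]["start"],
                    stop=v["viewport"]["stop"],
                    pixel_width=v["viewport"]["pixel_width"],
                ),
                tracks=tuple(
                    (t["source_url"], t["label"], TrackStyle(**t["style"]))
                    for t in v.get("tracks", [])
                ),
                link_group=v.get("link_group"),
                link_role=v.get("link_role", "independent"),
            )
            for v in obj.get("viewers", [])
        )
        sources = tuple(
            DasSourceRef(
                base_url=s["base_url"],
                title=s.get("title", ""),
                capabilities=frozenset(s.get("capabilities", ())),
                coordinate_system=s.get("coordinate_system", ""),
            )
            for s in obj.get("registered_sources", [])
        )
    except (KeyError, TypeError) as exc:
        raise DasParseError(f"session file is structurally incomplete: {exc}") from exc

    state = SessionState(viewers=viewers, registered_sources=sources, format_version=version)
    validate_session(state)
    return state
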