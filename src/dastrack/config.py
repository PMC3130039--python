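"""Application configuration: tier thresholds, cache budgets, styles.

Config lives in one YAML file; every field has a shipped default, and
CLI flags override the file.  Per-category style overrides let an
administrator give, say, everything in the ``variation`` category a
tick glyph without touching individual tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .cache import DEFAULT_BUDGET_BYTES, DEFAULT_TTL_SECONDS
from .errors import ArgumentError, ValidationError
from .render import RULER_HEIGHT_PX, TrackStyle


@dataclass(frozen=True)
class AppConfig:
    individual_threshold_bpp: float = 1000.0
    cache_budget_bytes: int = DEFAULT_BUDGET_BYTES
    cache_ttl_seconds: float = DEFAULT_TTL_SECONDS
    http_timeout_seconds: float = 30.0
    output_format: str = "png"
    target_ticks: int = 10
    ruler_height: int = RULER_HEIGHT_PX
    default_style: TrackStyle = field(default_factory=TrackStyle)
    category_styles: tuple[tuple[str, TrackStyle], ...] = ()

    def __post_init__(self):
        for name in (
            "individual_threshold_bpp",
            "cache_budget_bytes",
            "cache_ttl_seconds",
            "http_timeout_seconds",
            "target_ticks",
            "ruler_height",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name} must be positive")
        if self.output_format not in ("png", "svg"):
            raise ValidationError("output_format must be 'png' or 'svg'")

    def style_for(self, category: str | None) -> TrackStyle:
        for cat, style in self.category_styles:
            if cat == category:
                return style
        return self.default_style


def _style_from_obj(obj: dict, base: TrackStyle) -> TrackStyle:
    known = {"glyph", "fg_color", "bg_color", "track_height", "row_height", "min_gap_px", "show_labels"}
    unknown = set(obj) - known
    if unknown:
        raise ArgumentError(f"unknown style keys: {sorted(unknown)}")
    return replace(base, **obj)


def load_config(path: str) -> AppConfig:
    """Read a YAML config file, filling unset fields from defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        obj = yaml.safe_load(fh) or {}
    if not isinstance(obj, dict):
        raise ArgumentError(f"config file {path} must contain a mapping")
    base = AppConfig()
    style = _style_from_obj(obj.pop("default_style", {}), base.default_style)
    cat_styles = tuple(
        (cat, _style_from_obj(s, style)) for cat, s in obj.pop("category_styles", {}).items()
    )
    scalar_fields = {
        "individual_threshold_bpp",
        "cache_budget_bytes",
        "cache_ttl_seconds",
        "http_timeout_seconds",
        "output_format",
        "target_ticks",
        "ruler_height",
    }
    unknown = set(obj) - scalar_fields
    if unknown:
        raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
    return AppConfig(default_style=style, category_styles=cat_styles, **obj)


def dump_default_config() -> str:
    """The full default configuration as YAML (for `config init`)."""
    cfg = AppConfig()
    s = cfg.default_style
    return yaml.safe_dump(
        {
            "individual_threshold_bpp": cfg.individual_threshold_bpp,
            "cache_budget_bytes": cfg.cache_budget_bytes,
            "cache_ttl_seconds": cfg.cache_ttl_seconds,
            "http_timeout_seconds": cfg.http_timeout_seconds,
            "output_format": cfg.output_format,
            "target_ticks": cfg.target_ticks,
            "ruler_height": cfg.ruler_height,
            "default_style": {
                "glyph": s.glyph,
                "fg_color": s.fg_color,
                "bg_color": s.bg_color,
                "track_height": s.track_height,
                "row_height": s.row_height,
                "min_gap_px": s.min_gap_px,
                "show_labels": s.show_labels,
            },
            "category_styles": {},
        },
        sort_keys=True,
    )
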