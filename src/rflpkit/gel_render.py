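"""Virtual agarose gel rendering of digest band patterns.

Migration follows the standard log-linear mobility model
``d = clamp(a - b * log10(length_bp), 0, 1)`` with ``d`` the relative
migration distance down the lane (0 = well, 1 = gel front): shorter
fragments migrate further, equal lengths co-migrate.  Output is either a
plain-text gel for terminals or a deterministic SVG 1.1 document
(byte-identical for identical input), with band thickness scaled by
multiplicity so co-migrating fragments show as a heavier band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "GelLane",
    "GelConfig",
    "DEFAULT_LADDER",
    "migration_distance",
    "render_gel_text",
    "render_gel_svg",
    "ladder_lane",
]

# 100 bp ladder steps plus 1.5 kb and the 1107 bp full-length marker:
# spans every fragment size the six-species panel produces (119-1107 bp).
DEFAULT_LADDER: tuple[int, ...] = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 1107, 1500)


@dataclass(frozen=True)
class GelLane:
    """One gel lane: a label and its bands as (length bp, multiplicity)."""

    label: str
    bands: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if any(length < 1 for length, _ in self.bands):
            raise ValueError(f"lane {self.label!r}: band lengths must be >= 1 bp")


@dataclass(frozen=True)
class GelConfig:
    """Migration constants and canvas geometry.

    Defaults a=3.0, b=0.9 place 100-1500 bp across the full lane height.
    """

    a: float = 3.0
    b: float = 0.9
    lane_width: int = 60
    lane_height: int = 360
    margin_top: int = 40
    margin_left: int = 20
    text_rows: int = 18


def migration_distance(length_bp: float, a: float = 3.0, b: float = 0.9) -> float:
    """Relative migration distance of a fragment, clamped to [0, 1]."""
    if length_bp < 1:
        raise ValueError(f"fragment length must be >= 1 bp, got {length_bp}")
    if b <= 0:
        raise ValueError("migration slope b must be > 0")
    return min(1.0, max(0.0, a - b * math.log10(length_bp)))


def ladder_lane(steps: Sequence[int] = DEFAULT_LADDER, label: str = "ladder") -> GelLane:
    return GelLane(label=label, bands=tuple((s, 1) for s in sorted(steps, reverse=True)))


def _check_lanes(lanes: Sequence[GelLane]) -> None:
    if not lanes:
        raise ValueError("at least one lane is required")


def render_gel_text(lanes: Sequence[GelLane], config: GelConfig = GelConfig()) -> str:
    """ASCII gel: one column per lane, '=' band marks ordered by migration."""
    _check_lanes(lanes)
    rows = config.text_rows
    width = max(12, max(len(l.label) for l in lanes) + 2)
    grid = [["".ljust(width) for _ in lanes] for _ in range(rows)]
    for j, lane in enumerate(lanes):
        for length, mult in lane.bands:
            d = migration_distance(length, config.a, config.b)
            r = min(rows - 1, int(round(d * (rows - 1))))
            mark = ("=" * min(3, mult)).ljust(3) + f" {length}"
            grid[r][j] = mark.ljust(width)
    header = "".join(l.label.ljust(width) for l in lanes)
    lines = [header, "-" * (width * len(lanes))]
    lines.extend("".join(row).rstrip() for row in grid)
    return "\n".join(lines) + "\n"


def render_gel_svg(lanes: Sequence[GelLane], config: GelConfig = GelConfig()) -> str:
    """SVG 1.1 gel image; a pure function of (lanes, config)."""
    _check_lanes(lanes)
    c = config
    width = c.margin_left * 2 + c.lane_width * len(lanes)
    height = c.margin_top + c.lane_height + 20
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" viewBox="0 0 {width} {height}">',
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="#1a1a2e"/>',
    ]
    for j, lane in enumerate(lanes):
        x0 = c.margin_left + j * c.lane_width
        cx = x0 + c.lane_width // 2
        parts.append(
            f'<text x="{cx}" y="{c.margin_top - 12}" fill="#cccccc" font-size="11" '
            f'font-family="monospace" text-anchor="middle">{_xml_escape(lane.label)}</text>'
        )
        parts.append(
            f'<rect x="{x0 + 6}" y="{c.margin_top}" width="{c.lane_width - 12}" '
            f'height="{c.lane_height}" fill="#16213e"/>'
        )
        for length, mult in sorted(lane.bands, reverse=True):
            d = migration_distance(length, c.a, c.b)
            y = c.margin_top + d * c.lane_height
            thickness = 2 + 2 * min(mult - 1, 3)  # heavier band for co-migration
            parts.append(
                f'<rect x="{x0 + 8}" y="{y - thickness / 2:.2f}" '
                f'width="{c.lane_width - 16}" height="{thickness}" fill="#e0e0e0">'
                f"<title>{length} bp x{mult}</title></rect>"
            )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
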