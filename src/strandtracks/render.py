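"""Scene composition and deterministic vector output (SVG, PDF, EPS).

Every track renderer lowers its payload to one flat list of drawing
primitives (the scene graph); SVG, PDF and EPS writers serialize that same
list, so the three formats are views of one canonical scene.  Output is
byte-deterministic: fixed float precision, fixed attribute order, no
timestamps — two renders of the same scene are identical bytes.

Display conventions: positive-strand signal above and negative-strand signal
below a central line; SNP lines colored green/red/black/orange for the
A/T/C/G alternate allele; insertions red, deletions blue; forward reads as
red right-pointing arrows, reverse reads blue left-pointing; pair connectors
solid green; splice connectors dashed.  Since static vector output has no
hover, the mouse-over content (read IDs, allele proportions and p-values,
InDel sequences) goes into a JSON sidecar keyed by element id.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

from .formats_io import BedRecord, GenomicInterval, WigInterval
from .read_layout import LayoutResult, PairGlyph
from .track_compute import (
    IndelTrackEntry,
    SnpCall,
    StrandCoverage,
    overlay_scale,
    wig_to_arrays,
)

logger = logging.getLogger("strandtracks")

SUPPORTED_FORMATS = ("svg", "pdf", "eps")

# Named palette; every color used anywhere in a scene must be listed here so
# the PDF/EPS writers can resolve it to RGB.
PALETTE: dict[str, tuple[int, int, int]] = {
    "green": (0, 128, 0),
    "red": (220, 20, 20),
    "black": (0, 0, 0),
    "orange": (255, 140, 0),
    "blue": (30, 60, 220),
    "gray": (128, 128, 128),
    "lightgray": (200, 200, 200),
    "darkgray": (80, 80, 80),
    "yellow": (230, 200, 0),
    "purple": (128, 0, 160),
    "teal": (0, 150, 150),
    "brown": (139, 90, 43),
    "white": (255, 255, 255),
}

OVERLAY_PALETTE = ("yellow", "green", "purple", "teal", "brown")

# Track geometry defaults (display units = px).
WIG_HALF_HEIGHT = 40
BED_ROW_HEIGHT = 14
SNP_TRACK_HEIGHT = 26
INDEL_TRACK_HEIGHT = 26
READ_ROW_HEIGHT = 7
TRACK_GAP = 14
LABEL_HEIGHT = 12
MARGIN = 4


@dataclass(frozen=True)
class StyleMap:
    """Resolved colors for every drawable kind; overridable per track."""

    allele_colors: dict = field(default_factory=lambda: {
        "A": "green", "T": "red", "C": "black", "G": "orange"})
    insertion_color: str = "red"
    deletion_color: str = "blue"
    forward_arrow: str = "red"
    reverse_arrow: str = "blue"
    pair_connector: str = "green"
    splice_dash: tuple[int, int] = (3, 3)
    wiggle_color: str = "darkgray"
    bed_color: str = "blue"
    overlay_palette: tuple[str, ...] = OVERLAY_PALETTE
    overlay_opacity: float = 0.5


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    color: str = "black"
    width: float = 1.0
    dash: tuple[int, int] | None = None
    opacity: float = 1.0
    cls: str = ""
    elem_id: str = ""


@dataclass(frozen=True)
class Rect:
    x: float
    y: float
    w: float
    h: float
    fill: str = "black"
    opacity: float = 1.0
    cls: str = ""
    elem_id: str = ""


@dataclass(frozen=True)
class Polygon:
    points: tuple[tuple[float, float], ...]
    fill: str = "black"
    opacity: float = 1.0
    cls: str = ""
    elem_id: str = ""


@dataclass(frozen=True)
class TextLabel:
    x: float
    y: float
    text: str
    size: float = 9.0
    color: str = "black"
    cls: str = ""


Primitive = Line | Rect | Polygon | TextLabel


@dataclass
class Group:
    """A named bundle of primitives (one per BED record, one per track)."""

    cls: str
    children: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Track payloads and Scene
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTrackPayload:
    records: list[BedRecord]
    name: str = "reference"
    kind: str = "reference"


@dataclass
class BedTrackPayload:
    records: list[BedRecord]
    name: str = "bed"
    kind: str = "bed"


@dataclass
class WiggleTrackPayload:
    """One or more signed wiggles; >1 member means an overlay on a shared scale."""

    members: list[list[WigInterval]]
    name: str = "wiggle"
    colors: tuple[str, ...] | None = None
    kind: str = "wiggle"


@dataclass
class SnpTrackPayload:
    calls: list[SnpCall]
    columns: dict = field(default_factory=dict)  # pos -> allele proportions for tooltips
    name: str = "snp"
    kind: str = "snp"


@dataclass
class IndelTrackPayload:
    entries: list[IndelTrackEntry]
    name: str = "indel"
    kind: str = "indel"


@dataclass
class ReadsTrackPayload:
    glyphs: list[PairGlyph]
    layout: LayoutResult
    name: str = "reads"
    max_rows: int = 50
    kind: str = "reads"


@dataclass
class Scene:
    window: GenomicInterval
    width_px: int
    tracks: list

    def __post_init__(self) -> None:
        if len(self.window) < 1 or self.width_px < 1:
            raise ValueError("scene needs a non-empty window and positive width")


# ---------------------------------------------------------------------------
# Coordinate transform
# ---------------------------------------------------------------------------


def genomic_to_pixel(window: GenomicInterval, width_px: int, pos: int | float) -> float:
    """Affine monotone map: window.start -> 0, window.end -> width_px.

    Positions outside the window are clipped (with a debug notice) so stray
    records never draw outside the canvas.
    """
    if pos < window.start or pos > window.end:
        logger.debug("position %s outside window %s:%d-%d; clipping",
                     pos, window.chrom, window.start, window.end)
        pos = min(max(pos, window.start), window.end)
    return (pos - window.start) * width_px / len(window)


# ---------------------------------------------------------------------------
# Per-track renderers: payload -> Group (primitives in local y, top = 0)
# ---------------------------------------------------------------------------


def _x(window: GenomicInterval, width: int, pos) -> float:
    return genomic_to_pixel(window, width, pos)


def render_bed_like_track(records: Sequence[BedRecord], window: GenomicInterval,
                          width: int, style: StyleMap, cls: str) -> tuple[Group, int]:
    """BED/reference records: exon boxes, intron connectors, strand marks.

    Records outside the window are excluded; each remaining record is one
    element group on its own row.
    """
    group = Group(cls=f"{cls}-track")
    visible = [r for r in records if r.interval.overlaps(window)]
    for row, rec in enumerate(visible):
        y = row * BED_ROW_HEIGHT
        mid = y + BED_ROW_HEIGHT / 2
        color = style.bed_color
        if rec.item_rgb is not None:
            color = _register_rgb(rec.item_rgb)
        sub = Group(cls=f"{cls}-record")
        x1 = _x(window, width, rec.interval.start)
        x2 = _x(window, width, rec.interval.end)
        exons = rec.exons if rec.blocks else [rec.interval]
        sub.children.append(Line(x1, mid, x2, mid, color=color, width=1.0,
                                 cls=f"{cls}-backbone"))
        for ex in exons:
            ex1 = _x(window, width, ex.start)
            ex2 = _x(window, width, ex.end)
            sub.children.append(Rect(ex1, y + 3, max(ex2 - ex1, 0.5),
                                     BED_ROW_HEIGHT - 6, fill=color,
                                     cls=f"{cls}-exon"))
        if rec.interval.strand in ("+", "-"):
            sub.children.append(TextLabel(min(x2 + 3, width - 8), mid + 3,
                                          rec.interval.strand, size=8,
                                          color=color, cls=f"{cls}-strand"))
        if rec.name:
            sub.children.append(TextLabel(max(x1, 2), y + BED_ROW_HEIGHT - 3,
                                          rec.name, size=8, color="darkgray",
                                          cls=f"{cls}-name"))
        group.children.append(sub)
    height = max(len(visible), 1) * BED_ROW_HEIGHT
    return group, height


def render_reference_track(records: Sequence[BedRecord], window: GenomicInterval,
                           width: int, style: StyleMap) -> tuple[Group, int]:
    return render_bed_like_track(records, window, width, style, "reference")


def _wiggle_polygon(pos_arr, neg_arr, window, width, center, half_h,
                    pos_max, neg_max, color, opacity, cls):
    """Step polygons above/below the central line from per-base arrays."""
    import numpy as np

    prims = []
    for arr, sign, vmax in ((pos_arr, -1, pos_max), (neg_arr, 1, neg_max)):
        if not np.any(arr):
            continue
        pts: list[tuple[float, float]] = []
        n = len(arr)
        scale = half_h / vmax if vmax > 0 else 0.0
        pts.append((_x(window, width, window.start), center))
        prev = 0.0
        for i in range(n):
            v = float(arr[i])
            if v != prev:
                xx = _x(window, width, window.start + i)
                pts.append((xx, center + sign * prev * scale))
                pts.append((xx, center + sign * v * scale))
                prev = v
        xend = _x(window, width, window.end)
        pts.append((xend, center + sign * prev * scale))
        pts.append((xend, center))
        prims.append(Polygon(tuple(pts), fill=color, opacity=opacity,
                             cls=cls))
    return prims


def render_wiggle_track(payload: WiggleTrackPayload, window: GenomicInterval,
                        width: int, style: StyleMap) -> tuple[Group, int]:
    """Signed wiggle(s): positive values above the central line, negative below.

    Overlay members share one y transform (one positive max, one negative
    max over all members) so equal heights mean equal values.
    """
    group = Group(cls="wiggle-track")
    height = 2 * WIG_HALF_HEIGHT
    center = float(WIG_HALF_HEIGHT)
    pos_max, neg_max = overlay_scale(payload.members, window)
    colors = payload.colors or (
        (style.wiggle_color,) if len(payload.members) == 1 else style.overlay_palette
    )
    opacity = style.overlay_opacity if len(payload.members) > 1 else 1.0
    for i, member in enumerate(payload.members):
        pos_arr, neg_arr = wig_to_arrays(member, window)
        color = colors[i % len(colors)]
        group.children.extend(_wiggle_polygon(
            pos_arr, neg_arr, window, width, center, WIG_HALF_HEIGHT - 2,
            pos_max, neg_max, color, opacity, "wig-poly"))
    group.children.append(Line(0, center, width, center, color="black",
                               width=1.0, cls="central-line"))
    group.children.append(TextLabel(2, 9, f"{payload.name}  [+{_fmt_scale(pos_max)}"
                                    f"/-{_fmt_scale(neg_max)}]",
                                    size=8, color="darkgray", cls="wig-scale"))
    return group, height


def _fmt_scale(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.1f}"


def render_snp_track(payload: SnpTrackPayload, window: GenomicInterval,
                     width: int, style: StyleMap, track_idx: int,
                     tooltips: dict) -> tuple[Group, int]:
    """One colored vertical line per SNP call; allele determines the color."""
    group = Group(cls="snp-track")
    for i, call in enumerate(payload.calls):
        if not (window.start <= call.pos < window.end):
            continue
        x = _x(window, width, call.pos + 0.5)
        eid = f"t{track_idx}-snp-{i}"
        group.children.append(Line(
            x, 4, x, SNP_TRACK_HEIGHT - 4,
            color=style.allele_colors[call.alt_base], width=1.5,
            cls="snp-line", elem_id=eid))
        tooltips[eid] = {
            "pos": call.pos + 1, "ref": call.ref_base, "alt": call.alt_base,
            "depth": call.depth, "var_count": call.var_count,
            "vaf": round(call.vaf, 4), "p_value": call.p_value,
            "proportions": payload.columns.get(call.pos),
        }
    return group, SNP_TRACK_HEIGHT


def render_indel_track(payload: IndelTrackPayload, window: GenomicInterval,
                       width: int, style: StyleMap, track_idx: int,
                       tooltips: dict) -> tuple[Group, int]:
    """Red (insertion) / blue (deletion) lines with sequence in the sidecar."""
    group = Group(cls="indel-track")
    for i, entry in enumerate(payload.entries):
        if not (window.start <= entry.position < window.end):
            continue
        eid = f"t{track_idx}-indel-{i}"
        if entry.is_insertion:
            x = _x(window, width, entry.position)
            color = style.insertion_color
            seq = entry.event.inserted_seq
            group.children.append(Line(x, 4, x, INDEL_TRACK_HEIGHT - 4,
                                       color=color, width=1.5,
                                       cls="indel-line", elem_id=eid))
        else:
            x1 = _x(window, width, entry.event.ref_start)
            x2 = _x(window, width, entry.event.ref_end)
            color = style.deletion_color
            seq = entry.event.deleted_seq
            mid = INDEL_TRACK_HEIGHT / 2
            group.children.append(Line(x1, mid, max(x2, x1 + 1), mid,
                                       color=color, width=2.0,
                                       cls="indel-line", elem_id=eid))
        tooltips[eid] = {
            "type": "insertion" if entry.is_insertion else "deletion",
            "pos": entry.position + 1, "sequence": seq, "support": entry.support,
        }
    return group, INDEL_TRACK_HEIGHT


def _segment_prims(glyph: PairGlyph, read, y_mid: float, window, width, style,
                   thickness: float) -> list:
    prims = []
    h = thickness
    for seg in read.segments:
        x1 = _x(window, width, seg.start)
        x2 = _x(window, width, seg.end)
        color = style.forward_arrow if read.arrow == "right" else style.reverse_arrow
        prims.append(Rect(x1, y_mid - h / 2, max(x2 - x1, 0.5), h, fill=color,
                          cls="read-segment"))
    # one arrowhead at the directional end of the read
    tip_seg = read.segments[-1] if read.arrow == "right" else read.segments[0]
    if read.arrow == "right":
        xt = _x(window, width, tip_seg.end)
        pts = ((xt, y_mid - 2.5 - h / 2), (xt + 4, y_mid), (xt, y_mid + 2.5 + h / 2))
        color = style.forward_arrow
    else:
        xt = _x(window, width, tip_seg.start)
        pts = ((xt, y_mid - 2.5 - h / 2), (xt - 4, y_mid), (xt, y_mid + 2.5 + h / 2))
        color = style.reverse_arrow
    prims.append(Polygon(pts, fill=color, cls="read-arrow"))
    for gap_start, gap_end in read.splice_connectors:
        x1 = _x(window, width, gap_start)
        x2 = _x(window, width, gap_end)
        prims.append(Line(x1, y_mid, x2, y_mid, color="darkgray", width=1.0,
                          dash=style.splice_dash, cls="splice-connector"))
    for mm in read.mismatch_marks:
        if not (window.start <= mm.ref_pos < window.end):
            continue
        x = _x(window, width, mm.ref_pos + 0.5)
        prims.append(Line(x, y_mid - h / 2 - 1, x, y_mid + h / 2 + 1,
                          color=style.allele_colors.get(mm.read_base, "gray"),
                          width=1.0, cls="mismatch-mark"))
    return prims


def render_reads_track(payload: ReadsTrackPayload, window: GenomicInterval,
                       width: int, style: StyleMap, track_idx: int,
                       tooltips: dict) -> tuple[Group, int]:
    """Aggregated read-pair glyphs packed in rows around the central line.

    Rows beyond ``max_rows`` per strand are clipped and announced with a
    "+k more rows" note rather than drawn.
    """
    group = Group(cls="reads-track")
    layout = payload.layout
    rows_pos = min(layout.n_rows_pos, payload.max_rows)
    rows_neg = min(layout.n_rows_neg, payload.max_rows)
    center = rows_pos * READ_ROW_HEIGHT + READ_ROW_HEIGHT
    height = center + rows_neg * READ_ROW_HEIGHT + READ_ROW_HEIGHT
    clipped = {"+": 0, "-": 0}
    for i, glyph in enumerate(payload.glyphs):
        row = layout.row_of(i)
        if row >= payload.max_rows:
            clipped[glyph.strand] += 1
            continue
        if glyph.strand == "+":
            y_mid = center - (row + 1) * READ_ROW_HEIGHT + READ_ROW_HEIGHT / 2
        else:
            y_mid = center + (row + 1) * READ_ROW_HEIGHT - READ_ROW_HEIGHT / 2
        thickness = float(glyph.thickness)
        eid = f"t{track_idx}-glyph-{i}"
        for read in (glyph.left_read, glyph.right_read):
            if read is None:
                continue
            group.children.extend(_segment_prims(glyph, read, y_mid, window,
                                                 width, style, thickness))
        pc = glyph.pair_connector
        if pc is not None:
            x1 = _x(window, width, pc[0])
            x2 = _x(window, width, pc[1])
            group.children.append(Line(x1, y_mid, x2, y_mid,
                                       color=style.pair_connector,
                                       width=1.0, cls="pair-connector",
                                       elem_id=eid))
        tooltips[eid] = {
            "read_ids": list(glyph.read_ids), "multiplicity": glyph.multiplicity,
            "strand": glyph.strand, "proper": glyph.proper, "mate": glyph.mate_label,
            "span": [glyph.span.chrom, glyph.span.start + 1, glyph.span.end],
        }
    group.children.append(Line(0, center, width, center, color="black",
                               width=1.0, cls="central-line"))
    for strand, n in clipped.items():
        if n:
            y = 8 if strand == "+" else height - 3
            extra = (layout.n_rows_pos if strand == "+" else layout.n_rows_neg) \
                - payload.max_rows
            group.children.append(TextLabel(2, y, f"+{extra} more rows ({n} glyphs)",
                                            size=8, color="gray",
                                            cls="overflow-note"))
    return group, height


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------


def _register_rgb(rgb: tuple[int, int, int]) -> str:
    name = f"rgb{rgb[0]}-{rgb[1]}-{rgb[2]}"
    PALETTE.setdefault(name, rgb)
    return name


def build_scene_graph(scene: Scene, style: StyleMap) -> tuple[list, int, dict]:
    """Lower every track to primitives; returns (flat groups, height, tooltips)."""
    groups: list[Group] = []
    tooltips: dict = {}
    y = MARGIN
    window, width = scene.window, scene.width_px
    for idx, payload in enumerate(scene.tracks):
        label = Group(cls="track-label")
        label.children.append(TextLabel(2, y + LABEL_HEIGHT - 3, payload.name,
                                        size=9, color="black", cls="track-name"))
        groups.append(_offset_group(label, 0))
        y += LABEL_HEIGHT
        if payload.kind == "reference":
            g, h = render_reference_track(payload.records, window, width, style)
        elif payload.kind == "bed":
            g, h = render_bed_like_track(payload.records, window, width, style, "bed")
        elif payload.kind == "wiggle":
            g, h = render_wiggle_track(payload, window, width, style)
        elif payload.kind == "snp":
            g, h = render_snp_track(payload, window, width, style, idx, tooltips)
        elif payload.kind == "indel":
            g, h = render_indel_track(payload, window, width, style, idx, tooltips)
        elif payload.kind == "reads":
            g, h = render_reads_track(payload, window, width, style, idx, tooltips)
        else:
            raise ValueError(f"unknown track payload kind {payload.kind!r}")
        groups.append(_offset_group(g, y))
        y += h + TRACK_GAP
    return groups, y + MARGIN, tooltips


def _offset_prim(p, dy: float):
    if isinstance(p, Line):
        return Line(p.x1, p.y1 + dy, p.x2, p.y2 + dy, p.color, p.width, p.dash,
                    p.opacity, p.cls, p.elem_id)
    if isinstance(p, Rect):
        return Rect(p.x, p.y + dy, p.w, p.h, p.fill, p.opacity, p.cls, p.elem_id)
    if isinstance(p, Polygon):
        return Polygon(tuple((x, yy + dy) for x, yy in p.points), p.fill,
                       p.opacity, p.cls, p.elem_id)
    if isinstance(p, TextLabel):
        return TextLabel(p.x, p.y + dy, p.text, p.size, p.color, p.cls)
    raise TypeError(type(p))


def _offset_group(g: Group, dy: float) -> Group:
    out = Group(cls=g.cls)
    for child in g.children:
        if isinstance(child, Group):
            out.children.append(_offset_group(child, dy))
        else:
            out.children.append(_offset_prim(child, dy))
    return out


# ---------------------------------------------------------------------------
# Serializers
# ---------------------------------------------------------------------------


def _f(x: float) -> str:
    return f"{x:.2f}"


def _color_css(name: str) -> str:
    r, g, b = PALETTE[name]
    return f"rgb({r},{g},{b})"


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
            .replace('"', "&quot;"))


def _svg_prim(p) -> str:
    if isinstance(p, Line):
        attrs = (f'x1="{_f(p.x1)}" y1="{_f(p.y1)}" x2="{_f(p.x2)}" y2="{_f(p.y2)}"'
                 f' stroke="{_color_css(p.color)}" stroke-width="{_f(p.width)}"')
        if p.dash:
            attrs += f' stroke-dasharray="{p.dash[0]},{p.dash[1]}"'
        if p.opacity != 1.0:
            attrs += f' stroke-opacity="{_f(p.opacity)}"'
        if p.cls:
            attrs += f' class="{p.cls}"'
        if p.elem_id:
            attrs += f' id="{p.elem_id}"'
        return f"<line {attrs}/>"
    if isinstance(p, Rect):
        attrs = (f'x="{_f(p.x)}" y="{_f(p.y)}" width="{_f(p.w)}" height="{_f(p.h)}"'
                 f' fill="{_color_css(p.fill)}"')
        if p.opacity != 1.0:
            attrs += f' fill-opacity="{_f(p.opacity)}"'
        if p.cls:
            attrs += f' class="{p.cls}"'
        if p.elem_id:
            attrs += f' id="{p.elem_id}"'
        return f"<rect {attrs}/>"
    if isinstance(p, Polygon):
        pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in p.points)
        attrs = f'points="{pts}" fill="{_color_css(p.fill)}"'
        if p.opacity != 1.0:
            attrs += f' fill-opacity="{_f(p.opacity)}"'
        if p.cls:
            attrs += f' class="{p.cls}"'
        if p.elem_id:
            attrs += f' id="{p.elem_id}"'
        return f"<polygon {attrs}/>"
    if isinstance(p, TextLabel):
        attrs = (f'x="{_f(p.x)}" y="{_f(p.y)}" font-size="{_f(p.size)}"'
                 f' font-family="Helvetica" fill="{_color_css(p.color)}"')
        if p.cls:
            attrs += f' class="{p.cls}"'
        return f"<text {attrs}>{_esc(p.text)}</text>"
    raise TypeError(type(p))


def _svg_group(g: Group, out: list[str], depth: int) -> None:
    pad = "  " * depth
    out.append(f'{pad}<g class="{g.cls}">')
    for child in g.children:
        if isinstance(child, Group):
            _svg_group(child, out, depth + 1)
        else:
            out.append("  " * (depth + 1) + _svg_prim(child))
    out.append(f"{pad}</g>")


def _to_svg(groups: list[Group], width: int, height: int) -> bytes:
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="rgb(255,255,255)"/>',
    ]
    for g in groups:
        _svg_group(g, out, 1)
    out.append("</svg>")
    return ("\n".join(out) + "\n").encode()


# --- PDF ---


def _pdf_color(name: str) -> tuple[float, float, float]:
    r, g, b = PALETTE[name]
    return r / 255.0, g / 255.0, b / 255.0


def _pdf_ops(p, height: int, alpha_names: dict[float, str]) -> str:
    """Content-stream operators for one primitive (y flipped to PDF space)."""
    def y(v: float) -> float:
        return height - v

    ops: list[str] = []
    alpha = getattr(p, "opacity", 1.0)
    ops.append(f"/{alpha_names[alpha]} gs")
    if isinstance(p, Line):
        r, g, b = _pdf_color(p.color)
        dash = f"[{p.dash[0]} {p.dash[1]}] 0 d" if p.dash else "[] 0 d"
        ops += [f"{r:.3f} {g:.3f} {b:.3f} RG", f"{p.width:.2f} w", dash,
                f"{p.x1:.2f} {y(p.y1):.2f} m {p.x2:.2f} {y(p.y2):.2f} l S"]
    elif isinstance(p, Rect):
        r, g, b = _pdf_color(p.fill)
        ops += [f"{r:.3f} {g:.3f} {b:.3f} rg",
                f"{p.x:.2f} {y(p.y + p.h):.2f} {p.w:.2f} {p.h:.2f} re f"]
    elif isinstance(p, Polygon):
        r, g, b = _pdf_color(p.fill)
        path = " ".join(
            f"{x:.2f} {y(yy):.2f} {'m' if i == 0 else 'l'}"
            for i, (x, yy) in enumerate(p.points))
        ops += [f"{r:.3f} {g:.3f} {b:.3f} rg", f"{path} f"]
    elif isinstance(p, TextLabel):
        r, g, b = _pdf_color(p.color)
        text = p.text.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")
        ops += [f"{r:.3f} {g:.3f} {b:.3f} rg",
                f"BT /F1 {p.size:.1f} Tf {p.x:.2f} {y(p.y):.2f} Td ({text}) Tj ET"]
    else:
        raise TypeError(type(p))
    return "\n".join(ops)


def _flatten(groups: list[Group]) -> list:
    flat: list = []

    def walk(g: Group) -> None:
        for child in g.children:
            if isinstance(child, Group):
                walk(child)
            else:
                flat.append(child)

    for g in groups:
        walk(g)
    return flat


def _to_pdf(groups: list[Group], width: int, height: int) -> bytes:
    prims = _flatten(groups)
    alphas = sorted({getattr(p, "opacity", 1.0) for p in prims} | {1.0})
    alpha_names = {a: f"GSa{i}" for i, a in enumerate(alphas)}
    content = "\n".join(_pdf_ops(p, height, alpha_names) for p in prims)
    stream = zlib.compress(content.encode(), 9)

    gstate_dict = " ".join(
        f"/{alpha_names[a]} <</Type /ExtGState /ca {a:.2f} /CA {a:.2f}>>"
        for a in alphas)
    objs = {
        1: "<</Type /Catalog /Pages 2 0 R>>",
        2: "<</Type /Pages /Kids [3 0 R] /Count 1>>",
        3: (f"<</Type /Page /Parent 2 0 R /MediaBox [0 0 {width} {height}] "
            "/Contents 4 0 R /Resources <</Font <</F1 5 0 R>> "
            f"/ExtGState <<{gstate_dict}>>>>>>"),
        5: "<</Type /Font /Subtype /Type1 /BaseFont /Helvetica>>",
    }
    buf = bytearray(b"%PDF-1.4\n")
    offsets = {}
    for num in (1, 2, 3, 4, 5):
        offsets[num] = len(buf)
        if num == 4:
            buf += (f"4 0 obj\n<</Length {len(stream)} /Filter /FlateDecode>>\n"
                    "stream\n").encode()
            buf += stream
            buf += b"\nendstream\nendobj\n"
        else:
            buf += f"{num} 0 obj\n{objs[num]}\nendobj\n".encode()
    xref_at = len(buf)
    buf += b"xref\n0 6\n0000000000 65535 f \n"
    for num in (1, 2, 3, 4, 5):
        buf += f"{offsets[num]:010d} 00000 n \n".encode()
    buf += (f"trailer\n<</Size 6 /Root 1 0 R>>\nstartxref\n{xref_at}\n"
            "%%EOF\n").encode()
    return bytes(buf)


# --- EPS ---


def _eps_prim(p, height: int) -> str:
    def y(v: float) -> float:
        return height - v

    if isinstance(p, Line):
        r, g, b = _pdf_color(p.color)
        dash = f"[{p.dash[0]} {p.dash[1]}] 0 setdash" if p.dash else "[] 0 setdash"
        return (f"{r:.3f} {g:.3f} {b:.3f} setrgbcolor {p.width:.2f} setlinewidth "
                f"{dash}\nnewpath {p.x1:.2f} {y(p.y1):.2f} moveto "
                f"{p.x2:.2f} {y(p.y2):.2f} lineto stroke")
    if isinstance(p, Rect):
        r, g, b = _pdf_color(p.fill)
        return (f"{r:.3f} {g:.3f} {b:.3f} setrgbcolor\n"
                f"newpath {p.x:.2f} {y(p.y + p.h):.2f} {p.w:.2f} {p.h:.2f} "
                "rectfill")
    if isinstance(p, Polygon):
        r, g, b = _pdf_color(p.fill)
        path = " ".join(
            f"{x:.2f} {y(yy):.2f} {'moveto' if i == 0 else 'lineto'}"
            for i, (x, yy) in enumerate(p.points))
        return (f"{r:.3f} {g:.3f} {b:.3f} setrgbcolor\nnewpath {path} closepath fill")
    if isinstance(p, TextLabel):
        r, g, b = _pdf_color(p.color)
        text = p.text.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")
        return (f"{r:.3f} {g:.3f} {b:.3f} setrgbcolor\n"
                f"/Helvetica findfont {p.size:.1f} scalefont setfont\n"
                f"{p.x:.2f} {y(p.y):.2f} moveto ({text}) show")
    raise TypeError(type(p))


def _to_eps(groups: list[Group], width: int, height: int) -> bytes:
    # PostScript has no transparency; overlay members draw opaque here.
    lines = [
        "%!PS-Adobe-3.0 EPSF-3.0",
        f"%%BoundingBox: 0 0 {width} {height}",
        "%%Pages: 1",
        "%%EndComments",
        "1 setlinecap 1 setlinejoin",
    ]
    for p in _flatten(groups):
        lines.append(_eps_prim(p, height))
    lines += ["showpage", "%%EOF"]
    return ("\n".join(lines) + "\n").encode()


def render_scene(scene: Scene, style: StyleMap | None = None,
                 fmt: str = "svg") -> tuple[bytes, dict]:
    """Serialize a scene; returns (document bytes, tooltip sidecar dict).

    Identical scenes yield byte-identical documents in every format; PDF and
    EPS are serializations of the same primitive list as the SVG.
    """
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    style = style or StyleMap()
    groups, height, tooltips = build_scene_graph(scene, style)
    height = int(height)
    if fmt == "svg":
        return _to_svg(groups, scene.width_px, height), tooltips
    if fmt == "pdf":
        return _to_pdf(groups, scene.width_px, height), tooltips
    return _to_eps(groups, scene.width_px, height), tooltips
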