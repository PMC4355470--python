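"""Scene composition and the SVG/PDF/EPS serializers."""

import re
import xml.etree.ElementTree as ET
import zlib

import pytest

from strandtracks.alignment_core import DeletionEvent, InsertionEvent
from strandtracks.formats_io import GenomicInterval, WigInterval, parse_bed_line
from strandtracks.read_layout import assign_rows
from strandtracks.render import (
    BedTrackPayload,
    IndelTrackPayload,
    Polygon,
    ReferenceTrackPayload,
    Scene,
    SnpTrackPayload,
    StyleMap,
    WiggleTrackPayload,
    build_scene_graph,
    genomic_to_pixel,
    render_reference_track,
    render_scene,
)
from strandtracks.track_compute import IndelTrackEntry, SnpCall
from .test_read_layout import singleton_glyph
from strandtracks.render import ReadsTrackPayload

WINDOW = GenomicInterval("chr1", 1000, 2000)


class TestGenomicToPixel:
    def test_boundaries_and_midpoint(self):
        assert genomic_to_pixel(WINDOW, 800, 1000) == 0.0
        assert genomic_to_pixel(WINDOW, 800, 2000) == 800.0
        assert genomic_to_pixel(WINDOW, 800, 1500) == 400.0

    def test_monotone(self):
        xs = [genomic_to_pixel(WINDOW, 640, p) for p in range(1000, 2001, 37)]
        assert xs == sorted(xs) and len(set(xs)) == len(xs)

    def test_outside_positions_clipped(self):
        assert genomic_to_pixel(WINDOW, 800, 900) == 0.0
        assert genomic_to_pixel(WINDOW, 800, 2100) == 800.0


def _svg_root(doc: bytes):
    return ET.fromstring(doc.decode())


def _count_class(root, cls):
    return sum(1 for e in root.iter() if e.get("class") == cls)


def _calls(n):
    return [SnpCall("chr1", 1100 + 50 * i, "A", "ACGT"[(i + 1) % 4], 40, 20,
                    0.5, 1e-6) for i in range(n)]


def _scene(tracks):
    return Scene(window=WINDOW, width_px=800, tracks=tracks)


class TestReferenceTrack:
    def test_two_exon_transcript_boxes_and_connector(self):
        line = "chr1\t1100\t1500\ttx\t0\t+\t1100\t1500\t0\t2\t100,100,\t0,300,"
        group, _ = render_reference_track([parse_bed_line(line)], WINDOW, 800,
                                          StyleMap())
        (rec,) = group.children
        boxes = [c for c in rec.children if c.cls == "reference-exon"]
        backbones = [c for c in rec.children if c.cls == "reference-backbone"]
        assert len(boxes) == 2 and len(backbones) == 1

    def test_out_of_window_record_excluded(self):
        recs = [parse_bed_line("chr1\t100\t900\tleft\t0\t+"),
                parse_bed_line("chr1\t1100\t1200\tin\t0\t+")]
        group, _ = render_reference_track(recs, WINDOW, 800, StyleMap())
        assert len(group.children) == 1

    def test_group_count_equals_visible_record_count(self):
        recs = [parse_bed_line(f"chr1\t{1000 + i * 50}\t{1040 + i * 50}\tg{i}\t0\t-")
                for i in range(7)]
        group, _ = render_reference_track(recs, WINDOW, 800, StyleMap())
        assert len(group.children) == 7


class TestRenderScene:
    def test_snp_element_count_matches_payload(self):
        doc, _ = render_scene(_scene([SnpTrackPayload(_calls(4))]))
        assert _count_class(_svg_root(doc), "snp-line") == 4

    def test_indel_element_count(self):
        entries = [IndelTrackEntry(InsertionEvent(1200, "TT"), 3),
                   IndelTrackEntry(DeletionEvent(1300, "GGG"), 2)]
        doc, _ = render_scene(_scene([IndelTrackPayload(entries)]))
        root = _svg_root(doc)
        assert _count_class(root, "indel-line") == 2

    def test_central_line_once_per_signed_track(self):
        wig = WiggleTrackPayload([[WigInterval("chr1", 1100, 1200, 5.0)]])
        glyphs = [singleton_glyph("+", 1100, 1200)]
        reads = ReadsTrackPayload(glyphs, assign_rows(glyphs))
        doc, _ = render_scene(_scene([wig, reads, SnpTrackPayload([])]))
        assert _count_class(_svg_root(doc), "central-line") == 2

    def test_read_segment_count_matches_glyph_segments(self):
        glyphs = [singleton_glyph("+", 1100, 1200, "a"),
                  singleton_glyph("-", 1300, 1400, "b")]
        reads = ReadsTrackPayload(glyphs, assign_rows(glyphs))
        doc, _ = render_scene(_scene([reads]))
        root = _svg_root(doc)
        assert _count_class(root, "read-segment") == 2
        assert _count_class(root, "read-arrow") == 2

    def test_byte_identical_determinism_all_formats(self):
        tracks = [SnpTrackPayload(_calls(3)),
                  WiggleTrackPayload([[WigInterval("chr1", 1100, 1300, 7.0)],
                                      [WigInterval("chr1", 1200, 1500, -4.0)]])]
        for fmt in ("svg", "pdf", "eps"):
            a, _ = render_scene(_scene(tracks), fmt=fmt)
            b, _ = render_scene(_scene(tracks), fmt=fmt)
            assert a == b, fmt

    def test_unsupported_format_lists_supported(self):
        with pytest.raises(ValueError, match="svg, pdf, eps"):
            render_scene(_scene([SnpTrackPayload([])]), fmt="png")

    def test_svg_is_well_formed_with_fixture_tracks(self, basic_reads,
                                                    basic_bundle):
        from strandtracks.read_layout import aggregate_duplicates, build_glyphs
        from strandtracks.track_compute import (compute_strand_coverage,
                                                coverage_to_wig)
        region = GenomicInterval("chrT", 900, 4100)
        cov = compute_strand_coverage(basic_reads, region, "fr_firststrand")
        glyphs = aggregate_duplicates(
            build_glyphs([r for r in basic_reads if r.pos < 4100],
                         "fr_firststrand"))
        scene = Scene(window=region, width_px=1000, tracks=[
            WiggleTrackPayload([coverage_to_wig(cov)]),
            ReadsTrackPayload(glyphs, assign_rows(glyphs)),
        ])
        doc, tooltips = render_scene(scene)
        root = _svg_root(doc)  # parses as XML
        # tooltip sidecar ids all exist in the document
        ids = {e.get("id") for e in root.iter() if e.get("id")}
        assert set(tooltips) <= ids | set()
        assert _count_class(root, "central-line") == 2


class TestWigglePolygons:
    def test_values_never_cross_central_line(self):
        wig = WiggleTrackPayload([
            [WigInterval("chr1", 1100, 1300, 9.0),
             WigInterval("chr1", 1400, 1600, -5.0)]])
        groups, _, _ = build_scene_graph(_scene([wig]), StyleMap())
        polys = [p for g in groups for p in _flatten(g)
                 if isinstance(p, Polygon) and p.cls == "wig-poly"]
        assert len(polys) == 2
        # the two polygons sit on opposite sides of one shared baseline
        base0 = polys[0].points[0][1]
        base1 = polys[1].points[0][1]
        assert base0 == base1
        assert all(y <= base0 for _, y in polys[0].points)   # positive above
        assert all(y >= base1 for _, y in polys[1].points)   # negative below

    def test_overlay_members_share_transform(self):
        # equal values in different members must reach equal heights
        m1 = [WigInterval("chr1", 1100, 1200, 10.0)]
        m2 = [WigInterval("chr1", 1300, 1400, 10.0),
              WigInterval("chr1", 1450, 1500, 20.0)]
        wig = WiggleTrackPayload([m1, m2])
        groups, _, _ = build_scene_graph(_scene([wig]), StyleMap())
        polys = [p for g in groups for p in _flatten(g)
                 if isinstance(p, Polygon) and p.cls == "wig-poly"]
        h = [max(y for _, y in p.points) - min(y for _, y in p.points)
             for p in polys]
        # member 2's 20 is the shared max; member 1's 10 reaches half of it
        assert h[0] == pytest.approx(h[1] / 2)


def _flatten(group):
    for child in group.children:
        if hasattr(child, "children"):
            yield from _flatten(child)
        else:
            yield child


class TestPdfEps:
    def test_pdf_structure_and_xref(self):
        doc, _ = render_scene(_scene([SnpTrackPayload(_calls(2))]), fmt="pdf")
        assert doc.startswith(b"%PDF-1.4") and doc.rstrip().endswith(b"%%EOF")
        xref_at = int(doc[doc.rindex(b"startxref") + 9:
                          doc.rindex(b"%%EOF")].strip())
        assert doc[xref_at:xref_at + 4] == b"xref"
        entries = doc[xref_at:].split(b"\n")[3:8]
        for num, line in enumerate(entries, 1):
            off = int(line.split()[0])
            assert doc[off:off + 8].startswith(f"{num} 0 obj".encode()[:8])
        stream = re.search(rb"stream\n(.*?)\nendstream", doc, re.S).group(1)
        content = zlib.decompress(stream)
        assert content.count(b" S") >= 2  # the two SNP strokes

    def test_eps_structure(self):
        doc, _ = render_scene(_scene([SnpTrackPayload(_calls(2))]), fmt="eps")
        text = doc.decode()
        assert text.startswith("%!PS-Adobe-3.0 EPSF-3.0")
        assert "%%BoundingBox: 0 0 800" in text
        assert text.count("lineto stroke") >= 2
        assert text.rstrip().endswith("%%EOF")
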