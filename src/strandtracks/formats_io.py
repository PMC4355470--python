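"""Reading and writing of the external formats the track builder touches.

Covers BED (6/9/12 columns, UCSC semantics), the signed 4-column wiggle
(bedGraph-style) dialect, a persisted linear binning index for fast region
retrieval on text tracks, the track-configuration XML dialect, and thin
wrappers for indexed BAM and FASTA access (pysam / pyfaidx).

All coordinates past the parser boundary are 0-based half-open.  The signed
wiggle value encodes transcript strand: positive values are drawn above the
central line, negative values below.
"""

from __future__ import annotations

import json
import logging
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import pysam

logger = logging.getLogger("strandtracks")

# Linear index bin width (bases).  16 kb mirrors the finest level of the
# classic UCSC/tabix binning scheme; fine enough that gene-scale queries touch
# a handful of bins.
INDEX_BIN_SIZE = 16384
INDEX_SUFFIX = ".sti"  # "strandtracks index" sidecar

STRANDS = ("+", "-", ".")
TRACK_TYPES = (
    "reference",
    "bed",
    "wiggle",
    "bam_wiggle",
    "overlay_wiggle",
    "snp",
    "indel",
    "reads",
)


class ParseError(ValueError):
    """A malformed line or document, with enough context to find it."""


class IndexRequiredError(RuntimeError):
    """Raised when region retrieval is attempted without an index."""


# ---------------------------------------------------------------------------
# Core coordinate types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap test; strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class BedRecord:
    """One BED line of 6, 9 or 12 columns.

    ``blocks`` holds (block_start_offset, block_size) pairs relative to
    ``interval.start`` and is present exactly for 12-column records, where the
    blocks are the transcript's exons.
    """

    interval: GenomicInterval
    name: str
    score: float
    column_count: int
    thick_start: int | None = None
    thick_end: int | None = None
    item_rgb: tuple[int, int, int] | None = None
    blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.column_count not in (6, 9, 12):
            raise ValueError(f"column_count must be 6, 9 or 12, got {self.column_count}")
        if (self.column_count == 12) != bool(self.blocks):
            raise ValueError("blocks present iff column_count == 12")
        if self.blocks:
            span = len(self.interval)
            prev_end = None
            for off, size in self.blocks:
                if size <= 0 or off < 0 or off + size > span:
                    raise ValueError(f"block ({off},{size}) outside record span {span}")
                if prev_end is not None and off < prev_end:
                    raise ValueError("blocks must be sorted and non-overlapping")
                prev_end = off + size
            if self.blocks[0][0] != 0:
                raise ValueError("first block must start at record start")
            if self.blocks[-1][0] + self.blocks[-1][1] != span:
                raise ValueError("last block must end at record end")

    @property
    def exons(self) -> list[GenomicInterval]:
        """Blocks as absolute genomic intervals."""
        s = self.interval.start
        return [
            GenomicInterval(self.interval.chrom, s + off, s + off + size,
                            self.interval.strand)
            for off, size in self.blocks
        ]


@dataclass(frozen=True)
class WigInterval:
    """One signed bedGraph interval; the value's sign encodes strand."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"wiggle interval start {self.start} >= end {self.end}")
        if not (self.value == self.value and abs(self.value) != float("inf")):
            raise ValueError("wiggle value must be finite")


DEFAULT_SNP_PARAM_VALUES = {
    "min_depth": 8,
    "min_var_reads": 2,
    "min_vaf": 0.20,
    "min_base_qual": 15,
    "max_p": 0.01,
    "error_rate": 0.01,
}


@dataclass(frozen=True)
class TrackConfig:
    """One <track_xxx> entry of the configuration XML."""

    track_id: str
    track_type: str
    source_paths: tuple[str, ...]
    display_options: dict = field(default_factory=dict)
    snp_params: dict | None = None

    def __post_init__(self) -> None:
        if self.track_type not in TRACK_TYPES:
            raise ValueError(f"unknown track type {self.track_type!r}")
        if not self.source_paths:
            raise ValueError(f"track {self.track_id}: source_paths must be non-empty")
        if self.track_type == "overlay_wiggle" and len(self.source_paths) < 2:
            raise ValueError(
                f"track {self.track_id}: overlay_wiggle requires >=2 files, "
                f"got {len(self.source_paths)}"
            )
        if self.snp_params is not None and self.track_type != "snp":
            raise ValueError("snp_params only allowed on snp tracks")


# ---------------------------------------------------------------------------
# BED parsing / writing
# ---------------------------------------------------------------------------


def _parse_int(text: str, what: str, line_no: int | None) -> int:
    try:
        v = int(text)
    except ValueError:
        raise ParseError(_at(line_no, f"field {what}: not an integer: {text!r}"))
    if v < 0:
        raise ParseError(_at(line_no, f"field {what}: negative coordinate {v}"))
    return v


def _at(line_no: int | None, msg: str) -> str:
    return msg if line_no is None else f"line {line_no}: {msg}"


def parse_bed_line(line: str, expected_columns: int | None = None,
                   line_no: int | None = None) -> BedRecord:
    """Parse one tab-separated BED line of 6, 9 or 12 columns."""
    fields = line.rstrip("\n").split("\t")
    n = len(fields)
    if n not in (6, 9, 12):
        raise ParseError(_at(line_no, f"BED line has {n} fields, expected 6, 9 or 12"))
    if expected_columns is not None and n != expected_columns:
        raise ParseError(_at(line_no, f"expected {expected_columns} columns, got {n}"))

    chrom = fields[0]
    start = _parse_int(fields[1], "chromStart", line_no)
    end = _parse_int(fields[2], "chromEnd", line_no)
    if start >= end:
        raise ParseError(_at(line_no, f"chromStart {start} >= chromEnd {end}"))
    name = fields[3]
    try:
        score = float(fields[4])
    except ValueError:
        raise ParseError(_at(line_no, f"field score: not numeric: {fields[4]!r}"))
    strand = fields[5]
    if strand not in STRANDS:
        raise ParseError(_at(line_no, f"field strand: {strand!r} not in {STRANDS}"))
    interval = GenomicInterval(chrom, start, end, strand)

    thick_start = thick_end = None
    item_rgb = None
    blocks: tuple[tuple[int, int], ...] = ()
    if n >= 9:
        thick_start = _parse_int(fields[6], "thickStart", line_no)
        thick_end = _parse_int(fields[7], "thickEnd", line_no)
        rgb_text = fields[8]
        if rgb_text in ("0", "."):
            item_rgb = None
        else:
            try:
                r, g, b = (int(x) for x in rgb_text.split(","))
            except ValueError:
                raise ParseError(_at(line_no, f"field itemRgb: bad triple {rgb_text!r}"))
            item_rgb = (r, g, b)
    if n == 12:
        count = _parse_int(fields[9], "blockCount", line_no)
        sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x != ""]
        starts = [int(x) for x in fields[11].rstrip(",").split(",") if x != ""]
        if len(sizes) != count or len(starts) != count:
            raise ParseError(
                _at(line_no, f"field blockSizes/blockStarts: expected {count} entries")
            )
        if count == 0:
            raise ParseError(_at(line_no, "field blockCount: must be >= 1"))
        if starts[-1] + sizes[-1] != end - start:
            raise ParseError(
                _at(line_no,
                    "field blockStarts: chromEnd != chromStart + last block "
                    f"offset + last block size ({start}+{starts[-1]}+{sizes[-1]} "
                    f"!= {end})")
            )
        blocks = tuple(zip(starts, sizes))
    try:
        return BedRecord(
            interval=interval, name=name, score=score, column_count=n,
            thick_start=thick_start, thick_end=thick_end, item_rgb=item_rgb,
            blocks=blocks,
        )
    except ValueError as exc:
        raise ParseError(_at(line_no, str(exc)))


def format_bed_line(rec: BedRecord) -> str:
    """Canonical tab-separated form; parse(format(r)) == r."""
    iv = rec.interval
    score = int(rec.score) if float(rec.score).is_integer() else rec.score
    out = [iv.chrom, str(iv.start), str(iv.end), rec.name, str(score), iv.strand]
    if rec.column_count >= 9:
        rgb = "0" if rec.item_rgb is None else ",".join(map(str, rec.item_rgb))
        out += [str(rec.thick_start), str(rec.thick_end), rgb]
    if rec.column_count == 12:
        out += [
            str(len(rec.blocks)),
            ",".join(str(s) for _, s in rec.blocks) + ",",
            ",".join(str(o) for o, _ in rec.blocks) + ",",
        ]
    return "\t".join(out)


# ---------------------------------------------------------------------------
# Signed 4-column wiggle (bedGraph dialect)
# ---------------------------------------------------------------------------


def parse_wig4_line(line: str, line_no: int | None = None) -> WigInterval:
    """Parse one whitespace-separated chrom/start/end/value line.

    fixedStep/variableStep headers are rejected: only the 4-column interval
    dialect is supported.
    """
    stripped = line.strip()
    if stripped.startswith(("fixedStep", "variableStep", "track")):
        raise ParseError(
            _at(line_no, "only the 4-column chrom/start/end/value wiggle dialect "
                         f"is supported, got header {stripped.split()[0]!r}")
        )
    fields = stripped.split()
    if len(fields) != 4:
        raise ParseError(_at(line_no, f"wiggle line has {len(fields)} fields, expected 4"))
    chrom = fields[0]
    start = _parse_int(fields[1], "start", line_no)
    end = _parse_int(fields[2], "end", line_no)
    try:
        value = float(fields[3])
    except ValueError:
        raise ParseError(_at(line_no, f"field value: not numeric: {fields[3]!r}"))
    try:
        return WigInterval(chrom, start, end, value)
    except ValueError as exc:
        raise ParseError(_at(line_no, str(exc)))


def format_wig4_line(w: WigInterval) -> str:
    value = int(w.value) if float(w.value).is_integer() else w.value
    return f"{w.chrom}\t{w.start}\t{w.end}\t{value}"


def write_wig4(intervals: Sequence[WigInterval], path: str) -> None:
    with open(path, "w") as fh:
        for w in intervals:
            fh.write(format_wig4_line(w) + "\n")


# ---------------------------------------------------------------------------
# Linear binning index for text tracks
# ---------------------------------------------------------------------------


def _sniff_kind(path: str) -> str:
    return "bed" if path.endswith((".bed", ".bed6", ".bed9", ".bed12")) else "wig"


def _iter_track_lines(path: str, kind: str):
    """Yield (chrom, start, end, raw_line) for every record line."""
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            if kind == "bed":
                rec = parse_bed_line(raw, line_no=line_no)
                yield rec.interval.chrom, rec.interval.start, rec.interval.end, raw.rstrip("\n")
            else:
                w = parse_wig4_line(raw, line_no=line_no)
                yield w.chrom, w.start, w.end, raw.rstrip("\n")


def build_index(path: str, kind: str | None = None) -> str:
    """Build and persist the binning index sidecar for a BED or wiggle file.

    Records land in every 16 kb bin they overlap; queries then touch only the
    bins overlapping the query window.  Unsorted input is indexed from a
    sorted copy of the records.  Returns the sidecar path.
    """
    kind = kind or _sniff_kind(path)
    try:
        records = sorted(_iter_track_lines(path, kind), key=lambda r: (r[0], r[1], r[2]))
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    bins: dict[str, dict[int, list]] = {}
    for chrom, start, end, raw in records:
        chrom_bins = bins.setdefault(chrom, {})
        for b in range(start // INDEX_BIN_SIZE, (end - 1) // INDEX_BIN_SIZE + 1):
            chrom_bins.setdefault(b, []).append([start, end, raw])
    sidecar = path + INDEX_SUFFIX
    payload = {
        "format": kind,
        "bin_size": INDEX_BIN_SIZE,
        "chroms": {c: {str(b): v for b, v in cb.items()} for c, cb in bins.items()},
    }
    with open(sidecar, "w") as fh:
        json.dump(payload, fh)
    logger.info("indexed %s: %d records, sidecar %s", path, len(records), sidecar)
    return sidecar


def _load_index(path: str) -> dict:
    sidecar = path + INDEX_SUFFIX
    if not os.path.exists(sidecar):
        raise IndexRequiredError(
            f"{path}: index required — run build_index first (expected sidecar "
            f"{sidecar})"
        )
    with open(sidecar) as fh:
        return json.load(fh)


def read_region(path: str, region: GenomicInterval):
    """Records overlapping ``region`` in ascending start order.

    BED files yield BedRecord, wiggle files WigInterval, BAM files pysam
    AlignedSegment.  A missing index raises IndexRequiredError; a chromosome
    absent from the file yields an empty list.
    """
    if path.endswith((".bam", ".sam", ".cram")):
        return bam_fetch(path, region)
    idx = _load_index(path)
    chrom_bins = idx["chroms"].get(region.chrom)
    if not chrom_bins:
        return []
    bin_size = idx["bin_size"]
    seen: set[tuple[int, int, str]] = set()
    hits = []
    for b in range(region.start // bin_size, (region.end - 1) // bin_size + 1):
        for start, end, raw in chrom_bins.get(str(b), ()):
            key = (start, end, raw)
            if key in seen:
                continue
            seen.add(key)
            if start < region.end and region.start < end:
                hits.append((start, end, raw))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    if idx["format"] == "bed":
        return [parse_bed_line(raw) for _, _, raw in hits]
    return [parse_wig4_line(raw) for _, _, raw in hits]


def bam_fetch(path: str, region: GenomicInterval) -> list:
    """Alignments overlapping ``region`` from an indexed BAM (or SAM via htslib)."""
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as bam:
        if not bam.has_index():
            raise IndexRequiredError(
                f"{path}: index required — expected companion index file "
                f"({path}.bai); sort and index the alignments first"
            )
        if region.chrom not in bam.references:
            return []
        return list(bam.fetch(region.chrom, region.start, region.end))


def read_fasta_region(path: str, region: GenomicInterval) -> str:
    """Uppercase reference bases for ``region`` (pyfaidx; builds .fai on demand)."""
    from pyfaidx import Fasta

    with Fasta(path) as fa:
        if region.chrom not in fa:
            raise KeyError(f"{region.chrom} not in {path}")
        return str(fa[region.chrom][region.start:region.end]).upper()


# ---------------------------------------------------------------------------
# Track-configuration XML
# ---------------------------------------------------------------------------

_SNP_PARAM_TAGS = ("min_depth", "min_var_reads", "min_vaf", "min_base_qual",
                   "max_p", "error_rate")
_BOOL_OPTIONS = ("hide_popup",)


def parse_track_xml(document: str) -> list[TrackConfig]:
    """Parse the <tracks> document into ordered TrackConfig entries.

    Each child element is named ``track_<type>``; document order is the
    vertical track order of the rendered scene.  SNP tracks may set any of
    the five calling thresholds; unset ones are filled from defaults.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise ParseError(f"track XML is not well-formed: {exc}") from exc
    configs: list[TrackConfig] = []
    for i, elem in enumerate(root):
        if not elem.tag.startswith("track_"):
            raise ParseError(f"unexpected element <{elem.tag}>: tracks must be "
                             "named track_<type>")
        track_type = elem.tag[len("track_"):]
        if track_type not in TRACK_TYPES:
            raise ParseError(
                f"<{elem.tag}>: unknown track type {track_type!r}; supported: "
                + ", ".join(TRACK_TYPES)
            )
        paths = tuple(e.text.strip() for e in elem.findall("file") if e.text)
        name_el = elem.find("name")
        track_id = (name_el.text.strip() if name_el is not None and name_el.text
                    else f"{track_type}_{i}")
        display: dict = {}
        color_el = elem.find("color")
        if color_el is not None and color_el.text:
            display["color"] = color_el.text.strip()
        for opt in _BOOL_OPTIONS:
            oe = elem.find(opt)
            if oe is not None and oe.text:
                display[opt] = oe.text.strip().lower() in ("1", "true", "yes")
        snp_params = None
        if track_type == "snp":
            snp_params = dict(DEFAULT_SNP_PARAM_VALUES)
            defaulted = []
            for tag in _SNP_PARAM_TAGS:
                pe = elem.find(tag)
                if pe is not None and pe.text:
                    cast = float if tag in ("min_vaf", "max_p", "error_rate") else int
                    snp_params[tag] = cast(pe.text.strip())
                else:
                    defaulted.append(tag)
            if defaulted:
                logger.info("snp track %s: defaults used for %s", track_id,
                            ", ".join(defaulted))
        try:
            configs.append(TrackConfig(track_id, track_type, paths, display, snp_params))
        except ValueError as exc:
            raise ParseError(f"<{elem.tag}>: {exc}") from exc
    return configs


def write_track_xml(configs: Sequence[TrackConfig]) -> str:
    """Serialize configs back to the XML dialect (semantic inverse of parse)."""
    root = ET.Element("tracks")
    for cfg in configs:
        el = ET.SubElement(root, f"track_{cfg.track_type}")
        ET.SubElement(el, "name").text = cfg.track_id
        for p in cfg.source_paths:
            ET.SubElement(el, "file").text = p
        if "color" in cfg.display_options:
            ET.SubElement(el, "color").text = str(cfg.display_options["color"])
        for opt in _BOOL_OPTIONS:
            if opt in cfg.display_options:
                ET.SubElement(el, opt).text = "true" if cfg.display_options[opt] else "false"
        if cfg.snp_params:
            for tag in _SNP_PARAM_TAGS:
                ET.SubElement(el, tag).text = str(cfg.snp_params[tag])
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")
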