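"""Readers and writers for the on-disk formats the pipeline touches.

All internal coordinates are 0-based half-open; 1-based inclusive
conventions exist only at the BLAST tabular boundary, where they are
normalized on parse. Sequences are upcased on read and characters outside
ACGTN are mapped to N.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

__all__ = [
    "Read",
    "Segment",
    "Link",
    "GafRecord",
    "PafRecord",
    "Hsp",
    "AssemblyGraph",
    "ParseError",
    "parse_gfa",
    "write_gfa",
    "parse_gaf",
    "parse_paf",
    "parse_blast6",
    "read_fastx",
    "write_fasta",
    "write_fastq",
    "read_bed",
    "write_bed",
    "revcomp",
    "clean_seq",
]

VALID_LABELS = {"plastid", "mitochondrion", "nuclear", "unknown"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CLEAN = re.compile(r"[^ACGTN]")


class ParseError(ValueError):
    """Structured parse failure naming the offending file/line."""

    def __init__(self, message: str, path: Optional[str] = None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


def clean_seq(seq: str) -> str:
    """Upcase and map non-ACGTN characters to N."""
    return _CLEAN.sub("N", seq.upper())


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A sequencing read, optionally with a classifier label."""

    id: str
    seq: str
    qual: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"read {self.id}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id}: quality length != sequence length")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"read {self.id}: unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Segment:
    """A node of an assembly graph."""

    id: str
    seq: Optional[str] = None
    length: Optional[int] = None

    def __post_init__(self):
        if self.seq is not None:
            if self.length is None:
                self.length = len(self.seq)
            elif self.length != len(self.seq):
                raise ValueError(f"segment {self.id}: length field disagrees with sequence")


@dataclass(frozen=True)
class Link:
    """An oriented edge of an assembly graph; overlap in exact-match bases."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap: int = 0

    def __post_init__(self):
        if self.from_orient not in "+-" or self.to_orient not in "+-":
            raise ValueError("link orientation must be + or -")
        if self.overlap < 0:
            raise ValueError("link overlap must be >= 0")


@dataclass
class AssemblyGraph:
    segments: list = field(default_factory=list)
    links: list = field(default_factory=list)

    @property
    def segment_ids(self) -> set:
        return {s.id for s in self.segments}

    def segment(self, sid: str) -> Segment:
        for s in self.segments:
            if s.id == sid:
                return s
        raise KeyError(sid)


@dataclass
class GafRecord:
    """One graph-alignment line; query interval 0-based half-open as in GAF."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    path: list  # [(segment_id, orient), ...]
    matches: int
    blocklen: int

    def __post_init__(self):
        if not (0 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(f"GAF {self.qname}: bad query interval")
        if self.blocklen <= 0 or not (0 < self.matches <= self.blocklen):
            raise ValueError(f"GAF {self.qname}: matches {self.matches} > blocklen {self.blocklen}")

    @property
    def identity(self) -> float:
        return self.matches / self.blocklen


@dataclass
class PafRecord:
    """One PAF line; optional cs:Z difference string retained."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    blocklen: int
    mapq: int = 60
    cs: Optional[str] = None


@dataclass
class Hsp:
    """A BLAST high-scoring segment pair, coordinate-normalized.

    The query is an organellar genome, the subject a nuclear sequence.
    ``sstart``/``send`` are stored 0-based half-open with start < end; the
    original subject orientation is kept in ``strand``.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    strand: str

    def __post_init__(self):
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError("pident outside [0, 100]")
        if self.length < 1:
            raise ValueError("alignment length < 1")
        if self.sstart >= self.send:
            raise ValueError("normalized nuclear interval must satisfy start < end")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastx(path, label: Optional[str] = None) -> Iterator[Read]:
    """Stream reads from FASTA or FASTQ, optionally gzipped.

    Format is sniffed from the filename (.fq/.fastq → FASTQ).
    """
    name = str(path)
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield Read(id=rec.id, seq=clean_seq(str(rec.seq)), qual=qual, label=label)


def write_fasta(records: Iterable, path) -> None:
    """Write (name, seq) pairs or Read objects as FASTA."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            if isinstance(rec, Read):
                name, seq = rec.id, rec.seq
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(reads: Iterable[Read], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFA 1.x

_OVERLAP_RE = re.compile(r"^(\d+)M$")


def parse_gfa(path) -> AssemblyGraph:
    """Parse a GFA 1.x file with S and L lines.

    Overlaps must be "*", "0M" or "<n>M"; other CIGARs (I/D/X ops) are an
    unsupported dialect and rejected. Links referencing unknown segments
    raise a :class:`ParseError` naming the line.
    """
    segments: list = []
    links: list = []
    seg_ids: set = set()
    link_lines: list = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise ParseError("S line with fewer than 3 columns", str(path), lineno)
                sid, seq = fields[1], fields[2]
                length = None
                for opt in fields[3:]:
                    if opt.startswith("LN:i:"):
                        length = int(opt[5:])
                if seq == "*":
                    segments.append(Segment(id=sid, seq=None, length=length))
                else:
                    segments.append(Segment(id=sid, seq=clean_seq(seq)))
                seg_ids.add(sid)
            elif tag == "L":
                if len(fields) < 6:
                    raise ParseError("L line with fewer than 6 columns", str(path), lineno)
                link_lines.append((lineno, fields))
    for lineno, fields in link_lines:
        fid, fo, tid, to, ov = fields[1], fields[2], fields[3], fields[4], fields[5]
        if fid not in seg_ids or tid not in seg_ids:
            raise ParseError(f"link references unknown segment ({fid} or {tid})", str(path), lineno)
        if ov == "*":
            overlap = 0
        else:
            m = _OVERLAP_RE.match(ov)
            if not m:
                raise ParseError(f"unsupported overlap CIGAR {ov!r} (only <n>M)", str(path), lineno)
            overlap = int(m.group(1))
        links.append(Link(fid, fo, tid, to, overlap))
    return AssemblyGraph(segments=segments, links=links)


def write_gfa(graph: AssemblyGraph, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for s in graph.segments:
            seq = s.seq if s.seq is not None else "*"
            ln = s.length if s.length is not None else (len(s.seq) if s.seq else 0)
            fh.write(f"S\t{s.id}\t{seq}\tLN:i:{ln}\n")
        for l in graph.links:
            fh.write(f"L\t{l.from_id}\t{l.from_orient}\t{l.to_id}\t{l.to_orient}\t{l.overlap}M\n")


# ---------------------------------------------------------------------------
# GAF

_PATH_STEP = re.compile(r"([><])([^><]+)")


def _parse_gaf_path(s: str) -> list:
    """GAF path grammar: '>' forward, '<' reverse, or a bare stable id."""
    if s and s[0] in "<>":
        return [(sid, "+" if op == ">" else "-") for op, sid in _PATH_STEP.findall(s)]
    return [(s, "+")]


def parse_gaf(path) -> list:
    """Parse a tab-separated GAF file into :class:`GafRecord` objects.

    Trailing optional tag columns are ignored. matches > blocklen is a
    malformed record.
    """
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError("GAF line with fewer than 12 columns", str(path), lineno)
            try:
                rec = GafRecord(
                    qname=f[0],
                    qlen=int(f[1]),
                    qstart=int(f[2]),
                    qend=int(f[3]),
                    strand=f[4],
                    path=_parse_gaf_path(f[5]),
                    matches=int(f[9]),
                    blocklen=int(f[10]),
                )
            except ValueError as e:
                raise ParseError(str(e), str(path), lineno) from e
            records.append(rec)
    return records


def write_gaf(records: Iterable[GafRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            p = "".join((">" if o == "+" else "<") + sid for sid, o in r.path)
            plen = r.blocklen  # placeholder path length; consumers use cols 10/11
            fh.write(
                f"{r.qname}\t{r.qlen}\t{r.qstart}\t{r.qend}\t{r.strand}\t{p}"
                f"\t{plen}\t0\t{plen}\t{r.matches}\t{r.blocklen}\t60\n"
            )


# ---------------------------------------------------------------------------
# PAF (with cs tag)

def parse_paf(path) -> list:
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError("PAF line with fewer than 12 columns", str(path), lineno)
            cs = None
            for opt in f[12:]:
                if opt.startswith("cs:Z:"):
                    cs = opt[5:]
            records.append(
                PafRecord(
                    qname=f[0], qlen=int(f[1]), qstart=int(f[2]), qend=int(f[3]),
                    strand=f[4],
                    tname=f[5], tlen=int(f[6]), tstart=int(f[7]), tend=int(f[8]),
                    matches=int(f[9]), blocklen=int(f[10]), mapq=int(f[11]), cs=cs,
                )
            )
    return records


def write_paf(records: Iterable[PafRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            cols = [
                r.qname, r.qlen, r.qstart, r.qend, r.strand,
                r.tname, r.tlen, r.tstart, r.tend, r.matches, r.blocklen, r.mapq,
            ]
            line = "\t".join(str(c) for c in cols)
            if r.cs is not None:
                line += f"\tcs:Z:{r.cs}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

def parse_blast6(path) -> list:
    """Parse 12-column BLAST tabular output into coordinate-normalized HSPs.

    sstart > send flags the minus strand and the subject (nuclear) interval
    is normalized to start < end; all coordinates become 0-based half-open.
    """
    hsps = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ParseError(f"expected 12 columns, got {len(f)}", str(path), lineno)
            sstart, send = int(f[8]), int(f[9])
            strand = "+" if sstart <= send else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            hsps.append(
                Hsp(
                    qseqid=f[0], sseqid=f[1],
                    pident=float(f[2]), length=int(f[3]),
                    qstart=int(f[6]) - 1, qend=int(f[7]),
                    sstart=lo - 1, send=hi,
                    evalue=float(f[10]), bitscore=float(f[11]),
                    strand=strand,
                )
            )
    return hsps


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list:
    """Read BED3+ as (chrom, start, end, *rest) tuples (0-based half-open)."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError("BED line with fewer than 3 columns", str(path), lineno)
            out.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return out


def write_bed(intervals: Iterable, path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")
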