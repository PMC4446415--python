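"""Readers and writers for the formats the toolkit speaks.

Standard formats (FASTA, FASTQ, SAM, VCF) go through Biopython and pysam.
The thesaurus table itself — a sorted, tab-delimited list of similar-region
pairs with their recorded substitution differences — is bespoke and defined
here, together with the in-memory :class:`ThesaurusTable` and its
symmetric streaming/overlap queries.

Coordinate conventions: all positions in this package, in the table and in
VCF output are 1-based inclusive, matching VCF/SAM.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

THESAURUS_FORMAT_VERSION = "1"

#: FILTER codes attached to pathological variants.
MARK_MANY = "TS_MANY"
MARK_INDEL = "TS_INDEL"
MARK_ERRORS = "TS_ERRORS"
ALL_MARKS = (MARK_MANY, MARK_INDEL, MARK_ERRORS)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed interval [start, end] on a named sequence, 1-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} precedes start {self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True, order=True)
class Mismatch:
    """One recorded substitution inside a thesaurus entry.

    ``pos`` is a 1-based position in the *origin* interval; ``alt_base`` is
    the base of the alternate region expressed in the origin frame
    (i.e. reverse-complemented for minus-strand entries).
    """

    pos: int
    origin_base: str
    alt_base: str


@dataclass(frozen=True, order=True)
class ThesaurusEntry:
    """A pair of similar genomic intervals with recorded differences."""

    origin: GenomicInterval
    alt: GenomicInterval
    strand: str
    mismatches: tuple[Mismatch, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.origin) != len(self.alt):
            raise ValueError(
                "thesaurus entries are ungapped: origin and alt lengths differ "
                f"({len(self.origin)} vs {len(self.alt)})"
            )
        for mm in self.mismatches:
            if not self.origin.contains(mm.pos):
                raise ValueError(
                    f"mismatch position {mm.pos} outside origin {self.origin}"
                )

    # -- coordinate and allele projection ---------------------------------

    def project(self, pos: int) -> int:
        """Map an origin position onto the alternate interval."""
        if not self.origin.contains(pos):
            raise ValueError(f"position {pos} outside origin {self.origin}")
        offset = pos - self.origin.start
        if self.strand == "+":
            return self.alt.start + offset
        return self.alt.end - offset

    def project_base(self, base: str) -> str:
        """Strand-normalize an allele when projecting across the entry."""
        return complement_base(base) if self.strand == "-" else base

    def flipped(self) -> "ThesaurusEntry":
        """The same similarity viewed from the alternate side.

        Projection is an involution, so ``entry.flipped().flipped() == entry``.
        """
        mms = tuple(
            sorted(
                Mismatch(
                    pos=self.project(mm.pos),
                    origin_base=self.project_base(mm.alt_base),
                    alt_base=self.project_base(mm.origin_base),
                )
                for mm in self.mismatches
            )
        )
        return ThesaurusEntry(
            origin=self.alt, alt=self.origin, strand=self.strand, mismatches=mms
        )


def _entry_sort_key(e: ThesaurusEntry):
    return (e.origin.chrom, e.origin.start, e.origin.end,
            e.alt.chrom, e.alt.start, e.strand)


class ThesaurusTable:
    """Sorted collection of thesaurus entries with symmetric overlap lookup.

    Each region pair is stored once; a mirrored index keyed by the alternate
    interval resolves queries that hit the alt side, returning the flipped
    entry so callers always see the query locus on the origin side.
    """

    def __init__(self, entries: Iterable[ThesaurusEntry],
                 header: Mapping[str, str] | None = None):
        self.entries: list[ThesaurusEntry] = sorted(entries, key=_entry_sort_key)
        self.header: dict[str, str] = dict(header or {})
        self._origin_trees: dict[str, IntervalTree] | None = None
        self._alt_trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ThesaurusEntry]:
        return iter(self.entries)

    def _build_trees(self) -> None:
        origin: dict[str, IntervalTree] = {}
        alt: dict[str, IntervalTree] = {}
        for i, e in enumerate(self.entries):
            origin.setdefault(e.origin.chrom, IntervalTree()).addi(
                e.origin.start, e.origin.end + 1, i)
            alt.setdefault(e.alt.chrom, IntervalTree()).addi(
                e.alt.start, e.alt.end + 1, i)
        self._origin_trees = origin
        self._alt_trees = alt

    def query(self, interval: GenomicInterval) -> list[ThesaurusEntry]:
        """All entries whose origin or alt side overlaps ``interval``.

        Alt-side hits are returned flipped. Unknown chromosomes yield an
        empty list.
        """
        if self._origin_trees is None:
            self._build_trees()
        assert self._origin_trees is not None and self._alt_trees is not None
        hits: list[ThesaurusEntry] = []
        tree = self._origin_trees.get(interval.chrom)
        if tree is not None:
            for iv in tree.overlap(interval.start, interval.end + 1):
                hits.append(self.entries[iv.data])
        tree = self._alt_trees.get(interval.chrom)
        if tree is not None:
            for iv in tree.overlap(interval.start, interval.end + 1):
                hits.append(self.entries[iv.data].flipped())
        # self-similar entries may be found identically through both sides
        return sorted(set(hits), key=_entry_sort_key)

    def query_position(self, chrom: str, pos: int) -> list[ThesaurusEntry]:
        return self.query(GenomicInterval(chrom, pos, pos))

    def covered_chroms(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            out.add(e.origin.chrom)
            out.add(e.alt.chrom)
        return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file as ``{name: uppercase sequence}``.

    Names are truncated at the first whitespace. Duplicate names and empty
    records are format errors.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: dict[str, str] = {}
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        name = rec.id
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record: {name!r}")
        if name in out:
            raise ValueError(f"duplicate FASTA record name: {name!r}")
        out[name] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike,
                width: int = 70) -> None:
    records = [
        _BioSeqRecord(_BioSeq(s), id=name, description="")
        for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_fastq(reads: Sequence, path: str | os.PathLike,
                quality_char: str = "I") -> None:
    """Write objects with ``.name``/``.seq`` attributes as FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{quality_char * len(r.seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in _BioSeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Thesaurus table on disk
# ---------------------------------------------------------------------------


def _open_text(path: str | os.PathLike, mode: str) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")  # type: ignore[return-value]
    return open(path, mode)  # type: ignore[return-value]


def write_thesaurus(entries: Iterable[ThesaurusEntry] | ThesaurusTable,
                    path: str | os.PathLike,
                    header: Mapping[str, str] | None = None) -> None:
    """Serialize entries sorted by origin coordinate.

    One tab-delimited line per entry: origin chrom/start/end, alt
    chrom/start/end, strand, and ``pos:originBase:altBase`` mismatches joined
    by ';' ('.' when none). ``#key=value`` header lines carry build
    parameters. Unsorted input is rejected.
    """
    if isinstance(entries, ThesaurusTable):
        header = dict(entries.header, **(header or {}))
        entries = entries.entries
    entries = list(entries)
    keys = [(e.origin.chrom, e.origin.start) for e in entries]
    if keys != sorted(keys):
        raise ValueError("thesaurus entries must be sorted by origin coordinate")
    with _open_text(path, "w") as fh:
        fh.write(f"#thesaurus-format={THESAURUS_FORMAT_VERSION}\n")
        for k, v in (header or {}).items():
            fh.write(f"#{k}={v}\n")
        for e in entries:
            mms = ";".join(
                f"{m.pos}:{m.origin_base}:{m.alt_base}" for m in e.mismatches
            ) or "."
            fh.write(
                f"{e.origin.chrom}\t{e.origin.start}\t{e.origin.end}\t"
                f"{e.alt.chrom}\t{e.alt.start}\t{e.alt.end}\t{e.strand}\t{mms}\n"
            )


def read_thesaurus(path: str | os.PathLike) -> ThesaurusTable:
    """Parse a thesaurus table; malformed lines raise with their line number."""
    header: dict[str, str] = {}
    entries: list[ThesaurusEntry] = []
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    if k != "thesaurus-format":
                        header[k] = v
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ValueError(
                    f"{path}: line {lineno}: expected 8 columns, got {len(parts)}"
                )
            try:
                origin = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                alt = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
                strand = parts[6]
                mms: list[Mismatch] = []
                if parts[7] != ".":
                    for token in parts[7].split(";"):
                        p, ob, ab = token.split(":")
                        mms.append(Mismatch(int(p), ob, ab))
                entries.append(
                    ThesaurusEntry(origin, alt, strand, tuple(mms))
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed thesaurus entry: {exc}"
                ) from exc
    return ThesaurusTable(entries, header)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VariantCall:
    """One called variant (single sample, site-level representation)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    filters: tuple[str, ...] = ()
    info: dict = field(default_factory=dict)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)

    @property
    def depth(self) -> int | None:
        return self.info.get("DP")

    @property
    def alt_depth(self) -> int | None:
        return self.info.get("VD")

    def ts_alt_sites(self) -> list[tuple[str, int, str]]:
        """Structured alternate-site links parsed from the TS_ALT INFO key."""
        raw = self.info.get("TS_ALT")
        if raw is None:
            return []
        if isinstance(raw, str):
            raw = (raw,)
        out = []
        for token in raw:
            chrom, pos, strand = token.rsplit(":", 2)
            out.append((chrom, int(pos), strand))
        return out


def _vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Qualifying read depth at the site")
    header.info.add("VD", 1, "Integer", "Reads supporting the variant allele")
    header.info.add("TS_ALT", ".", "String",
                    "Thesaurus alternate sites as chrom:pos:strand")
    header.info.add("TS_CLUSTER", 1, "Integer",
                    "Thesaurus cluster identifier")
    header.filters.add(MARK_MANY, None, None,
                       "Linked to an excessive number of alternate sites")
    header.filters.add(MARK_INDEL, None, None,
                       "Supported by reads with insertions, deletions or "
                       "splice junctions")
    header.filters.add(MARK_ERRORS, None, None,
                       "Supported by reads with a large number of mismatches")
    return header


def write_vcf(records: Sequence[VariantCall], path: str | os.PathLike,
              contigs: Mapping[str, int]) -> None:
    """Write site-level VCF 4.2; TS_* keys are always declared in the header."""
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in records:
            rec = vf.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                alleles=(call.ref, call.alt),
                qual=call.qual,
            )
            for f in call.filters:
                rec.filter.add(f)
            for k, v in call.info.items():
                rec.info[k] = v
            vf.write(rec)


def read_vcf(path: str | os.PathLike) -> list[VariantCall]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"VCF file not found: {path}")
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: not a parseable VCF: {exc}") from exc
    out: list[VariantCall] = []
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            alt = alts[0] if alts else "."
            filters = tuple(rec.filter.keys())
            if filters == ("PASS",):
                filters = ()
            info = {}
            for k, v in rec.info.items():
                if isinstance(v, tuple) and len(v) == 1:
                    v = v[0]
                info[k] = v
            out.append(VariantCall(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref or ".",
                alt=alt, qual=rec.qual, filters=filters, info=info,
            ))
    return out


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


@dataclass
class AlignedRead:
    """One mapped read record (forward-strand sequence, 1-based position)."""

    name: str
    chrom: str
    pos: int
    strand: str
    cigar: str
    mapq: int
    seq: str


def read_alignments(path: str | os.PathLike,
                    stats: dict | None = None) -> Iterator[AlignedRead]:
    """Yield mapped records from SAM/BAM; unmapped reads are counted/skipped."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"alignment file not found: {path}")
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: not a parseable SAM/BAM: {exc}") from exc
    with af:
        try:
            for rec in af:
                if rec.is_unmapped or rec.reference_name is None:
                    if stats is not None:
                        stats["unmapped"] = stats.get("unmapped", 0) + 1
                    continue
                yield AlignedRead(
                    name=rec.query_name or "",
                    chrom=rec.reference_name,
                    pos=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    cigar=rec.cigarstring or "",
                    mapq=rec.mapping_quality,
                    seq=(rec.query_sequence or "").upper(),
                )
        except (ValueError, OSError) as exc:
            raise ValueError(f"{path}: truncated or malformed record: {exc}") from exc


def write_sam(reads: Sequence[AlignedRead], path: str | os.PathLike,
              contigs: Mapping[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    names = list(contigs)
    ordered = sorted(reads, key=lambda r: (names.index(r.chrom), r.pos, r.name))
    with pysam.AlignmentFile(str(path), "w", header=header) as af:
        for r in ordered:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = r.name
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = names.index(r.chrom)
            seg.reference_start = r.pos - 1
            seg.mapping_quality = r.mapq
            seg.cigarstring = r.cigar
            seg.query_sequence = r.seq
            af.write(seg)
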