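"""Thesaurus construction: terminal-seed ungapped all-mapping of tiled reads.

The table of similar genomic regions is built by tiling the reference with
error-free reads (100 bp every 10 bp by default), enumerating every ungapped
placement of each read on either strand that (i) matches the terminal seed
k-mers exactly, (ii) has at most four mismatches in total and (iii) none in
the first or last five bases. Alternate placements with up to three
mismatches become region-pair entries; entries on the same diagonal are
merged into longer regions of similarity and extended up- and downstream to
cover the inter-read sampling gap, then sorted.

Terminal-seed misses for individual reads are deliberate: overlapping reads
tiled 10 bp apart recover the same similarity from a neighbouring frame, so
the merged table still covers the region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import (
    AlignedRead,
    GenomicInterval,
    Mismatch,
    ThesaurusEntry,
    ThesaurusTable,
    revcomp,
    write_thesaurus,
)
from .simulate import SimRead, tile_reads

MAX_MISMATCHES = 4
PROTECTED_TERMINAL = 5
MAX_ENTRY_MISMATCHES = 3
DEFAULT_EXTEND = 10

# base-5 codes: A,C,G,T -> 0..3, anything else -> 4, so a k-mer containing an
# ambiguous base can never collide with an A/C/G/T-only query code.
_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = out * 5 + codes[i: i + n]
    return out


class SeedIndex:
    """Exact-match index of every genome k-mer (default k = 5).

    k equals the protected terminal length: the terminal bases of a read are
    the only seeds for alignment. Lookups serve both strands — a minus-strand
    query is resolved against the forward index via reverse complementation.
    """

    def __init__(self, genome: Mapping[str, str], k: int = PROTECTED_TERMINAL):
        if k < 1:
            raise ValueError("seed length must be >= 1")
        if not genome:
            raise ValueError("cannot index an empty genome")
        if min(len(s) for s in genome.values()) < k:
            raise ValueError(
                f"seed length {k} exceeds the shortest chromosome"
            )
        self.k = k
        self.genome = dict(genome)
        self.codes: dict[str, np.ndarray] = {}
        self._sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, seq in genome.items():
            codes = _encode(seq)
            self.codes[chrom] = codes
            kc = _kmer_codes(codes, k)
            order = np.argsort(kc, kind="stable")
            self._sorted[chrom] = (kc[order], order)

    def _forward_hits(self, chrom: str, kmer_code: int) -> np.ndarray:
        sorted_codes, order = self._sorted[chrom]
        lo = np.searchsorted(sorted_codes, kmer_code, side="left")
        hi = np.searchsorted(sorted_codes, kmer_code, side="right")
        return np.sort(order[lo:hi])

    def occurrences(self, kmer: str, strand: str = "+") -> list[tuple[str, int]]:
        """1-based start positions of exact matches of ``kmer``.

        For the minus strand, positions are where the reverse complement of
        ``kmer`` occurs on the forward sequence.
        """
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        query = kmer if strand == "+" else revcomp(kmer)
        if any(b not in "ACGT" for b in query):
            return []
        code = 0
        for b in query:
            code = code * 5 + int(_CODE[ord(b)])
        out = []
        for chrom in self.genome:
            for p in self._forward_hits(chrom, code):
                out.append((chrom, int(p) + 1))
        return out

    def _hits_code(self, chrom: str, codes: np.ndarray) -> np.ndarray:
        code = 0
        for c in codes:
            code = code * 5 + int(c)
        return self._forward_hits(chrom, code)


@dataclass(frozen=True)
class UngappedAlignment:
    """One ungapped placement of a read, with its mismatch ledger.

    Mismatch offsets are 0-based in the read; ``genome_base`` is the
    reference base expressed in the read's strand frame (complemented for
    minus-strand placements).
    """

    read_name: str
    origin: GenomicInterval | None
    placement: GenomicInterval
    strand: str
    mismatches: tuple[tuple[int, str, str], ...]  # (offset, read_base, genome_base)

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatches)


def all_map_read(
    read_seq: str,
    index: SeedIndex,
    max_mm: int = MAX_MISMATCHES,
    protected: int = PROTECTED_TERMINAL,
    read_name: str = "",
    origin: GenomicInterval | None = None,
    stats: dict | None = None,
) -> list[UngappedAlignment]:
    """All ungapped placements of a read reachable from its terminal seeds.

    Candidate positions come from exact matches of the first or last
    ``protected`` bases on either strand; each candidate is verified in full
    against the constraints (no indels by construction, <= ``max_mm``
    mismatches, clean protected terminals). Reads containing non-ACGT bases
    are skipped and counted.
    """
    L = len(read_seq)
    if L <= 2 * protected:
        raise ValueError("read shorter than twice the protected terminal")
    if any(b not in "ACGT" for b in read_seq):
        if stats is not None:
            stats["skipped_ambiguous"] = stats.get("skipped_ambiguous", 0) + 1
        return []
    k = index.k
    arange = np.arange(L)
    results: dict[tuple[str, int, str], UngappedAlignment] = {}
    for strand in "+-":
        q = read_seq if strand == "+" else revcomp(read_seq)
        qcodes = _encode(q)
        for chrom, codes in index.codes.items():
            clen = len(codes)
            if clen < L:
                continue
            head = index._hits_code(chrom, qcodes[:k])
            tail = index._hits_code(chrom, qcodes[L - k:]) - (L - k)
            starts = np.unique(np.concatenate([head, tail]))
            starts = starts[(starts >= 0) & (starts <= clen - L)]
            if len(starts) == 0:
                continue
            windows = codes[starts[:, None] + arange]
            mm = windows != qcodes
            counts = mm.sum(axis=1)
            ok = (
                (counts <= max_mm)
                & ~mm[:, :protected].any(axis=1)
                & ~mm[:, L - protected:].any(axis=1)
            )
            for row in np.nonzero(ok)[0]:
                s0 = int(starts[row])
                offsets = np.nonzero(mm[row])[0]
                mms = []
                for j in offsets:
                    j = int(j)
                    gbase = index.genome[chrom][s0 + j]
                    if strand == "+":
                        mms.append((j, q[j], gbase))
                    else:
                        off = L - 1 - j
                        mms.append((off, read_seq[off],
                                    revcomp(gbase)))
                mms.sort()
                placement = GenomicInterval(chrom, s0 + 1, s0 + L)
                key = (chrom, s0, strand)
                if key not in results:
                    results[key] = UngappedAlignment(
                        read_name=read_name,
                        origin=origin,
                        placement=placement,
                        strand=strand,
                        mismatches=tuple(mms),
                    )
    return sorted(
        results.values(),
        key=lambda a: (a.placement.chrom, a.placement.start, a.strand),
    )


# ---------------------------------------------------------------------------
# Entries
# ---------------------------------------------------------------------------


def _interval_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def alignments_to_entries(
    alignments: Iterable[UngappedAlignment],
    max_entry_mm: int = MAX_ENTRY_MISMATCHES,
) -> list[ThesaurusEntry]:
    """Convert alternate placements of origin-tagged reads into entries.

    The trivial self-placement is excluded; placements with more than
    ``max_entry_mm`` mismatches are dropped. Each region pair is emitted
    once, canonically ordered origin <= alt (the partner read generates the
    mirror, which is redundant because the table query is symmetric).
    """
    out: set[ThesaurusEntry] = set()
    for al in alignments:
        if al.origin is None:
            raise ValueError("alignments must carry their true origin")
        if (al.placement == al.origin and al.strand == "+"
                and al.n_mismatch == 0):
            continue
        if al.n_mismatch > max_entry_mm:
            continue
        if _interval_key(al.origin) > _interval_key(al.placement):
            continue
        mms = tuple(sorted(
            Mismatch(
                pos=al.origin.start + off,
                origin_base=read_base,
                alt_base=genome_base,
            )
            for off, read_base, genome_base in al.mismatches
        ))
        out.add(ThesaurusEntry(
            origin=al.origin, alt=al.placement, strand=al.strand,
            mismatches=mms,
        ))
    return sorted(out, key=lambda e: (_interval_key(e.origin),
                                      _interval_key(e.alt), e.strand))


def _diagonal(e: ThesaurusEntry) -> int:
    if e.strand == "+":
        return e.alt.start - e.origin.start
    return e.alt.end + e.origin.start


def _entry_from_origin(origin: GenomicInterval, alt_chrom: str, strand: str,
                       diag: int, mms: tuple[Mismatch, ...]) -> ThesaurusEntry:
    if strand == "+":
        alt = GenomicInterval(alt_chrom, origin.start + diag,
                              origin.end + diag)
    else:
        alt = GenomicInterval(alt_chrom, diag - origin.end,
                              diag - origin.start)
    return ThesaurusEntry(origin, alt, strand, mms)


def merge_entries(
    entries: Sequence[ThesaurusEntry],
    extend: int = DEFAULT_EXTEND,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[ThesaurusEntry]:
    """Merge same-diagonal entries into longer regions, then extend.

    Entries sharing (origin chrom, alt chrom, strand, diagonal offset) whose
    origin intervals overlap or abut become one entry covering their union,
    with mismatch lists unioned. Each merged region is then extended by
    ``extend`` bp both directions (clipped at chromosome ends and so that
    origin and alt stay equal-length). ``extend=0`` makes the operation
    idempotent.
    """
    groups: dict[tuple[str, str, str, int], list[ThesaurusEntry]] = {}
    for e in entries:
        key = (e.origin.chrom, e.alt.chrom, e.strand, _diagonal(e))
        groups.setdefault(key, []).append(e)
    merged: list[ThesaurusEntry] = []
    for (ochrom, achrom, strand, diag), group in groups.items():
        group.sort(key=lambda e: (e.origin.start, e.origin.end))
        cur_start, cur_end = group[0].origin.start, group[0].origin.end
        cur_mms: set[Mismatch] = set(group[0].mismatches)
        flush = []
        for e in group[1:]:
            if e.origin.start <= cur_end + 1:
                cur_end = max(cur_end, e.origin.end)
                cur_mms.update(e.mismatches)
            else:
                flush.append((cur_start, cur_end, cur_mms))
                cur_start, cur_end = e.origin.start, e.origin.end
                cur_mms = set(e.mismatches)
        flush.append((cur_start, cur_end, cur_mms))
        for start, end, mms in flush:
            origin = GenomicInterval(ochrom, start, end)
            entry = _entry_from_origin(origin, achrom, strand, diag,
                                       tuple(sorted(mms)))
            if extend > 0:
                entry = _extend_entry(entry, extend, chrom_lengths)
            merged.append(entry)
    merged.sort(key=lambda e: (_interval_key(e.origin),
                               _interval_key(e.alt), e.strand))
    return merged


def _extend_entry(e: ThesaurusEntry, extend: int,
                  chrom_lengths: Mapping[str, int] | None) -> ThesaurusEntry:
    def chrom_len(chrom: str) -> int:
        if chrom_lengths is None:
            return 10 ** 12
        return chrom_lengths[chrom]

    o, a = e.origin, e.alt
    if e.strand == "+":
        left = min(extend, o.start - 1, a.start - 1)
        right = min(extend, chrom_len(o.chrom) - o.end,
                    chrom_len(a.chrom) - a.end)
    else:
        left = min(extend, o.start - 1, chrom_len(a.chrom) - a.end)
        right = min(extend, chrom_len(o.chrom) - o.end, a.start - 1)
    origin = GenomicInterval(o.chrom, o.start - left, o.end + right)
    return _entry_from_origin(origin, a.chrom, e.strand, _diagonal(e),
                              e.mismatches)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def build_thesaurus(
    reference: Mapping[str, str],
    read_len: int = 100,
    step: int = 10,
    max_mm: int = MAX_MISMATCHES,
    entry_mm: int = MAX_ENTRY_MISMATCHES,
    seed_len: int = PROTECTED_TERMINAL,
    extend: int = DEFAULT_EXTEND,
    path=None,
    index: SeedIndex | None = None,
) -> ThesaurusTable:
    """Tile, all-map, convert, merge, extend, sort — the full construction.

    Deterministic; the table header records all build parameters. If
    ``path`` is given the table is also written to disk.
    """
    if index is None:
        index = SeedIndex(reference, k=seed_len)
    alignments: list[UngappedAlignment] = []
    stats: dict = {}
    for read in tile_reads(reference, read_len=read_len, step=step):
        origin = GenomicInterval(read.chrom, read.start,
                                 read.start + read_len - 1)
        alignments.extend(all_map_read(
            read.seq, index, max_mm=max_mm, protected=seed_len,
            read_name=read.name, origin=origin, stats=stats,
        ))
    entries = alignments_to_entries(alignments, max_entry_mm=entry_mm)
    chrom_lengths = {chrom: len(seq) for chrom, seq in reference.items()}
    merged = merge_entries(entries, extend=extend, chrom_lengths=chrom_lengths)
    header = {
        "read-len": str(read_len),
        "step": str(step),
        "max-mm": str(max_mm),
        "entry-mm": str(entry_mm),
        "seed-len": str(seed_len),
        "extend": str(extend),
    }
    table = ThesaurusTable(merged, header)
    if path is not None:
        write_thesaurus(table, path)
    return table


# ---------------------------------------------------------------------------
# Read alignment (stand-in for an external aligner)
# ---------------------------------------------------------------------------


def align_reads(
    reads: Sequence[SimRead],
    index: SeedIndex,
    max_mm: int = MAX_MISMATCHES,
    protected: int = PROTECTED_TERMINAL,
    seed: int = 0,
    stats: dict | None = None,
) -> list[AlignedRead]:
    """Place each read once, choosing uniformly among minimal-mismatch ties.

    Mapping quality encodes placement confidence: 60 for a unique placement,
    20 for a unique best among several, 0 for tied bests (the read is as
    likely to belong elsewhere). This mirrors how mappers randomly
    distribute reads from repeated sequence.
    """
    rng = np.random.default_rng(seed)
    out: list[AlignedRead] = []
    for read in reads:
        placements = all_map_read(read.seq, index, max_mm=max_mm,
                                  protected=protected, read_name=read.name,
                                  stats=stats)
        if not placements:
            if stats is not None:
                stats["unplaced"] = stats.get("unplaced", 0) + 1
            continue
        best = min(p.n_mismatch for p in placements)
        bests = [p for p in placements if p.n_mismatch == best]
        chosen = bests[int(rng.integers(len(bests)))]
        if len(placements) == 1:
            mapq = 60
        elif len(bests) == 1:
            mapq = 20
        else:
            mapq = 0
        seq = read.seq if chosen.strand == "+" else revcomp(read.seq)
        out.append(AlignedRead(
            name=read.name,
            chrom=chosen.placement.chrom,
            pos=chosen.placement.start,
            strand=chosen.strand,
            cigar=f"{len(read.seq)}M",
            mapq=mapq,
            seq=seq,
        ))
    return out
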