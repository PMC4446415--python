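"""Thesaurus annotation of variant calls.

The core filtering step: for each called SNV, look up thesaurus entries
covering its locus, test whether the variant-carrying reads are consistent
with each entry (their mismatches must be explainable by the entry's recorded
differences, by other called variants near either locus, or by a small
residual), and attach alternate-site links. Linked variants self-organize
into clusters (connected components), which support pooled B-allele
frequency estimates.

Annotation is a pure decoration: it never deletes or reorders calls, so it
slots into existing pipelines the way a VCF filter does.
"""

from __future__ import annotations

import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import (
    AlignedRead,
    GenomicInterval,
    MARK_ERRORS,
    MARK_INDEL,
    MARK_MANY,
    ThesaurusEntry,
    ThesaurusTable,
    VariantCall,
    read_alignments,
    write_vcf,
)

# Default link thresholds. The method requires both a minimum read count and
# a minimum fraction of variant-carrying reads to be consistent with an entry
# before a link is declared; variants linked to an excessive number of sites
# are marked instead of enumerated.
MIN_LINK_READS = 2
MIN_LINK_FRACTION = 0.5
MAX_LINKS = 100
#: reads with more non-variant mismatches than the thesaurus mapper itself
#: tolerates cannot be explained by any entry and trigger TS_ERRORS.
ERROR_CAP = 4
MAX_EXTRA_MISMATCHES = 2

_CIGAR_INDEL_OPS = set("IDN")


# ---------------------------------------------------------------------------
# Read storage and per-variant observations
# ---------------------------------------------------------------------------


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


class StoredRead:
    """One aligned read with precomputed mismatch ledger vs the reference."""

    __slots__ = ("name", "chrom", "start", "end", "strand", "mapq", "seq",
                 "cigar", "has_indel_or_splice", "mismatches", "_blocks")

    def __init__(self, rec: AlignedRead, reference: Mapping[str, str]):
        self.name = rec.name
        self.chrom = rec.chrom
        self.start = rec.pos
        self.strand = rec.strand
        self.mapq = rec.mapq
        self.seq = rec.seq
        self.cigar = rec.cigar
        ops = _parse_cigar(rec.cigar) if rec.cigar else [("M", len(rec.seq))]
        self.has_indel_or_splice = any(op in _CIGAR_INDEL_OPS for op, _ in ops)
        # aligned blocks: (ref_start 1-based, read offset 0-based, length)
        blocks: list[tuple[int, int, int]] = []
        ref_pos = rec.pos
        read_off = 0
        for op, n in ops:
            if op in "M=X":
                blocks.append((ref_pos, read_off, n))
                ref_pos += n
                read_off += n
            elif op in "DN":
                ref_pos += n
            elif op in "IS":
                read_off += n
            elif op in "HP":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {op!r} in {rec.cigar}")
        self._blocks = blocks
        self.end = ref_pos - 1
        ref = reference[rec.chrom]
        mms: list[tuple[int, str]] = []
        for rs, ro, n in blocks:
            ref_block = ref[rs - 1: rs - 1 + n]
            read_block = rec.seq[ro: ro + n]
            if ref_block != read_block:
                a = np.frombuffer(ref_block.encode(), dtype=np.uint8)
                b = np.frombuffer(read_block.encode(), dtype=np.uint8)
                for i in np.nonzero(a != b)[0]:
                    mms.append((rs + int(i), read_block[int(i)]))
        self.mismatches: tuple[tuple[int, str], ...] = tuple(mms)

    def aligned_base(self, pos: int) -> str | None:
        """Read base aligned to reference position ``pos`` (None in a gap)."""
        for rs, ro, n in self._blocks:
            if rs <= pos < rs + n:
                return self.seq[ro + (pos - rs)]
        return None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


class ReadStore:
    """Position-sorted in-memory alignment with O(log n) overlap fetch."""

    def __init__(self, reads: Iterable[AlignedRead],
                 reference: Mapping[str, str]):
        by_chrom: dict[str, list[StoredRead]] = {}
        for rec in reads:
            if rec.chrom not in reference:
                raise ValueError(
                    f"alignment chromosome {rec.chrom!r} absent from reference"
                )
            by_chrom.setdefault(rec.chrom, []).append(StoredRead(rec, reference))
        self._by_chrom: dict[str, tuple[list[StoredRead], list[int], int]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r.start, r.name))
            starts = [r.start for r in recs]
            maxspan = max((r.end - r.start + 1) for r in recs)
            self._by_chrom[chrom] = (recs, starts, maxspan)
        self.reference = reference

    @classmethod
    def from_sam(cls, path: str | os.PathLike,
                 reference: Mapping[str, str]) -> "ReadStore":
        return cls(read_alignments(path), reference)

    def __len__(self) -> int:
        return sum(len(recs) for recs, _, _ in self._by_chrom.values())

    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def reads(self, chrom: str) -> list[StoredRead]:
        item = self._by_chrom.get(chrom)
        return item[0] if item else []

    def fetch(self, chrom: str, pos: int, end: int | None = None) -> list[StoredRead]:
        """Reads overlapping [pos, end] (end defaults to pos)."""
        if end is None:
            end = pos
        item = self._by_chrom.get(chrom)
        if item is None:
            return []
        recs, starts, maxspan = item
        lo = bisect_left(starts, pos - maxspan + 1)
        hi = bisect_right(starts, end)
        return [r for r in recs[lo:hi] if r.end >= pos]


@dataclass
class ReadObservation:
    """A read overlapping a variant position, summarized for linking."""

    read_name: str
    interval: GenomicInterval
    strand: str
    carries_variant: bool
    n_errors: int
    has_indel_or_splice: bool
    mismatches: tuple[tuple[int, str], ...]


def collect_variant_reads(store: ReadStore, variant: VariantCall,
                          window: int = 0) -> list[ReadObservation]:
    """Observations for every read overlapping ``variant.pos`` (± window).

    ``n_errors`` counts mismatches against the reference other than the
    variant base itself; an uncovered position yields an empty list.
    """
    out = []
    for r in store.fetch(variant.chrom, variant.pos - window,
                         variant.pos + window):
        base = r.aligned_base(variant.pos)
        carries = base == variant.alt
        n_err = sum(1 for p, _ in r.mismatches if p != variant.pos)
        out.append(ReadObservation(
            read_name=r.name,
            interval=r.interval,
            strand=r.strand,
            carries_variant=carries,
            n_errors=n_err,
            has_indel_or_splice=r.has_indel_or_splice,
            mismatches=r.mismatches,
        ))
    return out


# ---------------------------------------------------------------------------
# Links
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AltSiteLink:
    """A called variant tied to an alternate genomic site."""

    from_chrom: str
    from_pos: int
    to_chrom: str
    to_pos: int
    strand: str
    proj_ref: str
    proj_alt: str
    supporting_reads: int
    supporting_fraction: float

    @property
    def target(self) -> tuple[str, int]:
        return (self.to_chrom, self.to_pos)


@dataclass
class AnnotatedVariant:
    """A variant call decorated with links, marks and cluster membership."""

    call: VariantCall
    links: tuple[AltSiteLink, ...] = ()
    marks: set = field(default_factory=set)
    cluster_id: int | None = None


@dataclass
class VariantCluster:
    """Connected component of linked calls plus uncalled peripheral sites."""

    id: int
    members: list[AnnotatedVariant]
    peripheral: list[tuple[str, int, str, str]]  # chrom, pos, proj_ref, proj_alt


def project_position(entry: ThesaurusEntry, pos: int) -> tuple[str, int, str]:
    """Map an origin-side position through an entry: (chrom, pos, strand)."""
    return (entry.alt.chrom, entry.project(pos), entry.strand)


def read_consistent_with_entry(
    obs: ReadObservation,
    entry: ThesaurusEntry,
    called_variants: Mapping[tuple[str, int], str],
    max_extra_mm: int = MAX_EXTRA_MISMATCHES,
) -> bool:
    """Can this read's mismatches be explained under the entry's hypothesis?

    A mismatch is explained if it matches an entry-recorded difference, a
    called variant at the origin side, or a called variant whose projection
    lands at the alternate side; at most ``max_extra_mm`` residual mismatches
    (sequencing errors) are tolerated.
    """
    entry_mm = {(m.pos, m.alt_base) for m in entry.mismatches}
    residual = 0
    for pos, base in obs.mismatches:
        if entry.origin.contains(pos):
            if (pos, base) in entry_mm:
                continue
            proj = entry.project(pos)
            if called_variants.get((entry.alt.chrom, proj)) == \
                    entry.project_base(base):
                continue
        if called_variants.get((entry.origin.chrom, pos)) == base:
            continue
        residual += 1
        if residual > max_extra_mm:
            return False
    return True


def link_variant(
    variant: VariantCall,
    observations: Sequence[ReadObservation],
    entries: Sequence[ThesaurusEntry],
    called_variants: Mapping[tuple[str, int], str],
    reference: Mapping[str, str] | None = None,
    min_reads: int = MIN_LINK_READS,
    min_fraction: float = MIN_LINK_FRACTION,
    error_cap: int = ERROR_CAP,
    max_links: int = MAX_LINKS,
    max_extra_mm: int = MAX_EXTRA_MISMATCHES,
) -> tuple[tuple[AltSiteLink, ...], set]:
    """Evaluate candidate entries at one variant; return (links, marks)."""
    marks: set = set()
    var_obs = [o for o in observations if o.carries_variant]
    if any(o.has_indel_or_splice for o in var_obs):
        marks.add(MARK_INDEL)
    if any(o.n_errors > error_cap for o in var_obs):
        marks.add(MARK_ERRORS)
    links: dict[tuple[str, int], AltSiteLink] = {}
    if var_obs:
        for entry in entries:
            if not entry.origin.contains(variant.pos):
                continue
            n_support = sum(
                read_consistent_with_entry(o, entry, called_variants,
                                           max_extra_mm)
                for o in var_obs
            )
            fraction = n_support / len(var_obs)
            if n_support < min_reads or fraction < min_fraction:
                continue
            to_chrom, to_pos, strand = project_position(entry, variant.pos)
            if (to_chrom, to_pos) == (variant.chrom, variant.pos):
                continue
            # reference base at the alternate locus, in its own frame
            entry_mm = {m.pos: m for m in entry.mismatches}
            if variant.pos in entry_mm:
                proj_ref = entry.project_base(entry_mm[variant.pos].alt_base)
            elif reference is not None and to_chrom in reference:
                proj_ref = reference[to_chrom][to_pos - 1]
            else:
                proj_ref = entry.project_base(variant.ref)
            link = AltSiteLink(
                from_chrom=variant.chrom, from_pos=variant.pos,
                to_chrom=to_chrom, to_pos=to_pos, strand=strand,
                proj_ref=proj_ref,
                proj_alt=entry.project_base(variant.alt),
                supporting_reads=n_support,
                supporting_fraction=fraction,
            )
            prev = links.get(link.target)
            if prev is None or link.supporting_reads > prev.supporting_reads:
                links[link.target] = link
    if len(links) > max_links:
        marks.add(MARK_MANY)
        return (), marks
    ordered = tuple(sorted(links.values(),
                           key=lambda l: (l.to_chrom, l.to_pos)))
    return ordered, marks


# ---------------------------------------------------------------------------
# Whole-VCF annotation
# ---------------------------------------------------------------------------


def annotate_vcf(
    calls: Sequence[VariantCall],
    store: ReadStore,
    table: ThesaurusTable,
    reference: Mapping[str, str],
    min_reads: int = MIN_LINK_READS,
    min_fraction: float = MIN_LINK_FRACTION,
    error_cap: int = ERROR_CAP,
    max_links: int = MAX_LINKS,
    max_extra_mm: int = MAX_EXTRA_MISMATCHES,
    merge_tol: int = 0,
) -> tuple[list[AnnotatedVariant], list[VariantCluster]]:
    """Annotate every SNV call with links/marks and group them into clusters.

    Input order is preserved; non-SNV records pass through untouched. A VCF
    chromosome missing from the reference is a hard error.
    """
    for call in calls:
        if call.chrom not in reference:
            raise ValueError(
                f"variant chromosome {call.chrom!r} absent from reference"
            )
    called_index = {
        (c.chrom, c.pos): c.alt for c in calls if c.is_snv
    }
    annotated: list[AnnotatedVariant] = []
    for call in calls:
        if not call.is_snv:
            annotated.append(AnnotatedVariant(call))
            continue
        entries = table.query_position(call.chrom, call.pos)
        if not entries:
            annotated.append(AnnotatedVariant(call))
            continue
        observations = collect_variant_reads(store, call)
        links, marks = link_variant(
            call, observations, entries, called_index, reference,
            min_reads=min_reads, min_fraction=min_fraction,
            error_cap=error_cap, max_links=max_links,
            max_extra_mm=max_extra_mm,
        )
        annotated.append(AnnotatedVariant(call, links, marks))
    clusters = cluster_variants(annotated, merge_tol=merge_tol)
    return annotated, clusters


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_variants(annotated: Sequence[AnnotatedVariant],
                     merge_tol: int = 0) -> list[VariantCluster]:
    """Connected components of the link graph over called variants.

    An edge joins u and v when one of u's links lands within ``merge_tol``
    of v's position. Link targets that coincide with no call attach to the
    component as peripheral sites. Every variant lands in exactly one
    cluster; unlinked variants are singletons.
    """
    n = len(annotated)
    uf = _UnionFind(n)
    pos_sorted: dict[str, tuple[list[int], list[int]]] = {}
    for i, av in enumerate(annotated):
        pos_sorted.setdefault(av.call.chrom, ([], []))
    for chrom in pos_sorted:
        items = sorted(
            (av.call.pos, i) for i, av in enumerate(annotated)
            if av.call.chrom == chrom
        )
        pos_sorted[chrom] = ([p for p, _ in items], [i for _, i in items])

    def calls_near(chrom: str, pos: int) -> list[int]:
        item = pos_sorted.get(chrom)
        if item is None:
            return []
        positions, idx = item
        lo = bisect_left(positions, pos - merge_tol)
        hi = bisect_right(positions, pos + merge_tol)
        return idx[lo:hi]

    peripheral_of: dict[int, list[tuple[str, int, str, str]]] = {}
    for i, av in enumerate(annotated):
        for link in av.links:
            near = calls_near(link.to_chrom, link.to_pos)
            if near:
                for j in near:
                    uf.union(i, j)
            else:
                peripheral_of.setdefault(i, []).append(
                    (link.to_chrom, link.to_pos, link.proj_ref, link.proj_alt)
                )

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    ordered_roots = sorted(
        groups,
        key=lambda r: min((annotated[i].call.chrom, annotated[i].call.pos)
                          for i in groups[r]),
    )
    clusters: list[VariantCluster] = []
    for cid, root in enumerate(ordered_roots, start=1):
        members = sorted(groups[root],
                         key=lambda i: (annotated[i].call.chrom,
                                        annotated[i].call.pos))
        seen: set[tuple[str, int]] = {
            (annotated[i].call.chrom, annotated[i].call.pos) for i in members
        }
        peripheral: list[tuple[str, int, str, str]] = []
        for i in members:
            for site in peripheral_of.get(i, []):
                if (site[0], site[1]) not in seen:
                    seen.add((site[0], site[1]))
                    peripheral.append(site)
        for i in members:
            annotated[i].cluster_id = cid
        clusters.append(VariantCluster(
            id=cid,
            members=[annotated[i] for i in members],
            peripheral=sorted(peripheral),
        ))
    return clusters


# ---------------------------------------------------------------------------
# Pooled B-allele frequency
# ---------------------------------------------------------------------------


@dataclass
class SiteBaf:
    chrom: str
    pos: int
    allele: str
    variant_reads: int
    depth: int

    @property
    def baf(self) -> float:
        return self.variant_reads / self.depth


@dataclass
class ClusterBaf:
    """Per-cluster BAF summary.

    ``pooled`` divides the total variant evidence gathered over all member
    and peripheral sites by the *mean* depth per site: on a haploid genome a
    variant whose reads are scattered over similar copies recovers a value
    near 1. ``pooled_fraction`` is the plain reads ratio (total variant /
    total depth) reported for comparison.
    """

    cluster_id: int
    sites: list[SiteBaf]
    pooled: float | None
    pooled_fraction: float | None

    @property
    def member_bafs(self) -> list[float]:
        return [s.baf for s in self.sites if s.allele is not None]


def pooled_baf(cluster: VariantCluster, store: ReadStore) -> ClusterBaf:
    """Pool variant-supporting reads over all sites of a cluster.

    Sites with zero depth contribute nothing and are skipped. Alleles at
    peripheral sites are the strand-projected images of the called alleles.
    """
    site_alleles: dict[tuple[str, int], str] = {}
    for av in cluster.members:
        site_alleles[(av.call.chrom, av.call.pos)] = av.call.alt
    for chrom, pos, _ref, alt in cluster.peripheral:
        site_alleles.setdefault((chrom, pos), alt)
    sites: list[SiteBaf] = []
    for (chrom, pos), allele in sorted(site_alleles.items()):
        var = 0
        depth = 0
        for r in store.fetch(chrom, pos):
            base = r.aligned_base(pos)
            if base is None:
                continue
            depth += 1
            if base == allele:
                var += 1
        if depth == 0:
            continue
        sites.append(SiteBaf(chrom, pos, allele, var, depth))
    if not sites:
        return ClusterBaf(cluster.id, [], None, None)
    total_var = sum(s.variant_reads for s in sites)
    total_depth = sum(s.depth for s in sites)
    mean_depth = total_depth / len(sites)
    return ClusterBaf(
        cluster_id=cluster.id,
        sites=sites,
        pooled=total_var / mean_depth,
        pooled_fraction=total_var / total_depth,
    )


# ---------------------------------------------------------------------------
# Output plumbing
# ---------------------------------------------------------------------------


def annotated_to_calls(annotated: Sequence[AnnotatedVariant]) -> list[VariantCall]:
    """Fold links/marks back into VCF records (TS_ALT / TS_CLUSTER / FILTER)."""
    out = []
    for av in annotated:
        call = replace(av.call)
        info = dict(call.info)
        if av.links:
            info["TS_ALT"] = tuple(
                f"{l.to_chrom}:{l.to_pos}:{l.strand}" for l in av.links
            )
        if av.cluster_id is not None and (av.links or av.marks):
            info["TS_CLUSTER"] = av.cluster_id
        call.info = info
        call.filters = tuple(sorted(set(call.filters) | av.marks))
        out.append(call)
    return out


def write_annotated_vcf(annotated: Sequence[AnnotatedVariant],
                        path: str | os.PathLike,
                        contigs: Mapping[str, int]) -> None:
    write_vcf(annotated_to_calls(annotated), path, contigs)


LINK_TSV_COLUMNS = ("from_chrom", "from_pos", "to_chrom", "to_pos", "strand",
                    "proj_ref", "proj_alt", "reads", "fraction", "cluster_id")


def write_links(annotated: Sequence[AnnotatedVariant],
                path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LINK_TSV_COLUMNS) + "\n")
        for av in annotated:
            for l in av.links:
                fh.write(
                    f"{l.from_chrom}\t{l.from_pos}\t{l.to_chrom}\t{l.to_pos}\t"
                    f"{l.strand}\t{l.proj_ref}\t{l.proj_alt}\t"
                    f"{l.supporting_reads}\t{l.supporting_fraction:.4f}\t"
                    f"{av.cluster_id if av.cluster_id is not None else '.'}\n"
                )


def read_links(path: str | os.PathLike) -> list[AltSiteLink]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {lineno}: malformed link row")
            row = dict(zip(header, parts))
            out.append(AltSiteLink(
                from_chrom=row["from_chrom"], from_pos=int(row["from_pos"]),
                to_chrom=row["to_chrom"], to_pos=int(row["to_pos"]),
                strand=row["strand"], proj_ref=row["proj_ref"],
                proj_alt=row["proj_alt"], supporting_reads=int(row["reads"]),
                supporting_fraction=float(row["fraction"]),
            ))
    return out


def attach_links(calls: Sequence[VariantCall],
                 links: Sequence[AltSiteLink]) -> list[AnnotatedVariant]:
    """Rebuild AnnotatedVariants from a call set plus a link table."""
    by_source: dict[tuple[str, int], list[AltSiteLink]] = {}
    for l in links:
        by_source.setdefault((l.from_chrom, l.from_pos), []).append(l)
    out = []
    for call in calls:
        ls = tuple(sorted(by_source.get((call.chrom, call.pos), ()),
                          key=lambda l: (l.to_chrom, l.to_pos)))
        marks = set(call.filters) & {MARK_MANY, MARK_INDEL, MARK_ERRORS}
        out.append(AnnotatedVariant(call, ls, marks))
    return out
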