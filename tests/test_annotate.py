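"""Projection, read-consistency rules, linking, clustering and pooled BAF."""

import networkx as nx
import numpy as np
import pytest

from varthesaurus import annotate as an
from varthesaurus import thesaurus_build as tb
from varthesaurus.annotate import ReadObservation, ReadStore
from varthesaurus.seqio import (
    AlignedRead,
    GenomicInterval,
    MARK_ERRORS,
    MARK_INDEL,
    MARK_MANY,
    Mismatch,
    ThesaurusEntry,
    ThesaurusTable,
    VariantCall,
)
from varthesaurus.simulate import RepeatGenomeSpec, make_repeat_genome

ENTRY_PLUS = ThesaurusEntry(GenomicInterval("A", 1, 100),
                            GenomicInterval("B", 501, 600), "+")
ENTRY_MINUS = ThesaurusEntry(GenomicInterval("A", 1, 100),
                             GenomicInterval("B", 501, 600), "-")


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


class TestProjection:
    def test_plus_strand_affine(self):
        assert an.project_position(ENTRY_PLUS, 1) == ("B", 501, "+")
        assert an.project_position(ENTRY_PLUS, 100) == ("B", 600, "+")

    def test_minus_strand_mirror(self):
        assert an.project_position(ENTRY_MINUS, 1) == ("B", 600, "-")
        assert an.project_position(ENTRY_MINUS, 100) == ("B", 501, "-")

    def test_outside_origin_is_contract_error(self):
        with pytest.raises(ValueError, match="outside"):
            an.project_position(ENTRY_PLUS, 101)

    def test_projection_is_involution(self):
        rng = np.random.default_rng(3)
        from conftest import random_entries
        for entry in random_entries(rng, 100):
            pos = int(rng.integers(entry.origin.start, entry.origin.end + 1))
            back = entry.flipped().project(entry.project(pos))
            assert back == pos


# ---------------------------------------------------------------------------
# Read consistency
# ---------------------------------------------------------------------------


def _obs(mismatches, carries=True, indel=False, n_errors=None):
    mms = tuple(mismatches)
    return ReadObservation(
        read_name="r", interval=GenomicInterval("A", 1, 100), strand="+",
        carries_variant=carries,
        n_errors=len(mms) if n_errors is None else n_errors,
        has_indel_or_splice=indel, mismatches=mms,
    )


class TestReadConsistency:
    ENTRY = ThesaurusEntry(
        GenomicInterval("A", 1, 100), GenomicInterval("B", 501, 600), "+",
        (Mismatch(40, "C", "T"),),
    )

    def test_entry_recorded_mismatch_is_explained(self):
        obs = _obs([(40, "T")])
        assert an.read_consistent_with_entry(obs, self.ENTRY, {})

    def test_called_variant_at_origin_is_explained(self):
        obs = _obs([(55, "G")])
        assert an.read_consistent_with_entry(obs, self.ENTRY,
                                             {("A", 55): "G"})

    def test_called_variant_at_projected_site_is_explained(self):
        # origin position 30 projects to B:530
        obs = _obs([(30, "G")])
        assert an.read_consistent_with_entry(obs, self.ENTRY,
                                             {("B", 530): "G"})

    def test_minus_strand_projection_complements_allele(self):
        entry = ThesaurusEntry(
            GenomicInterval("A", 1, 100), GenomicInterval("B", 501, 600), "-")
        obs = _obs([(30, "G")])
        # A:30 projects to B:571 with complemented allele C
        assert an.read_consistent_with_entry(obs, entry, {("B", 571): "C"})
        assert not an.read_consistent_with_entry(
            obs, entry, {("B", 571): "G"}, max_extra_mm=0)

    def test_residual_budget(self):
        two = _obs([(10, "G"), (20, "G")])
        three = _obs([(10, "G"), (20, "G"), (30, "G")])
        assert an.read_consistent_with_entry(two, self.ENTRY, {})
        assert not an.read_consistent_with_entry(three, self.ENTRY, {})


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------


class TestLinkVariant:
    VARIANT = VariantCall("A", 50, "A", "G")
    ENTRY = ThesaurusEntry(GenomicInterval("A", 1, 100),
                           GenomicInterval("B", 501, 600), "+")

    def _clean_obs(self, n, carries=True):
        return [_obs([(50, "G")], carries=carries) for _ in range(n)]

    def test_no_entries_no_links_no_marks(self):
        links, marks = an.link_variant(self.VARIANT, self._clean_obs(5), [],
                                       {("A", 50): "G"})
        assert links == () and marks == set()

    def test_link_emitted_with_projected_alleles(self):
        links, marks = an.link_variant(
            self.VARIANT, self._clean_obs(5), [self.ENTRY], {("A", 50): "G"})
        [link] = links
        assert (link.to_chrom, link.to_pos, link.strand) == ("B", 550, "+")
        assert link.proj_alt == "G"
        assert link.supporting_reads == 5
        assert marks == set()

    def test_below_min_reads_or_fraction_no_link(self):
        links, _ = an.link_variant(
            self.VARIANT, self._clean_obs(1), [self.ENTRY], {("A", 50): "G"})
        assert links == ()
        mixed = self._clean_obs(2) + [
            _obs([(50, "G"), (10, "T"), (20, "T"), (30, "T")])
            for _ in range(3)
        ]
        links, _ = an.link_variant(self.VARIANT, mixed, [self.ENTRY],
                                   {("A", 50): "G"})
        assert links == ()  # 2 of 5 consistent < 50%

    def test_excess_links_collapse_to_many_mark(self):
        entries = [
            ThesaurusEntry(GenomicInterval("A", 1, 100),
                           GenomicInterval("B", 501 + 1000 * i,
                                           600 + 1000 * i), "+")
            for i in range(5)
        ]
        links, marks = an.link_variant(
            self.VARIANT, self._clean_obs(5), entries, {("A", 50): "G"},
            max_links=3)
        assert links == () and marks == {MARK_MANY}

    def test_indel_and_error_marks(self):
        obs = [_obs([(50, "G")], indel=True),
               _obs([(50, "G")], n_errors=9)]
        _, marks = an.link_variant(self.VARIANT, obs, [], {("A", 50): "G"})
        assert marks == {MARK_INDEL, MARK_ERRORS}


# ---------------------------------------------------------------------------
# Read store / observations
# ---------------------------------------------------------------------------


class TestCollectVariantReads:
    def _store(self):
        ref = {"c": "ACGTACGTAC" * 10}
        reads = [
            AlignedRead("r1", "c", 1, "+", "20M", 60,
                        "ACGTACGTACACGTACGTAC".replace("C", "C")),
            AlignedRead("r2", "c", 5, "+", "20M", 60,
                        ref["c"][4:24]),
            AlignedRead("r3", "c", 5, "+", "5M2D15M", 60,
                        ref["c"][4:9] + ref["c"][11:26]),
        ]
        return ref, reads

    def test_counts_match_manual_pileup(self):
        spec = RepeatGenomeSpec(4_000, 1, 2, 300, 0.0, seed=5)
        genome, _ = make_repeat_genome(spec)
        from varthesaurus.simulate import sample_reads
        idx = tb.SeedIndex(genome)
        reads = sample_reads(genome, coverage=5, error_rate=0.01, seed=2)
        aligned = tb.align_reads(reads, idx, seed=3)
        store = ReadStore(aligned, genome)
        rng = np.random.default_rng(4)
        for _ in range(25):
            pos = int(rng.integers(200, 3800))
            alt = str(rng.choice(list("ACGT")))
            variant = VariantCall("chr1", pos, genome["chr1"][pos - 1], alt)
            obs = an.collect_variant_reads(store, variant)
            # independent oracle: walk the raw alignment records
            expected_total = expected_carrying = 0
            for r in aligned:
                if r.pos <= pos <= r.pos + len(r.seq) - 1:
                    expected_total += 1
                    if r.seq[pos - r.pos] == alt:
                        expected_carrying += 1
            assert len(obs) == expected_total
            assert sum(o.carries_variant for o in obs) == expected_carrying

    def test_deletion_flagged_as_indel(self):
        ref = {"c": "A" * 50}
        read = AlignedRead("r", "c", 1, "+", "10M2D10M", 60, "A" * 20)
        store = ReadStore([read], ref)
        [obs] = an.collect_variant_reads(store, VariantCall("c", 15, "A", "G"))
        assert obs.has_indel_or_splice
        assert not obs.carries_variant  # position 11-12 deleted, 15 is ref

    def test_uncovered_position_empty(self):
        ref = {"c": "A" * 50}
        store = ReadStore([AlignedRead("r", "c", 1, "+", "10M", 60, "A" * 10)],
                          ref)
        assert an.collect_variant_reads(store,
                                        VariantCall("c", 40, "A", "G")) == []


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _annotated(chrom, pos, links=()):
    av = an.AnnotatedVariant(VariantCall(chrom, pos, "A", "G"))
    av.links = tuple(
        an.AltSiteLink(chrom, pos, c, p, "+", "A", "G", 5, 1.0)
        for c, p in links
    )
    return av


class TestClustering:
    def test_no_links_all_singletons(self):
        avs = [_annotated("c", p) for p in (10, 20, 30)]
        clusters = an.cluster_variants(avs)
        assert [len(cl.members) for cl in clusters] == [1, 1, 1]
        assert sorted(av.cluster_id for av in avs) == [1, 2, 3]

    def test_mutual_pair_one_cluster(self):
        a = _annotated("c", 10, [("c", 20)])
        b = _annotated("c", 20, [("c", 10)])
        [cluster] = an.cluster_variants([a, b])
        assert len(cluster.members) == 2
        assert cluster.peripheral == []

    def test_uncalled_target_becomes_peripheral(self):
        a = _annotated("c", 10, [("c", 999)])
        [cluster] = an.cluster_variants([a])
        assert cluster.peripheral == [("c", 999, "A", "G")]

    def test_components_match_networkx_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            positions = rng.choice(np.arange(10, 10_000, 10), size=n,
                                   replace=False)
            avs = [_annotated("c", int(p)) for p in positions]
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i in range(n):
                for j in rng.choice(n, size=int(rng.integers(0, 3))):
                    j = int(j)
                    if j != i:
                        avs[i].links = avs[i].links + (
                            an.AltSiteLink("c", int(positions[i]), "c",
                                           int(positions[j]), "+", "A", "G",
                                           5, 1.0),)
                        g.add_edge(i, j)
            clusters = an.cluster_variants(avs)
            ours = {frozenset(id(m) for m in cl.members) for cl in clusters}
            theirs = {frozenset(id(avs[i]) for i in comp)
                      for comp in nx.connected_components(g)}
            assert ours == theirs


# ---------------------------------------------------------------------------
# Pooled BAF
# ---------------------------------------------------------------------------


class TestPooledBaf:
    def test_single_site_all_variant_reads(self):
        ref = {"c": "A" * 200}
        reads = [AlignedRead(f"r{i}", "c", 41, "+", "20M", 60,
                             "A" * 9 + "G" + "A" * 10) for i in range(10)]
        store = ReadStore(reads, ref)
        av = _annotated("c", 50)
        [cluster] = an.cluster_variants([av])
        result = an.pooled_baf(cluster, store)
        assert result.pooled == 1.0
        assert result.sites[0].baf == 1.0

    def test_uncovered_peripheral_site_skipped(self):
        ref = {"c": "A" * 2000}
        reads = [AlignedRead(f"r{i}", "c", 41, "+", "20M", 60,
                             "A" * 9 + "G" + "A" * 10) for i in range(4)]
        store = ReadStore(reads, ref)
        av = _annotated("c", 50, [("c", 1500)])
        [cluster] = an.cluster_variants([av])
        result = an.pooled_baf(cluster, store)
        assert [s.pos for s in result.sites] == [50]
        assert result.pooled == 1.0

    def test_scattered_haploid_evidence_pools_toward_unity(self):
        # variant reads split between two identical loci: per-site ~0.5 each,
        # pooled over both recovers ~1
        ref = {"c": "A" * 400}
        reads = []
        for i in range(5):
            reads.append(AlignedRead(f"v{i}", "c", 41, "+", "20M", 0,
                                     "A" * 9 + "G" + "A" * 10))
            reads.append(AlignedRead(f"w{i}", "c", 241, "+", "20M", 0,
                                     "A" * 9 + "G" + "A" * 10))
            reads.append(AlignedRead(f"x{i}", "c", 41, "+", "20M", 0, "A" * 20))
            reads.append(AlignedRead(f"y{i}", "c", 241, "+", "20M", 0,
                                     "A" * 20))
        store = ReadStore(reads, ref)
        a = _annotated("c", 50, [("c", 250)])
        b = _annotated("c", 250, [("c", 50)])
        [cluster] = an.cluster_variants([a, b])
        result = an.pooled_baf(cluster, store)
        assert result.sites[0].baf == 0.5
        assert result.pooled == 1.0
        assert result.pooled_fraction == 0.5


# ---------------------------------------------------------------------------
# Whole-VCF annotation
# ---------------------------------------------------------------------------


class TestAnnotateVcf:
    def test_unknown_chromosome_is_hard_error(self):
        ref = {"c": "A" * 200}
        store = ReadStore([], ref)
        with pytest.raises(ValueError, match="chrM"):
            an.annotate_vcf([VariantCall("chrM", 5, "A", "G")], store,
                            ThesaurusTable([]), ref)

    def test_order_preserved_and_non_snv_passthrough(self):
        ref = {"c": "A" * 200}
        store = ReadStore([], ref)
        calls = [VariantCall("c", 10, "A", "G"),
                 VariantCall("c", 20, "AT", "A"),  # deletion passes through
                 VariantCall("c", 30, "A", "C")]
        annotated, _ = an.annotate_vcf(calls, store, ThesaurusTable([]), ref)
        assert [av.call for av in annotated] == calls
        assert all(av.links == () and av.marks == set() for av in annotated)

    def test_two_copy_repeat_mutual_links_end_to_end(self):
        # one planted variant in copy 1 of an identical 2-copy repeat;
        # lenient calling yields calls at both loci, which link mutually
        spec = RepeatGenomeSpec(10_000, 1, 2, 500, 0.0, seed=21)
        genome, ann = make_repeat_genome(spec)
        c1, c2 = ann[0]
        var_pos = c1.start + 250
        sample = dict(genome)
        s = list(sample["chr1"])
        ref_base = s[var_pos - 1]
        alt_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        s[var_pos - 1] = alt_base
        sample["chr1"] = "".join(s)

        idx = tb.SeedIndex(genome)
        table = tb.build_thesaurus(genome, index=idx)
        from varthesaurus.simulate import sample_reads
        from varthesaurus.evaluate import naive_pileup_caller
        reads = sample_reads(sample, coverage=10, seed=22)
        aligned = tb.align_reads(reads, idx, seed=23)
        store = ReadStore(aligned, genome)
        calls = naive_pileup_caller(store, genome, min_mq=0, min_reads=2,
                                    min_fraction=0.3)
        annotated, clusters = an.annotate_vcf(calls, store, table, genome)
        mirror = var_pos - c1.start + c2.start
        linked = {av.call.pos: {l.to_pos for l in av.links}
                  for av in annotated if av.links}
        assert var_pos in linked and mirror in linked[var_pos]
        assert mirror in linked and var_pos in linked[mirror]
        # both calls fall in one cluster
        ids = {av.cluster_id for av in annotated
               if av.call.pos in (var_pos, mirror)}
        assert len(ids) == 1

    def test_links_survive_vcf_and_tsv_round_trip(self, tmp_path):
        ref = {"c": "A" * 200}
        av = _annotated("c", 10, [("c", 150)])
        av.cluster_id = 1
        an.write_annotated_vcf([av], tmp_path / "a.vcf", {"c": 200})
        an.write_links([av], tmp_path / "a.links.tsv")
        from varthesaurus.seqio import read_vcf
        [call] = read_vcf(tmp_path / "a.vcf")
        assert call.ts_alt_sites() == [("c", 150, "+")]
        assert call.info["TS_CLUSTER"] == 1
        links = an.read_links(tmp_path / "a.links.tsv")
        assert [(l.from_pos, l.to_pos) for l in links] == [(10, 150)]
        [back] = an.attach_links([call], links)
        assert back.links == links[0:1] or back.links == tuple(links)
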