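"""Synthetic data generation.

Everything the rest of the toolkit needs for testing and benchmarking is
generated here: repeat-family genomes (i.i.d. random background with pasted,
slightly diverged repeat copies — the simplest model producing controllable
low-mappability regions), planted SNVs at a per-kilobase rate, error-free
tiled reads for thesaurus construction, shotgun reads at a chosen coverage
and error rate, and the small worked-example fixture whose link topology
exercises the thesaurus-aware accounting.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .annotate import AltSiteLink, AnnotatedVariant
from .seqio import GenomicInterval, VariantCall, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatGenomeSpec:
    """Parameters of a synthetic repeat-family genome.

    ``divergence`` is the expected pairwise substitution fraction between
    copies of the same family (each copy is mutated independently from the
    family consensus at half this rate). It is capped at 0.04 so that copies
    stay within the all-mapper's four-mismatch reach per 100 bp.
    """

    genome_length: int
    n_families: int = 1
    copies_per_family: int = 2
    repeat_length: int = 500
    divergence: float = 0.0
    seed: int = 0
    chrom: str = "chr1"
    min_gap: int = 150

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 0.04:
            raise ValueError("divergence must be within [0, 0.04]")
        total = self.n_families * self.copies_per_family * self.repeat_length
        n_copies = self.n_families * self.copies_per_family
        if total + (n_copies + 1) * self.min_gap > self.genome_length:
            raise ValueError(
                "repeat copies plus minimum gaps exceed genome length "
                f"({total} bp of repeats in {self.genome_length} bp)"
            )


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def make_repeat_genome(
    spec: RepeatGenomeSpec,
) -> tuple[dict[str, str], dict[int, list[GenomicInterval]]]:
    """Generate a genome and the per-family repeat-copy intervals.

    The background is i.i.d. uniform A/C/G/T; each family is a random
    consensus whose copies are pasted at random non-overlapping positions
    after per-base substitution at ``divergence / 2``.
    """
    rng = np.random.default_rng(spec.seed)
    genome = rng.choice(_BASES, size=spec.genome_length)
    n_copies = spec.n_families * spec.copies_per_family
    slack = (spec.genome_length
             - n_copies * spec.repeat_length
             - (n_copies + 1) * spec.min_gap)
    # split the slack over the n_copies + 1 gaps, then lay copies end to end
    extra = rng.multinomial(slack, np.full(n_copies + 1, 1 / (n_copies + 1)))
    gaps = extra + spec.min_gap
    family_of_slot = np.repeat(np.arange(spec.n_families),
                               spec.copies_per_family)
    rng.shuffle(family_of_slot)
    consensus = {
        fam: rng.choice(_BASES, size=spec.repeat_length)
        for fam in range(spec.n_families)
    }
    annotation: dict[int, list[GenomicInterval]] = {
        fam: [] for fam in range(spec.n_families)
    }
    cursor = 0
    for slot, fam in enumerate(family_of_slot):
        cursor += int(gaps[slot])
        copy = consensus[fam].copy()
        if spec.divergence > 0:
            hit = rng.random(spec.repeat_length) < spec.divergence / 2
            for i in np.nonzero(hit)[0]:
                others = _BASES[_BASES != copy[i]]
                copy[i] = rng.choice(others)
        genome[cursor: cursor + spec.repeat_length] = copy
        annotation[int(fam)].append(
            GenomicInterval(spec.chrom, cursor + 1,
                            cursor + spec.repeat_length)
        )
        cursor += spec.repeat_length
    return {spec.chrom: _decode(genome)}, annotation


# ---------------------------------------------------------------------------
# Planted variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


def plant_variants(
    reference: Mapping[str, str],
    rate_per_kb: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, str], list[TruthVariant]]:
    """Plant SNVs by per-base binomial sampling at ``rate_per_kb / 1000``.

    Returns the mutated sample genome and the truth set; the sample differs
    from the reference exactly at the truth positions.
    """
    if rate_per_kb < 0:
        raise ValueError("rate_per_kb must be >= 0")
    rng = np.random.default_rng(seed)
    sample: dict[str, str] = {}
    truth: list[TruthVariant] = []
    for chrom in reference:
        seq = np.frombuffer(reference[chrom].encode(), dtype=np.uint8).copy()
        hit = rng.random(len(seq)) < rate_per_kb / 1000.0
        for i in np.nonzero(hit)[0]:
            ref_base = chr(seq[i])
            if ref_base not in "ACGT":
                continue
            others = _BASES[_BASES != seq[i]]
            alt = rng.choice(others)
            seq[i] = alt
            truth.append(TruthVariant(chrom, int(i) + 1, ref_base, chr(alt)))
        sample[chrom] = _decode(seq)
    return sample, sorted(truth)


def truth_to_calls(truth: list[TruthVariant]) -> list[VariantCall]:
    return [VariantCall(t.chrom, t.pos, t.ref, t.alt) for t in truth]


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimRead:
    """A simulated read with its recorded true origin."""

    name: str
    seq: str
    chrom: str
    start: int  # 1-based position of the leftmost aligned base
    strand: str


def tile_reads(reference: Mapping[str, str], read_len: int = 100,
               step: int = 10) -> list[SimRead]:
    """Error-free reads starting at 1, 1+step, ... on the forward strand.

    Interior per-base depth is exactly ``read_len / step``. Chromosomes
    shorter than ``read_len`` are skipped with a warning.
    """
    if read_len < step:
        raise ValueError("read_len must be at least step")
    reads: list[SimRead] = []
    for chrom, seq in reference.items():
        if len(seq) < read_len:
            warnings.warn(
                f"chromosome {chrom!r} shorter than read length; skipped"
            )
            continue
        for start0 in range(0, len(seq) - read_len + 1, step):
            reads.append(SimRead(
                name=f"{chrom}|{start0 + 1}",
                seq=seq[start0: start0 + read_len],
                chrom=chrom,
                start=start0 + 1,
                strand="+",
            ))
    return reads


def _inject_errors(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < error_rate
    for i in np.nonzero(hit)[0]:
        others = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(others)
    return _decode(arr)


def sample_reads(
    sample: Mapping[str, str],
    coverage: float = 10.0,
    error_rate: float = 0.0,
    read_len: int = 100,
    seed: int = 0,
    mode: str = "regular",
    paired: bool = False,
    insert_size: int = 300,
) -> list[SimRead]:
    """Shotgun reads from the sample genome.

    ``regular`` mode tiles fragment starts every ``read_len / coverage``
    bases so every interior position is covered by exactly ``coverage``
    reads; ``random`` mode draws starts uniformly. Errors are substitutions
    only. Paired mode emits both ends of a fixed-size insert.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must be within [0, 0.1)")
    if mode not in ("regular", "random"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    rng = np.random.default_rng(seed)
    reads: list[SimRead] = []
    counter = 0

    def emit(chrom: str, start0: int, seq_str: str) -> None:
        nonlocal counter
        window = seq_str[start0: start0 + read_len]
        strand = "+" if rng.integers(2) == 0 else "-"
        read_seq = window if strand == "+" else revcomp(window)
        read_seq = _inject_errors(read_seq, error_rate, rng)
        counter += 1
        reads.append(SimRead(
            name=f"r{counter:07d}",
            seq=read_seq,
            chrom=chrom,
            start=start0 + 1,
            strand=strand,
        ))

    span = insert_size if paired else read_len
    for chrom, seq_str in sample.items():
        L = len(seq_str)
        if L < span:
            continue
        if mode == "regular":
            stride = max(1, int(round(read_len / coverage)))
            if paired:
                stride *= 2  # two reads per fragment
            starts = range(0, L - span + 1, stride)
        else:
            n = int(round(coverage * L / (read_len * (2 if paired else 1))))
            starts = sorted(int(s) for s in rng.integers(0, L - span + 1, n))
        for s in starts:
            emit(chrom, s, seq_str)
            if paired:
                emit(chrom, s + insert_size - read_len, seq_str)
    return reads


def write_read_origins(reads: list[SimRead], path) -> None:
    """Sidecar TSV recording each read's true origin."""
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstart\tstrand\n")
        for r in reads:
            fh.write(f"{r.name}\t{r.chrom}\t{r.start}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------


@dataclass
class WorkedExample:
    """The illustrative 1-kb genome: three true variants, five calls.

    Topology: the orange variant's evidence is called at its true locus
    (100) and at a similar locus (150), with mutual links. The blue variant
    (400) is called only at the wrong locus (420), which links back to the
    true site. The red variant is called at its true locus (700) and at a
    similar locus (750); the latter additionally links to a third similar
    locus (800) that is not in the call set. The specific coordinates are
    arbitrary; only the topology matters.
    """

    genome_length: int
    truth: list[TruthVariant]
    calls: list[AnnotatedVariant]

    @property
    def plain_calls(self) -> list[VariantCall]:
        return [av.call for av in self.calls]


def worked_example_fixture() -> WorkedExample:
    chrom = "toy"

    def link(fp: int, tp: int, alt: str, ref: str) -> AltSiteLink:
        return AltSiteLink(chrom, fp, chrom, tp, "+", ref, alt, 5, 1.0)

    truth = [
        TruthVariant(chrom, 100, "A", "G"),
        TruthVariant(chrom, 400, "C", "T"),
        TruthVariant(chrom, 700, "G", "A"),
    ]
    calls = [
        AnnotatedVariant(VariantCall(chrom, 100, "A", "G"),
                         links=(link(100, 150, "G", "A"),)),
        AnnotatedVariant(VariantCall(chrom, 150, "A", "G"),
                         links=(link(150, 100, "G", "A"),)),
        AnnotatedVariant(VariantCall(chrom, 420, "C", "T"),
                         links=(link(420, 400, "T", "C"),)),
        AnnotatedVariant(VariantCall(chrom, 700, "G", "A"),
                         links=(link(700, 750, "A", "G"),)),
        AnnotatedVariant(VariantCall(chrom, 750, "G", "A"),
                         links=(link(750, 700, "A", "G"),
                                link(750, 800, "A", "G"))),
    ]
    return WorkedExample(genome_length=1000, truth=truth, calls=calls)


# ---------------------------------------------------------------------------
# Benchmark conditions
# ---------------------------------------------------------------------------


def benchmark_genome_spec(seed: int = 0,
                          genome_length: int = 100_000) -> RepeatGenomeSpec:
    """The repeat-rich benchmark genome: 3 families x 5 copies, 1% divergence.

    The 5 kb repeat unit (segmental-duplication scale) makes low-mappability
    sequence 75% of the genome, the regime the benchmark is designed to
    probe.
    """
    return RepeatGenomeSpec(
        genome_length=genome_length,
        n_families=3,
        copies_per_family=5,
        repeat_length=5000,
        divergence=0.01,
        seed=seed,
    )
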