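import numpy as np
import pytest

from varthesaurus.seqio import GenomicInterval, Mismatch, ThesaurusEntry
from varthesaurus.evaluate import run_benchmark


def random_entries(rng: np.random.Generator, n: int,
                   chroms=("chrA", "chrB"), max_pos: int = 10_000,
                   length_range=(20, 200)) -> list[ThesaurusEntry]:
    """Random, structurally valid thesaurus entries (sorted by origin)."""
    entries = []
    for _ in range(n):
        length = int(rng.integers(*length_range))
        ochrom = str(rng.choice(chroms))
        achrom = str(rng.choice(chroms))
        ostart = int(rng.integers(1, max_pos - length))
        astart = int(rng.integers(1, max_pos - length))
        strand = "+" if rng.random() < 0.5 else "-"
        mms = []
        used = set()
        for _ in range(int(rng.integers(0, 4))):
            pos = ostart + int(rng.integers(0, length))
            if pos in used:
                continue
            used.add(pos)
            ob, ab = rng.choice(list("ACGT"), size=2, replace=False)
            mms.append(Mismatch(pos, str(ob), str(ab)))
        entries.append(ThesaurusEntry(
            GenomicInterval(ochrom, ostart, ostart + length - 1),
            GenomicInterval(achrom, astart, astart + length - 1),
            strand, tuple(sorted(mms)),
        ))
    entries.sort(key=lambda e: (e.origin.chrom, e.origin.start, e.origin.end,
                                e.alt.chrom, e.alt.start, e.strand))
    return entries


@pytest.fixture(scope="session")
def benchmark():
    """The repeat-genome benchmark, run once and shared by evaluation tests."""
    return run_benchmark(seed=1)
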