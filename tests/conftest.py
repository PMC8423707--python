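import numpy as np
import pytest

from crypticsplice.annotation_io import GenomicInterval, JunctionCountMatrix


@pytest.fixture
def toy_gtf(tmp_path):
    """Single plus-strand transcript with exons [1,100],[201,300],[401,500]."""
    lines = []
    for s, e in [(1, 100), (201, 300), (401, 500)]:
        lines.append(
            f'chr1\ttest\texon\t{s}\t{e}\t.\t+\t.\tgene_id "G1"; transcript_id "T1";'
        )
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def toy_genome(tmp_path):
    """Deterministic 600 bp contig with a known sequence."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    path = tmp_path / "genome.fa"
    path.write_text(">chr1\n" + "\n".join(seq[i : i + 60] for i in range(0, 600, 60)) + "\n")
    return str(path), seq


def make_matrix(junction_tuples, counts, groups=None):
    """Build a JunctionCountMatrix from (chrom, start, end, strand) tuples."""
    counts = np.asarray(counts)
    n_samples = counts.shape[1]
    samples = [f"s{i+1}" for i in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = {s: ("control" if i < half else "knockdown")
                  for i, s in enumerate(samples)}
    junctions = [GenomicInterval(*t) for t in junction_tuples]
    return JunctionCountMatrix(junctions, samples, groups, counts)


@pytest.fixture
def cassette_matrix():
    """One cassette cluster: introns [101,200], [301,400], skip [101,400]."""
    return make_matrix(
        [("chr1", 101, 200, "+"), ("chr1", 301, 400, "+"), ("chr1", 101, 400, "+")],
        [[30, 40, 35, 200, 210, 190],
         [50, 45, 55, 180, 200, 195],
         [200, 190, 210, 20, 25, 30]],
    )
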