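"""Genomic interval types and readers for GTF, junction counts, FASTA and
conservation tracks.

All coordinates are held internally as 1-based inclusive (GTF-native).
BED-dialect inputs (regtools BED12, bedGraph) are converted on read, so a
stored intron ``[s, e]`` covers exactly the intronic bases ``s..e``.
Junction identity is ``(chrom, start, end, strand)``; a junction with
unknown strand (``.``) compares equal to either stranded form when matched
against an annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default chromosome-name alias map (UCSC -> GENCODE style).
DEFAULT_CHROM_ALIASES: dict[str, str] = {}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end} on {self.chrom}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def strand_compatible(self, other: "GenomicInterval") -> bool:
        return self.strand == "." or other.strand == "." or self.strand == other.strand

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


class TranscriptAnnotation:
    """Exons per transcript plus the derived (deduplicated) intron-junction set."""

    def __init__(
        self,
        exons: Mapping[str, Sequence[GenomicInterval]],
        gene_of_transcript: Mapping[str, str],
    ) -> None:
        self.exons: dict[str, list[GenomicInterval]] = {
            tx: sorted(exs) for tx, exs in exons.items()
        }
        self.gene_of_transcript = dict(gene_of_transcript)
        self.junctions: set[tuple[str, int, int, str]] = set()
        #: (chrom, start, end) -> strand-agnostic membership
        self._junctions_nostrand: set[tuple[str, int, int]] = set()
        self.gene_map: dict[tuple[str, int, int], str] = {}
        for tx, exs in self.exons.items():
            gene = self.gene_of_transcript.get(tx, tx)
            for a, b in zip(exs, exs[1:]):
                if b.start <= a.end + 1:
                    continue  # overlapping/adjacent exons yield no intron
                j = (a.chrom, a.end + 1, b.start - 1, a.strand)
                self.junctions.add(j)
                self._junctions_nostrand.add(j[:3])
                self.gene_map.setdefault(j[:3], gene)
            for e in exs:
                self.gene_map.setdefault((e.chrom, e.start, e.end), gene)

    def is_annotated(self, junction: GenomicInterval) -> bool:
        """True if the intron interval is an annotated junction.

        Unknown strand on either side matches either orientation.
        """
        if junction.strand == ".":
            return junction.key()[:3] in self._junctions_nostrand
        return (
            junction.key() in self.junctions
            or (junction.chrom, junction.start, junction.end, ".") in self.junctions
        )

    def gene_for(self, interval: GenomicInterval) -> str | None:
        return self.gene_map.get((interval.chrom, interval.start, interval.end))


@dataclass
class JunctionCountMatrix:
    """Intron-interval x sample matrix of junction-spanning read counts."""

    junctions: list[GenomicInterval]
    samples: list[str]
    groups: dict[str, str]
    counts: np.ndarray  # shape (n_junctions, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.junctions), len(self.samples)):
            raise ValueError("counts shape does not match junctions x samples")
        if (self.counts < 0).any():
            raise ValueError("negative junction counts")
        keys = [j.key() for j in self.junctions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate junctions in matrix")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    def group_indices(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(self.groups[s], []).append(i)
        return out

    def to_tsv(self, path: str) -> None:
        """Write the plain 1-based-inclusive TSV dialect (round-trips exactly)."""
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tstrand\t" + "\t".join(self.samples) + "\n")
            fh.write("#groups\t.\t.\t.\t" + "\t".join(self.groups[s] for s in self.samples) + "\n")
            for j, row in zip(self.junctions, self.counts):
                fh.write(
                    f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t"
                    + "\t".join(str(int(c)) for c in row)
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str) -> "JunctionCountMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            samples = header[4:]
            second = fh.readline().rstrip("\n").split("\t")
            if second and second[0] == "#groups":
                groups = dict(zip(samples, second[4:]))
                rows = fh.readlines()
            else:
                groups = {s: "unknown" for s in samples}
                rows = [("\t".join(second) + "\n")] + fh.readlines()
        junctions, counts = [], []
        for line in rows:
            parts = line.rstrip("\n").split("\t")
            junctions.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), parts[3])
            )
            counts.append([int(c) for c in parts[4:]])
        return cls(junctions, samples, groups, np.asarray(counts, dtype=np.int64))


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(
    path: str,
    feature_filter: Iterable[str] = ("exon",),
    chrom_aliases: Mapping[str, str] | None = None,
) -> TranscriptAnnotation:
    """Read exon features from a GENCODE-dialect GTF and derive the junction set.

    GTF is 1-based inclusive; coordinates are kept as-is. Exon records
    lacking a ``transcript_id`` attribute are skipped with a warning;
    malformed lines raise a :class:`ValueError` naming the line number.
    """
    wanted = set(feature_filter)
    aliases = dict(chrom_aliases or DEFAULT_CHROM_ALIASES)
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of_tx: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: malformed GTF line {lineno} "
                                 f"({len(parts)} fields, expected 9)")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = parts[:9]
            if feature not in wanted:
                continue
            try:
                iv = GenomicInterval(
                    aliases.get(chrom, chrom), int(start), int(end),
                    strand if strand in "+-" else ".",
                )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            attrs = _parse_gtf_attributes(attr)
            tx = attrs.get("transcript_id")
            if tx is None:
                logger.warning("%s line %d: exon without transcript_id skipped", path, lineno)
                continue
            exons.setdefault(tx, []).append(iv)
            if "gene_id" in attrs:
                gene_of_tx.setdefault(tx, attrs["gene_id"])
    return TranscriptAnnotation(exons, gene_of_tx)


def _read_regtools_bed12(path: str, aliases: Mapping[str, str]) -> dict[tuple, int]:
    """regtools `junctions extract` BED12: anchors + blockSizes encode the intron.

    0-based half-open anchor span; intron = [start + blockSize1, end - blockSize2)
    half-open, converted here to 1-based inclusive.
    """
    out: dict[tuple, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 12:
                raise ValueError(f"{path}: BED12 line {lineno} has {len(p)} fields")
            chrom = aliases.get(p[0], p[0])
            start, end = int(p[1]), int(p[2])
            count = int(p[4])
            if count < 0:
                raise ValueError(f"{path}: negative count at line {lineno}")
            strand = p[5] if p[5] in "+-" else "."
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            if len(sizes) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 blocks, got {len(sizes)}")
            intron_start0 = start + sizes[0]          # 0-based inclusive first intronic base
            intron_end0 = end - sizes[1]              # 0-based exclusive
            key = (chrom, intron_start0 + 1, intron_end0, strand)
            if key in out:
                logger.info("%s line %d: duplicate junction %s, counts summed", path, lineno, key)
            out[key] = out.get(key, 0) + count
    return out


def _read_plain_tsv(path: str, aliases: Mapping[str, str]) -> dict[tuple, int]:
    out: dict[tuple, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or line.lower().startswith("chrom\t"):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 5:
                raise ValueError(f"{path}: TSV line {lineno} has {len(p)} fields, expected 5")
            count = int(p[4])
            if count < 0:
                raise ValueError(f"{path}: negative count at line {lineno}")
            strand = p[3] if p[3] in "+-" else "."
            key = (aliases.get(p[0], p[0]), int(p[1]), int(p[2]), strand)
            if key in out:
                logger.info("%s line %d: duplicate junction %s, counts summed", path, lineno, key)
            out[key] = out.get(key, 0) + count
    return out


def read_junction_counts(
    paths: Sequence[str],
    dialect: str = "plain_tsv",
    sample_names: Sequence[str] | None = None,
    groups: Mapping[str, str] | None = None,
    chrom_aliases: Mapping[str, str] | None = None,
) -> JunctionCountMatrix:
    """Read per-sample junction files into one union matrix.

    ``dialect`` is ``"regtools_bed12"`` (0-based half-open with anchor
    blocks) or ``"plain_tsv"`` (chrom, start, end, strand, count; 1-based
    inclusive). Junctions absent from a sample get count 0.
    """
    if dialect not in ("regtools_bed12", "plain_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    aliases = dict(chrom_aliases or DEFAULT_CHROM_ALIASES)
    reader = _read_regtools_bed12 if dialect == "regtools_bed12" else _read_plain_tsv
    per_sample = [reader(p, aliases) for p in paths]

    # chromosome-naming sanity: mixing "chr1" and "1" styles across samples
    styles = [{k[0].startswith("chr") for k in d} for d in per_sample if d]
    flat = set().union(*styles) if styles else set()
    if len(flat) > 1:
        names = sorted({k[0] for d in per_sample for k in d})
        raise ValueError(f"inconsistent chromosome naming across samples: {names}")

    if sample_names is None:
        sample_names = [f"sample{i+1}" for i in range(len(paths))]
    groups = dict(groups or {s: "unknown" for s in sample_names})

    all_keys = sorted(set().union(*per_sample) if per_sample else set())
    counts = np.zeros((len(all_keys), len(paths)), dtype=np.int64)
    index = {k: i for i, k in enumerate(all_keys)}
    for s, d in enumerate(per_sample):
        for k, c in d.items():
            counts[index[k], s] = c
    junctions = [GenomicInterval(*k) for k in all_keys]
    return JunctionCountMatrix(junctions, list(sample_names), groups, counts)


@dataclass
class SequenceRecord:
    """Exon body plus flanks, all in transcript (5'->3') orientation."""

    interval: GenomicInterval
    body: str
    upstream: str
    downstream: str
    truncated: bool = False


def extract_sequences(
    genome: str | Fasta,
    intervals: Sequence[GenomicInterval],
    flank: int = 100,
) -> list[SequenceRecord]:
    """Extract exon-body and flanking sequences in transcript orientation.

    On the minus strand sequences are reverse-complemented and the flanks
    swapped, so ``upstream`` is always 5' of the exon as transcribed.
    Strand must be known; flanks truncated at contig ends are flagged.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(genome)
    records = []
    for iv in intervals:
        if iv.strand == ".":
            raise ValueError(f"strand required for {iv.chrom}:{iv.start}-{iv.end}")
        if iv.chrom not in fa:
            raise ValueError(f"unknown contig {iv.chrom}")
        contig_len = len(fa[iv.chrom])
        if iv.end > contig_len or iv.start < 1:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside contig (len {contig_len})"
            )
        left_start = max(1, iv.start - flank)
        right_end = min(contig_len, iv.end + flank)
        truncated = left_start != iv.start - flank or right_end != iv.end + flank
        seq = str(fa[iv.chrom][left_start - 1 : right_end]).upper()
        off = iv.start - left_start
        left = seq[:off]
        body = seq[off : off + iv.length]
        right = seq[off + iv.length :]
        if iv.strand == "-":
            body = reverse_complement(body)
            upstream, downstream = reverse_complement(right), reverse_complement(left)
        else:
            upstream, downstream = left, right
        records.append(SequenceRecord(iv, body, upstream, downstream, truncated))
    return records


class BaseScoreTrack:
    """Per-base score track (e.g. PhyloP conservation) from a bedGraph.

    Intervals are stored 1-based inclusive; queries outside coverage
    return NaN, and means are taken over covered bases only.
    """

    MISSING = float("nan")

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # per chrom: (starts, ends, scores) sorted by start, non-overlapping
        self._data = dict(intervals)

    @classmethod
    def from_bedgraph(cls, path: str, chrom_aliases: Mapping[str, str] | None = None) -> "BaseScoreTrack":
        aliases = dict(chrom_aliases or DEFAULT_CHROM_ALIASES)
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "score"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "score": float},
        )
        df["chrom"] = df["chrom"].map(lambda c: aliases.get(c, c))
        data = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy() + 1     # bedGraph is 0-based half-open
            ends = sub["end"].to_numpy()
            if (starts[1:] <= ends[:-1]).any():
                bad = int(np.argmax(starts[1:] <= ends[:-1]))
                raise ValueError(f"overlapping bedGraph intervals on {chrom} near row {bad}")
            data[chrom] = (starts, ends, sub["score"].to_numpy())
        return cls(data)

    def query(self, chrom: str, pos: int) -> float:
        """Score at a 1-based position, NaN if uncovered."""
        if chrom not in self._data:
            return self.MISSING
        starts, ends, scores = self._data[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos <= ends[i]:
            return float(scores[i])
        return self.MISSING

    def mean(self, interval: GenomicInterval) -> float:
        """Mean score over covered bases of the interval; NaN if none covered."""
        if interval.chrom not in self._data:
            return self.MISSING
        starts, ends, scores = self._data[interval.chrom]
        lo = np.searchsorted(ends, interval.start, side="left")
        hi = np.searchsorted(starts, interval.end, side="right")
        total, nbases = 0.0, 0
        for i in range(lo, hi):
            a = max(starts[i], interval.start)
            b = min(ends[i], interval.end)
            if a <= b:
                total += scores[i] * (b - a + 1)
                nbases += b - a + 1
        return total / nbases if nbases else self.MISSING
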