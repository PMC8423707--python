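"""Leafcutter-style clustering of overlapping splice junctions.

Junctions (intron intervals) on the same chromosome are connected when
their intervals share at least one base or when they share a splice site
(identical donor or acceptor coordinate); connected components become
clusters. Clusters are then pruned with three read-support filters:
a maximum intron length applied up front, an iterated minimum
proportional contribution per junction, and a minimum total read count
per cluster. Counts are pooled across all samples for these filters.

Strand handling: junctions of unknown strand ('.') may join a cluster of
either strand but are never allowed to bridge a '+' and a '-' cluster;
components are therefore formed per strand with unknown-strand junctions
eligible on both sides (a '.' junction overlapping both strands appears
in both clusters), and all-unknown components are emitted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation_io import GenomicInterval, JunctionCountMatrix

logger = logging.getLogger(__name__)

MAX_PRUNE_ITERATIONS = 100


@dataclass
class JunctionCluster:
    cluster_id: str
    junction_indices: list[int]  # indices into the source JunctionCountMatrix
    chrom: str
    strand: str
    span: GenomicInterval

    def __len__(self) -> int:
        return len(self.junction_indices)


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
            self.parent[rb] = ra


def _overlap_components(items: list[tuple[int, GenomicInterval]]) -> list[list[int]]:
    """Components under interval-overlap or shared-splice-site adjacency.

    ``items`` are (matrix index, interval) on one chromosome, already
    restricted to mutually strand-compatible junctions.
    """
    if not items:
        return []
    order = sorted(range(len(items)), key=lambda i: (items[i][1].start, items[i][1].end))
    uf = _UnionFind(len(items))

    # overlap edges via sweep over start-sorted intervals
    active: list[int] = []
    for pos in order:
        iv = items[pos][1]
        active = [a for a in active if items[a][1].end >= iv.start]
        for a in active:
            uf.union(a, pos)
        active.append(pos)

    # shared-splice-site edges (identical donor or acceptor coordinate)
    by_site: dict[tuple[str, int], list[int]] = {}
    for pos, (_, iv) in enumerate(items):
        by_site.setdefault(("s", iv.start), []).append(pos)
        by_site.setdefault(("e", iv.end), []).append(pos)
    for members in by_site.values():
        for a, b in zip(members, members[1:]):
            uf.union(a, b)

    comps: dict[int, list[int]] = {}
    for pos in range(len(items)):
        comps.setdefault(uf.find(pos), []).append(pos)
    return [[items[p][0] for p in comp] for comp in comps.values()]


def _connected_components(
    items: list[tuple[int, GenomicInterval]],
) -> list[list[int]]:
    """Per-strand components; unknown-strand junctions are eligible on
    both strands but never bridge '+' and '-'. All-unknown components
    (identical in both passes) are emitted once."""
    strands_present = {iv.strand for _, iv in items}
    if strands_present <= {"+", "."} or strands_present <= {"-", "."}:
        return _overlap_components(items)
    seen: set[frozenset[int]] = set()
    out: list[list[int]] = []
    for s in ("+", "-"):
        eligible = [(i, iv) for i, iv in items if iv.strand in (s, ".")]
        for comp in _overlap_components(eligible):
            key = frozenset(comp)
            if key not in seen:
                seen.add(key)
                out.append(comp)
    return out


def cluster_junctions(
    matrix: JunctionCountMatrix,
    min_cluster_reads: int = 60,
    min_prop: float = 0.001,
    max_intron: int = 200_000,
) -> list[JunctionCluster]:
    """Cluster junctions and apply the read-support and intron-length filters.

    Filters, in order: junctions with intron length > ``max_intron`` are
    removed before clustering; within each connected component, junctions
    contributing < ``min_prop`` of the component's pooled reads are
    dropped and components re-formed, iterated to a fixed point; finally
    components with pooled reads < ``min_cluster_reads`` or fewer than
    two junctions are discarded.
    """
    if matrix.n_junctions == 0:
        return []
    pooled = matrix.counts.sum(axis=1)
    surviving = [
        i for i, j in enumerate(matrix.junctions) if j.length <= max_intron
    ]

    by_chrom: dict[str, list[int]] = {}
    for i in surviving:
        by_chrom.setdefault(matrix.junctions[i].chrom, []).append(i)

    final_components: list[list[int]] = []
    for chrom in sorted(by_chrom):
        members = by_chrom[chrom]
        stable_components: list[list[int]] = []
        # prune low-contribution junctions and re-form components to a fixed point
        work = [members]
        iterations = 0
        while work and iterations < MAX_PRUNE_ITERATIONS:
            iterations += 1
            next_work: list[list[int]] = []
            for comp in work:
                items = [(i, matrix.junctions[i]) for i in sorted(comp)]
                for sub in _connected_components(items):
                    total = int(pooled[sub].sum())
                    if total <= 0:
                        continue
                    keep = [i for i in sub if pooled[i] >= min_prop * total]
                    if len(keep) == len(sub):
                        stable_components.append(sub)
                    elif len(keep) >= 2:
                        next_work.append(keep)
            work = next_work
        stable_components.extend(work)  # cap reached: accept as-is
        final_components.extend(stable_components)

    clusters: list[JunctionCluster] = []
    for comp in final_components:
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        if pooled[comp].sum() < min_cluster_reads:
            continue
        ivs = [matrix.junctions[i] for i in comp]
        strands = {iv.strand for iv in ivs} - {"."}
        strand = strands.pop() if len(strands) == 1 else "."
        span = GenomicInterval(
            ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs), strand
        )
        clusters.append(JunctionCluster("", comp, span.chrom, strand, span))

    clusters.sort(key=lambda c: (c.chrom, c.span.start, c.span.end, c.strand))
    seen: dict[tuple, int] = {}
    for c in clusters:
        base = (c.chrom, c.span.start, c.span.end, c.strand)
        seen[base] = seen.get(base, 0) + 1
        c.cluster_id = cluster_fingerprint(c, ordinal=seen[base])
    return clusters


def cluster_fingerprint(cluster: JunctionCluster, ordinal: int = 1) -> str:
    """Canonical, run-stable cluster id: ``chrom:minStart-maxEnd:strand:k``."""
    return f"{cluster.chrom}:{cluster.span.start}-{cluster.span.end}:{cluster.strand}:{ordinal}"


def cluster_counts(matrix: JunctionCountMatrix, cluster: JunctionCluster) -> np.ndarray:
    """Junction x sample count submatrix for a cluster."""
    return matrix.counts[cluster.junction_indices, :]
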