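"""Cassette topology, novelty annotation, PSI arithmetic and labels."""

import itertools

import numpy as np
import pytest

from conftest import make_matrix
from crypticsplice.annotation_io import GenomicInterval, read_gtf
from crypticsplice.cassette_classification import (
    CassetteEvent,
    annotate_novelty,
    classify_event,
    compute_psi,
    find_cassette_events,
    run_classification,
)
from crypticsplice.differential_splicing import differential_splicing
from crypticsplice.junction_clustering import cluster_junctions


def brute_force_triples(cluster, matrix, max_exon=250):
    """Independent enumeration of all ordered junction triples."""
    events = set()
    idx = cluster.junction_indices
    for ai, bi, si in itertools.permutations(idx, 3):
        j1, j2, skip = (matrix.junctions[ai], matrix.junctions[bi], matrix.junctions[si])
        if j1.start != skip.start or j2.end != skip.end:
            continue
        if not (j1.end < j2.start - 1):
            continue
        if j1.end >= skip.end or j2.start <= skip.start:
            continue
        exon = (j1.end + 1, j2.start - 1)
        if exon[1] - exon[0] + 1 <= max_exon:
            events.add(exon)
    return events


def _event(matrix):
    (cluster,) = cluster_junctions(matrix, min_cluster_reads=1)
    events = find_cassette_events(cluster, matrix)
    assert len(events) == 1
    return events[0]


class TestTopology:
    def test_basic_cassette_found(self, cassette_matrix):
        e = _event(cassette_matrix)
        assert (e.exon.start, e.exon.end) == (201, 300)
        assert e.exon.length == 100
        assert e.containing_intron.key() == ("chr1", 101, 400, "+")

    def test_oversized_exon_removed(self):
        # exon [201, 500] = 300 bp > 250
        m = make_matrix(
            [("chr1", 101, 200, "+"), ("chr1", 501, 600, "+"), ("chr1", 101, 600, "+")],
            np.full((3, 2), 50),
        )
        (cluster,) = cluster_junctions(m, min_cluster_reads=1)
        assert find_cassette_events(cluster, m) == []

    def test_mismatched_outer_boundaries_no_event(self):
        m = make_matrix(
            [("chr1", 101, 200, "+"), ("chr1", 301, 400, "+"), ("chr1", 90, 400, "+")],
            np.full((3, 2), 50),
        )
        (cluster,) = cluster_junctions(m, min_cluster_reads=1)
        assert find_cassette_events(cluster, m) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_small_clusters(self, seed):
        """Random <=8-junction clusters match brute-force triple enumeration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        sites = sorted(rng.choice(np.arange(100, 2000, 37), size=2 * n, replace=False))
        juncs, seen = [], set()
        while len(juncs) < n:
            a, b = sorted(rng.choice(sites, size=2, replace=False))
            if a < b and (a, b) not in seen:
                seen.add((a, b))
                juncs.append(("chr1", int(a), int(b), "+"))
        m = make_matrix(juncs, rng.integers(1, 100, size=(n, 2)))
        clusters = cluster_junctions(m, min_cluster_reads=1, min_prop=1e-9)
        for cluster in clusters:
            if len(cluster) < 3:
                continue
            ours = {(e.exon.start, e.exon.end)
                    for e in find_cassette_events(cluster, m)}
            assert ours == brute_force_triples(cluster, m)

    def test_duplicate_exons_keep_highest_support_triple(self):
        # two inclusion pairs produce the same exon; skip junctions differ
        m = make_matrix(
            [("chr1", 101, 200, "+"), ("chr1", 301, 400, "+"),
             ("chr1", 101, 400, "+"),
             ("chr1", 101, 200, "."), ("chr1", 301, 450, "+"),
             ],
            [[5, 5], [5, 5], [50, 50], [100, 100], [7, 7]],
        )
        clusters = cluster_junctions(m, min_cluster_reads=1)
        events = [e for c in clusters for e in find_cassette_events(c, m)]
        exons = [(e.exon.start, e.exon.end) for e in events]
        assert exons.count((201, 300)) == 1


class TestNovelty:
    def test_annotation_statuses(self, toy_gtf, cassette_matrix):
        ann = read_gtf(toy_gtf)  # junctions [101,200] and [301,400] annotated
        e = _event(cassette_matrix)
        # inclusion junctions annotated, skipping junction [101,400] is not
        assert annotate_novelty(e, ann) == "skipping_novel"
        assert e.novel

    def test_inclusion_novel_is_classic_cryptic(self, tmp_path, cassette_matrix):
        # annotate only the skipping isoform (exons [1,100], [401,500])
        p = tmp_path / "skip_only.gtf"
        p.write_text(
            'chr1\tt\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tt\texon\t401\t500\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        e = _event(cassette_matrix)
        assert annotate_novelty(e, read_gtf(str(p))) == "inclusion_novel"

    def test_both_annotated_and_fully_novel(self, tmp_path, cassette_matrix):
        p = tmp_path / "both.gtf"
        p.write_text(
            'chr1\tt\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "Ti";\n'
            'chr1\tt\texon\t201\t300\t.\t+\t.\tgene_id "G"; transcript_id "Ti";\n'
            'chr1\tt\texon\t401\t500\t.\t+\t.\tgene_id "G"; transcript_id "Ti";\n'
            'chr1\tt\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "Ts";\n'
            'chr1\tt\texon\t401\t500\t.\t+\t.\tgene_id "G"; transcript_id "Ts";\n'
        )
        e = _event(cassette_matrix)
        assert annotate_novelty(e, read_gtf(str(p))) == "both_annotated"
        assert not e.novel
        empty = tmp_path / "none.gtf"
        empty.write_text('chr2\tt\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n')
        assert annotate_novelty(e, read_gtf(str(empty))) == "fully_novel"


class TestPsi:
    def test_bounded_psi_arithmetic(self):
        # inclusion 30 and 50 -> m = 40; skipping 20 -> PSI = 40/60
        m = make_matrix(
            [("chr1", 101, 200, "+"), ("chr1", 301, 400, "+"), ("chr1", 101, 400, "+")],
            [[30, 30], [50, 50], [20, 20]],
            groups={"s1": "control", "s2": "knockdown"},
        )
        e = _event(m)
        compute_psi(e, m)
        assert e.psi_per_sample["s1"] == pytest.approx(40 / 60)

    def test_zero_inclusion_gives_zero_psi(self):
        m = make_matrix(
            [("chr1", 101, 200, "+"), ("chr1", 301, 400, "+"), ("chr1", 101, 400, "+")],
            [[0, 0], [0, 0], [100, 100]],
            groups={"s1": "control", "s2": "knockdown"},
        )
        e = CassetteEvent(
            cluster_id="c", exon=GenomicInterval("chr1", 201, 300, "+"),
            containing_intron=m.junctions[2],
            inclusion_junctions=(m.junctions[0], m.junctions[1]),
            skipping_junction=m.junctions[2],
            inclusion_indices=(0, 1), skipping_index=2,
        )
        compute_psi(e, m)
        assert e.psi_per_sample["s1"] == 0.0

    def test_group_means_and_dpsi(self, cassette_matrix):
        e = _event(cassette_matrix)
        compute_psi(e, cassette_matrix)
        psis = e.psi_per_sample
        ctrl = np.mean([psis["s1"], psis["s2"], psis["s3"]])
        case = np.mean([psis["s4"], psis["s5"], psis["s6"]])
        assert e.psi_control == pytest.approx(ctrl)
        assert e.dpsi == pytest.approx(case - ctrl)
        assert 0 <= e.psi_control <= 1 and -1 <= e.dpsi <= 1

    def test_low_coverage_sample_missing(self):
        m = make_matrix(
            [("chr1", 101, 200, "+"), ("chr1", 301, 400, "+"), ("chr1", 101, 400, "+")],
            [[2, 30], [2, 50], [3, 20]],
            groups={"s1": "control", "s2": "knockdown"},
        )
        e = _event(m)
        compute_psi(e, m, min_event_reads=15)
        assert np.isnan(e.psi_per_sample["s1"])
        assert not e.quantifiable  # control group all-missing


class TestClassify:
    @pytest.mark.parametrize("psi_control,dpsi,expected", [
        (0.05, 0.25, "cryptic"),
        (0.95, -0.20, "skiptic"),
        (0.50, 0.05, "weak"),
        (0.50, 0.30, "included"),
        (0.50, -0.30, "skipped"),
        (0.15, 0.25, "included"),   # control PSI too high for cryptic
        (0.85, -0.25, "skipped"),   # control PSI too low for skiptic
        (0.05, 0.08, "weak"),
    ])
    def test_label_rules(self, psi_control, dpsi, expected):
        e = CassetteEvent(
            cluster_id="c", exon=GenomicInterval("chr1", 201, 300, "+"),
            containing_intron=GenomicInterval("chr1", 101, 400, "+"),
            inclusion_junctions=(GenomicInterval("chr1", 101, 200, "+"),
                                 GenomicInterval("chr1", 301, 400, "+")),
            skipping_junction=GenomicInterval("chr1", 101, 400, "+"),
        )
        e.psi_control, e.dpsi = psi_control, dpsi
        e.psi_case = psi_control + dpsi
        assert classify_event(e) == expected

    def test_every_quantifiable_event_gets_exactly_one_label(self):
        rng = np.random.default_rng(1)
        labels = set()
        for _ in range(200):
            e = CassetteEvent(
                cluster_id="c", exon=GenomicInterval("chr1", 201, 300, "+"),
                containing_intron=GenomicInterval("chr1", 101, 400, "+"),
                inclusion_junctions=(GenomicInterval("chr1", 101, 200, "+"),
                                     GenomicInterval("chr1", 301, 400, "+")),
                skipping_junction=GenomicInterval("chr1", 101, 400, "+"),
            )
            e.psi_control = float(rng.uniform(0, 1))
            e.psi_case = float(rng.uniform(0, 1))
            e.dpsi = e.psi_case - e.psi_control
            labels.add(classify_event(e))
        assert labels <= {"cryptic", "skiptic", "included", "skipped", "weak"}


class TestRunClassification:
    def test_empty_table_when_nothing_significant(self):
        m = make_matrix(
            [("chr1", 101, 200, "+"), ("chr1", 301, 400, "+"), ("chr1", 101, 400, "+")],
            np.full((3, 4), 50),
            groups={"s1": "control", "s2": "control",
                    "s3": "knockdown", "s4": "knockdown"},
        )
        clusters = cluster_junctions(m, min_cluster_reads=1)
        results, _ = differential_splicing(m, clusters)
        events, table, summary = run_classification(m, clusters, results)
        assert len(table) == 0
        assert summary["n_cassette"] == 0
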