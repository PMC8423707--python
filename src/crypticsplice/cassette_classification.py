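"""Cassette-exon topology detection, PSI quantification, and the
cryptic/skiptic classification.

A cassette event inside a junction cluster is a triple of introns: two
inclusion junctions flanking a central exon and one skipping junction
spanning both, i.e. ``j1.start == skip.start``, ``j2.end == skip.end``
and exon ``[j1.end + 1, j2.start - 1]``. Putative exons longer than
250 bp are discarded.

Percent spliced in (PSI) per sample uses the bounded form
``m / (m + s)`` with ``m`` the mean of the two inclusion-junction counts
and ``s`` the skipping count. The unbounded literal ratio ``m / s`` is
available behind a flag but is capped at 1 for classification, since
the published "PSI > 90%" thresholds presuppose a bounded quantity.

Events are labelled: cryptic (control PSI < 0.10, dPSI > 0.10), skiptic
(control PSI > 0.90, dPSI < -0.10), otherwise included / skipped by the
sign of dPSI at |dPSI| >= 0.10, else weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import GenomicInterval, JunctionCountMatrix, TranscriptAnnotation
from .junction_clustering import JunctionCluster

logger = logging.getLogger(__name__)

MAX_EXON_LENGTH = 250
DEFAULT_MIN_EVENT_READS = 15


@dataclass
class CassetteEvent:
    cluster_id: str
    exon: GenomicInterval
    containing_intron: GenomicInterval       # the skipping junction's intron
    inclusion_junctions: tuple[GenomicInterval, GenomicInterval]
    skipping_junction: GenomicInterval
    inclusion_indices: tuple[int, int] = (0, 0)  # matrix rows
    skipping_index: int = 0
    annot_status: str = "unknown"
    psi_per_sample: dict[str, float] = field(default_factory=dict)
    psi_control: float = np.nan
    psi_case: float = np.nan
    dpsi: float = np.nan
    exon_set: str = "unclassified"
    gene: str | None = None
    quantifiable: bool = True

    @property
    def novel(self) -> bool:
        return self.annot_status != "both_annotated"


def find_cassette_events(
    cluster: JunctionCluster,
    matrix: JunctionCountMatrix,
    max_exon: int = MAX_EXON_LENGTH,
) -> list[CassetteEvent]:
    """Enumerate cassette triples in a cluster (topology only).

    Duplicate central exons arising from different triples are
    deduplicated keeping the triple with the highest pooled inclusion
    reads.
    """
    idx = cluster.junction_indices
    ivs = [(i, matrix.junctions[i]) for i in idx]
    pooled = matrix.counts.sum(axis=1)
    best: dict[tuple[int, int], CassetteEvent] = {}
    best_support: dict[tuple[int, int], int] = {}
    for si, skip in ivs:
        for ai, j1 in ivs:
            if ai == si or j1.start != skip.start or j1.end >= skip.end:
                continue
            for bi, j2 in ivs:
                if bi in (si, ai) or j2.end != skip.end or j2.start <= skip.start:
                    continue
                if j2.start <= j1.end + 1:
                    continue  # exon would be empty
                exon_start, exon_end = j1.end + 1, j2.start - 1
                if exon_end - exon_start + 1 > max_exon:
                    continue
                strand = skip.strand if skip.strand != "." else (
                    j1.strand if j1.strand != "." else j2.strand
                )
                key = (exon_start, exon_end)
                support = int(pooled[ai] + pooled[bi])
                if key in best and best_support[key] >= support:
                    continue
                best[key] = CassetteEvent(
                    cluster_id=cluster.cluster_id,
                    exon=GenomicInterval(skip.chrom, exon_start, exon_end, strand),
                    containing_intron=skip,
                    inclusion_junctions=(j1, j2),
                    skipping_junction=skip,
                    inclusion_indices=(ai, bi),
                    skipping_index=si,
                )
                best_support[key] = support
    return [best[k] for k in sorted(best)]


def annotate_novelty(event: CassetteEvent, annotation: TranscriptAnnotation) -> str:
    """Classify the event's junctions against the transcript reference."""
    j1, j2 = event.inclusion_junctions
    inc_annot = annotation.is_annotated(j1) and annotation.is_annotated(j2)
    skip_annot = annotation.is_annotated(event.skipping_junction)
    if inc_annot and skip_annot:
        status = "both_annotated"
    elif not inc_annot and skip_annot:
        status = "inclusion_novel"
    elif inc_annot and not skip_annot:
        status = "skipping_novel"
    else:
        status = "fully_novel"
    event.annot_status = status
    gene = annotation.gene_for(event.skipping_junction) or annotation.gene_for(j1)
    if gene is not None:
        event.gene = gene
    return status


def compute_psi(
    event: CassetteEvent,
    matrix: JunctionCountMatrix,
    min_event_reads: int = DEFAULT_MIN_EVENT_READS,
    control_group: str = "control",
    bounded: bool = True,
) -> CassetteEvent:
    """Per-sample and per-group PSI for a cassette event.

    ``m`` = mean of the two inclusion counts, ``s`` = skipping count;
    bounded PSI = ``m / (m + s)``. Samples with ``m + s`` below
    ``min_event_reads`` are treated as missing; group PSIs are means over
    non-missing samples and ``dpsi = psi_case - psi_control``.
    """
    a, b = event.inclusion_indices
    s_idx = event.skipping_index
    psi: dict[str, float] = {}
    for col, sample in enumerate(matrix.samples):
        m = 0.5 * (matrix.counts[a, col] + matrix.counts[b, col])
        s = float(matrix.counts[s_idx, col])
        if m + s < min_event_reads:
            psi[sample] = np.nan
            continue
        if bounded:
            psi[sample] = m / (m + s)
        else:
            psi[sample] = min(1.0, m / s) if s > 0 else 1.0
    event.psi_per_sample = psi

    groups = matrix.group_indices()
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in matrix groups")
    case_group = next(g for g in sorted(groups) if g != control_group)

    def group_mean(g: str) -> float:
        vals = [psi[matrix.samples[i]] for i in groups[g]]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else np.nan

    event.psi_control = group_mean(control_group)
    event.psi_case = group_mean(case_group)
    event.dpsi = event.psi_case - event.psi_control
    event.quantifiable = not (np.isnan(event.psi_control) or np.isnan(event.psi_case))
    if not event.quantifiable:
        logger.info("event %s:%d-%d unquantifiable (all-missing group)",
                    event.exon.chrom, event.exon.start, event.exon.end)
    return event


def classify_event(
    event: CassetteEvent,
    psi_low: float = 0.10,
    psi_high: float = 0.90,
    dpsi_threshold: float = 0.10,
) -> str:
    """Assign the exon_set label from control PSI and dPSI."""
    if not event.quantifiable:
        event.exon_set = "unquantifiable"
        return event.exon_set
    pc, d = event.psi_control, event.dpsi
    if pc < psi_low and d > dpsi_threshold:
        label = "cryptic"
    elif pc > psi_high and d < -dpsi_threshold:
        label = "skiptic"
    elif d >= dpsi_threshold:
        label = "included"
    elif d <= -dpsi_threshold:
        label = "skipped"
    else:
        label = "weak"
    event.exon_set = label
    return label


def events_to_table(events: list[CassetteEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "cluster_id": e.cluster_id,
                "gene": e.gene,
                "exon_coords": f"{e.exon.chrom}:{e.exon.start}-{e.exon.end}",
                "intron_coords": (
                    f"{e.containing_intron.chrom}:"
                    f"{e.containing_intron.start}-{e.containing_intron.end}"
                ),
                "strand": e.exon.strand,
                "exon_length": e.exon.length,
                "annot_status": e.annot_status,
                "novel": e.novel,
                "psi_control": e.psi_control,
                "psi_case": e.psi_case,
                "dpsi": e.dpsi,
                "exon_set": e.exon_set,
            }
        )
    return pd.DataFrame(rows)


def run_classification(
    matrix: JunctionCountMatrix,
    clusters: list[JunctionCluster],
    dm_results,
    annotation: TranscriptAnnotation | None = None,
    fdr: float = 0.05,
    dpsi_threshold: float = 0.10,
    psi_low: float = 0.10,
    psi_high: float = 0.90,
    min_event_reads: int = DEFAULT_MIN_EVENT_READS,
    control_group: str = "control",
    scan_all_clusters: bool = False,
) -> tuple[list[CassetteEvent], pd.DataFrame, dict]:
    """Scan significant clusters for cassette events and classify them.

    Returns the events, the results table and a summary-count dict
    (clusters tested/significant, cassette events, events with
    |dPSI| >= threshold, cryptic/skiptic and their novel subsets).
    """
    by_id = {r.cluster_id: r for r in dm_results}
    missing = [c.cluster_id for c in clusters if c.cluster_id not in by_id]
    if missing:
        raise ValueError(f"clusters without DM results: {missing[:5]}")

    events: list[CassetteEvent] = []
    n_significant = 0
    for c in clusters:
        r = by_id[c.cluster_id]
        if r.failed:
            continue
        if r.significant:
            n_significant += 1
        elif not scan_all_clusters:
            continue
        for e in find_cassette_events(c, matrix):
            compute_psi(e, matrix, min_event_reads=min_event_reads,
                        control_group=control_group)
            classify_event(e, psi_low=psi_low, psi_high=psi_high,
                           dpsi_threshold=dpsi_threshold)
            if annotation is not None:
                annotate_novelty(e, annotation)
            events.append(e)

    table = events_to_table(events)
    quant = [e for e in events if e.quantifiable]
    summary = {
        "n_clusters_tested": int(sum(1 for r in dm_results if not r.failed)),
        "n_significant": int(n_significant),
        "n_cassette": len(quant),
        "n_effect": int(sum(abs(e.dpsi) >= dpsi_threshold for e in quant)),
        "n_cryptic": int(sum(e.exon_set == "cryptic" for e in quant)),
        "n_novel_cryptic": int(sum(e.exon_set == "cryptic" and e.novel for e in quant)),
        "n_skiptic": int(sum(e.exon_set == "skiptic" for e in quant)),
        "n_novel_skiptic": int(sum(e.exon_set == "skiptic" and e.novel for e in quant)),
    }
    logger.info("classification summary: %s", summary)
    return events, table, summary
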