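"""End-to-end orchestration: junction files -> clusters -> DM test ->
cassette classification -> optional sequence features, with TSV outputs
and a JSON stage-count summary.

All thresholds default to the published analysis parameters
(FDR 0.05, |dPSI| 0.10, PSI bounds 0.10/0.90, max exon 250 bp, flank
100 bp, min cluster reads 60, min proportional contribution 0.001,
max intron 200 kb) and are echoed into every output header.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
from dataclasses import dataclass, field

import pandas as pd

from . import annotation_io, sequence_features
from .cassette_classification import run_classification
from .differential_splicing import differential_splicing as dm_test
from .junction_clustering import cluster_junctions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    junction_paths: list[str] = field(default_factory=list)
    junction_dialect: str = "plain_tsv"
    sample_names: list[str] | None = None
    sample_groups: dict[str, str] | None = None
    control_group: str = "control"
    gtf_path: str | None = None
    fasta_path: str | None = None
    conservation_path: str | None = None
    de_table_path: str | None = None
    out_dir: str = "crypticsplice_out"
    # published defaults
    fdr: float = 0.05
    dpsi: float = 0.10
    psi_low: float = 0.10
    psi_high: float = 0.90
    max_exon: int = 250
    flank: int = 100
    min_cluster_reads: int = 60
    min_prop: float = 0.001
    max_intron: int = 200_000
    min_event_reads: int = 15
    scan_all_clusters: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr", "dpsi", "psi_low", "psi_high", "min_prop"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def _write_tsv(df: pd.DataFrame, path: str, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write("# crypticsplice thresholds: " + json.dumps({
            "fdr": config.fdr, "dpsi": config.dpsi, "psi_low": config.psi_low,
            "psi_high": config.psi_high, "max_exon": config.max_exon,
            "min_cluster_reads": config.min_cluster_reads,
            "min_prop": config.min_prop, "max_intron": config.max_intron,
            "seed": config.seed,
        }) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: PipelineConfig,
    matrix: annotation_io.JunctionCountMatrix | None = None,
) -> dict:
    """Run the discovery cascade; returns the summary-count dict.

    A pre-built matrix may be passed directly (e.g. from the synthetic
    generator); otherwise junction files from the config are read.
    Partial outputs are removed on failure.
    """
    if matrix is None:
        if not config.junction_paths:
            raise FileNotFoundError("stage 'read_junctions': no junction files configured")
        for p in config.junction_paths:
            if not os.path.exists(p):
                raise FileNotFoundError(f"stage 'read_junctions': missing input {p}")
        matrix = annotation_io.read_junction_counts(
            config.junction_paths, dialect=config.junction_dialect,
            sample_names=config.sample_names, groups=config.sample_groups,
        )

    annotation = None
    if config.gtf_path:
        if not os.path.exists(config.gtf_path):
            raise FileNotFoundError(f"stage 'annotate': missing GTF {config.gtf_path}")
        annotation = annotation_io.read_gtf(config.gtf_path)

    os.makedirs(config.out_dir, exist_ok=True)
    try:
        clusters = cluster_junctions(
            matrix, min_cluster_reads=config.min_cluster_reads,
            min_prop=config.min_prop, max_intron=config.max_intron,
        )
        dm_results, dm_table = dm_test(matrix, clusters, fdr=config.fdr)
        events, cassette_table, summary = run_classification(
            matrix, clusters, dm_results, annotation=annotation,
            fdr=config.fdr, dpsi_threshold=config.dpsi,
            psi_low=config.psi_low, psi_high=config.psi_high,
            min_event_reads=config.min_event_reads,
            control_group=config.control_group,
            scan_all_clusters=config.scan_all_clusters,
        )
        summary["n_clusters"] = len(clusters)

        cluster_table = pd.DataFrame(
            {
                "cluster_id": [c.cluster_id for c in clusters],
                "chrom": [c.chrom for c in clusters],
                "span_start": [c.span.start for c in clusters],
                "span_end": [c.span.end for c in clusters],
                "strand": [c.strand for c in clusters],
                "n_junctions": [len(c) for c in clusters],
            }
        )
        _write_tsv(cluster_table, os.path.join(config.out_dir, "clusters.tsv"), config)
        _write_tsv(dm_table, os.path.join(config.out_dir, "dm_results.tsv"), config)
        _write_tsv(cassette_table, os.path.join(config.out_dir, "cassette_events.tsv"), config)

        if config.conservation_path and os.path.exists(config.conservation_path) and events:
            track = annotation_io.BaseScoreTrack.from_bedgraph(config.conservation_path)
            cons = sequence_features.conservation_summaries(events, track)
            _write_tsv(cons, os.path.join(config.out_dir, "conservation.tsv"), config)

        with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception:
        shutil.rmtree(config.out_dir, ignore_errors=True)
        raise
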