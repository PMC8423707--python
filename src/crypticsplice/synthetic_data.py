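"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (config, seed); the global seed
fans out to fixed per-generator substreams so stages are independently
reproducible. The junction generator plants cassette clusters on a toy
genome and draws counts from the same Dirichlet-multinomial family the
differential-splicing test assumes; cryptic events are planted with
control PSI below 10% and a positive PSI shift above 10%, skiptic
events mirrored. The annotation generator writes a matching toy
genome + GTF in which planted cryptic exons are absent from the
transcript models, so their inclusion junctions are novel. Motif-set
and neuron-detection generators mirror the k-mer-enrichment and
mislocalisation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation_io import GenomicInterval, JunctionCountMatrix

# substream offsets: one global seed, fixed fan-out per generator
_SUB_JUNCTIONS = 1
_SUB_MOTIF = 2
_SUB_DETECTIONS = 3
_SUB_GENOME = 4

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Default synthetic study conditions.

    200 cassette clusters (20 cryptic + 20 skiptic planted, rest null)
    over 3 control vs 3 knockdown samples at 500 reads per cluster per
    sample with Dirichlet-multinomial concentration 50 — a desk-scale
    mirror of a two-condition knockdown splicing experiment.
    """

    seed: int = 1
    n_clusters: int = 200
    n_cryptic: int = 20
    n_skiptic: int = 20
    samples_per_group: int = 3
    depth: int = 500
    concentration: float = 50.0
    psi_control_cryptic: tuple[float, float] = (0.0, 0.08)
    dpsi_cryptic: tuple[float, float] = (0.15, 0.40)
    psi_control_skiptic: tuple[float, float] = (0.92, 1.0)
    dpsi_skiptic: tuple[float, float] = (0.15, 0.40)  # magnitude of the negative shift
    cluster_spacing: int = 5_000
    exon_length: int = 100
    genome_length: int | None = None
    # motif generator
    motif: str = "CCCA"
    motif_prevalence_a: float = 0.86
    motif_prevalence_b: float = 0.48
    n_sequences: int = 100
    sequence_length: int = 100
    background: str = "ACGT"
    # detection generator
    n_cases: int = 35
    n_tiles_per_case: int = 129
    age_range: tuple[float, float] = (25.0, 96.0)
    onset_shift_years: float = 18.0
    misloc_midpoint: float = 95.0
    misloc_width: float = 12.0
    misloc_rate_max: float = 0.08
    misloc_case_sd: float = 1.5  # lognormal between-case variability of the rate
    normal_density_per_tile: float = 8.0

    def __post_init__(self) -> None:
        if self.n_cryptic + self.n_skiptic > self.n_clusters:
            raise ValueError("planted events exceed n_clusters")
        for p in (self.motif_prevalence_a, self.motif_prevalence_b):
            if not 0.0 <= p <= 1.0:
                raise ValueError("motif prevalence must lie in [0, 1]")
        lo, hi = self.psi_control_cryptic
        if not (0 <= lo < hi <= 0.10):
            raise ValueError("cryptic control PSI range must lie within [0, 0.10)")
        lo, hi = self.psi_control_skiptic
        if not (0.90 <= lo < hi <= 1.0):
            raise ValueError("skiptic control PSI range must lie within (0.90, 1]")


def _rng(config: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, offset])


def _cluster_layout(config: SimulationConfig, i: int) -> dict:
    """Deterministic coordinates of planted cluster ``i`` on the toy genome."""
    base = 1_000 + i * config.cluster_spacing
    L = config.exon_length
    return {
        "exon_up": (base, base + L - 1),
        "j1": (base + L, base + 2 * L - 1),
        "exon_cassette": (base + 2 * L, base + 3 * L - 1),
        "j2": (base + 3 * L, base + 4 * L - 1),
        "exon_down": (base + 4 * L, base + 5 * L - 1),
        "skip": (base + L, base + 4 * L - 1),
    }


def psi_to_usage(psi: float) -> np.ndarray:
    """Map a cassette PSI to a 3-junction usage vector (j1, j2, skip).

    With inclusion counts c1 = c2 = depth * psi / (1 + psi) and skip
    count depth * (1 - psi) / (1 + psi), the bounded PSI estimator
    mean(c1, c2) / (mean + skip) recovers ``psi`` in expectation.
    """
    p_inc = psi / (1.0 + psi)
    p_skip = (1.0 - psi) / (1.0 + psi)
    return np.array([p_inc, p_inc, p_skip])


def simulate_junction_dataset(
    config: SimulationConfig,
) -> tuple[JunctionCountMatrix, pd.DataFrame]:
    """Planted-truth junction count matrix over cassette-topology clusters.

    Cluster order (cryptic, skiptic, null) is fixed; the truth table
    records the planted class and target PSIs per cluster.
    """
    rng = _rng(config, _SUB_JUNCTIONS)
    n_ctrl = n_case = config.samples_per_group
    samples = [f"ctrl{i+1}" for i in range(n_ctrl)] + [f"kd{i+1}" for i in range(n_case)]
    groups = {s: ("control" if s.startswith("ctrl") else "knockdown") for s in samples}

    classes = (
        ["cryptic"] * config.n_cryptic
        + ["skiptic"] * config.n_skiptic
        + ["null"] * (config.n_clusters - config.n_cryptic - config.n_skiptic)
    )
    junctions: list[GenomicInterval] = []
    counts: list[np.ndarray] = []
    truth_rows = []
    for i, cls in enumerate(classes):
        lay = _cluster_layout(config, i)
        if cls == "cryptic":
            lo, hi = config.psi_control_cryptic
            psi_c = float(rng.uniform(lo, hi))
            dlo, dhi = config.dpsi_cryptic
            psi_k = min(1.0, psi_c + float(rng.uniform(dlo, dhi)))
        elif cls == "skiptic":
            lo, hi = config.psi_control_skiptic
            psi_c = float(rng.uniform(lo, hi))
            dlo, dhi = config.dpsi_skiptic
            psi_k = max(0.0, psi_c - float(rng.uniform(dlo, dhi)))
        else:
            psi_c = psi_k = float(rng.uniform(0.15, 0.85))
        usage_c, usage_k = psi_to_usage(psi_c), psi_to_usage(psi_k)

        block = np.zeros((3, len(samples)), dtype=np.int64)
        for s in range(len(samples)):
            usage = usage_c if s < n_ctrl else usage_k
            alpha = np.maximum(config.concentration * usage, 1e-6)
            p = rng.dirichlet(alpha)
            block[:, s] = rng.multinomial(config.depth, p)
        for name in ("j1", "j2", "skip"):
            a, b = lay[name]
            junctions.append(GenomicInterval("chr1", a, b, "+"))
        counts.append(block)
        truth_rows.append(
            {
                "cluster_index": i,
                "planted_class": cls,
                "psi_control_true": psi_c,
                "psi_case_true": psi_k,
                "dpsi_true": psi_k - psi_c,
                "exon_start": lay["exon_cassette"][0],
                "exon_end": lay["exon_cassette"][1],
                "skip_start": lay["skip"][0],
                "skip_end": lay["skip"][1],
            }
        )
    matrix = JunctionCountMatrix(junctions, samples, groups, np.vstack(counts))
    return matrix, pd.DataFrame(truth_rows)


def simulate_annotation(
    config: SimulationConfig,
    fasta_path: str | None = None,
    gtf_path: str | None = None,
) -> tuple[str, str]:
    """Toy genome FASTA and GTF matching :func:`simulate_junction_dataset`.

    Null and skiptic clusters get two transcript models (inclusion and
    skipping isoforms), so all three junctions are annotated; cryptic
    clusters get only the skipping isoform, leaving both inclusion
    junctions novel. Returns (fasta_text, gtf_text); writes files when
    paths are given.
    """
    rng = _rng(config, _SUB_GENOME)
    length = config.genome_length or (1_000 + config.n_clusters * config.cluster_spacing + 1_000)
    seq = "".join(rng.choice(BASES, size=length))
    classes = (
        ["cryptic"] * config.n_cryptic
        + ["skiptic"] * config.n_skiptic
        + ["null"] * (config.n_clusters - config.n_cryptic - config.n_skiptic)
    )
    gtf_lines = []

    def exon_line(tx: str, gene: str, start: int, end: int) -> str:
        attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
        return f"chr1\tsynthetic\texon\t{start}\t{end}\t.\t+\t.\t{attrs}"

    for i, cls in enumerate(classes):
        lay = _cluster_layout(config, i)
        gene = f"GENE{i:04d}"
        # skipping isoform: flanking exons only (annotates the skip junction)
        gtf_lines.append(exon_line(f"{gene}.skip", gene, *lay["exon_up"]))
        gtf_lines.append(exon_line(f"{gene}.skip", gene, *lay["exon_down"]))
        if cls != "cryptic":
            # inclusion isoform: all three exons (annotates j1 and j2)
            for ex in ("exon_up", "exon_cassette", "exon_down"):
                gtf_lines.append(exon_line(f"{gene}.inc", gene, *lay[ex]))

    fasta_text = ">chr1\n" + "\n".join(
        seq[i : i + 80] for i in range(0, len(seq), 80)
    ) + "\n"
    gtf_text = "\n".join(gtf_lines) + "\n"
    if fasta_path:
        with open(fasta_path, "w") as fh:
            fh.write(fasta_text)
    if gtf_path:
        with open(gtf_path, "w") as fh:
            fh.write(gtf_text)
    return fasta_text, gtf_text


def _random_sequences(rng: np.random.Generator, n: int, length: int, alphabet: str) -> list[str]:
    letters = np.array(list(alphabet))
    return ["".join(rng.choice(letters, size=length)) for _ in range(n)]


def simulate_motif_sequences(
    config: SimulationConfig,
) -> tuple[list[str], list[str]]:
    """Two sequence sets with the motif planted at different prevalences.

    Each sequence independently receives one planted occurrence of the
    motif (at a random position) with its set's prevalence, over an
    i.i.d. background drawn from ``config.background``.
    """
    if len(config.motif) >= config.sequence_length:
        raise ValueError("motif must be shorter than the sequences")
    rng = _rng(config, _SUB_MOTIF)

    def make_set(prevalence: float) -> list[str]:
        seqs = _random_sequences(rng, config.n_sequences, config.sequence_length,
                                 config.background)
        out = []
        for s in seqs:
            if rng.random() < prevalence:
                pos = int(rng.integers(0, len(s) - len(config.motif) + 1))
                s = s[:pos] + config.motif + s[pos + len(config.motif):]
            out.append(s)
        return out

    return make_set(config.motif_prevalence_a), make_set(config.motif_prevalence_b)


def misloc_tile_rate(config: SimulationConfig, age: float, group: str) -> float:
    """Expected abnormal neurons per tile: logistic ramp in age, with the
    disease group's midpoint advanced by ``onset_shift_years``."""
    mid = config.misloc_midpoint - (config.onset_shift_years if group == "disease" else 0.0)
    return config.misloc_rate_max / (1.0 + np.exp(-(age - mid) / config.misloc_width))


def simulate_detections(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-neuron detection tables plus cohort ages for two groups.

    Control ages are uniform over ``age_range``; disease ages are the
    same distribution shifted ``onset_shift_years`` younger, and the
    disease mislocalisation ramp is advanced by the same shift, so the
    planted cumulative-onset gap equals the shift. Per-tile abnormal
    and normal neuron counts are Poisson.
    """
    if config.n_cases < 4:
        raise ValueError("need at least 4 cases per group")
    rng = _rng(config, _SUB_DETECTIONS)
    lo, hi = config.age_range
    det_rows, cohort_rows = [], []
    for group in ("control", "disease"):
        shift = config.onset_shift_years if group == "disease" else 0.0
        ages = rng.uniform(lo - shift, hi - shift, size=config.n_cases)
        for c, age in enumerate(sorted(ages)):
            case_id = f"{group}{c+1:03d}"
            case_effect = float(np.exp(rng.normal(0.0, config.misloc_case_sd)))
            rate = misloc_tile_rate(config, age, group) * case_effect
            for tile in range(config.n_tiles_per_case):
                n_ab = int(rng.poisson(rate))
                n_no = int(rng.poisson(config.normal_density_per_tile))
                for _ in range(n_ab):
                    det_rows.append((case_id, tile, "abnormal"))
                for _ in range(n_no):
                    det_rows.append((case_id, tile, "normal"))
            cohort_rows.append(
                {"case_id": case_id, "group": group, "age_death": float(age),
                 "n_tiles": config.n_tiles_per_case}
            )
    detections = pd.DataFrame(det_rows, columns=["case_id", "tile_id", "label"])
    return detections, pd.DataFrame(cohort_rows)
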