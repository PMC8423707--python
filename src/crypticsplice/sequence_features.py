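"""Sequence-level features of cassette exons: reading-frame preservation,
mean conservation, rank tests between exon classes, and k-mer
presence/absence enrichment between sequence sets.

The k-mer statistic counts, for every DNA k-mer of length 2-4, the
fraction of sequences in each set containing at least one occurrence,
compares the two fractions with a chi-squared test of equal proportions
(no continuity correction) and applies a Bonferroni correction within
each k-mer-length family (4^k tests). Enrichment is reported as the
ratio of the two fractions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu

from .annotation_io import BaseScoreTrack, GenomicInterval

logger = logging.getLogger(__name__)

BASES = "ACGT"


def frame_preserving(exon_length: int) -> bool:
    """True when the exon's width is divisible by 3 (reading frame intact)."""
    if exon_length < 1:
        raise ValueError("exon length must be >= 1")
    return exon_length % 3 == 0


def mean_conservation(track: BaseScoreTrack, exon: GenomicInterval) -> float:
    """Mean per-base conservation over the exon's covered bases (NaN if none)."""
    return track.mean(exon)


def conservation_group_test(
    summaries: pd.DataFrame,
    group_a: str,
    group_b: str,
    value_col: str = "mean_phylop",
    group_col: str = "exon_set",
) -> dict:
    """Two-sided Wilcoxon rank-sum test of conservation between exon classes."""
    a = summaries.loc[summaries[group_col] == group_a, value_col].dropna().to_numpy()
    b = summaries.loc[summaries[group_col] == group_b, value_col].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if min(len(a), len(b)) < 3:
        logger.warning("group smaller than 3 (%d vs %d); p-value unstable", len(a), len(b))
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return {
        "group_a": group_a, "group_b": group_b,
        "n_a": len(a), "n_b": len(b),
        "median_a": float(np.median(a)), "median_b": float(np.median(b)),
        "statistic": float(stat), "p_value": float(p),
    }


def _two_proportion_chi2(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Chi-squared test of equal proportions on a 2x2 table, no Yates correction.

    Zero-margin tables (a k-mer in none or all sequences of both sets)
    carry no information and return (0, 1).
    """
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _presence_counts(sequences: list[str], kmers: list[str], k: int) -> np.ndarray:
    """Number of sequences containing each k-mer at least once.

    Sequences shorter than k (or whose only k-windows contain N) simply
    contain no k-mer.
    """
    index = {km: i for i, km in enumerate(kmers)}
    counts = np.zeros(len(kmers), dtype=np.int64)
    for seq in sequences:
        seen: set[int] = set()
        s = seq.upper()
        for i in range(len(s) - k + 1):
            j = index.get(s[i : i + k])
            if j is not None:
                seen.add(j)
        for j in seen:
            counts[j] += 1
    return counts


def kmer_enrichment(
    set_included: list[str],
    set_skipped: list[str],
    k_range: range | tuple[int, ...] = (2, 3, 4),
    region: str = "exon_body",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Presence/absence k-mer enrichment between two sequence sets.

    Returns one record per k-mer with the two presence proportions, the
    chi-squared statistic and p-value, the Bonferroni-adjusted p within
    the k-length family, and ``enrichment_ratio =
    prop_included / prop_skipped`` (inf when only the included set
    contains the k-mer). Sorted by adjusted p, then raw p, then k-mer.
    """
    if not set_included or not set_skipped:
        raise ValueError("both sequence sets must be non-empty")
    n1, n2 = len(set_included), len(set_skipped)
    frames = []
    for k in k_range:
        kmers = ["".join(t) for t in itertools.product(BASES, repeat=k)]
        x1 = _presence_counts(set_included, kmers, k)
        x2 = _presence_counts(set_skipped, kmers, k)
        n_tests = len(kmers)
        rows = []
        for km, a, b in zip(kmers, x1, x2):
            stat, p = _two_proportion_chi2(int(a), n1, int(b), n2)
            p1, p2 = a / n1, b / n2
            if p2 > 0:
                ratio = p1 / p2
            else:
                ratio = np.inf if p1 > 0 else np.nan
            rows.append((km, k, region, p1, p2, stat, p, min(1.0, p * n_tests), ratio))
        frames.append(pd.DataFrame(rows, columns=[
            "kmer", "k", "region", "prop_included", "prop_skipped",
            "chi2_stat", "p_value", "p_bonferroni", "enrichment_ratio",
        ]))
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values(["p_bonferroni", "p_value", "kmer"]).reset_index(drop=True)


def expand_pattern(pattern: str) -> list[str]:
    """Expand single-position bracket classes, e.g. ``CCC[AT]`` -> CCCA, CCCT."""
    choices: list[str] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i)
            if j == -1 or j == i + 1:
                raise ValueError(f"malformed bracket in pattern {pattern!r}")
            inner = pattern[i + 1 : j]
            if not set(inner) <= set(BASES):
                raise ValueError(f"invalid bases {inner!r} in pattern {pattern!r}")
            choices.append(inner)
            i = j + 1
        elif c == "]":
            raise ValueError(f"unbalanced ']' in pattern {pattern!r}")
        elif c in BASES:
            choices.append(c)
            i += 1
        else:
            raise ValueError(f"invalid character {c!r} in pattern {pattern!r}")
    return ["".join(t) for t in itertools.product(*choices)]


def pattern_presence(sequences: list[str], pattern: str) -> float:
    """Fraction of sequences containing at least one match of the pattern."""
    alts = expand_pattern(pattern)
    n = 0
    for seq in sequences:
        s = seq.upper()
        if any(a in s for a in alts):
            n += 1
    return n / len(sequences) if sequences else float("nan")


def conservation_summaries(events, track: BaseScoreTrack) -> pd.DataFrame:
    """Mean conservation per cassette-exon event, with class labels."""
    rows = []
    for e in events:
        rows.append({
            "exon_coords": f"{e.exon.chrom}:{e.exon.start}-{e.exon.end}",
            "mean_phylop": mean_conservation(track, e.exon),
            "exon_set": e.exon_set,
            "annot_status": e.annot_status,
        })
    return pd.DataFrame(rows)


def frame_preservation_fraction(lengths) -> float:
    """Fraction of exon lengths divisible by 3 (null expectation 1/3)."""
    lengths = np.asarray(list(lengths))
    if lengths.size == 0:
        return float("nan")
    return float((lengths % 3 == 0).mean())
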