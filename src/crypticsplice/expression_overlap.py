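"""Link splicing events to a differential-expression table.

The DE table (gene, log2 fold change, base mean, adjusted p) is consumed
as input — typically a DESeq2 export — never computed here. A null gene
set matched on expression level is selected by the mean of
``log10(baseMean)`` over the target genes plus or minus one standard
deviation, and the downregulation bias of the target set is compared to
that null with a chi-squared test of equal proportions.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .sequence_features import _two_proportion_chi2

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene", "log2fc", "base_mean", "adj_p")


def _check_table(de_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in de_table.columns]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    return de_table


def match_expression_null(
    de_table: pd.DataFrame,
    target_genes: Iterable[str],
    excluded_genes: Iterable[str] = (),
) -> list[str]:
    """Expression-matched null gene set.

    Genes whose ``log10(base_mean)`` lies within mean +/- 1 SD of the
    target genes' values, excluding the targets themselves and any
    further excluded genes (e.g. all differentially spliced genes).
    """
    de_table = _check_table(de_table)
    targets = set(target_genes)
    excluded = set(excluded_genes) | targets
    if len(targets) < 2:
        raise ValueError("need >= 2 target genes to define the expression window")
    sub = de_table[de_table["gene"].isin(targets) & (de_table["base_mean"] > 0)]
    if len(sub) < 2:
        raise ValueError("fewer than 2 target genes found in the DE table")
    logbm = np.log10(sub["base_mean"].to_numpy())
    mu, sd = float(np.mean(logbm)), float(np.std(logbm, ddof=1))
    pool = de_table[(de_table["base_mean"] > 0) & ~de_table["gene"].isin(excluded)]
    vals = np.log10(pool["base_mean"].to_numpy())
    mask = (vals >= mu - sd) & (vals <= mu + sd)
    null = pool.loc[mask, "gene"].tolist()
    logger.info("expression-matched null: %d genes in window [%.3f, %.3f] (log10 baseMean)",
                len(null), mu - sd, mu + sd)
    return null


def downregulation_bias(
    de_table: pd.DataFrame,
    target_genes: Iterable[str],
    null_genes: Iterable[str],
    fdr: float = 0.05,
) -> dict:
    """Proportion of significantly DE genes that are downregulated, per set.

    Only genes passing ``adj_p < fdr`` enter each proportion; the
    difference is tested with a two-proportion chi-squared test.
    """
    de_table = _check_table(de_table)
    targets, null = set(target_genes), set(null_genes)
    if targets & null:
        raise ValueError("target and null gene sets must be disjoint")

    def count(genes: set[str]) -> tuple[int, int]:
        sub = de_table[de_table["gene"].isin(genes) & (de_table["adj_p"] < fdr)]
        return int((sub["log2fc"] < 0).sum()), len(sub)

    down_t, n_t = count(targets)
    down_n, n_n = count(null)
    out = {
        "n_target_de": n_t, "n_target_down": down_t,
        "n_null_de": n_n, "n_null_down": down_n,
        "prop_target_down": down_t / n_t if n_t else np.nan,
        "prop_null_down": down_n / n_n if n_n else np.nan,
        "p_value": np.nan,
    }
    if n_t == 0 or n_n == 0:
        logger.warning("a gene set has no differentially expressed genes; p undefined")
        return out
    _, p = _two_proportion_chi2(down_t, n_t, down_n, n_n)
    out["p_value"] = p
    return out


def read_de_table(path: str) -> pd.DataFrame:
    """Read a DE results TSV, accepting DESeq2-style column names."""
    df = pd.read_csv(path, sep="\t")
    renames = {
        "log2FoldChange": "log2fc", "baseMean": "base_mean",
        "padj": "adj_p", "FDR": "adj_p", "gene_id": "gene", "gene_name": "gene",
    }
    df = df.rename(columns={k: v for k, v in renames.items() if k in df.columns})
    return _check_table(df)
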