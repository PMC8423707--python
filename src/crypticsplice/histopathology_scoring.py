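"""Quantitative mislocalisation scoring of per-neuron detection tables.

The framework mirrors a slide-scan workflow: random non-overlapping
1000 x 1000 px tiles (0.345 mm^2 each, at most 300) are sampled from a
region of interest; neurons within tiles carry a ``normal`` or
``abnormal`` label (abnormal = nuclear clearance of the protein with
cytoplasmic accumulation). Per case we report the density of normally
stained neurons per mm^2 and the mislocalisation score: the percentage
of tiles containing at least one abnormal neuron. Cumulative-frequency
curves over age at death compare the onset of mislocalisation between
groups, and cohort demographics are summarised per diagnostic group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

TILE_SIDE = 1000
TILE_AREA_MM2 = 0.345
MAX_TILES = 300
MAX_CONSECUTIVE_REJECTIONS = 10_000


@dataclass
class TileGrid:
    roi_width: int
    roi_height: int
    tile_side: int
    tile_area_mm2: float
    tiles: list[tuple[int, int]]  # top-left origins, pixel coordinates
    seed: int

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def tile_ids(self) -> list[int]:
        return list(range(len(self.tiles)))


@dataclass
class CaseScore:
    case_id: str
    n_tiles: int
    analysed_area_mm2: float
    normal_per_mm2: float
    misloc_pct: float
    abnormal_fraction: float


def sample_tiles(
    roi_width: int,
    roi_height: int,
    tile_side: int = TILE_SIDE,
    max_tiles: int = MAX_TILES,
    seed: int = 0,
    tile_area_mm2: float = TILE_AREA_MM2,
) -> TileGrid:
    """Seeded rejection sampling of non-overlapping square tiles in an ROI.

    Random origins are drawn until ``max_tiles`` are placed or 10,000
    consecutive draws are rejected for overlap. Deterministic for a
    fixed seed.
    """
    if roi_width < tile_side or roi_height < tile_side:
        raise ValueError("ROI smaller than one tile")
    rng = np.random.default_rng(seed)
    tiles: list[tuple[int, int]] = []
    rejections = 0
    while len(tiles) < max_tiles and rejections < MAX_CONSECUTIVE_REJECTIONS:
        x = int(rng.integers(0, roi_width - tile_side + 1))
        y = int(rng.integers(0, roi_height - tile_side + 1))
        if any(abs(x - tx) < tile_side and abs(y - ty) < tile_side for tx, ty in tiles):
            rejections += 1
            continue
        rejections = 0
        tiles.append((x, y))
    return TileGrid(roi_width, roi_height, tile_side, tile_area_mm2, tiles, seed)


def score_case(detections: pd.DataFrame, grid: TileGrid, case_id: str | None = None) -> CaseScore:
    """Density and mislocalisation metrics for one case.

    ``detections`` needs columns ``tile_id`` and ``label`` (normal /
    abnormal); every tile_id must exist in the grid. Tiles without
    detections still count toward the denominator.
    """
    if grid.n_tiles == 0:
        raise ValueError("grid has zero tiles")
    valid = set(grid.tile_ids())
    bad = set(detections["tile_id"]) - valid
    if bad:
        raise ValueError(f"detections reference unknown tiles: {sorted(bad)[:5]}")
    if case_id is None:
        case_id = str(detections["case_id"].iloc[0]) if len(detections) else "case"
    n_normal = int((detections["label"] == "normal").sum())
    n_abnormal = int((detections["label"] == "abnormal").sum())
    abnormal_tiles = detections.loc[detections["label"] == "abnormal", "tile_id"].nunique()
    area = grid.n_tiles * grid.tile_area_mm2
    return CaseScore(
        case_id=case_id,
        n_tiles=grid.n_tiles,
        analysed_area_mm2=area,
        normal_per_mm2=n_normal / area,
        misloc_pct=100.0 * abnormal_tiles / grid.n_tiles,
        abnormal_fraction=(
            n_abnormal / (n_abnormal + n_normal) if (n_abnormal + n_normal) else np.nan
        ),
    )


def cumulative_misloc_curve(scores: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cumulative mislocalisation over ascending age, normalised per group.

    ``scores`` needs columns ``case_id``, ``group``, ``age_death`` and
    ``misloc_pct``. Within each group, cases are sorted by age (ties
    broken by case_id) and the running mislocalisation total is divided
    by the group total, giving a 0 -> 1 curve. The group's median
    crossing age is the smallest age at which the curve reaches 0.5.
    Returns the per-case curve table and group -> crossing age.
    """
    curves = []
    crossing: dict[str, float] = {}
    for group, sub in scores.groupby("group"):
        if len(sub) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 cases")
        sub = sub.sort_values(["age_death", "case_id"], kind="stable").copy()
        total = sub["misloc_pct"].sum()
        if total <= 0:
            logger.warning("group %s has zero total mislocalisation; curve undefined", group)
            sub["cumulative"] = np.nan
            curves.append(sub)
            continue
        sub["cumulative"] = sub["misloc_pct"].cumsum() / total
        crossed = sub[sub["cumulative"] >= 0.5]
        crossing[group] = float(crossed["age_death"].iloc[0])
        curves.append(sub)
    return pd.concat(curves, ignore_index=True), crossing


def onset_gap(crossing: dict[str, float], early_group: str, late_group: str) -> float:
    """Years by which ``early_group``'s median mislocalisation precedes
    ``late_group``'s."""
    return crossing[late_group] - crossing[early_group]


def correlate_age(scores: pd.DataFrame, value_col: str = "misloc_pct") -> dict:
    """Two-sided Spearman rank correlation of a case score with age at death."""
    sub = scores.dropna(subset=["age_death", value_col])
    if len(sub) < 5:
        raise ValueError("need at least 5 cases for a rank correlation")
    vals = sub[value_col].to_numpy()
    if np.allclose(vals, vals[0]):
        logger.warning("constant scores; correlation undefined")
        return {"r": np.nan, "p_value": np.nan, "n": len(sub)}
    r, p = spearmanr(sub["age_death"], vals)
    return {"r": float(r), "p_value": float(p), "n": len(sub)}


def load_cohort_table() -> pd.DataFrame:
    """The packaged FTLD/ALS/control cohort demographics table (96 cases)."""
    with resources.files("crypticsplice.data").joinpath("cohort_table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _round_half_up(x: float, ndigits: int = 1) -> float:
    scale = 10 ** ndigits
    return np.floor(x * scale + 0.5) / scale


def cohort_summary(records: pd.DataFrame, group: str) -> dict:
    """Per-group demographic means (1-decimal, round-half-up) and M:F sex counts."""
    sub = records[records["group"] == group]
    if sub.empty:
        raise ValueError(f"no cases in group {group!r}")
    out: dict = {"group": group, "n": len(sub)}
    for col in ("age_onset", "age_death", "duration", "brain_weight", "pm_delay"):
        vals = pd.to_numeric(sub[col], errors="coerce").dropna()
        out[f"mean_{col}"] = _round_half_up(float(vals.mean())) if len(vals) else np.nan
    sexes = sub["sex"].value_counts()
    out["sex"] = f"{int(sexes.get('M', 0))}(M):{int(sexes.get('F', 0))}(F)"
    return out
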