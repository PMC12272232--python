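"""Inter-subject consistency of winner-take-all maps and axis comparison.

Consistency is the Spearman rank correlation of winning slab positions over
the voxels assigned in both maps of a subject pair, tabulated per axis and
hemisphere.  The three anatomical axes are compared with a Friedman test
over blocks (subject pair x hemisphere), followed by pairwise two-sided
Wilcoxon signed-rank post-hoc tests with Bonferroni adjustment.

The Friedman statistic uses the classic formula on tie-averaged ranks,

    chi2 = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1),

without a tie correction, so three identical columns give chi2 = 0, p = 1
rather than an indeterminate ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .wta_mapping import WTAMap

__all__ = ["MIN_OVERLAP_VOXELS", "ConsistencyTable", "AxisComparison",
           "wta_spearman", "consistency_table", "friedman_statistic",
           "compare_axes"]

#: Minimum jointly-assigned voxels for a pairwise Spearman to be defined.
MIN_OVERLAP_VOXELS = 10


def wta_spearman(a: WTAMap, b: WTAMap) -> float:
    """Spearman rho of winning slab positions over voxels assigned in both maps."""
    if a.axis != b.axis:
        raise ValueError("maps compare different axes")
    if a.winner.shape != b.winner.shape or not np.array_equal(
            a.cortex_indices, b.cortex_indices):
        raise ValueError("maps are on different cortex voxel sets")
    both = a.assigned & b.assigned
    n = int(both.sum())
    if n < MIN_OVERLAP_VOXELS:
        raise ValueError(
            f"only {n} jointly assigned voxels (< {MIN_OVERLAP_VOXELS})")
    rho = stats.spearmanr(a.winner_position[both], b.winner_position[both]).statistic
    return float(rho)


@dataclass
class ConsistencyTable:
    """All pairwise Spearman rhos for one axis and hemisphere."""

    axis: str
    hemisphere: str
    pairs: list                  # list of (subject_id_a, subject_id_b)
    rho: np.ndarray              # one value per pair (NaN where undefined)

    @property
    def mean_rho(self) -> float:
        return float(np.nanmean(self.rho))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "axis": self.axis, "hemisphere": self.hemisphere,
            "subject_a": [p[0] for p in self.pairs],
            "subject_b": [p[1] for p in self.pairs],
            "rho": self.rho,
        })


def consistency_table(maps: list[WTAMap], hemisphere: str) -> ConsistencyTable:
    """Pairwise consistency over all subject pairs for one axis/hemisphere.

    Pairs with insufficient overlap get NaN (kept so blocks stay aligned
    across axes; Friedman rows with missing cells are dropped there).
    """
    if len(maps) < 2:
        raise ValueError("need at least two subjects")
    axis = maps[0].axis
    pairs, rhos = [], []
    for a, b in combinations(maps, 2):
        pairs.append((a.subject_id, b.subject_id))
        try:
            rhos.append(wta_spearman(a, b))
        except ValueError:
            rhos.append(np.nan)
    return ConsistencyTable(axis=axis, hemisphere=hemisphere, pairs=pairs,
                            rho=np.asarray(rhos, dtype=float))


# ---------------------------------------------------------------------------
# Axis comparison
# ---------------------------------------------------------------------------

def friedman_statistic(blocks: np.ndarray) -> tuple[float, int, float]:
    """Friedman chi-square over an n x k block matrix (tie-averaged ranks).

    Returns (chi2, df, p) with df = k - 1 and p from the chi-square upper
    tail.  No tie correction is applied: fully tied rows contribute zero
    deviation, and identical columns yield chi2 = 0, p = 1.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValueError("blocks must be an n x k matrix")
    n, k = blocks.shape
    if n < 3:
        raise ValueError(f"Friedman test needs >= 3 complete blocks, got {n}")
    if k < 2:
        raise ValueError("Friedman test needs >= 2 conditions")
    if np.any(np.isnan(blocks)):
        raise ValueError("blocks contain missing cells")
    ranks = stats.rankdata(blocks, axis=1)
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(R ** 2)) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


@dataclass
class AxisComparison:
    """Friedman axis comparison with Bonferroni-adjusted Wilcoxon post-hocs."""

    chi2: float
    df: int
    p: float
    n_blocks: int
    axes: tuple
    posthoc: dict                # (axis_a, axis_b) -> adjusted p

    def to_frame(self) -> pd.DataFrame:
        rows = [{"axis_a": a, "axis_b": b, "p_adj": p}
                for (a, b), p in self.posthoc.items()]
        return pd.DataFrame(rows)


def compare_axes(tables: dict[str, list[ConsistencyTable]]) -> AxisComparison:
    """Compare consistency across axes with blocks = subject pair x hemisphere.

    ``tables`` maps axis -> list of ConsistencyTable (one per hemisphere).
    All axes must present the same (pair, hemisphere) blocks; blocks with a
    missing cell on any axis are dropped, and fewer than 3 surviving blocks
    is an error.
    """
    axes = tuple(sorted(tables))
    if len(axes) < 2:
        raise ValueError("need at least two axes to compare")
    frames = {}
    for ax in axes:
        df = pd.concat([t.to_frame() for t in tables[ax]], ignore_index=True)
        df["block"] = df["hemisphere"] + ":" + df["subject_a"] + "|" + df["subject_b"]
        frames[ax] = df.set_index("block")["rho"]
    blocks_index = frames[axes[0]].index
    for ax in axes[1:]:
        if not frames[ax].index.equals(blocks_index):
            raise ValueError("axes present different (pair, hemisphere) blocks")
    mat = np.column_stack([frames[ax].to_numpy() for ax in axes])
    keep = ~np.any(np.isnan(mat), axis=1)
    mat = mat[keep]
    chi2, df_, p = friedman_statistic(mat)
    posthoc = {}
    n_tests = len(list(combinations(range(len(axes)), 2)))
    for i, j in combinations(range(len(axes)), 2):
        diff = mat[:, i] - mat[:, j]
        if np.allclose(diff, 0):
            p_ij = 1.0
        else:
            p_ij = float(stats.wilcoxon(mat[:, i], mat[:, j],
                                        alternative="two-sided").pvalue)
        posthoc[(axes[i], axes[j])] = min(1.0, p_ij * n_tests)
    return AxisComparison(chi2=chi2, df=df_, p=p, n_blocks=mat.shape[0],
                          axes=axes, posthoc=posthoc)
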