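"""Winner-take-all cortical assignment maps and the group-consensus map.

Per subject, each cortical voxel is assigned to the seed slab with the
maximal across-run t among slabs passing the significance gate (or left
unassigned).  The group map averages, per voxel, the normalized winning-slab
positions over subjects with an assignment there, and keeps only voxels
where at least half the subjects are significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .roi_slabs import SlabLabeling, slab_position
from .seed_connectivity import StatMapStack

__all__ = ["UNASSIGNED", "WTAMap", "GroupWTAMap", "winner_take_all",
           "group_consensus"]

UNASSIGNED = -1


@dataclass
class WTAMap:
    """Per-cortical-voxel winning slab (or UNASSIGNED) for one subject/axis."""

    subject_id: str
    axis: str
    n_slabs: int
    cortex_indices: np.ndarray     # V x 3
    winner: np.ndarray             # V integer slab labels, UNASSIGNED where none
    winner_stat: np.ndarray        # V winning statistic (NaN where unassigned)
    winner_position: np.ndarray    # V normalized slab position (NaN where unassigned)

    @property
    def assigned(self) -> np.ndarray:
        return self.winner != UNASSIGNED

    @property
    def n_assigned(self) -> int:
        return int(self.assigned.sum())

    def to_volume(self, dims) -> np.ndarray:
        """Integer volume: 0 outside/unassigned, k+1 for winner slab k."""
        vol = np.zeros(dims, dtype=np.int16)
        vol[tuple(self.cortex_indices.T)] = self.winner + 1
        return vol


def winner_take_all(stack: StatMapStack, labeling: SlabLabeling,
                    stat: str = "mean_z") -> WTAMap:
    """Assign each cortical voxel to its maximally-correlated significant slab.

    Winner = argmax of the comparison statistic among slabs significant at
    the stack's alpha; exact ties go to the smaller slab label; no
    significant slab leaves the voxel unassigned.

    The comparison statistic defaults to the across-run mean Fisher z (the
    correlation strength itself): the winner is the slab the voxel is
    *maximally correlated* with, while the t-test serves only as the
    significance gate.  At small run counts the t ordering between two
    truly-correlated slabs is dominated by the heavy-tailed 1/sd factor
    rather than by effect size, so ranking by t (``stat='t'``, available for
    comparison) is unstable exactly where it matters.
    """
    if stack.n_slabs < 1:
        raise ValueError("stack has no slab maps")
    if stack.n_slabs != labeling.n_slabs:
        raise ValueError("stack/labeling slab count mismatch")
    if stat not in ("mean_z", "t"):
        raise ValueError("stat must be 'mean_z' or 't'")
    cmp_stat = stack.mean_z if stat == "mean_z" else stack.t
    c = np.where(stack.significant, cmp_stat, -np.inf)
    c = np.nan_to_num(c, nan=-np.inf)
    any_sig = np.any(stack.significant, axis=0)
    # np.argmax returns the first (smallest) index on ties.
    winner = np.where(any_sig, np.argmax(c, axis=0), UNASSIGNED)
    V = winner.shape[0]
    stat_arr = np.full(V, np.nan)
    posn = np.full(V, np.nan)
    idx = np.flatnonzero(any_sig)
    stat_arr[idx] = cmp_stat[winner[idx], idx]
    positions = np.array([slab_position(labeling, k)
                          for k in range(labeling.n_slabs)])
    posn[idx] = positions[winner[idx]]
    return WTAMap(subject_id=stack.subject_id, axis=stack.axis,
                  n_slabs=stack.n_slabs, cortex_indices=stack.cortex_indices,
                  winner=winner, winner_stat=stat_arr, winner_position=posn)


@dataclass
class GroupWTAMap:
    """Voxelwise mean winning position over subjects, gated by support."""

    axis: str
    n_subjects: int
    cortex_indices: np.ndarray
    mean_winner_position: np.ndarray   # V, NaN where below support threshold
    support: np.ndarray                # V integer count of assigning subjects

    @property
    def min_support(self) -> int:
        return ceil(self.n_subjects / 2)

    @property
    def retained(self) -> np.ndarray:
        return self.support >= self.min_support


def group_consensus(maps: list[WTAMap]) -> GroupWTAMap:
    """Average normalized winning positions across subjects.

    Per voxel: mean of ``winner_position`` over subjects with an assignment
    there; support = that count; voxels with support below ceil(n/2) are
    dropped (position NaN).  Positions (not raw labels) keep subjects with
    different slab counts commensurable.
    """
    if not maps:
        raise ValueError("group_consensus requires at least one WTA map")
    axis = maps[0].axis
    V = maps[0].winner.shape[0]
    for m in maps[1:]:
        if m.axis != axis:
            raise ValueError("all WTA maps must share one axis")
        if m.winner.shape[0] != V or not np.array_equal(
                m.cortex_indices, maps[0].cortex_indices):
            raise ValueError("all WTA maps must share the cortex voxel set")
    n = len(maps)
    pos = np.stack([m.winner_position for m in maps])      # n x V
    assigned = np.stack([m.assigned for m in maps])
    support = assigned.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_pos = np.nansum(np.where(assigned, pos, 0.0), axis=0) / support
    mean_pos[support == 0] = np.nan
    mean_pos[support < ceil(n / 2)] = np.nan
    return GroupWTAMap(axis=axis, n_subjects=n,
                       cortex_indices=maps[0].cortex_indices,
                       mean_winner_position=mean_pos,
                       support=support.astype(int))
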