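"""Within-sulcus topographic gradients: regression, polarity, axis selection.

Each sulcus is parameterized by a normalized [0, 1] coordinate along its
declared anatomical axis.  For one pulvinar slab axis, the voxels of all
subjects' winner-take-all maps falling inside the sulcus are pooled as
(sulcus position, winning slab position) points and fit by ordinary least
squares.  Polarity is the sign of a significant slope: *direct* when the
gradient runs with the sulcus axis (e.g. an IPS-like antero-posterior
mapping), *reversed* when it runs against it (the ACC-like inverted
mapping).  An axis is selected for a sulcus when it is significant in both
hemispheres with agreeing slope signs; among qualifying axes the one with
the larger min(|r_L|, |r_R|) wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .roi_slabs import axis_coordinate, infer_hemisphere
from .volume_io import ROIMask
from .wta_mapping import WTAMap

__all__ = ["MIN_POINTS", "POLARITY_ALPHA", "SulcusPath", "GradientFit",
           "parameterize_sulcus", "gradient_points", "fit_gradient",
           "select_axis", "piecewise_improves_bic"]

#: Minimum pooled points for a gradient fit.
MIN_POINTS = 10
#: Significance level for polarity and for the both-hemispheres criterion.
POLARITY_ALPHA = 0.05


@dataclass
class SulcusPath:
    """A sulcus mask with a normalized position per voxel along its axis."""

    name: str
    hemisphere: str
    mask: ROIMask
    position_axis: str
    indices: np.ndarray          # N x 3
    position_of_voxel: np.ndarray  # N in [0, 1]


def parameterize_sulcus(mask: ROIMask, position_axis: str,
                        hemisphere: str | None = None,
                        name: str | None = None) -> SulcusPath:
    """Normalized voxel positions (c - c_min) / (c_max - c_min) along an axis."""
    mask.require_nonempty()
    if hemisphere is None:
        hemisphere = infer_hemisphere(mask)
    ijk = mask.indices()
    if len(ijk) < 2:
        raise ValueError("sulcus mask needs at least 2 voxels")
    c = axis_coordinate(mask.geometry, ijk, position_axis, hemisphere)
    span = float(c.max() - c.min())
    if span <= 0:
        raise ValueError(
            f"sulcus mask has zero extent along {position_axis}")
    return SulcusPath(name=name or mask.name, hemisphere=hemisphere, mask=mask,
                      position_axis=position_axis, indices=ijk,
                      position_of_voxel=(c - c.min()) / span)


@dataclass
class GradientFit:
    """OLS fit of winning-slab position on sulcus position, with polarity."""

    sulcus: str
    hemisphere: str
    pulvinar_axis: str
    slope: float
    intercept: float
    r: float
    p: float
    n_points: int
    polarity: str                # 'direct' | 'reversed' | 'none'
    nonmonotone: bool = False    # two-segment fit beats the line by BIC

    def to_dict(self) -> dict:
        return {"sulcus": self.sulcus, "hemisphere": self.hemisphere,
                "pulvinar_axis": self.pulvinar_axis,
                "slope": float(self.slope), "r": float(self.r),
                "p": float(self.p), "n_points": int(self.n_points),
                "polarity": self.polarity,
                "nonmonotone": bool(self.nonmonotone)}


def gradient_points(maps: list[WTAMap], path: SulcusPath):
    """Pool (sulcus position, winner position) points over subjects.

    Only voxels inside the sulcus mask that carry an assignment contribute.
    """
    pos_lut = {tuple(v): p for v, p in zip(path.indices,
                                           path.position_of_voxel)}
    xs, ys = [], []
    for m in maps:
        for v, assigned, wpos in zip(m.cortex_indices, m.assigned,
                                     m.winner_position):
            if assigned:
                p = pos_lut.get(tuple(v))
                if p is not None:
                    xs.append(p)
                    ys.append(wpos)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def _bic(resid_ss: float, n: int, k_params: int) -> float:
    return n * np.log(max(resid_ss, 1e-300) / n) + k_params * np.log(n)


def piecewise_improves_bic(x: np.ndarray, y: np.ndarray) -> bool:
    """True when a two-segment broken line beats the single line by BIC.

    Breakpoints are scanned over inner quantiles of x; each segment gets its
    own intercept and slope.  Detection only — no segment inference.
    """
    n = len(x)
    if n < 20:
        return False
    X1 = np.column_stack([np.ones(n), x])
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    ss1 = float(np.sum((y - X1 @ b1) ** 2))
    bic1 = _bic(ss1, n, 2)
    best = np.inf
    for q in np.linspace(0.25, 0.75, 11):
        c = np.quantile(x, q)
        left = x <= c
        if left.sum() < 5 or (~left).sum() < 5:
            continue
        ss = 0.0
        for seg in (left, ~left):
            Xs = np.column_stack([np.ones(seg.sum()), x[seg]])
            if np.ptp(x[seg]) <= 0:
                ss += float(np.sum((y[seg] - y[seg].mean()) ** 2))
                continue
            bs, *_ = np.linalg.lstsq(Xs, y[seg], rcond=None)
            ss += float(np.sum((y[seg] - Xs @ bs) ** 2))
        best = min(best, _bic(ss, n, 5))  # 4 coefs + breakpoint
    return best < bic1


def fit_gradient(maps: list[WTAMap], path: SulcusPath,
                 alpha: float = POLARITY_ALPHA) -> GradientFit:
    """OLS regression of winning-slab position on sulcus position.

    Points are pooled voxels across subjects; slope, Pearson r and the
    two-sided p of the slope (t distribution, n - 2 df) are reported, and
    polarity is 'direct'/'reversed' for a significant positive/negative
    slope, else 'none'.
    """
    if not maps:
        raise ValueError("no WTA maps given")
    axis = maps[0].axis
    x, y = gradient_points(maps, path)
    n = len(x)
    if n < MIN_POINTS:
        raise ValueError(f"only {n} pooled points (< {MIN_POINTS})")
    if np.ptp(x) <= 0:
        raise ValueError("zero variance in sulcus positions")
    fit = stats.linregress(x, y)
    slope, r, p = float(fit.slope), float(fit.rvalue), float(fit.pvalue)
    if p < alpha:
        polarity = "direct" if slope > 0 else "reversed"
    else:
        polarity = "none"
    return GradientFit(sulcus=path.name, hemisphere=path.hemisphere,
                       pulvinar_axis=axis, slope=slope,
                       intercept=float(fit.intercept), r=r, p=p, n_points=n,
                       polarity=polarity,
                       nonmonotone=piecewise_improves_bic(x, y))


def select_axis(fits: dict[str, dict[str, GradientFit]],
                alpha: float = POLARITY_ALPHA) -> str | None:
    """Pick the pulvinar axis with a consistent significant gradient.

    ``fits`` maps axis -> {'L': fit, 'R': fit}.  An axis qualifies iff
    p < alpha in both hemispheres and the slope signs agree; among
    qualifying axes the one with the larger min(|r_L|, |r_R|) is returned,
    or None when no axis qualifies.
    """
    best_axis, best_score = None, -np.inf
    for ax, hemi in fits.items():
        if set(hemi) != {"L", "R"}:
            raise ValueError(f"axis {ax}: fits for both hemispheres required")
        fl, fr = hemi["L"], hemi["R"]
        if fl.p < alpha and fr.p < alpha and np.sign(fl.slope) == np.sign(fr.slope):
            score = min(abs(fl.r), abs(fr.r))
            if score > best_score:
                best_axis, best_score = ax, score
    return best_axis


def fits_table(fits: list[GradientFit]) -> pd.DataFrame:
    """Supplementary-style listing of all gradient regressions."""
    return pd.DataFrame([f.to_dict() for f in fits])
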