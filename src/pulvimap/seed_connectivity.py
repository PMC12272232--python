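"""Per-subject slab-seed connectivity: nuisance cleaning, smoothing, r -> z -> t.

For each seed slab the pipeline computes the Pearson correlation between the
slab's mean time series and every cortical voxel, per run, after removing
intercept, linear trend and the six head-motion regressors from both sides
(partial correlation).  Run-level correlations are Fisher z-transformed and
combined across runs with a one-sample t-test (df = n_runs - 1); voxels with
two-sided p below ``alpha`` (default 0.001, uncorrected) form the
significance gate used by the winner-take-all stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter

from .roi_slabs import SlabLabeling
from .volume_io import Image4D, ROIMask, RunData, require_same_grid

logger = logging.getLogger("pulvimap")

__all__ = ["StatMapStack", "clean_run", "smooth_gaussian", "slab_seed_series",
           "run_correlation_map", "fisher_z", "across_run_tmap",
           "preprocess_runs", "subject_statmaps", "FWHM_TO_SD"]

#: FWHM = 2 sqrt(2 ln 2) * sd for a Gaussian kernel.
FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _nuisance_design(run: RunData) -> np.ndarray:
    """Design matrix [intercept, linear trend, 6 motion regressors] (T x 8).

    Near-constant motion columns are rank-deficient against the intercept and
    are dropped with a warning.
    """
    T = run.image.n_volumes
    trend = np.linspace(-1.0, 1.0, T)
    cols = [np.ones(T), trend]
    for c in range(6):
        m = run.motion[:, c]
        if np.std(m) < 1e-12:
            logger.warning("run %s: motion column %d is constant; dropped",
                           run.run_id, c)
            continue
        cols.append(m - m.mean())
    return np.column_stack(cols)


def clean_run(run: RunData) -> Image4D:
    """OLS residuals of every voxel on [intercept, trend, motion]; mean-zero."""
    if run.image.n_volumes <= 8:
        raise ValueError("cleaning requires more than 8 volumes")
    X = _nuisance_design(run)
    data = run.image.data
    dims = data.shape[:3]
    Y = data.reshape(-1, data.shape[3]).T          # T x V
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T.reshape(dims + (data.shape[3],))
    return Image4D(geometry=run.image.geometry, data=out, tr_s=run.image.tr_s)


def smooth_gaussian(img: Image4D, fwhm_mm: float) -> Image4D:
    """Separable spatial Gaussian smoothing per volume; fwhm 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return Image4D(geometry=img.geometry, data=img.data.copy(),
                       tr_s=img.tr_s)
    sd_mm = fwhm_mm * FWHM_TO_SD
    sigma_vox = [sd_mm / v for v in img.geometry.voxel_size_mm] + [0.0]
    # 'nearest' keeps a constant volume exactly constant (DC invariance)
    out = gaussian_filter(img.data, sigma=sigma_vox, mode="nearest")
    return Image4D(geometry=img.geometry, data=out, tr_s=img.tr_s)


# ---------------------------------------------------------------------------
# Correlation machinery
# ---------------------------------------------------------------------------

def slab_seed_series(img: Image4D, labeling: SlabLabeling, label: int) -> np.ndarray:
    """Unweighted mean time series over one slab's voxels."""
    require_same_grid(img.geometry, labeling.geometry, "slab labeling")
    vox = labeling.slab_voxels(label)
    if len(vox) == 0:
        raise ValueError(f"slab {label} is empty")
    return img.data[tuple(vox.T)].mean(axis=0)


def run_correlation_map(img_clean: Image4D, seed_series: np.ndarray,
                        cortex: ROIMask) -> np.ndarray:
    """Pearson r of the seed series with every cortex voxel (NaN where a
    voxel has zero variance; such voxels are excluded downstream)."""
    require_same_grid(img_clean.geometry, cortex.geometry, "cortex mask")
    seed = np.asarray(seed_series, dtype=np.float64)
    if seed.shape != (img_clean.n_volumes,):
        raise ValueError("seed series length does not match image volumes")
    Y = img_clean.data[cortex.voxels]              # V x T
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sc = seed - seed.mean()
    seed_ss = float(sc @ sc)
    if seed_ss <= 0:
        raise ValueError("seed series has zero variance")
    vox_ss = np.einsum("ij,ij->i", Yc, Yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ sc) / np.sqrt(vox_ss * seed_ss)
    r[vox_ss <= 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def fisher_z(r):
    """Variance-stabilizing Fisher transform z = atanh(r); |r| must be < 1."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r[np.isfinite(r)]) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    return np.arctanh(r)


def across_run_tmap(z_maps: np.ndarray, alpha: float = 0.001,
                    two_sided: bool = True):
    """Combine per-run Fisher-z maps with a voxelwise one-sample t-test.

    ``z_maps`` is n_runs x V.  Returns ``(t, p, significant, mean_z)``; voxels
    missing (NaN) in any run are missing throughout.  A voxel with zero
    variance across runs but nonzero mean is significant by convention
    (p recorded as 0); zero mean and zero variance gives t = 0, p = 1.
    """
    z = np.asarray(z_maps, dtype=np.float64)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("across_run_tmap requires >= 2 runs of z-maps")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = z.shape[0]
    missing = np.any(np.isnan(z), axis=0)
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    t = np.full(z.shape[1], np.nan)
    p = np.full(z.shape[1], np.nan)
    ok = ~missing
    degen = ok & (sd == 0)
    reg = ok & (sd > 0)
    t[reg] = mean[reg] / (sd[reg] / np.sqrt(n))
    df = n - 1
    if two_sided:
        p[reg] = 2.0 * stats.t.sf(np.abs(t[reg]), df)
    else:
        p[reg] = stats.t.sf(t[reg], df)
    sgn = np.sign(mean[degen])
    t[degen] = np.where(sgn == 0, 0.0, np.inf) * np.where(sgn == 0, 1.0, sgn)
    p[degen] = np.where(mean[degen] == 0, 1.0, 0.0)
    significant = ok & (p < alpha)
    mean = np.where(ok, mean, np.nan)
    return t, p, significant, mean


# ---------------------------------------------------------------------------
# Per-subject stack
# ---------------------------------------------------------------------------

@dataclass
class StatMapStack:
    """Across-run statistics per slab over the cortex voxels of one subject."""

    subject_id: str
    axis: str
    alpha: float
    df: int
    cortex_indices: np.ndarray        # V x 3
    t: np.ndarray                     # n_slabs x V
    p: np.ndarray                     # n_slabs x V
    mean_z: np.ndarray                # n_slabs x V
    significant: np.ndarray           # n_slabs x V boolean

    @property
    def n_slabs(self) -> int:
        return self.t.shape[0]

    @property
    def mean_r(self) -> np.ndarray:
        """Mean correlation maps (Fisher-z average back-transformed)."""
        return np.tanh(self.mean_z)


def preprocess_runs(runs, fwhm_mm: float = 2.0) -> list[Image4D]:
    """Smooth then residualize every run; shared by all axes of one subject.

    Smoothing and nuisance projection commute exactly (one acts on space,
    the other on time), so the order is a convention, not a choice of model.
    """
    cleaned = []
    for run in runs:
        cleaned.append(clean_run(RunData(
            image=smooth_gaussian(run.image, fwhm_mm),
            motion=run.motion, run_id=run.run_id)))
    return cleaned


def subject_statmaps(runs, labeling: SlabLabeling, cortex: ROIMask,
                     fwhm_mm: float = 2.0, alpha: float = 0.001,
                     subject_id: str = "sub", two_sided: bool = True,
                     seed_resolution: str = "slab",
                     seed_mask: ROIMask | None = None,
                     cleaned: list | None = None) -> StatMapStack:
    """Full per-subject connectivity stack for one slab labeling.

    Each run is smoothed (2-mm FWHM default) then residualized against
    intercept, trend and motion; slab seed series are taken from the cleaned
    data so seed and target are cleaned identically.  Seed-nucleus voxels are
    excluded from the cortex target.  ``seed_resolution='voxel'`` runs the
    per-voxel-seed variant and keeps, per slab and cortical voxel, the seed
    voxel with the maximal across-run t.  ``cleaned`` short-circuits the
    preprocessing with already smoothed+residualized images (from
    :func:`preprocess_runs`); it must come from the same runs.
    """
    if seed_resolution not in ("slab", "voxel"):
        raise ValueError("seed_resolution must be 'slab' or 'voxel'")
    target_vox = cortex.voxels.copy()
    seed_vox = np.zeros(cortex.geometry.dims, dtype=bool)
    seed_vox[tuple(labeling.indices.T)] = True
    if seed_mask is not None:
        require_same_grid(cortex.geometry, seed_mask.geometry, "seed mask")
        seed_vox |= seed_mask.voxels
    target_vox &= ~seed_vox
    target = ROIMask(geometry=cortex.geometry, voxels=target_vox,
                     name=cortex.name)
    target.require_nonempty()

    for run in runs:
        require_same_grid(run.image.geometry, cortex.geometry, "run image")
    if cleaned is None:
        cleaned = preprocess_runs(runs, fwhm_mm)

    # guard against |r| rounding to exactly 1 in near-noiseless data
    r_cap = 1.0 - 1e-12

    n_slabs = labeling.n_slabs
    V = target.n_voxels
    if seed_resolution == "slab":
        z = np.empty((n_slabs, len(cleaned), V))
        for k in range(n_slabs):
            for r_i, img in enumerate(cleaned):
                seed = slab_seed_series(img, labeling, k)
                r = run_correlation_map(img, seed, target)
                z[k, r_i] = fisher_z(np.clip(r, -r_cap, r_cap))
        t = np.empty((n_slabs, V)); p = np.empty((n_slabs, V))
        mz = np.empty((n_slabs, V)); sig = np.zeros((n_slabs, V), dtype=bool)
        for k in range(n_slabs):
            t[k], p[k], sig[k], mz[k] = across_run_tmap(z[k], alpha, two_sided)
    else:
        t = np.full((n_slabs, V), -np.inf)
        p = np.ones((n_slabs, V))
        mz = np.zeros((n_slabs, V))
        sig = np.zeros((n_slabs, V), dtype=bool)
        for k in range(n_slabs):
            for vox in labeling.slab_voxels(k):
                zv = np.empty((len(cleaned), V))
                for r_i, img in enumerate(cleaned):
                    seed = img.data[tuple(vox)]
                    r = run_correlation_map(img, seed, target)
                    zv[r_i] = fisher_z(np.clip(r, -r_cap, r_cap))
                tv, pv, sv, mv = across_run_tmap(zv, alpha, two_sided)
                better = np.nan_to_num(tv, nan=-np.inf) > t[k]
                t[k][better] = tv[better]
                p[k][better] = pv[better]
                mz[k][better] = mv[better]
                sig[k][better] = sv[better]
        t[np.isinf(t) & (t < 0)] = np.nan
    return StatMapStack(subject_id=subject_id, axis=labeling.axis, alpha=alpha,
                        df=len(cleaned) - 1, cortex_indices=target.indices(),
                        t=t, p=p, mean_z=mz, significant=sig)
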