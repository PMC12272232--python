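"""Synthetic multi-subject resting-state cohort with planted pulvino-cortical topography.

Every stage of the analysis pipeline (slab seeds, winner-take-all maps,
consensus, consistency, gradient regressions) needs a ground-truth oracle.
This module generates one: a small-grid 4D BOLD-like cohort in which each
2-mm slab of a synthetic nucleus shares a latent AR(1) time series with one
cortical band of a synthetic sulcus, so the winner-take-all assignment, the
gradient axis and its polarity are known by construction.

The model per voxel time series is

    y(t) = signal_sd * L_k(t) + noise_sd * e(t) + motion_leak * m1(t)

where ``L_k`` is the unit-variance AR(1) latent of the voxel's slab (seed
voxels) or planted band (cortical band voxels; absent for null cortex),
``e`` is independent unit-variance AR(1) noise and ``m1`` the standardized
first motion regressor (a smooth random walk), leaking globally into every
voxel as a motion-correlated nuisance.  Latents are drawn independently per
subject, per hemisphere and per run; what is shared across subjects is the
band->slab *topography*, optionally destroyed with ``shared_topography=False``
(per-subject random permutation of the band map).  Per-subject jitter of the
band boundaries (mm along the sulcus axis) emulates inter-individual
variability in gradient placement.

Everything is deterministic given ``(rng_seed, subject_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .roi_slabs import SlabLabeling, axis_coordinate, slice_mask
from .volume_io import (Image4D, ROIMask, RunData, VolumeGeometry,
                        save_image4d, save_mask, save_motion, voxel_centers_mm)

__all__ = ["CohortConfig", "SulcusBand", "GroundTruth", "SubjectData",
           "generate_subject", "generate_cohort", "default_geometry"]

HEMIS = ("L", "R")


@dataclass(frozen=True)
class SulcusBand:
    """One planted sulcus: its name, the axis its bands run along, polarity."""

    name: str
    band_axis: str          # AP | VD | LM
    polarity: str           # 'direct' (band k <- slab k) or 'reversed'

    def __post_init__(self) -> None:
        if self.polarity not in ("direct", "reversed"):
            raise ValueError(f"polarity must be direct|reversed, got {self.polarity}")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the desk-scale emulation of the acquisition regime (multi-run
    MION-like series, 2-s TR, ~1-mm voxels, 2-mm seed slabs) with equal signal
    and noise standard deviations.
    """

    n_subjects: int = 4
    runs_per_subject: int = 2
    volumes_per_run: int = 200
    tr_s: float = 2.0
    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nucleus_center_mm: tuple[float, float, float] = (5.5, -3.5, 0.5)  # |x|, y, z
    nucleus_radii_mm: tuple[float, float, float] = (2.5, 4.5, 3.5)
    slab_axis: str = "AP"
    slab_thickness_mm: float = 2.0
    bands: tuple[SulcusBand, ...] = (SulcusBand("IPS", "AP", "direct"),
                                     SulcusBand("ACC", "AP", "reversed"))
    signal_sd: float = 1.0
    noise_sd: float = 1.0
    ar1_phi: float = 0.4
    motion_leak: float = 0.5
    subject_jitter_sd: float = 0.5   # mm, band-boundary shift per subject
    shared_topography: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.volumes_per_run < 50:
            raise ValueError("volumes_per_run must be >= 50")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in [0, 1)")
        if self.motion_leak < 0:
            raise ValueError("motion_leak must be >= 0")
        self.bands = tuple(b if isinstance(b, SulcusBand) else SulcusBand(*b)
                           for b in self.bands)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [list(asdict(b).values()) for b in self.bands]
        return d


@dataclass
class GroundTruth:
    """The planted generator: slab labelings, band maps, polarity, latents."""

    slab_labeling: dict          # hemisphere -> SlabLabeling over the nucleus
    band_assignment: dict        # (sulcus, hemisphere) -> DataFrame [i j k slab position]
    polarity: dict               # sulcus name -> 'direct' | 'reversed'
    band_axis: dict              # sulcus name -> axis
    jitter_mm: dict              # (sulcus, hemisphere) -> float
    latents: dict                # (hemisphere, run_index) -> n_slabs x T array


@dataclass
class SubjectData:
    subject_id: str
    runs: list
    seed_mask: ROIMask           # both hemispheres' nuclei
    cortex_mask: ROIMask         # sulci + null cortex, nucleus excluded
    sulcus_masks: dict           # (sulcus, hemisphere) -> ROIMask
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Geometry of the phantom
# ---------------------------------------------------------------------------

def default_geometry(config: CohortConfig) -> VolumeGeometry:
    """Grid centered on the origin so the mid-sagittal plane is x = 0."""
    dims = tuple(int(d) for d in config.grid_dims)
    vox = tuple(float(v) for v in config.voxel_size_mm)
    affine = np.diag([vox[0], vox[1], vox[2], 1.0])
    affine[:3, 3] = [-(d - 1) / 2.0 * v for d, v in zip(dims, vox)]
    return VolumeGeometry(dims=dims, voxel_size_mm=vox, affine=affine)


def _grid_mm(geometry: VolumeGeometry) -> np.ndarray:
    """World coordinates of every voxel center, shape dims + (3,)."""
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in geometry.dims], indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    return voxel_centers_mm(geometry, ijk).reshape(geometry.dims + (3,))


def _nucleus_mask(geometry: VolumeGeometry, config: CohortConfig,
                  hemisphere: str) -> ROIMask:
    xyz = _grid_mm(geometry)
    cx, cy, cz = config.nucleus_center_mm
    cx = -abs(cx) if hemisphere == "L" else abs(cx)
    rx, ry, rz = config.nucleus_radii_mm
    d2 = (((xyz[..., 0] - cx) / rx) ** 2 + ((xyz[..., 1] - cy) / ry) ** 2
          + ((xyz[..., 2] - cz) / rz) ** 2)
    return ROIMask(geometry=geometry, voxels=d2 <= 1.0,
                   name=f"nucleus_{hemisphere}")


# Box slots for planted sulci, expressed in (|x|, y, z) mm bounds; the long
# side is re-oriented to lie along the sulcus's band axis.  Chosen to clear
# the default nucleus (|x| in [3, 8], y in [-8, 1], z in [-3, 4]).
_SULCUS_SLOTS = (
    {"long": (2.4, 11.6), "abs_x": (8.4, 11.6), "other": (2.4, 6.6)},
    {"long": (2.4, 11.6), "abs_x": (0.4, 2.6), "other": (-6.6, -2.4)},
    {"long": (2.4, 11.6), "abs_x": (4.4, 7.6), "other": (-10.6, -7.4)},
)


def _sulcus_mask(geometry: VolumeGeometry, band: SulcusBand, slot: int,
                 hemisphere: str) -> ROIMask:
    if slot >= len(_SULCUS_SLOTS):
        raise ValueError(f"no geometry slot for sulcus #{slot}; at most "
                         f"{len(_SULCUS_SLOTS)} planted sulci are supported")
    s = _SULCUS_SLOTS[slot]
    xyz = _grid_mm(geometry)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    ax = abs(x)
    sign = -1.0 if hemisphere == "L" else 1.0
    if band.band_axis == "AP":
        box = {"y": s["long"], "ax": s["abs_x"], "z": s["other"]}
    elif band.band_axis == "VD":
        box = {"z": s["long"], "ax": s["abs_x"], "y": s["other"]}
    else:  # LM: long side along |x|; reuse the AP slot bounds for y/z
        box = {"ax": (2.4, 11.6), "y": s["abs_x"], "z": s["other"]}
    inside = np.ones(geometry.dims, dtype=bool)
    if "ax" in box:
        inside &= (ax >= box["ax"][0]) & (ax <= box["ax"][1])
    if "y" in box:
        inside &= (y >= box["y"][0]) & (y <= box["y"][1])
    if "z" in box:
        inside &= (z >= box["z"][0]) & (z <= box["z"][1])
    inside &= (sign * x) > 0
    return ROIMask(geometry=geometry, voxels=inside,
                   name=f"{band.name}_{hemisphere}")


def _null_cortex(geometry: VolumeGeometry) -> np.ndarray:
    """A dorsal strip of cortex with no planted signal (calibration voxels)."""
    xyz = _grid_mm(geometry)
    return (xyz[..., 2] >= 9.4) & (xyz[..., 2] <= 11.6)


# ---------------------------------------------------------------------------
# Stochastic building blocks
# ---------------------------------------------------------------------------

_AR_BURN = 64


def ar1_series(rng: np.random.Generator, phi: float, n: int,
               shape: tuple = ()) -> np.ndarray:
    """Unit-marginal-variance AR(1) series along the first axis, shape (n,)+shape."""
    e = rng.standard_normal((n + _AR_BURN,) + shape)
    if phi == 0:
        return e[_AR_BURN:]
    x = lfilter([np.sqrt(1.0 - phi * phi)], [1.0, -phi], e, axis=0)
    return x[_AR_BURN:]


def motion_walk(rng: np.random.Generator, n: int) -> np.ndarray:
    """Six smooth random-walk motion regressors (translations mm, rotations rad)."""
    steps = rng.standard_normal((n, 6))
    walk = np.cumsum(steps, axis=0)
    walk = gaussian_filter1d(walk, sigma=4.0, axis=0)
    walk -= walk.mean(axis=0)
    scale = np.array([0.05, 0.05, 0.05, 0.002, 0.002, 0.002])
    return walk * scale


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

def _band_of_position(pos: np.ndarray, n_slabs: int) -> np.ndarray:
    return np.clip(np.floor(pos * n_slabs).astype(int), 0, n_slabs - 1)


def generate_subject(config: CohortConfig, subject_index: int) -> SubjectData:
    """Generate one subject's runs, masks and ground truth.

    Deterministic given ``(config.rng_seed, subject_index)``.
    """
    geometry = default_geometry(config)
    rng = np.random.default_rng([int(config.rng_seed) % (2 ** 31),
                                 int(subject_index)])

    # --- structural layout (shared across subjects up to jitter) ---
    nuclei = {h: _nucleus_mask(geometry, config, h) for h in HEMIS}
    for h in HEMIS:
        nuclei[h].require_nonempty()
    labelings: dict[str, SlabLabeling] = {}
    for h in HEMIS:
        lab = slice_mask(nuclei[h], config.slab_axis, config.slab_thickness_mm,
                         hemisphere=h)
        c = axis_coordinate(geometry, lab.indices, config.slab_axis, h)
        if c.max() - c.min() < config.slab_thickness_mm:
            raise ValueError(
                f"nucleus extent along {config.slab_axis} "
                f"({c.max() - c.min():.2f} mm) is below slab thickness"
            )
        labelings[h] = lab
    n_slabs = labelings["L"].n_slabs

    sulcus_masks: dict[tuple[str, str], ROIMask] = {}
    for slot, band in enumerate(config.bands):
        for h in HEMIS:
            m = _sulcus_mask(geometry, band, slot, h)
            m.require_nonempty()
            if np.any(m.voxels & (nuclei["L"].voxels | nuclei["R"].voxels)):
                raise ValueError(f"band {band.name}/{h} overlaps the nucleus")
            sulcus_masks[(band.name, h)] = m

    seed_vox = nuclei["L"].voxels | nuclei["R"].voxels
    cortex_vox = _null_cortex(geometry).copy()
    for m in sulcus_masks.values():
        cortex_vox |= m.voxels
    cortex_vox &= ~seed_vox
    seed_mask = ROIMask(geometry=geometry, voxels=seed_vox, name="seed_nucleus")
    cortex_mask = ROIMask(geometry=geometry, voxels=cortex_vox, name="cortex")

    # --- planted band -> slab map, with per-subject boundary jitter ---
    band_assignment: dict[tuple[str, str], pd.DataFrame] = {}
    jitters: dict[tuple[str, str], float] = {}
    slab_perm = {h: np.arange(n_slabs) for h in HEMIS}
    if not config.shared_topography:
        for h in HEMIS:
            slab_perm[h] = rng.permutation(n_slabs)
    for band in config.bands:
        for h in HEMIS:
            mask = sulcus_masks[(band.name, h)]
            ijk = mask.indices()
            c = axis_coordinate(geometry, ijk, band.band_axis, h)
            delta = float(rng.normal(0.0, config.subject_jitter_sd))
            jitters[(band.name, h)] = delta
            span = c.max() - c.min()
            pos = np.clip((c - c.min() + delta) / span, 0.0, 1.0 - 1e-9)
            b = _band_of_position(pos, n_slabs)
            slab = b if band.polarity == "direct" else (n_slabs - 1 - b)
            slab = slab_perm[h][slab]
            band_assignment[(band.name, h)] = pd.DataFrame({
                "i": ijk[:, 0], "j": ijk[:, 1], "k": ijk[:, 2],
                "position": (c - c.min()) / span, "slab": slab,
            })

    # --- time series ---
    T = config.volumes_per_run
    runs: list[RunData] = []
    latents: dict[tuple[str, int], np.ndarray] = {}
    for r in range(config.runs_per_subject):
        data = ar1_series(rng, config.ar1_phi, T,
                          geometry.dims).astype(np.float64)  # (T, X, Y, Z)
        data *= config.noise_sd
        for h in HEMIS:
            lat = ar1_series(rng, config.ar1_phi, T, (n_slabs,))  # (T, n_slabs)
            latents[(h, r)] = lat.T.copy()
            lab = labelings[h]
            for k in range(n_slabs):
                vox = lab.slab_voxels(k)
                data[(slice(None),) + tuple(vox.T)] += \
                    config.signal_sd * lat[:, k][:, None]
            for band in config.bands:
                df = band_assignment[(band.name, h)]
                for k in range(n_slabs):
                    sel = df[df["slab"] == k]
                    if len(sel):
                        idx = (slice(None), sel["i"].to_numpy(),
                               sel["j"].to_numpy(), sel["k"].to_numpy())
                        data[idx] += config.signal_sd * lat[:, k][:, None]
        motion = motion_walk(rng, T)
        if config.motion_leak > 0:
            m1 = motion[:, 0]
            m1s = (m1 - m1.mean()) / m1.std()
            data += (config.motion_leak * m1s)[:, None, None, None]
        image = Image4D(geometry=geometry,
                        data=np.moveaxis(data, 0, -1).copy(), tr_s=config.tr_s)
        runs.append(RunData(image=image, motion=motion, run_id=f"run-{r:02d}"))

    truth = GroundTruth(
        slab_labeling=labelings,
        band_assignment=band_assignment,
        polarity={b.name: b.polarity for b in config.bands},
        band_axis={b.name: b.band_axis for b in config.bands},
        jitter_mm=jitters,
        latents=latents,
    )
    return SubjectData(subject_id=f"sub-{subject_index:02d}", runs=runs,
                       seed_mask=seed_mask, cortex_mask=cortex_mask,
                       sulcus_masks=sulcus_masks, truth=truth)


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, out_dir) -> Path:
    """Write a full cohort (runs, motion, masks, ground truth, manifest) to disk.

    Returns the path of the cohort manifest (YAML).  Regeneration with the
    same config is byte-identical for the ground-truth CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "subjects": []}
    for s in range(config.n_subjects):
        sub = generate_subject(config, s)
        sdir = out / sub.subject_id
        sdir.mkdir(exist_ok=True)
        entry: dict = {"subject_id": sub.subject_id, "runs": [],
                       "seed_mask": str(sdir / "seed_mask.nii.gz"),
                       "cortex_mask": str(sdir / "cortex_mask.nii.gz"),
                       "sulci": {}, "truth": {}}
        for run in sub.runs:
            bold = sdir / f"{run.run_id}_bold.nii.gz"
            mot = sdir / f"{run.run_id}_motion.txt"
            save_image4d(run.image, bold)
            save_motion(run.motion, mot)
            entry["runs"].append({"run_id": run.run_id, "bold": str(bold),
                                  "motion": str(mot), "tr_s": config.tr_s})
        save_mask(sub.seed_mask, entry["seed_mask"])
        save_mask(sub.cortex_mask, entry["cortex_mask"])
        for (name, h), m in sub.sulcus_masks.items():
            p = sdir / f"sulcus-{name}_{h}.nii.gz"
            save_mask(m, p)
            entry["sulci"][f"{name}_{h}"] = {
                "path": str(p), "sulcus": name, "hemisphere": h,
                "position_axis": sub.truth.band_axis[name],
            }
        rows = []
        for (name, h), df in sub.truth.band_assignment.items():
            d = df.copy()
            d.insert(0, "hemisphere", h)
            d.insert(0, "sulcus", name)
            rows.append(d)
        truth_df = pd.concat(rows, ignore_index=True)
        truth_path = sdir / "ground_truth_bands.csv"
        truth_df.to_csv(truth_path, index=False, float_format="%.10g")
        pol_path = sdir / "ground_truth_polarity.csv"
        pd.DataFrame({
            "sulcus": list(sub.truth.polarity),
            "band_axis": [sub.truth.band_axis[s_] for s_ in sub.truth.polarity],
            "polarity": [sub.truth.polarity[s_] for s_ in sub.truth.polarity],
        }).to_csv(pol_path, index=False)
        entry["truth"] = {"bands": str(truth_path), "polarity": str(pol_path)}
        manifest["subjects"].append(entry)
    manifest_path = out / "cohort.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
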