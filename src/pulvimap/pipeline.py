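"""End-to-end orchestration: simulate -> connect -> wta -> consensus ->
consistency -> gradients, plus session accounting.

The library surface here is :func:`analyze_cohort`, which takes in-memory
subjects (from :mod:`pulvimap.synthetic_cohort` or loaded from a cohort
manifest) and produces every analysis product; :func:`run_pipeline` wraps it
with disk I/O, a results JSON (schema-checked), CSV tables and a Markdown
report.  Everything is deterministic given the config's RNG seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import consistency_stats as cs
from . import local_gradients as lg
from .roi_slabs import AXES, SlabLabeling, slice_mask
from .seed_connectivity import StatMapStack, preprocess_runs, subject_statmaps
from .synthetic_cohort import CohortConfig, SubjectData, generate_cohort
from .volume_io import (ROIMask, RunData, load_image4d, load_mask, load_motion,
                        voxel_centers_mm)
from .wta_mapping import GroupWTAMap, WTAMap, group_consensus, winner_take_all

logger = logging.getLogger("pulvimap")

__all__ = ["SessionSpec", "session_minutes", "PipelineConfig",
           "split_hemispheres", "analyze_cohort", "CohortResult",
           "run_pipeline", "load_cohort", "validate_results"]


# ---------------------------------------------------------------------------
# Session accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSpec:
    """Acquisition accounting for one subject: run groups and TR."""

    subject_id: str
    runs: tuple               # ((n_runs, run_length_pulses), ...)
    tr_s: float


def session_minutes(spec: SessionSpec) -> float:
    """Total scan minutes: sum over run groups of n * pulses * TR / 60."""
    if spec.tr_s <= 0:
        raise ValueError("TR must be positive")
    if not spec.runs:
        raise ValueError("at least one run group is required")
    total = 0.0
    for n_runs, pulses in spec.runs:
        if n_runs <= 0 or pulses <= 0:
            raise ValueError(f"non-positive run group ({n_runs}, {pulses})")
        total += n_runs * pulses * spec.tr_s
    return total / 60.0


# ---------------------------------------------------------------------------
# Cohort analysis
# ---------------------------------------------------------------------------

def split_hemispheres(mask: ROIMask) -> dict[str, ROIMask]:
    """Split a mask at the mid-sagittal plane (world x = 0, RAS+)."""
    ijk = np.argwhere(np.ones(mask.geometry.dims, dtype=bool))
    x = voxel_centers_mm(mask.geometry, ijk)[:, 0].reshape(mask.geometry.dims)
    out = {}
    for h, sel in (("L", x < 0), ("R", x >= 0)):
        out[h] = ROIMask(geometry=mask.geometry, voxels=mask.voxels & sel,
                         name=f"{mask.name}_{h}")
    return out


@dataclass
class CohortResult:
    """All analysis products for one cohort."""

    axes: tuple
    subject_ids: list
    labelings: dict            # (axis, hemi) -> per-subject list of SlabLabeling
    stacks: dict               # (axis, hemi) -> list of StatMapStack
    wta: dict                  # (axis, hemi) -> list of WTAMap
    consensus: dict            # (axis, hemi) -> GroupWTAMap
    consistency: dict          # axis -> list of ConsistencyTable (per hemi)
    axis_comparison: object | None
    gradient_fits: dict        # sulcus -> axis -> hemi -> GradientFit
    selected_axis: dict        # sulcus -> axis | None

    def summary(self) -> dict:
        """Stable, machine-readable results summary."""
        out: dict = {
            "axes": list(self.axes),
            "n_subjects": len(self.subject_ids),
            "subjects": list(self.subject_ids),
            "assigned_voxels": {}, "consensus": {}, "consistency": {},
            "axis_comparison": None, "gradients": {},
        }
        for (ax, h), maps in self.wta.items():
            out["assigned_voxels"][f"{ax}_{h}"] = {
                m.subject_id: int(m.n_assigned) for m in maps}
        for (ax, h), g in self.consensus.items():
            out["consensus"][f"{ax}_{h}"] = {
                "n_retained": int(g.retained.sum()),
                "min_support": g.min_support,
            }
        for ax, tables in self.consistency.items():
            out["consistency"][ax] = {
                "mean_rho": float(np.nanmean(np.concatenate(
                    [t.rho for t in tables]))),
                "per_hemisphere": {t.hemisphere: t.mean_rho for t in tables},
            }
        if self.axis_comparison is not None:
            ac = self.axis_comparison
            out["axis_comparison"] = {
                "chi2": ac.chi2, "df": ac.df, "p": ac.p,
                "n_blocks": ac.n_blocks,
                "posthoc": {f"{a}_vs_{b}": p for (a, b), p in ac.posthoc.items()},
            }
        for sulcus, per_axis in self.gradient_fits.items():
            out["gradients"][sulcus] = {
                "selected_axis": self.selected_axis.get(sulcus),
                "fits": {ax: {h: f.to_dict() for h, f in per_h.items()}
                         for ax, per_h in per_axis.items()},
            }
        return out


def analyze_cohort(subjects: list[SubjectData],
                   axes: tuple = AXES,
                   alpha: float = 0.001,
                   fwhm_mm: float = 2.0,
                   slab_thickness_mm: float = 2.0,
                   seed_resolution: str = "slab",
                   two_sided: bool = True,
                   sulci: dict | None = None) -> CohortResult:
    """Run connectivity, WTA, consensus, consistency and gradients.

    The seed nucleus is split at the midline and analyzed per hemisphere
    against the ipsilateral cortex.  ``sulci`` maps (name, hemisphere) ->
    (ROIMask, position_axis); when None it is taken from the first subject's
    sulcus masks and planted band axes (synthetic cohorts).
    """
    if not subjects:
        raise ValueError("no subjects")
    axes = tuple(axes)
    subject_ids = [s.subject_id for s in subjects]
    labelings: dict = {k: [] for ax in axes for k in [(ax, "L"), (ax, "R")]}
    stacks: dict = {k: [] for k in labelings}
    wta: dict = {k: [] for k in labelings}

    for sub in subjects:
        seed_h = split_hemispheres(sub.seed_mask)
        cortex_h = split_hemispheres(sub.cortex_mask)
        cleaned = preprocess_runs(sub.runs, fwhm_mm)
        for h in ("L", "R"):
            seed_h[h].require_nonempty()
            for ax in axes:
                lab = slice_mask(seed_h[h], ax, slab_thickness_mm, hemisphere=h)
                stack = subject_statmaps(
                    sub.runs, lab, cortex_h[h], fwhm_mm=fwhm_mm, alpha=alpha,
                    subject_id=sub.subject_id, two_sided=two_sided,
                    seed_resolution=seed_resolution, seed_mask=sub.seed_mask,
                    cleaned=cleaned)
                labelings[(ax, h)].append(lab)
                stacks[(ax, h)].append(stack)
                wta[(ax, h)].append(winner_take_all(stack, lab))
                logger.info("%s %s/%s: %d slabs, %d assigned voxels",
                            sub.subject_id, ax, h, lab.n_slabs,
                            wta[(ax, h)][-1].n_assigned)

    consensus = {k: group_consensus(v) for k, v in wta.items() if v}

    consistency: dict = {}
    if len(subjects) >= 2:
        for ax in axes:
            consistency[ax] = [cs.consistency_table(wta[(ax, h)], h)
                               for h in ("L", "R")]
    comparison = None
    if len(axes) >= 2 and consistency:
        try:
            comparison = cs.compare_axes(consistency)
        except ValueError as exc:
            logger.warning("axis comparison skipped: %s", exc)

    if sulci is None:
        first = subjects[0]
        sulci = {key: (m, first.truth.band_axis[key[0]])
                 for key, m in first.sulcus_masks.items()}
    gradient_fits: dict = {}
    selected: dict = {}
    names = sorted({name for name, _ in sulci})
    for name in names:
        gradient_fits[name] = {}
        for ax in axes:
            gradient_fits[name][ax] = {}
            for h in ("L", "R"):
                mask, pos_axis = sulci[(name, h)]
                path = lg.parameterize_sulcus(mask, pos_axis, hemisphere=h,
                                              name=name)
                try:
                    fit = lg.fit_gradient(wta[(ax, h)], path)
                except ValueError as exc:
                    logger.warning("gradient %s %s/%s skipped: %s",
                                   name, ax, h, exc)
                    fit = lg.GradientFit(sulcus=name, hemisphere=h,
                                         pulvinar_axis=ax, slope=0.0,
                                         intercept=0.0, r=0.0, p=1.0,
                                         n_points=0, polarity="none")
                gradient_fits[name][ax][h] = fit
        selected[name] = lg.select_axis(gradient_fits[name])

    return CohortResult(axes=axes, subject_ids=subject_ids,
                        labelings=labelings, stacks=stacks, wta=wta,
                        consensus=consensus, consistency=consistency,
                        axis_comparison=comparison,
                        gradient_fits=gradient_fits, selected_axis=selected)


# ---------------------------------------------------------------------------
# Disk pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: str = "pulvimap_out"
    cohort_manifest: str | None = None     # existing cohort; None -> simulate
    simulate: CohortConfig = field(default_factory=CohortConfig)
    alpha: float = 0.001
    fwhm_mm: float = 2.0
    slab_thickness_mm: float = 2.0
    axes: tuple = AXES
    seed_resolution: str = "slab"
    two_sided: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.slab_thickness_mm <= 0:
            raise ValueError("slab thickness must be positive")
        unknown = set(self.axes) - set(AXES)
        if unknown:
            raise ValueError(f"unknown axes {unknown}")
        if isinstance(self.simulate, dict):
            self.simulate = CohortConfig(**self.simulate)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            if "bands" in sim:
                sim["bands"] = tuple(tuple(b) for b in sim["bands"])
            raw["simulate"] = CohortConfig(**sim)
        if "axes" in raw:
            raw["axes"] = tuple(raw["axes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir, "cohort_manifest": self.cohort_manifest,
            "simulate": self.simulate.to_dict(), "alpha": self.alpha,
            "fwhm_mm": self.fwhm_mm,
            "slab_thickness_mm": self.slab_thickness_mm,
            "axes": list(self.axes), "seed_resolution": self.seed_resolution,
            "two_sided": self.two_sided, "rng_seed": self.rng_seed,
        }


@dataclass
class _LoadedTruth:
    band_axis: dict


def load_cohort(manifest_path) -> tuple[list[SubjectData], dict]:
    """Load a cohort written by :func:`generate_cohort` (or hand-assembled).

    Returns (subjects, sulci) where sulci maps (name, hemisphere) ->
    (ROIMask, position_axis).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    subjects = []
    sulci: dict = {}
    for entry in manifest["subjects"]:
        runs = []
        for r in entry["runs"]:
            img = load_image4d(r["bold"], tr_s=r.get("tr_s"))
            motion = load_motion(r["motion"], n_volumes=img.n_volumes)
            runs.append(RunData(image=img, motion=motion, run_id=r["run_id"]))
        seed = load_mask(entry["seed_mask"], name="seed_nucleus")
        cortex = load_mask(entry["cortex_mask"], name="cortex")
        sub_sulci = {}
        band_axis = {}
        for key, s in entry.get("sulci", {}).items():
            m = load_mask(s["path"], name=key)
            sub_sulci[(s["sulcus"], s["hemisphere"])] = m
            band_axis[s["sulcus"]] = s["position_axis"]
            if (s["sulcus"], s["hemisphere"]) not in sulci:
                sulci[(s["sulcus"], s["hemisphere"])] = (m, s["position_axis"])
        subjects.append(SubjectData(
            subject_id=entry["subject_id"], runs=runs, seed_mask=seed,
            cortex_mask=cortex, sulcus_masks=sub_sulci,
            truth=_LoadedTruth(band_axis=band_axis)))
    return subjects, sulci


RESULTS_SCHEMA = {
    "axes": list, "n_subjects": int, "subjects": list,
    "assigned_voxels": dict, "consensus": dict, "consistency": dict,
    "axis_comparison": (dict, type(None)), "gradients": dict,
}


def validate_results(results: dict) -> None:
    """Structural check of the results JSON against the stable schema."""
    for key, typ in RESULTS_SCHEMA.items():
        if key not in results:
            raise ValueError(f"results JSON missing key {key!r}")
        if not isinstance(results[key], typ):
            raise ValueError(f"results JSON key {key!r} has type "
                             f"{type(results[key]).__name__}")


def _write_volume(path, data, affine) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def run_pipeline(config: PipelineConfig, stages: set | None = None) -> dict:
    """Run the configured pipeline and write the report bundle.

    ``stages`` limits what is written (subset of {'connect', 'wta',
    'consensus', 'consistency', 'gradients'}); analysis is always carried to
    the requested products.  Returns the results summary dict.
    """
    all_stages = {"connect", "wta", "consensus", "consistency", "gradients"}
    stages = all_stages if stages is None else set(stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_manifest is None:
        sim = config.simulate
        if sim.rng_seed != config.rng_seed:
            sim = CohortConfig(**{**sim.to_dict(), "rng_seed": config.rng_seed})
            sim.bands = tuple(tuple(b) if not hasattr(b, "name") else b
                              for b in sim.bands)
        manifest = generate_cohort(sim, out / "cohort")
        logger.info("simulated cohort at %s", manifest)
    else:
        manifest = Path(config.cohort_manifest)
    subjects, sulci = load_cohort(manifest)

    result = analyze_cohort(
        subjects, axes=config.axes, alpha=config.alpha,
        fwhm_mm=config.fwhm_mm, slab_thickness_mm=config.slab_thickness_mm,
        seed_resolution=config.seed_resolution, two_sided=config.two_sided,
        sulci=sulci or None)

    geometry = subjects[0].seed_mask.geometry
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    if "connect" in stages:
        for (ax, h), stacks in result.stacks.items():
            for stack, lab in zip(stacks, result.labelings[(ax, h)]):
                vol = np.zeros(geometry.dims + (stack.n_slabs,), dtype=np.float32)
                for k in range(stack.n_slabs):
                    vol[tuple(stack.cortex_indices.T) + (k,)] = stack.t[k]
                _write_volume(maps_dir / f"{stack.subject_id}_{ax}_{h}_tmaps.nii.gz",
                              np.nan_to_num(vol), geometry.affine)
    if "wta" in stages:
        for (ax, h), maps in result.wta.items():
            for m in maps:
                _write_volume(maps_dir / f"{m.subject_id}_{ax}_{h}_wta.nii.gz",
                              m.to_volume(geometry.dims), geometry.affine)
    if "consensus" in stages:
        for (ax, h), g in result.consensus.items():
            pos = np.zeros(geometry.dims, dtype=np.float32)
            sup = np.zeros(geometry.dims, dtype=np.float32)
            pos[tuple(g.cortex_indices.T)] = np.nan_to_num(
                g.mean_winner_position, nan=-1.0)
            sup[tuple(g.cortex_indices.T)] = g.support
            _write_volume(maps_dir / f"group_{ax}_{h}_position.nii.gz", pos,
                          geometry.affine)
            _write_volume(maps_dir / f"group_{ax}_{h}_support.nii.gz", sup,
                          geometry.affine)
    if "consistency" in stages and result.consistency:
        pd.concat([t.to_frame() for ts in result.consistency.values()
                   for t in ts], ignore_index=True).to_csv(
            out / "consistency_pairs.csv", index=False)
        if result.axis_comparison is not None:
            ac = result.axis_comparison
            with open(out / "axis_comparison.json", "w") as fh:
                json.dump({"chi2": ac.chi2, "df": ac.df, "p": ac.p,
                           "n_blocks": ac.n_blocks,
                           "posthoc": {f"{a}_vs_{b}": p
                                       for (a, b), p in ac.posthoc.items()}},
                          fh, indent=2)
    if "gradients" in stages and result.gradient_fits:
        lg.fits_table([f for per_ax in result.gradient_fits.values()
                       for per_h in per_ax.values()
                       for f in per_h.values()]).to_csv(
            out / "gradient_fits.csv", index=False)

    summary = result.summary()
    validate_results(summary)
    with open(out / "results.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    _write_report(out, summary)
    return summary


def _write_report(out: Path, summary: dict) -> None:
    lines = ["# Pulvino-cortical topography report", ""]
    lines.append(f"Subjects: {', '.join(summary['subjects'])}")
    lines.append("")
    lines.append("## Assigned voxels per winner-take-all map")
    for key, per_sub in sorted(summary["assigned_voxels"].items()):
        counts = ", ".join(f"{s}: {n}" for s, n in sorted(per_sub.items()))
        lines.append(f"- {key}: {counts}")
    lines.append("")
    lines.append("## Group consensus (voxels retained at >= half support)")
    for key, info in sorted(summary["consensus"].items()):
        lines.append(f"- {key}: {info['n_retained']} voxels "
                     f"(min support {info['min_support']})")
    if summary["consistency"]:
        lines.append("")
        lines.append("## Inter-subject consistency (mean Spearman rho)")
        for ax, info in sorted(summary["consistency"].items()):
            lines.append(f"- {ax}: {info['mean_rho']:.3f}")
    if summary["axis_comparison"]:
        ac = summary["axis_comparison"]
        lines.append("")
        lines.append(f"Friedman chi2({ac['df']}) = {ac['chi2']:.2f}, "
                     f"p = {ac['p']:.3g} over {ac['n_blocks']} blocks")
    if summary["gradients"]:
        lines.append("")
        lines.append("## Sulcus gradients")
        for sulcus, info in sorted(summary["gradients"].items()):
            lines.append(f"- {sulcus}: selected axis {info['selected_axis']}")
            for ax, per_h in sorted(info["fits"].items()):
                for h, f in sorted(per_h.items()):
                    lines.append(
                        f"  - {ax}/{h}: slope {f['slope']:+.3f}, "
                        f"r {f['r']:+.3f}, p {f['p']:.3g}, "
                        f"n {f['n_points']}, {f['polarity']}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
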