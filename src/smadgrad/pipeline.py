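"""End-to-end pipeline: simulate/read -> segment -> contour -> quantify -> compare.

One output directory per run holds, per embryo, the stack (when
simulated), ground truth, nucleus records, contour polyline, binned
profile and fit; per run, the per-embryo fit table, the condition
comparison, a resolved configuration copy, and a manifest.  All
randomness derives from the configured seed, and a rerun with the same
configuration reproduces byte-identical CSV outputs.
"""
from __future__ import annotations

import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .config import RunConfig, dump_config, load_config
from .core import NucleusRecord, PipelineError, RawStack
from .contour import ContourResult, contour_from_records, select_central_slices
from .gradient import (GradientFit, bin_profile, compare_conditions,
                       fit_exponential)
from .segmentation import SegmentationConfig, segment_stack
from .stackio import (comparison_to_frame, fits_to_frame, read_stack,
                      write_contour_csv, write_profile_csv, write_records_csv,
                      write_stack)
from .synthetic import (EmbryoGeometry, GradientParams, GroundTruthTable,
                        NoiseParams, OpticsParams, simulate_embryo,
                        write_ground_truth)


def derive_seed(base_seed: int, *keys: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and index keys."""
    ss = np.random.SeedSequence([int(base_seed)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _seg_config(cfg: RunConfig, corrections: Optional[dict]) -> SegmentationConfig:
    s = cfg.segmentation
    return SegmentationConfig(
        blur_sigma_px=s.blur_sigma_px, window_px=s.window_px, offset=s.offset,
        offset_k=s.offset_k, offset_min=s.offset_min,
        min_area_px=s.min_area_px, max_area_px=s.max_area_px,
        measure_on_raw=s.measure_on_raw,
        subtract_background=s.subtract_background, corrections=corrections)


def intensity_records(records, cfg: RunConfig, nuclear_brightness: Optional[float]):
    """Apply the configured intensity normalization, returning new records.

    ``nuclear_ratio`` replaces each pSmad2 mean by
    ``scale * mean_psmad2 / mean_nuclear``: because both channels share the
    same label pixels, blob profile and depth attenuation, their ratio
    cancels those factors per record; with ``scale`` set to the (known or
    assumed) nuclear-channel brightness this is a calibrated estimate of
    the underlying pSmad2 intensity.  ``embryo_median`` divides by the
    median nuclear mean across the embryo.  ``none`` leaves raw means.
    """
    mode = cfg.analysis.normalization
    if mode == "none":
        return list(records)
    scale = cfg.analysis.ratio_scale
    if scale is None:
        scale = nuclear_brightness if nuclear_brightness is not None else 1.0
    out = []
    if mode == "embryo_median":
        med = float(np.median([r.mean_nuclear_intensity for r in records])) or 1.0
        for r in records:
            out.append(NucleusRecord(**{**r.__dict__,
                                        "mean_psmad2_intensity":
                                            r.mean_psmad2_intensity / med}))
        return out
    for r in records:
        denom = r.mean_nuclear_intensity
        val = scale * r.mean_psmad2_intensity / denom if denom > 0 else 0.0
        out.append(NucleusRecord(**{**r.__dict__, "mean_psmad2_intensity": val}))
    return out


@dataclass
class EmbryoResult:
    condition: str
    name: str
    records: list
    central_slices: list
    contour_result: Optional[ContourResult]
    fit: Optional[GradientFit]
    truth: Optional[GroundTruthTable]
    stack_meta: dict


def process_stack(stack: RawStack, cfg: RunConfig, *, center_slice=None,
                  corrections=None, nuclear_brightness=None):
    """Segment one stack, build its contour, assign distances, and fit the gradient.

    Returns ``(records_with_distances, central_slices, ContourResult, fit)``.
    """
    try:
        records = segment_stack(stack, _seg_config(cfg, corrections))
    except Exception as exc:
        raise PipelineError("segment", str(exc)) from exc
    if not records:
        return [], [], None, None
    c = cfg.contour
    try:
        central = select_central_slices(records, c.n_central_slices,
                                        center=center_slice if center_slice is not None
                                        else c.center_slice)
        cloud_z = None if c.cloud_slices == "all" else central
        cres = contour_from_records(
            records, pixel_size_um=stack.pixel_size_um, z_indices=cloud_z,
            min_sep_fraction=c.min_sep_fraction,
            curvature_window_um=c.curvature_window_um,
            band_radius_um=c.band_radius_um,
            sg_window_pts=c.sg_window_pts, sg_polyorder=c.sg_polyorder)
    except Exception as exc:
        raise PipelineError("contour", str(exc)) from exc
    from .contour import assign_distances
    central_records = [r for r in records if r.z_index in set(central)]
    annotated = assign_distances(central_records, cres.contour)
    fit = None
    try:
        fit_input = intensity_records(annotated, cfg, nuclear_brightness)
        fit = fit_exponential(fit_input, bin_width_um=cfg.analysis.bin_width_um)
    except ValueError as exc:
        warnings.warn(f"gradient fit skipped: {exc}", stacklevel=2)
    return annotated, central, cres, fit


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig | str | Path, out_dir) -> dict:
    """Execute the full pipeline described by ``config`` into ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    cfg = load_config(config) if not isinstance(config, RunConfig) else config
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not cfg.overwrite:
        raise PipelineError("setup", f"output directory {out} is not empty "
                                     "(set overwrite: true to reuse)")
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "resolved_config.yaml")

    manifest: dict = {
        "tool": "smadgrad",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "warnings": [],
        "inputs": {},
    }
    corrections = None
    if cfg.segmentation.corrections_file:
        with open(cfg.segmentation.corrections_file) as fh:
            raw = yaml.safe_load(fh)
        corrections = {int(k): v for k, v in (raw or {}).items()}

    geometry = EmbryoGeometry(**cfg.geometry.model_dump())
    optics = OpticsParams(**cfg.optics.model_dump())

    results: list[EmbryoResult] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for ci, cond in enumerate(cfg.conditions):
            if cfg.simulate:
                gradient = GradientParams(**cond.gradient.model_dump())
                for ei in range(cond.n_embryos):
                    seed = derive_seed(cfg.seed, ci, ei)
                    noise = (NoiseParams(photon_scale=cfg.noise.photon_scale,
                                         read_noise_sd=cfg.noise.read_noise_sd,
                                         seed=seed)
                             if cfg.noise.enabled else None)
                    try:
                        stack, truth, meta = simulate_embryo(
                            geometry, gradient, optics, noise, seed=seed,
                            z_halfdepth_um=cfg.simulation.z_halfdepth_um,
                            pad_um=cfg.simulation.pad_um,
                            nuclear_brightness=cfg.simulation.nuclear_brightness)
                    except Exception as exc:
                        raise PipelineError(
                            "simulate", f"{cond.name}/embryo{ei}: {exc}") from exc
                    name = f"{cond.name}_embryo{ei}"
                    write_stack(stack, out / f"{name}_stack.tif")
                    write_ground_truth(truth, out / f"{name}_truth.csv")
                    # pin the contour center slice to the simulated mid-plane:
                    # per-slab nucleus counts on a spherical shell are flat
                    # (Archimedes), so a count argmax would be noise-driven
                    center = (cfg.contour.center_slice
                              if cfg.contour.center_slice is not None
                              else meta["mid_slice"])
                    annotated, central, cres, fit = process_stack(
                        stack, cfg, center_slice=center, corrections=corrections,
                        nuclear_brightness=meta["nuclear_brightness"])
                    results.append(EmbryoResult(cond.name, name, annotated,
                                                central, cres, fit, truth, meta))
            else:
                for ei, spath in enumerate(cond.stacks):
                    try:
                        stack = read_stack(spath,
                                           pixel_size_um=cfg.optics.pixel_size_um,
                                           z_spacing_um=cfg.optics.z_spacing_um)
                    except Exception as exc:
                        raise PipelineError("read", str(exc)) from exc
                    manifest["inputs"][str(spath)] = _sha256(Path(spath))
                    name = f"{cond.name}_embryo{ei}"
                    annotated, central, cres, fit = process_stack(
                        stack, cfg, corrections=corrections)
                    results.append(EmbryoResult(cond.name, name, annotated,
                                                central, cres, fit, None,
                                                {"source": str(spath)}))
        manifest["warnings"] = sorted({str(w.message) for w in caught})

    fits_by_cond: dict[str, list] = {}
    for res in results:
        write_records_csv(res.records, out / f"{res.name}_records.csv")
        if res.contour_result is not None:
            write_contour_csv(res.contour_result.contour,
                              out / f"{res.name}_contour.csv")
        if res.records:
            profile = bin_profile(
                intensity_records(res.records, cfg,
                                  res.stack_meta.get("nuclear_brightness")),
                cfg.analysis.bin_width_um)
            write_profile_csv(profile, out / f"{res.name}_profile.csv")
        if res.fit is not None:
            fits_by_cond.setdefault(res.condition, []).append((res.name, res.fit))

    all_fits = [(n, f) for fits in fits_by_cond.values() for (n, f) in fits]
    if all_fits:
        fits_to_frame([f for _, f in all_fits],
                      [n for n, _ in all_fits]).to_csv(out / "fits.csv", index=False)

    if len(fits_by_cond) >= 2:
        names = [c.name for c in cfg.conditions if c.name in fits_by_cond]
        n1, n2 = names[0], names[1]
        try:
            comp = compare_conditions([f for _, f in fits_by_cond[n1]],
                                      [f for _, f in fits_by_cond[n2]],
                                      n_boot=cfg.analysis.n_boot,
                                      seed=derive_seed(cfg.seed, 9999),
                                      ci_level=cfg.analysis.ci_level)
            comparison_to_frame(comp, n1, n2).to_csv(out / "comparison.csv",
                                                     index=False)
        except ValueError as exc:
            manifest["warnings"].append(f"comparison skipped: {exc}")

    if cfg.write_figures and all_fits:
        _write_profile_figure(results, cfg, out / "profiles.png")

    manifest["stages"]["embryos"] = {
        res.name: {"n_records": len(res.records),
                   "central_slices": list(map(int, res.central_slices)),
                   "contour_length_um": (res.contour_result.contour.total_length_um
                                         if res.contour_result else None),
                   "fit_converged": bool(res.fit.converged) if res.fit else False}
        for res in results
    }
    manifest["resolved_config"] = cfg.model_dump()
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    os.replace(tmp, out / "manifest.json")
    return manifest


def _write_profile_figure(results, cfg: RunConfig, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = plt.get_cmap("tab10")
    cond_color = {}
    for res in results:
        if not res.records:
            continue
        cond_color.setdefault(res.condition, colors(len(cond_color)))
        col = cond_color[res.condition]
        prof = bin_profile(
            intensity_records(res.records, cfg,
                              res.stack_meta.get("nuclear_brightness")),
            cfg.analysis.bin_width_um)
        ax.plot(prof.bin_centers_um, prof.mean_intensity, "o-", ms=3, lw=0.8,
                color=col, alpha=0.5)
        if res.fit is not None and res.fit.converged:
            d = np.linspace(0, np.nanmax(prof.bin_centers_um), 200)
            ax.plot(d, res.fit.baseline + res.fit.amplitude *
                    np.exp(-d / res.fit.decay_length_um), color=col, lw=1.5)
    for cond, col in cond_color.items():
        ax.plot([], [], color=col, label=cond)
    ax.set_xlabel("distance from margin (µm)")
    ax.set_ylabel("mean pSmad2 intensity (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
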