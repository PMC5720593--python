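"""Reading and writing stacks and tabular results.

Stacks are multi-page TIFF, either one interleaved file (pages in ZC order:
for each z-plane, channel 0 then channel 1) or two single-channel files.
Calibration is stored in the ImageDescription tag as JSON and can be
overridden by configuration (configuration wins; a warning records the
conflict).  Tables are plain CSV.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import NucleusRecord, RawStack, StackFormatError, records_to_frame
from .gradient import ComparisonResult, GradientFit, GradientProfile


def write_stack(stack: RawStack, path, second_path=None) -> None:
    """Write a stack as interleaved multi-page TIFF (or two files if ``second_path``)."""
    desc = json.dumps({
        "pixel_size_um": stack.pixel_size_um,
        "z_spacing_um": stack.z_spacing_um,
        "origin_um": list(stack.origin_um),
        "channels": ["nuclear", "psmad2"],
    })
    if second_path is None:
        pages = np.empty((stack.n_slices * 2,) + stack.nuclear.shape[1:],
                         dtype=np.float32)
        pages[0::2] = stack.nuclear
        pages[1::2] = stack.psmad2
        tifffile.imwrite(path, pages, description=desc, photometric="minisblack")
    else:
        tifffile.imwrite(path, stack.nuclear.astype(np.float32), description=desc,
                         photometric="minisblack")
        tifffile.imwrite(second_path, stack.psmad2.astype(np.float32), description=desc,
                         photometric="minisblack")


def _read_meta(tif: tifffile.TiffFile) -> dict:
    try:
        desc = tif.pages[0].tags["ImageDescription"].value
        return json.loads(desc)
    except Exception:
        return {}


def read_stack(path, second_path=None, pixel_size_um: Optional[float] = None,
               z_spacing_um: Optional[float] = None) -> RawStack:
    """Read a two-channel stack; explicit calibration overrides file metadata.

    A single path must contain interleaved ZC pages (even page count); with
    ``second_path`` the two files hold one channel each.  Missing channels,
    shape mismatches, and absent calibration raise
    :class:`~smadgrad.core.StackFormatError` naming the file.
    """
    path = Path(path)
    if not path.exists():
        raise StackFormatError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        meta = _read_meta(tif)
        data = tif.asarray()
    if second_path is not None:
        second_path = Path(second_path)
        if not second_path.exists():
            raise StackFormatError(f"missing pSmad2 channel file: {second_path}")
        with tifffile.TiffFile(second_path) as tif2:
            data2 = tif2.asarray()
        nuclear, psmad2 = np.atleast_3d(data), np.atleast_3d(data2)
        if nuclear.shape != psmad2.shape:
            raise StackFormatError(
                f"channel shape mismatch between {path} {nuclear.shape} "
                f"and {second_path} {psmad2.shape}")
    else:
        data = np.atleast_3d(data)
        if data.ndim != 3 or data.shape[0] % 2 != 0 or data.shape[0] < 2:
            raise StackFormatError(
                f"{path}: expected interleaved ZC pages (even count >= 2), "
                f"got shape {data.shape}; missing pSmad2 channel?")
        nuclear = data[0::2]
        psmad2 = data[1::2]

    file_px = meta.get("pixel_size_um")
    file_dz = meta.get("z_spacing_um")
    px = pixel_size_um if pixel_size_um is not None else file_px
    dz = z_spacing_um if z_spacing_um is not None else file_dz
    if px is None or dz is None:
        raise StackFormatError(
            f"{path}: calibration (pixel_size_um, z_spacing_um) neither in "
            "file metadata nor supplied by configuration")
    for name, conf, filed in (("pixel_size_um", pixel_size_um, file_px),
                              ("z_spacing_um", z_spacing_um, file_dz)):
        if conf is not None and filed is not None and not np.isclose(conf, filed):
            warnings.warn(
                f"{path}: config {name}={conf} overrides file metadata {filed}",
                stacklevel=2)
    origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
    return RawStack(nuclear=np.asarray(nuclear, dtype=np.float32),
                    psmad2=np.asarray(psmad2, dtype=np.float32),
                    pixel_size_um=float(px), z_spacing_um=float(dz),
                    origin_um=origin)


def write_records_csv(records: Sequence[NucleusRecord], path) -> None:
    records_to_frame(list(records)).to_csv(path, index=False)


def write_contour_csv(contour, path) -> None:
    pd.DataFrame({
        "s_um": contour.arc_length_um,
        "x_um": contour.points_um[:, 0],
        "y_um": contour.points_um[:, 1],
    }).to_csv(path, index=False)


def write_profile_csv(profile: GradientProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)


def fits_to_frame(fits: Sequence[GradientFit], labels: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame([{
        "embryo": lab,
        "amplitude": f.amplitude,
        "decay_length_um": f.decay_length_um,
        "baseline": f.baseline,
        "residual_rms": f.residual_rms,
        "converged": f.converged,
        "flag": f.flag or "",
        "n_records": f.n_records,
    } for f, lab in zip(fits, labels)])


def comparison_to_frame(res: ComparisonResult, name1: str, name2: str) -> pd.DataFrame:
    return pd.DataFrame([{
        "condition1": name1,
        "condition2": name2,
        "amplitude_ratio": res.amplitude_ratio,
        "amplitude_ci_low": res.amplitude_ci[0],
        "amplitude_ci_high": res.amplitude_ci[1],
        "decay_length_ratio": res.decay_length_ratio,
        "decay_length_ci_low": res.decay_length_ci[0],
        "decay_length_ci_high": res.decay_length_ci[1],
        "ci_level": res.ci_level,
        "n_condition1": res.n_condition1,
        "n_condition2": res.n_condition2,
        "seed": res.seed,
    }])
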