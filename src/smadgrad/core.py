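"""Core containers and errors shared across the pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd


class PackingInfeasibleError(RuntimeError):
    """Requested nucleus count cannot be placed at the required spacing."""


class RasterOverflowError(ValueError):
    """A nucleus center lies outside the raster volume."""


class StackFormatError(ValueError):
    """An image stack on disk is missing a channel, shape-mismatched, or uncalibrated."""


class DegenerateHullError(ValueError):
    """The projected centroid cloud has no usable convex hull or margin pair."""


class DisconnectedMaskError(ValueError):
    """The two margin endpoints fall in disconnected foreground components."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RawStack:
    """Two-channel 3D confocal stack with physical calibration.

    Channel 0 (``nuclear``) is the nuclear stain used for segmentation;
    channel 1 (``psmad2``) is the pSmad2 immunostain whose per-nucleus
    intensity is the gradient readout.  Volumes are indexed ``(z, y, x)``
    and share shape and calibration.  ``origin_um`` records where the
    raster sits in the embryo frame (x0, y0, z0), so that simulator truth
    and measured centroids live in the same coordinates.
    """

    nuclear: np.ndarray
    psmad2: np.ndarray
    pixel_size_um: float
    z_spacing_um: float
    origin_um: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.nuclear.shape != self.psmad2.shape:
            raise StackFormatError(
                f"channel shapes differ: {self.nuclear.shape} vs {self.psmad2.shape}"
            )
        if self.nuclear.ndim != 3:
            raise StackFormatError("stack volumes must be 3D (z, y, x)")
        if self.pixel_size_um <= 0 or self.z_spacing_um <= 0:
            raise StackFormatError("calibration must be strictly positive")

    @property
    def n_slices(self) -> int:
        return self.nuclear.shape[0]

    def channel(self, i: int) -> np.ndarray:
        if i == 0:
            return self.nuclear
        if i == 1:
            return self.psmad2
        raise IndexError("RawStack has exactly 2 channels")


@dataclass
class NucleusRecord:
    """One segmented nucleus cross-section (2D, per z-slice; no z-linking).

    ``label`` is the per-slice connected-component label; ``id`` is unique
    across the whole stack.  Intensities are means over the constituent
    pixels of the raw channels.  ``margin_distance_um`` is filled by the
    contour stage and is ``None`` until assigned.
    """

    id: int
    z_index: int
    label: int
    centroid_x_um: float
    centroid_y_um: float
    area_px: int
    mean_nuclear_intensity: float
    mean_psmad2_intensity: float
    margin_distance_um: Optional[float] = None


_RECORD_COLUMNS = [
    "id", "z_index", "label", "centroid_x_um", "centroid_y_um", "area_px",
    "mean_nuclear_intensity", "mean_psmad2_intensity", "margin_distance_um",
]


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    """Tabulate records; the empty case keeps the full schema."""
    if not records:
        return pd.DataFrame(columns=_RECORD_COLUMNS)
    df = pd.DataFrame([asdict(r) for r in records])
    return df[_RECORD_COLUMNS]


def frame_to_records(df: pd.DataFrame) -> list[NucleusRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        md = d.get("margin_distance_um")
        out.append(NucleusRecord(
            id=int(d["id"]), z_index=int(d["z_index"]), label=int(d["label"]),
            centroid_x_um=float(d["centroid_x_um"]),
            centroid_y_um=float(d["centroid_y_um"]),
            area_px=int(d["area_px"]),
            mean_nuclear_intensity=float(d["mean_nuclear_intensity"]),
            mean_psmad2_intensity=float(d["mean_psmad2_intensity"]),
            margin_distance_um=None if md is None or (isinstance(md, float) and np.isnan(md)) else float(md),
        ))
    return out
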