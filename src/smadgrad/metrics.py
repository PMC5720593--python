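"""Recovery metrics against simulator ground truth.

Detection is scored per z-slice: the expected objects in a slice are the
nuclei whose rasterized cross-section there is large enough to pass the
configured size filter (computed in closed form from the spherical nucleus
envelope on the pixel grid), and detections are matched to them by
Hungarian assignment on in-plane centroid distance with a match radius.
Distance fidelity compares pipeline-assigned margin distances with the
true geodesic arc distances of the matched nuclei.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .core import NucleusRecord
from .synthetic import GroundTruthTable, cross_section_area_px


@dataclass
class DetectionScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def match_points(detected_xy: np.ndarray, true_xy: np.ndarray,
                 radius_um: float) -> tuple[int, list[tuple[int, int]]]:
    """Hungarian matching of detections to truth within ``radius_um``.

    Returns (number of matches, list of (det_index, true_index) pairs).
    """
    detected_xy = np.asarray(detected_xy, dtype=float).reshape(-1, 2)
    true_xy = np.asarray(true_xy, dtype=float).reshape(-1, 2)
    if len(detected_xy) == 0 or len(true_xy) == 0:
        return 0, []
    cost = cdist(detected_xy, true_xy)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] <= radius_um]
    return len(pairs), pairs


def expected_truth_by_slice(truth: GroundTruthTable, n_slices: int,
                            z_spacing_um: float, pixel_size_um: float,
                            nucleus_radius_um: float, min_area_px: int) -> dict:
    """For each slice, the truth rows whose expected cross-section passes the size filter."""
    tab = truth.table
    tab = tab[tab["in_stack"]] if "in_stack" in tab.columns else tab
    out: dict[int, pd.DataFrame] = {}
    for zi in range(n_slices):
        z_um = zi * z_spacing_um
        near = tab[np.abs(tab["z_um"] - z_um) < nucleus_radius_um]
        if not len(near):
            out[zi] = near
            continue
        keep = [cross_section_area_px((row.x_um, row.y_um, row.z_um), z_um,
                                      nucleus_radius_um, pixel_size_um) >= min_area_px
                for row in near.itertuples(index=False)]
        out[zi] = near[np.asarray(keep, dtype=bool)]
    return out


def detection_score(records: Sequence[NucleusRecord], truth: GroundTruthTable,
                    n_slices: int, z_spacing_um: float, pixel_size_um: float,
                    nucleus_radius_um: float, min_area_px: int,
                    match_radius_um: float = 2.0,
                    slices: Sequence[int] | None = None) -> DetectionScore:
    """Aggregate per-slice detection counts (micro-averaged over slices)."""
    by_slice = expected_truth_by_slice(truth, n_slices, z_spacing_um,
                                       pixel_size_um, nucleus_radius_um,
                                       min_area_px)
    use = range(n_slices) if slices is None else slices
    tp = fp = fn = 0
    for zi in use:
        det = [r for r in records if r.z_index == zi]
        det_xy = np.array([[r.centroid_x_um, r.centroid_y_um] for r in det]) \
            if det else np.empty((0, 2))
        tru = by_slice.get(zi)
        tru_xy = tru[["x_um", "y_um"]].to_numpy() if tru is not None and len(tru) \
            else np.empty((0, 2))
        m, _ = match_points(det_xy, tru_xy, match_radius_um)
        tp += m
        fp += len(det_xy) - m
        fn += len(tru_xy) - m
    return DetectionScore(tp=tp, fp=fp, fn=fn)


def distance_fidelity(records: Sequence[NucleusRecord], truth: GroundTruthTable,
                      n_slices: int, z_spacing_um: float, pixel_size_um: float,
                      nucleus_radius_um: float, min_area_px: int,
                      match_radius_um: float = 2.0) -> pd.DataFrame:
    """Match distance-annotated records to truth nuclei; return paired distances.

    Output columns: ``assigned_um`` (pipeline margin distance),
    ``d_true_um`` (simulator geodesic distance), ``i_true``.
    """
    by_slice = expected_truth_by_slice(truth, n_slices, z_spacing_um,
                                       pixel_size_um, nucleus_radius_um,
                                       min_area_px)
    rows = []
    for zi in sorted({r.z_index for r in records}):
        det = [r for r in records if r.z_index == zi
               and r.margin_distance_um is not None]
        tru = by_slice.get(zi)
        if not det or tru is None or not len(tru):
            continue
        det_xy = np.array([[r.centroid_x_um, r.centroid_y_um] for r in det])
        tru_xy = tru[["x_um", "y_um"]].to_numpy()
        _, pairs = match_points(det_xy, tru_xy, match_radius_um)
        for di, ti in pairs:
            rows.append({"assigned_um": det[di].margin_distance_um,
                         "d_true_um": float(tru["d_true_um"].iloc[ti]),
                         "i_true": float(tru["i_true"].iloc[ti])})
    return pd.DataFrame(rows, columns=["assigned_um", "d_true_um", "i_true"])


def matched_intensity_fit(records: Sequence[NucleusRecord], truth: GroundTruthTable,
                          n_slices: int, z_spacing_um: float, pixel_size_um: float,
                          nucleus_radius_um: float, min_area_px: int,
                          slices: Sequence[int],
                          nuclear_brightness: float,
                          match_radius_um: float = 2.0):
    """Gradient-parameter recovery through rendering, segmentation and measurement.

    Matches segmented records in ``slices`` to truth nuclei, builds
    calibrated per-record intensities ``C * mean_psmad2 / mean_nuclear``
    (the channel ratio cancels blob shape and depth attenuation; C is the
    known nuclear-channel brightness) and fits the exponential gradient
    model against the *true* geodesic distances — isolating intensity
    recovery from the separately validated contour stage.
    """
    from .gradient import fit_exponential_xy

    by_slice = expected_truth_by_slice(truth, n_slices, z_spacing_um,
                                       pixel_size_um, nucleus_radius_um,
                                       min_area_px)
    d, I = [], []
    for zi in sorted(set(int(z) for z in slices)):
        det = [r for r in records if r.z_index == zi]
        tru = by_slice.get(zi)
        if not det or tru is None or not len(tru):
            continue
        det_xy = np.array([[r.centroid_x_um, r.centroid_y_um] for r in det])
        _, pairs = match_points(det_xy, tru[["x_um", "y_um"]].to_numpy(),
                                match_radius_um)
        for di, ti in pairs:
            r = det[di]
            if r.mean_nuclear_intensity > 0:
                d.append(float(tru["d_true_um"].iloc[ti]))
                I.append(nuclear_brightness * r.mean_psmad2_intensity
                         / r.mean_nuclear_intensity)
    return fit_exponential_xy(np.asarray(d), np.asarray(I))


def fidelity_summary(paired: pd.DataFrame, contour_length_um: float) -> dict:
    """Median absolute distance error (also as % of contour length) and Spearman rho."""
    err = np.abs(paired["assigned_um"] - paired["d_true_um"])
    rho = spearmanr(paired["assigned_um"], paired["d_true_um"]).statistic
    return {
        "n": int(len(paired)),
        "median_abs_error_um": float(np.median(err)),
        "median_abs_error_pct_of_L": float(100 * np.median(err) / contour_length_um),
        "spearman_rho": float(rho),
    }
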