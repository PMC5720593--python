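"""Gradient profiles, exponential fits, and condition comparisons.

The signaling gradient is summarized by fitting, per embryo,

    I(d) = b + A * exp(-d / lambda)

to per-nucleus pSmad2 intensity versus margin distance d, with A >= 0
("amplitude", the peak signal above baseline at the margin), lambda > 0
("range", the exponential decay length in µm) and b >= 0 (baseline).
Binned profiles are a presentation layer; fits use the per-nucleus data.
Conditions (e.g. wild-type-like vs mutant-like) are compared by ratios of
across-embryo median amplitude and decay length, with percentile bootstrap
confidence intervals resampling embryos within each condition.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import NucleusRecord


@dataclass
class GradientProfile:
    """Binned intensity-vs-distance profile; empty bins have count 0 and NaN mean."""

    bin_centers_um: np.ndarray
    mean_intensity: np.ndarray
    sd_intensity: np.ndarray
    count: np.ndarray
    bin_width_um: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_um": self.bin_centers_um,
            "mean_intensity": self.mean_intensity,
            "sd_intensity": self.sd_intensity,
            "count": self.count,
        })


@dataclass
class GradientFit:
    """Fitted gradient metrics; parameters are withheld (NaN) unless converged.

    ``flag`` is ``"amplitude-null"`` when the data are consistent with a
    flat profile (A ~ 0), in which case lambda is unidentifiable and
    should not be interpreted.
    """

    amplitude: float
    decay_length_um: float
    baseline: float
    residual_rms: float
    converged: bool
    flag: Optional[str] = None
    n_records: int = 0


@dataclass
class ComparisonResult:
    """Condition-2 / condition-1 ratios of median amplitude and decay length with bootstrap CIs."""

    amplitude_ratio: float
    decay_length_ratio: float
    ci_level: float
    amplitude_ci: tuple
    decay_length_ci: tuple
    n_condition1: int
    n_condition2: int
    seed: int


def _distances_intensities(records: Sequence[NucleusRecord], intensity_attr: str):
    d, I = [], []
    for r in records:
        if r.margin_distance_um is not None and np.isfinite(r.margin_distance_um):
            d.append(r.margin_distance_um)
            I.append(getattr(r, intensity_attr))
    return np.asarray(d, dtype=float), np.asarray(I, dtype=float)


def bin_profile(records: Sequence[NucleusRecord], bin_width_um: float = 20.0,
                intensity_attr: str = "mean_psmad2_intensity") -> GradientProfile:
    """Bin records by margin distance into contiguous bins starting at 0."""
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    d, I = _distances_intensities(records, intensity_attr)
    if len(d) == 0:
        raise ValueError("no records with an assigned margin distance")
    n_bins = int(np.floor(d.max() / bin_width_um)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = I[which == b]
        if len(vals):
            means[b] = vals.mean()
            sds[b] = vals.std(ddof=0)
    centers = (edges[:-1] + edges[1:]) / 2
    return GradientProfile(bin_centers_um=centers, mean_intensity=means,
                           sd_intensity=sds, count=counts,
                           bin_width_um=float(bin_width_um))


def fit_exponential_xy(d: np.ndarray, I: np.ndarray,
                       bin_width_um: float = 20.0) -> GradientFit:
    """Bounded least-squares fit of b + A*exp(-d/lambda) on per-nucleus data.

    Initialization comes from a binned profile: b0 = smallest bin mean,
    A0 = largest minus smallest bin mean, and lambda0 = d_half / ln 2 where
    d_half is the distance at which the profile first falls halfway from
    its peak toward b0.  Bounds: A, b in [0, inf), lambda in (0, 10 * max
    distance].  Deterministic given the data.
    """
    d = np.asarray(d, dtype=float)
    I = np.asarray(I, dtype=float)
    if len(d) < 10:
        raise ValueError(f"need >= 10 records to fit, got {len(d)}")
    n_bins_spanned = len(np.unique(np.floor(d / bin_width_um)))
    if n_bins_spanned < 3:
        raise ValueError(
            f"records span only {n_bins_spanned} distance bins (< 3)")

    dummy = [NucleusRecord(id=i, z_index=0, label=0, centroid_x_um=0.0,
                           centroid_y_um=0.0, area_px=0,
                           mean_nuclear_intensity=0.0,
                           mean_psmad2_intensity=float(v),
                           margin_distance_um=float(dd))
             for i, (dd, v) in enumerate(zip(d, I))]
    prof = bin_profile(dummy, bin_width_um)
    means = prof.mean_intensity[np.isfinite(prof.mean_intensity)]
    centers = prof.bin_centers_um[np.isfinite(prof.mean_intensity)]
    b0 = float(means.min())
    A0 = float(means.max() - means.min())
    half_level = b0 + A0 / 2
    below = centers[means <= half_level]
    d_half = float(below[0]) if len(below) else float(d.max()) / 2
    lam0 = max(d_half, bin_width_um / 2) / np.log(2)
    lam_max = 10.0 * float(d.max())
    lam0 = min(max(lam0, 1e-6), lam_max)

    model = lambda x, A, lam, b: b + A * np.exp(-x / lam)
    try:
        popt, _ = curve_fit(model, d, I, p0=[max(A0, 1e-9), lam0, b0],
                            bounds=([0.0, 1e-9, 0.0], [np.inf, lam_max, np.inf]),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=20000)
        converged = True
    except RuntimeError:
        return GradientFit(amplitude=np.nan, decay_length_um=np.nan,
                           baseline=np.nan, residual_rms=np.nan,
                           converged=False, flag="no-convergence",
                           n_records=len(d))
    A, lam, b = (float(v) for v in popt)
    resid = I - model(d, A, lam, b)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    flag = None
    scale = max(abs(I).max(), 1e-12)
    if A < 1e-3 * scale:
        flag = "amplitude-null"
    return GradientFit(amplitude=A, decay_length_um=lam, baseline=b,
                       residual_rms=rms, converged=converged, flag=flag,
                       n_records=len(d))


def fit_exponential(records: Sequence[NucleusRecord], bin_width_um: float = 20.0,
                    intensity_attr: str = "mean_psmad2_intensity") -> GradientFit:
    """Fit the exponential gradient model to distance-annotated records."""
    d, I = _distances_intensities(records, intensity_attr)
    return fit_exponential_xy(d, I, bin_width_um=bin_width_um)


def _usable(fits: Sequence[GradientFit]) -> list[GradientFit]:
    return [f for f in fits if f.converged]


def compare_conditions(fits_cond1: Sequence[GradientFit],
                       fits_cond2: Sequence[GradientFit],
                       n_boot: int = 1000, seed: int = 0,
                       ci_level: float = 0.95) -> ComparisonResult:
    """Ratios of across-embryo median amplitude and decay length (cond2 / cond1).

    The embryo is the unit of replication: the percentile bootstrap
    resamples embryos with replacement within each condition.
    Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    f1 = _usable(fits_cond1)
    f2 = _usable(fits_cond2)
    if not f1 or not f2:
        raise ValueError("each condition needs >= 1 converged fit")
    A1 = np.array([f.amplitude for f in f1])
    A2 = np.array([f.amplitude for f in f2])
    L1 = np.array([f.decay_length_um for f in f1])
    L2 = np.array([f.decay_length_um for f in f2])
    amp_ratio = float(np.median(A2) / np.median(A1))
    lam_ratio = float(np.median(L2) / np.median(L1))
    rng = np.random.default_rng(seed)
    boots_a = np.empty(n_boot)
    boots_l = np.empty(n_boot)
    for i in range(n_boot):
        i1 = rng.integers(0, len(f1), len(f1))
        i2 = rng.integers(0, len(f2), len(f2))
        boots_a[i] = np.median(A2[i2]) / np.median(A1[i1])
        boots_l[i] = np.median(L2[i2]) / np.median(L1[i1])
    alpha = (1 - ci_level) / 2
    amp_ci = tuple(np.quantile(boots_a, [alpha, 1 - alpha]))
    lam_ci = tuple(np.quantile(boots_l, [alpha, 1 - alpha]))
    return ComparisonResult(amplitude_ratio=amp_ratio, decay_length_ratio=lam_ratio,
                            ci_level=ci_level,
                            amplitude_ci=(float(amp_ci[0]), float(amp_ci[1])),
                            decay_length_ci=(float(lam_ci[0]), float(lam_ci[1])),
                            n_condition1=len(f1), n_condition2=len(f2), seed=seed)
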