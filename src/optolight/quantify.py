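"""From operator outputs to the experiment's quantities.

* plasmid transfection rates (absolute and relative co-introduction),
* reporter signal-area time series and the induction-specificity statistic
  S (ratio of time-and-region-averaged mCherry signal, irradiated over
  unirradiated),
* the two-arm frequency model linking S to the leak rate f_leak and
  induction rate f_induce, and its inversion,
* pixel-binned stain-vs-mCherry dose–response curves,
* EdU-positive fractions with binomial intervals.

The frequency model: in a region of N_cell cells with co-introduction rate
f_co, the expected number of reporter-positive cells is N_cell·f_co·f_leak
without light and N_cell·f_co·(1 − (1 − f_leak)(1 − f_induce)) with light,
so the specificity

    S = (f_leak + f_induce − f_leak·f_induce) / f_leak
      = 1 + f_induce/f_leak − f_induce

is independent of N_cell and f_co; for small f_leak, S ≈ 1 + f_induce/f_leak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import ops
from .ops import BinaryMask, ChannelCounts, ImageStack, RegionSpec

__all__ = [
    "PipelineParams",
    "TransfectionRates",
    "SpecificityEstimate",
    "BinnedResponse",
    "transfection_rates",
    "measure_transfection",
    "mcherry_area_series",
    "specificity_measured",
    "model_S",
    "model_S_approx",
    "estimate_f_induce",
    "binned_response",
    "response_slope",
    "edu_fraction",
    "measure_edu_counts",
]


@dataclass(frozen=True)
class PipelineParams:
    """Operator parameters of the measurement chain (defaults recorded here).

    ``prominence`` is the maxima noise tolerance used for cell counting,
    calibrated on the bundled synthetic fixture to ≥ 95% counting accuracy;
    ``min_cluster_area`` (pixels) defaults to ≈ 0.3 × the rendered median
    nucleus area.  ``match_reference`` indexes the frame that anchors
    histogram matching (-1: the final frame).  Thresholding is per frame
    after matching (switchable to a single threshold from the reference
    frame with ``per_frame_threshold=False``).
    """

    smooth_radius: float = 1.0
    prominence: float = 15.0
    pairing_radius_px: float = 3.0
    threshold_method: str = "isodata"
    match_reference: int = -1
    per_frame_threshold: bool = True
    median_radius: float = 1.5
    min_cluster_area: int = 6
    bin_size: float = 50.0


# ---------------------------------------------------------------------------
# transfection rates


@dataclass(frozen=True)
class TransfectionRates:
    """Nucleus and reporter detection counts with the derived co-rates."""

    n_total: int
    n_p1: int
    n_p2: int
    n_both: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")
        if self.n_both > min(self.n_p1, self.n_p2):
            raise ValueError("n_both cannot exceed either channel count")

    @property
    def n_either(self) -> int:
        return self.n_p1 + self.n_p2 - self.n_both

    @property
    def absolute_co(self) -> float:
        """Co-transfected cells over all cells."""
        return float(Fraction(self.n_both, self.n_total))

    @property
    def relative_co(self) -> float:
        """Co-transfected cells over cells with at least one plasmid (NaN if none)."""
        if self.n_either == 0:
            return float("nan")
        return float(Fraction(self.n_both, self.n_either))


def transfection_rates(n_total: int, counts: ChannelCounts) -> TransfectionRates:
    return TransfectionRates(n_total, counts.n_first, counts.n_second, counts.n_both)


def measure_transfection(
    stack: ImageStack,
    params: PipelineParams = PipelineParams(),
    time: int = 0,
    nuclear_channel: str = "nuclei",
    p1_channel: str = "iRFP",
    p2_channel: str = "EGFP",
) -> TransfectionRates:
    """Count nuclei and reporter-positive cells on smoothed Z projections."""
    def proj(ch: str) -> np.ndarray:
        return ops.gaussian_smooth(ops.max_project(stack, ch, time), params.smooth_radius)

    n_total, _ = ops.count_maxima(proj(nuclear_channel), params.prominence)
    counts = ops.count_cotransfected(
        proj(p1_channel), proj(p2_channel), params.prominence, params.pairing_radius_px
    )
    return transfection_rates(n_total, counts)


# ---------------------------------------------------------------------------
# signal areas and specificity


def mcherry_area_series(
    stack: ImageStack,
    params: PipelineParams = PipelineParams(),
    channel: str = "mCherry",
    regions: Sequence[RegionSpec] | None = None,
) -> pd.DataFrame:
    """Per-frame reporter signal area via the standard chain.

    Maximum Z projection → histogram matching of the time series to the
    reference frame → automatic (IsoData) threshold on the full frame →
    binary median filter → foreground area inside each analysis region
    (the whole frame when ``regions`` is None).  Thresholding the full frame
    matters when an irradiated and an unirradiated region share the frame:
    the threshold is then anchored by the induced signal.  Returns columns
    ``region, time_min, area_px, area_um2, threshold``.
    """
    series = np.stack([ops.max_project(stack, channel, t) for t in range(len(stack.timestamps))])
    matched = ops.histogram_match(series, params.match_reference)
    rows = []
    ref_mask = None
    if not params.per_frame_threshold:
        ref_mask = ops.auto_threshold(matched[params.match_reference], params.threshold_method)
    for t, time_min in enumerate(stack.timestamps):
        if params.per_frame_threshold:
            bm = ops.auto_threshold(matched[t], params.threshold_method)
        else:
            bm = BinaryMask(matched[t] > ref_mask.threshold, ref_mask.provenance, ref_mask.threshold)
        thr = bm.threshold
        bm = ops.median_filter_binary(bm, params.median_radius)
        for region in (regions if regions is not None else [None]):
            area_px, area_um2 = ops.signal_area(bm, stack.pixel_size, region)
            name = region.name if region is not None else ""
            rows.append((name, time_min, area_px, area_um2, thr))
    return pd.DataFrame(rows, columns=["region", "time_min", "area_px", "area_um2", "threshold"])


@dataclass
class SpecificityEstimate:
    """Measured induction specificity with the underlying model frequencies.

    ``S`` is the ratio of the time-averaged (per region) then
    region-averaged mCherry signal area, irradiated over unirradiated; the
    ``sd`` fields are the standard deviations of the per-region time
    averages.  ``infinite`` flags a zero unirradiated mean.  The model
    frequencies are optional attachments (estimated or ground truth).
    """

    mean_irradiated: float
    mean_unirradiated: float
    S: float
    n_irradiated: int
    n_unirradiated: int
    sd_irradiated: float = float("nan")
    sd_unirradiated: float = float("nan")
    infinite: bool = False
    f_leak: float | None = None
    f_induce: float | None = None
    f_co: float | None = None
    per_region: pd.DataFrame | None = None


def specificity_measured(
    areas: pd.DataFrame,
    region_col: str = "region",
    arm_col: str = "irradiated",
    value_col: str = "area_um2",
) -> SpecificityEstimate:
    """Specificity S from a long table of per-region, per-frame signal areas.

    Averaging order: time average within each region first, then the mean of
    those region averages within each arm; S is the ratio of arm means.  A
    zero unirradiated mean yields S = inf with the ``infinite`` flag set
    rather than an exception.
    """
    if areas.empty:
        raise ValueError("empty area table")
    per_region = (
        areas.groupby([region_col, arm_col], sort=False)[value_col].mean().reset_index()
    )
    irr = per_region.loc[per_region[arm_col], value_col]
    unirr = per_region.loc[~per_region[arm_col].astype(bool), value_col]
    if irr.empty or unirr.empty:
        raise ValueError("need at least one region per arm")
    mean_irr, mean_unirr = float(irr.mean()), float(unirr.mean())
    infinite = mean_unirr == 0
    S = float("inf") if infinite else mean_irr / mean_unirr
    return SpecificityEstimate(
        mean_irradiated=mean_irr,
        mean_unirradiated=mean_unirr,
        S=S,
        n_irradiated=len(irr),
        n_unirradiated=len(unirr),
        sd_irradiated=float(irr.std(ddof=1)) if len(irr) > 1 else float("nan"),
        sd_unirradiated=float(unirr.std(ddof=1)) if len(unirr) > 1 else float("nan"),
        infinite=infinite,
        per_region=per_region,
    )


# ---------------------------------------------------------------------------
# the frequency model


def model_S(f_leak: float, f_induce: float) -> float:
    """Exact model specificity S = 1 + f_induce/f_leak − f_induce.

    Derived from the two-arm frequency model; N_cell and f_co cancel.
    Undefined at f_leak = 0 (S diverges as leak vanishes).
    """
    if not 0 < f_leak <= 1:
        raise ValueError("f_leak must be in (0, 1]")
    if not 0 <= f_induce <= 1:
        raise ValueError("f_induce must be in [0, 1]")
    return (f_leak + f_induce - f_leak * f_induce) / f_leak


def model_S_approx(f_leak: float, f_induce: float) -> float:
    """Small-leak approximation S ≈ 1 + f_induce/f_leak.

    Overestimates the exact value by exactly ``f_induce``.
    """
    if not 0 < f_leak <= 1:
        raise ValueError("f_leak must be in (0, 1]")
    if not 0 <= f_induce <= 1:
        raise ValueError("f_induce must be in [0, 1]")
    return 1.0 + f_induce / f_leak


def estimate_f_induce(S: float, f_leak: float) -> tuple[float, bool]:
    """Invert the exact model: f_induce = (S − 1)·f_leak / (1 − f_leak).

    Returns ``(f_induce, clipped)``; values above 1 are clipped with the
    flag set.  Requires S ≥ 1 and 0 < f_leak < 1.
    """
    if not 0 < f_leak < 1:
        raise ValueError("f_leak must be in (0, 1)")
    if S < 1:
        raise ValueError("model requires S ≥ 1")
    f = (S - 1.0) * f_leak / (1.0 - f_leak)
    if f > 1.0 + 1e-9:
        return 1.0, True
    return min(f, 1.0), False


# ---------------------------------------------------------------------------
# binned dose–response


@dataclass
class BinnedResponse:
    """Per-bin stain statistics against reporter intensity (fixed bin width)."""

    bin_edges: np.ndarray  # len n_bins + 1, contiguous, width = bin_size
    mean_stain: np.ndarray  # NaN where a bin is empty
    sd_stain: np.ndarray  # NaN where undefined (n < 2)
    n_pixels: np.ndarray
    empty: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean_stain": self.mean_stain,
                "sd_stain": self.sd_stain,
                "n_pixels": self.n_pixels,
            }
        )


def binned_response(
    mcherry_img: np.ndarray,
    stain_img: np.ndarray,
    bin_size: float = 50.0,
    min_cluster_area: int = 6,
    bin_max: float | None = None,
    erode_radius: float = 1.5,
) -> BinnedResponse:
    """Mean/SD of stain intensity per reporter-intensity bin, over pixels.

    Small reporter clusters (below ``min_cluster_area`` pixels, as defined by
    the image's own auto-threshold) are removed first, and the surviving
    cluster mask is eroded by ``erode_radius`` pixels to drop partial-volume
    boundary pixels, where both channels fade together and would fake a
    correlation.  The remaining reporter-positive pixels are partitioned
    into contiguous bins of width ``bin_size`` starting at 0.  Pass
    ``bin_max`` to impose an identical bin grid across compared samples.
    An image with no reporter-positive pixels yields an empty, flagged
    response.
    """
    mcherry_img = np.asarray(mcherry_img, dtype=float)
    stain_img = np.asarray(stain_img, dtype=float)
    if mcherry_img.shape != stain_img.shape:
        raise ValueError("images must be aligned")
    _, keep = ops.remove_small_clusters(mcherry_img, min_cluster_area)
    if erode_radius > 0:
        keep = ndimage.binary_erosion(keep, structure=ops.disk_footprint(erode_radius))
    vals = mcherry_img[keep]
    stain = stain_img[keep]
    top = bin_max if bin_max is not None else (vals.max() if vals.size else bin_size)
    n_bins = max(1, int(math.ceil(top / bin_size)))
    edges = np.arange(n_bins + 1) * bin_size
    if vals.size == 0:
        nanarr = np.full(n_bins, np.nan)
        return BinnedResponse(edges, nanarr, nanarr.copy(), np.zeros(n_bins, int), empty=True)
    idx = np.clip((vals / bin_size).astype(int), 0, n_bins - 1)
    n = np.bincount(idx, minlength=n_bins)
    s1 = np.bincount(idx, weights=stain, minlength=n_bins)
    s2 = np.bincount(idx, weights=stain**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s1 / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, (s2 - s1**2 / np.maximum(n, 1)) / np.maximum(n - 1, 1), np.nan)
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[n < 2] = np.nan
    return BinnedResponse(edges, mean, sd, n.astype(int))


def response_slope(resp: BinnedResponse, min_pixels: int = 10) -> dict:
    """Pixel-weighted linear fit of bin-mean stain against bin center.

    Weighted least squares with weights = per-bin pixel counts; returns the
    slope, intercept, the slope's standard error and 95% CI, and the Pearson
    correlation between bin means and bin centers (unweighted, over used
    bins).  Bins with fewer than ``min_pixels`` pixels are excluded.
    """
    use = (resp.n_pixels >= min_pixels) & np.isfinite(resp.mean_stain)
    x = resp.bin_centers[use]
    y = resp.mean_stain[use]
    w = resp.n_pixels[use].astype(float)
    if x.size < 3:
        raise ValueError("need at least 3 populated bins for a slope")
    W = w.sum()
    xbar = (w * x).sum() / W
    ybar = (w * y).sum() / W
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    dof = x.size - 2
    sigma2 = (w * resid**2).sum() / dof
    se = math.sqrt(sigma2 / sxx)
    tcrit = stats.t.ppf(0.975, dof)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(r):
        r = 0.0  # zero-variance bin means: no linear association
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "stderr": float(se),
        "ci_low": float(slope - tcrit * se),
        "ci_high": float(slope + tcrit * se),
        "pearson_r": r,
        "n_bins": int(x.size),
    }


# ---------------------------------------------------------------------------
# EdU fractions


def edu_fraction(
    nuclei_counts: Sequence[int],
    edu_counts: Sequence[int],
    labels: Sequence[str] = ("irradiated", "unirradiated"),
    alpha: float = 0.05,
) -> dict:
    """Per-arm EdU-positive fractions with binomial (Wilson) intervals.

    ``nuclei_counts`` and ``edu_counts`` are parallel per-arm totals from the
    densest Z plane.  Also reports the first-minus-second difference with a
    Wald interval.  Zero nuclei in an arm yields NaN fractions with a flag.
    """
    if len(nuclei_counts) != len(edu_counts) or len(nuclei_counts) != len(labels):
        raise ValueError("counts and labels must be parallel")
    z = stats.norm.ppf(1 - alpha / 2)
    arms = {}
    for lab, n, k in zip(labels, nuclei_counts, edu_counts):
        if n == 0:
            arms[lab] = {"fraction": float("nan"), "ci": (float("nan"),) * 2,
                         "n": 0, "undefined": True}
            continue
        if k > n:
            raise ValueError("EdU count cannot exceed nucleus count")
        p = k / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        arms[lab] = {"fraction": p, "ci": (center - half, center + half),
                     "n": n, "undefined": False}
    out = {"arms": arms}
    l0, l1 = labels[0], labels[1]
    if not (arms[l0]["undefined"] or arms[l1]["undefined"]):
        p0, n0 = arms[l0]["fraction"], arms[l0]["n"]
        p1, n1 = arms[l1]["fraction"], arms[l1]["n"]
        se = math.sqrt(p0 * (1 - p0) / n0 + p1 * (1 - p1) / n1)
        diff = p0 - p1
        out["difference"] = {"estimate": diff, "ci": (diff - z * se, diff + z * se)}
    return out


def measure_edu_counts(
    stack: ImageStack,
    params: PipelineParams = PipelineParams(),
    nuclear_channel: str = "nuclei",
    edu_channel: str = "edu",
) -> tuple[int, int, int]:
    """Nucleus and EdU detections on the densest Z plane.

    The plane is chosen from the nuclear channel at the first time point (the
    structural snapshot); EdU is counted on the same plane of the endpoint
    frame.  Returns (z_index, n_nuclei, n_edu).
    """
    z = ops.densest_plane(stack, nuclear_channel, 0, params.prominence, params.smooth_radius)
    nuc = ops.gaussian_smooth(stack.frame(0, nuclear_channel)[z], params.smooth_radius)
    edu = ops.gaussian_smooth(stack.frame(len(stack.timestamps) - 1, edu_channel)[z],
                              params.smooth_radius)
    n_nuc, _ = ops.count_maxima(nuc, params.prominence)
    n_edu, _ = ops.count_maxima(edu, params.prominence)
    return z, n_nuc, n_edu
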