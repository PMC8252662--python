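"""Composable image operators for fluorescence time-lapse quantification.

These reproduce, as plain functions on NumPy arrays, the classical
processing chain used to quantify light-induced reporter expression:
maximum Z-projection, light Gaussian smoothing, prominence-based maxima
counting (cell counting), cross-channel detection matching
(co-transfection counting), histogram matching across a time series,
IsoData ("default") auto-thresholding, binary median filtering, small
cluster removal, signal-area measurement, and densest-Z-plane selection.

Conventions
-----------
* pixel indexing is 0-based, row-major; image arrays are ``(row, col)``;
  stacks are ``(time, z, channel, row, col)``.
* region rectangles are given in µm and converted to half-open pixel
  rectangles with edges rounded outward.
* thresholded foreground is "strictly above the threshold"; for float
  images the threshold is quantized to a 256-bin histogram grid.
* filters use reflect boundary handling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import exposure

__all__ = [
    "ImageStack",
    "RegionSpec",
    "BinaryMask",
    "DegenerateHistogramError",
    "max_project",
    "gaussian_smooth",
    "count_maxima",
    "count_cotransfected",
    "histogram_match",
    "isodata_threshold_index",
    "auto_threshold",
    "median_filter_binary",
    "disk_footprint",
    "signal_area",
    "remove_small_clusters",
    "densest_plane",
]


class DegenerateHistogramError(ValueError):
    """Raised when an operation needs intensity contrast that is absent."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ImageStack:
    """A multi-channel time-lapse stack with physical calibration.

    ``data`` has axes (time, z, channel, row, col); ``timestamps`` are in
    minutes from experiment start; ``pixel_size`` is µm/pixel.  Channels are
    addressed by name, never by position.
    """

    data: np.ndarray
    pixel_size: float
    timestamps: tuple[float, ...]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError("stack data must have axes (time, z, channel, row, col)")
        nt, _, nc = self.data.shape[:3]
        self.timestamps = tuple(float(t) for t in self.timestamps)
        self.channel_names = tuple(self.channel_names)
        if len(self.timestamps) != nt:
            raise ValueError("one timestamp per time point required")
        if len(self.channel_names) != nc:
            raise ValueError("one name per channel required")
        if any(b <= a for a, b in zip(self.timestamps, self.timestamps[1:])):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in stack (has {list(self.channel_names)})"
            ) from None

    def frame(self, time: int, channel: str) -> np.ndarray:
        """The (z, row, col) sub-stack for one time point and channel."""
        return self.data[time, :, self.channel_index(channel)]

    # -- I/O ---------------------------------------------------------------

    def to_tiff(self, path) -> None:
        """Write as OME-TIFF with TZCYX axes and physical calibration."""
        dt = np.diff(self.timestamps)
        meta = {
            "axes": "TZCYX",
            "PhysicalSizeX": self.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": self.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": list(self.channel_names)},
            "Description": "timestamps_min=" + ",".join(f"{t:g}" for t in self.timestamps),
        }
        if dt.size and np.allclose(dt, dt[0]):
            meta["TimeIncrement"] = float(dt[0])
            meta["TimeIncrementUnit"] = "min"
        tifffile.imwrite(path, self.data, ome=True, metadata=meta)

    @classmethod
    def from_tiff(cls, path, pixel_size: float | None = None,
                  timestamps: Sequence[float] | None = None,
                  channel_names: Sequence[str] | None = None) -> "ImageStack":
        """Read an OME-TIFF (or plain multi-page TIFF with explicit metadata)."""
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            # Reshape to TZCYX, inserting missing singleton axes.
            order = "TZCYX"
            for ax in order:
                if ax not in axes:
                    data = np.expand_dims(data, 0)
                    axes = ax + axes
            data = np.moveaxis(data, [axes.index(a) for a in order], range(5))
            meta = _parse_ome(tf) if tf.ome_metadata else {}
        pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size", 1.0)
        channel_names = tuple(channel_names) if channel_names is not None else tuple(
            meta.get("channel_names") or [f"C{i}" for i in range(data.shape[2])]
        )
        if timestamps is None:
            timestamps = meta.get("timestamps") or tuple(float(t) for t in range(data.shape[0]))
        return cls(data, pixel_size, tuple(timestamps), channel_names)


def _parse_ome(tf) -> dict:
    import re
    import xml.etree.ElementTree as ET

    out: dict = {}
    root = ET.fromstring(tf.ome_metadata)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pix = root.find(".//ome:Pixels", ns)
    if pix is not None:
        if pix.get("PhysicalSizeX"):
            out["pixel_size"] = float(pix.get("PhysicalSizeX"))
        names = [c.get("Name") for c in pix.findall("ome:Channel", ns)]
        if names and all(names):
            out["channel_names"] = names
    desc = root.find(".//ome:Image/ome:Description", ns)
    if desc is not None and desc.text:
        m = re.search(r"timestamps_min=([\d.,eE+-]+)", desc.text)
        if m:
            out["timestamps"] = tuple(float(x) for x in m.group(1).split(","))
    return out


@dataclass(frozen=True)
class RegionSpec:
    """A rectangular analysis unit, in µm, flagged irradiated or not."""

    origin: tuple[float, float]  # (x, y) µm from field origin
    width: float  # µm
    height: float  # µm
    irradiated: bool
    condition_label: str
    name: str = ""

    def to_pixel_rect(self, pixel_size: float) -> tuple[int, int, int, int]:
        """Half-open pixel rectangle (row0, row1, col0, col1), edges rounded outward."""
        x, y = self.origin
        col0 = math.floor(x / pixel_size)
        row0 = math.floor(y / pixel_size)
        col1 = math.ceil((x + self.width) / pixel_size)
        row1 = math.ceil((y + self.height) / pixel_size)
        return row0, row1, col0, col1


@dataclass
class BinaryMask:
    """A 2D boolean mask plus the operator chain that produced it."""

    mask: np.ndarray
    provenance: tuple[str, ...] = ()
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    def to_tiff(self, path) -> None:
        """Write as 8-bit TIFF (foreground 255), provenance in the description."""
        tifffile.imwrite(path, self.mask.astype(np.uint8) * 255,
                         description=" | ".join(self.provenance))


# ---------------------------------------------------------------------------
# operators


def max_project(stack: ImageStack, channel: str, time: int) -> np.ndarray:
    """Maximum-intensity Z projection of one channel at one time point."""
    frame = stack.frame(time, channel)
    if frame.shape[0] == 0:
        raise ValueError("stack has an empty Z axis")
    return frame.max(axis=0)


def gaussian_smooth(img: np.ndarray, radius: float = 1.0) -> np.ndarray:
    """Gaussian filter with σ = ``radius`` pixels (radius 0 is the identity)."""
    if radius < 0:
        raise ValueError("radius must be ≥ 0")
    img = np.asarray(img, dtype=float)
    if radius == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma=radius, mode="reflect")


def count_maxima(img: np.ndarray, prominence: float) -> tuple[int, np.ndarray]:
    """Count local maxima protruding more than ``prominence`` above their saddle.

    A maximum is reported when one cannot reach a higher pixel without first
    descending by more than ``prominence`` (the morphological h-maxima
    criterion, equivalent to a noise-tolerance maxima finder).  The global
    maximum of a non-constant image is always reported — there is no higher
    point to compare it against.  Plateau maxima are reported once, at their
    centroid.  A constant (blank) image yields zero detections.

    Returns ``(count, coords)`` with coords as an (n, 2) array of (row, col).
    """
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    img = np.asarray(img, dtype=float)
    if img.size == 0 or np.ptp(img) == 0:
        return 0, np.empty((0, 2))
    from skimage.morphology import h_maxima

    if np.ptp(img) > prominence:
        peaks = h_maxima(img, prominence)
    else:
        peaks = img == img.max()  # only the global maximum survives
    labels, n = ndimage.label(peaks, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        peaks = img == img.max()
        labels, n = ndimage.label(peaks, structure=np.ones((3, 3), dtype=int))
    coords = np.asarray(ndimage.center_of_mass(peaks, labels, range(1, n + 1)), dtype=float)
    return n, coords


@dataclass(frozen=True)
class ChannelCounts:
    """Detection counts from two reporter channels of the same field."""

    n_first: int
    n_second: int
    n_both: int

    @property
    def n_either(self) -> int:
        return self.n_first + self.n_second - self.n_both


def count_cotransfected(
    first_img: np.ndarray,
    second_img: np.ndarray,
    prominence: float,
    pairing_radius: float = 3.0,
) -> ChannelCounts:
    """Count detections in each channel and those present in both.

    Detections are matched greedily by increasing distance; a pair is
    accepted when its separation is ≤ ``pairing_radius`` pixels and neither
    detection is already matched.
    """
    if np.shape(first_img) != np.shape(second_img):
        raise ValueError("channel images must have the same shape")
    n1, c1 = count_maxima(first_img, prominence)
    n2, c2 = count_maxima(second_img, prominence)
    if n1 == 0 or n2 == 0:
        return ChannelCounts(n1, n2, 0)
    tree = cKDTree(c2)
    pairs = []
    dists, idx = tree.query(c1, k=min(n2, 4), distance_upper_bound=pairing_radius)
    dists, idx = np.atleast_2d(dists), np.atleast_2d(idx)
    for i in range(n1):
        for d, j in zip(dists[i], idx[i]):
            if np.isfinite(d):
                pairs.append((d, i, int(j)))
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    n_both = 0
    for _, i, j in pairs:
        if i not in used1 and j not in used2:
            used1.add(i)
            used2.add(j)
            n_both += 1
    return ChannelCounts(n1, n2, n_both)


def histogram_match(
    frames: np.ndarray,
    reference_index: int = -1,
    reference_image: np.ndarray | None = None,
) -> np.ndarray:
    """Map each frame's intensity histogram onto a reference frame's.

    ``frames`` has axes (time, row, col).  The mapping is monotone
    (quantile-to-quantile).  The reference is either a frame of the series
    (``reference_index``, returned unchanged) or an explicit
    ``reference_image`` — e.g. the signal-richest frame of a whole multi-field
    experiment, so that every frame of every field shares one intensity
    scale.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected a (time, row, col) series")
    ref = np.asarray(reference_image, dtype=float) if reference_image is not None \
        else frames[reference_index]
    if np.ptp(ref) == 0:
        raise DegenerateHistogramError("reference frame has a constant histogram")
    ref_pos = None if reference_image is not None else np.arange(len(frames))[reference_index]
    out = np.empty_like(frames)
    for i, fr in enumerate(frames):
        out[i] = fr if i == ref_pos else exposure.match_histograms(fr, ref)
    return out


def isodata_threshold_index(hist: np.ndarray) -> int:
    """IsoData (iterative intermeans) threshold on a histogram.

    Returns the bin index T such that T is a fixed point of
    ``T ← round((mean of bins ≤ T + mean of bins > T) / 2)``, reached by
    iterating from the overall mean (rounding, not flooring: flooring pins
    the iteration below a two-bin background spike).  Foreground is
    "bin index > T".
    """
    hist = np.asarray(hist, dtype=float)
    nz = np.nonzero(hist)[0]
    if nz.size == 0:
        raise DegenerateHistogramError("empty histogram")
    lo, hi = int(nz[0]), int(nz[-1])
    if lo == hi:
        raise DegenerateHistogramError("constant image: single occupied bin")
    bins = np.arange(hist.size)
    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * bins)
    total, moment = csum[-1], cmoment[-1]

    def step(t: int) -> int:
        mean_low = cmoment[t] / csum[t]
        mean_high = (moment - cmoment[t]) / (total - csum[t])
        return round((mean_low + mean_high) / 2)

    t = min(max(int(moment // total), lo), hi - 1)
    for _ in range(hist.size):
        t_new = min(max(step(t), lo), hi - 1)
        if t_new == t:
            break
        t = t_new
    return t


def auto_threshold(img: np.ndarray, method: str = "isodata", nbins: int = 256) -> BinaryMask:
    """Binarize an image with an automatic global threshold.

    ``method="isodata"`` is the iterative-intermeans procedure (the classical
    "default" auto-threshold); ``method="otsu"`` is available as an
    alternative.  Foreground is strictly above the threshold.  A constant
    image yields an empty mask with a warning.
    """
    img = np.asarray(img)
    if np.ptp(img) == 0:
        warnings.warn("constant image: auto_threshold returns an empty mask", stacklevel=2)
        return BinaryMask(np.zeros(img.shape, bool), ("auto_threshold[degenerate]",), None)
    if method == "otsu":
        from skimage.filters import threshold_otsu

        t = float(threshold_otsu(img, nbins=nbins))
        return BinaryMask(img > t, (f"auto_threshold[otsu,{t:g}]",), t)
    if method != "isodata":
        raise ValueError(f"unknown threshold method {method!r}")
    if np.issubdtype(img.dtype, np.integer) and np.ptp(img) < nbins:
        # exact per-integer-value histogram (the 8-bit case)
        base = int(img.min())
        hist = np.bincount((img - base).ravel())
        t_idx = isodata_threshold_index(hist)
        t = float(base + t_idx)
        mask = img > t
    else:
        lo, hi = float(img.min()), float(img.max())
        hist, edges = np.histogram(img, bins=nbins, range=(lo, hi))
        t_idx = isodata_threshold_index(hist)
        t = float(edges[t_idx + 1])
        # pixels in bins > t_idx; the top bin's right edge is inclusive
        idx = np.minimum((np.asarray(img, float) - lo) / (hi - lo) * nbins, nbins - 1).astype(int)
        mask = idx > t_idx
    return BinaryMask(mask, (f"auto_threshold[isodata,{t:g}]",), t)


def disk_footprint(radius: float) -> np.ndarray:
    """Boolean footprint of pixel offsets with Euclidean distance ≤ radius."""
    r = int(math.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius**2


def median_filter_binary(mask: BinaryMask | np.ndarray, radius: float = 1.5) -> BinaryMask:
    """Majority vote within the discrete disk of the given radius.

    Radius 1.5 gives the 9-pixel disk (the 3×3 box).  Isolated single pixels
    are removed; solid shapes are preserved (reflect boundary handling).
    """
    src = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    prov = mask.provenance if isinstance(mask, BinaryMask) else ()
    fp = disk_footprint(radius)
    out = ndimage.median_filter(src.astype(np.uint8), footprint=fp, mode="reflect") > 0
    return BinaryMask(out, prov + (f"median_filter_binary[r={radius:g}]",))


def signal_area(
    mask: BinaryMask | np.ndarray,
    pixel_size: float,
    region: RegionSpec | None = None,
) -> tuple[int, float]:
    """Foreground pixel count (and µm²) inside a region (whole frame if None)."""
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if region is not None:
        r0, r1, c0, c1 = region.to_pixel_rect(pixel_size)
        # outward edge rounding may overshoot the frame's own rounding by 1 px
        if r0 < 0 or c0 < 0 or r1 > m.shape[0] + 1 or c1 > m.shape[1] + 1:
            raise ValueError("region lies outside the mask bounds")
        m = m[r0 : min(r1, m.shape[0]), c0 : min(c1, m.shape[1])]
    n = int(m.sum())
    return n, n * pixel_size**2


def remove_small_clusters(
    arr: np.ndarray | BinaryMask,
    min_area: int,
    connectivity: int = 2,
    cluster_mask: np.ndarray | None = None,
) -> tuple[np.ndarray | BinaryMask, np.ndarray]:
    """Zero out connected clusters smaller than ``min_area`` pixels.

    For a boolean mask the small components are simply dropped.  For an
    intensity image, clusters are defined by ``cluster_mask`` (default: the
    image's own IsoData foreground) and pixels of small clusters are set to
    zero.  Returns ``(cleaned, kept_mask)`` where ``kept_mask`` marks pixels
    of the surviving clusters.  8-connectivity by default.
    """
    if min_area < 0:
        raise ValueError("min_area must be ≥ 0")
    structure = ndimage.generate_binary_structure(2, connectivity)
    if isinstance(arr, BinaryMask) or np.asarray(arr).dtype == bool:
        src = arr.mask if isinstance(arr, BinaryMask) else np.asarray(arr, bool)
        labels, n = ndimage.label(src, structure=structure)
        keep = _large_labels(labels, n, min_area)
        if isinstance(arr, BinaryMask):
            return BinaryMask(keep, arr.provenance + (f"remove_small_clusters[{min_area}]",)), keep
        return keep, keep
    img = np.asarray(arr)
    if cluster_mask is None:
        cluster_mask = auto_threshold(img).mask
    labels, n = ndimage.label(cluster_mask, structure=structure)
    keep = _large_labels(labels, n, min_area)
    cleaned = np.where(keep | ~cluster_mask, img, 0)
    return cleaned, keep


def _large_labels(labels: np.ndarray, n: int, min_area: int) -> np.ndarray:
    if n == 0 or min_area <= 1:
        return labels > 0
    sizes = np.bincount(labels.ravel())
    big = np.zeros(n + 1, bool)
    big[1:] = sizes[1:] >= min_area
    return big[labels]


def densest_plane(
    stack: ImageStack,
    channel: str,
    time: int,
    prominence: float,
    smooth_radius: float = 1.0,
) -> int:
    """Index of the Z plane with the most nucleus detections (ties → lowest)."""
    frame = stack.frame(time, channel)
    counts = [
        count_maxima(gaussian_smooth(frame[z], smooth_radius), prominence)[0]
        for z in range(frame.shape[0])
    ]
    return int(np.argmax(counts))
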