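"""Fluorescence-image quantification operators for tumor-slice sections.

Four operators cover the two readouts of the assay:

* tumor-area detection on the pan-cytokeratin channel (grayscale hole
  filling, Sobel edge detection, morphological cleanup, region filling);
* EdU-positive cell counting on the EdU channel (intensity threshold,
  small-object removal, hole filling, erosion, size-filtered counting);
* Otsu histogram thresholding (256-bin between-class-variance maximizer);
* TUNEL/DAPI pixel co-localization (binary Manders-style overlap fraction
  of TUNEL-positive pixels within the DAPI nuclear mask).

All operators act on single-channel 2D rasters normalized to ``[0, 1]``;
:class:`ImageField` carries the raw integer channels and performs the
bit-depth normalization so user thresholds are bit-depth independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import sobel_h, sobel_v
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk, erosion, opening, reconstruction

__all__ = [
    "ImageField",
    "SegmentationParams",
    "NoEdgesWarning",
    "fill_dark_holes",
    "sobel_magnitude",
    "keratin_area",
    "count_edu",
    "otsu_threshold",
    "tunel_fraction",
]

#: canonical channel names, in storage order
CHANNEL_ORDER = ("dapi", "keratin", "edu", "tunel")


class NoEdgesWarning(UserWarning):
    """Raised (as a warning) when edge detection finds no edges in a field."""


@dataclass
class ImageField:
    """One multi-channel microscopy field.

    Parameters
    ----------
    channels
        Mapping from channel name (any subset of ``dapi``, ``keratin``,
        ``edu``, ``tunel``) to a 2D integer intensity raster. All channels
        must share one shape.
    pixel_size
        Lateral pixel size in micrometres (isotropic).
    bit_depth
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    field_id
        Free-form identifier carried through to quantification records.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 0.7
    bit_depth: int = 16
    field_id: str = ""

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.channels:
            raise ValueError("field has no channels")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mixed shapes: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2D, got shape {shape}")
        top = 2**self.bit_depth - 1
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.min() < 0 or arr.max() > top:
                raise ValueError(
                    f"channel {name!r} intensities outside [0, {top}]"
                )
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def normalized(self, name: str) -> np.ndarray:
        """Return channel ``name`` as float64 scaled to ``[0, 1]``."""
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not present in field")
        return self.channels[name] / (2**self.bit_depth - 1)


@dataclass
class SegmentationParams:
    """Tunable parameters of the quantification operators.

    ``sobel_edge_threshold`` and ``edu_intensity_threshold`` are expressed
    on the normalized ``[0, 1]`` scale. The two size rules are applied
    literally: objects strictly smaller than ``min_object_px`` are removed
    before counting, and only objects strictly larger than
    ``count_min_px`` are counted after erosion (an object of exactly 10 px
    survives removal but is not counted).
    """

    sobel_edge_threshold: float = 0.1
    edu_intensity_threshold: float = 0.5
    min_object_px: int = 10
    count_min_px: int = 10
    opening_radius: int = 2
    closing_radius: int = 2
    erosion_radius: int = 1
    connectivity: int = 8

    def __post_init__(self) -> None:
        for name in ("sobel_edge_threshold", "edu_intensity_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("opening_radius", "closing_radius", "erosion_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_object_px <= 0:
            raise ValueError("min_object_px must be positive")
        if self.count_min_px <= 0:
            raise ValueError("count_min_px must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _skimage_connectivity(self) -> int:
        # skimage encodes 4-connectivity as 1 and 8-connectivity as 2
        return 1 if self.connectivity == 4 else 2


def _as_2d_float(raster: np.ndarray) -> np.ndarray:
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D raster, got ndim={arr.ndim}")
    return arr


def fill_dark_holes(raster: np.ndarray) -> np.ndarray:
    """Fill dark regions enclosed by brighter pixels.

    Grayscale hole filling by morphological reconstruction: the marker is
    the image maximum everywhere except on the border (which keeps its
    original values), and reconstruction by erosion against the image
    lowers the marker back down everywhere except inside enclosed dark
    basins. The output is pointwise >= the input, border pixels are
    unchanged, and the operation is idempotent.
    """
    arr = _as_2d_float(raster)
    if arr.size == 0:
        return arr.copy()
    seed = np.full_like(arr, arr.max())
    seed[0, :] = arr[0, :]
    seed[-1, :] = arr[-1, :]
    seed[:, 0] = arr[:, 0]
    seed[:, -1] = arr[:, -1]
    return reconstruction(seed, arr, method="erosion")


def sobel_magnitude(raster: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude normalized by the maximum attainable response.

    For input in ``[0, 1]`` each directional response lies in ``[-1, 1]``,
    so the Euclidean magnitude is divided by sqrt(2) to map onto ``[0, 1]``.
    """
    arr = _as_2d_float(raster)
    return np.hypot(sobel_h(arr), sobel_v(arr)) / np.sqrt(2.0)


def keratin_area(
    keratin_raster: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, int]:
    """Segment the cytokeratin-positive (tumor) area of a field.

    Pipeline: grayscale hole filling -> Sobel gradient magnitude ->
    threshold at ``sobel_edge_threshold`` -> morphological closing (disk)
    to bridge gaps in the edge map -> region filling -> opening (disk) to
    discard edge fragments too thin to bound a region. The returned area
    is the pixel count of the final mask.

    Returns
    -------
    mask : ndarray of bool
        Detected keratin-positive region.
    area_px : int
        Number of pixels in ``mask``.

    Warns
    -----
    NoEdgesWarning
        If no pixel exceeds the edge threshold (e.g. a uniform field); the
        returned area is then 0.
    """
    params = params or SegmentationParams()
    arr = _as_2d_float(keratin_raster)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("keratin raster must be normalized to [0, 1]")
    grad = sobel_magnitude(fill_dark_holes(arr))
    edges = grad > params.sobel_edge_threshold
    if not edges.any():
        warnings.warn("no edges detected", NoEdgesWarning, stacklevel=2)
        return np.zeros_like(edges), 0
    closed = closing(edges, disk(params.closing_radius))
    filled = ndi.binary_fill_holes(closed)
    mask = opening(filled, disk(params.opening_radius))
    return mask, int(mask.sum())


def count_edu(
    edu_raster: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[int, np.ndarray]:
    """Count EdU-positive cells in a field.

    Pipeline: binarize at ``edu_intensity_threshold`` -> remove connected
    components with fewer than ``min_object_px`` pixels -> fill enclosed
    holes by morphological reconstruction -> erode with a flat disk of
    ``erosion_radius`` -> count components with more than ``count_min_px``
    pixels.

    Returns
    -------
    count : int
        Number of EdU-positive cells.
    labels : ndarray of int
        Label raster in which the counted objects carry labels
        ``1..count`` and everything else 0.
    """
    params = params or SegmentationParams()
    arr = _as_2d_float(edu_raster)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("edu raster must be normalized to [0, 1]")
    conn = params._skimage_connectivity
    mask = arr > params.edu_intensity_threshold
    pre_labels = cc_label(mask, connectivity=conn)
    sizes = np.bincount(pre_labels.ravel())
    keep = sizes >= params.min_object_px  # strictly-smaller objects removed
    keep[0] = False
    mask = keep[pre_labels]
    mask = fill_dark_holes(mask.astype(float)) > 0.5
    mask = erosion(mask, disk(params.erosion_radius))
    labels = cc_label(mask, connectivity=conn)
    counted = np.zeros_like(labels)
    count = 0
    for lab in range(1, labels.max() + 1):
        obj = labels == lab
        if obj.sum() > params.count_min_px:
            count += 1
            counted[obj] = count
    return count, counted


def otsu_threshold(raster: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of a raster over an ``nbins``-bin histogram.

    Scans every candidate cut level (lower class = bins up to and
    including the level) and returns the intensity maximizing the
    between-class variance. When several levels tie, their mean is used,
    so a two-valued image yields the midpoint between its values.
    Pixels classify as positive when strictly above the returned value.

    Raises
    ------
    ValueError
        If the raster is constant ("degenerate histogram").
    """
    arr = np.asarray(raster, dtype=float).ravel()
    lo, hi = arr.min(), arr.max()
    if lo == hi:
        raise ValueError("degenerate histogram: raster has a single value")
    counts, edges = np.histogram(arr, bins=nbins, range=(lo, hi))
    counts = counts.astype(float)
    n = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)
    w1 = n - w0
    sum0 = np.cumsum(counts * centers)
    mu0 = np.divide(sum0, w0, out=np.zeros_like(sum0), where=w0 > 0)
    mu1 = np.divide(sum0[-1] - sum0, w1, out=np.zeros_like(sum0), where=w1 > 0)
    var_b = w0 * w1 * (mu0 - mu1) ** 2
    var_b[-1] = -np.inf  # a cut at the top bin leaves one class empty
    best = np.flatnonzero(var_b == var_b[:-1].max())
    level = best.mean()
    # threshold sits at the upper edge of the (possibly fractional) cut bin
    width = (hi - lo) / nbins
    return float(lo + (level + 1.0) * width)


def tunel_fraction(tunel_raster: np.ndarray, dapi_raster: np.ndarray) -> float:
    """Percentage of DAPI-positive pixels that are also TUNEL-positive.

    Both channels are thresholded independently with
    :func:`otsu_threshold`; the result is the binary Manders-style overlap
    fraction ``100 * |DAPI & TUNEL| / |DAPI|``, using DAPI as the internal
    reference for total nuclear content.

    Raises
    ------
    ValueError
        If the two rasters differ in shape, or if no DAPI-positive pixel
        is found ("no nuclei detected").
    """
    tunel = _as_2d_float(tunel_raster)
    dapi = _as_2d_float(dapi_raster)
    if tunel.shape != dapi.shape:
        raise ValueError(
            f"shape mismatch: tunel {tunel.shape} vs dapi {dapi.shape}"
        )
    dapi_mask = dapi > otsu_threshold(dapi)
    n_dapi = int(dapi_mask.sum())
    if n_dapi == 0:
        raise ValueError("no nuclei detected: empty DAPI mask")
    tunel_mask = tunel > otsu_threshold(tunel)
    overlap = int(np.logical_and(dapi_mask, tunel_mask).sum())
    return 100.0 * overlap / n_dapi
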