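"""Training-free star-convex segmentation stage.

Produces a label map and a set of star polygons from a four-channel
fluorescence frame.  The stage is deliberately classical and deterministic:
images are locally contrast-enhanced, an object-probability map is built
from the enhanced nuclear (DAPI) and cytokeratin (PE) channels combined
with an interior-distance transform (so maxima sit at object centers),
candidate centers above ``prob_thresh`` are expanded to star polygons by
ray-casting, overlapping candidates are pruned by greedy NMS at
``nms_thresh``, and the survivors are rasterized into a label map.

The stage is pluggable: any externally produced label map can be fed to the
downstream feature-extraction and audit stages instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .starconvex import (
    NmsParams,
    StarPolygon,
    nms,
    polygon_window_mask,
    rays_from_mask,
)

__all__ = [
    "CHANNELS",
    "ChannelStack",
    "SegParams",
    "local_contrast_enhance",
    "object_probability",
    "segment",
]

CHANNELS = ("dapi", "pe", "apc", "spare")


@dataclass
class ChannelStack:
    """One frame's co-registered channel images.

    ``data`` has shape (4, H, W) in channel order DAPI, CK-PE, CD45-APC,
    spare; intensities are nonnegative instrument counts at ``bit_depth``
    bits.
    """

    data: np.ndarray
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 3:
            raise ValueError("stack must be (n_channels >= 3, H, W)")
        if np.min(self.data) < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def channel(self, name: str) -> np.ndarray:
        return self.data[CHANNELS.index(name)]


@dataclass
class SegParams:
    """Post-processing parameters of the segmentation stage.

    ``prob_thresh`` and ``nms_thresh`` both default to 0.3.  ``window_px``
    is the local contrast-enhancement window (65 px ~ 42 um at 0.64 um/px:
    larger than a cell, smaller than a clump).  ``min_contrast`` is the
    dynamic-range floor (instrument counts) below which a window is treated
    as contrast-free, so read noise is not stretched to full scale.
    ``fg_thresh`` is the fixed threshold on the enhanced channel maximum
    that defines foreground; it admits single-channel events (tdEVs, bare
    nuclei) because the channels are combined with a maximum.
    """

    prob_thresh: float = 0.3
    nms_thresh: float = 0.3
    n_rays: int = 32
    window_px: int = 65
    weight_dapi: float = 1.0
    weight_pe: float = 1.0
    fg_thresh: float = 0.25
    min_contrast: float = 60.0
    enhance_max_range: float = 400.0
    min_distance_px: int = 3
    smooth_sigma: float = 1.0
    peak_window_px: int = 13

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_thresh <= 1.0 and 0.0 <= self.nms_thresh <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ValueError("window_px must be odd and >= 3")
        if self.n_rays < 4:
            raise ValueError("n_rays must be >= 4")


def local_contrast_enhance(
    image: np.ndarray,
    window_px: int,
    min_contrast: float = 0.0,
    max_range: float | None = None,
) -> np.ndarray:
    """Sliding-window min-max normalization to [0, 1].

    Each pixel maps to ``(v - local_min) / (local_max - local_min)`` over a
    ``window_px`` square window; windows whose dynamic range is at or below
    ``min_contrast`` (default: zero range only) map to 0.  The output is
    invariant under affine rescaling ``v -> a*v + b`` (a > 0) wherever the
    window has contrast above the floor.

    ``max_range`` optionally caps the normalization denominator (values
    then clip at 1): without it, one very bright cell drags every fainter
    neighbor in its window toward 0 — the faint-near-bright failure mode
    of windowed enhancement.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    img = np.asarray(image, dtype=float)
    lo = ndi.minimum_filter(img, size=window_px, mode="nearest")
    hi = ndi.maximum_filter(img, size=window_px, mode="nearest")
    rng = hi - lo
    out = np.zeros_like(img)
    ok = rng > max(min_contrast, 0.0)
    denom = rng if max_range is None else np.minimum(rng, max_range)
    np.divide(img - lo, denom, out=out, where=ok)
    out[~ok] = 0.0
    return np.clip(out, 0.0, 1.0)


def _foreground(stack: ChannelStack, params: SegParams) -> tuple[np.ndarray, np.ndarray]:
    """Enhanced DAPI/PE combination and the binary foreground."""
    dapi = local_contrast_enhance(
        stack.channel("dapi"), params.window_px, params.min_contrast,
        params.enhance_max_range,
    )
    pe = local_contrast_enhance(
        stack.channel("pe"), params.window_px, params.min_contrast,
        params.enhance_max_range,
    )
    combined = np.maximum(params.weight_dapi * dapi, params.weight_pe * pe)
    combined = np.clip(combined, 0.0, 1.0)
    fg = combined > params.fg_thresh
    return combined, fg


def object_probability(stack: ChannelStack, params: SegParams) -> np.ndarray:
    """Pseudo-probability map in [0, 1] whose local maxima sit at object
    centers.

    The enhanced DAPI/PE maximum is smoothed and multiplied by the interior
    distance transform of the foreground, normalized against its local
    maximum over roughly one cell diameter, so that each object (large
    cell or small vesicle alike) peaks near 1 at its center and falls to 0
    at its boundary and in the background.
    """
    combined, fg = _foreground(stack, params)
    if not fg.any():
        return np.zeros(stack.shape)
    smoothed = ndi.gaussian_filter(combined, params.smooth_sigma)
    dt = ndi.distance_transform_edt(fg)
    # Normalize the distance transform against its local maximum (window of
    # roughly one cell diameter) rather than per connected component: in
    # dense frames many cells share one foreground component, and a
    # component-wide normalization would suppress the smaller cells.
    local_max = ndi.maximum_filter(dt, size=params.peak_window_px, mode="nearest")
    norm = np.where(local_max > 0, dt / np.maximum(local_max, 1e-9), 0.0)
    return np.clip(smoothed * norm, 0.0, 1.0)


def _candidate_polygons(
    stack: ChannelStack, params: SegParams
) -> list[StarPolygon]:
    """Detect probability peaks and expand each to a star polygon.

    Touching objects share one connected foreground component, so each
    peak's support is delimited by a marker-controlled watershed of the
    foreground before ray-casting; the polygon score is the peak
    probability.
    """
    prob = object_probability(stack, params)
    _, fg = _foreground(stack, params)
    peaks = peak_local_max(
        prob,
        min_distance=params.min_distance_px,
        threshold_abs=params.prob_thresh,
        exclude_border=False,
    )
    if peaks.size == 0:
        return []
    markers = np.zeros(stack.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    dt = ndi.distance_transform_edt(fg)
    regions = watershed(-dt, markers=markers, mask=fg)
    polys: list[StarPolygon] = []
    for i, (r, c) in enumerate(peaks, start=1):
        region = regions == i
        if not region[r, c]:
            continue
        poly = rays_from_mask(region, (float(r), float(c)), n_rays=params.n_rays)
        poly.score = float(np.clip(prob[r, c], 0.0, 1.0))
        polys.append(poly)
    return polys


def segment(
    stack: ChannelStack, params: SegParams | None = None
) -> tuple[np.ndarray, list[StarPolygon]]:
    """Segment a frame into labeled events.

    Returns a label map (0 = background, labels contiguous 1..n, each label
    4-connected) and the kept star polygons in label order.  Overlap between
    kept polygons is resolved pixel-wise in favor of the higher score.
    Deterministic: identical inputs give identical outputs.
    """
    if params is None:
        params = SegParams()
    shape = stack.shape
    candidates = _candidate_polygons(stack, params)
    kept = nms(candidates, NmsParams(nms_thresh=params.nms_thresh), shape)
    labels = np.zeros(shape, dtype=np.int32)
    out_polys: list[StarPolygon] = []
    next_label = 1
    # NMS output is already in descending-score keep order: paint each
    # polygon only onto still-unclaimed pixels so higher scores win overlaps.
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for poly in kept:
        (r0, c0, r1, c1), local = polygon_window_mask(poly, shape)
        if local is None:
            continue
        view = labels[r0:r1, c0:c1]
        mask = local & (view == 0)
        if not mask.any():
            continue
        # keep the largest 4-connected piece so labels stay connected
        lab, n = ndi.label(mask, structure=four)
        if n > 1:
            sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
        view[mask] = next_label
        out_polys.append(poly)
        next_label += 1
    return labels, out_polys
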