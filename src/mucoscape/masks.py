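"""Mucosal/luminal mask generation by channel thresholding, and mask edges.

The mucosal mask is produced by thresholding the DAPI channel so the
region of interest is limited to the mucosa; the luminal mask by
thresholding the Eub channel and eliminating the mucosal mask. Raw
nucleus thresholding yields speckle, so both masks go through the same
morphological cleanup (closing, hole filling, small-object removal,
optional largest-component selection). Mask disjointness is enforced
exactly: the mucosal mask is subtracted from the luminal mask again
after cleanup.

Edges: the "outer" edges returned by :func:`mask_edges` are the two
boundaries bounding the inter-mask gap — the mucosa's lumen-facing side
and the lumen's mucosa-facing side — so the distance between them spans
the bacteria-free inner mucus layer. Components use 8-connectivity;
boundary pixels are mask pixels with at least one 4-neighbor outside
the mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import threshold_otsu

from .errors import EmptyCompartmentError, ParameterError, ValidationError
from .imagio import BinaryMask, MultichannelImage

logger = logging.getLogger(__name__)

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Thresholding and cleanup parameters for one compartment mask."""

    threshold_method: str = "otsu"
    fixed_threshold: Optional[float] = None
    min_object_area_um2: float = 50.0
    closing_radius_um: float = 2.0
    keep_largest_component: bool = True
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ParameterError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ParameterError("fixed_threshold required when method is 'fixed'")
        if self.threshold_method == "otsu" and self.fixed_threshold is not None:
            raise ParameterError("fixed_threshold only valid with method 'fixed'")
        if self.min_object_area_um2 < 0:
            raise ParameterError("min_object_area_um2 must be >= 0")
        if self.closing_radius_um < 0:
            raise ParameterError("closing_radius_um must be >= 0")


@dataclass
class EdgeContour:
    """Ordered boundary pixel coordinates of one mask edge."""

    points: np.ndarray  # (n, 2) int array of (row, col)
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int).reshape(-1, 2)
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")

    def __len__(self) -> int:
        return len(self.points)

    def points_um(self) -> np.ndarray:
        return self.points.astype(float) * self.pixel_size_um

    def arc_length_um(self) -> np.ndarray:
        """Cumulative arc length (um) along the ordered points; starts at 0."""
        if len(self.points) == 0:
            return np.empty(0)
        steps = np.linalg.norm(np.diff(self.points, axis=0).astype(float), axis=1)
        return np.concatenate(([0.0], np.cumsum(steps))) * self.pixel_size_um

    def total_length_um(self) -> float:
        arc = self.arc_length_um()
        return float(arc[-1]) if arc.size else 0.0


def _threshold(channel: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if params.threshold_method == "fixed":
        thr = params.fixed_threshold
    else:
        if np.ptp(channel) == 0:
            logger.warning("degenerate channel (constant); returning empty mask")
            return np.zeros(channel.shape, dtype=bool)
        thr = threshold_otsu(channel)
    mask = channel > thr
    if mask.all() or not mask.any():
        logger.warning(
            "threshold %.4g is degenerate (mask is %s)",
            thr,
            "full" if mask.all() else "empty",
        )
    return mask


def _cleanup(mask: np.ndarray, params: SegmentationParams, pixel_size_um: float) -> np.ndarray:
    out = mask
    r_px = int(round(params.closing_radius_um / pixel_size_um))
    if r_px > 0 and out.any():
        out = morphology.closing(out, morphology.disk(r_px))
    if params.fill_holes and out.any():
        out = ndi.binary_fill_holes(out)
    min_px = int(round(params.min_object_area_um2 / pixel_size_um**2))
    if min_px > 1 and out.any():
        labels, n = ndi.label(out, structure=_STRUCT8)
        if n:
            sizes = ndi.sum_labels(out, labels, index=np.arange(1, n + 1))
            small = np.flatnonzero(sizes < min_px) + 1
            if small.size:
                out = out & ~np.isin(labels, small)
    if params.keep_largest_component and out.any():
        labels, n = ndi.label(out, structure=_STRUCT8)
        if n > 1:
            sizes = ndi.sum_labels(out, labels, index=np.arange(1, n + 1))
            out = labels == (1 + int(np.argmax(sizes)))
    return out


def mucosal_mask(img: MultichannelImage, params: SegmentationParams) -> BinaryMask:
    """Threshold the DAPI channel into a contiguous mucosa ROI."""
    dapi = img.channel("DAPI")
    raw = _threshold(dapi, params)
    clean = _cleanup(raw, params, img.pixel_size_um)
    return BinaryMask(grid=clean, label="mucosal")


def luminal_mask(
    img: MultichannelImage, mucosal: BinaryMask, params: SegmentationParams
) -> BinaryMask:
    """Threshold the Eub channel and eliminate the mucosal mask.

    Disjointness with the mucosal mask is a hard postcondition: the
    mucosal mask is subtracted again after morphological cleanup.
    """
    eub = img.channel("Eub")
    if mucosal.shape != img.shape:
        raise ValidationError(
            f"mucosal mask shape {mucosal.shape} != image shape {img.shape}"
        )
    raw = _threshold(eub, params) & ~mucosal.grid
    clean = _cleanup(raw, params, img.pixel_size_um)
    clean &= ~mucosal.grid
    return BinaryMask(grid=clean, label="luminal")


def boundary_pixels(grid: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one in-image background 4-neighbor."""
    eroded = ndi.binary_erosion(grid, structure=_STRUCT4, border_value=1)
    return grid & ~eroded


def _order_chain(points: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbor ordering of boundary pixels into a chain."""
    n = len(points)
    if n <= 2:
        return points
    pts = points.astype(float)
    # start at the lexicographically smallest (col, row) point
    start = int(np.lexsort((pts[:, 0], pts[:, 1]))[0])
    order = np.empty(n, dtype=int)
    used = np.zeros(n, dtype=bool)
    order[0] = start
    used[start] = True
    current = start
    for i in range(1, n):
        d = np.linalg.norm(pts - pts[current], axis=1)
        d[used] = np.inf
        current = int(np.argmin(d))
        order[i] = current
        used[current] = True
    return points[order]


def _facing_edge(grid: np.ndarray, gap: np.ndarray) -> np.ndarray:
    """Boundary pixels of ``grid`` that are 4-adjacent to the gap region."""
    near_gap = ndi.binary_dilation(gap, structure=_STRUCT4)
    edge = boundary_pixels(grid) & near_gap
    if not edge.any():
        edge = boundary_pixels(grid)
    return edge


def mask_edges(
    mucosal: BinaryMask, luminal: BinaryMask
) -> tuple[EdgeContour, EdgeContour]:
    """Outer edges of the mucosal and luminal masks bounding their gap.

    Returns ``(mucosal_edge, luminal_edge)`` as ordered pixel chains.
    The gap is the background region adjacent to both masks; each
    returned edge consists of boundary pixels of its mask facing that
    gap. Raises :class:`EmptyCompartmentError` for an empty mask, in
    which case the layer thickness is undefined and must be reported as
    such by the caller.
    """
    if mucosal.is_empty():
        raise EmptyCompartmentError(
            "mucosal mask is empty; inner mucus thickness is undefined"
        )
    if luminal.is_empty():
        raise EmptyCompartmentError(
            "luminal mask is empty; inner mucus thickness is undefined"
        )
    if mucosal.shape != luminal.shape:
        raise ValidationError("mask shapes differ")

    background = ~mucosal.grid & ~luminal.grid
    gap = np.zeros_like(background)
    if background.any():
        labels, n = ndi.label(background, structure=_STRUCT4)
        near_muc = ndi.binary_dilation(mucosal.grid, structure=_STRUCT4)
        near_lum = ndi.binary_dilation(luminal.grid, structure=_STRUCT4)
        touching_muc = np.unique(labels[near_muc & background])
        touching_lum = np.unique(labels[near_lum & background])
        shared = np.intersect1d(touching_muc, touching_lum)
        shared = shared[shared > 0]
        if shared.size:
            gap = np.isin(labels, shared)

    if not gap.any():
        # masks touch everywhere (zero-thickness layer): fall back to the
        # full boundaries
        gap = background

    muc_edge = _facing_edge(mucosal.grid, gap)
    lum_edge = _facing_edge(luminal.grid, gap)

    px = 1.0
    muc_points = _order_chain(np.column_stack(np.nonzero(muc_edge)))
    lum_points = _order_chain(np.column_stack(np.nonzero(lum_edge)))
    return (
        EdgeContour(points=muc_points, pixel_size_um=px),
        EdgeContour(points=lum_points, pixel_size_um=px),
    )


def mask_edges_um(
    mucosal: BinaryMask, luminal: BinaryMask, pixel_size_um: float
) -> tuple[EdgeContour, EdgeContour]:
    """Like :func:`mask_edges` but with physical calibration attached."""
    muc, lum = mask_edges(mucosal, luminal)
    return (
        EdgeContour(points=muc.points, pixel_size_um=pixel_size_um),
        EdgeContour(points=lum.points, pixel_size_um=pixel_size_um),
    )
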