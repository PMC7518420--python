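"""Per-mask intensity, inner-mucus-layer thickness, and bacterial density.

Thickness follows the mask-edge procedure: sample 100 random points
along the luminal edge (without replacement; all points if the edge is
shorter) and record, for each, the minimal Euclidean distance to the
mucosal edge. Distances are pixel-center to pixel-center, converted to
micrometres by the pixel size; a brute-force all-pairs oracle shares
the same convention (see tests).

Bacterial density counts Eub local maxima inside a region mask, merges
maxima closer than one bacterium diameter, rejects objects larger than
the debris cutoff, and converts the count to a volumetric density via
the optical-section volume: volume_ml = area_um2 * section_um * 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import (
    EmptyCompartmentError,
    ParameterError,
    UndefinedStatisticError,
)
from .imagio import BinaryMask, MultichannelImage
from .masks import EdgeContour

ML_PER_UM3 = 1e-12


def mean_intensity(img: MultichannelImage, channel: str, mask: BinaryMask) -> float:
    """Arithmetic mean of one channel over the mask-true pixels."""
    values = img.channel(channel)
    if mask.shape != img.shape:
        raise UndefinedStatisticError(
            f"mask shape {mask.shape} does not match image shape {img.shape}"
        )
    if mask.is_empty():
        raise UndefinedStatisticError(
            f"mean intensity of {channel!r} over an empty {mask.label} mask is undefined"
        )
    return float(values[mask.grid].mean())


@dataclass
class ThicknessEstimate:
    """Minimal-distance estimate of the inner mucus layer."""

    per_point_distances_um: np.ndarray
    n_points: int
    mean_um: float
    median_um: float
    seed: int
    sampled_points: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), int)
    )


def inner_mucus_thickness(
    mucosal_edge: EdgeContour,
    luminal_edge: EdgeContour,
    n_points: int = 100,
    seed: int = 0,
) -> ThicknessEstimate:
    """Minimal distances from random luminal-edge points to the mucosal edge.

    Samples ``n_points`` luminal-edge pixels uniformly without
    replacement (all of them if the edge is shorter) and reports, per
    sampled point, the exact minimum Euclidean distance to any
    mucosal-edge pixel, in micrometres. Deterministic given ``seed``.
    """
    if n_points < 1:
        raise ParameterError("n_points must be >= 1")
    if len(mucosal_edge) == 0 or len(luminal_edge) == 0:
        raise EmptyCompartmentError("cannot measure thickness from an empty edge")
    if mucosal_edge.pixel_size_um != luminal_edge.pixel_size_um:
        raise ParameterError("edge contours carry different pixel sizes")

    rng = np.random.default_rng(seed)
    k = min(n_points, len(luminal_edge))
    idx = rng.choice(len(luminal_edge), size=k, replace=False)
    sampled = luminal_edge.points[np.sort(idx)]

    tree = cKDTree(mucosal_edge.points.astype(float))
    dist_px, _ = tree.query(sampled.astype(float))
    dist_um = np.asarray(dist_px, dtype=float) * luminal_edge.pixel_size_um
    return ThicknessEstimate(
        per_point_distances_um=dist_um,
        n_points=k,
        mean_um=float(dist_um.mean()),
        median_um=float(np.median(dist_um)),
        seed=seed,
        sampled_points=sampled,
    )


@dataclass
class DensityEstimate:
    """Bacterium count over a region, converted to a volumetric density."""

    bacterium_count: int
    area_um2: float
    volume_ml: float
    density_per_ml: float

    @classmethod
    def from_count(
        cls, count: int, area_um2: float, section_thickness_um: float
    ) -> "DensityEstimate":
        if area_um2 <= 0:
            raise ParameterError("area_um2 must be > 0")
        volume_ml = area_um2 * section_thickness_um * ML_PER_UM3
        return cls(
            bacterium_count=int(count),
            area_um2=float(area_um2),
            volume_ml=float(volume_ml),
            density_per_ml=float(count) / volume_ml,
        )


@dataclass
class SpotParams:
    """Local-maximum bacterium detection parameters."""

    bacterium_radius_um: float = 0.5
    threshold_abs: Optional[float] = None  # None -> Otsu over region pixels
    debris_diameter_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.bacterium_radius_um <= 0:
            raise ParameterError("bacterium_radius_um must be > 0")
        if self.debris_diameter_factor <= 0:
            raise ParameterError("debris_diameter_factor must be > 0")


def detect_bacteria(
    img: MultichannelImage, region: BinaryMask, params: SpotParams
) -> np.ndarray:
    """Bacterium centers (row, col) in the Eub channel within a region.

    Counts local maxima above threshold, merging maxima closer than one
    bacterium diameter, and drops maxima belonging to connected
    above-threshold objects whose equivalent diameter exceeds the
    debris cutoff (debris is larger than bacteria).
    """
    eub = img.channel("Eub")
    if region.is_empty():
        raise UndefinedStatisticError("bacterium detection over an empty region")
    px = img.pixel_size_um
    in_region = eub[region.grid]
    if params.threshold_abs is not None:
        thr = params.threshold_abs
    else:
        if np.ptp(in_region) == 0:
            return np.empty((0, 2), dtype=int)
        thr = threshold_otsu(in_region)
        # guard against a near-empty region, where Otsu merely splits the
        # read noise: require the foreground class to clear the background
        # by >6 robust sigmas
        bg = in_region[in_region <= thr]
        fg = in_region[in_region > thr]
        if bg.size == 0 or fg.size == 0:
            return np.empty((0, 2), dtype=int)
        bg_med = np.median(bg)
        bg_sigma = 1.4826 * np.median(np.abs(bg - bg_med))
        if fg.mean() - bg.mean() < 6.0 * max(bg_sigma, 1e-12):
            return np.empty((0, 2), dtype=int)

    min_dist_px = max(1, int(round(2 * params.bacterium_radius_um / px)))
    peaks = peak_local_max(
        eub,
        min_distance=min_dist_px,
        threshold_abs=thr,
        labels=region.grid.astype(int),
        exclude_border=False,
    )
    if peaks.size == 0:
        return np.empty((0, 2), dtype=int)

    # debris filter on connected above-threshold objects
    objects = sk_label((eub > thr) & region.grid, connectivity=2)
    cutoff_um = params.debris_diameter_factor * 2 * params.bacterium_radius_um
    bad_labels = {
        p.label
        for p in regionprops(objects)
        if p.equivalent_diameter_area * px > cutoff_um
    }
    if bad_labels:
        keep = np.array(
            [objects[r, c] not in bad_labels for r, c in peaks], dtype=bool
        )
        peaks = peaks[keep]
    return peaks.astype(int)


def bacterial_density(
    img: MultichannelImage, region: BinaryMask, params: SpotParams | None = None
) -> DensityEstimate:
    """Volumetric bacterial density over a region of the Eub channel."""
    params = params or SpotParams()
    centers = detect_bacteria(img, region, params)
    area_um2 = region.area_px() * img.pixel_size_um**2
    return DensityEstimate.from_count(
        len(centers), area_um2, img.section_thickness_um
    )


def detection_region(
    mucosal_mask: BinaryMask, contact_band_um: float, pixel_size_um: float
) -> BinaryMask:
    """Everything outside the mucosa, eroding the mucosal mask first.

    Segmentation jitter can put the computed mucosal boundary a pixel or
    two above the true epithelial surface; eroding by the contact band
    plus a 1 um margin keeps epithelium-hugging bacteria detectable.
    """
    depth_px = max(1, int(round((contact_band_um + 1.0) / pixel_size_um)))
    eroded = ndi.binary_erosion(mucosal_mask.grid, iterations=depth_px)
    return BinaryMask(~eroded, label="other")


def epithelial_band(
    mucosal_edge: EdgeContour,
    band_width_um: float = 1.0,
    *,
    image_shape: tuple[int, int],
    mucosal_mask: BinaryMask | None = None,
) -> BinaryMask:
    """Non-mucosal pixels within ``band_width_um`` of the mucosal edge."""
    if band_width_um <= 0:
        raise ParameterError("band_width_um must be > 0")
    if len(mucosal_edge) == 0:
        raise EmptyCompartmentError("mucosal edge is empty")
    edge_img = np.zeros(image_shape, dtype=bool)
    pts = mucosal_edge.points
    edge_img[pts[:, 0], pts[:, 1]] = True
    dist_um = ndi.distance_transform_edt(~edge_img) * mucosal_edge.pixel_size_um
    band = dist_um <= band_width_um
    if mucosal_mask is not None:
        band &= ~mucosal_mask.grid
    else:
        band &= ~edge_img
    return BinaryMask(grid=band, label="other")
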