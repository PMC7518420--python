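"""Synthetic multichannel colonic cross-section phantoms with ground truth.

The phantom emulates the geometry the downstream analysis assumes: an
epithelial band of nucleated cells along the bottom of the frame, a
bacteria-free inner mucus layer of controllable thickness above it, a
bacteria-laden lumen of controllable volumetric density, an optional
dense bacterial band in direct epithelial contact, and luminal
autofluorescent debris larger than any bacterium. Channels are rendered
with a Poisson shot-noise + Gaussian read-noise + constant background
model. Identical spec + seed reproduces the output bit for bit.

Bacterial placement converts the volumetric density (per ml) into an
expected 2D count through the optical-section volume:

    expected count = density_per_ml * area_um2 * section_thickness_um * 1e-12

Luminal counts are Poisson draws around that expectation; the contact
band, when requested, is populated deterministically (rounded expected
count, evenly spaced across the span) so the truth density is exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError
from .imagio import (
    BinaryMask,
    MultichannelImage,
    mask_to_rle,
    rle_to_mask,
    write_image,
)

ML_PER_UM3 = 1e-12

# Rendering intensities (arbitrary fluorescence units).
_DAPI_TISSUE = 60.0
_DAPI_NUCLEUS = 60.0
_EUB_BACTERIUM = 150.0
_EUB_DEBRIS = 120.0
_WGA_MUCUS = 80.0
_NUCLEUS_SIGMA_UM = 1.5
_NUCLEUS_PER_UM2 = 1.0 / 25.0  # one nucleus per 25 um^2 of mucosa
_DEBRIS_RADIUS_FACTOR = 4.0  # debris radius in bacterium radii (diameter 4x)


@dataclass
class NoiseParams:
    poisson_scale: float = 1.0
    gaussian_sd: float = 2.0
    background: float = 10.0


@dataclass
class BiofilmPatch:
    """A contiguous span of epithelium-contacting bacteria."""

    span_um: float
    band_density_per_ml: float


@dataclass
class PhantomSpec:
    """Parameters of one synthetic cross-section.

    All physical lengths are strictly positive except
    ``inner_mucus_thickness_um``, which may be zero (no inner layer).
    """

    image_height_px: int = 256
    image_width_px: int = 256
    pixel_size_um: float = 0.5
    section_thickness_um: float = 5.0
    epithelium_profile: str = "flat"
    amplitude_um: float = 0.0
    period_um: float = 100.0
    epithelium_height_um: float = 40.0
    inner_mucus_thickness_um: float = 30.0
    bacterial_density_per_ml: float = 0.0
    bacterium_radius_um: float = 0.5
    biofilm: Optional[BiofilmPatch] = None
    n_debris: int = 0
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.noise, dict):
            self.noise = NoiseParams(**self.noise)
        if isinstance(self.biofilm, dict):
            self.biofilm = BiofilmPatch(**self.biofilm)
        self.validate()

    def validate(self) -> None:
        for name in ("image_height_px", "image_width_px"):
            if int(getattr(self, name)) <= 0:
                raise ParameterError(f"{name} must be a positive integer")
        for name in (
            "pixel_size_um",
            "section_thickness_um",
            "epithelium_height_um",
            "bacterium_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.inner_mucus_thickness_um < 0:
            raise ParameterError("inner_mucus_thickness_um must be >= 0")
        if self.bacterial_density_per_ml < 0:
            raise ParameterError("bacterial_density_per_ml must be >= 0")
        if self.n_debris < 0:
            raise ParameterError("n_debris must be >= 0")
        if self.epithelium_profile not in ("flat", "sinusoidal"):
            raise ParameterError(
                "epithelium_profile must be 'flat' or 'sinusoidal'"
            )
        if self.epithelium_profile == "sinusoidal":
            if self.amplitude_um < 0:
                raise ParameterError("amplitude_um must be >= 0")
            if self.period_um <= 0:
                raise ParameterError("period_um must be > 0")
        if self.biofilm is not None:
            if self.biofilm.span_um <= 0:
                raise ParameterError("biofilm.span_um must be > 0")
            if self.biofilm.band_density_per_ml <= 0:
                raise ParameterError("biofilm.band_density_per_ml must be > 0")
            if self.biofilm.span_um > self.image_width_px * self.pixel_size_um:
                raise ParameterError(
                    "biofilm.span_um exceeds the image width "
                    f"({self.image_width_px * self.pixel_size_um:g} um)"
                )
        if self.noise.poisson_scale <= 0:
            raise ParameterError("noise.poisson_scale must be > 0")
        if self.noise.gaussian_sd < 0:
            raise ParameterError("noise.gaussian_sd must be >= 0")
        if self.noise.background < 0:
            raise ParameterError("noise.background must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside every phantom."""

    mucosal_mask_true: np.ndarray
    luminal_mask_true: np.ndarray
    inner_mucus_thickness_um_true: float
    bacteria_centers: np.ndarray  # (n, 2) int, (row, col)
    band_density_per_ml_true: float
    biofilm_true: bool
    biofilm_span_um_true: float = 0.0
    band_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    epithelial_top_row: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def to_dict(self) -> dict:
        return {
            "mucosal_mask_true": mask_to_rle(self.mucosal_mask_true),
            "luminal_mask_true": mask_to_rle(self.luminal_mask_true),
            "inner_mucus_thickness_um_true": self.inner_mucus_thickness_um_true,
            "bacteria_centers": np.asarray(self.bacteria_centers).tolist(),
            "band_density_per_ml_true": self.band_density_per_ml_true,
            "biofilm_true": self.biofilm_true,
            "biofilm_span_um_true": self.biofilm_span_um_true,
            "band_centers": np.asarray(self.band_centers).tolist(),
            "epithelial_top_row": np.asarray(self.epithelial_top_row).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        return cls(
            mucosal_mask_true=rle_to_mask(d["mucosal_mask_true"]),
            luminal_mask_true=rle_to_mask(d["luminal_mask_true"]),
            inner_mucus_thickness_um_true=d["inner_mucus_thickness_um_true"],
            bacteria_centers=np.asarray(d["bacteria_centers"], int).reshape(-1, 2),
            band_density_per_ml_true=d["band_density_per_ml_true"],
            biofilm_true=d["biofilm_true"],
            biofilm_span_um_true=d.get("biofilm_span_um_true", 0.0),
            band_centers=np.asarray(d.get("band_centers", []), int).reshape(-1, 2),
            epithelial_top_row=np.asarray(d.get("epithelial_top_row", []), int),
        )


def expected_count(density_per_ml: float, area_um2: float, section_um: float) -> float:
    """Closed-form expected bacterium count in a sectioned region."""
    return density_per_ml * area_um2 * section_um * ML_PER_UM3


def _epithelial_top(spec: PhantomSpec) -> np.ndarray:
    """Topmost mucosal row index per column (epithelial surface)."""
    h, w, px = spec.image_height_px, spec.image_width_px, spec.pixel_size_um
    base = h - int(round(spec.epithelium_height_um / px))
    if spec.epithelium_profile == "flat":
        top = np.full(w, base, dtype=int)
    else:
        cols_um = np.arange(w) * px
        wave = spec.amplitude_um / px * np.sin(2 * np.pi * cols_um / spec.period_um)
        top = np.round(base - wave).astype(int)
    return np.clip(top, 1, h - 1)


def _render_spots(shape, centers, amplitude, sigma_px, rng=None) -> np.ndarray:
    """Sum of Gaussian spots with the given peak amplitude."""
    img = np.zeros(shape, dtype=float)
    if len(centers) == 0:
        return img
    centers = np.asarray(centers, dtype=int)
    np.add.at(img, (centers[:, 0], centers[:, 1]), 1.0)
    img = ndi.gaussian_filter(img, sigma=sigma_px, truncate=4.0)
    # restore peak height of an isolated spot to `amplitude`
    img *= amplitude * (2 * np.pi * sigma_px**2)
    return img


def _apply_noise(signal: np.ndarray, noise: NoiseParams, rng: np.random.Generator):
    out = rng.poisson(np.clip(signal, 0, None) * noise.poisson_scale).astype(float)
    out /= noise.poisson_scale
    if noise.gaussian_sd > 0:
        out += rng.normal(0.0, noise.gaussian_sd, size=signal.shape)
    out += noise.background
    return np.clip(out, 0.0, None)


def generate_phantom(spec: PhantomSpec) -> tuple[MultichannelImage, PhantomTruth]:
    """Generate one phantom image and its ground truth.

    Returns channels ``DAPI`` (nuclei + tissue), ``Eub`` (bacteria +
    debris) and ``WGA`` (inner mucus layer). Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w, px = spec.image_height_px, spec.image_width_px, spec.pixel_size_um
    rows = np.arange(h)[:, None]

    top = _epithelial_top(spec)
    mucosal = rows >= top[None, :]

    # distance (um) of every non-mucosal pixel to the mucosal set
    dist_um = ndi.distance_transform_edt(~mucosal) * px
    luminal = (~mucosal) & (dist_um >= spec.inner_mucus_thickness_um)
    mucus = (~mucosal) & ~luminal

    # --- luminal bacteria: Poisson count at the requested volumetric density
    lum_idx = np.flatnonzero(luminal.ravel())
    area_um2 = lum_idx.size * px * px
    lam = expected_count(spec.bacterial_density_per_ml, area_um2, spec.section_thickness_um)
    n_bact = int(rng.poisson(lam)) if lam > 0 else 0
    n_bact = min(n_bact, lum_idx.size)
    if n_bact > 0:
        chosen = rng.choice(lum_idx, size=n_bact, replace=False)
        centers = np.column_stack(np.unravel_index(chosen, (h, w)))
    else:
        centers = np.empty((0, 2), dtype=int)

    # --- contact-band bacteria (deterministic count, even spacing)
    band_centers = np.empty((0, 2), dtype=int)
    band_density_true = 0.0
    span_true = 0.0
    if spec.biofilm is not None:
        span_px = int(round(spec.biofilm.span_um / px))
        span_px = min(span_px, w)
        col0 = (w - span_px) // 2
        band_width_um = 1.0  # contact criterion band
        band_area_um2 = spec.biofilm.span_um * band_width_um
        # round half up so the truth density is never biased low
        n_band = int(
            np.floor(
                expected_count(
                    spec.biofilm.band_density_per_ml,
                    band_area_um2,
                    spec.section_thickness_um,
                )
                + 0.5
            )
        )
        if n_band > 0:
            if n_band == 1:
                cols = np.array([col0 + span_px // 2])
            else:
                cols = np.round(np.linspace(col0, col0 + span_px - 1, n_band)).astype(int)
            brows = top[cols] - 1  # one pixel above the surface: within 1 um
            band_centers = np.column_stack([brows, cols])
            vol_ml = band_area_um2 * spec.section_thickness_um * ML_PER_UM3
            band_density_true = n_band / vol_ml
            span_true = spec.biofilm.span_um

    all_centers = (
        np.vstack([centers, band_centers]) if band_centers.size else centers
    )

    # --- debris: bright discs in the lumen, larger than any bacterium
    debris_signal = np.zeros((h, w), dtype=float)
    if spec.n_debris > 0 and lum_idx.size > 0:
        debris_r_px = max(2, int(round(_DEBRIS_RADIUS_FACTOR * spec.bacterium_radius_um / px)))
        picks = rng.choice(lum_idx, size=min(spec.n_debris, lum_idx.size), replace=False)
        dr, dc = np.unravel_index(picks, (h, w))
        yy, xx = np.ogrid[:h, :w]
        for r, c in zip(dr, dc):
            disc = (yy - r) ** 2 + (xx - c) ** 2 <= debris_r_px**2
            debris_signal[disc] = _EUB_DEBRIS

    # --- DAPI: dim tissue body plus bright nuclei inside the mucosa
    dapi_signal = np.where(mucosal, _DAPI_TISSUE, 0.0)
    muc_idx = np.flatnonzero(mucosal.ravel())
    n_nuclei = int(round(muc_idx.size * px * px * _NUCLEUS_PER_UM2))
    if n_nuclei > 0:
        picks = rng.choice(muc_idx, size=min(n_nuclei, muc_idx.size), replace=False)
        nuc = np.column_stack(np.unravel_index(picks, (h, w)))
        dapi_signal += _render_spots((h, w), nuc, _DAPI_NUCLEUS, _NUCLEUS_SIGMA_UM / px)

    # --- Eub: diffraction-limited bacterial spots plus debris
    spot_sigma_px = (spec.bacterium_radius_um / 2.0) / px
    eub_signal = _render_spots((h, w), all_centers, _EUB_BACTERIUM, spot_sigma_px)
    eub_signal += debris_signal

    # --- WGA: the inner mucus layer
    wga_signal = np.where(mucus, _WGA_MUCUS, 0.0)

    channels = {}
    for name, signal in (("DAPI", dapi_signal), ("Eub", eub_signal), ("WGA", wga_signal)):
        channels[name] = _apply_noise(signal, spec.noise, rng)

    img = MultichannelImage(
        channels=channels,
        pixel_size_um=px,
        section_thickness_um=spec.section_thickness_um,
    )
    truth = PhantomTruth(
        mucosal_mask_true=mucosal,
        luminal_mask_true=luminal,
        inner_mucus_thickness_um_true=float(spec.inner_mucus_thickness_um),
        bacteria_centers=all_centers,
        band_density_per_ml_true=band_density_true,
        biofilm_true=spec.biofilm is not None and band_centers.size > 0,
        biofilm_span_um_true=span_true,
        band_centers=band_centers,
        epithelial_top_row=top,
    )
    return img, truth


def save_phantom(
    img: MultichannelImage, truth: PhantomTruth, spec: PhantomSpec, outdir: str | Path
) -> dict[str, Path]:
    """Write the phantom TIFF plus a JSON sidecar of spec and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image_path = write_image(img, outdir / "phantom.tif")
    sidecar = {
        "spec": spec.to_dict(),
        "truth": truth.to_dict(),
    }
    truth_path = outdir / "phantom_truth.json"
    truth_path.write_text(json.dumps(sidecar, sort_keys=True))
    return {"image": image_path, "truth": truth_path}


def load_truth(path: str | Path) -> tuple[PhantomSpec, PhantomTruth]:
    payload = json.loads(Path(path).read_text())
    return (
        PhantomSpec.from_dict(payload["spec"]),
        PhantomTruth.from_dict(payload["truth"]),
    )


def truth_masks(truth: PhantomTruth) -> tuple[BinaryMask, BinaryMask]:
    """Ground-truth masks wrapped as :class:`BinaryMask` objects."""
    return (
        BinaryMask(truth.mucosal_mask_true, label="mucosal"),
        BinaryMask(truth.luminal_mask_true, label="luminal"),
    )
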