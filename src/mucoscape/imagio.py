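"""Calibrated multichannel image I/O, binary masks, score sheets, provenance.

Images are plain multi-page TIFFs, one page per channel, with the channel
name stored in each page description. Masks are 8-bit TIFFs (0/255).
Score sheets are CSVs whose column layout mirrors a clinical biofilm
screening sheet. Every pipeline run writes a JSON provenance sidecar
carrying the config hash and the seed.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Default physical section thickness in micrometres.
DEFAULT_SECTION_THICKNESS_UM = 5.0

#: Score-sheet column layout (one row per sample).
REPORT_COLUMNS = (
    "Sample ID",
    "Mucus present",
    "Bacteria abundance per 200 μm CEC",
    "Percentage of biofilm coverage",
    "DAPI without Cy3",
    "Notes",
)

_REPORT_FIELDS = (
    "sample_id",
    "mucus_grade",
    "abundance_grade",
    "coverage_pct",
    "dapi_without_cy3",
    "notes",
)


@dataclass
class MultichannelImage:
    """Named 2D intensity channels sharing one physical calibration.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"DAPI"``, ``"Eub"``, ``"WGA"``)
        to a 2D array of non-negative finite intensities. All channels
        must share the same shape.
    pixel_size_um
        Physical size of one pixel in micrometres (isotropic).
    section_thickness_um
        Physical thickness of the tissue section in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    section_thickness_um: float = DEFAULT_SECTION_THICKNESS_UM

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("MultichannelImage requires at least one channel")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.section_thickness_um <= 0:
            raise ValidationError("section_thickness_um must be > 0")
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValidationError(f"channel {name!r} is not 2D")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValidationError(f"channel {name!r} contains negative values")
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValidationError(f"channels differ in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ConfigurationError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None


MASK_LABELS = ("mucosal", "luminal", "other")


@dataclass
class BinaryMask:
    """A boolean compartment mask tied to a source-image shape."""

    grid: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValidationError("mask grid must be 2D")
        if self.label not in MASK_LABELS:
            raise ValidationError(f"mask label must be one of {MASK_LABELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def area_px(self) -> int:
        return int(self.grid.sum())

    def is_empty(self) -> bool:
        return not self.grid.any()


# ---------------------------------------------------------------------------
# Image I/O


def write_image(img: MultichannelImage, path: str | Path) -> Path:
    """Write a multichannel image as a multi-page TIFF, one page per channel.

    The channel name is stored in each page description so the file
    round-trips without an external channel map.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tif:
        for name, arr in img.channels.items():
            tif.write(arr.astype(np.float32), description=name, contiguous=False)
    return path


def read_image(
    path: str | Path,
    channel_map: Mapping[int, str] | None = None,
    pixel_size_um: float | None = None,
    section_thickness_um: float | None = None,
    required_channels: Sequence[str] = (),
) -> MultichannelImage:
    """Read a multi-page TIFF into a :class:`MultichannelImage`.

    ``channel_map`` maps page index to channel name and overrides any names
    stored in the page descriptions. Missing calibration falls back to the
    package defaults with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            pages = list(tif.pages)
            arrays = [p.asarray() for p in pages]
            descriptions = [p.description or "" for p in pages]
    except Exception as exc:  # unreadable / not a TIFF
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc

    channels: dict[str, np.ndarray] = {}
    for i, arr in enumerate(arrays):
        if channel_map is not None and i in channel_map:
            name = channel_map[i]
        elif channel_map is None and descriptions[i]:
            name = descriptions[i]
        elif channel_map is None:
            name = f"ch{i}"
        else:
            continue  # explicit map given; unmapped pages are dropped
        channels[name] = np.asarray(arr, dtype=float)

    for name in required_channels:
        if name not in channels:
            raise ConfigurationError(
                f"required channel {name!r} not mapped for {path}; "
                f"got {sorted(channels)}"
            )

    if pixel_size_um is None:
        logger.warning("no pixel size for %s; defaulting to 0.5 um/px", path)
        pixel_size_um = 0.5
    if section_thickness_um is None:
        logger.warning(
            "no section thickness for %s; defaulting to %.1f um",
            path,
            DEFAULT_SECTION_THICKNESS_UM,
        )
        section_thickness_um = DEFAULT_SECTION_THICKNESS_UM

    return MultichannelImage(
        channels=channels,
        pixel_size_um=float(pixel_size_um),
        section_thickness_um=float(section_thickness_um),
    )


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit TIFF with values {0, 255}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (mask.grid.astype(np.uint8) * 255), description=mask.label)
    return path


def read_mask(path: str | Path, label: str | None = None) -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.pages[0].asarray()
        desc = tif.pages[0].description or ""
    if label is None:
        label = desc if desc in MASK_LABELS else "other"
    return BinaryMask(grid=arr > 0, label=label)


# ---------------------------------------------------------------------------
# Score sheet


def _format_percent(value: float) -> str:
    v = float(value)
    return f"{v:g}%"


def write_report(rows: Sequence[Mapping], path: str | Path) -> Path:
    """Write a per-sample score sheet CSV, one row per sample.

    Each record must carry ``sample_id``, ``mucus_grade``,
    ``abundance_grade``, ``coverage_pct`` (number in [0, 100], rendered
    with a trailing ``%``), ``dapi_without_cy3`` (bool or yes/no string)
    and ``notes``. Rows are written sorted by sample id.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validated = []
    for i, rec in enumerate(rows):
        for field_name in _REPORT_FIELDS:
            if field_name not in rec:
                raise ValidationError(
                    f"record {rec.get('sample_id', i)!r} is missing field {field_name!r}"
                )
        validated.append(rec)
    validated.sort(key=lambda r: str(r["sample_id"]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for rec in validated:
            flag = rec["dapi_without_cy3"]
            if isinstance(flag, str):
                flag_str = flag
            else:
                flag_str = "Yes" if flag else "No"
            writer.writerow(
                [
                    rec["sample_id"],
                    f"{float(rec['mucus_grade']):g}",
                    f"{float(rec['abundance_grade']):g}",
                    _format_percent(rec["coverage_pct"]),
                    flag_str,
                    rec["notes"],
                ]
            )
    return path


# ---------------------------------------------------------------------------
# Provenance and mask serialization helpers


def config_hash(config: Mapping) -> str:
    """Stable SHA-256 hash of a JSON-serializable config mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_provenance(
    path: str | Path, config: Mapping, seed: int, extra: Mapping | None = None
) -> Path:
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "config_hash": config_hash(config),
        "seed": int(seed),
        "package_version": __version__,
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    return path


def mask_to_rle(grid: np.ndarray) -> dict:
    """Run-length encode a boolean image (row-major, starting with zeros)."""
    flat = np.asarray(grid, dtype=bool).ravel()
    if flat.size == 0:
        return {"shape": list(grid.shape), "runs": []}
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:  # runs must start with a zero-run
        runs = [0] + runs
    return {"shape": list(np.asarray(grid).shape), "runs": runs}


def rle_to_mask(encoded: Mapping) -> np.ndarray:
    shape = tuple(encoded["shape"])
    runs = encoded["runs"]
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    value = False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return flat.reshape(shape)
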