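"""Shared data model and file I/O.

Images are collections of perfectly aligned grayscale planes keyed by
channel *role* (``nuclei``, ``brightfield``, ``k10``, ``k14``, ``gh2ax``,
``tracker`` or ``other:<name>``).  All physical parameters are expressed
in micrometres and converted to pixels internally; intensities are kept
in the arbitrary units of the camera and are never rescaled on load.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("epicyto")

#: Channel roles with a fixed meaning in the pipeline.  Arbitrary extra
#: channels are allowed under the role ``other:<name>``.
KNOWN_ROLES = ("nuclei", "brightfield", "k10", "k14", "gh2ax", "tracker")


def _check_role(role: str) -> None:
    if role in KNOWN_ROLES or role.startswith("other:"):
        return
    raise ValueError(
        f"unknown channel role {role!r}; expected one of {KNOWN_ROLES} or 'other:<name>'"
    )


@dataclass
class MultiChannelImage:
    """Registered grayscale planes plus the physical pixel size.

    Alignment of the planes is an input contract (all channels are
    assumed to come from the same camera over the same stage position),
    not something the pipeline corrects for.
    """

    planes: Dict[str, np.ndarray]
    pixel_size_um: float
    bit_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("MultiChannelImage requires at least one plane")
        shapes = set()
        for role, plane in self.planes.items():
            _check_role(role)
            plane = np.asarray(plane)
            if plane.ndim != 2:
                raise ValueError(f"plane {role!r} is not 2-D (shape {plane.shape})")
            if not np.all(np.isfinite(plane)):
                raise ValueError(f"plane {role!r} contains non-finite values")
            if plane.min() < 0:
                raise ValueError(f"plane {role!r} contains negative intensities")
            self.planes[role] = plane
            shapes.add(plane.shape)
        if len(shapes) != 1:
            raise ValueError(f"planes have mismatched shapes: {sorted(shapes)}")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be a positive finite scalar")
        if self.bit_depth is None:
            dt = next(iter(self.planes.values())).dtype
            self.bit_depth = dt.itemsize * 8 if dt.kind in "ui" else None

    @property
    def shape(self) -> tuple:
        return next(iter(self.planes.values())).shape

    def __contains__(self, role: str) -> bool:
        return role in self.planes

    def channel(self, role: str) -> np.ndarray:
        if role not in self.planes:
            raise KeyError(f"channel role {role!r} not present; have {sorted(self.planes)}")
        return self.planes[role]


@dataclass
class LabelMask:
    """Integer label raster: 0 = background, k > 0 = object k."""

    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if arr.dtype.kind not in "ui":
            if not np.array_equal(arr, arr.astype(np.int64)):
                raise ValueError("label mask must contain integers")
            arr = arr.astype(np.int64)
        if arr.min() < 0:
            raise ValueError("label mask must be non-negative")
        self.labels = arr

    @property
    def max_label(self) -> int:
        return int(self.labels.max(initial=0))


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    All lengths are micrometres; conversions to pixels happen in each
    stage via :meth:`px`.  Thresholding rules are either ``"otsu"``, an
    absolute number, or ``"bg+k*sd"`` (background mean plus ``k``
    standard deviations of a stated control population).
    """

    pixel_size_um: float = 1.0

    # nuclei detection
    nuclei_smooth_sigma_um: float = 1.0
    nuclei_min_area_um2: float = 10.0
    nuclei_threshold: str | float = "otsu"
    nuclei_peak_min_distance_um: float = 3.0

    # nuclei map
    connect_radius_um: Optional[float] = None  # None -> 1.5 x median NN spacing
    map_min_area_um2: float = 100.0

    # brightfield area
    bf_smooth_sigma_um: float = 2.0
    bf_threshold: str | float = "otsu"
    bf_min_area_um2: float = 200.0

    # strata partition
    side_margin_factor: float = 2.0          # x median nucleus diameter
    density_bandwidth_um: float = 3.0
    density_support_fraction: float = 0.05   # fraction of density max

    # cell masks
    cell_max_radius_um: float = 10.0

    # gating: role -> rule ("otsu", number, or "bg+k*sd")
    gates: Dict[str, object] = field(default_factory=dict)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "nuclei_smooth_sigma_um",
            "nuclei_min_area_um2",
            "nuclei_peak_min_distance_um",
            "map_min_area_um2",
            "bf_smooth_sigma_um",
            "bf_min_area_um2",
            "side_margin_factor",
            "density_bandwidth_um",
            "density_support_fraction",
            "cell_max_radius_um",
        ):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive, got {value!r}")
        if self.connect_radius_um is not None and self.connect_radius_um <= 0:
            raise ValueError("connect_radius_um must be positive or None")

    def px(self, um: float) -> float:
        """Convert a length in micrometres to (fractional) pixels."""
        return um / self.pixel_size_um

    def px_area(self, um2: float) -> float:
        return um2 / self.pixel_size_um**2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(data)
        logger.info("loaded config from %s: %s", path, cfg.to_dict())
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# image / mask / table I/O
# ---------------------------------------------------------------------------

def load_section(
    path: str | Path,
    channel_map: Mapping[str, int],
    pixel_size_um: float,
) -> MultiChannelImage:
    """Load a single- or multi-plane TIFF/OME-TIFF as a MultiChannelImage.

    ``channel_map`` maps channel roles to zero-based plane indices in the
    file.  Intensities are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        n = len(pages)
        planes = {}
        for role, idx in channel_map.items():
            _check_role(role)
            if not (0 <= int(idx) < n):
                raise IndexError(
                    f"plane index out of range: channel {role!r} requests plane "
                    f"{idx} of a {n}-plane file"
                )
            planes[role] = pages[int(idx)].asarray()
    return MultiChannelImage(planes=planes, pixel_size_um=float(pixel_size_um))


def save_section(image: MultiChannelImage, path: str | Path, order=None) -> list:
    """Write planes as a multi-page TIFF; returns the plane order used."""
    order = list(order) if order is not None else sorted(image.planes)
    stack = np.stack([image.planes[r] for r in order])
    tifffile.imwrite(path, stack, photometric="minisblack")
    return order


def save_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as a 16- or 32-bit single-plane TIFF."""
    mx = mask.max_label
    if mx <= np.iinfo(np.uint16).max:
        arr = mask.labels.astype(np.uint16)
    elif mx <= np.iinfo(np.uint32).max:
        arr = mask.labels.astype(np.uint32)
    else:
        raise ValueError(f"label count {mx} exceeds 32-bit TIFF range")
    tifffile.imwrite(path, arr)


def load_label_mask(path: str | Path, provenance: str = "") -> LabelMask:
    return LabelMask(labels=tifffile.imread(path), provenance=provenance)


def save_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell table as CSV (one header row, stable column order)."""
    table.to_csv(path, index=False)


def load_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
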