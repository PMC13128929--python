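"""Core domain types for flatmount image quantification.

All rasters use (row, col) indexing, 0-based, with coordinates referring to
pixel centers.  Physical quantities are expressed in micrometres (lengths)
and µm² (areas) via the isotropic ``pixel_size`` of the parent image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "FlatmountImage",
    "VesselMask",
    "NucleusRecord",
    "PunctumRecord",
    "AreaReport",
    "QuantParams",
    "ENDOTHELIAL",
    "PERICYTE",
    "OTHER_NON_ENDOTHELIAL",
    "EXTRAVASCULAR",
    "INTACT_SEGMENT",
    "REGRESSING_SEGMENT",
]

ENDOTHELIAL = "endothelial"
PERICYTE = "pericyte"
OTHER_NON_ENDOTHELIAL = "other_non_endothelial"

EXTRAVASCULAR = "extravascular"
INTACT_SEGMENT = "intact_segment"
REGRESSING_SEGMENT = "regressing_segment"


@dataclass
class FlatmountImage:
    """A named multi-channel fluorescence raster with a physical pixel size.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"DAPI"``, ``"CD31"``, ``"TUNEL"``)
        to a 2-D non-negative intensity array.  All channels must share the
        same shape.
    pixel_size
        Isotropic pixel size in micrometres per pixel; must be positive.
    metadata
        Free-form acquisition descriptors.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.channels:
            raise ValueError("at least one channel is required")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError("channel rasters must be 2-D")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            )
        return self.channels[name]


@dataclass
class VesselMask:
    """Binary vessel footprint derived from an endothelial membrane channel.

    ``fill_state`` records that morphological closing and hole filling have
    been applied ("solid" mask); classification steps require it.
    """

    mask: np.ndarray
    source_channel: str
    pixel_size: float
    fill_state: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2


@dataclass
class NucleusRecord:
    """A segmented nucleus with morphology, class and marker intensities.

    ``circularity`` is the shape index 4πA/P² (1 for a circle, low for
    elongated nuclei), clipped to 1.0 against digitization overshoot.
    ``marker_intensities`` holds background-corrected integrated intensities
    (arbitrary units); negative values after correction are retained.
    """

    nucleus_id: int
    coords: np.ndarray  # (n_pixels, 2) array of (row, col)
    centroid: tuple[float, float]
    area_um2: float
    perimeter_um: float
    circularity: float
    cell_class: str | None = None
    marker_intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("nucleus area must be positive")
        if not 0.0 <= self.circularity <= 1.0:
            raise ValueError("circularity must lie in [0, 1]")


@dataclass
class PunctumRecord:
    """A segmented TUNEL punctum (apoptotic nucleus fragment)."""

    punctum_id: int
    coords: np.ndarray
    centroid: tuple[float, float]
    area_um2: float
    location_class: str = EXTRAVASCULAR
    segment_id: int | None = None


@dataclass
class AreaReport:
    """Per-channel positive areas with optional ratios and percent-of-control.

    Ratios (e.g. GPR124-positive area / CD31-positive area) are defined only
    for a strictly positive denominator.
    """

    areas_um2: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)
    percent_of_control: dict[str, float] = field(default_factory=dict)

    def add_ratio(self, name: str, numerator: str, denominator: str) -> float:
        num = self.areas_um2[numerator]
        den = self.areas_um2[denominator]
        if den <= 0:
            raise ValueError(
                f"ratio {name!r}: denominator channel {denominator!r} has zero positive area"
            )
        self.ratios[name] = num / den
        return self.ratios[name]

    def add_percent_of_control(self, name: str, control_mean: float) -> float:
        """Express a stored ratio as a percentage of a control-group mean ratio."""
        if control_mean == 0:
            raise ValueError("control-group mean must be non-zero")
        self.percent_of_control[name] = 100.0 * self.ratios[name] / control_mean
        return self.percent_of_control[name]


@dataclass
class QuantParams:
    """Tunable parameters of the flatmount quantification stage.

    Defaults mirror the published analysis where a value was stated
    (IsoData nuclear threshold, Yen puncta threshold, pericyte circularity
    cutoff 0.6); size filters replace the manual exclusion of staining
    artifacts and are configurable.
    """

    circularity_cutoff: float = 0.6
    nuclear_threshold_method: str = "isodata"
    puncta_threshold_method: str = "yen"
    mask_threshold_method: str = "otsu"
    mask_closing_radius_px: int = 3
    min_nucleus_area_um2: float = 10.0
    min_punctum_area_um2: float = 2.0
    min_mask_object_area_um2: float = 50.0
    watershed_min_separation_um: float = 7.0
    smoothing_sigma_px: float = 1.0  # pre-threshold denoising; 0 disables

    def __post_init__(self) -> None:
        if not 0.0 < self.circularity_cutoff <= 1.0:
            raise ValueError("circularity_cutoff must lie in (0, 1]")
        for name in ("min_nucleus_area_um2", "min_punctum_area_um2", "min_mask_object_area_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
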