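"""Shared domain types and errors.

All raster channels are 2-D float arrays with intensities in arbitrary
units on [0, 1] (0 = lowest, 1 = highest), as microscopy exports are
rescaled on ingest.  Physical scale is carried explicitly as micrometers
per pixel; nothing downstream ever reasons in raw pixels alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

SITES = ("inner", "outer")

#: Canonical channel names, in on-disk order.
CHANNELS = ("nuclear", "red", "far_red", "blue", "isotype")

#: Cellular strata from basal to outermost, then the cornified layer.
STRATA = ("SB", "SS", "SG", "SC")

REGION_ROLES = ("epidermis", "stratum_corneum", "dermis", "whole_tissue")


class EpiquantError(Exception):
    """Base class for package errors."""


class ValidationError(EpiquantError, ValueError):
    """A spec/config/input object failed validation; message names the field."""


class InputError(EpiquantError, ValueError):
    """A file or raster input is malformed or inconsistent."""


class SegmentationError(EpiquantError, RuntimeError):
    """Segmentation produced no usable region."""


@dataclass(frozen=True)
class ImageSection:
    """A multi-channel section image plus physical scale and provenance.

    Parameters
    ----------
    channels:
        Mapping of channel name to 2-D float array in [0, 1].  All
        channels must share one shape.
    pixel_size_um:
        Side length of one pixel in micrometers (> 0).
    subject_id, site, section_index:
        Study provenance.  ``site`` is ``"inner"`` or ``"outer"``.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float
    subject_id: str = ""
    site: str = "inner"
    section_index: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.site not in SITES:
            raise ValidationError(f"site must be one of {SITES}, got {self.site!r}")
        if not self.channels:
            raise ValidationError("channels: at least one channel required")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError(f"channels: rasters disagree on shape: {shapes}")
        for name, arr in self.channels.items():
            a = np.asarray(arr)
            if a.ndim != 2:
                raise ValidationError(f"channels[{name!r}]: expected 2-D raster")
            if a.size and (a.min() < 0 or a.max() > 1):
                raise ValidationError(f"channels[{name!r}]: intensities outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.channels[name])
        except KeyError:
            raise InputError(
                f"channel {name!r} missing; available: {sorted(self.channels)}"
            ) from None


@dataclass(frozen=True)
class RegionMask:
    """A binary region of a section (epidermis, SC, dermis or whole tissue)."""

    mask: np.ndarray
    region_role: str
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.region_role not in REGION_ROLES:
            raise ValidationError(
                f"region_role must be one of {REGION_ROLES}, got {self.region_role!r}"
            )
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValidationError("mask must be a 2-D raster")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.pixel_count * self.pixel_size_um**2

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6

    def is_empty(self) -> bool:
        return not self.mask.any()


@dataclass(frozen=True)
class SectionMeasurement:
    """One named scalar metric measured on one section.

    ``value`` carries the metric's natural units (µm for thickness,
    nuclei/mm for parakeratosis, %, AU/pixel or cells/mm² elsewhere).
    Corrected values (``isotype_corrected=True``) are floored at 0.
    """

    subject_id: str
    site: str
    section_index: int
    metric_name: str
    value: float
    isotype_corrected: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValidationError(f"{self.metric_name}: value must be finite")
        if self.isotype_corrected and self.value < 0:
            raise ValidationError(f"{self.metric_name}: corrected value below 0")


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject per-site summary (median over 3–5 sections)."""

    subject_id: str
    site: str
    metric_name: str
    median: float
    n_sections: int

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValidationError("n_sections must be >= 1")


@dataclass(frozen=True)
class IsotypeBaseline:
    """Background measured on an isotype-control stain, same units as the
    metric it corrects (%, AU/pixel intensity, or cells/mm²)."""

    subject_id: str
    section_index: int
    stain_name: str
    baseline_value: float

    def __post_init__(self) -> None:
        if self.baseline_value < 0:
            raise ValidationError("baseline_value must be >= 0")


#: A zero background, for uncorrected measurement paths.
ZERO_BASELINE = IsotypeBaseline("", 0, "none", 0.0)


@dataclass(frozen=True)
class CellGate:
    """Size/intensity gate defining a marker-positive cell.

    Defaults follow the published gates: detections are connected
    components of pixels above ``intensity_threshold`` whose area lies
    in [10, 33] µm²; per-pixel AU thresholds 0.03 (CD4) and 0.025 (CCR5).
    """

    area_min_um2: float = 10.0
    area_max_um2: float = 33.0
    intensity_threshold: float = 0.03

    def __post_init__(self) -> None:
        if not 0 < self.area_min_um2 < self.area_max_um2:
            raise ValidationError("require 0 < area_min_um2 < area_max_um2")
        if not 0 < self.intensity_threshold < 1:
            raise ValidationError("intensity_threshold must lie in (0, 1)")


CD4_GATE = CellGate(intensity_threshold=0.03)
CCR5_GATE = CellGate(intensity_threshold=0.025)


@dataclass(frozen=True)
class DensityResult:
    """Cell density for one subject/site/marker/compartment, with the
    per-subject isotype background and its floored subtraction."""

    subject_id: str
    site: str
    marker: str
    compartment: str
    raw_density: float
    baseline_density: float = 0.0
    corrected_density: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.raw_density < 0 or self.baseline_density < 0:
            raise ValidationError("densities must be >= 0")
        if self.corrected_density is None:
            object.__setattr__(
                self,
                "corrected_density",
                max(0.0, self.raw_density - self.baseline_density),
            )
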