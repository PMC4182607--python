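"""Ground-truthed synthetic sections and paired cohorts.

The generator emulates the data layout of a paired inner/outer foreskin
morphometry study so every downstream stage (segmentation, morphometry,
stain quantification, cell detection, paired statistics) can be exercised
against known truth without any external download.

A synthetic section is a horizontal epithelial strip: background above,
then the cornified stratum corneum (SC), then the living strata
SG → SS → SB, then dermis to the bottom edge.  The basal (SB/dermis)
boundary may undulate sinusoidally, which reproduces the
length ≫ thickness geometry the area/Feret thickness estimator assumes.
The red channel carries epidermal autofluorescence (by default the
cellular strata SB–SG only; whether the SC autofluoresces is exposed as
an option), the nuclear channel carries non-overlapping nuclei, stain
channels carry membrane (Voronoi cell borders) or cytosolic (uniform
fill) patterns per stratum, marker channels carry size-controlled
infiltrating cells, and the isotype channel is pure background.

Cohorts are generated at measurement level by default: per-subject,
per-site, per-section log-normal metric draws with configurable
multiplicative inner-vs-outer effects, analyte panels with log-normal
inner/outer ratios, and hemoglobin contamination flags.  Full image
rendering per section is available for end-to-end pipeline runs.

All randomness flows from the single explicit seed of each spec; equal
(spec, seed) yields bit-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from ._core import (
    CHANNELS,
    STRATA,
    ImageSection,
    RegionMask,
    ValidationError,
)

logger = logging.getLogger(__name__)

MARKER_CHANNEL = {"CD4": "blue", "CCR5": "far_red"}

# Default rendering intensities (AU on [0, 1]).
AUTOFLUORESCENCE_AU = 0.5
NUCLEUS_AU = 0.85
NUCLEUS_RADIUS_UM = 2.5


@dataclass(frozen=True)
class CellSpec:
    """One infiltrating cell to render: nominal area, AU intensity on its
    marker channels, marker set (subset of {CD4, CCR5}), compartment."""

    area_um2: float
    intensity: float = 0.5
    markers: frozenset = frozenset({"CD4"})
    compartment: str = "epidermis"

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", frozenset(self.markers))
        if self.area_um2 <= 0:
            raise ValidationError("cell_spec.area_um2 must be > 0")
        if not 0 < self.intensity <= 1:
            raise ValidationError("cell_spec.intensity must lie in (0, 1]")
        if not self.markers <= {"CD4", "CCR5"}:
            raise ValidationError("cell_spec.markers must be a subset of {CD4, CCR5}")
        if self.compartment not in ("epidermis", "dermis"):
            raise ValidationError("cell_spec.compartment must be epidermis or dermis")


@dataclass(frozen=True)
class SectionSpec:
    """Everything needed to render one section deterministically.

    ``strata_fractions`` are SB/SS/SG/SC height fractions of
    ``epidermis_height_px`` (the full epithelium including SC) and must
    sum to 1.  ``stains`` maps channel name → stratum → (pattern,
    intensity) with pattern in {membrane, cytosolic, none}.
    """

    width_px: int = 512
    height_px: int = 144
    pixel_size_um: float = 1.0
    epidermis_height_px: float = 72.0
    strata_fractions: tuple = (0.30, 0.40, 0.15, 0.15)  # SB, SS, SG, SC
    undulation_amplitude_px: float = 0.0
    undulation_period_px: float = 64.0
    nuclei_density_per_mm2: float = 2000.0
    sc_nuclei_per_mm: float = 0.0
    stains: Mapping = field(default_factory=dict)
    isotype_background_level: float = 0.01
    cell_spec: tuple = ()
    noise_sd: float = 0.0
    include_sc_autofluorescence: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata_fractions", tuple(self.strata_fractions))
        object.__setattr__(self, "cell_spec", tuple(self.cell_spec))
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError("width_px/height_px must be positive integers")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.epidermis_height_px <= 0:
            raise ValidationError("epidermis_height_px must be > 0")
        fr = self.strata_fractions
        if len(fr) != 4 or any(f < 0 for f in fr):
            raise ValidationError("strata_fractions must be four nonnegative reals")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError("strata_fractions must sum to 1 within 1e-9")
        if self.undulation_amplitude_px < 0 or self.undulation_period_px <= 0:
            raise ValidationError("undulation parameters must be nonnegative (period > 0)")
        if self.nuclei_density_per_mm2 < 0:
            raise ValidationError("nuclei_density_per_mm2 must be >= 0")
        if self.sc_nuclei_per_mm < 0:
            raise ValidationError("sc_nuclei_per_mm must be >= 0")
        if not 0 <= self.isotype_background_level <= 1:
            raise ValidationError("isotype_background_level must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for ch, per_stratum in self.stains.items():
            for stratum, (pattern, inten) in per_stratum.items():
                if stratum not in STRATA:
                    raise ValidationError(f"stains[{ch!r}]: unknown stratum {stratum!r}")
                if pattern not in ("membrane", "cytosolic", "none"):
                    raise ValidationError(
                        f"stains[{ch!r}][{stratum!r}]: pattern must be "
                        "membrane|cytosolic|none"
                    )
                if not 0 <= inten <= 1:
                    raise ValidationError(
                        f"stains[{ch!r}][{stratum!r}]: intensity outside [0, 1]"
                    )


@dataclass(frozen=True)
class TrueCell:
    x: float  # column, pixel units
    y: float  # row, pixel units
    area_um2: float  # rendered pixel area
    markers: frozenset
    compartment: str


@dataclass
class GroundTruth:
    """Known truth for one rendered section (all masks/rasters pre-noise)."""

    true_epidermis_mask: np.ndarray
    true_sc_mask: np.ndarray
    true_dermis_mask: np.ndarray
    true_mean_thickness_um: float
    true_sc_thickness_um: float
    true_nuclei_count: int
    true_sc_nuclei_count: int
    true_coverage_pct: dict
    true_mean_intensity: dict
    true_cells: list
    true_counts_by_gate: dict
    pixel_size_um: float = 1.0

    @property
    def true_cell_centroids(self) -> list:
        return [(c.x, c.y, c.markers, c.compartment) for c in self.true_cells]

    def count_in_gate(
        self,
        marker: str,
        compartment: str | None = None,
        area_min_um2: float = 10.0,
        area_max_um2: float = 33.0,
    ) -> int:
        """Number of rendered cells carrying ``marker`` whose rendered area
        lies inside the gate, optionally restricted to a compartment."""
        return sum(
            1
            for c in self.true_cells
            if marker in c.markers
            and (compartment is None or c.compartment == compartment)
            and area_min_um2 <= c.area_um2 <= area_max_um2
        )

    def region(self, role: str) -> RegionMask:
        mask = {
            "epidermis": self.true_epidermis_mask,
            "stratum_corneum": self.true_sc_mask,
            "dermis": self.true_dermis_mask,
            "whole_tissue": self.true_epidermis_mask
            | self.true_sc_mask
            | self.true_dermis_mask,
        }[role]
        return RegionMask(mask=mask, region_role=role, pixel_size_um=self.pixel_size_um)


# ---------------------------------------------------------------------------
# Section rendering
# ---------------------------------------------------------------------------


def _band_heights(spec: SectionSpec) -> dict:
    """Integer band heights (px) for SB/SS/SG/SC; rounding is absorbed into
    the outermost (SC) band so heights always sum to round(epidermis_height)."""
    total = int(round(spec.epidermis_height_px))
    h = {s: int(round(f * spec.epidermis_height_px)) for s, f in zip(STRATA, spec.strata_fractions)}
    h["SC"] = max(0, total - h["SB"] - h["SS"] - h["SG"])
    return h


def _stratum_label_raster(spec: SectionSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Label raster: 0 background, 1..4 = SB..SC, 5 dermis; plus the
    per-column basal boundary row."""
    H, W = spec.height_px, spec.width_px
    h = _band_heights(spec)
    y0 = max(2, int(round(0.08 * H)))  # background margin above the SC surface
    rows = np.arange(H)[:, None]
    x = np.arange(W)[None, :]
    base_nominal = y0 + h["SC"] + h["SG"] + h["SS"] + h["SB"]
    if spec.undulation_amplitude_px > 0:
        wobble = spec.undulation_amplitude_px * np.sin(
            2 * np.pi * x / spec.undulation_period_px
        )
        base = np.clip(np.rint(base_nominal + wobble).astype(int), y0 + h["SC"], H)
    else:
        base = np.full((1, W), min(base_nominal, H), dtype=int)
    labels = np.zeros((H, W), dtype=np.uint8)
    code = {"SB": 1, "SS": 2, "SG": 3, "SC": 4}
    y_sc0, y_sc1 = y0, y0 + h["SC"]
    y_sg1 = y_sc1 + h["SG"]
    y_ss1 = y_sg1 + h["SS"]
    base2d = np.broadcast_to(base, (H, W))
    rows2d = np.broadcast_to(rows, (H, W))
    labels[(rows2d >= y_sc0) & (rows2d < y_sc1)] = code["SC"]
    labels[(rows2d >= y_sc1) & (rows2d < np.minimum(y_sg1, base2d))] = code["SG"]
    labels[(rows2d >= y_sg1) & (rows2d < np.minimum(y_ss1, base2d))] = code["SS"]
    labels[(rows2d >= y_ss1) & (rows2d < base2d)] = code["SB"]
    labels[rows2d >= base2d] = 5
    return labels, base.ravel(), h


def _place_points(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    min_sep_px: float,
    taken: list,
) -> list:
    """Sample up to ``n`` points (row, col) on True pixels of ``allowed``,
    each at least ``min_sep_px`` from every previously placed point."""
    coords = np.argwhere(allowed)
    if coords.size == 0 or n == 0:
        return []
    placed: list = []
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        r, c = coords[rng.integers(len(coords))]
        p = (r + rng.random(), c + rng.random())
        others = placed + taken
        if others:
            arr = np.asarray([(q[0], q[1]) for q in others])
            d2 = ((arr - np.asarray(p)) ** 2).sum(axis=1)
            if d2.min() < min_sep_px**2:
                continue
        placed.append(p)
    if len(placed) < n:
        logger.warning(
            "placed %d of %d requested points (region too crowded)", len(placed), n
        )
    return placed


def _render_disks(
    canvas: np.ndarray, centers: Sequence, radius_px: float, intensity: float
) -> list[int]:
    """Paint disks and return each disk's rendered pixel count."""
    H, W = canvas.shape
    areas = []
    for cy, cx in centers:
        r0 = max(0, int(math.floor(cy - radius_px - 1)))
        r1 = min(H, int(math.ceil(cy + radius_px + 2)))
        c0 = max(0, int(math.floor(cx - radius_px - 1)))
        c1 = min(W, int(math.ceil(cx + radius_px + 2)))
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disk = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= radius_px**2
        canvas[r0:r1, c0:c1][disk] = np.maximum(canvas[r0:r1, c0:c1][disk], intensity)
        areas.append(int(disk.sum()))
    return areas


def _render_membrane(
    canvas: np.ndarray, region: np.ndarray, seeds: Sequence, intensity: float
) -> None:
    """Thin high-intensity cell borders: boundaries of the nearest-seed
    (Voronoi) tessellation restricted to ``region``.  Needs ≥ 2 seeds."""
    if len(seeds) < 2:
        return
    coords = np.argwhere(region)
    tree = cKDTree(np.asarray(seeds))
    _, owner = tree.query(coords)
    lab = np.full(canvas.shape, -1, dtype=np.int32)
    lab[tuple(coords.T)] = owner
    edge = np.zeros(canvas.shape, dtype=bool)
    # A region pixel is membrane if a 4-neighbour inside the region has a
    # different owning nucleus.
    for dr, dc in ((1, 0), (0, 1)):
        a = lab[: canvas.shape[0] - dr, : canvas.shape[1] - dc]
        b = lab[dr:, dc:]
        diff = (a != b) & (a >= 0) & (b >= 0)
        edge[: canvas.shape[0] - dr, : canvas.shape[1] - dc] |= diff
        edge[dr:, dc:] |= diff
    canvas[edge] = np.maximum(canvas[edge], intensity)


def generate_section(spec: SectionSpec) -> tuple[ImageSection, GroundTruth]:
    """Render one section and its ground truth.

    Returns an :class:`ImageSection` with the canonical channels
    (nuclear, red, far_red, blue, isotype) and a :class:`GroundTruth`
    whose masks, thickness values, nuclei/cell counts and per-channel
    stain summaries are computed from the pre-noise render.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px
    px = spec.pixel_size_um
    labels, base, h = _stratum_label_raster(spec)

    cellular = (labels >= 1) & (labels <= 3)  # SB..SG
    sc = labels == 4
    dermis = labels == 5
    epidermis = cellular | sc if spec.include_sc_autofluorescence else cellular

    clean = {name: np.zeros((H, W), dtype=np.float64) for name in CHANNELS}
    clean["red"][epidermis] = AUTOFLUORESCENCE_AU
    clean["isotype"][:] = spec.isotype_background_level

    # --- nuclei -----------------------------------------------------------
    r_nuc = NUCLEUS_RADIUS_UM / px
    min_sep = 2 * r_nuc + 2.0
    area_mm2 = cellular.sum() * px**2 / 1e6
    n_nuclei = int(round(spec.nuclei_density_per_mm2 * area_mm2))
    # keep nuclei clear of the epidermis border so centroids stay inside
    inner_cellular = binary_erosion(cellular, iterations=max(1, int(math.ceil(r_nuc))))
    nuclei = _place_points(rng, inner_cellular, n_nuclei, min_sep, [])
    width_mm = W * px / 1e3
    n_sc = int(round(spec.sc_nuclei_per_mm * width_mm))
    inner_sc = binary_erosion(sc, iterations=1) if h["SC"] > 2 else sc
    sc_nuclei = _place_points(rng, inner_sc, n_sc, min_sep, nuclei)
    _render_disks(clean["nuclear"], nuclei + sc_nuclei, r_nuc, NUCLEUS_AU)

    # --- stratified stain patterns ---------------------------------------
    code = {"SB": 1, "SS": 2, "SG": 3, "SC": 4}
    for ch, per_stratum in spec.stains.items():
        if ch not in clean:
            raise ValidationError(f"stains: unknown channel {ch!r}")
        for stratum, (pattern, inten) in per_stratum.items():
            region = labels == code[stratum]
            if pattern == "none" or inten == 0:
                continue
            if pattern == "cytosolic":
                clean[ch][region] = np.maximum(clean[ch][region], inten)
            else:  # membrane
                seeds = [p for p in nuclei + sc_nuclei if labels[int(p[0]), int(p[1])] == code[stratum]]
                _render_membrane(clean[ch], region, seeds, inten)

    # --- infiltrating cells ----------------------------------------------
    true_cells: list[TrueCell] = []
    placed_cells: list = []
    r_cell_max = max(
        (math.sqrt(cs.area_um2 / math.pi) / px for cs in spec.cell_spec), default=0.0
    )
    for cs in spec.cell_spec:
        r_cell = math.sqrt(cs.area_um2 / math.pi) / px
        target = cellular if cs.compartment == "epidermis" else dermis
        pad = max(1, int(math.ceil(r_cell)) + 1)
        interior = binary_erosion(target, iterations=pad)
        sep = r_cell + r_cell_max + 3.0
        pts = _place_points(rng, interior, 1, sep, placed_cells)
        if not pts:
            logger.warning("could not place cell (area %.1f µm²)", cs.area_um2)
            continue
        placed_cells.extend(pts)
        (cy, cx) = pts[0]
        rendered_area_px = 0
        for marker in cs.markers:
            areas = _render_disks(clean[MARKER_CHANNEL[marker]], [(cy, cx)], r_cell, cs.intensity)
            rendered_area_px = areas[0]
        true_cells.append(
            TrueCell(
                x=cx,
                y=cy,
                area_um2=rendered_area_px * px**2,
                markers=cs.markers,
                compartment=cs.compartment,
            )
        )

    # --- truth summaries (pre-noise) --------------------------------------
    extent_um = W * px
    truth = GroundTruth(
        true_epidermis_mask=epidermis.copy(),
        true_sc_mask=sc.copy(),
        true_dermis_mask=dermis.copy(),
        true_mean_thickness_um=epidermis.sum() * px**2 / extent_um,
        true_sc_thickness_um=sc.sum() * px**2 / extent_um if sc.any() else 0.0,
        true_nuclei_count=len(nuclei),
        true_sc_nuclei_count=len(sc_nuclei),
        true_coverage_pct={
            ch: 100.0 * float((clean[ch][epidermis] > 1e-12).mean()) if epidermis.any() else 0.0
            for ch in CHANNELS
        },
        true_mean_intensity={
            ch: float(clean[ch][epidermis].mean()) if epidermis.any() else 0.0
            for ch in CHANNELS
        },
        true_cells=true_cells,
        true_counts_by_gate={
            m: sum(1 for c in true_cells if m in c.markers and 10.0 <= c.area_um2 <= 33.0)
            for m in ("CD4", "CCR5")
        },
        pixel_size_um=px,
    )

    channels = {}
    for ch in CHANNELS:
        img = clean[ch]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[ch] = np.clip(img, 0.0, 1.0)
    section = ImageSection(channels=channels, pixel_size_um=px)
    return section, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricModel:
    """Log-normal model for one imaging metric.

    ``outer_median`` anchors the outer-foreskin scale; variance splits
    into a subject effect shared between sites, a site-level effect, and
    section-to-section noise (all SDs on the log scale).
    """

    name: str
    outer_median: float
    sigma_subject: float = 0.35
    sigma_site: float = 0.15
    sigma_section: float = 0.10
    unit: str = ""


@dataclass(frozen=True)
class AnalyteModel:
    """Log-normal model for one explant/lysate analyte: outer-site median
    concentration and the geometric mean + log-SD of the inner/outer ratio."""

    name: str
    outer_median: float
    ratio_gm: float = 1.0
    ratio_sigma: float = 1.0
    sigma_subject: float = 0.6
    compartment: str = "epidermis"
    unit: str = "ng/ml"


def default_metric_models() -> tuple[MetricModel, ...]:
    """Imaging metrics with outer-site medians on the scale of the study
    (SC ≈ 19.9 µm, claudin-1 intensity ≈ 0.039 AU/px, CCR5 epidermal
    density ≈ 6.5 cells/mm², ...)."""
    return (
        MetricModel("epithelium_thickness_um", 250.0, unit="um"),
        MetricModel("sc_thickness_um", 19.90, unit="um"),
        MetricModel("parakeratosis_per_mm", 0.3, unit="nuclei/mm"),
        MetricModel("ki67_pct", 10.0, unit="%"),
        MetricModel("claudin1_coverage_pct", 53.27, unit="%"),
        MetricModel("claudin1_intensity_au", 0.039, unit="AU/pixel"),
        MetricModel("claudin4_coverage_pct", 58.86, unit="%"),
        MetricModel("claudin4_intensity_au", 0.047, unit="AU/pixel"),
        MetricModel("claudin4_polarization_au", 0.838, unit="AU/pixel"),
        MetricModel("occludin_coverage_pct", 52.77, unit="%"),
        MetricModel("occludin_intensity_au", 0.027, unit="AU/pixel"),
        MetricModel("cd4_density_whole", 50.0, unit="cells/mm2"),
        MetricModel("ccr5_density_whole", 40.0, unit="cells/mm2"),
        MetricModel("cd4ccr5_density_whole", 5.0, unit="cells/mm2"),
        MetricModel("cd4_density_epidermis", 10.0, unit="cells/mm2"),
        MetricModel("ccr5_density_epidermis", 6.46, unit="cells/mm2"),
        MetricModel("cd4ccr5_density_epidermis", 0.25, unit="cells/mm2"),
    )


def default_analyte_models() -> tuple[AnalyteModel, ...]:
    return (
        AnalyteModel("IP-10", 2.2),
        AnalyteModel("GM-CSF", 0.94),
        AnalyteModel("RANTES", 5.7),
        AnalyteModel("IFN-gamma", 0.88),
        AnalyteModel("RANTES_dermis", 19.8, compartment="dermis"),
        AnalyteModel("MIP-1alpha_dermis", 1.0, compartment="dermis"),
        AnalyteModel("fibronectin", 100.0, compartment="lysate"),
        AnalyteModel("keratin6", 50.0, compartment="lysate"),
        AnalyteModel("involucrin", 20.0, compartment="lysate"),
        AnalyteModel("keratin1_10", 30.0, compartment="lysate"),
    )


def study_effects() -> dict:
    """Inner/outer effect ratios matching the direction and magnitude of
    the study's findings (SC thinning to ~0.8, claudin-1 gains, claudin-4
    depolarization, CCR5/double-positive enrichment, cytokine ratios)."""
    metric = {
        "sc_thickness_um": 0.8,
        "claudin1_coverage_pct": 58.85 / 53.27,
        "claudin1_intensity_au": 0.060 / 0.039,
        "claudin4_polarization_au": 0.267 / 0.838,
        "occludin_intensity_au": 0.042 / 0.027,
        "ccr5_density_whole": 2.0,
        "ccr5_density_epidermis": 21.34 / 6.46,
        "cd4ccr5_density_epidermis": 2.01 / 0.25,
    }
    analyte = {
        "IP-10": 4.0,
        "GM-CSF": 3.0,
        "RANTES": 2.0,
        "IFN-gamma": 1.25,
        "RANTES_dermis": 1.5,
        "MIP-1alpha_dermis": 1.3,
    }
    return {"metric": metric, "analyte": analyte}


HEMOGLOBIN_LOD = 1.0  # ng/ml, synthetic assay floor
HEMOGLOBIN_LOD_CI = 0.2  # one confidence-interval width above the floor


@dataclass(frozen=True)
class CohortSpec:
    """Paired cohort: n subjects × {inner, outer} × sections_per_site.

    ``effects`` maps metric name → multiplicative inner/outer ratio
    (1 = null); ``analyte_effects`` overrides each analyte's ratio
    geometric mean.  ``hemoglobin_contamination_rate`` is the per-subject
    probability that the epidermal explant is dermally contaminated
    (hemoglobin at or above LOD + 1 CI).
    """

    n_subjects: int = 17
    sections_per_site: int = 4
    effects: Mapping = field(default_factory=dict)
    analyte_effects: Mapping = field(default_factory=dict)
    metric_models: tuple = field(default_factory=default_metric_models)
    analyte_models: tuple = field(default_factory=default_analyte_models)
    hemoglobin_contamination_rate: float = 0.15
    render_sections: bool = False
    section_template: SectionSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric_models", tuple(self.metric_models))
        object.__setattr__(self, "analyte_models", tuple(self.analyte_models))
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.sections_per_site < 1:
            raise ValidationError("sections_per_site must be >= 1")
        if not 3 <= self.sections_per_site <= 5:
            logger.warning(
                "sections_per_site=%d outside the usual 3–5 range",
                self.sections_per_site,
            )
        if not 0 <= self.hemoglobin_contamination_rate <= 1:
            raise ValidationError("hemoglobin_contamination_rate must lie in [0, 1]")
        known = {m.name for m in self.metric_models}
        for name in self.effects:
            if name not in known:
                raise ValidationError(f"effects: unknown metric {name!r}")
        known_a = {a.name for a in self.analyte_models}
        for name in self.analyte_effects:
            if name not in known_a:
                raise ValidationError(f"analyte_effects: unknown analyte {name!r}")
        for m in self.metric_models:
            if m.sigma_subject <= 0 or m.sigma_site <= 0 or m.sigma_section <= 0:
                raise ValidationError(f"metric {m.name}: dispersions must be positive")


def null_cohort_spec(
    n_subjects: int = 17,
    n_metrics: int = 43,
    n_analytes: int = 10,
    seed: int = 0,
    **kwargs,
) -> CohortSpec:
    """A fully-null cohort with an arbitrary-size comparison family
    (``n_metrics`` paired metrics + ``n_analytes`` ratio analytes), used
    for type-I / FDR calibration runs."""
    metrics = tuple(
        MetricModel(f"metric_{i:02d}", outer_median=10.0) for i in range(n_metrics)
    )
    analytes = tuple(
        AnalyteModel(f"analyte_{i:02d}", outer_median=5.0) for i in range(n_analytes)
    )
    return CohortSpec(
        n_subjects=n_subjects,
        metric_models=metrics,
        analyte_models=analytes,
        hemoglobin_contamination_rate=0.0,
        seed=seed,
        **kwargs,
    )


@dataclass
class CohortData:
    """Generated paired dataset.

    ``sections``: long frame (subject_id, site, metric, section_index,
    value); ``summaries``: per-subject medians; ``analytes``: (subject_id,
    site, analyte, compartment, concentration); ``explants``: per
    subject/site/compartment hemoglobin QC rows with the truth flag.
    ``rendered`` holds (ImageSection, GroundTruth) lists per
    (subject_id, site) when image rendering was requested.
    """

    spec: CohortSpec
    sections: pd.DataFrame
    summaries: pd.DataFrame
    analytes: pd.DataFrame
    explants: pd.DataFrame
    rendered: dict = field(default_factory=dict)


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Draw a paired cohort under ``spec``.

    Metric values are log-normal: value = median_outer · exp(subject) ·
    ratio^{[site=inner]} · exp(site) · exp(section).  A null spec (all
    ratios 1) makes inner and outer exchangeable by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_subjects, spec.sections_per_site
    subjects = [f"S{i + 1:03d}" for i in range(n)]

    sec_rows = []
    for m in spec.metric_models:
        ratio = float(spec.effects.get(m.name, 1.0))
        subj = rng.normal(0.0, m.sigma_subject, size=n)
        for si, site in enumerate(("inner", "outer")):
            site_eff = rng.normal(0.0, m.sigma_site, size=n)
            sect = rng.normal(0.0, m.sigma_section, size=(n, k))
            log_mu = (
                math.log(m.outer_median)
                + (math.log(ratio) if site == "inner" else 0.0)
            )
            vals = np.exp(log_mu + subj[:, None] + site_eff[:, None] + sect)
            for i, sid in enumerate(subjects):
                for j in range(k):
                    sec_rows.append((sid, site, m.name, j, vals[i, j]))
    sections = pd.DataFrame(
        sec_rows, columns=["subject_id", "site", "metric", "section_index", "value"]
    )
    summaries = (
        sections.groupby(["subject_id", "site", "metric"], sort=False)["value"]
        .agg(["median", "size"])
        .reset_index()
        .rename(columns={"median": "value", "size": "n_sections"})
    )

    an_rows = []
    for a in spec.analyte_models:
        gm = float(spec.analyte_effects.get(a.name, a.ratio_gm))
        subj = np.exp(rng.normal(math.log(a.outer_median), a.sigma_subject, size=n))
        ratios = np.exp(rng.normal(math.log(gm), a.ratio_sigma, size=n))
        for i, sid in enumerate(subjects):
            an_rows.append((sid, "outer", a.name, a.compartment, subj[i]))
            an_rows.append((sid, "inner", a.name, a.compartment, subj[i] * ratios[i]))
    analytes = pd.DataFrame(
        an_rows, columns=["subject_id", "site", "analyte", "compartment", "concentration"]
    )

    contaminated = rng.random(n) < spec.hemoglobin_contamination_rate
    exp_rows = []
    for i, sid in enumerate(subjects):
        for site in ("inner", "outer"):
            for compartment in ("epidermis", "dermis"):
                if compartment == "epidermis" and contaminated[i]:
                    hb = HEMOGLOBIN_LOD + HEMOGLOBIN_LOD_CI * (1.0 + rng.exponential(2.0))
                elif compartment == "epidermis":
                    hb = HEMOGLOBIN_LOD * rng.random()
                else:
                    hb = HEMOGLOBIN_LOD + rng.exponential(20.0)  # dermis is vascular
                exp_rows.append(
                    (
                        sid,
                        site,
                        compartment,
                        hb,
                        HEMOGLOBIN_LOD,
                        HEMOGLOBIN_LOD_CI,
                        bool(contaminated[i]) if compartment == "epidermis" else False,
                    )
                )
    explants = pd.DataFrame(
        exp_rows,
        columns=[
            "subject_id",
            "site",
            "compartment",
            "hemoglobin_ng_ml",
            "lod",
            "lod_ci",
            "contaminated",
        ],
    )

    rendered: dict = {}
    if spec.render_sections:
        template = spec.section_template or SectionSpec()
        med = dict(
            summaries.set_index(["subject_id", "site", "metric"])["value"]
        )
        for sid in subjects:
            for site in ("inner", "outer"):
                secs = []
                for j in range(k):
                    sc_um = med.get((sid, site, "sc_thickness_um"), 15.0)
                    total = template.epidermis_height_px
                    sc_frac = min(
                        0.6, sc_um / template.pixel_size_um / total
                    )
                    rest = 1.0 - sc_frac
                    fr = (0.30 / 0.85 * rest, 0.40 / 0.85 * rest, 0.15 / 0.85 * rest, sc_frac)
                    fr = tuple(f / sum(fr) for f in fr)
                    sub_seed = int(rng.integers(0, 2**31 - 1))
                    sspec = replace(template, strata_fractions=fr, seed=sub_seed)
                    secs.append(generate_section(sspec))
                rendered[(sid, site)] = secs
    return CohortData(
        spec=spec,
        sections=sections,
        summaries=summaries,
        analytes=analytes,
        explants=explants,
        rendered=rendered,
    )
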