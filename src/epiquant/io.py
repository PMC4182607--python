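"""Formats, configuration and pipeline orchestration.

Sections travel as multi-channel TIFF (channels in the canonical order
nuclear, red, far_red, blue, isotype) with a JSON sidecar that is the
source of truth for pixel size and provenance — TIFF resolution tags are
ignored to avoid writer-dialect ambiguity.  Measurements use one
long/tidy CSV schema throughout.  All file writes are atomic
(write-then-rename), so interrupted runs never leave truncated outputs.

``run_pipeline`` wires the stages end to end on a synthetic cohort:
simulate → segment → measure (thickness, parakeratosis, stains, cells)
→ per-subject medians → hemoglobin QC filter → family statistics →
CSV/JSON report.  Every output carries the seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from ._core import (
    CHANNELS,
    CD4_GATE,
    CCR5_GATE,
    ImageSection,
    InputError,
    RegionMask,
    SectionMeasurement,
)
from . import cells as _cells
from . import morphometry as _morph
from . import stains as _stains
from .segmentation import detect_nuclei, segment_epidermis
from .stats import (
    Comparison,
    ExplantRecord,
    FamilyDeclaration,
    filter_explants,
    run_comparison_family,
)
from .synthetic import CohortSpec, SectionSpec, generate_cohort, generate_section

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------------


def atomic_write_bytes(path, data: bytes) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_bytes(data)
    os.replace(tmp, path)


def atomic_write_text(path, text: str) -> None:
    atomic_write_bytes(path, text.encode())


def write_csv(path, df: pd.DataFrame) -> None:
    atomic_write_text(path, df.to_csv(index=False))


# ---------------------------------------------------------------------------
# Section I/O
# ---------------------------------------------------------------------------


def write_section(path, section: ImageSection, ground_truth_extra: dict | None = None) -> None:
    """Write a section as float32 multi-channel TIFF + JSON sidecar."""
    path = Path(path)
    names = [c for c in CHANNELS if c in section.channels] + [
        c for c in section.channels if c not in CHANNELS
    ]
    stack = np.stack([np.asarray(section.channels[c], dtype=np.float32) for c in names])
    tmp = path.with_name(path.name + ".tmp")
    tifffile.imwrite(tmp, stack, photometric="minisblack")
    os.replace(tmp, path)
    sidecar = {
        "pixel_size_um": section.pixel_size_um,
        "channel_names": names,
        "subject_id": section.subject_id,
        "site": section.site,
        "section_index": section.section_index,
    }
    if ground_truth_extra:
        sidecar["ground_truth"] = ground_truth_extra
    atomic_write_text(path.with_suffix(path.suffix + ".json"), json.dumps(sidecar, indent=1))


def read_section(path) -> ImageSection:
    """Read a section TIFF + its ``<name>.<ext>.json`` sidecar.

    Integer-typed TIFFs are rescaled to [0, 1] by their dtype maximum
    (e.g. 16-bit / 65535).
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise InputError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InputError(f"{path}: expected a (channels, H, W) stack, got {arr.shape}")
    names = meta.get("channel_names")
    if not names or len(names) != arr.shape[0]:
        raise InputError(f"{path}: sidecar channel_names do not match {arr.shape[0]} planes")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    arr = arr.astype(np.float64)
    return ImageSection(
        channels={n: arr[i] for i, n in enumerate(names)},
        pixel_size_um=float(meta["pixel_size_um"]),
        subject_id=str(meta.get("subject_id", "")),
        site=str(meta.get("site", "inner")),
        section_index=int(meta.get("section_index", 0)),
    )


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run parameters (all on the spec's natural units)."""

    n_subjects: int = 6
    sections_per_site: int = 3
    seed: int = 0
    noise_sd: float = 0.0
    pixel_size_um: float = 1.0
    effects: dict = field(default_factory=dict)
    analyte_effects: dict = field(default_factory=dict)
    family_size: int = 53
    significant_p: float = 0.05
    trend_p: float = 0.10
    coverage_threshold: float | str = 0.01
    cell_detection_threshold: float | None = None
    stain_channel: str = "far_red"
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("significant_p", "trend_p"):
            v = getattr(cfg, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1]")
        return cfg


def _default_section_template(cfg: PipelineConfig) -> SectionSpec:
    """Rendered-section template: membrane stain in SG/SS on the stain
    channel plus a few in-gate CD4/CCR5 cells in each compartment."""
    from .synthetic import CellSpec

    cell_spec = tuple(
        CellSpec(area_um2=20.0, intensity=0.5, markers=frozenset(m), compartment=comp)
        for comp in ("epidermis", "dermis")
        for m in ({"CD4"}, {"CCR5"}, {"CD4", "CCR5"})
    )
    return SectionSpec(
        pixel_size_um=cfg.pixel_size_um,
        sc_nuclei_per_mm=2.0,
        stains={cfg.stain_channel: {"SG": ("membrane", 0.6), "SS": ("cytosolic", 0.3)}},
        cell_spec=cell_spec,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )


def measure_section(
    section: ImageSection,
    sc_outline: RegionMask,
    cfg: PipelineConfig,
    subject_id: str,
    site: str,
    section_index: int,
) -> list[SectionMeasurement]:
    """Measure one section: segmentation-based thickness, parakeratosis
    against the provided SC outline, stain metrics, and cell densities."""
    epi = segment_epidermis(section)
    out = []

    def add(metric, value, corrected=False):
        out.append(
            SectionMeasurement(
                subject_id=subject_id,
                site=site,
                section_index=section_index,
                metric_name=metric,
                value=float(value),
                isotype_corrected=corrected,
            )
        )

    add("epithelium_thickness_um", _morph.mean_thickness(epi))
    add("sc_thickness_um", _morph.mean_thickness(sc_outline))
    n_sc, _ = detect_nuclei(section, sc_outline)
    add("parakeratosis_per_mm", _morph.parakeratosis_density(n_sc, sc_outline))
    n_epi, _ = detect_nuclei(section, epi)
    add("epidermal_nuclei", n_epi)

    ch = section.channel(cfg.stain_channel)
    cov_base = _stains.isotype_baseline_from_section(
        section, epi, "coverage", threshold=cfg.coverage_threshold
    )
    int_base = _stains.isotype_baseline_from_section(section, epi, "intensity")
    add(
        "stain_coverage_pct",
        _stains.coverage_percent(ch, epi, threshold=cfg.coverage_threshold, isotype=cov_base),
        corrected=True,
    )
    add("stain_intensity_au", _stains.mean_intensity(ch, epi, isotype=int_base), corrected=True)
    add("stain_polarization_au", _stains.polarization_asm(ch, epi))

    whole = RegionMask(
        mask=np.ones(section.shape, dtype=bool),
        region_role="whole_tissue",
        pixel_size_um=section.pixel_size_um,
    )
    dets = {}
    for marker, gate, channel in (("cd4", CD4_GATE, "blue"), ("ccr5", CCR5_GATE, "far_red")):
        for comp, region in (("epidermis", epi), ("whole", whole)):
            n, d = _cells.detect_cells(
                section.channel(channel), region, gate, cfg.cell_detection_threshold
            )
            n_iso, _ = _cells.detect_cells(
                section.channel("isotype"), region, gate, cfg.cell_detection_threshold
            )
            raw = _cells.density(n, region)
            base = _cells.density(n_iso, region)
            add(f"{marker}_density_{comp}", max(0.0, raw - base), corrected=True)
            dets[(marker, comp)] = d
    for comp, region in (("epidermis", epi), ("whole", whole)):
        ndp = _cells.double_positive(
            dets[("cd4", comp)], dets[("ccr5", comp)], pixel_size_um=section.pixel_size_um
        )
        add(f"cd4ccr5_density_{comp}", _cells.density(ndp, region), corrected=True)
    return out


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic-cohort pipeline and write its report.

    Returns the report dict; writes sections.csv, summaries.csv,
    comparisons.csv and report.json under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.getLogger("epiquant").setLevel(cfg.log_level)
    logger.info("pipeline start: seed=%d hash=%s", cfg.seed, cfg.config_hash())

    spec = CohortSpec(
        n_subjects=cfg.n_subjects,
        sections_per_site=cfg.sections_per_site,
        effects=cfg.effects,
        analyte_effects=cfg.analyte_effects,
        render_sections=True,
        section_template=_default_section_template(cfg),
        seed=cfg.seed,
    )
    cohort = generate_cohort(spec)

    measurements: list[SectionMeasurement] = []
    for (sid, site), secs in cohort.rendered.items():
        for j, (section, truth) in enumerate(secs):
            measurements.extend(
                measure_section(section, truth.region("stratum_corneum"), cfg, sid, site, j)
            )

    sections_df = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "site": m.site,
                "metric": m.metric_name,
                "section_index": m.section_index,
                "value": m.value,
                "isotype_corrected": m.isotype_corrected,
            }
            for m in measurements
        ]
    )
    summaries_df = (
        sections_df.groupby(["subject_id", "site", "metric"], sort=False)["value"]
        .agg(["median", "size"])
        .reset_index()
        .rename(columns={"median": "value", "size": "n_sections"})
    )

    # hemoglobin QC: excluded subjects lose their epidermal analyte rows
    records = [
        ExplantRecord(
            subject_id=r.subject_id,
            site=r.site,
            compartment=r.compartment,
            hemoglobin_concentration=r.hemoglobin_ng_ml,
            lod=r.lod,
            lod_ci=r.lod_ci,
        )
        for r in cohort.explants.itertuples()
    ]
    kept, excluded = filter_explants(records)
    excluded_subjects = sorted({e.record.subject_id for e in excluded})
    analytes_df = cohort.analytes[
        ~(
            (cohort.analytes["compartment"] == "epidermis")
            & cohort.analytes["subject_id"].isin(excluded_subjects)
        )
    ]

    class _Dataset:
        summaries = summaries_df
        analytes = analytes_df

    comps = [Comparison(m, "paired") for m in summaries_df["metric"].unique()]
    comps += [Comparison(a, "ratio") for a in analytes_df["analyte"].unique()]
    family = FamilyDeclaration(
        tuple(comps),
        family_size=max(cfg.family_size, len(comps)),
        significant_p=cfg.significant_p,
        trend_p=cfg.trend_p,
    )
    results = run_comparison_family(_Dataset, family)

    comparisons_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    provenance = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    for df in (sections_df, summaries_df, comparisons_df):
        for k, v in provenance.items():
            df[k] = v
    write_csv(out_dir / "sections.csv", sections_df)
    write_csv(out_dir / "summaries.csv", summaries_df)
    write_csv(out_dir / "comparisons.csv", comparisons_df)

    report = {
        **provenance,
        "n_subjects": cfg.n_subjects,
        "sections_per_site": cfg.sections_per_site,
        "n_measurements": len(measurements),
        "excluded_subjects": excluded_subjects,
        "n_explants_kept": len(kept),
        "family_size": family.m,
        "comparisons": [dataclasses.asdict(r) for r in results],
    }
    atomic_write_text(out_dir / "report.json", json.dumps(report, indent=1))
    logger.info("pipeline done: %d comparisons", len(results))
    return report
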