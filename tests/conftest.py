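import numpy as np
import pytest

from epiquant import CellSpec, RegionMask, SectionSpec, generate_section


@pytest.fixture(scope="session")
def flat_spec():
    """Noise-free flat strip with no cells and no SC nuclei."""
    return SectionSpec(seed=11)


@pytest.fixture(scope="session")
def flat_section(flat_spec):
    return generate_section(flat_spec)


@pytest.fixture(scope="session")
def rich_spec():
    """Noise-free section with undulation, SC nuclei, stains and cells."""
    return SectionSpec(
        seed=5,
        undulation_amplitude_px=5.0,
        undulation_period_px=96.0,
        sc_nuclei_per_mm=3.0,
        stains={"far_red": {"SG": ("membrane", 0.6), "SS": ("cytosolic", 0.3)}},
        cell_spec=tuple(
            CellSpec(area_um2=20.0, intensity=0.5, markers=frozenset({m}), compartment=c)
            for m in ("CD4", "CCR5")
            for c in ("epidermis", "dermis")
        ),
    )


@pytest.fixture(scope="session")
def rich_section(rich_spec):
    return generate_section(rich_spec)


def rect_mask(w, h, pixel_size_um=1.0, role="epidermis"):
    return RegionMask(np.ones((h, w), dtype=bool), role, pixel_size_um)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
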