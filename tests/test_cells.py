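"""Size-gated cell detection, densities, isotype subtraction, pairing."""

import itertools

import numpy as np
import pytest

from epiquant import (
    CCR5_GATE,
    CD4_GATE,
    CellGate,
    CellSpec,
    DensityResult,
    RegionMask,
    SectionSpec,
    density,
    detect_cells,
    double_positive,
    generate_section,
    subtract_isotype_density,
)
from epiquant._core import ValidationError
from epiquant.cells import Detection

from conftest import rect_mask


def blob_image(areas_px, intensity=0.5, size=100, spacing=20):
    img = np.zeros((size, size))
    yy, xx = np.mgrid[:size, :size]
    for i, a in enumerate(areas_px):
        r = np.sqrt(a / np.pi)
        cy, cx = 15 + spacing * (i // 4), 15 + spacing * (i % 4)
        img[(yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= r**2] = intensity
    return img


def test_area_gate_keeps_only_in_range_blobs():
    img = blob_image([5, 20, 50])
    n, dets = detect_cells(img, rect_mask(100, 100, role="whole_tissue"), CD4_GATE)
    assert n == 1
    assert 10 <= dets[0].area_um2 <= 33


def test_below_threshold_blob_not_detected():
    img = blob_image([20], intensity=0.02)
    n, _ = detect_cells(img, rect_mask(100, 100, role="whole_tissue"), CD4_GATE)
    assert n == 0
    n2, _ = detect_cells(
        blob_image([20], intensity=0.028), rect_mask(100, 100, role="whole_tissue"), CCR5_GATE
    )
    assert n2 == 1  # above the 0.025 CCR5 threshold


def test_widening_area_gate_never_decreases_count(rng):
    img = rng.random((80, 80)) * 0.6
    region = rect_mask(80, 80, role="whole_tissue")
    wide = CellGate(5.0, 60.0, 0.3)
    narrow = CellGate(10.0, 33.0, 0.3)
    assert detect_cells(img, region, wide)[0] >= detect_cells(img, region, narrow)[0]


def test_raising_threshold_never_increases_count_on_separated_blobs():
    """Threshold monotonicity holds in the detector's operating regime of
    isolated objects: a higher threshold can only drop or shrink blobs.
    (On percolating noise an upper area gate breaks this, as one giant
    cluster can split into many in-gate fragments.)"""
    img = blob_image([20] * 4, intensity=0.3) + blob_image([20] * 3, intensity=0.2)[::-1]
    img = np.clip(img, 0, 1)
    region = rect_mask(100, 100, role="whole_tissue")
    counts = [
        detect_cells(img, region, CellGate(10.0, 33.0, thr))[0]
        for thr in (0.05, 0.15, 0.25, 0.35)
    ]
    assert counts[0] >= 1
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_centroid_membership_assigns_straddling_cells():
    img = blob_image([20], size=40, spacing=0)  # centred at (15, 15)
    left = np.zeros((40, 40), bool)
    left[:, :16] = True
    right = ~left
    n_left, _ = detect_cells(img, RegionMask(left, "epidermis", 1.0), CD4_GATE)
    n_right, _ = detect_cells(img, RegionMask(right, "epidermis", 1.0), CD4_GATE)
    assert (n_left, n_right) == (1, 0)


def test_density_arithmetic_and_additivity():
    # 0.5 mm² region at 10 µm/px: 5000 px
    region = rect_mask(100, 50, pixel_size_um=10.0, role="whole_tissue")
    assert density(10, region) == pytest.approx(20.0)
    assert density(0, region) == 0.0
    half_a = rect_mask(50, 50, pixel_size_um=10.0, role="whole_tissue")
    assert (density(4, half_a) + density(6, half_a)) / 2 == pytest.approx(
        density(10, region)
    )
    with pytest.raises(ValidationError):
        density(-1, region)


def test_isotype_density_subtraction_floors_and_validates():
    raw = DensityResult("s1", "inner", "CCR5", "epidermis", raw_density=21.34)
    iso = DensityResult("s1", "inner", "isotype", "epidermis", raw_density=4.2)
    corr = subtract_isotype_density(raw, iso)
    assert corr.corrected_density == pytest.approx(17.14)
    big = DensityResult("s1", "inner", "isotype", "epidermis", raw_density=30.0)
    assert subtract_isotype_density(raw, big).corrected_density == 0.0
    zero = DensityResult("s1", "inner", "isotype", "epidermis", raw_density=0.0)
    assert subtract_isotype_density(raw, zero).corrected_density == raw.raw_density
    other = DensityResult("s2", "inner", "isotype", "epidermis", raw_density=1.0)
    with pytest.raises(ValidationError):
        subtract_isotype_density(raw, other)


def brute_force_max_pairing(a, b, radius):
    """Oracle: maximum matching by exhaustion over injections (≤ 10 cells)."""
    if len(a) > len(b):
        a, b = b, a
    best = 0
    idx = range(len(b))
    for perm in itertools.permutations(idx, len(a)):
        ok = sum(
            1
            for i, j in enumerate(perm)
            if np.hypot(a[i][0] - b[j][0], a[i][1] - b[j][1]) <= radius
        )
        best = max(best, ok)
    return best


def test_double_positive_edges():
    pts = [(5.0, 5.0), (20.0, 20.0), (40.0, 5.0)]
    assert double_positive(pts, pts, 3.0) == 3
    far = [(200.0, 200.0)]
    assert double_positive(pts, far, 3.0) == 0
    assert double_positive([], pts, 3.0) == 0


def test_double_positive_matches_brute_force(rng):
    for _ in range(30):
        na, nb = rng.integers(1, 6, size=2)
        a = [tuple(p) for p in rng.random((na, 2)) * 20]
        b = [tuple(p) for p in rng.random((nb, 2)) * 20]
        r = float(rng.uniform(1, 8))
        got = double_positive(a, b, r)
        assert got == brute_force_max_pairing(a, b, r)
        assert got <= min(na, nb)


def test_truth_recovery_over_many_seeds():
    """Noise-free in-gate counts equal generator truth; centroids within 1 px."""
    for seed in range(20):
        spec = SectionSpec(
            seed=seed,
            cell_spec=tuple(
                CellSpec(20.0, 0.5, frozenset({"CD4"}), "epidermis") for _ in range(8)
            ),
        )
        section, truth = generate_section(spec)
        epi = truth.region("epidermis")
        n, dets = detect_cells(section.channels["blue"], epi, CD4_GATE)
        assert n == truth.count_in_gate("CD4", "epidermis") == 8
        got = np.sort(np.array([(d.y, d.x) for d in dets]), axis=0)
        want = np.sort(np.array([(c.y, c.x) for c in truth.true_cells]), axis=0)
        assert np.abs(got - want).max() <= 1.0


def test_double_positive_truth_recovery():
    spec = SectionSpec(
        seed=31,
        cell_spec=(
            CellSpec(20.0, 0.5, frozenset({"CD4", "CCR5"}), "epidermis"),
            CellSpec(20.0, 0.5, frozenset({"CD4", "CCR5"}), "epidermis"),
            CellSpec(20.0, 0.5, frozenset({"CD4"}), "epidermis"),
            CellSpec(20.0, 0.5, frozenset({"CCR5"}), "epidermis"),
        ),
    )
    section, truth = generate_section(spec)
    epi = truth.region("epidermis")
    _, cd4 = detect_cells(section.channels["blue"], epi, CD4_GATE)
    _, ccr5 = detect_cells(section.channels["far_red"], epi, CCR5_GATE)
    ndp = double_positive(cd4, ccr5, 3.0)
    assert ndp == sum(1 for c in truth.true_cells if c.markers == {"CD4", "CCR5"}) == 2


def test_empty_region_is_an_error():
    with pytest.raises(ValidationError):
        detect_cells(np.ones((5, 5)), RegionMask(np.zeros((5, 5), bool), "epidermis", 1.0), CD4_GATE)
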