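"""Epidermis delineation and nuclei detection.

The epidermis is outlined from its red-channel autofluorescence by
global thresholding (Otsu by default, or a fixed manual AU value),
followed by removal of small objects and hole filling.  Externally
provided outline masks — the stand-in for manual H&E outlining — are
loaded verbatim.  Nuclei are counted as connected components of the
nuclear counterstain whose centroid lies inside a region of interest;
touching nuclei are *not* declumped (documented limitation).

8-neighbour connectivity is used for all connected-component labelling
throughout the package.
"""

from __future__ import annotations

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters, measure, morphology

from ._core import ImageSection, InputError, RegionMask, SegmentationError

#: Connected-component connectivity used everywhere (8-neighbour).
CONNECTIVITY = 2
_NDI_STRUCT = np.ones((3, 3), dtype=bool)

DEFAULT_MIN_OBJECT_AREA_UM2 = 500.0
DEFAULT_NUCLEUS_MIN_AREA_UM2 = 5.0
DEFAULT_NUCLEUS_THRESHOLD = 0.5


def _threshold_value(image: np.ndarray, method) -> float:
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "otsu":
        if np.ptp(image) == 0:
            # constant image: no foreground/background separation possible
            return float(image.max())
        return float(filters.threshold_otsu(image))
    raise InputError(f"unknown threshold method {method!r}")


def segment_epidermis(
    section: ImageSection,
    method="otsu",
    min_object_area_um2: float = DEFAULT_MIN_OBJECT_AREA_UM2,
    channel: str = "red",
) -> RegionMask:
    """Outline the epidermis from red-channel autofluorescence.

    Parameters
    ----------
    method:
        ``"otsu"`` or a fixed AU threshold in [0, 1].  Foreground is
        strictly above the threshold.
    min_object_area_um2:
        Objects smaller than this are discarded before hole filling;
        the epidermis is a single large structure.

    Raises
    ------
    SegmentationError
        If no foreground survives ("no epidermis detected").
    """
    img = section.channel(channel)
    thr = _threshold_value(img, method)
    mask = img > thr
    min_px = int(np.ceil(min_object_area_um2 / section.pixel_size_um**2))
    if min_px > 1:
        # remove objects with area < min_px (max_size removes areas <= value)
        mask = morphology.remove_small_objects(
            mask, max_size=min_px - 1, connectivity=CONNECTIVITY
        )
    mask = ndimage.binary_fill_holes(mask, structure=_NDI_STRUCT)
    if not mask.any():
        raise SegmentationError("no epidermis detected (empty foreground)")
    return RegionMask(mask=mask, region_role="epidermis", pixel_size_um=section.pixel_size_um)


def load_outline_mask(
    path,
    pixel_size_um: float,
    region_role: str = "epidermis",
    expected_shape: tuple[int, int] | None = None,
) -> RegionMask:
    """Load a manually-delineated outline mask (single-channel TIFF, any
    nonzero pixel = inside).  The mask is trusted input and preserved
    verbatim — no cleanup."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim != 2:
        raise InputError(f"{path}: expected a single-channel mask, got shape {arr.shape}")
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise InputError(
            f"{path}: mask shape {arr.shape} does not match section {tuple(expected_shape)}"
        )
    mask = arr > 0
    if not mask.any():
        raise InputError(f"{path}: empty region")
    return RegionMask(mask=mask, region_role=region_role, pixel_size_um=pixel_size_um)


def save_mask(path, region: RegionMask) -> None:
    """Write a mask as 0/255 single-channel TIFF."""
    tifffile.imwrite(path, (region.mask.astype(np.uint8) * 255))


def detect_nuclei(
    section: ImageSection,
    within: RegionMask,
    threshold: float = DEFAULT_NUCLEUS_THRESHOLD,
    min_area_um2: float = DEFAULT_NUCLEUS_MIN_AREA_UM2,
    channel: str = "nuclear",
) -> tuple[int, np.ndarray]:
    """Count stained nuclei whose centroid lies inside ``within``.

    Returns ``(count, centroids)`` with centroids as an (n, 2) array of
    (row, col) pixel coordinates.  Objects below ``min_area_um2`` are
    rejected as noise.  Touching nuclei merge into one detection (no
    declumping).  Zero nuclei is a valid result.
    """
    img = section.channel(channel)
    if img.shape != within.mask.shape:
        raise InputError("region mask shape does not match section")
    labels = measure.label(img > threshold, connectivity=CONNECTIVITY)
    min_px = min_area_um2 / section.pixel_size_um**2
    centroids = []
    for prop in measure.regionprops(labels):
        if prop.area < min_px:
            continue
        r, c = prop.centroid
        if within.mask[int(round(r)) if round(r) < img.shape[0] else img.shape[0] - 1,
                       int(round(c)) if round(c) < img.shape[1] else img.shape[1] - 1]:
            centroids.append((r, c))
    cents = np.asarray(centroids, dtype=float).reshape(-1, 2)
    return len(centroids), cents
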