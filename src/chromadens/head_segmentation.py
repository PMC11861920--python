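"""Sperm-head segmentation: thresholding, component filtering, erosion.

Stained heads are darker than the smear background, so the foreground of the
histogram threshold is the *dark* side.  Connected components are filtered by
area, solidity and eccentricity to discard tails, debris and fused heads,
then each surviving head loses its perimeter pixels to a morphological
erosion before any intensity statistics are computed (per-head mean and
coefficient of variation are taken over the eroded mask).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .imaging_io import IntensityImage

log = logging.getLogger(__name__)


class DegenerateHistogramError(ValueError):
    """Otsu thresholding on an (effectively) constant image."""


class HeadTooSmallError(ValueError):
    """Erosion removed every pixel of the head."""


@dataclass
class SegmentationParams:
    """Tunables for head extraction; defaults suit bovine heads at ~0.1 um/px.

    Bovine sperm heads are compact ovals; tails are thin and highly
    eccentric, which the ``max_eccentricity`` bound rejects, and touching
    heads fuse into low-solidity blobs rejected by ``min_solidity``.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area_px: int = 400
    max_area_px: int = 20000
    min_solidity: float = 0.85
    max_eccentricity: float = 0.95
    erosion_radius_px: int = 1
    erosion_iterations: int = 1
    exclude_border: bool = True
    fill_holes: bool = False

    def __post_init__(self) -> None:
        if self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and not (
            self.fixed_threshold is not None and 0 < self.fixed_threshold < 1
        ):
            raise ValueError("fixed threshold must lie in (0, 1)")
        if self.erosion_iterations < 1:
            raise ValueError("erosion_iterations must be >= 1")
        if self.erosion_radius_px < 1:
            raise ValueError("erosion_radius_px must be >= 1")


@dataclass
class SpermHead:
    """One segmented head, stored as a bounding-box-local boolean mask."""

    label: int
    mask: np.ndarray          # bool, local to bbox
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    image_shape: tuple[int, int]
    centroid: tuple[float, float]
    area_px: int
    mean_intensity: float
    cv_intensity: float

    def coords(self) -> np.ndarray:
        """Global (row, col) coordinates of the mask pixels."""
        local = np.argwhere(self.mask)
        return local + np.array(self.bbox[:2])

    def linear_indices(self) -> np.ndarray:
        """Mask pixels as raveled indices in the full image frame."""
        c = self.coords()
        return c[:, 0] * self.image_shape[1] + c[:, 1]

    def full_mask(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass
class LabeledHeads:
    heads: list[SpermHead]
    label_image: np.ndarray
    params_used: SegmentationParams
    threshold: float
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.heads)


def threshold_histogram(
    img: IntensityImage, params: SegmentationParams
) -> tuple[np.ndarray, float]:
    """Binary foreground mask of pixels darker than the histogram threshold.

    Otsu's between-class-variance maximization over 256 bins by default; a
    fixed threshold may be supplied instead.  Returns (mask, threshold).
    """
    values = img.values
    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)
    else:
        if np.ptp(values) == 0:
            raise DegenerateHistogramError("constant image has no histogram valley")
        thr = float(threshold_otsu(values, nbins=256))
    return values < thr, thr


def erode_head(mask: np.ndarray, radius_px: int, iterations: int) -> np.ndarray:
    """Morphological erosion by a disk structuring element, iterated.

    Radius 1 uses the 4-connected cross footprint (the digital disk of
    radius 1).  Raises :class:`HeadTooSmallError` if the mask vanishes.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not mask.any():
        raise ValueError("mask is empty")
    footprint = disk(radius_px)
    out = np.asarray(mask, dtype=bool)
    for _ in range(iterations):
        out = ndimage.binary_erosion(out, structure=footprint, border_value=0)
        if not out.any():
            raise HeadTooSmallError("erosion removed the whole head")
    return out


def extract_heads(
    mask: np.ndarray, img: IntensityImage, params: SegmentationParams
) -> LabeledHeads:
    """Extract filtered, eroded sperm heads from a binary foreground mask.

    8-connected components are filtered by area, solidity and eccentricity
    (and optionally by border contact); survivors are eroded, relabelled
    1..n in raster order of their centroids, and given mean / CV intensity
    statistics over the eroded mask.  Zero survivors is a valid result;
    every rejection is recorded with its reason.
    """
    if mask.shape != img.values.shape:
        raise ValueError("mask and image shapes differ")
    work = np.asarray(mask, dtype=bool)
    if params.fill_holes:
        work = ndimage.binary_fill_holes(work)
    labels = measure.label(work, connectivity=2)
    rejected: list[tuple[int, str]] = []
    survivors = []
    h, w = work.shape
    for rp in measure.regionprops(labels):
        reasons = []
        if rp.area < params.min_area_px:
            reasons.append(f"area {rp.area} < {params.min_area_px}")
        if rp.area > params.max_area_px:
            reasons.append(f"area {rp.area} > {params.max_area_px}")
        if rp.solidity < params.min_solidity:
            reasons.append(f"solidity {rp.solidity:.3f} < {params.min_solidity}")
        if rp.eccentricity > params.max_eccentricity:
            reasons.append(f"eccentricity {rp.eccentricity:.3f} > {params.max_eccentricity}")
        if params.exclude_border:
            r0, c0, r1, c1 = rp.bbox
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                reasons.append("touches image border")
        if reasons:
            rejected.append((rp.label, "; ".join(reasons)))
            log.debug("rejected component %d: %s", rp.label, reasons)
            continue
        survivors.append(rp)

    heads: list[SpermHead] = []
    for rp in survivors:
        try:
            eroded = erode_head(
                rp.image, params.erosion_radius_px, params.erosion_iterations
            )
        except HeadTooSmallError:
            rejected.append((rp.label, "vanished under erosion"))
            continue
        # keep the largest piece if erosion disconnected the mask
        sub = measure.label(eroded, connectivity=2)
        if sub.max() > 1:
            sizes = np.bincount(sub.ravel())[1:]
            eroded = sub == (int(np.argmax(sizes)) + 1)
            log.debug("component %d split under erosion; kept largest piece", rp.label)
        r0, c0, r1, c1 = rp.bbox
        local = np.argwhere(eroded)
        centroid = (local[:, 0].mean() + r0, local[:, 1].mean() + c0)
        vals = img.values[r0:r1, c0:c1][eroded]
        mean = float(vals.mean())
        # population std (divisor n); exactly 0 for a constant head
        std = 0.0 if np.ptp(vals) == 0 else float(vals.std())
        heads.append(
            SpermHead(
                label=0,
                mask=eroded,
                bbox=rp.bbox,
                image_shape=work.shape,
                centroid=centroid,
                area_px=int(eroded.sum()),
                mean_intensity=mean,
                cv_intensity=std / mean if mean > 0 else 0.0,
            )
        )

    heads.sort(key=lambda hd: (hd.centroid[0], hd.centroid[1]))
    label_image = np.zeros(work.shape, dtype=np.int32)
    for i, head in enumerate(heads, start=1):
        head.label = i
        r0, c0, r1, c1 = head.bbox
        label_image[r0:r1, c0:c1][head.mask] = i
    return LabeledHeads(
        heads=heads,
        label_image=label_image,
        params_used=params,
        threshold=float("nan"),
        rejected=rejected,
    )
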