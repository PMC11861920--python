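"""Reference selection and per-head relative-deficit densitometry.

The normally compacted stain level of a smear is estimated from the sample
itself: the K (default 10) lightest and most homogeneous heads — highest
mean pixel value, lowest coefficient of variation, combined by equal-weight
rank-sum — define the reference intensity.  Each head's pixels are then
expressed as a relative deficit against that single sample-wide reference,

    deficit(p) = (reference - I(p)) / reference,

smoothed with a truncated Gaussian (sigma = 2, truncation radius = 5,
renormalized over in-mask support), and thresholded at a stain-specific tau:
7% for toluidine blue, 4% for the Feulgen reaction.  Surviving 8-connected
components above a minimum size are the decompacted (altered) regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .head_segmentation import LabeledHeads, SpermHead
from .imaging_io import IntensityImage, Outline, Stain, trace_boundaries

#: Stain-specific deficit thresholds: regions this far below reference are altered.
DEFAULT_TAU = {Stain.TB: 0.07, Stain.FR: 0.04}


class EmptySampleError(ValueError):
    """No heads to work with."""


@dataclass
class ReferenceSet:
    head_labels: list[int]
    reference_intensity: float
    K: int = 10


@dataclass
class DeficitMap:
    """Per-pixel relative deficit for one head (bounding-box local)."""

    head_label: int
    deficit: np.ndarray       # float, local to bbox; meaningful on mask only
    mask: np.ndarray          # bool, local to bbox
    bbox: tuple[int, int, int, int]
    image_shape: tuple[int, int]
    smoothed: bool = False


@dataclass
class AlteredRegionSet:
    """Thresholded altered regions of one head."""

    head_label: int
    components: list[np.ndarray]  # local (row, col) coords per component
    altered_mask: np.ndarray      # bool, local to bbox
    bbox: tuple[int, int, int, int]
    image_shape: tuple[int, int]
    head_area_px: int
    altered_fraction: float
    tau: float
    min_component_px: int

    def component_areas(self) -> list[int]:
        return [len(c) for c in self.components]

    def altered_linear_indices(self) -> np.ndarray:
        local = np.argwhere(self.altered_mask)
        g = local + np.array(self.bbox[:2])
        return g[:, 0] * self.image_shape[1] + g[:, 1]


def select_reference(heads: LabeledHeads | list[SpermHead], K: int = 10) -> ReferenceSet:
    """Pick the K lightest, most homogeneous heads and pool their means.

    Heads are ranked by mean intensity (descending) and by coefficient of
    variation (ascending); the two ranks are summed with equal weight and
    the K lowest scores win.  Ties break toward higher mean intensity, then
    lower label.  The reference intensity is the mean of the selected heads'
    mean intensities.
    """
    head_list = heads.heads if isinstance(heads, LabeledHeads) else list(heads)
    n = len(head_list)
    if n == 0:
        raise EmptySampleError("cannot select a reference from zero heads")
    if n < K:
        warnings.warn(
            f"only {n} heads available for a reference of K={K}; using all",
            stacklevel=2,
        )
    means = np.array([h.mean_intensity for h in head_list])
    cvs = np.array([h.cv_intensity for h in head_list])
    labels = np.array([h.label for h in head_list])
    score = rankdata(-means, method="average") + rankdata(cvs, method="average")
    order = np.lexsort((labels, -means, score))
    chosen = order[: min(K, n)]
    ref = float(means[chosen].mean())
    return ReferenceSet(
        head_labels=[int(labels[i]) for i in chosen], reference_intensity=ref, K=K
    )


def deficit_map(img: IntensityImage, head: SpermHead, ref: ReferenceSet) -> DeficitMap:
    """Relative intensity deficit of each mask pixel versus the reference.

    Pixels lighter than the reference keep their negative deficit.
    """
    if ref.reference_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    r0, c0, r1, c1 = head.bbox
    local = img.values[r0:r1, c0:c1]
    deficit = (ref.reference_intensity - local) / ref.reference_intensity
    return DeficitMap(
        head_label=head.label,
        deficit=deficit,
        mask=head.mask,
        bbox=head.bbox,
        image_shape=head.image_shape,
        smoothed=False,
    )


def gaussian_kernel(sigma: float = 2.0, radius: int = 5) -> np.ndarray:
    """Discrete 2-D Gaussian truncated at ``radius`` (window 2*radius+1), sum 1."""
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth_deficit(dm: DeficitMap, sigma: float = 2.0, radius: int = 5) -> DeficitMap:
    """Mask-restricted Gaussian smoothing of the deficit map.

    Pixels outside the head mask carry zero weight and the kernel is
    renormalized over the in-mask support, so a constant field is preserved
    exactly, even at the mask boundary.
    """
    if dm.smoothed:
        raise ValueError("deficit map is already smoothed")
    kernel = gaussian_kernel(sigma, radius)
    maskf = dm.mask.astype(float)
    num = ndimage.convolve(dm.deficit * maskf, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(maskf, kernel, mode="constant", cval=0.0)
    out = np.zeros_like(dm.deficit)
    np.divide(num, den, out=out, where=dm.mask)
    return DeficitMap(
        head_label=dm.head_label,
        deficit=out,
        mask=dm.mask,
        bbox=dm.bbox,
        image_shape=dm.image_shape,
        smoothed=True,
    )


def default_min_component_px(head_area_px: int) -> int:
    """Minimum altered-component size: max(5, 0.5% of head area)."""
    return max(5, int(round(0.005 * head_area_px)))


def altered_regions(
    dm: DeficitMap, tau: float | None = None, min_component_px: int | None = None,
    stain: Stain | None = None,
) -> AlteredRegionSet:
    """Threshold the smoothed deficit at tau and keep sizeable components.

    ``tau`` defaults from the stain tag (TB 0.07, FR 0.04).  Components are
    8-connected; those below ``min_component_px`` (default max(5, 0.5% of
    the head area)) are dropped before the altered fraction is computed.
    """
    if not dm.smoothed:
        raise ValueError("altered_regions expects a smoothed deficit map")
    if tau is None:
        if stain is None or stain not in DEFAULT_TAU:
            raise ValueError("tau not given and stain has no default threshold")
        tau = DEFAULT_TAU[stain]
    if not (0 < tau < 1):
        raise ValueError("tau must lie in (0, 1)")
    head_area = int(dm.mask.sum())
    if min_component_px is None:
        min_component_px = default_min_component_px(head_area)
    above = (dm.deficit >= tau) & dm.mask
    labels, n = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    components = []
    kept = np.zeros_like(above)
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() >= min_component_px:
            components.append(np.argwhere(comp))
            kept |= comp
    return AlteredRegionSet(
        head_label=dm.head_label,
        components=components,
        altered_mask=kept,
        bbox=dm.bbox,
        image_shape=dm.image_shape,
        head_area_px=head_area,
        altered_fraction=float(kept.sum()) / head_area if head_area else 0.0,
        tau=float(tau),
        min_component_px=min_component_px,
    )


def boundary_outlines(ars: AlteredRegionSet) -> list[Outline]:
    """Closed pixel-edge polylines around each altered component (global coords)."""
    outlines: list[Outline] = []
    offset = ars.bbox[:2]
    for coords in ars.components:
        local = np.zeros_like(ars.altered_mask)
        local[coords[:, 0], coords[:, 1]] = True
        outlines.extend(trace_boundaries(local, offset=offset))
    return outlines
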