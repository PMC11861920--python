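"""Location-based decompaction taxonomy, TEM grading and AO calling.

TB/FR heads are classified by *where* their altered (decompacted) regions
sit: a head frame (principal axes, base at the broader end) partitions the
mask into four quartiles Q1..Q4 from base to apex plus an axial band, and a
fixed-precedence decision list maps regional coverage onto the categories

    N    normal (altered fraction below f_min)
    TD   total decompaction
    BAD  base-apex decompaction
    BHD  basal half decompaction
    BD   base decompaction
    CAD  central axis decompaction
    DD   dispersed decompaction (fallback)

TEM sections are graded G1-G4 from the count of small clear (electron-
lucent) spots and the largest clear-region fraction; an explicit N0 grade is
reported for heads with no findings so that G1-G4 percentages stay
comparable across samples.  AO heads are called intact or denatured from the
red share of their red+green fluorescence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .head_segmentation import SpermHead
from .densitometry import AlteredRegionSet
from .imaging_io import IntensityImage, Micrograph, Stain

log = logging.getLogger(__name__)


class Category(str, Enum):
    N = "N"
    BD = "BD"
    BHD = "BHD"
    CAD = "CAD"
    BAD = "BAD"
    TD = "TD"
    DD = "DD"


class TEMGrade(str, Enum):
    N0 = "N0"
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"
    G4 = "G4"


class GeometryError(ValueError):
    """Degenerate head mask (too few or collinear pixels)."""


class UnstainedHeadError(ValueError):
    """AO head with zero red+green signal."""


@dataclass
class HeadFrame:
    """Orthonormal head axes; the major axis points from base to apex."""

    major_axis: np.ndarray
    minor_axis: np.ndarray
    center: tuple[float, float]
    length_px: float
    width_px: float
    base_sign: int = 1
    ambiguous_base: bool = False


@dataclass
class RegionPartition:
    """Quartiles along the major axis (base -> apex) plus the axial band.

    Pixel sets are stored as raveled indices into the full image frame so
    they intersect cheaply with altered-region masks.
    """

    quartiles: list[np.ndarray]      # Q1..Q4 linear indices
    axial_band: np.ndarray           # linear indices
    head_indices: np.ndarray
    image_shape: tuple[int, int]

    @property
    def basal_half(self) -> np.ndarray:
        return np.concatenate([self.quartiles[0], self.quartiles[1]])


@dataclass
class PatternRules:
    """Decision-list thresholds for the location taxonomy.

    The taxonomy's semantics are location containment; these cutoffs make
    that operational and every one is a config key.
    """

    f_min: float = 0.02                    # below -> N
    td_min_fraction: float = 0.75          # altered fraction -> TD
    bad_end_coverage: float = 0.25         # coverage in both Q1 and Q4 -> BAD
    bhd_basal_altered_fraction: float = 0.80
    bhd_basal_coverage: float = 0.40
    bd_q1_altered_fraction: float = 0.80
    cad_axial_altered_fraction: float = 0.80


@dataclass
class PatternCall:
    head_label: int
    category: Category
    features: dict = field(default_factory=dict)


@dataclass
class TEMHeadObservation:
    head_label: int
    n_clear_spots: int
    largest_clear_fraction: float
    grade: TEMGrade | None = None


@dataclass
class AOHeadObservation:
    head_label: int
    mean_red: float
    mean_green: float
    red_fraction: float
    call: str  # "intact" | "denatured"


@dataclass
class SmearSummary:
    modality: str
    n_heads: int
    counts: dict
    percent_altered: float


# ---------------------------------------------------------------------------
# Head geometry
# ---------------------------------------------------------------------------

def head_axes(head: SpermHead) -> HeadFrame:
    """Principal axes of the head mask; base = broader major-axis end.

    Axes come from the second central moments of the pixel coordinates.  The
    base end is the major-axis end whose terminal 25% of the length holds
    more mask area (i.e. is broader); the major axis is oriented to point
    base -> apex.  Near-circular heads get a deterministic orientation and
    an ambiguity flag.
    """
    coords = head.coords().astype(float)
    if len(coords) < 3:
        raise GeometryError("head mask has fewer than 3 pixels")
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-9:
        raise GeometryError("collinear head mask")
    major = evecs[:, 1]
    minor = evecs[:, 0]
    # deterministic sign convention before the base rule
    if major[0] < 0 or (major[0] == 0 and major[1] < 0):
        major = -major
    t = centered @ major
    v = centered @ minor
    length = float(t.max() - t.min() + 1.0)
    width = float(v.max() - v.min() + 1.0)

    lo_slab = t <= t.min() + 0.25 * length
    hi_slab = t >= t.max() - 0.25 * length
    lo_area, hi_area = int(lo_slab.sum()), int(hi_slab.sum())
    ambiguous = False
    denom = max(lo_area, hi_area)
    if denom == 0 or abs(lo_area - hi_area) / denom < 0.01:
        ambiguous = True
        log.debug("head %d: base/apex orientation ambiguous", head.label)
    elif hi_area > lo_area:
        # broad end sits at positive t; flip so the base is at negative t
        major = -major
        minor = -minor
    return HeadFrame(
        major_axis=major,
        minor_axis=minor,
        center=(float(center[0]), float(center[1])),
        length_px=length,
        width_px=width,
        base_sign=1,
        ambiguous_base=ambiguous,
    )


def region_partition(frame: HeadFrame, head: SpermHead) -> RegionPartition:
    """Assign each mask pixel to a quartile (base -> apex) and the axial band.

    Quartile boundaries are the 25/50/75 percentiles of the pixels' signed
    projections onto the major axis; the axial band is every pixel whose
    perpendicular distance to the major-axis line is at most width/6.
    """
    coords = head.coords().astype(float)
    lin = head.linear_indices()
    centered = coords - np.array(frame.center)
    t = centered @ frame.major_axis
    v = centered @ frame.minor_axis
    q25, q50, q75 = np.percentile(t, [25, 50, 75])
    idx = np.searchsorted([q25, q50, q75], t, side="right")
    quartiles = [lin[idx == k] for k in range(4)]
    band = lin[np.abs(v) <= frame.width_px / 6.0]
    return RegionPartition(
        quartiles=quartiles,
        axial_band=band,
        head_indices=lin,
        image_shape=head.image_shape,
    )


# ---------------------------------------------------------------------------
# TB/FR location taxonomy
# ---------------------------------------------------------------------------

def classify_pattern(
    ars: AlteredRegionSet, part: RegionPartition, rules: PatternRules | None = None
) -> PatternCall:
    """Decision list N -> TD -> BAD -> BHD -> BD -> CAD -> DD.

    Every altered head matching no positive rule falls through to DD
    (dispersed decompaction), so the list is total and each head receives
    exactly one category.
    """
    rules = rules or PatternRules()
    altered = ars.altered_linear_indices()
    n_alt = len(altered)
    af = ars.altered_fraction

    q_cov = []
    q_frac = []
    for q in part.quartiles:
        inter = np.intersect1d(altered, q, assume_unique=False).size
        q_cov.append(inter / len(q) if len(q) else 0.0)
        q_frac.append(inter / n_alt if n_alt else 0.0)
    basal = part.basal_half
    basal_inter = np.intersect1d(altered, basal).size
    basal_cov = basal_inter / len(basal) if len(basal) else 0.0
    basal_frac = basal_inter / n_alt if n_alt else 0.0
    axial_inter = np.intersect1d(altered, part.axial_band).size
    axial_frac = axial_inter / n_alt if n_alt else 0.0
    spread = sum(1 for f in q_frac if f > 0)

    features = {
        "altered_fraction": af,
        "quartile_coverage": q_cov,
        "quartile_altered_fraction": q_frac,
        "basal_coverage": basal_cov,
        "basal_altered_fraction": basal_frac,
        "axial_altered_fraction": axial_frac,
        "n_components": len(ars.components),
        "quartile_spread": spread,
    }

    if af < rules.f_min:
        cat = Category.N
    elif af >= rules.td_min_fraction:
        cat = Category.TD
    elif q_cov[0] >= rules.bad_end_coverage and q_cov[3] >= rules.bad_end_coverage:
        cat = Category.BAD
    elif (
        basal_frac >= rules.bhd_basal_altered_fraction
        and basal_cov >= rules.bhd_basal_coverage
    ):
        cat = Category.BHD
    elif q_frac[0] >= rules.bd_q1_altered_fraction:
        cat = Category.BD
    elif axial_frac >= rules.cad_axial_altered_fraction:
        cat = Category.CAD
    else:
        cat = Category.DD
    return PatternCall(head_label=ars.head_label, category=cat, features=features)


# ---------------------------------------------------------------------------
# TEM grading
# ---------------------------------------------------------------------------

def detect_clear_regions(
    img: IntensityImage,
    head: SpermHead,
    clear_tau: float = 0.60,
    small_spot_max_fraction: float = 0.02,
) -> TEMHeadObservation:
    """Find electron-lucent (clear) regions inside a TEM head section.

    TEM polarity is inverted relative to the stains: condensed chromatin is
    dark and decompacted areas are light, so clear pixels are those with
    normalized intensity >= ``clear_tau``.  Components at most
    ``small_spot_max_fraction`` of the head section count as small spots;
    the largest bigger component gives ``largest_clear_fraction`` (0 if
    there is none).
    """
    from scipy import ndimage

    r0, c0, r1, c1 = head.bbox
    local = img.values[r0:r1, c0:c1]
    clear = (local >= clear_tau) & head.mask
    labels, n = ndimage.label(clear, structure=np.ones((3, 3), dtype=int))
    head_area = int(head.mask.sum())
    n_spots = 0
    largest = 0.0
    for i in range(1, n + 1):
        frac = float((labels == i).sum()) / head_area
        if frac <= small_spot_max_fraction:
            n_spots += 1
        else:
            largest = max(largest, frac)
    return TEMHeadObservation(
        head_label=head.label, n_clear_spots=n_spots, largest_clear_fraction=largest
    )


def grade_tem(obs: TEMHeadObservation) -> TEMGrade:
    """Closed-form chromatin grade from clear-spot count and clear fraction.

    G1: up to three small clear spots; G2: up to six small spots or a
    clearer region up to 1/4 of the head; G3: more than six spots or a
    region up to half; G4: a clear area over half the head.  N0 marks a head
    with no findings.
    """
    n, f = obs.n_clear_spots, obs.largest_clear_fraction
    if f > 0.5:
        grade = TEMGrade.G4
    elif n > 6 or f > 0.25:
        grade = TEMGrade.G3
    elif n >= 4 or f > 0:
        grade = TEMGrade.G2
    elif 1 <= n <= 3:
        grade = TEMGrade.G1
    else:
        grade = TEMGrade.N0
    obs.grade = grade
    return grade


# ---------------------------------------------------------------------------
# Acridine orange calling
# ---------------------------------------------------------------------------

def classify_ao(
    m: Micrograph, head: SpermHead, red_fraction_threshold: float = 0.40,
    red_channel: int = 0, green_channel: int = 1,
) -> AOHeadObservation:
    """Intact/denatured call from the red share of red+green fluorescence.

    Double-stranded DNA fluoresces green, denatured single-stranded DNA red;
    yellow/orange (red overlapping green) marks denaturation onset, encoded
    as red_fraction = R / (R + G) >= threshold (boundary inclusive).
    """
    if m.pixels.ndim != 3 or m.pixels.shape[2] != 3:
        raise ValueError("AO classification requires a 3-channel micrograph")
    full_scale = float(2**m.bit_depth - 1)
    r0, c0, r1, c1 = head.bbox
    local = m.pixels[r0:r1, c0:c1].astype(np.float64) / full_scale
    mean_red = float(local[:, :, red_channel][head.mask].mean())
    mean_green = float(local[:, :, green_channel][head.mask].mean())
    total = mean_red + mean_green
    if total <= 0:
        raise UnstainedHeadError(f"head {head.label} has no red/green signal")
    rf = mean_red / total
    call = "denatured" if rf >= red_fraction_threshold else "intact"
    return AOHeadObservation(
        head_label=head.label,
        mean_red=mean_red,
        mean_green=mean_green,
        red_fraction=rf,
        call=call,
    )


# ---------------------------------------------------------------------------
# Smear summary
# ---------------------------------------------------------------------------

class EmptySampleError(ValueError):
    pass


def summarize_smear(calls: list) -> SmearSummary:
    """Per-category counts and the percentage of altered heads.

    Works on one modality at a time: pattern calls (altered = category != N),
    TEM observations (altered = grade != N0) or AO observations (altered =
    denatured).
    """
    if not calls:
        raise EmptySampleError("cannot summarize an empty smear")
    first = calls[0]
    if any(type(c) is not type(first) for c in calls):
        raise ValueError("summarize_smear expects a single modality")
    if isinstance(first, PatternCall):
        modality = "decompaction"
        keys = [c.category.value for c in calls]
        normal = sum(1 for k in keys if k == Category.N.value)
    elif isinstance(first, TEMHeadObservation):
        modality = "tem"
        keys = [(c.grade or grade_tem(c)).value for c in calls]
        normal = sum(1 for k in keys if k == TEMGrade.N0.value)
    elif isinstance(first, AOHeadObservation):
        modality = "ao"
        keys = [c.call for c in calls]
        normal = sum(1 for k in keys if k == "intact")
    else:
        raise TypeError(f"unsupported call type {type(first)}")
    n = len(calls)
    counts = dict(Counter(keys))
    return SmearSummary(
        modality=modality,
        n_heads=n,
        counts=counts,
        percent_altered=100.0 * (n - normal) / n,
    )
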