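"""Synthetic micrograph phantoms with exact ground truth.

Phantoms are statistical test doubles for stained-smear (TB/FR), acridine
orange (AO) and TEM imagery: paddle-shaped head masks (broad base, tapered
apex) on a uniform background, with decompaction patterns stamped according
to the location taxonomy, Gaussian pixel noise, and optional tail-like
debris.  Stamps are cut against the analyzer's own head frame and quartile
partition of the ground-truth mask, with a safety margin inside every rule
boundary, so the assigned category is recoverable by construction.  No
optics are modelled (no PSF, no chromatic effects).

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
generator seeded from the spec, so a fixed seed reproduces images and
ground truth bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .head_segmentation import SpermHead
from .imaging_io import Micrograph, Stain
from .pattern_classification import Category, TEMGrade, head_axes

PATTERN_CATEGORIES = [c.value for c in Category]
TEM_GRADES = [g.value for g in TEMGrade]
AO_STATES = ["intact", "denatured"]

#: margin (px) kept between a stamp and the rule boundary it must not cross
STAMP_MARGIN = 2.0


class InfeasibleSpecError(ValueError):
    """Head placement failed within the attempt cap."""


@dataclass
class PhantomSpec:
    """Study-like generation conditions for one synthetic smear image.

    Geometry approximates bovine heads at the magnification of a x100
    objective with a x2 intermediate lens (head length ~9 um -> ~55 px).
    Intensities follow each modality's polarity: TB/FR heads darker than
    background, TEM heads dark with light (electron-lucent) clear regions,
    AO heads bright on a dark field.
    """

    image_size: tuple[int, int] = (512, 512)
    n_heads: int = 8
    head_axes_px: tuple[tuple[float, float], tuple[float, float]] = ((26.0, 30.0), (13.0, 15.0))
    background_intensity: float = 0.92
    head_intensity: float = 0.75
    assignments: Sequence[str] | None = None   # category / grade / AO state per head
    stain: Stain = Stain.TB
    deficit_depth: float = 0.15
    noise_sigma: float = 0.01
    debris: int = 0
    taper: float = 0.30
    seed: int = 0
    # TEM-specific levels
    tem_background: float = 0.75
    tem_head_intensity: float = 0.25
    tem_clear_intensity: float = 0.85

    def __post_init__(self) -> None:
        self.stain = Stain(self.stain)
        if not (0 < self.deficit_depth < 1):
            raise ValueError("deficit_depth must lie in (0, 1)")
        if self.assignments is not None and len(self.assignments) != self.n_heads:
            raise ValueError("one assignment per head required")


@dataclass
class GroundTruthHead:
    label: int
    centroid: tuple[float, float]
    mask: np.ndarray                      # bool, local to bbox
    bbox: tuple[int, int, int, int]
    image_shape: tuple[int, int]
    assignment: str
    stamp_mask: np.ndarray                # bool, local to bbox
    stamped_fraction: float               # |stamp| / |mask|, exact mask ratio

    def as_head(self) -> SpermHead:
        """View the ground-truth mask as a SpermHead (no intensity stats)."""
        return SpermHead(
            label=self.label,
            mask=self.mask,
            bbox=self.bbox,
            image_shape=self.image_shape,
            centroid=self.centroid,
            area_px=int(self.mask.sum()),
            mean_intensity=0.0,
            cv_intensity=0.0,
        )


@dataclass
class GroundTruth:
    heads: list[GroundTruthHead]
    spec: PhantomSpec

    def __len__(self) -> int:
        return len(self.heads)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _paddle_mask(
    a: float, b: float, theta: float, taper: float
) -> tuple[np.ndarray, int]:
    """Rasterize a paddle (base-broad, apex-tapered ellipse); returns (mask, half)."""
    half = int(np.ceil(a)) + 2
    n = 2 * half + 1
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    d = np.array([np.cos(theta), np.sin(theta)])
    u = rr * d[0] + cc * d[1]
    v = -rr * d[1] + cc * d[0]
    s = 1.0 - taper * ((np.clip(u / a, -1, 1) + 1.0) / 2.0) ** 2
    mask = (u / a) ** 2 + (v / (b * s)) ** 2 <= 1.0
    return mask, half


def _frame_coords(mask: np.ndarray, bbox, image_shape):
    """Analyzer head frame + per-pixel (t, v) projections for a GT mask."""
    coords_local = np.argwhere(mask)
    centroid = (
        coords_local[:, 0].mean() + bbox[0],
        coords_local[:, 1].mean() + bbox[1],
    )
    head = SpermHead(
        label=0, mask=mask, bbox=bbox, image_shape=image_shape,
        centroid=centroid, area_px=int(mask.sum()),
        mean_intensity=0.5, cv_intensity=0.0,
    )
    frame = head_axes(head)
    coords = head.coords().astype(float)
    centered = coords - np.array(frame.center)
    t = centered @ frame.major_axis
    v = centered @ frame.minor_axis
    return frame, coords_local, t, v


def _slab_cut(t: np.ndarray, target_count: int, cap: float) -> np.ndarray:
    """Boolean slab t <= cut holding ~target_count pixels, never past cap."""
    target_count = max(1, min(target_count, len(t)))
    cut = min(np.sort(t)[target_count - 1], cap)
    slab = t <= cut
    if not slab.any():
        slab = t <= t.min() + 1.0
    return slab


def stamp_pattern(
    mask: np.ndarray,
    bbox: tuple[int, int, int, int],
    image_shape: tuple[int, int],
    category: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stamped-region mask (local to bbox) realizing one taxonomy category.

    Templates, cut against the analyzer's quartile partition of this mask:
    BD a basal cap (~55% of Q1); BHD a slab over ~72% of the basal half;
    CAD a band within width/6 of the axis over the inner 80% of the length;
    BAD caps at both ends (~50% of Q1 and Q4); TD the whole head; DD 3-5
    small off-axis blobs in >= 3 quartiles; N stamps nothing.
    """
    cat = Category(category)
    if cat is Category.N:
        return np.zeros_like(mask)
    if cat is Category.TD:
        return mask.copy()

    frame, coords_local, t, v = _frame_coords(mask, bbox, image_shape)
    q25, q50, q75 = np.percentile(t, [25, 50, 75])
    stamp_sel = np.zeros(len(t), dtype=bool)

    if cat is Category.BD:
        n_q1 = int((t <= q25).sum())
        stamp_sel = _slab_cut(t, int(0.55 * n_q1), q25 - STAMP_MARGIN)
    elif cat is Category.BHD:
        n_basal = int((t <= q50).sum())
        stamp_sel = _slab_cut(t, int(0.72 * n_basal), q50 - STAMP_MARGIN)
    elif cat is Category.BAD:
        n_q1 = int((t <= q25).sum())
        n_q4 = int((t > q75).sum())
        low = _slab_cut(t, int(0.50 * n_q1), q25 - STAMP_MARGIN)
        high = _slab_cut(-t, int(0.50 * n_q4), -(q75 + STAMP_MARGIN))
        stamp_sel = low | high
    elif cat is Category.CAD:
        q10, q90 = np.percentile(t, [10, 90])
        bw = max(1.5, frame.width_px / 6.0 - STAMP_MARGIN)
        stamp_sel = (np.abs(v) <= bw) & (t >= q10) & (t <= q90)
    elif cat is Category.DD:
        n_blobs = int(rng.integers(3, 6))
        qidx = np.searchsorted([q25, q50, q75], t, side="right")
        quart_order = rng.permutation(4)
        chosen = [int(quart_order[i % 4]) for i in range(n_blobs)]
        sign = 1.0
        for q in chosen:
            in_q = qidx == q
            if not in_q.any():
                continue
            tq = t[in_q]
            vq = v[in_q]
            t_mid = 0.5 * (tq.min() + tq.max())
            v_target = sign * 0.6 * np.abs(vq).max()
            sign = -sign
            # nearest mask pixel to the (t_mid, v_target) frame position
            d2 = (t - t_mid) ** 2 + (v - v_target) ** 2
            centre = coords_local[int(np.argmin(d2))]
            dist2 = ((coords_local - centre) ** 2).sum(axis=1)
            stamp_sel |= dist2 <= 3.5**2

    stamp = np.zeros_like(mask)
    stamp[coords_local[stamp_sel, 0], coords_local[stamp_sel, 1]] = True
    return stamp & mask


def _tem_stamp(
    mask: np.ndarray,
    bbox: tuple[int, int, int, int],
    image_shape: tuple[int, int],
    grade: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Clear-region stamp for a TEM grade.

    Small spots are 2 px-radius disks (~1% of the section each); clear
    regions are axial slabs cut from the mask interior (a dark rim of 2 px
    is kept so the thresholded head stays a single filled component).
    """
    g = TEMGrade(grade)
    stamp = np.zeros_like(mask)
    if g is TEMGrade.N0:
        return stamp
    frame, coords_local, t, v = _frame_coords(mask, bbox, image_shape)

    def place_spots(k: int) -> None:
        fracs = np.linspace(0.2, 0.8, k)
        tpos = t.min() + fracs * (t.max() - t.min())
        sign = 1.0
        for tp in tpos:
            v_target = sign * 0.35 * np.abs(v).max()
            sign = -sign
            d2 = (t - tp) ** 2 + (v - v_target) ** 2
            centre = coords_local[int(np.argmin(d2))]
            dist2 = ((coords_local - centre) ** 2).sum(axis=1)
            sel = dist2 <= 2.0**2
            stamp[coords_local[sel, 0], coords_local[sel, 1]] = True

    def place_region(frac: float) -> None:
        interior = ndimage.binary_erosion(
            mask, structure=ndimage.generate_binary_structure(2, 1), iterations=2
        )
        keep = interior[coords_local[:, 0], coords_local[:, 1]]
        target = int(frac * mask.sum())
        order = np.argsort(t)
        chosen = [i for i in order if keep[i]][:target]
        stamp[coords_local[chosen, 0], coords_local[chosen, 1]] = True

    if g is TEMGrade.G1:
        place_spots(int(rng.integers(1, 4)))
    elif g is TEMGrade.G2:
        if rng.random() < 0.5:
            place_spots(int(rng.integers(4, 7)))
        else:
            place_region(0.15)
    elif g is TEMGrade.G3:
        if rng.random() < 0.5:
            place_spots(int(rng.integers(7, 10)))
        else:
            place_region(0.38)
    elif g is TEMGrade.G4:
        place_region(0.62)
    return stamp & mask


# ---------------------------------------------------------------------------
# Image assembly
# ---------------------------------------------------------------------------

def _place_heads(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping head placements >= 5 px from borders."""
    h, w = spec.image_size
    (a_lo, a_hi), (b_lo, b_hi) = spec.head_axes_px
    placements = []
    attempts = 0
    while len(placements) < spec.n_heads:
        attempts += 1
        if attempts > 10_000:
            raise InfeasibleSpecError(
                f"could not place {spec.n_heads} heads in {spec.image_size}"
            )
        a = float(rng.uniform(a_lo, a_hi))
        b = float(rng.uniform(b_lo, b_hi))
        theta = float(rng.uniform(0, np.pi))
        margin = a + 6
        if 2 * margin >= min(h, w):
            raise InfeasibleSpecError("heads larger than the image")
        r = float(rng.uniform(margin, h - margin))
        c = float(rng.uniform(margin, w - margin))
        ok = all(
            np.hypot(r - pr, c - pc) > a + pa + 6 for pr, pc, pa, _, _ in placements
        )
        if ok:
            placements.append((r, c, a, b, theta))
    return placements


def _add_debris(canvas, occupied, spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Stamp tail-like filaments (2 px wide) clear of every head."""
    h, w = canvas.shape[:2]
    blocked = ndimage.binary_dilation(occupied, iterations=4)
    placed = 0
    attempts = 0
    while placed < spec.debris and attempts < 2_000:
        attempts += 1
        length = float(rng.uniform(80, 150))
        theta = float(rng.uniform(0, np.pi))
        r0 = float(rng.uniform(5, h - 5))
        c0 = float(rng.uniform(5, w - 5))
        steps = int(length * 2)
        rr = r0 + np.cos(theta) * np.linspace(0, length, steps)
        cc = c0 + np.sin(theta) * np.linspace(0, length, steps)
        inb = (rr >= 1) & (rr < h - 1) & (cc >= 1) & (cc < w - 1)
        rr, cc = rr[inb].astype(int), cc[inb].astype(int)
        if len(rr) < 60:
            continue
        fil = np.zeros((h, w), dtype=bool)
        fil[rr, cc] = True
        fil = ndimage.binary_dilation(fil)  # ~2-3 px wide
        if (fil & blocked).any():
            continue
        if canvas.ndim == 3:
            canvas[fil] = spec.head_intensity
        else:
            canvas[fil] = (
                spec.tem_head_intensity if spec.stain is Stain.TEM else spec.head_intensity
            )
        placed += 1


def _default_assignments(spec: PhantomSpec, rng: np.random.Generator) -> list[str]:
    if spec.stain is Stain.TEM:
        pool = TEM_GRADES
    elif spec.stain is Stain.AO:
        pool = AO_STATES
    else:
        pool = PATTERN_CATEGORIES
    return [pool[int(rng.integers(len(pool)))] for _ in range(spec.n_heads)]


def generate_phantom(spec: PhantomSpec) -> tuple[Micrograph, GroundTruth]:
    """Render one phantom micrograph and its exact ground truth.

    Deterministic for a fixed spec (PCG64 seeded from ``spec.seed``).  The
    per-head ``stamped_fraction`` recorded in the ground truth is the exact
    rasterized ratio |stamp| / |mask|.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    placements = _place_heads(spec, rng)
    assignments = (
        list(spec.assignments)
        if spec.assignments is not None
        else _default_assignments(spec, rng)
    )

    is_ao = spec.stain is Stain.AO
    is_tem = spec.stain is Stain.TEM
    if is_ao:
        canvas = np.full((h, w, 3), 0.03)
    elif is_tem:
        canvas = np.full((h, w), spec.tem_background)
    else:
        canvas = np.full((h, w), spec.background_intensity)
    occupied = np.zeros((h, w), dtype=bool)

    gt_heads: list[GroundTruthHead] = []
    for i, ((r, c, a, b, theta), assignment) in enumerate(
        zip(placements, assignments), start=1
    ):
        local, half = _paddle_mask(a, b, theta, spec.taper)
        r0, c0 = int(round(r)) - half, int(round(c)) - half
        bbox = (r0, c0, r0 + local.shape[0], c0 + local.shape[1])
        view = (slice(r0, bbox[2]), slice(c0, bbox[3]))

        if is_ao:
            if assignment == "denatured":
                head_rgb = (0.80, 0.30, 0.05)
            else:
                head_rgb = (0.06, 0.80, 0.05)
            for ch, val in enumerate(head_rgb):
                plane = canvas[:, :, ch][view]
                plane[local] = val
            stamp = np.zeros_like(local)
        elif is_tem:
            canvas[view][local] = spec.tem_head_intensity
            stamp = _tem_stamp(local, bbox, (h, w), assignment, rng)
            canvas[view][stamp] = spec.tem_clear_intensity
        else:
            canvas[view][local] = spec.head_intensity
            stamp = stamp_pattern(local, bbox, (h, w), assignment, rng)
            canvas[view][stamp] = spec.head_intensity * (1.0 - spec.deficit_depth)

        occupied[view] |= local
        coords_local = np.argwhere(local)
        centroid = (coords_local[:, 0].mean() + r0, coords_local[:, 1].mean() + c0)
        gt_heads.append(
            GroundTruthHead(
                label=i,
                centroid=centroid,
                mask=local,
                bbox=bbox,
                image_shape=(h, w),
                assignment=assignment,
                stamp_mask=stamp,
                stamped_fraction=float(stamp.sum()) / float(local.sum()),
            )
        )

    if spec.debris:
        _add_debris(canvas, occupied, spec, rng)
    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    pixels = np.round(canvas * 255).astype(np.uint8)
    micro = Micrograph(pixels=pixels, bit_depth=8, stain=spec.stain, source_path="<phantom>")
    return micro, GroundTruth(heads=gt_heads, spec=spec)
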