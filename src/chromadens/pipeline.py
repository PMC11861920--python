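"""End-to-end smear analysis for each modality.

Glues segmentation, densitometry and classification into one call per
micrograph and returns both per-head calls and the smear summary, plus the
intermediate objects (reference set, altered regions) needed for overlays
and audit tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import densitometry as dens
from . import head_segmentation as seg
from . import pattern_classification as pat
from .imaging_io import IntensityImage, Micrograph, Outline, Stain, to_intensity


@dataclass
class SmearResult:
    stain: Stain
    heads: seg.LabeledHeads
    calls: list
    summary: pat.SmearSummary | None
    reference: dens.ReferenceSet | None = None
    altered: list[dens.AlteredRegionSet] = field(default_factory=list)
    intensity: IntensityImage | None = None

    def outlines(self) -> list[Outline]:
        out: list[Outline] = []
        for ars in self.altered:
            out.extend(dens.boundary_outlines(ars))
        return out


def analyze_decompaction(
    m: Micrograph,
    seg_params: seg.SegmentationParams | None = None,
    rules: pat.PatternRules | None = None,
    tau: float | None = None,
    K: int = 10,
    sigma: float = 2.0,
    radius: int = 5,
    channel_policy: str = "luminance",
    invert: bool = False,
) -> SmearResult:
    """TB/FR pipeline: segment, reference, deficit, smooth, classify, summarize."""
    if m.stain not in (Stain.TB, Stain.FR):
        raise ValueError("decompaction analysis applies to TB/FR micrographs")
    seg_params = seg_params or seg.SegmentationParams()
    img = to_intensity(m, channel_policy=channel_policy, invert=invert)
    mask, thr = seg.threshold_histogram(img, seg_params)
    heads = seg.extract_heads(mask, img, seg_params)
    heads.threshold = thr
    calls: list[pat.PatternCall] = []
    altered: list[dens.AlteredRegionSet] = []
    reference = None
    if heads.heads:
        reference = dens.select_reference(heads, K=K)
        for head in heads.heads:
            dm = dens.smooth_deficit(
                dens.deficit_map(img, head, reference), sigma=sigma, radius=radius
            )
            ars = dens.altered_regions(dm, tau=tau, stain=m.stain)
            frame = pat.head_axes(head)
            part = pat.region_partition(frame, head)
            calls.append(pat.classify_pattern(ars, part, rules))
            altered.append(ars)
    summary = pat.summarize_smear(calls) if calls else None
    return SmearResult(
        stain=m.stain,
        heads=heads,
        calls=calls,
        summary=summary,
        reference=reference,
        altered=altered,
        intensity=img,
    )


def analyze_tem(
    m: Micrograph,
    seg_params: seg.SegmentationParams | None = None,
    clear_tau: float = 0.60,
    small_spot_max_fraction: float = 0.02,
) -> SmearResult:
    """TEM pipeline: segment (holes filled: clear regions are lighter than
    background), detect clear regions, grade."""
    if m.stain is not Stain.TEM:
        raise ValueError("TEM analysis requires a TEM micrograph")
    if seg_params is None:
        seg_params = seg.SegmentationParams(fill_holes=True)
    img = to_intensity(m, channel_policy="asis")
    mask, thr = seg.threshold_histogram(img, seg_params)
    heads = seg.extract_heads(mask, img, seg_params)
    heads.threshold = thr
    calls = []
    for head in heads.heads:
        obs = pat.detect_clear_regions(
            img, head, clear_tau=clear_tau,
            small_spot_max_fraction=small_spot_max_fraction,
        )
        pat.grade_tem(obs)
        calls.append(obs)
    summary = pat.summarize_smear(calls) if calls else None
    return SmearResult(stain=m.stain, heads=heads, calls=calls, summary=summary, intensity=img)


def analyze_ao(
    m: Micrograph,
    seg_params: seg.SegmentationParams | None = None,
    red_fraction_threshold: float = 0.40,
) -> SmearResult:
    """AO pipeline: segment on inverted luminance (heads fluoresce on a dark
    field), then call intact/denatured per head from red vs green."""
    if m.stain is not Stain.AO:
        raise ValueError("AO analysis requires an AO micrograph")
    seg_params = seg_params or seg.SegmentationParams()
    img = to_intensity(m, channel_policy="luminance", invert=True)
    mask, thr = seg.threshold_histogram(img, seg_params)
    heads = seg.extract_heads(mask, img, seg_params)
    heads.threshold = thr
    calls = []
    for head in heads.heads:
        try:
            calls.append(
                pat.classify_ao(m, head, red_fraction_threshold=red_fraction_threshold)
            )
        except pat.UnstainedHeadError:
            heads.rejected.append((head.label, "no red/green signal"))
    summary = pat.summarize_smear(calls) if calls else None
    return SmearResult(stain=m.stain, heads=heads, calls=calls, summary=summary, intensity=img)


def analyze(m: Micrograph, **kwargs) -> SmearResult:
    """Dispatch on the micrograph's stain tag."""
    if m.stain in (Stain.TB, Stain.FR):
        return analyze_decompaction(m, **kwargs)
    if m.stain is Stain.TEM:
        return analyze_tem(m, **kwargs)
    return analyze_ao(m, **kwargs)


def match_heads_to_truth(result: SmearResult, truth, max_dist: float = 2.0):
    """Greedy centroid matching of segmented heads to ground-truth heads.

    Returns a list of (ground_truth_head, call) pairs for matches within
    ``max_dist`` pixels; used by phantom-recovery checks.
    """
    pairs = []
    calls_by_label = {c.head_label: c for c in result.calls}
    used = set()
    for gt in truth.heads:
        best, best_d = None, np.inf
        for head in result.heads.heads:
            if head.label in used:
                continue
            d = float(np.hypot(head.centroid[0] - gt.centroid[0], head.centroid[1] - gt.centroid[1]))
            if d < best_d:
                best, best_d = head, d
        if best is not None and best_d <= max_dist:
            used.add(best.label)
            pairs.append((gt, calls_by_label.get(best.label), best_d))
    return pairs
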