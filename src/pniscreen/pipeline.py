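"""End-to-end screening: probability maps -> candidates -> review -> study summary.

Ties the modules together the way the clinical workflow runs: per slide,
threshold both class channels, label and size-filter the components, compute
nerve-tumor pair distances, and build deduplicated candidate fields; per
case, pool candidates across slides, present the top k, review each against
ground truth, and call the case.  ``run_synthetic_study`` wraps this around
the synthetic-study generator, processing one case at a time so arbitrarily
large studies run in bounded memory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .clinical import CaseResult, StudySummary, aggregate_case, review_candidate, study_summary
from .config import PipelineConfig
from .postprocess import LabeledRegions, binarize, filter_small, label_components
from .proximity import Candidate, build_candidates, component_min_distances, rank_top_k, suppress_overlaps
from .segmentation import NoiseModel, ProbabilityMap, oracle_noise_segment
from .synthgen import GroundTruth, SyntheticCase, TileSpec, generate_case, study_case_specs

__all__ = ["SlideScreen", "StudyOutcome", "screen_slide", "screen_case", "run_synthetic_study"]


@dataclass
class SlideScreen:
    """Per-slide screening products kept around for review and export."""

    slide_id: str
    nerve_regions: LabeledRegions
    tumor_regions: LabeledRegions
    candidates: list[Candidate]


@dataclass
class StudyOutcome:
    summary: StudySummary
    sensitivity: float
    specificity: float
    n_positive_truth: int
    n_negative_truth: int
    results: list[CaseResult] = field(default_factory=list)
    truth: dict[str, bool] = field(default_factory=dict)


def screen_slide(
    pmap: ProbabilityMap, slide_id: str, config: PipelineConfig = PipelineConfig()
) -> SlideScreen:
    """Threshold, label, size-filter, and pair up one slide's probability map."""
    regions = {}
    for cls in ("tumor", "nerve"):
        mask = binarize(pmap, cls, config.threshold)
        labeled = label_components(mask, connectivity=config.connectivity)
        regions[cls] = filter_small(labeled, config.min_area[cls])
    pairs = component_min_distances(
        regions["nerve"], regions["tumor"], max_distance=config.ranking.max_distance
    )
    candidates = build_candidates(
        pairs,
        regions["nerve"],
        regions["tumor"],
        regions["tumor"].foreground(),
        config=config.ranking,
        slide_id=slide_id,
        encirclement_epsilon=config.review.encirclement_epsilon,
    )
    candidates = suppress_overlaps(candidates, config.ranking.overlap_suppression)
    return SlideScreen(
        slide_id=slide_id,
        nerve_regions=regions["nerve"],
        tumor_regions=regions["tumor"],
        candidates=candidates,
    )


def screen_case(
    case: SyntheticCase,
    noise: NoiseModel,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> tuple[CaseResult, list[Candidate]]:
    """Segment (oracle-noise), screen, rank, and review one synthetic case."""
    rng = np.random.default_rng(seed)
    screens: dict[str, SlideScreen] = {}
    gts: dict[str, GroundTruth] = {}
    for i, (_tile, gt) in enumerate(case.slides):
        slide_id = f"{case.spec.case_id}_s{i:03d}"
        slide_noise = dataclasses.replace(noise, rng_seed=int(rng.integers(2**31)))
        pmap = oracle_noise_segment(gt, slide_noise)
        screen = screen_slide(pmap, slide_id, config)
        if screen.candidates:
            screens[slide_id] = screen
            gts[slide_id] = gt
    pooled = [c for s in screens.values() for c in s.candidates]
    k = config.ranking.k_tumor_only if case.spec.tumor_only else config.ranking.k
    ranked = rank_top_k(pooled, k)
    reviews = [
        review_candidate(
            c,
            screens[c.slide_id].nerve_regions,
            screens[c.slide_id].tumor_regions,
            gts[c.slide_id],
            config.review,
        )
        for c in ranked
    ]
    return aggregate_case(case.spec.case_id, ranked, reviews), ranked


def run_synthetic_study(
    n_cases: int = 30,
    prevalence: float = 0.5,
    seed: int = 0,
    noise: NoiseModel = NoiseModel(miss_rate=0.1, spurious_rate=2.0),
    config: PipelineConfig = PipelineConfig(),
    tile_spec: TileSpec | None = None,
    events_per_positive: int = 1,
    n_tumor_only: int = 0,
) -> StudyOutcome:
    """Simulate and screen a whole study, one case at a time.

    Tiles are generated without RGB rendering (the oracle-noise segmenter
    reads ground truth; rendering only matters for presentation artifacts),
    then discarded after screening, so memory stays flat in the study size.
    """
    rng = np.random.default_rng(seed)
    results: list[CaseResult] = []
    truth: dict[str, bool] = {}
    for spec, case_seed in study_case_specs(
        n_cases, prevalence, seed, n_tumor_only, events_per_positive
    ):
        case = generate_case(spec, case_seed, tile_spec=tile_spec, render=False)
        result, _ranked = screen_case(case, noise, config, seed=int(rng.integers(2**31)))
        results.append(result)
        truth[spec.case_id] = spec.pni_positive

    tp = sum(r.pni_called for r in results if truth[r.case_id])
    tn = sum(not r.pni_called for r in results if not truth[r.case_id])
    n_pos = sum(truth.values())
    n_neg = n_cases - n_pos
    summary = study_summary(results, truth)
    return StudyOutcome(
        summary=summary,
        sensitivity=tp / n_pos if n_pos else 1.0,
        specificity=tn / n_neg if n_neg else 1.0,
        n_positive_truth=n_pos,
        n_negative_truth=n_neg,
        results=results,
        truth=truth,
    )
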