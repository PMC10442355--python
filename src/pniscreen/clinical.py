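"""Case-level PNI calling with a simulated pathologist review, plus study statistics.

The screening pipeline never calls PNI on its own: it presents the k closest
nerve-tumor fields of a case, and a reviewer decides each one.  Here the
reviewer is simulated with access to ground truth and applies the standard
histologic rule: tumor abutting a nerve outside the main tumor body is PNI;
for a nerve inside the tumor body, the tumor must encircle at least 33% of
the nerve circumference to call invasion rather than focal abutment.

Study-level comparison uses a pooled two-proportion z-test (equivalent to the
Pearson chi-square on the 2x2 table, no continuity correction) — the test
that reproduces the clinical study's printed p-value from its printed case
counts — and a Mann-Whitney rank-sum test for per-case quantities such as
first-positive image ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import convex_hull_image
from statsmodels.stats.proportion import proportions_ztest

from ._codes import NERVE, TUMOR
from .postprocess import LabeledRegions, label_components
from .proximity import Candidate, measure_encirclement
from .synthgen import GroundTruth

__all__ = [
    "ReviewRule",
    "CaseResult",
    "StudySummary",
    "review_candidate",
    "aggregate_case",
    "two_proportion_test",
    "rank_sum_test",
    "study_summary",
    "summary_from_counts",
]


@dataclass(frozen=True)
class ReviewRule:
    """The simulated reviewer's decision rule.

    ``contact_distance`` is the largest rasterized pixel-center distance still
    counting as abutment (true contact rasterizes to at most 2 px);
    ``encirclement_min`` is the minimum encircled fraction for intratumoral
    nerves (0.33 per the histologic criterion).
    """

    contact_distance: float = 2.0
    encirclement_min: float = 0.33
    require_encirclement_inside_tumor: bool = True
    encirclement_epsilon: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.encirclement_min <= 1.0:
            raise ValueError("encirclement_min must lie in [0, 1]")
        if self.contact_distance < 0:
            raise ValueError("contact_distance must be >= 0")


@dataclass
class CaseResult:
    case_id: str
    pni_called: bool
    first_positive_rank: int | None
    n_confirmed: int
    n_candidates_reviewed: int

    def __post_init__(self) -> None:
        if self.pni_called != (self.n_confirmed >= 1):
            raise ValueError("pni_called must equal n_confirmed >= 1")
        if self.first_positive_rank is not None and not (
            1 <= self.first_positive_rank <= self.n_candidates_reviewed
        ):
            raise ValueError("first_positive_rank out of range")


@dataclass
class StudySummary:
    n_cases: int
    report_positive: int
    algorithm_positive: int
    missed_by_algorithm: int  # report-positive, algorithm-negative
    newly_detected: int  # report-negative, algorithm-positive
    report_positive_rate: float
    algorithm_positive_rate: float
    sensitivity_vs_report: float
    z_statistic: float
    p_value: float
    per_case: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "report_positive": self.report_positive,
            "algorithm_positive": self.algorithm_positive,
            "missed_by_algorithm": self.missed_by_algorithm,
            "newly_detected": self.newly_detected,
            "report_positive_rate": self.report_positive_rate,
            "algorithm_positive_rate": self.algorithm_positive_rate,
            "sensitivity_vs_report": self.sensitivity_vs_report,
            "z_statistic": self.z_statistic,
            "p_value": self.p_value,
            "per_case": self.per_case,
        }


# ---------------------------------------------------------------------------
# simulated review


def _matched_component(pred_pixels: np.ndarray, gt_regions: LabeledRegions) -> int | None:
    """Ground-truth component with the largest overlap with the predicted pixels."""
    overlapping = gt_regions.labels[pred_pixels]
    overlapping = overlapping[overlapping > 0]
    if overlapping.size == 0:
        return None
    return int(np.bincount(overlapping).argmax())


def _bbox_union(a: np.ndarray, b: np.ndarray, margin: int, shape) -> tuple[slice, slice]:
    rows, cols = np.nonzero(a | b)
    r0 = max(int(rows.min()) - margin, 0)
    r1 = min(int(rows.max()) + margin + 1, shape[0])
    c0 = max(int(cols.min()) - margin, 0)
    c1 = min(int(cols.max()) + margin + 1, shape[1])
    return slice(r0, r1), slice(c0, c1)


def _gt_pair_distance(nerve_comp: np.ndarray, tumor_comp: np.ndarray) -> float:
    if (nerve_comp & tumor_comp).any():
        return 0.0
    win = _bbox_union(nerve_comp, tumor_comp, margin=2, shape=nerve_comp.shape)
    dist = ndimage.distance_transform_edt(~tumor_comp[win])
    return float(dist[nerve_comp[win]].min())


def _nerve_inside_tumor_body(nerve_comp: np.ndarray, tumor_comp: np.ndarray) -> bool:
    """Nerve centroid inside the filled convex hull of the tumor component."""
    rows, cols = np.nonzero(nerve_comp)
    centroid = (int(round(rows.mean())), int(round(cols.mean())))
    trows, tcols = np.nonzero(tumor_comp)
    r0, r1 = int(trows.min()), int(trows.max()) + 1
    c0, c1 = int(tcols.min()), int(tcols.max()) + 1
    if not (r0 <= centroid[0] < r1 and c0 <= centroid[1] < c1):
        return False
    hull = convex_hull_image(tumor_comp[r0:r1, c0:c1])
    return bool(hull[centroid[0] - r0, centroid[1] - c0])


def review_candidate(
    candidate: Candidate,
    nerve_regions: LabeledRegions,
    tumor_regions: LabeledRegions,
    gt: GroundTruth,
    rule: ReviewRule = ReviewRule(),
) -> bool:
    """Simulated pathologist review of one candidate field.

    The candidate is confirmed iff its predicted nerve and tumor components
    each overlap a true component of their class, and the *true* components
    satisfy the histologic rule: contact (within ``contact_distance``) for a
    nerve outside the main tumor body, or encirclement of at least
    ``encirclement_min`` for a nerve inside it.  A predicted tumor that only
    overlaps a benign gland is rejected.
    """
    if nerve_regions.shape != gt.class_mask.shape:
        raise ValueError("candidate regions and ground truth are from different slides")
    pred_nerve = nerve_regions.component(candidate.nerve_id)
    pred_tumor = tumor_regions.component(candidate.tumor_id)

    gt_nerve_regions = label_components(gt.class_bool(NERVE), connectivity=8)
    gt_tumor_regions = label_components(gt.class_bool(TUMOR), connectivity=8)
    nid = _matched_component(pred_nerve, gt_nerve_regions)
    tid = _matched_component(pred_tumor, gt_tumor_regions)
    if nid is None or tid is None:
        return False

    nerve_comp = gt_nerve_regions.labels == nid
    tumor_comp = gt_tumor_regions.labels == tid
    distance = _gt_pair_distance(nerve_comp, tumor_comp)
    if distance > max(rule.contact_distance, rule.encirclement_epsilon):
        return False  # no abutment at all: nothing to confirm

    inside = _nerve_inside_tumor_body(nerve_comp, tumor_comp)
    if inside and rule.require_encirclement_inside_tumor:
        enc = measure_encirclement(
            nid, gt_nerve_regions, gt.class_bool(TUMOR), epsilon=rule.encirclement_epsilon
        )
        return enc >= rule.encirclement_min
    return distance <= rule.contact_distance


def aggregate_case(
    case_id: str, ranked_candidates: Sequence[Candidate], reviews: Sequence[bool]
) -> CaseResult:
    """Fold per-candidate reviews into the case-level PNI call."""
    if len(ranked_candidates) != len(reviews):
        raise ValueError("reviews must align 1:1 with ranked candidates")
    confirmed = [i for i, ok in enumerate(reviews) if ok]
    return CaseResult(
        case_id=case_id,
        pni_called=bool(confirmed),
        first_positive_rank=confirmed[0] + 1 if confirmed else None,
        n_confirmed=len(confirmed),
        n_candidates_reviewed=len(reviews),
    )


# ---------------------------------------------------------------------------
# study statistics


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided, no continuity correction.

    z**2 equals the Pearson chi-square statistic of the corresponding 2x2
    table.  Degenerate pooled proportions (0 or 1) give (0.0, 1.0).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n and n >= 1")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small tie-free samples (n_a + n_b <= 12), otherwise
    the tie-corrected normal approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 12 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


def study_summary(
    case_results: Sequence[CaseResult],
    report_labels: Mapping[str, bool],
) -> StudySummary:
    """Contingency of algorithm-assisted calls against report labels.

    ``report_labels`` maps case_id to the pathology-report PNI status (the
    study's baseline).  Attaches the pooled two-proportion z-test comparing
    the report-positive rate with the algorithm-positive rate.
    """
    if set(r.case_id for r in case_results) != set(report_labels):
        raise ValueError("case results and report labels must cover the same cases")
    n = len(case_results)
    report_pos = sum(bool(v) for v in report_labels.values())
    algo_pos = sum(r.pni_called for r in case_results)
    missed = sum(
        1 for r in case_results if report_labels[r.case_id] and not r.pni_called
    )
    newly = sum(1 for r in case_results if not report_labels[r.case_id] and r.pni_called)
    z, p = two_proportion_test(report_pos, n, algo_pos, n)
    per_case = [
        {
            "case_id": r.case_id,
            "report_label": bool(report_labels[r.case_id]),
            "pni_called": r.pni_called,
            "first_positive_rank": r.first_positive_rank,
            "n_confirmed": r.n_confirmed,
            "n_candidates_reviewed": r.n_candidates_reviewed,
        }
        for r in case_results
    ]
    return StudySummary(
        n_cases=n,
        report_positive=report_pos,
        algorithm_positive=algo_pos,
        missed_by_algorithm=missed,
        newly_detected=newly,
        report_positive_rate=report_pos / n if n else 0.0,
        algorithm_positive_rate=algo_pos / n if n else 0.0,
        sensitivity_vs_report=(report_pos - missed) / report_pos if report_pos else 1.0,
        z_statistic=z,
        p_value=p,
        per_case=per_case,
    )


def summary_from_counts(
    n_cases: int, report_positive: int, missed_by_algorithm: int, newly_detected: int
) -> StudySummary:
    """Study summary reconstructed from published case counts.

    Builds the per-case contingency implied by (report-positive count, cases
    the algorithm missed among them, report-negative cases the algorithm
    newly detected) and runs the same summary computation as for simulated
    studies.
    """
    if not 0 <= report_positive <= n_cases:
        raise ValueError("report_positive out of range")
    if missed_by_algorithm > report_positive:
        raise ValueError("cannot miss more positives than exist")
    if newly_detected > n_cases - report_positive:
        raise ValueError("cannot newly detect more negatives than exist")
    results = []
    labels = {}
    for i in range(n_cases):
        case_id = f"case_{i:03d}"
        report = i < report_positive
        if report:
            called = i >= missed_by_algorithm  # first `missed` positives missed
        else:
            called = i - report_positive < newly_detected
        labels[case_id] = report
        results.append(
            CaseResult(
                case_id=case_id,
                pni_called=called,
                first_positive_rank=1 if called else None,
                n_confirmed=1 if called else 0,
                n_candidates_reviewed=1,
            )
        )
    return study_summary(results, labels)
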