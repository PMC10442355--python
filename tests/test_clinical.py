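"""Simulated review, case aggregation, and study-level statistics."""

import numpy as np
import pytest
from scipy import stats

from pniscreen.clinical import (
    CaseResult,
    ReviewRule,
    aggregate_case,
    rank_sum_test,
    review_candidate,
    study_summary,
    summary_from_counts,
    two_proportion_test,
)
from pniscreen.postprocess import label_components
from pniscreen.proximity import RankingConfig, build_candidates, component_min_distances
from pniscreen.synthgen import GroundTruth


def _disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _candidates_from(pred_nerve, pred_tumor, field_size=64):
    nr = label_components(pred_nerve)
    tr = label_components(pred_tumor)
    pairs = component_min_distances(nr, tr)
    cands = build_candidates(pairs, nr, tr, pred_tumor, RankingConfig(field_size=field_size))
    return cands, nr, tr


class TestReviewCandidate:
    def test_contact_outside_tumor_body_confirmed(self):
        # tumor blob abutting a nerve bar from one side
        shape = (96, 96)
        nerve = np.zeros(shape, dtype=bool)
        nerve[40:56, 8:88] = True
        tumor = _disk(shape, (20, 48), 19) & ~nerve  # touches the top edge of the bar
        mask = np.zeros(shape, dtype=np.uint8)
        mask[nerve] = 2
        mask[tumor] = 1
        gt = GroundTruth(class_mask=mask)
        [cand], nr, tr = _candidates_from(nerve, tumor)
        assert cand.min_distance <= 2.0
        assert review_candidate(cand, nr, tr, gt, ReviewRule())

    def test_benign_gland_pairing_not_confirmed(self):
        # the segmenter mistakes a benign gland (code 3) for tumor right next
        # to a nerve; the reviewer sees benign tissue and rejects
        shape = (96, 96)
        nerve = np.zeros(shape, dtype=bool)
        nerve[40:56, 8:88] = True
        benign = _disk(shape, (20, 48), 19) & ~nerve
        mask = np.zeros(shape, dtype=np.uint8)
        mask[nerve] = 2
        mask[benign] = 3
        gt = GroundTruth(class_mask=mask)
        [cand], nr, tr = _candidates_from(nerve, benign)  # prediction calls it tumor
        assert not review_candidate(cand, nr, tr, gt, ReviewRule())

    def _intratumoral_nerve(self, contact_fraction):
        """Nerve disk inside a tumor ring that touches it over a given arc."""
        shape = (128, 128)
        center = (64, 64)
        nerve = _disk(shape, center, 14)
        rr, cc = np.ogrid[:128, :128]
        radius = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
        angle = np.arctan2(rr - center[0], cc - center[1])  # -pi..pi
        ring = (radius >= 22) & (radius <= 34)  # detached ring: hull holds the nerve
        contact = (
            (radius > 14)
            & (radius <= 23)
            & (np.abs(angle) <= contact_fraction * np.pi)
        )
        tumor = (ring | contact) & ~nerve
        mask = np.zeros(shape, dtype=np.uint8)
        mask[nerve] = 2
        mask[tumor] = 1
        return nerve, tumor, GroundTruth(class_mask=mask)

    def test_intratumoral_focal_abutment_not_confirmed(self):
        nerve, tumor, gt = self._intratumoral_nerve(contact_fraction=0.2)
        [cand], nr, tr = _candidates_from(nerve, tumor)
        assert cand.min_distance <= 2.0
        assert 0.1 <= cand.encirclement <= 0.3  # ~20% contact
        assert not review_candidate(cand, nr, tr, gt, ReviewRule())

    def test_intratumoral_encirclement_above_third_confirmed(self):
        nerve, tumor, gt = self._intratumoral_nerve(contact_fraction=0.45)
        [cand], nr, tr = _candidates_from(nerve, tumor)
        assert review_candidate(cand, nr, tr, gt, ReviewRule())

    def test_slide_mismatch_rejected(self):
        nerve = np.zeros((32, 32), dtype=bool)
        nerve[10:20, 10:20] = True
        tumor = np.zeros((32, 32), dtype=bool)
        tumor[0:5, 0:5] = True
        [cand], nr, tr = _candidates_from(nerve, tumor, field_size=16)
        gt = GroundTruth(class_mask=np.zeros((64, 64), dtype=np.uint8))
        with pytest.raises(ValueError, match="different slides"):
            review_candidate(cand, nr, tr, gt)


class TestAggregateCase:
    def _cands(self, n):
        from test_proximity import _cand

        return [_cand(float(i)) for i in range(n)]

    def test_no_confirmations(self):
        res = aggregate_case("c", self._cands(3), [False] * 3)
        assert not res.pni_called
        assert res.first_positive_rank is None
        assert res.n_candidates_reviewed == 3

    def test_first_confirmed_rank(self):
        reviews = [False, False, True, False, False, False, True, False]
        res = aggregate_case("c", self._cands(8), reviews)
        assert res.pni_called
        assert res.first_positive_rank == 3
        assert res.n_confirmed == 2

    def test_single_confirmed_candidate(self):
        res = aggregate_case("c", self._cands(1), [True])
        assert res.first_positive_rank == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="1:1"):
            aggregate_case("c", self._cands(2), [True])


class TestTwoProportionTest:
    def test_reproduces_published_study_p_value(self):
        _, p = two_proportion_test(31, 59, 48, 59)
        assert 0.000875 <= p < 0.000885  # 0.00088 to 2 significant figures

    def test_equal_proportions(self):
        z, p = two_proportion_test(5, 10, 5, 10)
        assert z == 0.0
        assert p == 1.0

    def test_extreme_table_against_normal_cdf_oracle(self):
        z, p = two_proportion_test(0, 10, 10, 10)
        z_expected = 1.0 / np.sqrt(0.05)  # pooled p=0.5, se=sqrt(0.25*(2/10))
        p_expected = 2 * stats.norm.sf(z_expected)
        assert abs(z) == pytest.approx(z_expected, rel=1e-9)
        assert p == pytest.approx(p_expected, rel=1e-9)
        assert p == pytest.approx(7.7e-6, rel=0.05)

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_test(0, 10, 0, 10) == (0.0, 1.0)
        assert two_proportion_test(10, 10, 10, 10) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_z_squared_equals_pearson_chi_square(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(5, 80)), int(rng.integers(5, 80))
        x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
        pooled = (x1 + x2) / (n1 + n2)
        if pooled in (0.0, 1.0):
            return
        z, _ = two_proportion_test(x1, n1, x2, n2)
        table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
        chi2 = stats.chi2_contingency(table, correction=False).statistic
        assert z**2 == pytest.approx(chi2, abs=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(5, 4, 1, 10)


class TestRankSumTest:
    def test_identical_samples(self):
        _, p = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_fully_separated_small_samples_exact(self):
        u, p = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3) enumerated orderings

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a = list(rng.normal(size=9))
        b = list(rng.normal(1.0, size=7))
        ref = rank_sum_test(a, b)
        for _ in range(3):
            rng.shuffle(a)
            rng.shuffle(b)
            assert rank_sum_test(a, b) == pytest.approx(ref)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestStudySummary:
    def test_published_case_counts(self):
        s = summary_from_counts(59, report_positive=31, missed_by_algorithm=1, newly_detected=18)
        assert s.algorithm_positive == 48
        assert s.algorithm_positive_rate == pytest.approx(0.814, abs=0.0005)
        assert s.report_positive_rate == pytest.approx(0.525, abs=0.0005)
        assert s.sensitivity_vs_report == pytest.approx(30 / 31)
        assert 0.000875 <= s.p_value < 0.000885

    def test_all_negative(self):
        results = [
            CaseResult(f"c{i}", False, None, 0, 1) for i in range(6)
        ]
        labels = {f"c{i}": False for i in range(6)}
        s = study_summary(results, labels)
        assert s.report_positive_rate == 0.0
        assert s.algorithm_positive_rate == 0.0
        assert s.p_value == 1.0

    def test_exact_agreement_has_no_discordance(self):
        results = [
            CaseResult("a", True, 1, 1, 5),
            CaseResult("b", False, None, 0, 5),
        ]
        s = study_summary(results, {"a": True, "b": False})
        assert (s.missed_by_algorithm, s.newly_detected) == (0, 0)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same cases"):
            study_summary([CaseResult("a", False, None, 0, 1)], {"b": True})


def test_case_result_invariants():
    with pytest.raises(ValueError):
        CaseResult("c", True, None, 0, 4)  # called without confirmation
    with pytest.raises(ValueError):
        CaseResult("c", True, 9, 1, 4)  # rank beyond reviewed candidates
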