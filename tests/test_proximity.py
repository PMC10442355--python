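"""Nerve-tumor distances, encirclement, candidate building and ranking."""

import numpy as np
import pytest

import brute_oracles as brute
from pniscreen.postprocess import label_components
from pniscreen.proximity import (
    Candidate,
    RankingConfig,
    build_candidates,
    component_min_distances,
    crop_field,
    measure_encirclement,
    rank_top_k,
    suppress_overlaps,
)


def _regions(mask, connectivity=8):
    return label_components(np.asarray(mask, dtype=bool), connectivity)


class TestComponentMinDistances:
    def test_three_four_five_triangle(self):
        nerve = np.zeros((8, 8), dtype=bool)
        tumor = np.zeros((8, 8), dtype=bool)
        nerve[0, 0] = True
        tumor[3, 4] = True
        [(nid, tid, d, pair)] = component_min_distances(_regions(nerve), _regions(tumor))
        assert (nid, tid, d) == (1, 1, 5.0)
        assert pair == ((0, 0), (3, 4))

    def test_overlapping_components_have_distance_zero(self):
        nerve = np.zeros((6, 6), dtype=bool)
        nerve[2:4, 2:4] = True
        tumor = nerve.copy()
        [(_, _, d, _)] = component_min_distances(_regions(nerve), _regions(tumor))
        assert d == 0.0

    def test_no_tumor_components(self):
        nerve = np.ones((4, 4), dtype=bool)
        assert component_min_distances(_regions(nerve), _regions(np.zeros((4, 4)))) == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            component_min_distances(_regions(np.zeros((4, 4))), _regions(np.zeros((5, 5))))

    def test_max_distance_filters_pairs(self):
        nerve = np.zeros((40, 40), dtype=bool)
        tumor = np.zeros((40, 40), dtype=bool)
        nerve[0, 0] = True
        tumor[0, 5] = tumor[30, 30] = True
        pairs = component_min_distances(_regions(nerve), _regions(tumor), max_distance=10)
        assert [(p[1], p[2]) for p in pairs] == [(1, 5.0)]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(16, 48), rng.integers(16, 48))
        nerve = brute.random_blob_mask(rng, shape, p=0.25)
        tumor = brute.random_blob_mask(rng, shape, p=0.25) & ~nerve
        nr, tr = _regions(nerve), _regions(tumor)
        pairs = component_min_distances(nr, tr)
        assert len(pairs) == nr.n_components * tr.n_components
        for nid, tid, d, (np_px, tp_px) in pairs:
            expected = brute.all_pairs_min_distance(nr.labels == nid, tr.labels == tid)
            assert d == pytest.approx(expected, abs=0.0)
            # reported pair realizes the reported distance
            assert np.hypot(np_px[0] - tp_px[0], np_px[1] - tp_px[1]) == pytest.approx(d)

    def test_transpose_symmetry(self):
        # component numbering changes under transposition, distances do not
        rng = np.random.default_rng(99)
        nerve = brute.random_blob_mask(rng, (30, 44), p=0.2)
        tumor = brute.random_blob_mask(rng, (30, 44), p=0.2) & ~nerve
        d1 = sorted(d for _, _, d, _ in component_min_distances(_regions(nerve), _regions(tumor)))
        d2 = sorted(d for _, _, d, _ in component_min_distances(_regions(nerve.T), _regions(tumor.T)))
        assert d1 == pytest.approx(d2, abs=0.0)


class TestEncirclement:
    def _disk(self, shape, center, radius):
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2

    def test_full_annulus_gives_one(self):
        nerve = self._disk((64, 64), (32, 32), 10)
        tumor = self._disk((64, 64), (32, 32), 14) & ~self._disk((64, 64), (32, 32), 11)
        frac = measure_encirclement(1, _regions(nerve), tumor, epsilon=3.0)
        assert frac == 1.0

    def test_no_tumor_gives_zero(self):
        nerve = self._disk((32, 32), (16, 16), 6)
        assert measure_encirclement(1, _regions(nerve), np.zeros((32, 32), bool)) == 0.0

    def test_half_plane_beside_disk_covers_about_half(self):
        # tumor fills the half-plane through the disk center (nerve carved out),
        # so the right half of the circumference is in contact and the left is far
        nerve = self._disk((64, 64), (32, 32), 12)
        tumor = np.zeros((64, 64), dtype=bool)
        tumor[:, 33:] = True
        tumor &= ~nerve
        frac = measure_encirclement(1, _regions(nerve), tumor, epsilon=3.0)
        expected = brute.encirclement(nerve, tumor, epsilon=3.0)
        assert frac == pytest.approx(expected, abs=1e-12)
        assert frac == pytest.approx(0.5, abs=0.1)

    def test_matches_boundary_oracle_on_random_masks(self):
        rng = np.random.default_rng(7)
        nerve = brute.random_blob_mask(rng, (28, 28), p=0.3)
        tumor = brute.random_blob_mask(rng, (28, 28), p=0.2) & ~nerve
        regions = _regions(nerve)
        for nid in regions.areas:
            got = measure_encirclement(nid, regions, tumor, epsilon=2.5)
            expected = brute.encirclement(regions.labels == nid, tumor, epsilon=2.5)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_component_rejected(self):
        nerve = self._disk((32, 32), (16, 16), 5)
        with pytest.raises(KeyError):
            measure_encirclement(9, _regions(nerve), np.zeros((32, 32), bool))


class TestBuildCandidates:
    def test_empty_pairs(self):
        r = _regions(np.zeros((8, 8)))
        assert build_candidates([], r, r, np.zeros((8, 8), bool)) == []

    def test_pair_beyond_max_distance_excluded(self):
        nerve = np.zeros((200, 200), dtype=bool)
        tumor = np.zeros((200, 200), dtype=bool)
        nerve[0, 0] = True
        tumor[150, 150] = True
        nr, tr = _regions(nerve), _regions(tumor)
        pairs = component_min_distances(nr, tr)
        cands = build_candidates(pairs, nr, tr, tumor, RankingConfig(max_distance=100.0))
        assert cands == []

    def test_contact_pair_gets_full_encirclement(self):
        rr, cc = np.ogrid[:64, :64]
        nerve = (rr - 32) ** 2 + (cc - 32) ** 2 <= 100
        tumor = ((rr - 32) ** 2 + (cc - 32) ** 2 <= 196) & ~nerve
        nr, tr = _regions(nerve), _regions(tumor)
        pairs = component_min_distances(nr, tr)
        [cand] = build_candidates(pairs, nr, tr, tumor, RankingConfig(field_size=32))
        assert cand.min_distance <= 2.0
        assert cand.encirclement == 1.0

    def test_separated_pair_has_zero_encirclement(self):
        nerve = np.zeros((64, 64), dtype=bool)
        tumor = np.zeros((64, 64), dtype=bool)
        nerve[10, 10] = True
        tumor[10, 30] = True
        nr, tr = _regions(nerve), _regions(tumor)
        [cand] = build_candidates(
            component_min_distances(nr, tr), nr, tr, tumor, RankingConfig(field_size=16)
        )
        assert cand.encirclement == 0.0
        assert cand.min_distance == 20.0


def _cand(distance, window=(0, 0, 32, 32), slide="s", areas=(10, 10)):
    return Candidate(
        slide_id=slide,
        nerve_id=1,
        tumor_id=1,
        min_distance=distance,
        closest_pair=((0, 0), (0, 1)),
        encirclement=0.0,
        field_window=window,
        nerve_area=areas[0],
        tumor_area=areas[1],
    )


class TestSuppressAndRank:
    def test_identical_windows_keep_closest(self):
        kept = suppress_overlaps([_cand(3.0), _cand(2.0)], iou_threshold=0.5)
        assert [c.min_distance for c in kept] == [2.0]

    def test_disjoint_windows_all_kept(self):
        kept = suppress_overlaps(
            [_cand(3.0, (0, 0, 16, 16)), _cand(2.0, (100, 100, 16, 16))]
        )
        assert len(kept) == 2

    def test_empty_input(self):
        assert suppress_overlaps([]) == []

    def test_rank_orders_by_distance(self):
        cands = [_cand(3.0), _cand(0.0), _cand(12.5)]
        top = rank_top_k(cands, k=2)
        assert [c.min_distance for c in top] == [0.0, 3.0]

    def test_rank_returns_all_when_k_large(self):
        cands = [_cand(float(i)) for i in range(5)]
        assert len(rank_top_k(cands, k=40)) == 5

    def test_rank_breaks_ties_by_area_then_position(self):
        a = _cand(1.0, (0, 0, 8, 8), areas=(5, 5))
        b = _cand(1.0, (4, 0, 8, 8), areas=(50, 50))
        assert rank_top_k([a, b], 2) == [b, a]

    def test_rank_invariant_to_input_permutation(self):
        rng = np.random.default_rng(0)
        cands = [
            _cand(float(rng.integers(0, 4)), (int(rng.integers(0, 64)), 0, 8, 8))
            for _ in range(20)
        ]
        ranked = rank_top_k(cands, 10)
        for _ in range(5):
            perm = [cands[i] for i in rng.permutation(len(cands))]
            assert rank_top_k(perm, 10) == ranked


class TestCropField:
    def test_whole_tile_window_is_identity(self):
        tile = np.random.default_rng(1).integers(0, 255, (32, 32, 3), dtype=np.uint8)
        crop, window = crop_field(tile, _cand(1.0, (0, 0, 32, 32)))
        assert np.array_equal(crop, tile)
        assert window == (0, 0, 32, 32)

    def test_corner_window_clamped_but_full_size(self):
        nerve = np.zeros((300, 300), dtype=bool)
        tumor = np.zeros((300, 300), dtype=bool)
        nerve[2, 2] = True
        tumor[2, 4] = True
        nr, tr = _regions(nerve), _regions(tumor)
        [cand] = build_candidates(
            component_min_distances(nr, tr), nr, tr, tumor, RankingConfig(field_size=128)
        )
        r0, c0, h, w = cand.field_window
        assert (r0, c0) == (0, 0)
        assert (h, w) == (128, 128)

    def test_crop_paste_round_trip(self):
        tile = np.random.default_rng(2).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        cand = _cand(1.0, (10, 20, 16, 8))
        crop, (r0, c0, h, w) = crop_field(tile, cand)
        restored = tile.copy()
        restored[r0 : r0 + h, c0 : c0 + w] = crop
        assert np.array_equal(restored, tile)

    def test_degenerate_window_rejected(self):
        tile = np.zeros((16, 16, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="window"):
            crop_field(tile, _cand(1.0, (0, 0, 0, 4)))
        with pytest.raises(ValueError, match="window"):
            crop_field(tile, _cand(1.0, (10, 10, 16, 16)))
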