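"""Distance-map construction, agreement scoring and contact precision."""

import numpy as np
import pytest

from conftest import rotation_matrix
from distfold.distmat import (
    DistanceMap,
    contact_precision,
    map_agreement,
    map_from_structure,
    read_map,
    write_map,
)
from distfold.fixtures import FixtureSpec, make_structure
from distfold.structio import FormatError, Structure


def _chain(coords, seq=None):
    coords = np.asarray(coords, dtype=float)
    return Structure("t", seq or "A" * len(coords), coords)


def test_collinear_chain_geometry():
    s = _chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    dm = map_from_structure(s)
    assert dm.d[0, 2] == pytest.approx(7.6)
    assert not dm.mask[1, 1]  # diagonal masked


def test_map_invariant_under_rigid_motion(coil20):
    R = rotation_matrix([1, 2, 3], 1.1)
    moved = coil20.transformed(R, np.array([5.0, -3.0, 2.0]))
    np.testing.assert_allclose(
        map_from_structure(coil20).d, map_from_structure(moved).d, atol=1e-9
    )


def test_map_matches_brute_force_double_loop(coil20):
    dm = map_from_structure(coil20)
    L = coil20.L
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            expect = float(np.sqrt(((coil20.ca_coords[i] - coil20.ca_coords[j]) ** 2).sum()))
            assert dm.d[i, j] == pytest.approx(expect, abs=1e-10)


class TestContactPrecision:
    def test_perfect_prediction_scores_one(self):
        s = make_structure(FixtureSpec(L=60, topology="helix_bundle", seed=3))
        pred = map_from_structure(s)
        stats = contact_precision(pred, s)
        assert stats.precision_top_L_half_long == 1.0
        assert stats.n_evaluated <= 30

    def test_all_far_prediction_scores_zero(self):
        # compact native but every long-range pair predicted at 30 Å; since
        # ranking is by predicted distance the evaluated pairs are all wrong
        # whenever no native long-range pair is within 8 Å
        s = make_structure(FixtureSpec(L=50, topology="zigzag", seed=0))
        L = s.L
        d = np.full((L, L), 30.0)
        mask = np.ones((L, L), bool)
        dm = DistanceMap(d=d, mask=mask)
        stats = contact_precision(dm, s)
        assert stats.precision_top_L_half_long == 0.0

    def test_matches_exhaustive_top_set_enumeration(self):
        s = make_structure(FixtureSpec(L=60, topology="random_coil", seed=5))
        rng = np.random.default_rng(7)
        L = s.L
        noise = rng.uniform(2.0, 25.0, size=(L, L))
        d = (noise + noise.T) / 2
        conf = rng.random((L, L))
        conf = (conf + conf.T) / 2
        mask = np.ones((L, L), bool)
        pred = DistanceMap(d=d, mask=mask, confidence=conf)
        stats = contact_precision(pred, s)

        # oracle: enumerate eligible pairs, sort by (-conf, i, j), take top L//2
        native = map_from_structure(s)
        pairs = [(i, j) for i in range(L) for j in range(i + 24, L)]
        pairs.sort(key=lambda p: (-conf[p], p[0], p[1]))
        top = pairs[: L // 2]
        expect = sum(native.d[p] <= 8.0 for p in top) / len(top)
        assert stats.precision_top_L_half_long == pytest.approx(expect)

    def test_invariant_under_monotone_score_transform(self):
        s = make_structure(FixtureSpec(L=60, topology="helix_bundle", seed=9))
        pred = map_from_structure(s)
        conf = np.exp(-pred.d / 10.0)
        np.fill_diagonal(conf, 0.0)
        a = contact_precision(DistanceMap(pred.d, pred.mask, confidence=conf), s)
        b = contact_precision(
            DistanceMap(pred.d, pred.mask, confidence=conf ** 3), s
        )
        assert a.precision_top_L_half_long == b.precision_top_L_half_long

    def test_no_eligible_pairs_is_an_error(self):
        s = _chain(np.cumsum(np.tile([3.8, 0, 0], (5, 1)), axis=0))
        pred = map_from_structure(s)
        with pytest.raises(ValueError):
            contact_precision(pred, s)  # L=5 has no |i-j| >= 24 pairs


class TestMapAgreement:
    def test_exact_model_scores_one(self, bundle40):
        pred = map_from_structure(bundle40)
        assert map_agreement(pred, bundle40) == pytest.approx(1.0)

    def test_rigidly_moved_model_scores_one(self, bundle40):
        pred = map_from_structure(bundle40)
        moved = bundle40.transformed(rotation_matrix([0, 0, 1], 2.0), np.array([1.0, 2, 3]))
        assert map_agreement(pred, moved) == pytest.approx(1.0)

    def test_hand_computed_kernel_mean(self):
        # 3 residues at spacing 3.0; prediction shifts d(0,1) by +2 and d(1,2) by -1
        model = _chain([[0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        d = np.array([[0, 5.0, 6.0], [5.0, 0, 2.0], [6.0, 2.0, 0]])
        mask = np.ones((3, 3), bool)
        pred = DistanceMap(d=d, mask=mask)
        # residuals (model - pred)/2: (3-5)/2=-1, (6-6)/2=0, (3-2)/2=0.5
        expect = (1 / (1 + 1.0) + 1 / (1 + 0.0) + 1 / (1 + 0.25)) / 3
        assert map_agreement(pred, model, d_max=20.0) == pytest.approx(expect)

    def test_confidence_weighting(self):
        model = _chain([[0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        d = np.array([[0, 5.0, 6.0], [5.0, 0, 2.0], [6.0, 2.0, 0]])
        conf = np.array([[0, 1.0, 0.0], [1.0, 0, 0.5], [0.0, 0.5, 0]])
        pred = DistanceMap(d=d, mask=np.ones((3, 3), bool), confidence=conf)
        expect = (1.0 * 0.5 + 0.0 * 1.0 + 0.5 * 0.8) / 1.5
        assert map_agreement(pred, model, d_max=20.0) == pytest.approx(expect)

    def test_no_scorable_pairs_is_an_error(self):
        model = _chain([[0, 0, 0], [3.8, 0, 0]])
        d = np.array([[0, 30.0], [30.0, 0]])
        pred = DistanceMap(d=d, mask=np.ones((2, 2), bool))
        with pytest.raises(ValueError):
            map_agreement(pred, model)  # 30 Å exceeds d_max


class TestMapIO:
    @pytest.mark.parametrize("fmt", ["matrix_txt", "rr_pairs"])
    def test_round_trip(self, tmp_path, coil20, fmt):
        dm = map_from_structure(coil20)
        path = tmp_path / "map.txt"
        write_map(dm, path, fmt=fmt)
        back = read_map(path, fmt=fmt)
        np.testing.assert_array_equal(back.mask, dm.mask)
        np.testing.assert_allclose(back.d[back.mask], dm.d[dm.mask], atol=1e-4)

    def test_rr_line_index_convention(self, tmp_path):
        path = tmp_path / "p.rr"
        path.write_text("1 10 0 8 0.9\n")
        dm = read_map(path, fmt="rr_pairs")
        assert dm.L == 10
        assert dm.mask[0, 9] and dm.mask[9, 0]
        assert dm.d[0, 9] == pytest.approx(4.0)  # midpoint of [0, 8]
        assert dm.confidence[0, 9] == pytest.approx(0.9)

    def test_non_square_matrix_is_an_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1 2 3 4\n1 2 3 4\n1 2 3 4\n")
        with pytest.raises(FormatError):
            read_map(path)

    def test_conflicting_duplicates_are_an_error(self, tmp_path):
        path = tmp_path / "dup.rr"
        path.write_text("1 5 0 8 0.9\n5 1 0 12 0.9\n")
        with pytest.raises(FormatError):
            read_map(path, fmt="rr_pairs")

    def test_masked_entries_survive_matrix_round_trip(self, tmp_path):
        d = np.array([[0, 5.0, 1.0], [5.0, 0, 7.0], [1.0, 7.0, 0]])
        mask = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], bool)
        dm = DistanceMap(d=d, mask=mask)
        path = tmp_path / "m.txt"
        write_map(dm, path)
        back = read_map(path)
        np.testing.assert_array_equal(back.mask, mask)


def test_distance_map_invariants_enforced():
    with pytest.raises(ValueError):
        DistanceMap(d=np.ones((3, 2)), mask=np.ones((3, 2), bool))
    asym = np.array([[0, 1.0], [2.0, 0]])
    with pytest.raises(ValueError):
        DistanceMap(d=asym, mask=np.ones((2, 2), bool))
    with pytest.raises(ValueError):
        DistanceMap(d=-np.ones((2, 2)), mask=np.ones((2, 2), bool))
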