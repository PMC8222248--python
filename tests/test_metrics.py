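"""Superposition metrics against independent oracles, and Z-score aggregation.

The independent oracles here deliberately avoid the package's code paths:
superposition uses Horn's quaternion method instead of SVD, and the
TM/GDT oracle enumerates every contiguous fragment of every length >= 4.
"""

import numpy as np
import pandas as pd
import pytest

from conftest import rotation_matrix
from oracles import gdt_oracle, quaternion_rmsd, tm_oracle
from distfold.fixtures import FixtureSpec, make_decoys, make_structure
from distfold.metrics import gdt_ts, kabsch_rmsd, tm_d0, tm_score, zscore_rank
from distfold.structio import Structure


def _chain(coords, seq=None):
    coords = np.asarray(coords, dtype=float)
    return Structure("t", seq or "A" * len(coords), coords)


class TestKabsch:
    def test_rigid_copy_has_zero_rmsd(self, coil20):
        moved = coil20.transformed(rotation_matrix([3, 1, 4], 0.8), np.array([1.0, -2, 5]))
        rmsd, R, t = kabsch_rmsd(moved, coil20)
        assert rmsd < 1e-6
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_quaternion_reference(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 5, size=(10, 3))
        b = a.copy()
        b[4] += [1.0, 0, 0]  # one residue displaced 1 Å
        assert kabsch_rmsd(_chain(a), _chain(b))[0] == pytest.approx(
            quaternion_rmsd(a, b), abs=1e-9
        )
        # and on fully random pairs
        for _ in range(5):
            a = rng.normal(0, 5, size=(12, 3))
            b = rng.normal(0, 5, size=(12, 3))
            assert kabsch_rmsd(_chain(a), _chain(b))[0] == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-9
            )

    def test_reflection_keeps_positive_rmsd(self, coil20):
        mirror = Structure("m", coil20.sequence, coil20.ca_coords * [1, 1, -1])
        assert kabsch_rmsd(mirror, coil20)[0] > 0.1

    def test_subset_below_three_is_an_error(self, coil20):
        with pytest.raises(ValueError):
            kabsch_rmsd(coil20, coil20, subset=[0, 1])


class TestTMScore:
    def test_identity_is_one(self, bundle40):
        rep = tm_score(bundle40, bundle40)
        assert rep.tm_score == pytest.approx(1.0)
        assert rep.d0 == pytest.approx(1.24 * (40 - 15) ** (1 / 3) - 1.8)

    def test_mirror_of_compact_fold_below_one(self, bundle40):
        mirror = Structure("m", bundle40.sequence, bundle40.ca_coords * [1, 1, -1])
        assert tm_score(mirror, bundle40).tm_score < 0.95

    def test_short_chain_is_an_error(self):
        s = _chain(np.cumsum(np.tile([3.8, 0, 0], (10, 1)), axis=0))
        with pytest.raises(ValueError):
            tm_score(s, s)

    def test_production_matches_exhaustive_oracle(self):
        natives = [make_structure(FixtureSpec(L=18, topology=t, seed=s))
                   for t in ("helix_bundle", "random_coil") for s in (0, 1)]
        models = [make_decoys(n, sigmas=[2.0], n_per_sigma=1, seed=5)[0] for n in natives]
        for m, n in zip(models, natives):
            fast = tm_score(m, n).tm_score
            oracle = tm_oracle(m.ca_coords, n.ca_coords)
            assert fast == pytest.approx(oracle, abs=0.01)

    def test_score_at_least_global_superposition_lower_bound(self, bundle40):
        decoy = make_decoys(bundle40, sigmas=[3.0], n_per_sigma=1, seed=2)[0]
        rmsd, R, t = kabsch_rmsd(decoy, bundle40)
        d = np.linalg.norm(decoy.ca_coords @ R.T + t - bundle40.ca_coords, axis=1)
        d0 = tm_d0(bundle40.L)
        lower = float(np.mean(1 / (1 + (d / d0) ** 2)))
        assert tm_score(decoy, bundle40).tm_score >= lower - 1e-9

    def test_monotone_degradation_with_noise(self, bundle40):
        medians = []
        for sigma in (0.5, 2.0, 6.0):
            decoys = make_decoys(bundle40, sigmas=[sigma], n_per_sigma=7, seed=3)
            medians.append(np.median([tm_score(d, bundle40).tm_score for d in decoys]))
        assert medians[0] > medians[1] > medians[2]


class TestGDT:
    def test_identity_is_hundred(self, bundle40):
        assert gdt_ts(bundle40, bundle40) == pytest.approx(100.0)

    def test_half_displaced_scores_at_least_fifty(self, bundle40):
        coords = bundle40.ca_coords.copy()
        coords[20:] += 50.0
        half = Structure("h", bundle40.sequence, coords)
        assert gdt_ts(half, bundle40) >= 50.0

    def test_production_matches_exhaustive_oracle(self):
        natives = [make_structure(FixtureSpec(L=16, topology="random_coil", seed=s))
                   for s in (3, 4)]
        for n in natives:
            m = make_decoys(n, sigmas=[2.5], n_per_sigma=1, seed=9)[0]
            oracle = gdt_oracle(m.ca_coords, n.ca_coords)
            assert gdt_ts(m, n) == pytest.approx(oracle, abs=1.0)


class TestZScoreRank:
    def test_two_predictor_two_point_z(self):
        raw = pd.DataFrame({
            "predictor": ["a", "b"], "target": ["t", "t"],
            "gdt_ts": [10.0, 20.0], "qcs": [0.0, 0.0], "molprobity": [0.0, 0.0],
        })
        out = zscore_rank(raw)
        assert out["z"].loc["a", "t"] == pytest.approx(-1.0)
        assert out["z"].loc["b", "t"] == pytest.approx(1.0)
        assert out["sum_z"]["b"] == pytest.approx(1.0)

    def test_three_by_two_hand_computed(self):
        # raw = gdt + qcs + 0.1*mol; frozen z-values hand-computed from
        # (raw - mean)/population-sd per target
        raw = pd.DataFrame({
            "predictor": ["p1", "p2", "p3"] * 2,
            "target": ["t1"] * 3 + ["t2"] * 3,
            "gdt_ts": [80.0, 60.0, 20.0, 50.0, 90.0, 70.0],
            "qcs": [70.0, 50.0, 30.0, 40.0, 80.0, 60.0],
            "molprobity": [20.0, 10.0, 0.0, 10.0, 30.0, 20.0],
        })
        out = zscore_rank(raw)
        np.testing.assert_allclose(
            out["z"].loc[["p1", "p2", "p3"], "t1"],
            [1.137431, 0.159081, -1.296512], atol=1e-5,
        )
        np.testing.assert_allclose(
            out["z"].loc[["p1", "p2", "p3"], "t2"],
            [-1.224745, 1.224745, 0.0], atol=1e-5,
        )
        # nothing below the -2 floor with three predictors (|z| <= sqrt(2))
        np.testing.assert_allclose(
            out["sum_z"].loc[["p1", "p2", "p3"]],
            [-0.087314, 1.383826, -1.296512], atol=1e-5,
        )
        # raising the floor to -1 discards p3 on t1 and p1 on t2
        out_floor = zscore_rank(raw, floor=-1.0)
        np.testing.assert_allclose(
            out_floor["sum_z"].loc[["p1", "p2", "p3"]],
            [1.137431, 1.383826, 0.0], atol=1e-5,
        )

    def test_discard_rule_triggers_below_minus_two(self):
        # six predictors, one far outlier: its z = -sqrt(5) < -2 and is discarded
        raw = pd.DataFrame({
            "predictor": list("abcdef") * 1,
            "target": ["t"] * 6,
            "gdt_ts": [10.0] * 5 + [-50.0],
            "qcs": [0.0] * 6, "molprobity": [0.0] * 6,
        })
        out = zscore_rank(raw)
        assert out["z"].loc["f", "t"] == pytest.approx(-np.sqrt(5))
        assert out["sum_z"]["f"] == 0.0
        clipped = zscore_rank(raw, discard_below_floor=False)
        assert clipped["sum_z"]["f"] == pytest.approx(-2.0)

    def test_missing_prediction_equals_zero_z(self):
        base = pd.DataFrame({
            "predictor": ["a", "b", "c"] * 2,
            "target": ["t1"] * 3 + ["t2"] * 3,
            "gdt_ts": [1.0, 2.0, 3.0, 4.0, 5.0, 4.5],
            "qcs": [0.0] * 6, "molprobity": [0.0] * 6,
        })
        # not predicting t2 contributes exactly 0, like a z of 0 would
        missing = base[~((base.predictor == "c") & (base.target == "t2"))]
        out_missing = zscore_rank(missing)
        out_full = zscore_rank(base)
        assert out_missing["sum_z"]["c"] == pytest.approx(out_full["z"].loc["c", "t1"])

    def test_zero_spread_target_gives_zero_z(self):
        raw = pd.DataFrame({
            "predictor": ["a", "b"], "target": ["t", "t"],
            "gdt_ts": [5.0, 5.0], "qcs": [0.0, 0.0], "molprobity": [0.0, 0.0],
        })
        out = zscore_rank(raw)
        assert (out["z"] == 0).all().all()

    def test_invariant_under_positive_affine_rescaling(self):
        rng = np.random.default_rng(4)
        raw = pd.DataFrame({
            "predictor": list("abcd") * 2,
            "target": ["t1"] * 4 + ["t2"] * 4,
            "gdt_ts": rng.uniform(20, 90, 8),
            "qcs": rng.uniform(20, 90, 8), "molprobity": rng.uniform(0, 40, 8),
        })
        out = zscore_rank(raw)
        scaled = raw.copy()
        for t, (slope, offset) in {"t1": (3.0, 10.0), "t2": (0.5, -4.0)}.items():
            sel = scaled.target == t
            for c in ("gdt_ts", "qcs", "molprobity"):
                scaled.loc[sel, c] = scaled.loc[sel, c] * slope
            # affine offset applied through one metric column
            scaled.loc[sel, "gdt_ts"] += offset
        out2 = zscore_rank(scaled)
        np.testing.assert_allclose(out["sum_z"], out2["sum_z"].loc[out["sum_z"].index],
                                   atol=1e-9)
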