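import numpy as np
import pytest

from cgdesign.constants import ALPHABET, AA_INDEX, BLOSUM62
from cgdesign.metrics import (blosum_scores, composition_deviation,
                              confusion_logodds, core_surface_recovery,
                              evaluate_designs, gdt_ts,
                              hydrophobic_conservation, kabsch_rmsd,
                              perplexity, recovery, rsa_classify)
from cgdesign.structures import DesignRecord
from cgdesign.synthetic import SyntheticSpec, label_sequence, make_backbone

from conftest import random_rigid_motion


def test_blosum62_table_matches_biopython():
    from Bio.Align import substitution_matrices
    ref = substitution_matrices.load("BLOSUM62")
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            assert BLOSUM62[i, j] == ref[a][b]


class TestPerplexity:
    def test_uniform_is_twenty(self):
        probs = [np.full((8, 20), 1 / 20)]
        assert np.isclose(perplexity(probs, ["ACDEFGHI"]), 20.0)

    def test_certain_is_one(self):
        native = "ACDEF"
        probs = np.zeros((5, 20))
        for i, c in enumerate(native):
            probs[i, AA_INDEX[c]] = 1.0
        assert np.isclose(perplexity([probs], [native]), 1.0)

    def test_hand_computed_two_residue_case(self):
        # probabilities 0.5 and 0.125 -> exp(-(ln .5 + ln .125)/2) = 4
        probs = np.full((2, 20), 1e-9)
        probs[0, AA_INDEX["A"]] = 0.5
        probs[1, AA_INDEX["C"]] = 0.125
        assert np.isclose(perplexity([probs], ["AC"]), 4.0, rtol=1e-6)

    def test_pooled_over_structures(self):
        # pooled: exp(mean over ALL residues), not mean of per-structure
        p1 = np.full((1, 20), 1e-9); p1[0, 0] = 0.5
        p2 = np.full((3, 20), 1e-9)
        for i in range(3):
            p2[i, 0] = 0.125
        got = perplexity([p1, p2], ["A", "AAA"])
        expected = np.exp(-(np.log(.5) + 3 * np.log(.125)) / 4)
        assert np.isclose(got, expected, rtol=1e-6)


class TestRecovery:
    def test_identical_and_disjoint(self):
        assert recovery("ACDEF", "ACDEF") == 100.0
        assert recovery("GGGGG", "ACDEF") == 0.0

    def test_partial(self):
        assert recovery("ACDEFGHIKA", "ACDEFGHIKL"[:9] + "C") == 90.0
        native = "ACDEFGHIKL"
        designed = "ACDEFGH" + "AAA"
        assert recovery(designed, native) == 70.0

    def test_masked_positions_excluded(self):
        mask = np.array([True, True, False, True])
        assert recovery("AAAA", "AACA", mask) == 100.0


class TestComposition:
    def test_identical_compositions_give_zero(self):
        dev, med = composition_deviation(["ACDEF"], ["FEDCA"])
        assert med == 0.0
        assert np.nanmax(dev) == 0.0

    def test_hand_computed_deviation(self):
        # native: A at 10%, designed: A at 15% -> deviation 0.5
        native = ["A" + "C" * 9]
        designed = ["AAAC" + "C" * 16]
        dev, _ = composition_deviation(native * 2, designed)
        assert np.isclose(dev[AA_INDEX["A"]], 0.5)

    def test_scale_free(self):
        a = composition_deviation(["ACDEF"], ["AADEF"])
        b = composition_deviation(["ACDEF"] * 4, ["AADEF"] * 4)
        assert np.allclose(a[0], b[0], equal_nan=True)


class TestConfusion:
    def test_uniform_pairing_gives_zero_matrix(self):
        # every (x, y) pair occurs exactly once: p = q_x q_y exactly
        native = "".join(a * 20 for a in ALPHABET)
        designed = ALPHABET * 20
        s, _ = confusion_logodds([native], [designed])
        assert np.abs(s).max() < 1e-12

    def test_joint_distribution_sums_to_one(self):
        rng = np.random.default_rng(0)
        native = "".join(rng.choice(list(ALPHABET), size=300))
        designed = "".join(rng.choice(list(ALPHABET), size=300))
        counts = np.zeros((20, 20))
        for x, y in zip(native, designed):
            counts[AA_INDEX[x], AA_INDEX[y]] += 1
        p = (counts + 1) / (counts + 1).sum()
        assert np.isclose(p.sum(), 1.0, atol=1e-9)
        s, r = confusion_logodds([native], [designed])
        qx, qy = p.sum(axis=1, keepdims=True), p.sum(axis=0, keepdims=True)
        assert np.allclose(s, np.log2(p / (qx * qy)), atol=1e-12)
        assert -1.0 <= r <= 1.0

    def test_self_substitution_has_positive_diagonal(self):
        rng = np.random.default_rng(1)
        native = "".join(rng.choice(list(ALPHABET), size=2000))
        s, r = confusion_logodds([native], [native])
        assert (np.diag(s) > 0).all()
        assert r > 0.5  # self-substitution resembles BLOSUM's diagonal


class TestBlosumScore:
    def test_one_hot_native_scores_relative_one(self):
        native = "AWCY"
        probs = np.zeros((4, 20))
        for i, c in enumerate(native):
            probs[i, AA_INDEX[c]] = 1.0
        absolute, relative = blosum_scores(probs, native)
        assert np.isclose(relative, 1.0)
        expected = np.mean([BLOSUM62[AA_INDEX[c], AA_INDEX[c]]
                            for c in native])
        assert np.isclose(absolute, expected)

    def test_uniform_prediction_averages_native_row(self):
        probs = np.full((1, 20), 1 / 20)
        absolute, _ = blosum_scores(probs, "W")
        assert np.isclose(absolute, BLOSUM62[AA_INDEX["W"]].mean())

    def test_score_bounded_by_native_row(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet(np.ones(20), size=6)
        native = "ACDWYM"
        absolute, _ = blosum_scores(probs, native)
        rows = np.array([BLOSUM62[AA_INDEX[c]] for c in native])
        assert rows.min() <= absolute <= rows.max()


class TestHydrophobic:
    def test_identity_is_fully_conserved(self):
        out = hydrophobic_conservation("LIKE", "LIKE")
        assert out["joint"] == 100.0

    def test_class_flip_is_zero(self):
        out = hydrophobic_conservation("LLLL", "KKKK")
        assert out["joint"] == 0.0
        assert out["hydrophobic"] == 0.0

    def test_mixed_case_hand_computed(self):
        # LKLK vs VKDE: L->V conserved (both hydrophobic), K->K conserved,
        # L->D flip, K->E conserved (both hydrophilic) -> 3/4 joint
        out = hydrophobic_conservation("LKLK", "VKDE")
        assert out["joint"] == 75.0
        assert out["hydrophobic"] == 50.0
        assert out["hydrophilic"] == 100.0


class TestRsa:
    def test_extended_peptide_is_all_surface(self):
        s = make_backbone(SyntheticSpec(segments=[("strand", 8)]))
        s.native_seq = "A" * 8
        classes = rsa_classify(s)
        assert classes == ["surface"] * 8

    def test_rigid_motion_invariant(self):
        s = make_backbone(SyntheticSpec(segments=[("helix", 10),
                                                  ("strand", 6)], seed=2))
        s.native_seq = label_sequence(s)
        base = rsa_classify(s)
        rng = np.random.default_rng(3)
        R, t = random_rigid_motion(rng)
        moved = s.transformed(R, t)
        moved.native_seq = s.native_seq
        assert rsa_classify(moved) == base

    def test_core_surface_recovery_keys(self):
        s = make_backbone(SyntheticSpec(segments=[("helix", 12)]))
        s.native_seq = label_sequence(s)
        out = core_surface_recovery(s, s.native_seq)
        assert set(out) == {"core", "surface"}
        for v in out.values():
            assert np.isnan(v) or v == 100.0


class TestKabsch:
    def test_rigid_copy_is_zero(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(10, 3)) * 5
        R, t = random_rigid_motion(rng)
        assert kabsch_rmsd(P, P @ R.T + t) < 1e-6

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(12, 3)) * 5
        Q = P + rng.normal(size=(12, 3))
        assert np.isclose(kabsch_rmsd(P, Q), kabsch_rmsd(Q, P), atol=1e-9)

    def test_matches_independent_optimizer(self):
        # displaced-atom case checked against direct numerical minimization
        # over rotations (scipy) as an independent superposition oracle
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(6)
        P = rng.normal(size=(10, 3)) * 4
        Q = P.copy()
        Q[3] += np.array([3.0, 0.0, 0.0])

        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)

        def cost(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            d = Pc @ R.T - Qc
            d = d - d.mean(axis=0)  # re-optimize translation
            return np.sqrt((d ** 2).sum() / len(P))

        best = min(minimize(cost, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 5000}).fun
                   for x0 in [np.zeros(3), np.array([0.1, -0.2, 0.3]),
                              np.array([1.0, 1.0, -1.0])])
        assert np.isclose(kabsch_rmsd(P, Q), best, atol=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


class TestGdtTs:
    def test_identical_structures_score_100(self):
        rng = np.random.default_rng(7)
        P = rng.normal(size=(20, 3)) * 6
        assert gdt_ts(P, P) == 100.0

    def test_incommensurate_scales_score_near_zero(self):
        # collinear traces with 1 A vs 30 A spacing: no superposition can
        # bring more than one pair within 8 A
        n = 20
        P = np.stack([np.arange(n), np.zeros(n), np.zeros(n)], axis=1) * 1.0
        Q = P * 30.0
        assert gdt_ts(P, Q) <= 100.0 / n + 1e-9

    def test_matches_exhaustive_seed_oracle(self):
        # independent oracle: exhaustive enumeration of contiguous seeds of
        # every length >= 3, each refined the same way
        from cgdesign.metrics import kabsch_rotation
        rng = np.random.default_rng(8)
        P = rng.normal(size=(20, 3)) * 6
        Q = P.copy()
        Q[10:] += rng.normal(size=(10, 3)) * 1.5

        def distances(subset):
            R, cP, cQ = kabsch_rotation(P[subset], Q[subset])
            return np.linalg.norm((P - P[subset].mean(axis=0)) @ R.T
                                  - (Q - Q[subset].mean(axis=0)), axis=1)

        cand = [distances(np.arange(20))]
        for length in range(3, 21):
            for start in range(0, 21 - length):
                subset = np.arange(start, start + length)
                for _ in range(3):
                    d = distances(subset)
                    grown = np.flatnonzero(d <= 4.0)
                    if len(grown) < 3 or np.array_equal(grown, subset):
                        break
                    subset = grown
                cand.append(distances(subset))
        dmat = np.stack(cand)
        oracle = np.mean([100.0 * (dmat <= c).mean(axis=1).max()
                          for c in (1.0, 2.0, 4.0, 8.0)])
        impl = gdt_ts(P, Q)
        assert impl <= oracle + 1e-9
        assert oracle - impl < 5.0  # 7-mer seeding recovers the optimum here
        assert np.isclose(impl, oracle, atol=1e-6)


class TestEvaluateDesigns:
    def _native_records(self, structures):
        records = []
        for s in structures:
            probs = np.zeros((s.length, 20))
            for i, c in enumerate(s.native_seq):
                probs[i, AA_INDEX[c]] = 1.0
            records.append(DesignRecord(
                structure_id=s.name, probabilities=probs,
                sequences=[s.native_seq], temperature=0.0, seed=0))
        return records

    def test_native_self_evaluation_fixed_point(self):
        structures = []
        for seed in (1, 2):
            s = make_backbone(SyntheticSpec(
                segments=[("helix", 10), ("coil", 5), ("strand", 8)],
                seed=seed))
            s.native_seq = label_sequence(s)
            structures.append(s)
        report = evaluate_designs(structures, self._native_records(structures))
        assert report.recovery_median == 100.0
        assert report.recovery_pooled == 100.0
        assert np.isclose(report.perplexity, 1.0)
        assert np.isclose(report.relative_blosum_score_median, 1.0)
        assert report.composition_rel_dev_median == 0.0
        assert report.hydrophobic_conservation["joint"] == 100.0
        assert report.lcr_percent == report.native_lcr_percent

    def test_length_mismatch_rejected(self):
        s = make_backbone(SyntheticSpec(segments=[("helix", 10)]))
        s.native_seq = label_sequence(s)
        record = DesignRecord(
            structure_id=s.name, probabilities=np.full((5, 20), 1 / 20),
            sequences=["AAAAA"], temperature=0.0, seed=0)
        with pytest.raises(ValueError, match="length"):
            evaluate_designs([s], [record])
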