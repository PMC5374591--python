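import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from burialcrf import (
    FeatureConfig,
    assemble_singlet_features,
    build_doublet_features,
    contact_number,
    cosine_doublet,
    mutual_information,
    mutual_information_doublet,
    one_hot_profile,
    sequence_conservation,
)
from burialcrf.pssm import SequenceProfile


def random_profile(rng, L):
    freq = rng.dirichlet(np.ones(20), size=L)
    return SequenceProfile(frequencies=freq)


class TestConservation:
    def test_zero_iff_background(self, rng):
        prof = SequenceProfile(frequencies=np.full((3, 20), 0.05))
        np.testing.assert_allclose(sequence_conservation(prof), 0.0, atol=1e-12)
        prof2 = random_profile(rng, 5)
        sc = sequence_conservation(prof2)
        assert (sc > 1e-6).all()  # random columns differ from background

    def test_point_mass_closed_form(self):
        freq = np.zeros((1, 20))
        freq[0, 0] = 1.0
        prof = SequenceProfile(frequencies=freq)
        assert sequence_conservation(prof)[0] == pytest.approx(np.log2(20))

    def test_matches_direct_summation(self, rng):
        prof = random_profile(rng, 10)
        q = rng.dirichlet(np.ones(20))
        prof.background = q
        sc = sequence_conservation(prof)
        for i in range(10):
            direct = sum(
                p * np.log2(p / q[a])
                for a, p in enumerate(prof.frequencies[i])
                if p > 0
            )
            assert sc[i] == pytest.approx(direct, abs=1e-12)


class TestContactNumber:
    def test_pair_inside_radius(self):
        coords = np.zeros((6, 3))
        coords[5] = [7.9, 0, 0]
        coords[1:5] = 1000.0  # park the middle residues far away
        cn = contact_number(coords)
        assert cn[0] == 1 and cn[5] == 1

    def test_boundary_is_strict(self):
        coords = np.zeros((6, 3))
        coords[5] = [8.0, 0, 0]
        coords[1:5] = 1000.0
        assert contact_number(coords).sum() == 0

    def test_matches_all_pairs_brute_force(self, rng):
        coords = rng.uniform(0, 25, size=(30, 3))
        cn = contact_number(coords)
        for i in range(30):
            ref = sum(
                1
                for j in range(30)
                if abs(i - j) >= 5 and np.linalg.norm(coords[i] - coords[j]) < 8.0
            )
            assert cn[i] == ref

    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(0, 25, size=(25, 3))
        R = Rotation.random(random_state=7).as_matrix()
        moved = coords @ R.T + np.array([3.0, -11.0, 42.0])
        np.testing.assert_array_equal(contact_number(coords), contact_number(moved))

    def test_short_chain_all_zero(self):
        assert contact_number(np.zeros((4, 3))).sum() == 0


class TestDoubletFeatures:
    def test_outer_product_mi_is_zero(self, rng):
        prof = random_profile(rng, 6)
        for d in (2, 3, 4):
            assert mutual_information_doublet(prof, 5, d) == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_correlated_joint_one_bit(self):
        prof = one_hot_profile("ACDE")
        joint = np.diag([0.5, 0.5])
        assert mutual_information_doublet(prof, 2, 2, joint=joint) == pytest.approx(1.0)

    def test_mi_matches_direct_summation(self, rng):
        joint = rng.dirichlet(np.ones(16)).reshape(4, 4)
        mi = mutual_information(joint)
        pr, pc = joint.sum(1), joint.sum(0)
        direct = sum(
            joint[a, b] * np.log2(joint[a, b] / (pr[a] * pc[b]))
            for a in range(4)
            for b in range(4)
            if joint[a, b] > 0
        )
        assert mi == pytest.approx(direct, abs=1e-12)
        assert mi == pytest.approx(mutual_information(joint.T), abs=1e-12)  # symmetry

    def test_cosine_identical_and_orthogonal(self):
        prof = one_hot_profile("AAC")
        assert cosine_doublet(prof, 1, 1) == pytest.approx(1.0)
        assert cosine_doublet(prof, 2, 1) == pytest.approx(0.0)

    def test_cosine_matches_formula_and_symmetry(self, rng):
        prof = random_profile(rng, 8)
        a, b = prof.frequencies[2], prof.frequencies[6]
        ref = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cosine_doublet(prof, 6, 4) == pytest.approx(ref, abs=1e-12)

    def test_out_of_range_positions(self, rng):
        prof = random_profile(rng, 5)
        with pytest.raises(IndexError):
            mutual_information_doublet(prof, 1, 2)
        with pytest.raises(IndexError):
            cosine_doublet(prof, 1, 2)

    def test_build_doublet_matrices(self, rng):
        prof = random_profile(rng, 9)
        U = build_doublet_features(prof)
        assert set(U) == {1, 2, 3, 4}
        for d in (2, 3, 4):
            assert U[d].shape == (9, 4)
            assert (U[d][:d] == 0).all()        # rows without a partner
            assert (U[d][d:, 0] == 1).all()      # bias
            assert (U[d][:, 1] >= 0).all()       # MI
            assert (np.abs(U[d][:, 2]) <= 1).all()  # cosine
            assert (U[d][:, 3] == 0).all()       # cmap default


class TestSingletAssembly:
    def test_minimal_one_hot_config(self):
        cfg = FeatureConfig(
            include_bias=False,
            include_terminal=False,
            include_profile=False,
            include_conservation=False,
            include_ss_probs=False,
        )
        X, reg = assemble_singlet_features("ACD", config=cfg)
        assert X.shape == (3, 21)
        assert reg.names() == ["residue_onehot"]
        np.testing.assert_array_equal(X.sum(axis=1), np.ones(3))

    def test_width_equals_registry_sum(self, rng):
        prof = random_profile(rng, 4)
        X, reg = assemble_singlet_features("ACDE", profile=prof, ss_string="HHCC")
        assert X.shape[1] == reg.width == sum(w for _, w in reg.groups)

    def test_profile_group_equals_frequency_rows(self, rng):
        prof = random_profile(rng, 4)
        X, reg = assemble_singlet_features("ACDE", profile=prof)
        np.testing.assert_array_equal(X[:, reg.slice_of("profile")], prof.frequencies)

    def test_missing_groups_zero_filled_and_flagged(self):
        X, reg = assemble_singlet_features("ACDE")
        assert "profile:missing" in reg.names()
        assert (X[:, reg.slice_of("profile:missing")] == 0).all()

    def test_deterministic(self, rng):
        prof = random_profile(rng, 4)
        a, _ = assemble_singlet_features("ACDE", profile=prof, ss_string="HHCC")
        b, _ = assemble_singlet_features("ACDE", profile=prof, ss_string="HHCC")
        assert a.tobytes() == b.tobytes()

    def test_window_columns(self, rng):
        prof = random_profile(rng, 5)
        cfg = FeatureConfig(window=1)
        X, reg = assemble_singlet_features("ACDEF", profile=prof, config=cfg)
        left = X[:, reg.slice_of("profile@-1")]
        assert (left[0] == 0).all()
        np.testing.assert_array_equal(left[1:], prof.frequencies[:-1])

    def test_length_mismatch_rejected(self, rng):
        prof = random_profile(rng, 3)
        with pytest.raises(ValueError):
            assemble_singlet_features("ACDE", profile=prof)
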