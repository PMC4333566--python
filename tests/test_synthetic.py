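"""Ground-truth generators: determinism, construction accuracy."""
import numpy as np
import pytest

from memprobe.alignment import conservation_profile
from memprobe.geometry import dihedral
from memprobe.secondary import helicity_profile
from memprobe.synthetic import (
    HELIX_PHI,
    HELIX_PSI,
    HelixSpec,
    MsaSpec,
    build_backbone,
    derive_seed,
    expected_helical_mask,
    gen_dose_response,
    gen_helix_trajectory,
    gen_msa,
    gen_spherical_pocket,
)


class TestMsaGenerator:
    def test_frequency_one_gives_exact_100(self):
        aln, _ = gen_msa(MsaSpec(n_rows=20, length=5, class_freq=1.0, seed=1))
        prof = conservation_profile(aln)
        np.testing.assert_allclose(prof.class_pct, 100.0)

    def test_same_seed_reproduces_bytes(self):
        a1, _ = gen_msa(MsaSpec(n_rows=30, length=8, seed=42))
        a2, _ = gen_msa(MsaSpec(n_rows=30, length=8, seed=42))
        assert a1.rows == a2.rows and a1.ids == a2.ids

    def test_different_seed_differs(self):
        a1, _ = gen_msa(MsaSpec(n_rows=30, length=8, seed=42))
        a2, _ = gen_msa(MsaSpec(n_rows=30, length=8, seed=43))
        assert a1.rows != a2.rows

    def test_reference_row_gap_free(self):
        aln, _ = gen_msa(MsaSpec(n_rows=40, length=12, gap_prob=0.5, seed=3))
        assert "-" not in aln.reference_row

    def test_binomial_recovery_at_n1000(self):
        aln, _ = gen_msa(MsaSpec(n_rows=1000, length=10, class_freq=0.8, seed=7))
        prof = conservation_profile(aln)
        assert np.all(np.abs(prof.class_pct - 80.0) < 3.0)


class TestBackboneBuilder:
    def test_helical_ca_ca_distance(self, ideal_helix_20):
        ca = ideal_helix_20.coords[ideal_helix_20.select(names="CA")]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        np.testing.assert_allclose(d, 3.8, atol=0.05)

    def test_helical_rise_per_residue(self):
        frame = build_backbone(HELIX_PHI, HELIX_PSI, 18)
        ca = frame.coords[frame.select(names="CA")]
        centered = ca - ca.mean(axis=0)
        axis = np.linalg.svd(centered)[2][0]
        proj = centered @ axis
        rise = np.abs(np.diff(np.sort(proj))).mean()
        assert rise == pytest.approx(1.5, abs=0.1)

    def test_dihedral_round_trip(self, rng):
        n = 10
        phi = rng.uniform(-180, 180, n)
        psi = rng.uniform(-180, 180, n)
        frame = build_backbone(phi, psi, n)
        N = frame.coords[frame.select(names="N")]
        CA = frame.coords[frame.select(names="CA")]
        C = frame.coords[frame.select(names="C")]
        for i in range(1, n):
            assert dihedral(C[i - 1], N[i], CA[i], C[i]) == pytest.approx(
                phi[i], abs=1e-6
            )
        for i in range(n - 1):
            assert dihedral(N[i], CA[i], C[i], N[i + 1]) == pytest.approx(
                psi[i], abs=1e-6
            )

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_backbone(-57.0, -47.0, 1)


class TestHelixTrajectoryGenerator:
    def test_no_unwinding_interior_fully_helical(self):
        trajs, truth = gen_helix_trajectory(
            HelixSpec(n_residues=10, n_frames=5, n_replicas=1, seed=0)
        )
        prof = helicity_profile(trajs)
        np.testing.assert_allclose(prof.mean[1:9], 1.0)
        np.testing.assert_allclose(prof.mean, truth["mean_fraction"])

    def test_unwind_fraction_recovered_exactly_without_noise(self):
        trajs, truth = gen_helix_trajectory(
            HelixSpec(n_residues=20, n_frames=50, n_replicas=2,
                      unwind={10: 0.4}, seed=5)
        )
        prof = helicity_profile(trajs)
        np.testing.assert_allclose(prof.per_replica, truth["per_replica_fraction"])
        assert truth["per_replica_fraction"][0][9] == pytest.approx(0.6)

    def test_distinct_replicas_have_positive_sd(self):
        trajs, _ = gen_helix_trajectory(
            HelixSpec(n_residues=15, n_frames=30, n_replicas=3,
                      unwind={8: 0.5}, seed=9)
        )
        assert helicity_profile(trajs).sd[7] > 0.0

    def test_identical_replica_seeds_give_sd_zero(self):
        trajs, _ = gen_helix_trajectory(
            HelixSpec(n_residues=15, n_frames=30, n_replicas=3,
                      unwind={8: 0.5}, seed=9, replica_seeds=[11, 11, 11])
        )
        np.testing.assert_allclose(helicity_profile(trajs).sd, 0.0, atol=1e-12)

    def test_determinism(self):
        spec = HelixSpec(n_residues=10, n_frames=5, n_replicas=2,
                         unwind={5: 0.4}, seed=21)
        t1, _ = gen_helix_trajectory(spec)
        t2, _ = gen_helix_trajectory(spec)
        for a, b in zip(t1, t2):
            for fa, fb in zip(a.frames, b.frames):
                np.testing.assert_array_equal(fa.coords, fb.coords)

    def test_expected_mask_matches_geometry(self, rng):
        from memprobe.secondary import assign_secondary_structure
        from memprobe.synthetic import UNWOUND_PHI_RANGE, UNWOUND_PSI_RANGE

        n = 25
        for _ in range(20):
            unwound = set(
                int(r) for r in rng.choice(np.arange(1, n + 1),
                                           size=rng.integers(0, 4), replace=False)
            )
            phi = np.full(n, HELIX_PHI)
            psi = np.full(n, HELIX_PSI)
            for r in unwound:
                phi[r - 1] = rng.uniform(*UNWOUND_PHI_RANGE)
                psi[r - 1] = rng.uniform(*UNWOUND_PSI_RANGE)
            frame = build_backbone(phi, psi, n)
            got = assign_secondary_structure(frame).codes == "H"
            np.testing.assert_array_equal(got, expected_helical_mask(n, unwound))


class TestOtherGenerators:
    def test_dose_response_midpoint_identity(self):
        data, _ = gen_dose_response(7.0, concentrations=[1e-7], top=100.0,
                                    bottom=20.0)
        assert data.signal[0] == pytest.approx(60.0)

    def test_dose_response_asymptote(self):
        # far below IC50 the competitor displaces nothing: signal -> top
        data, _ = gen_dose_response(7.0, hill=-1.0, concentrations=[1e-13],
                                    top=100.0, bottom=0.0)
        assert data.signal[0] == pytest.approx(100.0, abs=0.01)

    def test_spherical_pocket_on_shell(self):
        fr = gen_spherical_pocket(radius=8.0, n_atoms=100)
        r = np.linalg.norm(fr.coords, axis=1)
        np.testing.assert_allclose(r, 8.0, atol=1e-9)

    def test_derive_seed_stable_and_bounded(self):
        assert derive_seed(3, "msa") == derive_seed(3, "msa")
        assert derive_seed(3, "msa") != derive_seed(3, "helix")
        assert 0 <= derive_seed(2**20, "x") < 2**31
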