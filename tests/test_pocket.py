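"""Cavity volume, contact occupancy, salt bridges and area per lipid."""
import numpy as np
import pytest

from memprobe.pdbio import StructureFrame, Trajectory
from memprobe.pocket import (
    CavityConfig,
    area_per_lipid,
    cavity_volume,
    contact_occupancy,
    salt_bridge_trace,
)
from memprobe.synthetic import (
    gen_contact_trace,
    gen_lipid_boxes,
    gen_salt_bridge_trace,
    gen_spherical_pocket,
)

from conftest import random_rotation


def _frame(names, resids, resnames, coords, chains=None, box=None):
    n = len(names)
    return StructureFrame(
        atom_names=np.array(names),
        residue_numbers=np.array(resids, dtype=int),
        residue_names=np.array(resnames),
        chains=np.array(chains) if chains is not None else np.full(n, "A"),
        coords=np.asarray(coords, dtype=float),
        box=box,
    )


_EMPTY = _frame([], [], [], np.zeros((0, 3)))


def _region(half):
    return ((-half, half), (-half, half), (-half, half))


class TestCavityVolume:
    def test_empty_region_is_exact(self):
        cfg = CavityConfig(region=_region(10.0), seed_point=(0, 0, 0),
                           grid_spacing=1.0)
        assert cavity_volume(_EMPTY, cfg) == pytest.approx(8000.0)

    def test_single_atom_occlusion_matches_analytic_sphere(self):
        atom = _frame(["C"], [1], ["SPH"], [[0.0, 0.0, 0.0]])
        cfg = CavityConfig(region=_region(10.0), seed_point=(9.0, 9.0, 9.0),
                           grid_spacing=0.5, probe_radius=1.4)
        v = cavity_volume(atom, cfg)
        excluded = 8000.0 - v
        analytic = 4.0 / 3.0 * np.pi * (1.7 + 1.4) ** 3
        assert excluded == pytest.approx(analytic, rel=0.05)

    def test_convergence_under_grid_refinement(self):
        shell = gen_spherical_pocket(radius=10.0, n_atoms=500)
        v = {}
        for spacing in (1.0, 0.5):
            cfg = CavityConfig(region=_region(8.0), seed_point=(0, 0, 0),
                               grid_spacing=spacing)
            v[spacing] = cavity_volume(shell, cfg)
        assert abs(v[0.5] - v[1.0]) / v[0.5] < 0.02

    def test_monotone_nonincreasing_as_atoms_added(self, rng):
        cfg = CavityConfig(region=_region(8.0), seed_point=(7.0, 7.0, 7.0),
                           grid_spacing=1.0)
        coords = rng.uniform(-4, 4, size=(8, 3))
        prev = cavity_volume(_EMPTY, cfg)
        for k in range(1, len(coords) + 1):
            fr = _frame(["C"] * k, range(1, k + 1), ["X"] * k, coords[:k])
            vol = cavity_volume(fr, cfg)
            assert vol <= prev + 1e-9
            prev = vol

    def test_occluded_seed_rejected(self):
        atom = _frame(["C"], [1], ["X"], [[0.0, 0.0, 0.0]])
        cfg = CavityConfig(region=_region(5.0), seed_point=(0, 0, 0))
        with pytest.raises(ValueError, match="occluded"):
            cavity_volume(atom, cfg)

    def test_seed_outside_region_rejected(self):
        with pytest.raises(ValueError, match="inside region"):
            CavityConfig(region=_region(5.0), seed_point=(9.0, 0, 0))


class TestContactOccupancy:
    def test_fixed_close_ligand_fraction_one(self):
        frames = []
        for f in range(5):
            frames.append(_frame(
                ["CA", "C1"], [1, 900], ["ALA", "LIG"],
                [[0, 0, 0], [3.0, 0, 0]], chains=["A", "L"],
            ))
        occ = contact_occupancy(Trajectory(frames=frames),
                                {"resnames": "LIG"}, [1], cutoff=6.0)
        assert occ.fractions[0] == 1.0

    def test_constructed_21_percent(self):
        traj, truth = gen_contact_trace(n_frames=100, target_fraction=0.21, seed=4)
        occ = contact_occupancy(traj, truth["ligand_selection"],
                                [truth["contact_residue"]])
        assert occ.fractions[0] == pytest.approx(0.21)

    def test_tiny_cutoff_all_zero(self):
        traj, truth = gen_contact_trace(n_frames=20, target_fraction=1.0, seed=4)
        occ = contact_occupancy(traj, truth["ligand_selection"],
                                [truth["contact_residue"]], cutoff=0.1)
        assert occ.fractions[0] == 0.0

    def test_pooling_is_frame_weighted(self):
        t1, tr1 = gen_contact_trace(n_frames=50, target_fraction=0.2, seed=1)
        t2, tr2 = gen_contact_trace(n_frames=150, target_fraction=0.4, seed=2)
        t2 = Trajectory(frames=t2.frames, replica_id="contact2")
        occ = contact_occupancy([t1, t2], tr1["ligand_selection"],
                                [tr1["contact_residue"]])
        pooled = (0.2 * 50 + 0.4 * 150) / 200
        assert occ.fractions[0] == pytest.approx(pooled)
        assert occ.per_replica["contact"][0] == pytest.approx(0.2)
        assert occ.per_replica["contact2"][0] == pytest.approx(0.4)

    def test_frame_order_invariance(self):
        traj, truth = gen_contact_trace(n_frames=40, target_fraction=0.3, seed=6)
        base = contact_occupancy(traj, truth["ligand_selection"],
                                 [truth["contact_residue"]]).fractions
        rev = Trajectory(frames=list(reversed(traj.frames)), replica_id="r")
        out = contact_occupancy(rev, truth["ligand_selection"],
                                [truth["contact_residue"]]).fractions
        np.testing.assert_allclose(out, base)

    def test_rigid_transform_invariance(self, rng):
        traj, truth = gen_contact_trace(n_frames=30, target_fraction=0.5, seed=8)
        base = contact_occupancy(traj, truth["ligand_selection"],
                                 [truth["contact_residue"]]).fractions
        R = random_rotation(rng)
        t = rng.normal(size=3) * 30
        moved = Trajectory(
            frames=[fr.transformed(R, t) for fr in traj.frames], replica_id="m"
        )
        out = contact_occupancy(moved, truth["ligand_selection"],
                                [truth["contact_residue"]]).fractions
        np.testing.assert_allclose(out, base)

    def test_empty_ligand_selection_rejected(self):
        traj, _ = gen_contact_trace(n_frames=5, target_fraction=0.0, seed=0)
        with pytest.raises(ValueError, match="empty ligand"):
            contact_occupancy(traj, {"resnames": "NOPE"}, [5])


class TestSaltBridge:
    _DONORS = {"resids": 694, "names": ["HZ1", "HZ2", "HZ3"]}
    _ACCEPTORS = {"resids": 670, "names": ["OD1", "OD2"]}

    def test_constructed_35_percent(self):
        traj, truth = gen_salt_bridge_trace(n_frames=100, occupancy=0.35, seed=3)
        trace = salt_bridge_trace(traj, self._DONORS, self._ACCEPTORS, 3.5)
        assert trace.occupancy == pytest.approx(0.35)
        assert trace.mean == pytest.approx(truth["mean"])
        assert trace.sd == pytest.approx(truth["sd"])

    def test_exact_threshold_excluded_under_strict_inequality(self):
        traj, _ = gen_salt_bridge_trace(distances=[3.5] * 10)
        trace = salt_bridge_trace(traj, self._DONORS, self._ACCEPTORS, 3.5)
        assert trace.occupancy == 0.0

    def test_minimum_over_pairs(self):
        # acceptors at 4 Å and 2 Å from nearest donor -> minimum 2 Å
        fr = _frame(
            ["HZ1", "OD1", "OD2"], [694, 670, 670], ["LYS", "ASP", "ASP"],
            [[0, 0, 0], [4.0, 0, 0], [-2.0, 0, 0]],
        )
        trace = salt_bridge_trace(
            Trajectory(frames=[fr]),
            {"resids": 694, "names": "HZ1"},
            {"resids": 670, "names": ["OD1", "OD2"]},
        )
        assert trace.distances[0] == pytest.approx(2.0)

    def test_occupancy_equals_empirical_cdf_below_threshold(self, rng):
        dists = rng.uniform(2.0, 6.0, size=200)
        traj, _ = gen_salt_bridge_trace(distances=dists)
        for thr in (2.5, 3.5, 4.5):
            trace = salt_bridge_trace(traj, self._DONORS, self._ACCEPTORS, thr)
            assert trace.occupancy == pytest.approx((dists < thr).mean())

    def test_unknown_atom_name_reported(self):
        traj, _ = gen_salt_bridge_trace(n_frames=3, occupancy=0.0)
        with pytest.raises(KeyError, match="NE2"):
            salt_bridge_trace(traj, {"names": "NE2"}, self._ACCEPTORS)


class TestAreaPerLipid:
    def _boxed(self, boxes):
        frames = []
        for i, b in enumerate(boxes):
            frames.append(_frame(["P"], [1], ["POP"], [[0, 0, 0]],
                                 box=np.array(b, dtype=float)))
        return Trajectory(frames=frames)

    def test_hand_example(self):
        traj = self._boxed([[80.0, 80.0, 100.0]])
        series = area_per_lipid(traj, 200)
        assert series.areas[0] == pytest.approx(64.0)

    def test_constant_box_sd_zero(self):
        traj = self._boxed([[80.0, 80.0, 100.0]] * 5)
        assert area_per_lipid(traj, 200).sd == 0.0

    def test_protein_area_correction(self):
        traj = self._boxed([[80.0, 80.0, 100.0]])
        series = area_per_lipid(traj, 200, protein_area=400.0)
        assert series.areas[0] == pytest.approx((6400.0 - 400.0) / 100.0)

    def test_generator_hits_target(self):
        traj, truth = gen_lipid_boxes(n_frames=50, area_per_lipid=65.58,
                                      n_lipids_total=200, jitter_sd=0.0)
        series = area_per_lipid(traj, 200)
        assert series.mean == pytest.approx(65.58, abs=1e-9)
        assert series.sd == 0.0

    def test_missing_box_rejected(self):
        fr = _frame(["P"], [1], ["POP"], [[0, 0, 0]])
        with pytest.raises(ValueError, match="no box"):
            area_per_lipid(Trajectory(frames=[fr]), 200)

    def test_odd_lipid_count_rejected(self):
        traj = self._boxed([[80.0, 80.0, 100.0]])
        with pytest.raises(ValueError, match="even"):
            area_per_lipid(traj, 201)
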