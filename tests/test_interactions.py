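"""Contacts, salt bridges, RDFs, superposition and RMSD series."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ionsite import interactions as ia
from ionsite import synth
from ionsite.structio import AtomRecord, Selection, Structure, Trajectory


class TestContacts:
    def test_pair_within_threshold(self):
        atoms = [
            AtomRecord(1, "O", "O", "GLU", 343, "A", 0, 0, 0),
            AtomRecord(2, "O", "O", "VAL", 341, "A", 3.4, 0, 0),
        ]
        st = Structure(atoms)
        cl = ia.contacts(st, Selection(resid=343), Selection(resid=341))
        assert len(cl) == 1
        assert cl.pairs[0][2] == pytest.approx(3.4)

    def test_each_pair_reported_once_no_self_pairs(self, k_site):
        cl = ia.contacts(k_site, Selection(element="O"), Selection(element="O"), 10.0)
        labels = {frozenset((a, b)) for a, b, _ in cl.pairs}
        assert len(labels) == len(cl.pairs)
        assert all(a != b for a, b, _ in cl.pairs)

    def test_empty_selection_gives_empty_list(self, k_site):
        cl = ia.contacts(k_site, Selection(chain="Z"), Selection(element="O"))
        assert len(cl) == 0


class TestSaltBridge:
    def test_static_bound(self, saltbridge_topology):
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=saltbridge_topology, sigma=0.0, n_frames=20)
        )
        series = ia.saltbridge_series(
            traj, Selection(name="NZ"), Selection(resname="GLU"), 4.0
        )
        # N at (3, 0, 0), O-pair COM at (-0.25, 0, 0)
        assert series.distances == pytest.approx(np.full(20, 3.25))
        assert series.occupancy == 1.0

    def test_two_state_occupancy_recovers_bernoulli_p(self, saltbridge_topology):
        ts = synth.TwoStateSpec(
            atom_index=0, anchor_index=1, d_bound=2.7, d_unbound=5.0, p_bound=0.7
        )
        traj = synth.make_trajectory(
            synth.TrajSpec(
                reference=saltbridge_topology, sigma=0.0, n_frames=10_000,
                seed=17, two_state=ts,
            )
        )
        series = ia.saltbridge_series(
            traj, Selection(name="NZ"), Selection(resname="GLU"), 4.0
        )
        assert series.occupancy == pytest.approx(0.7, abs=0.01)

    def test_all_unbound_gives_zero(self, saltbridge_topology):
        ts = synth.TwoStateSpec(
            atom_index=0, anchor_index=1, d_bound=5.0, d_unbound=6.0, p_bound=0.5
        )
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=saltbridge_topology, n_frames=100, seed=1, two_state=ts)
        )
        series = ia.saltbridge_series(
            traj, Selection(name="NZ"), Selection(resname="GLU"), 4.0
        )
        assert series.occupancy == 0.0

    def test_wrong_oxygen_count_rejected(self, saltbridge_topology):
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=saltbridge_topology, n_frames=2)
        )
        with pytest.raises(ValueError):
            ia.saltbridge_series(traj, Selection(name="NZ"), Selection(name="OE1"), 4.0)


class TestRDF:
    def test_constant_distance_single_bin(self, saltbridge_topology):
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=saltbridge_topology, sigma=0.0, n_frames=50)
        )
        result = ia.rdf(traj, Selection(name="NZ"), Selection(resname="GLU"),
                        bin_width=0.1, r_max=6.0)
        # all mass in the bin containing 3.25 Å
        idx = np.searchsorted(result.bin_edges, 3.25, side="right") - 1
        assert result.g[idx] * 0.1 == pytest.approx(1.0)
        assert np.sum(result.g) * 0.1 == pytest.approx(1.0)

    def test_probability_density_integrates_to_one(self, saltbridge_topology):
        ts = synth.TwoStateSpec(
            atom_index=0, anchor_index=1, d_bound=2.7, d_unbound=5.0, p_bound=0.7
        )
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=saltbridge_topology, sigma=0.05,
                           n_frames=2000, seed=5, two_state=ts)
        )
        result = ia.rdf(traj, Selection(name="NZ"), Selection(resname="GLU"),
                        bin_width=0.05, r_max=8.0)
        assert np.sum(result.g) * 0.05 == pytest.approx(1.0, abs=1e-6)

    def test_two_state_peak_mass_ratio(self, saltbridge_topology):
        ts = synth.TwoStateSpec(
            atom_index=0, anchor_index=1, d_bound=2.7, d_unbound=5.0, p_bound=0.7
        )
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=saltbridge_topology, sigma=0.0,
                           n_frames=10_000, seed=23, two_state=ts)
        )
        result = ia.rdf(traj, Selection(name="NZ"), Selection(resname="GLU"),
                        bin_width=0.1, r_max=8.0)
        centers = result.bin_centers
        mass_bound = np.sum(result.g[centers < 4.0]) * 0.1
        mass_unbound = np.sum(result.g[centers >= 4.0]) * 0.1
        assert mass_bound == pytest.approx(0.7, abs=0.02)
        assert mass_unbound == pytest.approx(0.3, abs=0.02)

    def test_ideal_gas_shell_normalized_is_flat_unity(self):
        traj = synth.make_ideal_gas(2, box=20.0, n_frames=40_000, seed=9)
        result = ia.rdf(
            traj, Selection(resid=1), Selection(resid=2),
            bin_width=0.5, r_max=8.0, mode="shell_normalized",
        )
        band = (result.bin_centers > 2.0) & (result.bin_centers < 8.0)
        assert np.mean(result.g[band]) == pytest.approx(1.0, abs=0.03)
        # every bin in the band within 3x its sampling error of 1
        centers = result.bin_centers[band]
        expected_counts = 40_000 * 4 * math.pi * centers**2 * 0.5 / 20.0**3
        rel_err = 3.0 / np.sqrt(expected_counts)
        assert np.all(np.abs(result.g[band] - 1.0) < np.maximum(3 * rel_err, 0.1))

    def test_shell_normalized_needs_box_or_density(self, saltbridge_topology):
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=saltbridge_topology, n_frames=3)
        )
        with pytest.raises(ValueError):
            ia.rdf(traj, Selection(name="NZ"), Selection(resname="GLU"),
                   mode="shell_normalized")

    def test_nm_export_rescales_axis_and_density(self, saltbridge_topology):
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=saltbridge_topology, sigma=0.0, n_frames=10)
        )
        result = ia.rdf(traj, Selection(name="NZ"), Selection(resname="GLU"),
                        bin_width=0.1, r_max=6.0)
        nm = result.in_nm()
        assert nm.bin_edges[-1] == pytest.approx(0.6)
        assert np.sum(nm.g) * 0.01 == pytest.approx(1.0)


class TestSuperpose:
    def test_identity_on_self(self):
        rng = np.random.default_rng(0)
        ref = rng.random((8, 3)) * 10
        moved, R, t, rmsd = ia.superpose(ref, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(1)
        ref = rng.random((10, 3)) * 10
        R_true = Rotation.from_euler("xyz", [90, 30, -45], degrees=True).as_matrix()
        mobile = ref @ R_true.T + np.array([5.0, -2.0, 7.0])
        moved, R, t, rmsd = ia.superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(moved, ref, atol=1e-6)

    def test_never_reflects(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.random((5, 3))
            b = rng.random((5, 3))
            _, R, _, _ = ia.superpose(a, b)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self):
        """Independent cross-check of the rotation against scipy's solver."""
        rng = np.random.default_rng(3)
        ref = rng.random((12, 3)) * 5
        mobile = ref @ Rotation.random(random_state=4).as_matrix().T + 1.0
        mobile = mobile + rng.normal(0, 0.1, mobile.shape)
        _, R, _, rmsd = ia.superpose(mobile, ref)
        A = mobile - mobile.mean(axis=0)
        B = ref - ref.mean(axis=0)
        rot, _ = Rotation.align_vectors(B, A)
        np.testing.assert_allclose(R, rot.as_matrix(), atol=1e-8)

    def test_noisy_copy_rmsd_matches_noise_model(self):
        """With 3-D Gaussian noise σ per coordinate, the expected mean-square
        deviation per atom is 3σ² (minus the d.o.f. absorbed by the fit)."""
        rng = np.random.default_rng(5)
        ref = rng.random((500, 3)) * 20
        sigma = 0.1
        mobile = ref + rng.normal(0, sigma, ref.shape)
        _, _, _, rmsd = ia.superpose(mobile, ref)
        assert rmsd == pytest.approx(sigma * math.sqrt(3), rel=0.05)

    def test_collinear_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError):
            ia.superpose(pts, pts[::-1])


class TestRMSDSeries:
    def test_zero_for_copies_of_reference(self, k_site):
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=k_site, sigma=0.0, n_frames=6)
        )
        series = ia.rmsd_series(
            traj, Selection(element="O"), k_site, Selection(element="O")
        )
        assert series.per_frame == pytest.approx(np.zeros(6), abs=1e-12)

    def test_single_atom_gaussian_norm_mean(self, k_site):
        """A lone jittering atom's mean displacement is σ√(8/π)."""
        sigma = 0.1
        per_atom = np.zeros(len(k_site))
        per_atom[-1] = sigma
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=k_site, sigma=per_atom, n_frames=10_000, seed=5)
        )
        rigid = Selection(resid=(338, 339, 341, 343, 795))
        mobile = Selection(resid=820, name="OE2")
        series = ia.rmsd_series(traj, mobile, k_site, rigid)
        expected = sigma * math.sqrt(8 / math.pi)
        assert series.mean == pytest.approx(expected, rel=0.03)

    def test_mean_rmsd_ordered_by_sigma(self, k_site):
        means = []
        for sigma in (0.05, 0.15):
            traj = synth.make_trajectory(
                synth.TrajSpec(reference=k_site, sigma=sigma, n_frames=500, seed=11)
            )
            series = ia.rmsd_series(
                traj, Selection(element="O"), k_site, Selection(element="O")
            )
            means.append(series.mean)
        assert means[0] < means[1]

    def test_invariant_under_joint_rigid_motion(self, k_site):
        traj = synth.make_trajectory(
            synth.TrajSpec(reference=k_site, sigma=0.1, n_frames=20, seed=2)
        )
        series1 = ia.rmsd_series(
            traj, Selection(element="O"), k_site, Selection(element="O")
        )
        R = Rotation.from_euler("z", 123, degrees=True).as_matrix()
        t = np.array([3.0, -4.0, 5.0])
        moved_frames = traj.frames @ R.T + t
        moved_traj = Trajectory(k_site.with_coords(k_site.coords @ R.T + t), moved_frames)
        series2 = ia.rmsd_series(
            moved_traj, Selection(element="O"),
            k_site.with_coords(k_site.coords @ R.T + t), Selection(element="O"),
        )
        np.testing.assert_allclose(series2.per_frame, series1.per_frame, atol=1e-9)

    def test_atom_count_mismatch_rejected(self, k_site, three_waters):
        traj = synth.make_trajectory(synth.TrajSpec(reference=k_site, n_frames=2))
        with pytest.raises(ValueError):
            ia.rmsd_series(traj, Selection(element="O"), three_waters, Selection(element="O"))
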