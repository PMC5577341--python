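"""Geometric observables against brute-force and closed-form oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from remdkit import (
    Ensemble,
    RegionScheme,
    build_topology,
    contact_difference,
    contact_map,
    kabsch_rmsd,
    mixture_topology,
    per_residue_contact_count,
    radius_of_gyration,
    reaction_coordinates,
    rmsd_series,
    salt_bridge_frequency,
    sasa,
)
from remdkit.geometry import centered_moving_average
from remdkit.secstruct import CLASSES
from remdkit.synth import synthetic_topology


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        top, _ = synthetic_topology(2)
        frame = np.array([[0.0, 0, 0], [0.2, 0, 0]])
        assert radius_of_gyration(frame, top, [0, 1]) == pytest.approx(0.1)

    def test_coincident_atoms(self):
        top, _ = synthetic_topology(5)
        assert radius_of_gyration(np.zeros((5, 3)), top, range(5)) == 0.0

    def test_matches_direct_sum(self, rng):
        top = build_topology("DAEFRH")
        frame = rng.normal(0, 0.5, (top.n_atoms, 3))
        sel = np.arange(top.n_atoms)
        m = top.masses()
        com = (frame * m[:, None]).sum(0) / m.sum()
        expected = np.sqrt((m * ((frame - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(frame, top, sel) == pytest.approx(expected)

    def test_empty_selection_rejected(self):
        top, _ = synthetic_topology(2)
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((2, 3)), top, [])


def _quaternion_rmsd(a, b):
    """Independent superposition oracle (Horn's quaternion method)."""
    a = a - a.mean(0)
    b = b - b.mean(0)
    sxx = a.T @ b
    k = np.empty((4, 4))
    k[0, 0] = sxx[0, 0] + sxx[1, 1] + sxx[2, 2]
    k[0, 1] = k[1, 0] = sxx[1, 2] - sxx[2, 1]
    k[0, 2] = k[2, 0] = sxx[2, 0] - sxx[0, 2]
    k[0, 3] = k[3, 0] = sxx[0, 1] - sxx[1, 0]
    k[1, 1] = sxx[0, 0] - sxx[1, 1] - sxx[2, 2]
    k[1, 2] = k[2, 1] = sxx[0, 1] + sxx[1, 0]
    k[1, 3] = k[3, 1] = sxx[0, 2] + sxx[2, 0]
    k[2, 2] = -sxx[0, 0] + sxx[1, 1] - sxx[2, 2]
    k[2, 3] = k[3, 2] = sxx[1, 2] + sxx[2, 1]
    k[3, 3] = -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]
    lam = np.linalg.eigvalsh(k)[-1]
    msd = max(((a**2).sum() + (b**2).sum() - 2 * lam) / len(a), 0.0)
    return np.sqrt(msd)


class TestKabsch:
    def test_identical_frames(self, rng):
        x = rng.normal(0, 1, (7, 3))
        assert kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        x = rng.normal(0, 1, (10, 3))
        rot = Rotation.from_rotvec(rng.normal(0, 2, 3))
        y = rot.apply(x) + np.array([1.0, -5.0, 2.0])
        assert kabsch_rmsd(x, y) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (4, 3))
        b = rng.normal(0, 1, (4, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(_quaternion_rmsd(a, b), abs=1e-10)

    def test_collinear_selection_still_proper(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        b = -a  # improper-looking correspondence
        assert kabsch_rmsd(a, b) == pytest.approx(_quaternion_rmsd(a, b), abs=1e-10)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_raw_rmsd_without_superposition(self):
        a = np.zeros((4, 3))
        b = np.zeros((4, 3))
        b[:, 0] = 1.0
        assert kabsch_rmsd(a, b, superpose=False) == pytest.approx(1.0)


class TestRMSDSeries:
    def test_copies_of_reference_are_zero(self, rng):
        top, _ = synthetic_topology(6)
        ref = rng.normal(0, 1, (6, 3))
        ens = Ensemble(topology=top, coords=np.repeat(ref[None], 5, axis=0))
        series = rmsd_series(ens, ref, np.arange(6))
        assert np.allclose(series.values, 0.0, atol=1e-12)

    def test_moving_average_of_constant(self):
        times = np.arange(10.0)
        ma = centered_moving_average(times, np.full(10, 3.3), 4.0)
        assert np.allclose(ma, 3.3)

    def test_three_point_window(self):
        ma = centered_moving_average(np.array([0.0, 1, 2]), np.array([1.0, 2, 3]), 2.0)
        assert ma[1] == pytest.approx(2.0)

    def test_window_below_sampling_rejected(self, rng):
        top, _ = synthetic_topology(4)
        ens = Ensemble(
            topology=top,
            coords=rng.normal(0, 1, (4, 4, 3)),
            times=np.arange(4.0) * 10.0,
        )
        with pytest.raises(ValueError, match="window"):
            rmsd_series(ens, ens.coords[0], np.arange(4), ma_window=1.0)


def _brute_force_contacts(ens, ra, rb, mode, cutoff, min_sep):
    top = ens.topology
    out = np.zeros((ens.n_frames, len(ra), len(rb)))
    for f in range(ens.n_frames):
        for i, a in enumerate(ra):
            for j, b in enumerate(rb):
                if np.array_equal(ra, rb) and abs(a - b) < min_sep:
                    continue
                if mode == "ca":
                    ia = [k for k in range(top.n_atoms)
                          if top.atom_resid[k] == a and top.atom_names[k] == "CA"]
                    ib = [k for k in range(top.n_atoms)
                          if top.atom_resid[k] == b and top.atom_names[k] == "CA"]
                else:
                    ia = [k for k in range(top.n_atoms)
                          if top.atom_resid[k] == a and top.elements[k] != "H"]
                    ib = [k for k in range(top.n_atoms)
                          if top.atom_resid[k] == b and top.elements[k] != "H"]
                dmin = min(
                    np.linalg.norm(ens.coords[f, p] - ens.coords[f, q])
                    for p in ia for q in ib
                )
                out[f, i, j] = dmin < cutoff
    return out


class TestContactMap:
    def test_fixed_pair_probability_one(self):
        top = build_topology("GG")
        coords = np.zeros((4, top.n_atoms, 3))
        ca = top.ca_indices()
        coords[:, ca[1], 0] = 0.5
        ens = Ensemble(topology=top, coords=coords)
        cmap = contact_map(ens, [0], [1], "ca", 0.65, 0, n_blocks=2)
        assert cmap.probability[0, 0] == 1.0

    def test_min_seq_sep_zeroes_near_diagonal(self, rng):
        top = build_topology("GGGG")
        coords = rng.normal(0, 0.01, (4, top.n_atoms, 3))  # everything close
        ens = Ensemble(topology=top, coords=coords)
        cmap = contact_map(ens, range(4), range(4), "ca", 0.65, 3, n_blocks=2)
        for i in range(4):
            for j in range(4):
                if abs(i - j) < 3:
                    assert cmap.probability[i, j] == 0.0

    @pytest.mark.parametrize("mode", ["ca", "heavy"])
    def test_matches_brute_force(self, mode, rng):
        top = build_topology("DAEFRH")
        coords = rng.normal(0, 0.4, (10, top.n_atoms, 3))
        ens = Ensemble(topology=top, coords=coords)
        ra = np.arange(6)
        cmap = contact_map(ens, ra, ra, mode, 0.65, 3, n_blocks=2)
        expected = _brute_force_contacts(ens, ra, ra, mode, 0.65, 3).mean(0)
        assert np.allclose(cmap.probability, expected)

    def test_probabilities_in_unit_interval(self, rng):
        top = build_topology("DAEFRH")
        ens = Ensemble(topology=top, coords=rng.normal(0, 0.4, (8, top.n_atoms, 3)))
        cmap = contact_map(ens, range(6), range(6), "heavy", 0.5, 3)
        assert np.all((cmap.probability >= 0) & (cmap.probability <= 1))
        assert np.all(cmap.se >= 0)

    def test_invalid_cutoff_and_mode(self, rng):
        top = build_topology("GG")
        ens = Ensemble(topology=top, coords=rng.normal(0, 1, (2, top.n_atoms, 3)))
        with pytest.raises(ValueError):
            contact_map(ens, [0], [1], "ca", -1.0)
        with pytest.raises(ValueError):
            contact_map(ens, [0], [1], "banana", 0.5)


class TestContactDifference:
    def _map(self, p):
        from remdkit.geometry import ContactMap

        p = np.asarray(p, float)
        return ContactMap(np.arange(p.shape[0]), np.arange(p.shape[1]),
                          p, np.zeros_like(p), "ca", 0.65, 3)

    def test_identical_maps_all_masked(self):
        m = self._map([[0.5, 0.2], [0.2, 0.1]])
        assert np.all(contact_difference(m, m, 0.06).difference == 0.0)

    def test_threshold_is_strict(self):
        bound = self._map([[0.55, 0.57]])
        free = self._map([[0.50, 0.50]])
        d = contact_difference(bound, free, 0.06)
        assert d.difference[0, 0] == 0.0  # Δ = 0.05 masked
        assert d.difference[0, 1] == pytest.approx(0.07)  # Δ = 0.07 kept

    def test_operand_swap_negates(self):
        a = self._map([[0.9, 0.1]])
        b = self._map([[0.1, 0.9]])
        d1 = contact_difference(a, b, 0.06).difference
        d2 = contact_difference(b, a, 0.06).difference
        assert np.allclose(d1, -d2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            contact_difference(self._map([[0.1]]), self._map([[0.1, 0.2]]), 0.06)


class TestInterchainCounts:
    def test_no_contacts_gives_zeros(self):
        top = mixture_topology(hexapeptide="WT")
        coords = np.zeros((4, top.n_atoms, 3))
        coords[:, top.atom_indices(chain_id="B"), 0] += 50.0
        coords[:, :, 1] = np.arange(top.n_atoms)[None, :] * 0.001
        ens = Ensemble(topology=top, coords=coords)
        means, ses = per_residue_contact_count(ens, "A", "B", 0.4)
        assert np.all(means == 0.0)

    def test_matches_pair_enumeration(self, rng):
        top = mixture_topology(hexapeptide="WT")
        coords = rng.normal(0, 0.8, (3, top.n_atoms, 3))
        ens = Ensemble(topology=top, coords=coords)
        means, _ = per_residue_contact_count(ens, "A", "B", 0.4, n_blocks=3)
        atoms_a = top.atom_indices(chain_id="A", heavy_only=True)
        for j, r in enumerate(top.chain_residue_ordinals("B")):
            gb = top.atom_indices(residue_ordinals=[r], heavy_only=True)
            count = 0
            for f in range(3):
                for p in gb:
                    for q in atoms_a:
                        if np.linalg.norm(coords[f, p] - coords[f, q]) < 0.4:
                            count += 1
            assert means[j] == pytest.approx(count / 3)

    def test_same_chain_rejected(self, rng):
        top = build_topology("GG")
        ens = Ensemble(topology=top, coords=rng.normal(0, 1, (2, top.n_atoms, 3)))
        with pytest.raises(ValueError):
            per_residue_contact_count(ens, "A", "A", 0.4)


class TestSaltBridge:
    def _dk_ensemble(self, distances):
        top = build_topology("DK")
        od1 = top.atom_indices(names=("OD1",))[0]
        nz = top.atom_indices(names=("NZ",))[0]
        coords = np.zeros((len(distances), top.n_atoms, 3))
        coords[:, :, 1] = np.arange(top.n_atoms)[None, :] * 0.05
        coords[:, od1] = 0.0
        for f, d in enumerate(distances):
            coords[f, nz] = [d, 0.0, 0.0]
        # push the other O away so OD1 controls the minimum
        od2 = top.atom_indices(names=("OD2",))[0]
        coords[:, od2] = [0.0, 5.0, 0.0]
        return Ensemble(topology=top, coords=coords), top

    def test_half_of_frames_bridged(self):
        ens, top = self._dk_ensemble([0.35, 0.50])
        freq, _ = salt_bridge_frequency(ens, 0, 1, 0.40, n_blocks=2)
        assert freq == pytest.approx(50.0)

    def test_all_frames_bridged(self):
        ens, top = self._dk_ensemble([0.2, 0.3, 0.35, 0.39])
        freq, se = salt_bridge_frequency(ens, 0, 1, 0.40)
        assert freq == pytest.approx(100.0)
        assert se == 0.0

    def test_wrong_residue_type_rejected(self):
        top = build_topology("AK")
        ens = Ensemble(topology=top, coords=np.zeros((2, top.n_atoms, 3)) +
                       np.arange(top.n_atoms)[None, :, None] * 0.05)
        with pytest.raises(ValueError, match="acidic"):
            salt_bridge_frequency(ens, 0, 1, 0.4, n_blocks=2)


class TestSASA:
    def test_isolated_sphere_analytic(self):
        top, _ = synthetic_topology(1)  # carbon-like, vdW 0.17 nm
        total, per = sasa(np.zeros((1, 3)), top, probe=0.14, n_points=960)
        analytic = 4 * np.pi * (3.1**2)  # (1.7+1.4) Å radius
        assert total == pytest.approx(analytic, rel=1e-6)

    def test_fully_overlapping_atoms(self):
        top, _ = synthetic_topology(2)
        frame = np.zeros((2, 3))  # identical positions, identical radii
        total, _ = sasa(frame, top, probe=0.14, n_points=240)
        single, _ = sasa(np.zeros((1, 3)), top, probe=0.14, n_points=240,
                         atom_indices=[0])
        # two coincident spheres expose exactly one sphere's area in total
        assert total == pytest.approx(single, rel=1e-9)

    def test_hydrophobic_subset_bounded_by_total(self, rng):
        top = build_topology("DAEFRH")
        frame = rng.normal(0, 0.3, (top.n_atoms, 3))
        total, _ = sasa(frame, top, 0.14, 120, subset="all")
        hydro, _ = sasa(frame, top, 0.14, 120, subset="hydrophobic")
        assert 0.0 <= hydro <= total

    def test_too_few_points_rejected(self):
        top, _ = synthetic_topology(1)
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), top, 0.14, 10)


class TestReactionCoordinates:
    def test_all_strand_gives_one(self, ab42_topology):
        labels = np.full(42, CLASSES.index("COIL"), np.int8)
        scheme = RegionScheme()
        chc_ctr = [r - 1 for r in scheme.residues("CHC+CTR")]
        labels[chc_ctr] = CLASSES.index("STRAND")
        frame = np.zeros((ab42_topology.n_atoms, 3))
        frame[:, 0] = np.arange(ab42_topology.n_atoms) * 0.1
        nbeta, nc = reaction_coordinates(labels, frame, ab42_topology, scheme)
        assert nbeta == 1.0

    def test_half_strand(self, ab42_topology):
        labels = np.full(42, CLASSES.index("COIL"), np.int8)
        scheme = RegionScheme()
        chc_ctr = [r - 1 for r in scheme.residues("CHC+CTR")]
        labels[chc_ctr[:9]] = CLASSES.index("STRAND")
        frame = np.zeros((ab42_topology.n_atoms, 3))
        frame[:, 0] = np.arange(ab42_topology.n_atoms) * 0.1
        nbeta, _ = reaction_coordinates(labels, frame, ab42_topology, scheme)
        assert nbeta == pytest.approx(0.5)

    def test_distant_regions_zero_contact(self, ab42_topology):
        labels = np.full(42, CLASSES.index("COIL"), np.int8)
        frame = np.zeros((ab42_topology.n_atoms, 3))
        frame[:, 0] = np.arange(ab42_topology.n_atoms) * 0.1  # extended line
        _, nc = reaction_coordinates(labels, frame, ab42_topology, RegionScheme())
        assert nc == 0.0
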