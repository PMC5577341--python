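"""Topology construction, region scheme, production-window selection, I/O."""

import numpy as np
import pytest

import remdkit
from remdkit import (
    Ensemble,
    RegionScheme,
    SequenceLibrary,
    build_topology,
    region_residues,
    select_production,
    total_sampled_time_us,
)
from remdkit.io import (
    apply_parameter_table,
    read_ensemble,
    write_ensemble,
    write_parameter_table,
)


class TestBuildTopology:
    @pytest.mark.parametrize(
        "seq,n_res,n_heavy",
        [
            ("DAEFRH", 6, 54),  # D8+A5+E9+F11+R11+H10
            ("A", 1, 5),  # N, CA, C, O, CB
            ("DVEFRH", 6, 56),
            ("G", 1, 4),
        ],
    )
    def test_heavy_atom_counts(self, seq, n_res, n_heavy):
        top = build_topology(seq)
        assert top.n_residues == n_res
        assert int((top.elements != "H").sum()) == n_heavy

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 1"):
            build_topology("X")
        with pytest.raises(ValueError, match="position 3"):
            build_topology("AAXA")

    def test_oxt_terminal_mode(self):
        plain = build_topology("AG")
        oxt = build_topology("AG", terminal_mode="oxt")
        assert oxt.n_atoms == plain.n_atoms + 1
        assert oxt.atom_names[-1] == "OXT"

    def test_amide_h_skipped_for_first_residue_and_proline(self):
        top = build_topology("APA")
        h_res = [top.atom_resid[i] for i, n in enumerate(top.atom_names) if n == "H"]
        assert h_res == [2]  # only the final alanine donates

    def test_abeta42_sequence_charges(self):
        top = build_topology(remdkit.ABETA42_SEQUENCE)
        # 3×D + 3×E (−1 each) vs 2×K + 1×R (+1): net −3 e
        assert top.charges.sum() == pytest.approx(-3.0, abs=1e-9)


class TestSequencesAndRegions:
    def test_sequence_library_invariants(self):
        lib = SequenceLibrary()
        assert len(lib.abeta42) == 42
        assert {s[1] for s in lib.hexapeptides.values()} == {"A", "V", "T"}

    def test_region_lookup(self):
        scheme = RegionScheme()
        assert region_residues(scheme, "CHC") == list(range(17, 22))
        assert region_residues(scheme, "CTR") == list(range(30, 43))
        assert len(region_residues(scheme, "CHC+CTR")) == 18

    def test_primary_regions_partition(self):
        scheme = RegionScheme()
        seen = []
        for name in scheme.primary:
            seen.extend(scheme.residues(name))
        assert sorted(seen) == list(range(1, 43))
        assert len(seen) == len(set(seen))

    def test_unknown_region_rejected(self):
        with pytest.raises(KeyError):
            RegionScheme().residues("nope")


def _bookkeeping_ensemble(n_replicas, t_end=200_000.0, dt=50.0):
    """One-atom-per-frame trajectory purely for frame accounting."""
    top = build_topology("G")
    times = np.arange(0.0, t_end + dt, dt)
    n = len(times)
    return Ensemble(
        topology=top,
        coords=np.zeros((n * n_replicas, top.n_atoms, 3)),
        times=np.tile(times, n_replicas),
        replicas=np.repeat(np.arange(n_replicas), n),
    )


class TestSelectProduction:
    def test_single_replica_window_count(self):
        ens = _bookkeeping_ensemble(1)
        prod = select_production(ens, 60_000.0, 200_000.0, 50.0)
        assert prod.n_frames == 2800  # (200000−60000)/50, window half-open

    def test_half_open_window_excludes_start(self):
        ens = _bookkeeping_ensemble(1, t_end=200.0, dt=50.0)
        prod = select_production(ens, 100.0, 200.0, 50.0)
        assert sorted(prod.times.tolist()) == [150.0, 200.0]

    def test_empty_window_warns(self):
        ens = _bookkeeping_ensemble(1, t_end=100.0, dt=50.0)
        with pytest.warns(UserWarning, match="no frames"):
            prod = select_production(ens, 300.0, 400.0, 50.0)
        assert prod.n_frames == 0

    def test_incommensurate_stride_rejected(self):
        ens = _bookkeeping_ensemble(1, t_end=500.0, dt=50.0)
        with pytest.raises(ValueError, match="multiple"):
            select_production(ens, 0.0, 500.0, 75.0)

    def test_idempotent(self):
        ens = _bookkeeping_ensemble(2, t_end=1000.0, dt=50.0)
        once = select_production(ens, 200.0, 800.0, 100.0)
        twice = select_production(once, 200.0, 800.0, 100.0)
        assert np.array_equal(once.times, twice.times)
        assert np.array_equal(once.coords, twice.coords)

    def test_replica_filter(self):
        ens = _bookkeeping_ensemble(4, t_end=1000.0, dt=50.0)
        prod = select_production(ens, 0.0, 1000.0, 50.0, replica_ids=[0, 2])
        assert set(prod.replicas.tolist()) == {0, 2}

    def test_total_sampled_time(self):
        assert total_sampled_time_us(64, 200.0) == pytest.approx(12.8)


class TestEnsembleInvariants:
    def test_atom_count_mismatch_rejected(self, hexapeptide_topology):
        with pytest.raises(ValueError, match="atom count"):
            Ensemble(
                topology=hexapeptide_topology,
                coords=np.zeros((2, 3, 3)),
            )

    def test_nonfinite_coordinates_rejected(self, hexapeptide_topology):
        coords = np.zeros((1, hexapeptide_topology.n_atoms, 3))
        coords[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Ensemble(topology=hexapeptide_topology, coords=coords)

    def test_times_must_be_sorted_within_replica(self, hexapeptide_topology):
        n = hexapeptide_topology.n_atoms
        with pytest.raises(ValueError, match="non-decreasing"):
            Ensemble(
                topology=hexapeptide_topology,
                coords=np.zeros((2, n, 3)),
                times=[2.0, 1.0],
                replicas=[0, 0],
            )


class TestEnsembleIO:
    def test_pdb_round_trip(self, hexapeptide_topology, rng, tmp_path):
        coords = rng.normal(0, 1, (3, hexapeptide_topology.n_atoms, 3))
        ens = Ensemble(topology=hexapeptide_topology, coords=coords)
        path = tmp_path / "ens.pdb"
        write_ensemble(ens, path)
        back = read_ensemble(path, topology=hexapeptide_topology)
        assert back.n_frames == 3
        # PDB stores 0.001 Å = 1e-4 nm precision
        assert np.allclose(back.coords, ens.coords, atol=1.1e-4)

    def test_pdb_rebuilds_topology(self, hexapeptide_topology, rng, tmp_path):
        coords = rng.normal(0, 1, (2, hexapeptide_topology.n_atoms, 3))
        path = tmp_path / "ens.pdb"
        write_ensemble(
            Ensemble(topology=hexapeptide_topology, coords=coords), path
        )
        back = read_ensemble(path)
        assert back.topology.n_atoms == hexapeptide_topology.n_atoms
        assert back.topology.residue_names == hexapeptide_topology.residue_names

    def test_two_chain_pdb_keeps_chain_ids(self, ab42_topology, tmp_path):
        from remdkit import mixture_topology

        top = mixture_topology(hexapeptide="WT")
        coords = np.zeros((1, top.n_atoms, 3))
        coords[:, :, 0] = np.arange(top.n_atoms) * 0.01
        path = tmp_path / "two.pdb"
        write_ensemble(Ensemble(topology=top, coords=coords), path)
        text = path.read_text()
        assert " A " in text or " A1" in text
        assert text.count("TER") >= 2
        back = read_ensemble(path)
        assert back.topology.chain_ids == ["A", "B"]

    def test_model_atom_count_mismatch_names_counts(self, tmp_path):
        pdb = (
            "MODEL        1\n"
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.400   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ENDMDL\nEND\n"
        )
        path = tmp_path / "bad.pdb"
        path.write_text(pdb)
        with pytest.raises(ValueError, match="2 vs 1|1 vs 2"):
            read_ensemble(path)

    def test_empty_ensemble_rejected(self, hexapeptide_topology, tmp_path):
        ens = Ensemble(
            topology=hexapeptide_topology,
            coords=np.zeros((0, hexapeptide_topology.n_atoms, 3)),
        )
        with pytest.raises(ValueError, match="empty"):
            write_ensemble(ens, tmp_path / "x.pdb")

    def test_frame_store_round_trip(self, hexapeptide_topology, rng, tmp_path):
        coords = rng.normal(0, 1, (5, hexapeptide_topology.n_atoms, 3))
        ens = Ensemble(
            topology=hexapeptide_topology,
            coords=coords,
            times=np.arange(5.0),
            replicas=np.array([0, 0, 1, 1, 1]),
            temperatures=np.full(5, 300.0),
        )
        path = tmp_path / "store.npz"
        write_ensemble(ens, path, fmt="store")
        back = read_ensemble(path, fmt="store", topology=hexapeptide_topology)
        assert np.array_equal(back.coords, ens.coords)
        assert np.array_equal(back.replicas, ens.replicas)
        assert np.array_equal(back.temperatures, ens.temperatures)

    def test_parameter_table_round_trip(self, hexapeptide_topology, tmp_path):
        path = tmp_path / "params.tsv"
        write_parameter_table(hexapeptide_topology, path)
        top2 = apply_parameter_table(hexapeptide_topology, path)
        assert np.allclose(top2.charges, hexapeptide_topology.charges)
        assert np.allclose(top2.born_radii, hexapeptide_topology.born_radii)
        assert np.array_equal(top2.hydrophobic, hexapeptide_topology.hydrophobic)


class TestTopologyValidation:
    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            remdkit.Topology(
                chain_ids=["A"],
                residue_names=["GLY"],
                residue_chains=["A"],
                residue_numbers=[1],
                atom_names=["CA"],
                atom_resid=[0],
                sigmas=[-0.1],
            )

    def test_noncontiguous_residue_numbers_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            remdkit.Topology(
                chain_ids=["A"],
                residue_names=["GLY", "GLY"],
                residue_chains=["A", "A"],
                residue_numbers=[1, 3],
                atom_names=["CA", "CA"],
                atom_resid=[0, 1],
            )
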