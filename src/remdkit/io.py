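"""Ensemble and parameter I/O.

Multi-model PDB (via Bio.PDB) is the interchange format; a compressed .npz
frame store keeps per-frame replica/temperature metadata that PDB cannot
carry. Force-field parameters round-trip through a TSV table
(residue, atom, charge, sigma, epsilon, born_radius, hydrophobic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .core import Ensemble, Topology
from .templates import THREE_TO_ONE, element_of

_NM2A = 10.0


def write_ensemble(ensemble: Ensemble, path, fmt: str = "pdb") -> None:
    """Write an ensemble as a multi-model PDB or an internal .npz store."""
    if ensemble.n_frames == 0:
        raise ValueError("cannot write an empty ensemble")
    if fmt == "pdb":
        _write_pdb(ensemble, path)
    elif fmt == "store":
        write_frame_store(ensemble, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_ensemble(path, fmt: str = "pdb", topology: Topology | None = None) -> Ensemble:
    """Read an ensemble from multi-model PDB or the internal store.

    PDB reading rebuilds a topology (default force-field parameters) unless
    one is supplied; the store format requires the matching topology.
    """
    if fmt == "pdb":
        return _read_pdb(path, topology)
    if fmt == "store":
        if topology is None:
            raise ValueError("the internal store requires a topology")
        return read_frame_store(path, topology)
    raise ValueError(f"unknown format {fmt!r}")


def _write_pdb(ensemble: Ensemble, path) -> None:
    top = ensemble.topology
    builder = StructureBuilder()
    builder.init_structure("ens")
    for fi in range(ensemble.n_frames):
        builder.init_model(fi, fi)
        current_chain = None
        serial = 1
        for ai in range(top.n_atoms):
            rid = top.atom_resid[ai]
            chain = top.residue_chains[rid]
            if chain != current_chain:
                builder.init_chain(chain)
                builder.init_seg("    ")
                current_chain = chain
                seen = set()
            resnum = int(top.residue_numbers[rid])
            if resnum not in seen:
                builder.init_residue(top.residue_names[rid], " ", resnum, " ")
                seen.add(resnum)
            name = top.atom_names[ai]
            builder.init_atom(
                name,
                ensemble.coords[fi, ai] * _NM2A,
                0.0,
                1.0,
                " ",
                name.center(4) if len(name) < 4 else name,
                serial,
                element_of(name),
            )
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def _read_pdb(path, topology: Topology | None) -> Ensemble:
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    frames = []
    meta = None
    for model in structure:
        chain_ids, residue_names, residue_chains, residue_numbers = [], [], [], []
        atom_names, atom_resid, coords = [], [], []
        for chain in model:
            chain_ids.append(chain.id)
            local = 0
            for residue in chain:
                residue_names.append(residue.get_resname())
                residue_chains.append(chain.id)
                local += 1
                residue_numbers.append(local)
                rid = len(residue_names) - 1
                for atom in residue:
                    atom_names.append(atom.get_name())
                    atom_resid.append(rid)
                    coords.append(atom.get_coord() / _NM2A)
        frames.append(np.array(coords))
        this_meta = (chain_ids, residue_names, residue_chains, residue_numbers,
                     atom_names, atom_resid)
        if meta is None:
            meta = this_meta
        elif len(this_meta[4]) != len(meta[4]):
            raise ValueError(
                f"models disagree on atom count: {len(meta[4])} vs "
                f"{len(this_meta[4])}"
            )
    if meta is None:
        raise ValueError(f"no models found in {path}")
    if topology is None:
        topology = Topology(
            chain_ids=meta[0],
            residue_names=meta[1],
            residue_chains=meta[2],
            residue_numbers=meta[3],
            atom_names=meta[4],
            atom_resid=meta[5],
        )
    coords = np.stack(frames)
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"PDB atom count {coords.shape[1]} does not match topology "
            f"atom count {topology.n_atoms}"
        )
    return Ensemble(topology=topology, coords=coords)


# -- internal frame store ---------------------------------------------------

def write_frame_store(ensemble: Ensemble, path) -> None:
    np.savez_compressed(
        path,
        coords=ensemble.coords,
        times=ensemble.times,
        replicas=ensemble.replicas,
        temperatures=ensemble.temperatures,
        n_atoms=np.array([ensemble.topology.n_atoms]),
    )


def read_frame_store(path, topology: Topology) -> Ensemble:
    with np.load(path) as data:
        if int(data["n_atoms"][0]) != topology.n_atoms:
            raise ValueError(
                f"store atom count {int(data['n_atoms'][0])} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        return Ensemble(
            topology=topology,
            coords=data["coords"],
            times=data["times"],
            replicas=data["replicas"],
            temperatures=data["temperatures"],
        )


# -- force-field parameter table -------------------------------------------

def write_parameter_table(topology: Topology, path) -> None:
    """Write per-atom parameters as TSV."""
    df = parameter_frame(topology)
    df.to_csv(path, sep="\t", index=False)


def parameter_frame(topology: Topology) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue": [
                topology.residue_names[r] for r in topology.atom_resid
            ],
            "resnum": [
                int(topology.residue_numbers[r]) for r in topology.atom_resid
            ],
            "chain": [
                topology.residue_chains[r] for r in topology.atom_resid
            ],
            "atom": topology.atom_names,
            "charge": topology.charges,
            "sigma": topology.sigmas,
            "epsilon": topology.epsilons,
            "born_radius": topology.born_radii,
            "hydrophobic": topology.hydrophobic.astype(int),
        }
    )


def apply_parameter_table(topology: Topology, path) -> Topology:
    """Load a TSV parameter table onto a matching topology (row order)."""
    df = pd.read_csv(path, sep="\t")
    if len(df) != topology.n_atoms:
        raise ValueError(
            f"parameter table has {len(df)} rows for {topology.n_atoms} atoms"
        )
    return Topology(
        chain_ids=topology.chain_ids,
        residue_names=topology.residue_names,
        residue_chains=topology.residue_chains,
        residue_numbers=topology.residue_numbers,
        atom_names=topology.atom_names,
        atom_resid=topology.atom_resid,
        charges=df["charge"].to_numpy(),
        sigmas=df["sigma"].to_numpy(),
        epsilons=df["epsilon"].to_numpy(),
        born_radii=df["born_radius"].to_numpy(),
        hydrophobic=df["hydrophobic"].to_numpy().astype(bool),
    )
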