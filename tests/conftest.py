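"""Shared fixtures: small topologies, ensembles, and an mdtraj bridge.

mdtraj is used strictly as an independent reference (DSSP oracle); all
computation under test comes from remdkit itself.
"""

import numpy as np
import pytest

from remdkit import Ensemble, build_topology, mixture_topology


@pytest.fixture(scope="session")
def ab42_topology():
    return mixture_topology()


@pytest.fixture(scope="session")
def hexapeptide_topology():
    return build_topology("DAEFRH", chain_id="B")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_ensemble(topology, coords, **kw):
    return Ensemble(topology=topology, coords=np.asarray(coords, float), **kw)


@pytest.fixture(scope="session")
def mdtraj_dssp():
    """Reference DSSP: returns five-class integer codes via mdtraj."""
    md = pytest.importorskip("mdtraj")

    fold = {"H": 0, "G": 1, "E": 2, "B": 2, "T": 3, "S": 3}

    def run(topology, coords):
        t = md.Topology()
        chains, residues = {}, {}
        for rid, (rname, chain) in enumerate(
            zip(topology.residue_names, topology.residue_chains)
        ):
            if chain not in chains:
                chains[chain] = t.add_chain()
            residues[rid] = t.add_residue(rname, chains[chain])
        for name, rid in zip(topology.atom_names, topology.atom_resid):
            t.add_atom(name, md.element.get_by_symbol(name[0]), residues[rid])
        coords = np.asarray(coords, float)
        if coords.ndim == 2:
            coords = coords[None]
        traj = md.Trajectory(coords, t)
        raw = md.compute_dssp(traj, simplified=False)
        return np.vectorize(lambda c: fold.get(c, 4))(raw)

    return run
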