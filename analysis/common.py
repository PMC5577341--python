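"""Shared configuration for the numbered analysis scripts.

Ensembles are generated once by 01_generate_ensembles.py into scratch/ (the
internal .npz frame store) and reloaded by the later stages; every table the
scripts print lands under results/.
"""

from pathlib import Path

from remdkit import mixture_topology
from remdkit.io import read_frame_store

ROOT = Path(__file__).resolve().parent.parent
ENSEMBLE_DIR = ROOT / "scratch" / "ensembles"
RESULTS = ROOT / "results"

SEED = 1
N_FRAMES = 2000
VARIANTS = ("WT", "A2V", "A2T")
N_BLOCKS = 4


def system_names():
    return ("free",) + VARIANTS


def topology_for(name):
    return mixture_topology(hexapeptide=None if name == "free" else name)


def load_ensemble(name):
    path = ENSEMBLE_DIR / f"{name}.npz"
    if not path.exists():
        raise SystemExit(
            f"missing {path}; run analysis/01_generate_ensembles.py first"
        )
    return read_frame_store(path, topology_for(name))
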