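"""Gromos clustering of each state sub-population (0.3 nm Cα-RMSD cutoff).

Clusters up to 120 frames per rectangular state for every system, records
cluster sizes/centres, and reports how many top clusters cover 90% of each
sub-population — a compact measure of conformational diversity.
"""

import json

import numpy as np

import common
from remdkit import (
    DEFAULT_STATES,
    assign_ss_ensemble,
    cumulative_population,
    gromos_cluster,
    pairwise_rmsd_matrix,
    rc_series,
)

CUTOFF = 0.3
MAX_FRAMES = 120


def main():
    common.RESULTS.mkdir(exist_ok=True)
    report = {}
    for name in common.system_names():
        ens = common.load_ensemble(name)
        ca = ens.topology.backbone_indices()["CA"][
            ens.topology.chain_residue_ordinals("A")
        ]
        labels = assign_ss_ensemble(ens)
        rc = rc_series(ens, labels)
        report[name] = {}
        for state in DEFAULT_STATES:
            idx = np.flatnonzero(state.contains(rc.nbeta, rc.ncontact))
            if idx.size < 4:
                continue
            sub = ens.subset(idx[:MAX_FRAMES])
            result = gromos_cluster(pairwise_rmsd_matrix(sub, ca), CUTOFF)
            k90 = next(
                k for k in range(1, len(result.members) + 1)
                if cumulative_population(result, k) >= 0.9
            )
            report[name][state.name] = {
                "n_frames": int(sub.n_frames),
                "n_clusters": len(result.members),
                "top_cluster_pct": round(100 * result.sizes[0] / sub.n_frames, 1),
                "clusters_for_90_pct": k90,
            }
        covered = ", ".join(
            f"{s}:{v['n_clusters']}cl" for s, v in report[name].items()
        )
        print(f"{name}: {covered}")
    out = common.RESULTS / "06_clustering.json"
    out.write_text(json.dumps(report, indent=1))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
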