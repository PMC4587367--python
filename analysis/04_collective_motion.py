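"""PCA projections and per-cluster fluctuation profiles.

Fits the Cα-coordinate PCA on frame set 2, projects all frames on the first
three components, and computes per-cluster RMSF plus mutant-minus-reference
RMSF differences.  Tables land under results/.
"""

import pandas as pd

from _common import RESULTS, frame_sets, make_systems

from mdtop.clustering import gromos_cluster
from mdtop.pca import cumulative_variance, fit_pca, project
from mdtop.superpose import pairwise_rmsd_matrix, rmsf, rmsf_difference


def main():
    topology, systems = make_systems()
    at = frame_sets(systems)["set2"]
    RESULTS.mkdir(exist_ok=True)

    model = fit_pca(at.coords, topology, "name CA")
    cum = cumulative_variance(model)
    scores = project(at.coords, model, 3)
    df = pd.DataFrame(scores, columns=["pc1", "pc2", "pc3"])
    df.insert(0, "system", at.provenance["system"])
    df.to_csv(RESULTS / "04_pca_projections.tsv", sep="\t", index=False)
    print(f"first three components carry {cum[2]:.1%} of the variance;")
    centers = df.groupby("system").mean(numeric_only=True)
    print("per-system centres in PC space (A):")
    print(centers.round(2).to_string())

    mat = pairwise_rmsd_matrix(at.coords, topology, "name CA or name CB")
    cluster_model = gromos_cluster(mat, 2.2)
    rows = []
    for c in range(min(cluster_model.n_clusters, 3)):
        members = cluster_model.members(c)
        profile = rmsf(at.coords[members], topology, "name CA")
        for atom, val in zip(profile.selection, profile.values_nm):
            rows.append(
                {"cluster": c + 1, "residue": int(topology.res_ids[atom]),
                 "rmsf_nm": val}
            )
    pd.DataFrame(rows).to_csv(RESULTS / "04_rmsf_clusters.tsv", sep="\t", index=False)

    by_system = {}
    for label, group in at.provenance.groupby("system", sort=False):
        by_system[label] = rmsf(
            at.coords[group.index.to_numpy()], topology, "name CA"
        )
    ref = by_system["WT"]
    diff_rows = []
    for label, profile in by_system.items():
        if label == "WT":
            continue
        delta = rmsf_difference(profile, ref)
        for atom, val in zip(profile.selection, delta):
            diff_rows.append(
                {"system": label, "residue": int(topology.res_ids[atom]),
                 "delta_rmsf_nm": val}
            )
    pd.DataFrame(diff_rows).to_csv(
        RESULTS / "04_rmsf_differences.tsv", sep="\t", index=False
    )
    print("per-cluster RMSF and mutant-minus-WT differences written.")


if __name__ == "__main__":
    main()
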