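#!/usr/bin/env python
"""Cluster ligand chemical space and pocket space; characterize the groups.

Ligand space: Ward agglomeration of the datasets from d = 1 - Delta, tree
exported as Newick, heat-map ordering written alongside.  Pocket space:
Ward agglomeration of the 117-descriptor pocket vectors (standardized
Euclidean distances), cut at k = 4, and each cluster characterized by the
pocket descriptors that separate it from all remaining clusters at the
strict alpha = 1e-4.
"""

from pathlib import Path

import pandas as pd

from ippispace import characterize_clusters, cut_tree, overlap_to_distance, ward_cluster
from ippispace.pockets import read_pocket_vectors

RESULTS = Path(__file__).resolve().parent.parent / "results"
ALPHA_POCKET = 1e-4
K_POCKET = 4


def main() -> None:
    # ---- ligand space -----------------------------------------------------
    overlap = pd.read_csv(RESULTS / "overlap_matrix.csv", index_col=0)
    tree = ward_cluster(overlap_to_distance(overlap))
    (RESULTS / "ligand_space.nwk").write_text(tree.to_newick() + "\n")
    order = tree.leaf_order()
    overlap.loc[order, order].to_csv(RESULTS / "overlap_matrix_reordered.csv")
    assignments = cut_tree(tree, 4)
    assignments.to_csv(RESULTS / "ligand_space_clusters.csv", index_label="dataset")
    print("ligand-space clusters (k=4):")
    for c in sorted(assignments.unique()):
        members = ", ".join(assignments[assignments == c].index)
        print(f"  cluster {c}: {members}")

    # ---- pocket space -----------------------------------------------------
    vectors = read_pocket_vectors(RESULTS / "pocket_vectors.csv")
    dist = pd.read_csv(RESULTS / "pocket_distances.csv", index_col="pocket")
    ptree = ward_cluster(dist)
    (RESULTS / "pocket_space.nwk").write_text(ptree.to_newick() + "\n")
    passign = cut_tree(ptree, K_POCKET)
    passign.to_csv(RESULTS / "pocket_space_clusters.csv", index_label="pocket")

    truth = pd.read_csv(RESULTS / "pocket_groups.csv", index_col="pocket")["group"]
    purity = (
        passign.groupby(truth).nunique().eq(1).mean()
    )
    print(f"pocket-space cut at k={K_POCKET}: "
          f"{purity:.0%} of archetype groups fall into a single cluster")

    report = characterize_clusters(passign, vectors, list(vectors.columns),
                                   alpha=ALPHA_POCKET)
    report.to_csv(RESULTS / "pocket_cluster_characterization.csv", index=False)
    print(f"{len(report)} (cluster, descriptor) pairs significant at "
          f"alpha={ALPHA_POCKET:g}; examples:")
    for _, row in report.head(5).iterrows():
        print(f"  cluster {row['cluster']}: {row['descriptor']} {row['direction']}")


if __name__ == "__main__":
    main()
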