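"""Fuzzy clustering of the discovery cohort and cluster-number selection.

Filters to the 5% most variable probes, computes the centred-Pearson
dissimilarity, evaluates Dunn and Calinski–Harabasz indices for 2–10
clusters, runs the fuzzy clustering at k=3, and writes memberships,
validity indices, membership diagnostics and barycentric plot coordinates
to results/.

Run from the repository root:  python analysis/02_cluster.py
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from tnbcsub.fuzzy_clustering import (
    FannyConfig,
    barycentric_coordinates,
    membership_diagnostics,
    validity_indices,
)
from tnbcsub.pipeline import cluster_cohort
from tnbcsub.simulate import CohortSpec, MacrophageSpec, generate_macrophage_reference, generate_tnbc_cohort

SEED = 11
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    mac = generate_macrophage_reference(MacrophageSpec(seed=SEED))
    cohort = generate_tnbc_cohort(CohortSpec(seed=SEED), macrophage_truth=mac.truth)
    res = cluster_cohort(cohort.expression, k=3, seed=SEED)
    print(f"retained {res.filtered.shape[0]} probes; "
          f"fanny objective {res.partition.objective:.4f} "
          f"({res.partition.iterations} iterations)")

    vi = validity_indices(
        res.filtered, res.dissimilarity, range(2, 11), FannyConfig(seed=SEED)
    )
    vi.to_csv(RESULTS / "02_validity_indices.tsv", sep="\t", index=False)
    best = vi.loc[vi["calinski_harabasz"].idxmax(), "k"]
    print(f"Calinski-Harabasz favours k={int(best)}; partition taken at k=3")

    u = pd.DataFrame(
        res.partition.u,
        index=cohort.expression.columns,
        columns=[f"u_C{i + 1}" for i in range(3)],
    )
    u["crisp_label"] = res.labels
    u.to_csv(RESULTS / "02_memberships.tsv", sep="\t", index_label="sample_id")

    diag = membership_diagnostics(res.partition, threshold=0.9, gap_pair=(1, 2))
    rows = []
    for k, d in diag["clusters"].items():
        rows.append({"cluster": f"C{k + 1}", **{x: d[x] for x in ("n", "min", "median", "n_above_threshold")}})
    pd.DataFrame(rows).to_csv(RESULTS / "02_membership_diagnostics.tsv", sep="\t", index=False)
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"C2/C3 membership gaps below 0.2: {diag['gap']['n_below_gap_threshold']}")

    vertices = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    xy = barycentric_coordinates(res.partition, vertices)
    pd.DataFrame(xy, index=u.index, columns=["x", "y"]).to_csv(
        RESULTS / "02_barycentric_coordinates.tsv", sep="\t", index_label="sample_id"
    )

    sizes = res.labels.value_counts().sort_index()
    ari = adjusted_rand_score(cohort.truth.to_numpy(), res.labels.to_numpy())
    print(f"cluster sizes: {sizes.tolist()}; ARI vs planted clusters: {ari:.3f}")
    pd.DataFrame({"cluster": sizes.index, "n": sizes.to_numpy()}).assign(ari=ari).to_csv(
        RESULTS / "02_cluster_sizes.csv", index=False
    )


if __name__ == "__main__":
    main()
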