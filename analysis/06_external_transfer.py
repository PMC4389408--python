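"""Transfer the discovery partition to the external cohort with PAM.

Trains the nearest-shrunken-centroid classifier on the discovery cohort's
fuzzy clusters (feature space: the same top-variance probe set used for
clustering), predicts the external cohort, clusters the external cohort
independently with the same fuzzy procedure, and reports the discordance
between the two labelings after optimal cluster matching.

Run from the repository root:  python analysis/06_external_transfer.py
"""

from pathlib import Path

import pandas as pd

from tnbcsub.pam import save_model
from tnbcsub.pipeline import cluster_cohort, matched_agreement, transfer_partition
from tnbcsub.simulate import CohortSpec, MacrophageSpec, generate_macrophage_reference, generate_tnbc_cohort

SEED_DISCOVERY = 11
SEED_EXTERNAL = 2011
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    mac = generate_macrophage_reference(MacrophageSpec(seed=SEED_DISCOVERY))
    discovery = generate_tnbc_cohort(
        CohortSpec(seed=SEED_DISCOVERY), macrophage_truth=mac.truth
    )
    external = generate_tnbc_cohort(
        CohortSpec(seed=SEED_EXTERNAL), macrophage_truth=mac.truth
    )

    clu = cluster_cohort(discovery.expression, k=3, seed=SEED_DISCOVERY)
    model, pred = transfer_partition(clu, external.expression, seed=SEED_DISCOVERY)
    save_model(model, RESULTS / "06_pam_model.json")
    print(f"PAM: delta={model.delta:.3f}, "
          f"{len(model.active_genes)}/{len(model.gene_ids)} active genes, "
          f"priors={[round(p, 3) for p in model.priors]}")

    clu_ext = cluster_cohort(external.expression, k=3, seed=SEED_EXTERNAL)
    agree = matched_agreement(clu_ext.labels.to_numpy(), pred["label"].to_numpy())
    n = len(pred)
    discordant = round((1 - agree) * n)
    print(f"external fuzzy clustering vs PAM prediction: "
          f"{discordant}/{n} samples differently classified "
          f"({100 * (1 - agree):.2f}% discordance)")

    out = pred.copy()
    out["fuzzy_label"] = clu_ext.labels
    out.to_csv(RESULTS / "06_external_predictions.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        [{"n_external": n, "n_discordant": discordant,
          "discordance_pct": 100 * (1 - agree), "delta": model.delta}]
    ).to_csv(RESULTS / "06_transfer_summary.csv", index=False)


if __name__ == "__main__":
    main()
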