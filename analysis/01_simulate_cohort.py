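"""Generate the synthetic study cohorts and the macrophage reference.

Draws the 107-patient discovery cohort (three latent clusters at
22.4/44.9/32.7%, claudin-low subpopulation inside cluster 3), an
independent external cohort from the same generative process on the same
platform, and the two-class M1/M2 macrophage reference with planted
differential genes.  Full fixture sets (expression/annotation/clinical/
truth tables) go to scratch/ — they are large and regenerable — while
small summaries land in results/.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

import pandas as pd

from tnbcsub.simulate import (
    CohortSpec,
    MacrophageSpec,
    generate_macrophage_reference,
    generate_tnbc_cohort,
    write_fixture_set,
)

SEED_DISCOVERY = 11
SEED_EXTERNAL = 2011
SEED_MACROPHAGE = 11

RESULTS = Path("results")
SCRATCH = Path("scratch")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    mac = generate_macrophage_reference(MacrophageSpec(seed=SEED_MACROPHAGE))
    discovery = generate_tnbc_cohort(
        CohortSpec(seed=SEED_DISCOVERY), macrophage_truth=mac.truth
    )
    external = generate_tnbc_cohort(
        CohortSpec(seed=SEED_EXTERNAL), macrophage_truth=mac.truth
    )

    for name, cohort in (("discovery", discovery), ("external", external)):
        paths = write_fixture_set(cohort, SCRATCH / name)
        print(f"{name}: {cohort.expression.shape[0]} probes x "
              f"{cohort.expression.shape[1]} samples -> {paths['expression'].parent}")
    mac.expression.to_csv(SCRATCH / "macrophage_reference.tsv", sep="\t")
    mac.truth.to_csv(SCRATCH / "macrophage_truth.tsv", sep="\t")

    summary = pd.DataFrame(
        {
            "cohort": ["discovery", "external"],
            "n_samples": [discovery.expression.shape[1], external.expression.shape[1]],
            "n_probes": [discovery.expression.shape[0], external.expression.shape[0]],
            "planted_sizes": [
                discovery.truth.value_counts().sort_index().tolist(),
                external.truth.value_counts().sort_index().tolist(),
            ],
            "claudin_low_in_C3": [
                int(discovery.claudin_low[discovery.truth == "C3"].sum()),
                int(external.claudin_low[external.truth == "C3"].sum()),
            ],
        }
    )
    summary.to_csv(RESULTS / "01_cohort_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"macrophage reference: {mac.expression.shape[0]} genes, "
          f"{len(mac.truth)} planted DE genes")


if __name__ == "__main__":
    main()
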