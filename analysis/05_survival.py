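"""Survival and clinicopathologic annotation of the clusters.

Kaplan–Meier / logrank comparison of event-free survival across the three
clusters, per-SD Cox fits of the immune metagenes on the basal clusters,
ANOVA with Tukey HSD on age, and the correlation structure of the module
scores.

Run from the repository root:  python analysis/05_survival.py
"""

from pathlib import Path

import pandas as pd

from tnbcsub.pipeline import build_m2m1_signature, dissect_basal_clusters
from tnbcsub.simulate import CohortSpec, MacrophageSpec, generate_macrophage_reference, generate_tnbc_cohort
from tnbcsub.survival import cox_univariate, group_compare, kaplan_meier, logrank_test

SEED = 11
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    mac = generate_macrophage_reference(MacrophageSpec(seed=SEED))
    cohort = generate_tnbc_cohort(CohortSpec(seed=SEED), macrophage_truth=mac.truth)
    clin = cohort.clinical
    efs = clin.rename(columns={"efs_time": "time", "efs_event": "event"})[["time", "event"]]

    lr = logrank_test(efs, cohort.truth)
    print(f"EFS logrank across clusters: chi2={lr['statistic']:.2f}, p={lr['p_value']:.4f}")
    curves = kaplan_meier(efs, cohort.truth)
    pd.concat(
        {g: c.set_index("time") for g, c in curves.items()}, names=["cluster", "time"]
    ).to_csv(RESULTS / "05_km_curves.tsv", sep="\t")

    rows = [{"comparison": "C1-C2-C3", **lr}]
    for a, b in (("C1", "C2"), ("C1", "C3"), ("C2", "C3")):
        mask = cohort.truth.isin([a, b]).to_numpy()
        sub = logrank_test(efs[mask], cohort.truth[mask])
        rows.append({"comparison": f"{a}-{b}", **sub})
        print(f"EFS logrank {a} vs {b}: p={sub['p_value']:.4f}")
    pd.DataFrame(rows).to_csv(RESULTS / "05_logrank.csv", index=False)

    # per-SD Cox fits of immune metagenes and M2/M1 on the basal clusters
    sig, _ = build_m2m1_signature(mac, seed=SEED)
    profile = dissect_basal_clusters(cohort, sig, cohort.truth)
    basal = profile.group.index
    efs_basal = efs.loc[basal]
    cox_rows = []
    scores = profile.metagene_scores.T
    scores["M2/M1"] = profile.m2m1
    for module in scores.columns:
        fit = cox_univariate(efs_basal, scores.loc[basal, module].to_numpy())
        cox_rows.append(
            {"score": module, "hr_per_sd": fit.hazard_ratio,
             "ci_low": fit.ci95[0], "ci_high": fit.ci95[1], "p": fit.p_value}
        )
    cox = pd.DataFrame(cox_rows)
    cox.to_csv(RESULTS / "05_cox_metagenes.csv", index=False)
    print(cox.round(4).to_string(index=False))

    ages = {c: clin.loc[(cohort.truth == c).to_numpy(), "age"].to_numpy() for c in ("C1", "C2", "C3")}
    an = group_compare(ages, "anova_tukey")
    print(f"age ANOVA p={an['p_value']:.4g}; pairwise: "
          + ", ".join(f"{a} vs {b}: {p:.3g}" for (a, b), p in an["pairwise_p"].items()))
    pd.DataFrame(
        [{"group1": a, "group2": b, "p_adj": p} for (a, b), p in an["pairwise_p"].items()]
    ).assign(anova_p=an["p_value"]).to_csv(RESULTS / "05_age_anova.csv", index=False)


if __name__ == "__main__":
    main()
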