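"""High-level workflow steps composing the library modules.

These are the operations the analysis drivers and the reproduction script
share: cluster a cohort, build the signed M2/M1 macrophage signature from
a two-class reference, dissect the immune response of the basal clusters,
and transfer a partition to an external cohort with the PAM classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .expression_io import filter_top_variance
from .fuzzy_clustering import (
    FannyConfig,
    FuzzyPartition,
    centred_pearson_dissimilarity,
    crisp_assign,
    fanny,
)
from .immune import ImmuneProfile, dissect_immune_response
from .pam import PamModel, pam_predict, pam_train
from .sam import sam_two_class, select_q0_genes
from .signatures import GeneSignature, build_signed_signature
from .simulate import MacrophageReference, SyntheticCohort

__all__ = [
    "ClusterResult",
    "cluster_cohort",
    "build_m2m1_signature",
    "dissect_basal_clusters",
    "transfer_partition",
    "matched_agreement",
]


@dataclass
class ClusterResult:
    filtered: pd.DataFrame  # top-variance probes x samples
    dissimilarity: pd.DataFrame
    partition: FuzzyPartition
    labels: pd.Series  # crisp cluster names C1..Ck per sample


def cluster_cohort(
    E: pd.DataFrame, k: int = 3, fraction: float = 0.05, seed: int = 0,
    r: float | None = None,
) -> ClusterResult:
    """Variance-filter, build the correlation distance, run fanny, assign.

    Crisp clusters are named C1..Ck in decreasing membership-column order
    of appearance (cluster indices are arbitrary; names are for reading).
    """
    Ef = filter_top_variance(E, fraction)
    D = centred_pearson_dissimilarity(Ef)
    cfg = FannyConfig(k=k, seed=seed) if r is None else FannyConfig(k=k, seed=seed, r=r)
    part = fanny(D, cfg)
    labels = pd.Series(
        [f"C{i + 1}" for i in crisp_assign(part)], index=E.columns, name="cluster"
    )
    return ClusterResult(Ef, D, part, labels)


def build_m2m1_signature(
    ref: MacrophageReference, n_perm: int = 300, seed: int = 0
) -> tuple[GeneSignature, pd.DataFrame]:
    """SAM on the M1/M2 reference, keep genes at q = 0%, weight by ±1.

    Weights follow the M2-versus-M1 contrast, so a high score means an
    M2-skewed (pro-tumourigenic) macrophage profile.
    """
    res = sam_two_class(ref.expression, ref.labels.to_numpy(), n_perm=n_perm, seed=seed)
    ann = pd.DataFrame(
        {"probe_id": ref.expression.index, "gene_symbol": ref.expression.index}
    )
    q0 = select_q0_genes(res, ann)
    sig = build_signed_signature(
        ref.expression, ref.labels.to_numpy(), list(q0.index), name="M2/M1"
    )
    return sig, q0


def dissect_basal_clusters(
    cohort: SyntheticCohort,
    m2m1: GeneSignature,
    labels: pd.Series,
    basal_clusters=("C2", "C3"),
) -> ImmuneProfile:
    return dissect_immune_response(
        cohort.expression,
        cohort.modules,
        m2m1,
        labels,
        restrict_to=list(basal_clusters),
        ann=cohort.annotation,
    )


def transfer_partition(
    train: ClusterResult,
    E_external: pd.DataFrame,
    seed: int = 0,
    cv_folds: int = 5,
) -> tuple[PamModel, pd.DataFrame]:
    """Train PAM on the training cohort's crisp clusters, predict external.

    The feature space is the training cohort's top-variance probe set;
    external probes missing from it are dropped symmetrically.
    """
    model = pam_train(train.filtered, train.labels.to_numpy(), cv_folds=cv_folds, seed=seed)
    E_ext = E_external.reindex(model.gene_ids).dropna()
    pred = pam_predict(model, E_ext)
    return model, pred


def matched_agreement(labels_a, labels_b) -> float:
    """Best one-to-one agreement between two label sets of the same samples.

    Cluster names on two cohorts are arbitrary, so the comparison matches
    them by maximising the confusion-matrix trace (Hungarian assignment)
    before counting agreements.  Returns the agreement fraction.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    conf = pd.crosstab(a, b)
    r, c = linear_sum_assignment(-conf.to_numpy())
    return float(conf.to_numpy()[r, c].sum() / len(a))
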