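"""Immune-response dissection of the basal-enriched clusters.

The seven immune metagenes (HCK, LCK, IgG, STAT1, Interferon, MHC-I,
MHC-II — myeloid cells, T cells, B cells, interferon signalling/response
and antigen presentation) are scored on the samples of the two
basal-enriched clusters, Ward's hierarchical clustering of the
standardized metagene profile splits them into two groups, and the group
with the higher overall immune expression is labelled HIR (high immune
response), the other LIR.  The signed M2/M1 macrophage score is carried
alongside: M2-skewed (pro-tumourigenic) profiles are expected in LIR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .signatures import GeneSignature, score_module_mean, score_signature

logger = logging.getLogger(__name__)

__all__ = [
    "ImmuneProfile",
    "DEFAULT_IMMUNE_MODULES",
    "ward_cluster_cut",
    "dissect_immune_response",
    "compare_metagenes_between_clusters",
]

DEFAULT_IMMUNE_MODULES = ("HCK", "LCK", "IgG", "STAT1", "Interferon", "MHC-I", "MHC-II")


@dataclass
class ImmuneProfile:
    sample_ids: list
    metagene_scores: pd.DataFrame  # modules x samples
    m2m1: pd.Series
    group: pd.Series  # "HIR" / "LIR" per sample


def ward_cluster_cut(X: pd.DataFrame, k: int, standardize: bool = True) -> pd.Series:
    """Ward agglomeration of samples on (optionally z-scored) features.

    ``X`` is features × samples.  Features are standardized so no single
    module dominates the Euclidean geometry; the tree is cut into ``k``
    groups.  Deterministic: ties in merge distances resolve by scipy's
    fixed ordering of observation indices.
    """
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds number of samples ({X.shape[1]})")
    M = X.to_numpy(dtype=float).T  # samples x features
    if standardize:
        sd = M.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        M = (M - M.mean(axis=0)) / sd
    Z = linkage(M, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=X.columns, name="ward_group")


def dissect_immune_response(
    E: pd.DataFrame,
    modules: dict,
    m2m1_sig: GeneSignature,
    cluster_labels: pd.Series,
    restrict_to=None,
    ann: pd.DataFrame | None = None,
    include_m2m1_in_clustering: bool = False,
) -> ImmuneProfile:
    """Split the basal clusters into HIR/LIR on their immune metagenes.

    ``cluster_labels`` assigns each sample its fuzzy-cluster label;
    ``restrict_to`` names the (basal-enriched) clusters to dissect — by
    default all labelled samples are used.  Metagene and M2/M1 scores are
    computed, Ward clustering with k=2 runs on the standardized metagenes
    (optionally with the M2/M1 score as an extra feature), and the group
    with the higher grand mean of metagene scores is labelled HIR.
    """
    cluster_labels = pd.Series(cluster_labels)
    if restrict_to is not None:
        keep = cluster_labels.index[cluster_labels.isin(restrict_to)]
    else:
        keep = cluster_labels.index
    if len(keep) < 4:
        raise ValueError(f"only {len(keep)} samples in the restricted set (need >= 4)")
    Es = E[keep]
    scores = score_module_mean(Es, modules, ann)
    m2m1 = score_signature(Es, m2m1_sig, ann)
    feats = pd.concat([scores, m2m1.to_frame().T]) if include_m2m1_in_clustering else scores
    cut = ward_cluster_cut(feats, k=2)
    grand = {g: scores.loc[:, cut == g].to_numpy().mean() for g in (1, 2)}
    hir = max(grand, key=grand.get)
    group = cut.map(lambda g: "HIR" if g == hir else "LIR").rename("group")
    return ImmuneProfile(
        sample_ids=list(keep), metagene_scores=scores, m2m1=m2m1, group=group
    )


def compare_metagenes_between_clusters(
    scores: pd.DataFrame, cluster_labels: pd.Series
) -> pd.DataFrame:
    """Per-module two-group comparison (Welch t-test) between two clusters.

    ``scores`` is modules × samples; ``cluster_labels`` must take exactly
    two values over the scored samples.  Returns group means, mean
    difference (second group minus first, in sorted label order) and the
    two-sided Welch p-value; degenerate groups give an absent p-value.
    """
    labels = pd.Series(cluster_labels).loc[scores.columns]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    a, b = (scores.loc[:, labels == g] for g in groups)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for module in scores.index:
        xa, xb = a.loc[module].to_numpy(), b.loc[module].to_numpy()
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0 and xa.mean() == xb.mean():
            p = 1.0 if np.array_equal(np.sort(xa), np.sort(xb)) else np.nan
            logger.info("module %s: degenerate groups, p-value set to %s", module, p)
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        rows.append(
            {
                "module": module,
                f"mean_{groups[0]}": xa.mean(),
                f"mean_{groups[1]}": xb.mean(),
                "difference": xb.mean() - xa.mean(),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("module")
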