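"""Nearest-shrunken-centroid (PAM) classification for cluster transfer.

Trains the Tibshirani "prediction analysis for microarrays" classifier on
the cohort's fuzzy-cluster labels and applies it to an external cohort:
class centroids are expressed as standardized deviations from the overall
centroid, soft-thresholded by a shrinkage amount delta chosen by
cross-validation (largest delta within one standard error of the minimum
CV error), and new samples are assigned by the shrunken-centroid
discriminant with class-prior correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = ["PamModel", "pam_train", "pam_predict", "save_model", "load_model"]


@dataclass
class PamModel:
    class_names: list
    gene_ids: list
    overall_centroid: np.ndarray  # per gene
    class_centroids: np.ndarray  # genes x classes (unshrunken)
    pooled_sd: np.ndarray  # per gene
    s0_pam: float  # median pooled sd, regularises the denominator
    mk: np.ndarray  # per class: sqrt(1/n_k - 1/n)
    delta: float
    priors: np.ndarray
    cv_error_curve: list = field(default_factory=list)  # (delta, error, se)

    def shrunken_deviations(self, delta: float | None = None) -> np.ndarray:
        """Soft-thresholded standardized deviations d'_kg (genes x classes)."""
        if delta is None:
            delta = self.delta
        denom = self.mk[None, :] * (self.pooled_sd + self.s0_pam)[:, None]
        d = (self.class_centroids - self.overall_centroid[:, None]) / denom
        return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)

    def shrunken_centroids(self, delta: float | None = None) -> np.ndarray:
        denom = self.mk[None, :] * (self.pooled_sd + self.s0_pam)[:, None]
        return self.overall_centroid[:, None] + denom * self.shrunken_deviations(delta)

    @property
    def active_genes(self) -> np.ndarray:
        """Genes with any nonzero shrunken deviation at the selected delta."""
        return np.flatnonzero((self.shrunken_deviations() != 0).any(axis=1))


def _fit_centroids(X: np.ndarray, y: np.ndarray, classes: list):
    """X is genes x samples. Returns centroids, pooled sd, m_k, priors."""
    n = X.shape[1]
    k = len(classes)
    overall = X.mean(axis=1)
    cent = np.empty((X.shape[0], k))
    ss = np.zeros(X.shape[0])
    nk = np.empty(k, dtype=int)
    for j, c in enumerate(classes):
        idx = np.flatnonzero(y == c)
        nk[j] = len(idx)
        Xc = X[:, idx]
        cent[:, j] = Xc.mean(axis=1)
        ss += ((Xc - cent[:, [j]]) ** 2).sum(axis=1)
    sd = np.sqrt(ss / (n - k))
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    priors = nk / n
    return overall, cent, sd, mk, priors


def _discriminant(
    X: np.ndarray, centroids: np.ndarray, sd_reg: np.ndarray, priors: np.ndarray
) -> np.ndarray:
    """delta_k(x) = sum_g (x_g - c_kg)^2 / (s_g+s0)^2 - 2 log pi_k.

    X genes x samples; returns samples x classes (smaller is better).
    """
    scores = np.empty((X.shape[1], centroids.shape[1]))
    for j in range(centroids.shape[1]):
        z = (X - centroids[:, [j]]) / sd_reg[:, None]
        scores[:, j] = (z**2).sum(axis=0) - 2.0 * np.log(priors[j])
    return scores


def pam_train(
    E: pd.DataFrame,
    labels,
    delta_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
) -> PamModel:
    """Train the nearest-shrunken-centroid model with CV-chosen shrinkage.

    ``E`` is genes (or probes) × samples; ``labels`` one class per sample.
    The shrinkage delta is selected by stratified ``cv_folds``-fold
    cross-validation as the largest delta whose error is within one
    standard error of the minimum (ties to stronger shrinkage, the pamr
    heuristic).  Deterministic under ``seed``.
    """
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < cv_folds]
    if small:
        raise ValueError(
            f"classes {small} have fewer members than cv_folds={cv_folds}; "
            "reduce the number of folds"
        )
    X = E.to_numpy(dtype=float)
    overall, cent, sd, mk, priors = _fit_centroids(X, y, classes)
    s0 = float(np.median(sd))
    model = PamModel(
        class_names=classes,
        gene_ids=list(E.index),
        overall_centroid=overall,
        class_centroids=cent,
        pooled_sd=sd,
        s0_pam=s0,
        mk=mk,
        delta=0.0,
        priors=priors,
    )
    if delta_grid is None:
        dmax = float(np.abs(model.shrunken_deviations(0.0)).max())
        delta_grid = np.linspace(0.0, dmax, 30)
    delta_grid = np.asarray(delta_grid, dtype=float)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_errors = np.empty((cv_folds, len(delta_grid)))
    for f, (tr, te) in enumerate(skf.split(X.T, y)):
        ov_f, cent_f, sd_f, mk_f, pri_f = _fit_centroids(X[:, tr], y[tr], classes)
        s0_f = float(np.median(sd_f))
        sub = PamModel(
            class_names=classes,
            gene_ids=model.gene_ids,
            overall_centroid=ov_f,
            class_centroids=cent_f,
            pooled_sd=sd_f,
            s0_pam=s0_f,
            mk=mk_f,
            delta=0.0,
            priors=pri_f,
        )
        for di, delta in enumerate(delta_grid):
            cents = sub.shrunken_centroids(delta)
            scores = _discriminant(X[:, te], cents, sd_f + s0_f, pri_f)
            pred = np.asarray(classes)[np.argmin(scores, axis=1)]
            fold_errors[f, di] = float(np.mean(pred != y[te]))
    err = fold_errors.mean(axis=0)
    se = fold_errors.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(err))
    cutoff = err[best] + se[best]
    chosen = int(max(np.flatnonzero(err <= cutoff)))  # largest delta under 1-SE
    model.delta = float(delta_grid[chosen])
    model.cv_error_curve = [
        (float(d), float(e), float(s)) for d, e, s in zip(delta_grid, err, se)
    ]
    return model


def pam_predict(
    model: PamModel, E_new: pd.DataFrame, min_overlap: float = 0.8
) -> pd.DataFrame:
    """Assign each new sample to the nearest shrunken centroid.

    Genes of the model missing from ``E_new`` are dropped from all
    centroids symmetrically; an overlap below ``min_overlap`` of the model
    genes raises.  Returns per-class discriminant scores (smaller is
    closer) plus the winning ``label`` per sample.
    """
    present = [g for g in model.gene_ids if g in E_new.index]
    if len(present) < min_overlap * len(model.gene_ids):
        raise ValueError(
            f"only {len(present)}/{len(model.gene_ids)} model genes measured "
            f"(< floor {min_overlap:.0%})"
        )
    pos = {g: i for i, g in enumerate(model.gene_ids)}
    idx = np.array([pos[g] for g in present])
    cents = model.shrunken_centroids()[idx]
    sd_reg = (model.pooled_sd + model.s0_pam)[idx]
    X = E_new.loc[present].to_numpy(dtype=float)
    scores = _discriminant(X, cents, sd_reg, model.priors)
    out = pd.DataFrame(scores, index=E_new.columns, columns=model.class_names)
    out["label"] = np.asarray(model.class_names)[np.argmin(scores, axis=1)]
    return out


def save_model(model: PamModel, path) -> None:
    doc = {
        "class_names": model.class_names,
        "gene_ids": model.gene_ids,
        "overall_centroid": model.overall_centroid.tolist(),
        "class_centroids": model.class_centroids.tolist(),
        "pooled_sd": model.pooled_sd.tolist(),
        "s0_pam": model.s0_pam,
        "mk": model.mk.tolist(),
        "delta": model.delta,
        "priors": model.priors.tolist(),
        "cv_error_curve": model.cv_error_curve,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> PamModel:
    with open(path) as fh:
        doc = json.load(fh)
    return PamModel(
        class_names=doc["class_names"],
        gene_ids=doc["gene_ids"],
        overall_centroid=np.asarray(doc["overall_centroid"]),
        class_centroids=np.asarray(doc["class_centroids"]),
        pooled_sd=np.asarray(doc["pooled_sd"]),
        s0_pam=doc["s0_pam"],
        mk=np.asarray(doc["mk"]),
        delta=doc["delta"],
        priors=np.asarray(doc["priors"]),
        cv_error_curve=[tuple(t) for t in doc["cv_error_curve"]],
    )
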