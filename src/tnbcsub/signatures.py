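"""Gene-expression signature construction, scoring and centroid subtyping.

Three signature styles cover the annotation toolbox: a *signed* metagene
(weights +1/−1, e.g. the M2/M1 macrophage score built from a two-class
reference), plain *module means* (immune metagenes, proliferation, VEGF,
glycolysis), and *nearest-centroid* single-sample predictors that assign
each tumour to the most correlated published centroid (with an
"unclassified" outcome under a correlation floor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import collapse_probes_to_genes

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "CentroidModel",
    "build_signed_signature",
    "score_signature",
    "score_module_mean",
    "nearest_centroid_classify",
    "read_modules_gmt",
    "write_signature",
    "read_signature",
]


@dataclass
class GeneSignature:
    name: str
    genes: list
    weights: np.ndarray  # one finite nonzero weight per gene

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if not np.isfinite(self.weights).all() or (self.weights == 0).any():
            raise ValueError("weights must be finite and nonzero")


@dataclass
class CentroidModel:
    class_names: list
    centroids: pd.DataFrame  # genes x classes
    correlation_kind: str = "pearson"
    min_correlation: float = 0.1
    min_genes: int = 10

    def __post_init__(self) -> None:
        if self.centroids.empty:
            raise ValueError("centroid gene list is empty")
        if not -1 <= self.min_correlation <= 1:
            raise ValueError("min_correlation must be in [-1, 1]")
        if self.correlation_kind not in {"pearson", "spearman"}:
            raise ValueError(f"unknown correlation kind {self.correlation_kind!r}")
        self.centroids = self.centroids[self.class_names]


def _gene_level(E: pd.DataFrame, ann: pd.DataFrame | None) -> pd.DataFrame:
    """Collapse probe-level input to genes; gene-level input passes through."""
    return E if ann is None else collapse_probes_to_genes(E, ann)


def build_signed_signature(
    E_ref: pd.DataFrame,
    labels,
    retained: list,
    name: str = "M2/M1",
    up_class=None,
) -> GeneSignature:
    """Weight each retained gene +1 or −1 by its class-mean contrast.

    ``E_ref`` is a gene-collapsed two-class reference (e.g. M1 vs M2
    macrophages); a gene gets +1 when its mean in ``up_class`` (default:
    the lexically larger label, M2 for M1/M2) exceeds its mean in the other
    class, −1 when lower.  Exactly-equal means give the gene no direction
    and it is dropped with a log entry.
    """
    if len(retained) == 0:
        raise ValueError("empty retained gene list")
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"two classes required, got {classes}")
    if up_class is None:
        up_class = classes[1]
    other = classes[0] if up_class == classes[1] else classes[1]
    missing = [g for g in retained if g not in E_ref.index]
    if missing:
        raise ValueError(f"retained genes absent from reference: {missing[:10]}")
    mean_up = E_ref.loc[retained, labels == up_class].mean(axis=1)
    mean_lo = E_ref.loc[retained, labels == other].mean(axis=1)
    genes, weights = [], []
    for g in retained:
        if mean_up[g] == mean_lo[g]:
            logger.info("gene %s dropped: equal class means", g)
            continue
        genes.append(g)
        weights.append(1.0 if mean_up[g] > mean_lo[g] else -1.0)
    return GeneSignature(name=name, genes=genes, weights=np.asarray(weights))


def score_signature(
    E: pd.DataFrame, sig: GeneSignature, ann: pd.DataFrame | None = None
) -> pd.Series:
    """Weighted mean of the measured signature genes, per sample.

    score_s = (Σ_g w_g · x_{g,s}) / G over the G signature genes measured
    in ``E`` after probe collapse; unmeasured genes are dropped and the
    measured fraction logged.
    """
    G = _gene_level(E, ann)
    present = [g in G.index for g in sig.genes]
    n_meas = sum(present)
    if n_meas == 0:
        raise ValueError(f"no gene of signature {sig.name!r} measured")
    if n_meas < len(sig.genes):
        logger.info(
            "signature %s: %d/%d genes measured", sig.name, n_meas, len(sig.genes)
        )
    genes = [g for g, ok in zip(sig.genes, present) if ok]
    w = sig.weights[np.asarray(present)]
    scores = (G.loc[genes].to_numpy(dtype=float) * w[:, None]).sum(axis=0) / n_meas
    return pd.Series(scores, index=G.columns, name=sig.name)


def score_module_mean(
    E: pd.DataFrame, modules: dict, ann: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Unweighted per-module mean of gene-collapsed expression.

    ``modules`` maps module name → gene list (the seven immune metagenes,
    proliferation/VEGF/glycolysis scores, ...).  Result is modules ×
    samples.  A module with no measured gene raises, naming the module.
    """
    G = _gene_level(E, ann)
    rows = {}
    for name, genes in modules.items():
        measured = [g for g in genes if g in G.index]
        if not measured:
            raise ValueError(f"module {name!r} has no measured gene")
        if len(measured) < len(genes):
            logger.info("module %s: %d/%d genes measured", name, len(measured), len(genes))
        rows[name] = G.loc[measured].mean(axis=0)
    return pd.DataFrame(rows).T


def nearest_centroid_classify(
    E: pd.DataFrame, model: CentroidModel, ann: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Correlation-to-centroid subtype call per sample.

    Each sample is assigned the class whose centroid it correlates with
    best over the intersected gene set; a maximum correlation below
    ``model.min_correlation`` yields "unclassified".  Ties go to the class
    listed first in the model.  Returns a frame with one correlation column
    per class plus the ``label`` column.
    """
    G = _gene_level(E, ann)
    common = [g for g in model.centroids.index if g in G.index]
    if len(common) < model.min_genes:
        raise ValueError(
            f"only {len(common)} centroid genes measured "
            f"(< floor {model.min_genes})"
        )
    X = G.loc[common]
    C = model.centroids.loc[common]
    corr = pd.DataFrame(index=G.columns, columns=model.class_names, dtype=float)
    for cls in model.class_names:
        c = C[cls].to_numpy(dtype=float)
        for s in G.columns:
            x = X[s].to_numpy(dtype=float)
            if model.correlation_kind == "pearson":
                r = stats.pearsonr(x, c).statistic
            else:
                r = stats.spearmanr(x, c).statistic
            corr.loc[s, cls] = r
    # first class in model order wins ties (idxmax returns the first maximum)
    labels = corr.idxmax(axis=1)
    labels[corr.max(axis=1) < model.min_correlation] = "unclassified"
    out = corr.copy()
    out["label"] = labels
    return out


# ---------------------------------------------------------------------------
# file formats: GMT-like module lists, two-column signed signatures,
# genes x classes centroid tables

def read_modules_gmt(path) -> dict:
    """GMT-like TSV: name <tab> description <tab> gene1 <tab> gene2 ..."""
    modules = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            modules[parts[0]] = [g for g in parts[2:] if g]
    return modules


def write_signature(sig: GeneSignature, path) -> None:
    pd.DataFrame({"gene_symbol": sig.genes, "weight": sig.weights}).to_csv(
        path, sep="\t", index=False
    )


def read_signature(path, name: str | None = None) -> GeneSignature:
    df = pd.read_csv(path, sep="\t")
    return GeneSignature(
        name=name or str(path),
        genes=df["gene_symbol"].tolist(),
        weights=df["weight"].to_numpy(dtype=float),
    )


def read_centroids(path, **kwargs) -> CentroidModel:
    """Centroid TSV: first column gene symbols, header names the classes."""
    C = pd.read_csv(path, sep="\t", index_col=0)
    return CentroidModel(class_names=list(C.columns), centroids=C, **kwargs)
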