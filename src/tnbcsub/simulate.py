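"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators, fully deterministic under their seeds:

* :func:`generate_tnbc_cohort` — a 107-patient triple-negative cohort with
  three latent clusters at the study's proportions (22.4 / 44.9 / 32.7%,
  i.e. 24/48/35 patients by largest remainder), each carrying a distinct
  expression axis (luminal-AR up in cluster 1, proliferation up in
  clusters 2 > 3, immune up in cluster 3), a claudin-low-like
  subpopulation inside cluster 3 (luminal/adhesion down, EMT up),
  multi-probe genes, cluster-dependent ages and cluster-dependent
  exponential event hazards with the third cluster the most favourable.
* :func:`generate_macrophage_reference` — a two-class (M1 vs M2)
  macrophage gene-expression reference with planted differential genes of
  known direction, emulating the kind of public dataset a signed M2/M1
  signature is built from.

Expression is on the log2 scale: per-gene baselines N(8, 1), cluster
shifts of ``effect_size`` log2 units, sample noise ``noise_sd`` and a
small extra probe-level noise — magnitudes chosen to look like MAS5/log2
microarray summaries (values roughly 6–14).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .immune import DEFAULT_IMMUNE_MODULES

__all__ = [
    "CohortSpec",
    "MacrophageSpec",
    "SyntheticCohort",
    "MacrophageReference",
    "generate_tnbc_cohort",
    "generate_macrophage_reference",
    "simulate_cox_cohort",
    "largest_remainder_sizes",
    "write_fixture_set",
]


@dataclass
class CohortSpec:
    """Generative settings for the synthetic triple-negative cohort."""

    n_samples: int = 107
    cluster_proportions: tuple = (0.224, 0.449, 0.327)
    # sized so the top-5% variance filter is dominated by the planted
    # subtype axes, as on a real array where the differential probe
    # clusters sit inside the retained top-variance set
    n_background_genes: int = 4800
    luminal_block: int = 60
    proliferation_block: int = 60
    immune_genes_per_module: int = 10  # x 7 immune modules
    emt_block: int = 30
    probes_per_gene_probs: tuple = (0.7, 0.2, 0.1)  # P(1), P(2), P(3) probes
    effect_size: float = 1.5  # log2 shift of an active block
    noise_sd: float = 0.7
    probe_noise_sd: float = 0.25
    age_means: tuple = (64.6, 56.8, 51.9)
    age_sd: float = 12.0
    efs_hazards: tuple = (0.10, 0.10, 0.04)  # events / year, cluster 3 best
    os_hazard_factor: float = 0.6
    censor_hazard: float = 0.05  # independent censoring, events / year
    claudin_low_fraction_in_c3: float = 0.26
    seed: int = 0
    # the probe layout is a property of the array platform, not of the
    # cohort draw: cohorts generated with the same platform_seed share
    # probe identifiers, as two cohorts profiled on the same chip would
    platform_seed: int = 777

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if any(h <= 0 for h in self.efs_hazards):
            raise ValueError("hazards must be > 0")
        if not 0 <= self.claudin_low_fraction_in_c3 <= 1:
            raise ValueError("claudin_low_fraction_in_c3 must be in [0, 1]")
        if abs(sum(self.probes_per_gene_probs) - 1.0) > 1e-9:
            raise ValueError("probes_per_gene_probs must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("cluster_proportions", "age_means", "efs_hazards",
                    "probes_per_gene_probs"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class MacrophageSpec:
    """Generative settings for the two-class macrophage reference."""

    n_per_class: int = 10
    n_genes: int = 1000
    n_de: int = 100
    de_effect: float = 3.0  # log2 shift, ~3 sigma at the default noise
    de_direction_split: float = 0.6  # fraction of DE genes up in M2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if not 0 <= self.de_direction_split <= 1:
            raise ValueError("de_direction_split must be in [0, 1]")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # probes x samples, log2
    annotation: pd.DataFrame  # probe_id, gene_symbol
    truth: pd.Series  # planted cluster label (C1/C2/C3) per sample
    claudin_low: pd.Series  # planted claudin-low flag per sample
    clinical: pd.DataFrame  # age, efs/os times and events
    modules: dict = field(default_factory=dict)  # planted immune modules
    gene_blocks: dict = field(default_factory=dict)  # block name -> genes
    spec: CohortSpec | None = None

    def gene_expression(self) -> pd.DataFrame:
        from .expression_io import collapse_probes_to_genes

        return collapse_probes_to_genes(self.expression, self.annotation)

    def subtype_centroids(self) -> pd.DataFrame:
        """Planted-subtype centroids (gene-level class means) for SSP-style
        classification of cohorts drawn from the same process."""
        G = self.gene_expression()
        return pd.DataFrame(
            {c: G.loc[:, (self.truth == c).to_numpy()].mean(axis=1)
             for c in ("C1", "C2", "C3")}
        )


@dataclass
class MacrophageReference:
    expression: pd.DataFrame  # genes x samples, log2
    labels: pd.Series  # M1 / M2 per sample
    truth: pd.DataFrame  # planted DE genes with direction (+1 up in M2)
    spec: MacrophageSpec | None = None


def largest_remainder_sizes(proportions, total: int) -> np.ndarray:
    """Integer group sizes matching ``proportions`` as closely as possible.

    Floor each share, then hand the remaining units to the largest
    fractional parts (ties to the lowest index).  Reproduces 24/48/35 from
    (0.224, 0.449, 0.327) x 107.
    """
    raw = np.asarray(proportions, dtype=float) * total
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    short = total - int(sizes.sum())
    order = np.argsort(-remainder, kind="stable")  # ties to the lowest index
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def _probe_expand(
    gene_values: pd.DataFrame, rng: np.random.Generator, spec: CohortSpec
):
    """Expand gene-level values to probe rows with probe-level noise.

    The number of probes per gene is drawn from the platform seed so that
    every cohort on the same platform exposes identical probe ids.
    """
    platform_rng = np.random.default_rng(spec.platform_seed)
    counts = platform_rng.choice(
        [1, 2, 3], size=gene_values.shape[0], p=spec.probes_per_gene_probs
    )
    probe_ids, gene_of_probe = [], []
    for gene, c in zip(gene_values.index, counts):
        for j in range(c):
            probe_ids.append(f"{gene}_p{j + 1}")
            gene_of_probe.append(gene)
    base = gene_values.loc[gene_of_probe].to_numpy()
    noise = rng.normal(0.0, spec.probe_noise_sd, size=base.shape)
    E = pd.DataFrame(base + noise, index=probe_ids, columns=gene_values.columns)
    E.index.name = "probe_id"
    ann = pd.DataFrame({"probe_id": probe_ids, "gene_symbol": gene_of_probe})
    return E, ann


def generate_tnbc_cohort(
    spec: CohortSpec | None = None, macrophage_truth: pd.DataFrame | None = None
) -> SyntheticCohort:
    """Draw a full synthetic cohort: expression, annotation, clinical, truth.

    If ``macrophage_truth`` (from :class:`MacrophageReference`) is given,
    its planted genes are added to the cohort with their M2-up genes
    shifted up in cluster 2 (the low-immune-response analogue) and M1-up
    genes shifted up in cluster 3 — so a signed M2/M1 score computed on the
    cohort separates the clusters in the expected direction.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    sizes = largest_remainder_sizes(spec.cluster_proportions, spec.n_samples)
    labels = np.repeat(["C1", "C2", "C3"], sizes)
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    truth = pd.Series(labels, index=sample_ids, name="cluster")

    # claudin-low subpopulation inside cluster 3
    c3_idx = np.flatnonzero(labels == "C3")
    n_cl = int(round(spec.claudin_low_fraction_in_c3 * len(c3_idx)))
    cl_idx = rng.choice(c3_idx, size=n_cl, replace=False)
    claudin = pd.Series(False, index=sample_ids, name="claudin_low")
    claudin.iloc[cl_idx] = True

    # gene blocks
    blocks: dict[str, list[str]] = {
        "luminal_ar": [f"LUM{i + 1:03d}" for i in range(spec.luminal_block)],
        "proliferation": [f"PRO{i + 1:03d}" for i in range(spec.proliferation_block)],
        "emt": [f"EMT{i + 1:03d}" for i in range(spec.emt_block)],
    }
    modules = {}
    immune_genes = []
    for mod in DEFAULT_IMMUNE_MODULES:
        tag = mod.replace("-", "")
        genes = [f"IMM_{tag}_{i + 1:02d}" for i in range(spec.immune_genes_per_module)]
        modules[mod] = genes
        immune_genes.extend(genes)
    blocks["immune"] = immune_genes
    background = [f"BG{i + 1:04d}" for i in range(spec.n_background_genes)]
    genes = blocks["luminal_ar"] + blocks["proliferation"] + immune_genes + blocks["emt"]
    mac_up_c2: list[str] = []
    mac_up_c3: list[str] = []
    if macrophage_truth is not None:
        mac_up_c2 = macrophage_truth.index[macrophage_truth["direction"] > 0].tolist()
        mac_up_c3 = macrophage_truth.index[macrophage_truth["direction"] < 0].tolist()
        blocks["macrophage_m2"] = mac_up_c2
        blocks["macrophage_m1"] = mac_up_c3
        genes = genes + mac_up_c2 + mac_up_c3
    genes = genes + background

    baseline = rng.normal(8.0, 1.0, size=len(genes))
    shift = np.zeros((len(genes), spec.n_samples))
    gpos = {g: i for i, g in enumerate(genes)}
    e = spec.effect_size

    def add(block_genes, mask, amount):
        rows = [gpos[g] for g in block_genes]
        shift[np.ix_(rows, np.flatnonzero(mask))] += amount

    is_c1, is_c2, is_c3 = (labels == c for c in ("C1", "C2", "C3"))
    is_cl = claudin.to_numpy()
    add(blocks["luminal_ar"], is_c1, e)
    add(blocks["proliferation"], is_c2, e)
    add(blocks["proliferation"], is_c3, e / 2.0)
    add(blocks["immune"], is_c3, e)
    add(blocks["luminal_ar"], is_cl, -e)  # claudin-low: adhesion/luminal down
    add(blocks["emt"], is_cl, e)
    if mac_up_c2:
        add(mac_up_c2, is_c2, e)
    if mac_up_c3:
        add(mac_up_c3, is_c3, e)

    gene_values = pd.DataFrame(
        baseline[:, None] + shift + rng.normal(0.0, spec.noise_sd, size=shift.shape),
        index=genes,
        columns=sample_ids,
    )
    E, ann = _probe_expand(gene_values, rng, spec)

    # clinical table: cluster-dependent ages and exponential survival
    cluster_of = {"C1": 0, "C2": 1, "C3": 2}
    kidx = np.array([cluster_of[c] for c in labels])
    ages = rng.normal(np.asarray(spec.age_means)[kidx], spec.age_sd)
    efs_h = np.asarray(spec.efs_hazards)[kidx]
    t_event = rng.exponential(1.0 / efs_h)
    t_cens = rng.exponential(1.0 / spec.censor_hazard, size=spec.n_samples)
    efs_time = np.minimum(t_event, t_cens)
    efs_event = (t_event <= t_cens).astype(int)
    os_h = efs_h * spec.os_hazard_factor
    t_os = rng.exponential(1.0 / os_h)
    t_cens_os = rng.exponential(1.0 / spec.censor_hazard, size=spec.n_samples)
    os_time = np.minimum(t_os, t_cens_os)
    os_event = (t_os <= t_cens_os).astype(int)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": np.round(ages, 1),
            "efs_time": efs_time,
            "efs_event": efs_event,
            "os_time": os_time,
            "os_event": os_event,
        }
    ).set_index("sample_id")

    return SyntheticCohort(
        expression=E,
        annotation=ann,
        truth=truth,
        claudin_low=claudin,
        clinical=clinical,
        modules=modules,
        gene_blocks=blocks,
        spec=spec,
    )


def generate_macrophage_reference(spec: MacrophageSpec | None = None) -> MacrophageReference:
    """Draw the two-class macrophage reference with planted DE directions."""
    spec = spec or MacrophageSpec()
    rng = np.random.default_rng(spec.seed)
    genes = [f"MAC{i + 1:04d}" for i in range(spec.n_genes)]
    samples = [f"M1_{i + 1:02d}" for i in range(spec.n_per_class)] + [
        f"M2_{i + 1:02d}" for i in range(spec.n_per_class)
    ]
    labels = pd.Series(
        ["M1"] * spec.n_per_class + ["M2"] * spec.n_per_class,
        index=samples,
        name="class",
    )
    baseline = rng.normal(8.0, 1.0, size=spec.n_genes)
    X = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, len(samples)))
    n_up = int(round(spec.de_direction_split * spec.n_de))
    directions = np.array([1] * n_up + [-1] * (spec.n_de - n_up))
    m2_cols = np.arange(spec.n_per_class, 2 * spec.n_per_class)
    for gi, direction in enumerate(directions):
        X[gi, m2_cols] += direction * spec.de_effect
    E = pd.DataFrame(X, index=genes, columns=samples)
    E.index.name = "gene_symbol"
    truth = pd.DataFrame(
        {"gene_symbol": genes[: spec.n_de], "direction": directions}
    ).set_index("gene_symbol")
    return MacrophageReference(expression=E, labels=labels, truth=truth, spec=spec)


def simulate_cox_cohort(
    n: int,
    log_hr_per_sd: float,
    base_hazard: float = 0.1,
    censor_hazard: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Exponential survival with a continuous covariate of known effect.

    The covariate is standard normal, the hazard is
    ``base_hazard * exp(log_hr_per_sd * x)`` — proportional hazards by
    construction, for parameter-recovery checks of the Cox fit.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=n)
    t_event = rng.exponential(1.0 / (base_hazard * np.exp(log_hr_per_sd * x)))
    t_cens = rng.exponential(1.0 / censor_hazard, size=n)
    records = pd.DataFrame(
        {
            "time": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
        }
    )
    return records, x


def write_fixture_set(cohort: SyntheticCohort, outdir) -> dict:
    """Write the full plain-text fixture set for the pipeline.

    Expression TSV, annotation TSV, clinical CSV, planted-truth TSV, the
    immune modules as a GMT-like file and the planted-subtype centroid
    table.  Returns the path of each artefact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.tsv",
        "modules": outdir / "immune_modules.gmt",
        "centroids": outdir / "subtype_centroids.tsv",
    }
    from .expression_io import write_expression_table

    write_expression_table(cohort.expression, paths["expression"])
    cohort.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    cohort.clinical.to_csv(paths["clinical"])
    pd.DataFrame(
        {"cluster": cohort.truth, "claudin_low": cohort.claudin_low}
    ).to_csv(paths["truth"], sep="\t", index_label="sample_id")
    with open(paths["modules"], "w") as fh:
        for name, genes in cohort.modules.items():
            fh.write("\t".join([name, "planted immune module", *genes]) + "\n")
    cohort.subtype_centroids().to_csv(paths["centroids"], sep="\t", index_label="gene_symbol")
    return paths
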