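"""Survival and group-comparison statistics for cluster annotation.

Wraps the standard toolbox — Kaplan–Meier curves with logrank tests,
univariate Cox proportional-hazards fits (Efron ties, covariates scaled
per standard deviation by default), one-way ANOVA with Tukey's HSD,
Fisher's exact test (2×2 via the hypergeometric tail; r×c by exact
enumeration over tables with fixed margins) and Pearson correlation.
P-values are reported unadjusted, as is conventional for this style of
cohort annotation; Benjamini–Hochberg is available on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxFit",
    "validate_records",
    "kaplan_meier",
    "logrank_test",
    "cox_univariate",
    "group_compare",
    "fisher_exact_rxc",
    "bh_adjust",
]


@dataclass
class CoxFit:
    hazard_ratio: float
    ci95: tuple
    p_value: float
    scale: str
    log_hr: float
    converged: bool = True


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table (columns ``time`` > 0 and ``event`` in {0,1})."""
    if not {"time", "event"}.issubset(records.columns):
        raise ValueError("records need 'time' and 'event' columns")
    t = records["time"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or (t <= 0).any():
        raise ValueError("times must be finite and > 0")
    ev = records["event"].to_numpy()
    if not np.isin(ev, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return records


def kaplan_meier(records: pd.DataFrame, groups=None) -> dict:
    """Product-limit survival curve per group.

    Returns a dict mapping group label to a frame with columns ``time``,
    ``survival`` and ``at_risk``.  Subjects censored at an event time are
    counted at risk for that event (censoring handled after events at
    ties), the lifelines convention.
    """
    validate_records(records)
    if groups is None:
        groups = pd.Series("all", index=records.index)
    groups = pd.Series(groups, index=records.index)
    out = {}
    for g in groups.unique():
        sub = records.loc[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        table = kmf.event_table
        out[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": table["at_risk"].reindex(
                    kmf.survival_function_.index
                ).to_numpy(),
            }
        )
    return out


def logrank_test(records: pd.DataFrame, groups) -> dict:
    """K-sample logrank test over the pooled event times.

    Returns ``statistic`` (chi-square), ``df`` and ``p_value``.  With every
    subject censored there is no information: statistic 0, p = 1.
    """
    validate_records(records)
    groups = pd.Series(groups, index=records.index)
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    if records["event"].sum() == 0:
        return {"statistic": 0.0, "df": int(groups.nunique() - 1), "p_value": 1.0}
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return {
        "statistic": float(res.test_statistic),
        "df": int(groups.nunique() - 1),
        "p_value": float(res.p_value),
    }


def cox_univariate(
    records: pd.DataFrame, covariate, scale: str = "per_sd"
) -> CoxFit:
    """Univariate Cox proportional-hazards fit, Efron tie handling.

    ``scale='per_sd'`` standardises the covariate so the hazard ratio is
    per standard deviation — the natural scale for metagene scores;
    ``'per_unit'`` fits the covariate as given.  A monotone likelihood
    (perfect separation) is reported as a non-converged fit.
    """
    validate_records(records)
    x = np.asarray(covariate, dtype=float)
    if x.std(ddof=0) == 0:
        raise ValueError("covariate does not vary")
    if int(records["event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    if scale == "per_sd":
        x = x / x.std(ddof=1)
    elif scale != "per_unit":
        raise ValueError(f"unknown scale {scale!r}")
    df = pd.DataFrame(
        {"time": records["time"].to_numpy(), "event": records["event"].to_numpy(), "x": x}
    )
    cph = CoxPHFitter()
    converged = True
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception:
        converged = False
        return CoxFit(np.nan, (np.nan, np.nan), np.nan, scale, np.nan, converged=False)
    beta = float(cph.params_["x"])
    lo, hi = cph.confidence_intervals_.loc["x"].to_numpy(dtype=float)
    if abs(beta) > 20:  # monotone likelihood escapes lifelines' own warning
        converged = False
    return CoxFit(
        hazard_ratio=float(np.exp(beta)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p_value=float(cph.summary.loc["x", "p"]),
        scale=scale,
        log_hr=beta,
        converged=converged,
    )


def fisher_exact_rxc(table: np.ndarray) -> float:
    """Exact conditional test for an r×c contingency table.

    2×2 tables use the hypergeometric tail sum; larger tables enumerate
    every table with the observed margins and sum the probabilities of
    tables no more probable than the observed one (the standard
    generalised Fisher test; feasible for the small tables of cohort
    annotation).
    """
    T = np.asarray(table, dtype=int)
    if T.min() < 0:
        raise ValueError("counts must be non-negative")
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    if T.shape == (2, 2):
        return float(stats.fisher_exact(T).pvalue)
    row_sums = T.sum(axis=1)
    col_sums = T.sum(axis=0)
    from math import lgamma

    def log_table_prob(M: np.ndarray) -> float:
        lp = (
            sum(lgamma(r + 1) for r in row_sums)
            + sum(lgamma(c + 1) for c in col_sums)
            - lgamma(T.sum() + 1)
        )
        lp -= sum(lgamma(v + 1) for v in M.ravel())
        return lp

    obs_lp = log_table_prob(T)
    r, c = T.shape
    p_total = 0.0

    def recurse(i: int, remaining_cols: np.ndarray, rows_acc: list) -> None:
        nonlocal p_total
        if i == r - 1:
            last = remaining_cols
            if (last < 0).any():
                return
            M = np.vstack(rows_acc + [last])
            lp = log_table_prob(M)
            if lp <= obs_lp + 1e-9:
                p_total += np.exp(lp)
            return

        def fill(j: int, left: int, row_acc: list) -> None:
            if j == c - 1:
                if left <= remaining_cols[j]:
                    recurse(
                        i + 1,
                        remaining_cols - np.array(row_acc + [left]),
                        rows_acc + [np.array(row_acc + [left])],
                    )
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill(j + 1, left - v, row_acc + [v])

        fill(0, int(row_sums[i]), [])

    recurse(0, col_sums.copy(), [])
    return float(min(1.0, p_total))


def group_compare(data, kind: str) -> dict:
    """One umbrella for the annotation tests.

    ``kind='anova_tukey'``: ``data`` is a dict label → 1-D values; returns
    the overall F-test p and Tukey-adjusted pairwise p-values.
    ``kind='fisher_exact'``: ``data`` is an r×c count table.
    ``kind='pearson_cor'``: ``data`` is an (x, y) pair; returns r and the
    t-based two-sided p.
    """
    if kind == "anova_tukey":
        if len(data) < 2:
            raise ValueError("ANOVA needs at least two groups")
        arrays = {k: np.asarray(v, dtype=float) for k, v in data.items()}
        if any(len(v) < 2 for v in arrays.values()):
            raise ValueError("each group needs at least 2 values")
        f, p = stats.f_oneway(*arrays.values())
        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
        tukey = pairwise_tukeyhsd(values, labels)
        summ = pd.DataFrame(
            tukey._results_table.data[1:], columns=tukey._results_table.data[0]
        )
        pairs = {
            (row["group1"], row["group2"]): float(row["p-adj"])
            for _, row in summ.iterrows()
        }
        return {"F": float(f), "p_value": float(p), "pairwise_p": pairs}
    if kind == "fisher_exact":
        return {"p_value": fisher_exact_rxc(np.asarray(data))}
    if kind == "pearson_cor":
        x, y = (np.asarray(v, dtype=float) for v in data)
        if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
            raise ValueError("constant vector: correlation undefined")
        res = stats.pearsonr(x, y)
        return {"r": float(res.statistic), "p_value": float(res.pvalue)}
    raise ValueError(f"unknown kind {kind!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; off by default)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
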