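"""Downstream statistics for fitted subtype/stage models.

Stage correlates (Spearman + FDR), illness-duration bins, per-subtype symptom
trajectories (ANOVA across bins; covariate-adjusted between-subtype t-tests
within bins), inter-subtype morphometry contrasts (t, Cohen's d, Holm FWE),
and a generalization check of subtyping/staging on unseen data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import FitSettings, ZScoreEventModelSpec, assign, fit
from .selection import match_labels

__all__ = [
    "stage_correlates",
    "bin_duration",
    "symptom_trajectory",
    "intersubtype_morphometry",
    "generalization_check",
    "GeneralizationResult",
]

DURATION_BINS = ("early", "middle", "late")


def stage_correlates(stages: np.ndarray, measures: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho and two-sided p of stage against each measure, with
    Benjamini-Hochberg FDR across measures.  Pairs with missing values are
    dropped per measure; constant measures are reported as missing."""
    stages = np.asarray(stages, dtype=float)
    rows = {}
    for col in measures.columns:
        y = measures[col].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(stages)
        if ok.sum() < 10:
            raise ValueError(f"measure {col!r}: fewer than 10 paired observations")
        if np.ptp(y[ok]) == 0:
            rows[col] = (np.nan, np.nan)
            continue
        rho, p = stats.spearmanr(stages[ok], y[ok])
        rows[col] = (rho, p)
    out = pd.DataFrame(rows, index=["rho", "p"]).T
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


def bin_duration(
    durations: "np.ndarray | pd.Series", convention: str = "caption"
) -> pd.Categorical:
    """Early / middle / late illness-duration bins.

    ``caption`` convention (default): early <= 2 years, middle (2, 10], late
    > 10.  ``methods`` convention: early < 2, middle [2, 10], late > 10.
    """
    d = np.asarray(durations, dtype=float)
    if np.nanmin(d) < 0:
        raise ValueError("durations must be non-negative")
    if convention == "caption":
        edges = d <= 2.0, (d > 2.0) & (d <= 10.0), d > 10.0
    elif convention == "methods":
        edges = d < 2.0, (d >= 2.0) & (d <= 10.0), d > 10.0
    else:
        raise ValueError("convention must be 'caption' or 'methods'")
    labels = np.where(edges[0], "early", np.where(edges[1], "middle", "late"))
    labels = np.where(np.isnan(d), None, labels)
    return pd.Categorical(labels, categories=list(DURATION_BINS), ordered=True)


def _adjust(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, covariates]; rank deficiency (e.g. constant
    covariates) falls back to the minimum-norm solution, so zero-variance
    covariates reduce to plain centring."""
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def symptom_trajectory(
    clinical: pd.DataFrame,
    subtype_labels: np.ndarray,
    bins: pd.Categorical,
    subscales: "list[str] | None" = None,
    stage_col: str = "stage",
    min_cell: int = 3,
) -> dict:
    """Symptom course across duration bins.

    Returns ``{"anova": DataFrame, "contrasts": DataFrame}``: one-way ANOVA of
    each subscale across bins within each subtype, and per-bin two-sample
    t-tests between subtypes on residuals after regressing out age, sex and
    model stage (two-sided p, uncorrected).
    """
    labels = np.asarray(subtype_labels)
    bins = pd.Categorical(bins, categories=list(DURATION_BINS), ordered=True)
    if subscales is None:
        subscales = [c for c in clinical.columns if c.startswith("panss_")]
    covars = clinical[["age", "sex", stage_col]].to_numpy(dtype=float)

    anova_rows = []
    contrast_rows = []
    for scale in subscales:
        y_all = clinical[scale].to_numpy(dtype=float)
        for c in np.unique(labels):
            groups = []
            means = {}
            for b in DURATION_BINS:
                sel = (labels == c) & (np.asarray(bins) == b) & np.isfinite(y_all)
                if sel.sum() < min_cell:
                    warnings.warn(
                        f"{scale}: subtype {c} bin {b} has <{min_cell} subjects; ANOVA skipped"
                    )
                    groups = None
                    break
                groups.append(y_all[sel])
                means[b] = float(y_all[sel].mean())
            if groups is None:
                continue
            F, p = stats.f_oneway(*groups)
            anova_rows.append(
                {"subscale": scale, "subtype": int(c), "F": F, "p": p, **{
                    f"mean_{b}": means[b] for b in DURATION_BINS
                }}
            )
        for b in DURATION_BINS:
            sel = (np.asarray(bins) == b) & np.isfinite(y_all)
            sub = np.unique(labels[sel])
            if len(sub) < 2 or any((sel & (labels == c)).sum() < min_cell for c in sub[:2]):
                warnings.warn(f"{scale}: bin {b} lacks both subtypes; contrast skipped")
                continue
            resid = _adjust(y_all[sel], covars[sel])
            g0 = resid[labels[sel] == sub[0]]
            g1 = resid[labels[sel] == sub[1]]
            t, p = stats.ttest_ind(g0, g1)
            contrast_rows.append(
                {"subscale": scale, "bin": b, "t": t, "p": p,
                 "n_subtype1": len(g0), "n_subtype2": len(g1)}
            )
    return {
        "anova": pd.DataFrame(anova_rows),
        "contrasts": pd.DataFrame(contrast_rows),
    }


def intersubtype_morphometry(
    z_table: pd.DataFrame, subtype_labels: np.ndarray
) -> pd.DataFrame:
    """Two-sample t-test per measure between the two subtypes with Cohen's d
    (pooled SD, subtype1 - subtype2) and Holm-Bonferroni FWE adjustment."""
    labels = np.asarray(subtype_labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need two non-empty subtypes")
    a = z_table.loc[labels == groups[0]]
    b = z_table.loc[labels == groups[1]]
    rows = {}
    for col in z_table.columns:
        x, y = a[col].to_numpy(dtype=float), b[col].to_numpy(dtype=float)
        t, p = stats.ttest_ind(x, y)
        na, nb = len(x), len(y)
        sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / (na + nb - 2)
        d = (x.mean() - y.mean()) / np.sqrt(sp2) if sp2 > 0 else 0.0
        rows[col] = (x.mean(), y.mean(), t, p, d)
    out = pd.DataFrame(
        rows, index=["mean_subtype1", "mean_subtype2", "t", "p", "cohens_d"]
    ).T
    out["p_fwe"] = multipletests(out["p"], method="holm")[1]
    return out


@dataclass(frozen=True)
class GeneralizationResult:
    label_agreement: float  # fraction, after label matching
    stage_spearman: float
    stage_p: float
    n_unseen: int


def generalization_check(
    data: np.ndarray,
    train_idx: np.ndarray,
    unseen_idx: np.ndarray,
    spec: ZScoreEventModelSpec,
    K: int = 2,
    settings: FitSettings | None = None,
    seed: int = 0,
) -> GeneralizationResult:
    """Fit on a training subset and on the full data; label and stage the
    unseen subjects under both models; report matched-label agreement and the
    Spearman correlation of the two stagings."""
    X = np.asarray(data, dtype=float)
    train_idx = np.asarray(train_idx)
    unseen_idx = np.asarray(unseen_idx)
    if len(train_idx) == 0 or len(unseen_idx) == 0:
        raise ValueError("both subsets must be non-empty")
    settings = settings or FitSettings()
    sub_model = fit(X[train_idx], K, spec, settings, seed=seed)
    full_model = fit(X, K, spec, settings, seed=seed)
    a = assign(X[unseen_idx], full_model)
    b = assign(X[unseen_idx], sub_model)
    perm = match_labels(a.labels, b.labels, K)
    agreement = float(np.mean(a.labels == perm[b.labels]))
    rho, p = stats.spearmanr(a.stages, b.stages)
    return GeneralizationResult(
        label_agreement=agreement,
        stage_spearman=float(rho),
        stage_p=float(p),
        n_unseen=len(unseen_idx),
    )
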