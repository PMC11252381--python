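"""Multi-site harmonization of ROI volumes into normative z-scores.

Fixed composition order: (1) ordinary-least-squares residualization of each
ROI on sex, age, age^2, site and total intracranial volume; (2) ComBat
empirical-Bayes location/scale batch adjustment; (3) z-scoring relative to
the healthy-control distribution, multiplied by -1 so that a larger z means
more volume loss; (4) removal of subjects with any |z| above a 5-SD outlier
threshold.

The site term appears both in the regression and in ComBat, replicating the
published two-step procedure even though the steps overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import DEFAULT_ATLAS, ROIAtlas
from .simulate import feature_matrix

__all__ = [
    "CovariateDesign",
    "ZScoreTable",
    "OutlierReport",
    "residualize",
    "combat",
    "to_zscores",
    "remove_outliers",
    "harmonize_cohort",
]


@dataclass
class CovariateDesign:
    """Design matrix with intercept, sex, age, age^2, site dummies and TIV."""

    matrix: np.ndarray
    columns: list[str]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        age_col: str = "age",
        sex_col: str = "sex",
        site_col: str = "site",
        tiv_col: str = "tiv",
    ) -> "CovariateDesign":
        for col in (age_col, sex_col, site_col, tiv_col):
            if df[col].isna().any():
                raise ValueError(f"covariate {col!r} has missing values")
        site_counts = df[site_col].value_counts()
        if (site_counts < 2).any():
            small = list(site_counts.index[site_counts < 2])
            raise ValueError(f"sites with fewer than 2 subjects: {small}")
        age = df[age_col].to_numpy(dtype=float)
        cols = {
            "intercept": np.ones(len(df)),
            "sex": df[sex_col].to_numpy(dtype=float),
            "age": age,
            "age2": age**2,
            "tiv": df[tiv_col].to_numpy(dtype=float),
        }
        sites = sorted(df[site_col].astype(str).unique())
        for s in sites[1:]:  # first site is the reference level
            cols[f"site[{s}]"] = (df[site_col].astype(str) == s).to_numpy(dtype=float)
        X = np.column_stack(list(cols.values()))
        return cls(matrix=X, columns=list(cols.keys()))

    def assert_full_rank(self) -> None:
        X = self.matrix
        # centre/scale for a meaningful rank test, keeping the intercept
        scale = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        R = np.linalg.qr((X - X.mean(0)) / scale + 0.0, mode="r")
        # intercept column becomes zero after centring; ignore it
        diag = np.abs(np.diag(R))
        bad = [
            self.columns[i]
            for i in range(len(self.columns))
            if self.columns[i] != "intercept" and diag[i] < 1e-8 * max(diag.max(), 1.0)
        ]
        if bad:
            raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")


def residualize(
    volumes: pd.DataFrame,
    design: CovariateDesign,
    control_mask: np.ndarray,
    control_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI OLS residuals of volume on the covariate design.

    Coefficients are estimated on the pooled sample by default; pass
    ``control_only=True`` to estimate them on controls and apply to everyone.
    Returns (residuals, coefficients).
    """
    design.assert_full_rank()
    X = design.matrix
    Y = volumes.to_numpy(dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design and volume table have different numbers of subjects")
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_only:
        beta, *_ = np.linalg.lstsq(X[control_mask], Y[control_mask], rcond=None)
    else:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    coef = pd.DataFrame(beta, index=design.columns, columns=volumes.columns)
    return pd.DataFrame(resid, index=volumes.index, columns=volumes.columns), coef


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------


def _aprior(delta_hat_row: np.ndarray) -> float:
    m, s2 = delta_hat_row.mean(), delta_hat_row.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat_row: np.ndarray) -> float:
    m, s2 = delta_hat_row.mean(), delta_hat_row.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    z: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional posterior-mode updates for one batch's
    location (gamma*) and scale (delta^2*) across features."""
    n = z.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-30)),
            np.max(np.abs(d_new - d_old) / d_old),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat(
    residuals: pd.DataFrame,
    batch: "pd.Series | np.ndarray",
    conv: float = 1e-4,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Parametric empirical-Bayes ComBat location/scale batch adjustment.

    Per-feature standardization, per-batch additive (gamma) and multiplicative
    (delta^2) effects with normal / inverse-gamma priors whose hyperparameters
    are moment-matched, iterative conditional updates to convergence, then
    de-standardization with batch effects removed.  A single batch is returned
    unchanged; a batch with zero within-batch variance on any feature is an
    error.
    """
    batch = np.asarray(batch).astype(str)
    X = residuals.to_numpy(dtype=float)
    levels = np.unique(batch)
    if len(levels) == 1:
        return residuals.copy()
    n = X.shape[0]
    groups = [np.where(batch == g)[0] for g in levels]
    n_b = np.array([len(g) for g in groups])
    if (n_b < 2).any():
        raise ValueError("each batch needs at least 2 subjects")
    for g, idx in zip(levels, groups):
        v = X[idx].var(axis=0, ddof=1)
        if np.any(v <= 0):
            cols = list(residuals.columns[np.where(v <= 0)[0]])
            raise ValueError(f"batch {g!r} has zero within-batch variance on {cols}")

    batch_means = np.stack([X[idx].mean(axis=0) for idx in groups])  # (G, F)
    grand = (n_b / n) @ batch_means
    fitted = batch_means[np.searchsorted(levels, batch)]
    var_pooled = ((X - fitted) ** 2).mean(axis=0)
    s_data = (X - grand[None, :]) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.stack([s_data[idx].mean(axis=0) for idx in groups])
    delta_hat = np.stack([s_data[idx].var(axis=0, ddof=1) for idx in groups])
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)

    adjusted = np.empty_like(s_data)
    for i, idx in enumerate(groups):
        g_star, d_star = _it_sol(
            s_data[idx],
            gamma_hat[i],
            delta_hat[i],
            gamma_bar[i],
            t2[i],
            _aprior(delta_hat[i]),
            _bprior(delta_hat[i]),
            conv,
            max_iter,
        )
        adjusted[idx] = (s_data[idx] - g_star[None, :]) / np.sqrt(d_star)[None, :]
    out = adjusted * np.sqrt(var_pooled)[None, :] + grand[None, :]
    return pd.DataFrame(out, index=residuals.index, columns=residuals.columns)


# ---------------------------------------------------------------------------
# Normative z-scores and outlier removal
# ---------------------------------------------------------------------------


@dataclass
class ZScoreTable:
    """Subject-by-ROI normative deviations, oriented so larger = more loss."""

    values: pd.DataFrame
    control_mask: np.ndarray
    loss_oriented: bool = True

    def __post_init__(self) -> None:
        self.control_mask = np.asarray(self.control_mask, dtype=bool)
        if len(self.control_mask) != len(self.values):
            raise ValueError("control_mask length mismatch")

    @property
    def patients(self) -> pd.DataFrame:
        return self.values.loc[~self.control_mask]

    @property
    def controls(self) -> pd.DataFrame:
        return self.values.loc[self.control_mask]


@dataclass
class OutlierReport:
    removed_ids: list
    offending: dict  # id -> list of ROI names with |z| > threshold
    threshold: float

    def to_json(self, path: "str | Path | None" = None) -> str:
        payload = json.dumps(
            {
                "threshold_sd": self.threshold,
                "removed": [
                    {"subject": str(i), "rois": self.offending[i]} for i in self.removed_ids
                ],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def to_zscores(
    adjusted: pd.DataFrame,
    control_mask: np.ndarray,
    loss_direction: "int | np.ndarray" = 1,
) -> ZScoreTable:
    """Per-ROI z relative to controls, flipped so higher z = lower adjusted
    volume: z = -d * (x - control_mean) / control_sd with d = +1 when disease
    lowers the measure (the default for raw volumes)."""
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.sum() < 2:
        raise ValueError("need at least 2 controls to define the normative distribution")
    ctrl = adjusted.loc[control_mask]
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    if (sd <= 0).any():
        cols = list(sd.index[sd <= 0])
        raise ValueError(f"zero control SD for {cols}")
    d = np.broadcast_to(np.asarray(loss_direction, dtype=float), (adjusted.shape[1],))
    z = -(adjusted - mu) / sd * d
    return ZScoreTable(values=z, control_mask=control_mask, loss_oriented=True)


def remove_outliers(
    z: ZScoreTable, threshold: float = 5.0
) -> tuple[ZScoreTable, OutlierReport]:
    """Drop subjects with any regional |deviation| beyond `threshold` SDs."""
    bad = (z.values.abs() > threshold).any(axis=1)
    offending = {
        idx: list(z.values.columns[(z.values.loc[idx].abs() > threshold)])
        for idx in z.values.index[bad]
    }
    keep = ~bad.to_numpy()
    filtered = ZScoreTable(
        values=z.values.loc[~bad],
        control_mask=z.control_mask[keep],
        loss_oriented=z.loss_oriented,
    )
    report = OutlierReport(
        removed_ids=list(z.values.index[bad]), offending=offending, threshold=threshold
    )
    return filtered, report


def harmonize_cohort(
    cohort: pd.DataFrame,
    atlas: ROIAtlas = DEFAULT_ATLAS,
    control_only: bool = False,
    outlier_sd: float = 5.0,
) -> tuple[ZScoreTable, OutlierReport, pd.DataFrame]:
    """Full chain residualize -> combat -> to_zscores -> remove_outliers.

    Returns (z-score table indexed like the cohort, outlier report,
    regression coefficients)."""
    volumes = feature_matrix(cohort, atlas)
    design = CovariateDesign.from_frame(cohort)
    control_mask = (cohort["group"] == "control").to_numpy()
    resid, coef = residualize(volumes, design, control_mask, control_only=control_only)
    adjusted = combat(resid, cohort["site"])
    z = to_zscores(adjusted, control_mask, np.asarray(atlas.loss_direction))
    z.values.index = cohort.index
    z_clean, report = remove_outliers(z, threshold=outlier_sd)
    return z_clean, report, coef
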