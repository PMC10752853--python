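"""Inference chain for the speech-in-noise study.

Per-subject measures (one row each): figure-detection d', spectral-ripple
crossover (dB depth), temporal-modulation crossover (dB depth), sentence-
in-noise accuracy (proportion of words), and optionally the better-ear
low-frequency acoustic threshold (dB HL).

The chain comprises (1) a predictor collinearity screen, (2) bivariate
correlations with the outcome, (3) the multiple linear regression

    speech ~ 1 + sfg_dprime + ripple_crossover + tm_crossover

reported as normalized betas (all variables z-scored before OLS), SE, t, p,
partial correlations, R^2, adjusted R^2 and the overall F-test, and (4)
partial-residual vectors for effect visualization. Model fitting is
delegated to statsmodels OLS; the partial correlation of each predictor is
the correlation of the two residual vectors after regressing predictor and
outcome on the remaining predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr

PREDICTORS = ["sfg_dprime", "ripple_crossover_db", "tm_crossover_db"]
OUTCOME = "azbio_proportion"
ACOUSTIC = "acoustic_threshold_db_hl"
MODEL_COLUMNS = PREDICTORS + [OUTCOME]


class SingularDesignError(ValueError):
    """Raised when the regression design matrix is rank deficient."""


def _validate(table: pd.DataFrame, columns: list[str], min_n: int = 5) -> pd.DataFrame:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    sub = table[columns]
    if sub.isna().any().any():
        raise ValueError("missing values in model variables")
    if len(sub) < min_n:
        raise ValueError(f"need at least {min_n} subjects")
    for c in columns:
        if np.isclose(np.std(sub[c].to_numpy()), 0.0):
            raise ValueError(f"zero-variance column {c!r}")
    return sub


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return (x - x.mean()) / x.std(ddof=1)


def collinearity_screen(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson r and two-sided p among predictors (plus the
    acoustic threshold when present); flags nominally significant pairs."""
    cols = PREDICTORS + ([ACOUSTIC] if ACOUSTIC in table.columns else [])
    sub = _validate(table, cols)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r, p = pearsonr(sub[a], sub[b])
            rows.append({"var_a": a, "var_b": b, "r": r, "p": p, "flagged": p < alpha})
    return pd.DataFrame(rows)


def bivariate_outcome_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p of each candidate predictor vs the outcome."""
    cols = PREDICTORS + ([ACOUSTIC] if ACOUSTIC in table.columns else [])
    sub = _validate(table, cols + [OUTCOME])
    rows = []
    for c in cols:
        r, p = pearsonr(sub[c], sub[OUTCOME])
        rows.append({"predictor": c, "r": r, "p": p})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    """Table-shaped multiple regression summary."""

    predictors: tuple
    beta: np.ndarray          # normalized (standardized) coefficients
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    partial_rho: np.ndarray
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    f_p_value: float
    df_model: int
    df_resid: int
    n: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": list(self.predictors),
                "beta_normalized": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "partial_rho": self.partial_rho,
            }
        )


def adjusted_r2(r_squared: float, n: int, k: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1)."""
    return 1.0 - (1.0 - r_squared) * (n - 1) / (n - k - 1)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual of y on [1, X] by least squares."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def fit_speech_model(
    table: pd.DataFrame, predictors: list[str] | None = None
) -> RegressionResult:
    """OLS of the z-scored outcome on z-scored predictors.

    Normalized betas, their SE/t/p, partial correlations, R^2, adjusted R^2
    and the overall F-test; raises SingularDesignError on a rank-deficient
    design.
    """
    predictors = list(predictors or PREDICTORS)
    sub = _validate(table, predictors + [OUTCOME], min_n=len(predictors) + 2)
    n, k = len(sub), len(predictors)

    Xz = np.column_stack([zscore(sub[c].to_numpy()) for c in predictors])
    yz = zscore(sub[OUTCOME].to_numpy())
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xz])) < k + 1:
        raise SingularDesignError("design matrix is rank deficient")

    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    beta = fit.params[1:]
    se = fit.bse[1:]
    t = fit.tvalues[1:]
    p = fit.pvalues[1:]

    partial = np.empty(k)
    for i in range(k):
        others = np.delete(Xz, i, axis=1)
        rx = _residualize(Xz[:, i], others)
        ry = _residualize(yz, others)
        partial[i] = np.corrcoef(rx, ry)[0, 1]

    r2 = float(fit.rsquared)
    return RegressionResult(
        predictors=tuple(predictors),
        beta=np.asarray(beta),
        se=np.asarray(se),
        t=np.asarray(t),
        p=np.asarray(p),
        partial_rho=partial,
        r_squared=r2,
        adjusted_r_squared=adjusted_r2(r2, n, k),
        f_statistic=float(fit.fvalue),
        f_p_value=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=n,
    )


def partial_residual(
    table: pd.DataFrame,
    focal: str,
    predictors: list[str] | None = None,
    residualize_focal: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired vectors for an added-variable view of one predictor.

    Returns (focal axis, outcome residualized on the non-focal predictors).
    With ``residualize_focal`` the focal axis is also residualized, in which
    case the correlation of the pair equals the model's partial rho for that
    predictor.
    """
    predictors = list(predictors or PREDICTORS)
    if focal not in predictors:
        raise ValueError(f"unknown predictor {focal!r}")
    sub = _validate(table, predictors + [OUTCOME], min_n=len(predictors) + 2)
    others = [c for c in predictors if c != focal]
    X_other = np.column_stack([zscore(sub[c].to_numpy()) for c in others]) if others \
        else np.empty((len(sub), 0))
    y = zscore(sub[OUTCOME].to_numpy())
    xf = zscore(sub[focal].to_numpy())
    y_res = _residualize(y, X_other)
    x_axis = _residualize(xf, X_other) if residualize_focal else xf
    return x_axis, y_res


def plot_partial_residuals(table: pd.DataFrame, path=None):
    """One added-variable panel per predictor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(PREDICTORS), figsize=(4 * len(PREDICTORS), 3.5))
    result = fit_speech_model(table)
    for ax, pred, rho in zip(np.atleast_1d(axes), PREDICTORS, result.partial_rho):
        x, y = partial_residual(table, pred)
        ax.scatter(x, y, s=12)
        ax.set_title(f"{pred}\npartial rho = {rho:.3f}")
        ax.set_xlabel("predictor residual (z)")
        ax.set_ylabel("outcome residual (z)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
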