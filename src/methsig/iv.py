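"""Determinant-gene identification by instrumental-variable regression.

A gene's binary somatic mutation status instruments its own expression: if
mutation perturbs expression, and expression causally drives a methylation
signature's activity, then two-stage least squares (2SLS) on
(instrument = mutation, exposure = expression, outcome = activity,
covariates = cancer-type dummies) identifies the causal effect even when an
unobserved confounder links expression and activity.

The pipeline is: (1) screen genes with more than ``min_mut`` mutant samples
whose mutation status associates with the activity (Wilcoxon rank-sum,
BH FDR < 0.1); (2) per screened gene, fit 2SLS, the Wu-Hausman endogeneity
test (augmented-regression form), and the robust first-stage F
weak-instrument test; (3) BH-correct each p-value family separately and
call a gene a determinant when all three adjusted values clear the gate
(default FDR < 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._stats import bh_fdr, wilcoxon_rank_sum


def _design(n, covariates) -> np.ndarray:
    """Intercept + covariate dummies (first level alphabetically dropped)."""
    cols = [np.ones(n)]
    if covariates is not None:
        cov = pd.Series(np.asarray(covariates))
        dummies = pd.get_dummies(cov.astype("category"), drop_first=True,
                                 dtype=float)
        if dummies.shape[1]:
            cols.append(dummies.to_numpy())
    X = np.column_stack(cols) if len(cols) > 1 else cols[0][:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariate columns in the design")
    return X


def _ols(X, y):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, resid


def two_stage_least_squares(
    y, x, z, covariates=None
) -> tuple[float, float, float]:
    """2SLS estimate of the effect of exposure ``x`` on outcome ``y``.

    Stage 1 regresses x on the instrument z plus covariates; stage 2
    regresses y on the fitted exposure plus covariates.  The standard error
    uses the structural residuals (actual x, not the fitted values), the
    usual 2SLS correction.  Returns (beta_iv, se, Wald p).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    n = y.size
    if np.ptp(z) == 0:
        raise ValueError("degenerate instrument: z has no variance")
    C = _design(n, covariates)
    p2 = C.shape[1] + 1
    if n <= p2:
        raise ValueError("more parameters than observations")
    X1 = np.column_stack([C, z])
    g1, _ = _ols(X1, x)
    x_hat = X1 @ g1
    X2 = np.column_stack([x_hat, C])
    b2, _ = _ols(X2, y)
    beta_iv = float(b2[0])
    # 2SLS-corrected residuals: structural equation with the actual exposure
    resid = y - beta_iv * x - C @ b2[1:]
    sigma2 = float(resid @ resid) / (n - p2)
    XtX_inv = np.linalg.pinv(X2.T @ X2)
    se = float(np.sqrt(sigma2 * XtX_inv[0, 0]))
    tval = beta_iv / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(tval), df=n - p2))
    return beta_iv, se, p


def wu_hausman_test(y, x, z, covariates=None) -> float:
    """Endogeneity p value via the augmented (control-function) regression.

    Regress x on z + covariates, keep the residuals v; regress y on x,
    covariates and v; the t-test p of the v coefficient tests whether OLS
    and 2SLS differ (exposure endogeneity).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    n = y.size
    if np.ptp(z) == 0:
        raise ValueError("degenerate instrument: z has no variance")
    C = _design(n, covariates)
    X1 = np.column_stack([C, z])
    _, v = _ols(X1, x)
    X2 = np.column_stack([x, v, C])
    b, resid = _ols(X2, y)
    dof = n - X2.shape[1]
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X2.T @ X2)
    se_v = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    if se_v == 0:
        return 1.0
    tval = b[1] / se_v
    return float(2.0 * stats.t.sf(abs(tval), df=dof))


def weak_instrument_test(x, z, covariates=None) -> tuple[float, float]:
    """Robust first-stage F test of instrument strength.

    The Wald F for the instrument's coefficient in the regression of the
    exposure on instrument + covariates, with heteroscedasticity-robust
    (HC0) variance; with a single instrument and single exposure this is the
    standard rank-based weak-instrument statistic.  Returns (F, p).
    """
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    n = x.size
    if np.ptp(z) == 0:
        raise ValueError("degenerate instrument: z has no variance")
    C = _design(n, covariates)
    X = np.column_stack([C, z])
    b, resid = _ols(X, x)
    dof = n - X.shape[1]
    if float(resid @ resid) / max(float(x @ x), 1e-300) < 1e-24:
        return float("inf"), 0.0
    XtX_inv = np.linalg.pinv(X.T @ X)
    meat = X.T @ (X * (resid**2)[:, None])
    V = XtX_inv @ meat @ XtX_inv
    se_z = float(np.sqrt(V[-1, -1]))
    if se_z == 0:
        return float("inf"), 0.0
    F = float((b[-1] / se_z) ** 2)
    p = float(stats.f.sf(F, 1, dof))
    return F, p


def screen_mutation_association(
    activity,
    mut: pd.DataFrame,
    min_mut: int = 10,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Wilcoxon screen of mutation status vs signature activity.

    Genes with mutant count strictly greater than ``min_mut`` are tested
    (mutant vs wild-type activities, two-sided); BH correction is applied
    across the tested genes.  Returns a frame with screen_p / screen_fdr
    per tested gene and a ``selected`` flag (FDR < threshold).
    """
    act = pd.Series(activity)
    mut = mut.loc[:, act.index]
    counts = mut.sum(axis=1)
    tested = mut.index[counts > min_mut]
    if len(tested) == 0:
        import warnings

        warnings.warn(
            f"no gene has more than {min_mut} mutant samples", stacklevel=2
        )
        return pd.DataFrame(
            columns=["screen_p", "screen_fdr", "selected"]
        )
    pvals = []
    for g in tested:
        is_mut = mut.loc[g].to_numpy().astype(bool)
        _, p = wilcoxon_rank_sum(act[is_mut], act[~is_mut])
        pvals.append(p)
    fdr = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "screen_p": pvals,
            "screen_fdr": fdr,
            "selected": fdr < fdr_threshold,
        },
        index=tested,
    )


def select_determinants(
    results: pd.DataFrame, gate_fdr: float = 0.05
) -> pd.DataFrame:
    """Apply the triple BH gate to per-gene IV results.

    BH is applied separately within each p-value family (model, Wu-Hausman,
    weak instrument) across the tested genes of one signature; a gene is a
    determinant iff all three adjusted values fall below ``gate_fdr``.
    """
    out = results.copy()
    for fam in ("model", "wu_hausman", "weak"):
        out[f"fdr_{fam}"] = bh_fdr(out[f"{fam}_p"].to_numpy())
    out["determinant"] = (
        (out["fdr_wu_hausman"] < gate_fdr)
        & (out["fdr_weak"] < gate_fdr)
        & (out["fdr_model"] < gate_fdr)
    )
    return out


def run_iv_analysis(
    activity,
    mut: pd.DataFrame,
    expr: pd.DataFrame,
    covariates=None,
    signature: str = "MS1",
    min_mut: int = 10,
    screen_fdr: float = 0.1,
    gate_fdr: float = 0.05,
) -> pd.DataFrame:
    """Full determinant-gene analysis for one signature's activity.

    Screens genes by mutation-activity association, then runs 2SLS with the
    endogeneity and weak-instrument gates on the screened genes.
    """
    act = pd.Series(activity)
    screen = screen_mutation_association(
        act, mut, min_mut=min_mut, fdr_threshold=screen_fdr
    )
    genes = screen.index[screen["selected"]]
    rows = []
    for g in genes:
        z = mut.loc[g, act.index].to_numpy(float)
        x = expr.loc[g, act.index].to_numpy(float)
        y = act.to_numpy(float)
        beta_iv, se, model_p = two_stage_least_squares(y, x, z, covariates)
        wh_p = wu_hausman_test(y, x, z, covariates)
        weak_f, weak_p = weak_instrument_test(x, z, covariates)
        rows.append(
            {
                "gene": g,
                "signature": signature,
                "screen_p": screen.loc[g, "screen_p"],
                "screen_fdr": screen.loc[g, "screen_fdr"],
                "beta_iv": beta_iv,
                "se_iv": se,
                "model_p": model_p,
                "wu_hausman_p": wh_p,
                "weak_f": weak_f,
                "weak_p": weak_p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "gene", "signature", "screen_p", "screen_fdr", "beta_iv",
                "se_iv", "model_p", "wu_hausman_p", "weak_f", "weak_p",
                "fdr_model", "fdr_wu_hausman", "fdr_weak", "determinant",
            ]
        )
    table = pd.DataFrame(rows).set_index("gene")
    return select_determinants(table, gate_fdr=gate_fdr).reset_index()


class TwoStageLeastSquares(BaseEstimator, RegressorMixin):
    """Sklearn-style single-instrument 2SLS regressor.

    ``fit(X, y, instrument=z, covariates=c)`` with X the exposure (one
    column).  Fitted attributes carry the causal estimate and the two
    diagnostic tests.

    Attributes
    ----------
    coef_ : float, the 2SLS exposure coefficient.
    se_, model_p_ : Wald inference on the exposure coefficient.
    wu_hausman_p_ : endogeneity p value.
    weak_f_, weak_p_ : robust first-stage F and its p value.
    """

    def __init__(self):
        pass

    def fit(self, X, y, instrument=None, covariates=None):
        if instrument is None:
            raise ValueError("an instrument is required")
        x = np.asarray(X, float).reshape(len(y), -1)
        if x.shape[1] != 1:
            raise ValueError("exactly one exposure column is supported")
        x = x[:, 0]
        self.coef_, self.se_, self.model_p_ = two_stage_least_squares(
            y, x, instrument, covariates
        )
        self.wu_hausman_p_ = wu_hausman_test(y, x, instrument, covariates)
        self.weak_f_, self.weak_p_ = weak_instrument_test(
            x, instrument, covariates
        )
        self._covariates = covariates
        return self

    def predict(self, X):
        x = np.asarray(X, float).reshape(-1)
        return self.coef_ * x
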