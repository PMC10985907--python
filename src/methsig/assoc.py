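"""Clinical, immune and immunotherapy associations of signature activities.

Samples are dichotomized at the median activity (within the stratum the
caller passes in, typically per cancer type; ties go to the low group), and
the high/low contrast feeds Cox proportional-hazards survival models,
Wilcoxon comparisons of stage/age/response, and logistic models of ICI
response.  Immune-feature associations are summarized as per-cancer
Spearman correlations pooled into a meta-effect by inverse-variance
weighting on the Fisher-z scale.  For transcriptome-only cohorts a
gene-expression surrogate (GES) of a signature's activity is derived by
rank-correlation gene selection and a signed z-score average.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
import statsmodels.api as sm

from ._stats import bh_fdr, wilcoxon_rank_sum


def median_split(activity) -> pd.Series:
    """Label samples high/low by the median activity (ties are low)."""
    act = pd.Series(activity, dtype=float)
    if act.size < 2:
        raise ValueError("need at least 2 samples to split")
    if act.nunique() == 1:
        raise ValueError("degenerate split: activity is constant")
    med = act.median()
    return pd.Series(
        np.where(act > med, "high", "low"), index=act.index, name="group"
    )


def cox_survival(groups, os_time, os_event) -> dict:
    """Cox PH hazard ratio of the high vs low group (Breslow ties).

    Returns a dict with hr, ci_low, ci_high, p, coef.
    """
    df = pd.DataFrame(
        {
            "group": (pd.Series(groups) == "high").astype(int).to_numpy(),
            "time": np.asarray(os_time, float),
            "event": np.asarray(os_event, int),
        }
    )
    events_per_group = df.groupby("group")["event"].sum()
    if (events_per_group == 0).any() or len(events_per_group) < 2:
        raise ValueError("each group needs at least one event")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.loc["group"]
    return {
        "hr": float(s["exp(coef)"]),
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "p": float(s["p"]),
        "coef": float(s["coef"]),
    }


def group_compare(values, labels) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum between the two label groups."""
    v = pd.Series(values, dtype=float)
    lab = pd.Series(labels)
    groups = lab.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    a = v[(lab == groups[0]).to_numpy()]
    b = v[(lab == groups[1]).to_numpy()]
    return wilcoxon_rank_sum(a, b)


def _fisher_z_meta(rs, ns) -> tuple[float, float]:
    """Inverse-variance weighted mean of correlations on the Fisher-z scale.

    Weights are n - 3; returns (meta r, meta p from the pooled z test).
    """
    rs = np.asarray(rs, float)
    ns = np.asarray(ns, float)
    z = np.arctanh(np.clip(rs, -0.999999, 0.999999))
    w = ns - 3.0
    zbar = float(np.sum(w * z) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(zbar) / se))
    return float(np.tanh(zbar)), p


def time_correlation(
    activity, immune_features: pd.DataFrame, cancer_types, min_n: int = 4
) -> pd.DataFrame:
    """Per-cancer Spearman correlations with a Fisher-z meta-effect.

    For each immune feature, the Spearman correlation with activity is
    computed within each cancer type (strata with < ``min_n`` samples or a
    constant feature are excluded with a warning), combined by
    inverse-variance weighting (weights n - 3) on the Fisher-z scale, and
    BH-corrected across features.
    """
    act = pd.Series(activity, dtype=float)
    ct = pd.Series(cancer_types, index=act.index)
    rows = []
    for feat in immune_features.columns:
        vals = immune_features[feat]
        rs, ns, per = [], [], {}
        for c, idx in ct.groupby(ct).groups.items():
            if len(idx) < min_n:
                continue
            x = act.loc[idx].to_numpy()
            y = vals.loc[idx].to_numpy()
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                warnings.warn(
                    f"feature {feat!r} constant in stratum {c!r}; excluded",
                    stacklevel=2,
                )
                continue
            r = float(stats.spearmanr(x, y).statistic)
            rs.append(r)
            ns.append(len(idx))
            per[c] = r
        if not rs:
            continue
        if len(rs) == 1:
            meta_r = rs[0]
            meta_p = float(
                stats.spearmanr(
                    act.loc[ct == list(per)[0]],
                    vals.loc[ct == list(per)[0]],
                ).pvalue
            )
            flagged = True
        else:
            meta_r, meta_p = _fisher_z_meta(rs, ns)
            flagged = False
        rows.append(
            {
                "feature": feat,
                "meta_r": meta_r,
                "meta_p": meta_p,
                "n_strata": len(rs),
                "single_stratum": flagged,
                "per_stratum_r": per,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["meta_fdr"] = bh_fdr(out["meta_p"].to_numpy())
    return out


def variance_attribution(H: pd.DataFrame, cancer_types) -> pd.Series:
    """Fraction of each signature's activity variance between cancer types.

    One-way decomposition: between-group sum of squares over total sum of
    squares.  A single group yields 0.
    """
    ct = pd.Series(cancer_types, index=H.columns)
    out = {}
    for sig in H.index:
        act = H.loc[sig]
        grand = act.mean()
        total = float(((act - grand) ** 2).sum())
        if total == 0 or ct.nunique() < 2:
            out[sig] = 0.0
            continue
        between = float(
            sum(
                len(idx) * (act.loc[idx].mean() - grand) ** 2
                for _, idx in ct.groupby(ct).groups.items()
            )
        )
        out[sig] = between / total
    return pd.Series(out, name="variance_fraction")


def ici_multivariate(
    response, activity, tp53_status, foxa1_expr, model: str = "logistic"
) -> pd.DataFrame:
    """Multivariate model of ICI response on activity, TP53 and FOXA1.

    Logistic regression by IRLS (default) reporting odds ratios and Wald p
    per predictor; a linear-probability variant is available for parity
    with the Gaussian-error formulation.
    """
    resp = pd.Series(response)
    if resp.dtype == object:
        y = (resp == "responder").astype(float).to_numpy()
    else:
        y = resp.astype(float).to_numpy()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary")
    X = pd.DataFrame(
        {
            "activity": np.asarray(activity, float),
            "tp53_status": np.asarray(tp53_status, float),
            "foxa1_expr": np.asarray(foxa1_expr, float),
        }
    )
    constant = [c for c in X.columns if X[c].nunique() == 1]
    if constant:
        warnings.warn(
            f"constant predictors dropped: {constant}", stacklevel=2
        )
        X = X.drop(columns=constant)
    X = sm.add_constant(X)
    if model == "logistic":
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise ValueError(
                "logistic fit did not converge (possible separation); "
                "a penalized fit is not implemented"
            )
        est = np.exp(fit.params)
        colname = "odds_ratio"
    elif model == "linear":
        fit = sm.OLS(y, X).fit()
        est = fit.params
        colname = "coef"
    else:
        raise ValueError("model must be 'logistic' or 'linear'")
    return pd.DataFrame({colname: est, "p": fit.pvalues})


def derive_ges(
    expression: pd.DataFrame,
    activity,
    n_genes: int = 156,
    test_frac: float = 0.33,
    seed: int = 0,
) -> dict:
    """Gene-expression surrogate (GES) of a signature's activity.

    Genes are ranked by |Spearman correlation| with activity on a training
    split of cells/samples; the top ``n_genes`` are kept with their
    correlation sign.  The GES score of a cell is the mean z-scored
    expression of positively correlated genes minus that of negatively
    correlated genes.  The held-out AUC for separating high vs low activity
    (median split) is reported.

    ``expression`` is cells/samples x genes.
    """
    expr = expression
    act = pd.Series(activity, dtype=float).loc[expr.index]
    if n_genes > expr.shape[1]:
        raise ValueError(
            f"n_genes={n_genes} exceeds available genes ({expr.shape[1]})"
        )
    rng = np.random.default_rng(seed)
    n = len(expr)
    perm = rng.permutation(n)
    n_test = max(int(round(test_frac * n)), 1)
    test_idx = expr.index[perm[:n_test]]
    train_idx = expr.index[perm[n_test:]]

    X_train = expr.loc[train_idx]
    rho = X_train.apply(
        lambda col: stats.spearmanr(col, act.loc[train_idx]).statistic
    ).fillna(0.0)
    chosen = rho.abs().nlargest(n_genes).index
    weights = np.sign(rho.loc[chosen])

    mu = X_train.mean()
    sd = X_train.std(ddof=0).replace(0.0, 1.0)

    def score(frame: pd.DataFrame) -> pd.Series:
        z = (frame[chosen] - mu[chosen]) / sd[chosen]
        pos = chosen[weights.loc[chosen] > 0]
        neg = chosen[weights.loc[chosen] < 0]
        s = z[pos].mean(axis=1) if len(pos) else 0.0
        if len(neg):
            s = s - z[neg].mean(axis=1)
        return pd.Series(s, index=frame.index, name="ges_score")

    from sklearn.metrics import roc_auc_score

    test_scores = score(expr.loc[test_idx])
    high = (act.loc[test_idx] > act.loc[train_idx].median()).astype(int)
    auc = (
        float(roc_auc_score(high, test_scores))
        if high.nunique() == 2
        else float("nan")
    )
    return {
        "genes": list(chosen),
        "weights": weights,
        "score": score,
        "auc": auc,
        "threshold": float(score(expr).median()),
    }


def ges_fraction(scores, grouping, threshold: float | None = None) -> pd.Series:
    """Per-group fraction of cells with GES score above the threshold.

    Default threshold is the global median of the scores; empty groups get a
    missing fraction with a warning.
    """
    s = pd.Series(scores, dtype=float)
    g = pd.Series(grouping, index=s.index)
    if threshold is None:
        threshold = float(s.median())
    out = {}
    for grp, idx in g.groupby(g).groups.items():
        if len(idx) == 0:
            warnings.warn(f"empty group {grp!r}", stacklevel=2)
            out[grp] = np.nan
        else:
            out[grp] = float((s.loc[idx] > threshold).mean())
    return pd.Series(out, name="high_fraction")
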