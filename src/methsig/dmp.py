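"""Conserved differentially-methylated-position (DMP) calling.

Per probe, the beta value is modeled as

    beta_ij = b0 + b1*TY_i + b2*CY_ik + b3*(TY_i:CY_ik) + TO_i + e_ij

with TY the tissue type (tumor = 1), CY cancer-type dummies, TY:CY their
interaction, and TO the patient (pair) blocking factor.  In a matched design
the patient factor absorbs the CY main effects, so the fitted design is
[patient dummies | TY | TY:CY]; aliased CY columns are dropped automatically
and the test statistic is the joint F for the tissue effect (TY together
with all TY:CY columns) — a probe differential in any cancer type registers.

The null distribution comes from within-pair permutation: each round swaps
the tumor/normal roles of each pair independently with probability 1/2 and
recomputes the statistic for every probe (the same relabeling is shared
across probes, preserving inter-probe correlation).  The empirical P uses
the add-one estimator, (1 + #{perm >= obs}) / (1 + n_perm), so its minimum
is 1/(1 + n_perm) and it is never zero.

Poised DMPs pass the permutation P cutoff; conserved DMPs additionally
exceed the mirrored-percentile delta-beta magnitude threshold derived from
the opposite tail of the poised probes' pooled per-pair delta-beta values.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import BetaMatrix

#: statistic reported when the residual sum of squares underflows (perfect fit)
LARGE_STAT_SENTINEL = 1e12


@dataclass
class DeltaBetaThresholds:
    """Mirrored-percentile delta-beta cutoffs for conserved DMP calling."""

    hyper_threshold: float
    hypo_threshold: float
    percentile: float = 0.05

    def __post_init__(self) -> None:
        if not (self.hyper_threshold > 0 > self.hypo_threshold):
            raise ValueError(
                "need hyper_threshold > 0 > hypo_threshold, got "
                f"{self.hyper_threshold} / {self.hypo_threshold}"
            )


@dataclass
class ProbeModelFit:
    """Least-squares fit of the tissue-effect model for one probe."""

    coef: pd.Series
    tissue_stat: float
    tissue_effect: float
    df_resid: int


def _tissue_design(
    sheet: pd.DataFrame, ty: np.ndarray
) -> tuple[np.ndarray, list[str], int]:
    """Design matrix [patient dummies | TY | TY:CY_2..C] for given TY labels.

    Returns (X, column names, q) where q is the number of tested tissue
    columns.  CY main effects are aliased by the patient factor and omitted.
    """
    patients = pd.Categorical(sheet["patient_id"])
    P = pd.get_dummies(patients, dtype=float).to_numpy()
    names = [f"TO[{c}]" for c in patients.categories]
    cols = [P, ty[:, None].astype(float)]
    names.append("TY")
    ctypes = sorted(sheet["cancer_type"].unique())
    for c in ctypes[1:]:
        cols.append(
            (ty * (sheet["cancer_type"] == c).to_numpy())[:, None].astype(
                float
            )
        )
        names.append(f"TY:CY[{c}]")
    X = np.hstack(cols)
    q = 1 + max(len(ctypes) - 1, 0)
    return X, names, q


def _check_design(m: BetaMatrix) -> pd.DataFrame:
    sheet = m.samples
    if set(sheet["tissue_type"]) != {"tumor", "normal"}:
        raise ValueError("design must contain both tumor and normal samples")
    return sheet


def _batch_f_stats(
    Y: np.ndarray, X: np.ndarray, rss_reduced: np.ndarray, q: int
) -> np.ndarray:
    """Joint tissue-effect F statistics for all probes at once.

    Y is samples x probes; X the full design; ``rss_reduced`` the per-probe
    RSS under the patient-only model.  Uses a thin QR so each round costs one
    small factorization plus one matmul.
    """
    n = X.shape[0]
    Q, R = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-9 * max(abs(np.diag(R)).max(), 1)))
    if rank < X.shape[1]:
        raise ValueError("rank-deficient tissue design: TY columns aliased")
    total = np.einsum("ij,ij->j", Y, Y)
    proj = Q.T @ Y
    rss_full = np.maximum(total - np.einsum("ij,ij->j", proj, proj), 0.0)
    df = n - rank
    scale = np.einsum("ij,ij->j", Y, Y).max()
    tiny = max(scale, 1.0) * 1e-12
    num = np.maximum(rss_reduced - rss_full, 0.0) / q
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / (rss_full / df)
    f = np.where(rss_full <= tiny, LARGE_STAT_SENTINEL, f)
    return np.nan_to_num(f, nan=0.0)


def _reduced_rss(Y: np.ndarray, sheet: pd.DataFrame) -> np.ndarray:
    P = pd.get_dummies(pd.Categorical(sheet["patient_id"]), dtype=float)
    Qr, _ = np.linalg.qr(P.to_numpy())
    total = np.einsum("ij,ij->j", Y, Y)
    proj = Qr.T @ Y
    return np.maximum(total - np.einsum("ij,ij->j", proj, proj), 0.0)


def fit_probe_model(
    probe_values: np.ndarray, design: pd.DataFrame
) -> ProbeModelFit:
    """Fit the tissue-effect model for a single probe.

    Parameters
    ----------
    probe_values : array of per-sample beta values (design row order).
    design : sample sheet with patient_id, tissue_type, cancer_type.

    Returns the coefficient vector (patient effects, TY, TY:CY), the joint
    tissue-effect statistic (|t| of TY when a single cancer type is present,
    the joint F otherwise), the estimated tissue effect in the reference
    cancer type, and the residual degrees of freedom.
    """
    y = np.asarray(probe_values, dtype=float)
    sheet = design
    if set(sheet["tissue_type"]) != {"tumor", "normal"}:
        raise ValueError("design must contain both tissue types")
    ty = (sheet["tissue_type"] == "tumor").to_numpy().astype(float)
    X, names, q = _tissue_design(sheet, ty)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_r = _reduced_rss(y[:, None], sheet)
    f = _batch_f_stats(y[:, None], X, rss_r, q)[0]
    single_type = sheet["cancer_type"].nunique() == 1
    stat = float(np.sqrt(f)) if single_type else float(f)
    if f >= LARGE_STAT_SENTINEL:
        stat = LARGE_STAT_SENTINEL
    return ProbeModelFit(
        coef=pd.Series(coef, index=names),
        tissue_stat=stat,
        tissue_effect=float(coef[names.index("TY")]),
        df_resid=X.shape[0] - X.shape[1],
    )


def per_pair_delta_beta(m: BetaMatrix) -> pd.DataFrame:
    """Per-probe, per-pair delta beta (tumor minus matched normal)."""
    pairs = m.pairs()
    if len(pairs) == 0:
        raise ValueError("no tumor/normal pairs in the matrix")
    tum = m.values.loc[:, pairs["tumor"]].to_numpy()
    nrm = m.values.loc[:, pairs["normal"]].to_numpy()
    return pd.DataFrame(
        tum - nrm, index=m.probe_ids, columns=pairs["patient_id"]
    )


def compute_delta_beta(m: BetaMatrix) -> pd.Series:
    """Median over pairs of the per-pair delta beta, per probe."""
    return per_pair_delta_beta(m).median(axis=1).rename("median_delta_beta")


def permutation_null(
    m: BetaMatrix, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Within-pair permutation test of the tissue effect for every probe.

    Returns a DataFrame indexed by probe id with columns ``obs_stat`` and
    ``p_emp`` (add-one empirical P).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sheet = _check_design(m)
    pairs = m.pairs()  # raises on unpaired tumors
    n_pairs = len(pairs)
    Y = m.values.to_numpy(dtype=float).T  # samples x probes
    patient = sheet["patient_id"].to_numpy()
    pair_of_sample = np.array(
        [list(pairs["patient_id"]).index(p) for p in patient]
    )
    base_ty = (sheet["tissue_type"] == "tumor").to_numpy().astype(float)

    rss_r = _reduced_rss(Y, sheet)
    X, _, q = _tissue_design(sheet, base_ty)
    obs = _batch_f_stats(Y, X, rss_r, q)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(Y.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        flips = rng.random(n_pairs) < 0.5
        ty = np.where(flips[pair_of_sample], 1.0 - base_ty, base_ty)
        Xp, _, _ = _tissue_design(sheet, ty)
        perm = _batch_f_stats(Y, Xp, rss_r, q)
        exceed += perm >= obs
    p_emp = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(
        {"obs_stat": obs, "p_emp": p_emp}, index=m.probe_ids
    )


def derive_thresholds(
    per_pair_deltas_hyper: np.ndarray,
    per_pair_deltas_hypo: np.ndarray,
    percentile: float = 0.05,
) -> DeltaBetaThresholds:
    """Mirrored-percentile delta-beta thresholds from poised-DMP pools.

    The hyper threshold is the absolute value of the ``percentile`` quantile
    of the pooled per-pair delta betas of poised hyper probes (their "low
    methylation" extreme); the hypo threshold is minus the ``1 - percentile``
    quantile of the poised hypo pool.  Quantiles use linear interpolation
    between order statistics.
    """
    if not 0 < percentile < 0.5:
        raise ValueError("percentile must lie in (0, 0.5)")
    hyper_pool = np.asarray(per_pair_deltas_hyper, float).ravel()
    hypo_pool = np.asarray(per_pair_deltas_hypo, float).ravel()
    if hyper_pool.size == 0 or hypo_pool.size == 0:
        raise ValueError("delta-beta pools must be nonempty")
    q_low = float(np.quantile(hyper_pool, percentile))
    if q_low >= 0:
        warnings.warn(
            "lower quantile of the hyper pool is nonnegative; the mirrored-"
            "percentile rule degenerates (absolute value used)",
            stacklevel=2,
        )
    q_high = float(np.quantile(hypo_pool, 1.0 - percentile))
    return DeltaBetaThresholds(
        hyper_threshold=abs(q_low),
        hypo_threshold=-abs(q_high) if q_high >= 0 else q_high,
        percentile=percentile,
    )


def select_conserved(
    t: pd.DataFrame,
    thr: DeltaBetaThresholds,
    p_threshold: float = 0.001,
    n_perm: int | None = None,
) -> pd.DataFrame:
    """Flag poised and conserved DMPs.

    poised    <=> p_emp < p_threshold
    conserved <=> poised and median delta beta beyond the directional
                  threshold (strictly greater than hyper_threshold for
                  hyper, strictly below hypo_threshold for hypo).

    Probes with median delta beta exactly 0 fall on the hypo branch (<= 0
    convention) and can never be conserved.
    """
    if n_perm is not None and 1.0 / (1.0 + n_perm) >= p_threshold:
        warnings.warn(
            f"n_perm={n_perm} cannot reach p < {p_threshold}; attainable "
            f"minimum is {1.0 / (1.0 + n_perm):.3g}",
            stacklevel=2,
        )
    out = t.copy()
    mdb = out["median_delta_beta"]
    out["direction"] = np.where(mdb > 0, "hyper", "hypo")
    out["poised"] = out["p_emp"] < p_threshold
    out["conserved"] = out["poised"] & (
        ((out["direction"] == "hyper") & (mdb > thr.hyper_threshold))
        | ((out["direction"] == "hypo") & (mdb < thr.hypo_threshold))
    )
    return out


def annotate_dmp_context(
    t: pd.DataFrame, ann: pd.DataFrame, which: str = "conserved"
) -> pd.DataFrame:
    """Per-direction category fractions (island relation and region).

    Returns a tidy frame with columns direction, category_type, category,
    fraction; fractions sum to 1 within each (direction, category_type).
    An empty DMP set yields an empty frame.
    """
    sel = t[t[which]] if which in t.columns else t
    missing = sel.index.difference(ann.set_index("probe_id").index
                                   if "probe_id" in ann.columns else ann.index)
    if len(missing):
        raise ValueError(f"DMPs without annotation: {list(missing[:10])}")
    ann_idx = ann.set_index("probe_id") if "probe_id" in ann.columns else ann
    cols = ["direction", "category_type", "category", "fraction"]
    if len(sel) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for direction, grp in sel.groupby("direction"):
        sub = ann_idx.loc[grp.index]
        for cat_type in ("island_relation", "region"):
            frac = sub[cat_type].value_counts(normalize=True)
            for cat, f in frac.items():
                rows.append((direction, cat_type, cat, float(f)))
    return pd.DataFrame(rows, columns=cols)


class PairedPermutationDMP(BaseEstimator):
    """Conserved DMP caller on a paired tumor/normal beta matrix.

    Parameters
    ----------
    n_permutations : int
        Within-pair permutation rounds for the null (minimum attainable
        empirical P is 1/(1 + n_permutations)).
    p_threshold : float
        Empirical-P cutoff for the poised call.
    percentile : float
        Mirrored-percentile fraction for the delta-beta thresholds.
    threshold_pool : {"per_pair", "median"}
        Whether thresholds pool per-pair delta betas over poised probes and
        pairs (default) or use the distribution of per-probe medians.
    random_state : int
        Seed for the permutation stream.

    Attributes
    ----------
    dmp_table_ : DataFrame with obs_stat, p_emp, median_delta_beta,
        direction, poised, conserved per probe.
    thresholds_ : DeltaBetaThresholds
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        p_threshold: float = 0.001,
        percentile: float = 0.05,
        threshold_pool: str = "per_pair",
        random_state: int = 0,
    ):
        self.n_permutations = n_permutations
        self.p_threshold = p_threshold
        self.percentile = percentile
        self.threshold_pool = threshold_pool
        self.random_state = random_state

    def fit(self, m: BetaMatrix, y=None) -> "PairedPermutationDMP":
        if self.threshold_pool not in ("per_pair", "median"):
            raise ValueError("threshold_pool must be 'per_pair' or 'median'")
        table = permutation_null(
            m, n_perm=self.n_permutations, seed=self.random_state
        )
        table["median_delta_beta"] = compute_delta_beta(m)
        poised = table["p_emp"] < self.p_threshold
        hyper = poised & (table["median_delta_beta"] > 0)
        hypo = poised & (table["median_delta_beta"] <= 0)
        if hyper.sum() == 0 or hypo.sum() == 0:
            warnings.warn(
                "no poised probes in one direction; thresholds fall back to "
                "the pooled distribution of all probes",
                stacklevel=2,
            )
            hyper = table["median_delta_beta"] > 0
            hypo = ~hyper
        ppd = per_pair_delta_beta(m)
        if self.threshold_pool == "per_pair":
            pool_hyper = ppd.loc[table.index[hyper]].to_numpy().ravel()
            pool_hypo = ppd.loc[table.index[hypo]].to_numpy().ravel()
        else:
            pool_hyper = table.loc[hyper, "median_delta_beta"].to_numpy()
            pool_hypo = table.loc[hypo, "median_delta_beta"].to_numpy()
        self.thresholds_ = derive_thresholds(
            pool_hyper, pool_hypo, self.percentile
        )
        self.dmp_table_ = select_conserved(
            table,
            self.thresholds_,
            p_threshold=self.p_threshold,
            n_perm=self.n_permutations,
        )
        self.n_pairs_ = len(m.pairs())
        return self

    def conserved_probes(self, direction: str | None = None) -> pd.Index:
        """Probe ids flagged conserved, optionally restricted by direction."""
        t = self.dmp_table_
        sel = t["conserved"]
        if direction is not None:
            sel = sel & (t["direction"] == direction)
        return t.index[sel]
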